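"""Synthetic data with the statistical structure the analysis assumes.

Two generators cover the two pipeline stages. The QSAR generator draws
descriptor matrices as multivariate normals with optional equicorrelated
blocks and a sparse linear response k = intercept + X[support] @ beta +
Gaussian noise - the structure the subset-selection stage assumes. The
uptake generator produces three-dose dose-response sets (default doses
0.28, 1.0, 2.0 mM) from a known slope, intercept and homoscedastic
Gaussian noise, truncated at zero as below-quantitation readings are in
the real tables. Every generator is a pure function of its spec,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import DoseResponseSet, STANDARD_DOSES
from .descriptors import DescriptorMatrix
from .errors import SpecError


@dataclass(frozen=True)
class SyntheticQSARSpec:
    """Descriptor-matrix + sparse-linear-response generator settings."""

    n_samples: int
    n_descriptors: int
    true_support: tuple[int, ...]
    true_coefficients: tuple[float, ...]
    true_intercept: float = 0.0
    noise_sd: float = 0.1
    correlation_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_support) != len(self.true_coefficients):
            raise SpecError("support and coefficients differ in length")
        if any(not 0 <= i < self.n_descriptors for i in self.true_support):
            raise SpecError("support index out of range")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for indices, rho in self.correlation_blocks:
            if not -1 < rho < 1:
                raise SpecError(f"block correlation {rho} outside (-1, 1)")
            if any(not 0 <= i < self.n_descriptors for i in indices):
                raise SpecError("correlation block index out of range")

    def descriptor_names(self) -> list[str]:
        return [f"x{i:02d}" for i in range(self.n_descriptors)]


@dataclass(frozen=True)
class SyntheticUptakeSpec:
    """Three-dose uptake generator settings (per-replicate noise)."""

    true_slope: float
    true_intercept: float = 0.0
    noise_sd: float = 0.0
    n_replicates: int = 1
    doses: tuple[float, ...] = STANDARD_DOSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise SpecError("doses must be strictly increasing")


def _covariance(spec: SyntheticQSARSpec) -> np.ndarray:
    cov = np.eye(spec.n_descriptors)
    for indices, rho in spec.correlation_blocks:
        for i in indices:
            for j in indices:
                if i != j:
                    cov[i, j] = rho
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise SpecError("correlation blocks give a non-positive-definite covariance")
    return cov


def simulate_descriptor_matrix(spec: SyntheticQSARSpec) -> DescriptorMatrix:
    """Unit-variance multivariate-normal descriptor columns."""
    cov = _covariance(spec)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(cov)
    Z = rng.standard_normal((spec.n_samples, spec.n_descriptors))
    return DescriptorMatrix(
        compound_ids=[f"s{i:04d}" for i in range(spec.n_samples)],
        descriptor_names=spec.descriptor_names(),
        values=Z @ chol.T,
    )


def simulate_response(X: DescriptorMatrix, spec: SyntheticQSARSpec) -> np.ndarray:
    """y = intercept + X[support] @ beta + N(0, noise_sd).

    The noise stream is seeded independently of the descriptor stream so
    the same X can carry different noise realisations if specs differ
    only in seed usage downstream.
    """
    signal = spec.true_intercept + X.values[:, list(spec.true_support)] @ np.asarray(
        spec.true_coefficients
    )
    rng = np.random.default_rng(spec.seed + 1_000_003)
    return signal + spec.noise_sd * rng.standard_normal(len(X.compound_ids))


def simulate_uptake(spec: SyntheticUptakeSpec) -> list[DoseResponseSet]:
    """Replicated three-dose uptake curves, concentrations truncated at 0."""
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(spec.doses)
    sets = []
    for r in range(spec.n_replicates):
        conc = (
            spec.true_intercept
            + spec.true_slope * doses
            + spec.noise_sd * rng.standard_normal(doses.size)
        )
        conc = np.maximum(conc, 0.0)
        sets.append(
            DoseResponseSet(
                drug_id=f"sim{r:03d}",
                doses=tuple(float(d) for d in doses),
                internal_concentrations=tuple(float(c) for c in conc),
            )
        )
    return sets
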