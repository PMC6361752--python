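"""Stage 1: from instrument response to absorption slopes (k-values).

Internal concentrations are back-calculated through each drug's calibration
line, converted from ng/mL to the study's 1e-5 mM unit, and regressed on
the bath dose. The slope of that ordinary-least-squares line, fitted with
an intercept, is the drug's k-value: the larva-internal concentration
gained per mM of bath concentration. k > 5 marks readily absorbed drugs
(see :mod:`zfqsar.published`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .datasets import CalibrationCurve, DoseResponseSet, KReference
from .errors import (
    DegenerateCurveError,
    DomainError,
    InsufficientDataError,
    SingularDesignError,
    ZfqsarError,
)


@dataclass(frozen=True)
class KValueFit:
    """OLS summary of one drug's dose vs internal-concentration line.

    k (the slope) is in 1e-5 mM internal per mM bath; the intercept is in
    1e-5 mM; r_squared is the squared Pearson correlation of fitted vs
    observed values.
    """

    drug_id: str
    k: float
    intercept: float
    r_squared: float
    n_points: int


def back_calculate_concentration(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration line: concentration = (y - b) / a, in ng/mL.

    Negative results (responses below the fitted blank) are returned as-is
    with a warning so extrapolation below the calibrated range is visible;
    truncation is the caller's decision.
    """
    if curve.slope_a == 0:
        raise DegenerateCurveError(f"{curve.drug_id}: calibration slope is zero")
    conc = (response - curve.intercept_b) / curve.slope_a
    if conc < 0:
        warnings.warn(
            f"{curve.drug_id}: back-calculated concentration {conc:.4g} ng/mL "
            "is negative (response below calibration intercept)",
            stacklevel=2,
        )
    return conc


def mass_to_molar(
    conc_ng_per_ml: float, molecular_weight: float, dilution_factor: float = 1.0
) -> float:
    """Convert ng/mL to the study unit 1e-5 mM.

    1 ng/mL = 1e-6 g/L = (1e-3 / MW) mM = (100 / MW) * 1e-5 mM, so the
    result is ``conc * dilution_factor * 100 / MW``. The dilution factor
    covers any sample work-up dilution not already folded into the
    measured value; the fixtures assume 1.0.
    """
    if molecular_weight <= 0:
        raise DomainError(f"molecular weight must be positive, got {molecular_weight}")
    if dilution_factor <= 0:
        raise DomainError(f"dilution factor must be positive, got {dilution_factor}")
    return conc_ng_per_ml * dilution_factor * 100.0 / molecular_weight


def fit_dose_response(
    doses: Sequence[float], concentrations: Sequence[float], drug_id: str = ""
) -> KValueFit:
    """OLS line (with intercept) of internal concentration on bath dose.

    Returns the slope as the k-value. Zero concentrations (below-LOQ
    readings) are legitimate inputs and enter the regression unchanged.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError(
            f"{drug_id or 'input'}: {x.size} doses vs {y.size} concentrations"
        )
    if x.size < 2:
        raise InsufficientDataError(
            f"{drug_id or 'input'}: need >= 2 points, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise SingularDesignError(
            f"{drug_id or 'input'}: all doses equal; slope undefined", ("dose",)
        )
    with warnings.catch_warnings():
        # linregress warns on constant y; the slope 0 answer is what we want
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return KValueFit(
        drug_id=drug_id,
        k=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(x.size),
    )


def compute_k_table(sets: Iterable[DoseResponseSet]) -> list[KValueFit]:
    """Fit every dose-response set; errors are tagged with the drug id."""
    fits = []
    for s in sets:
        try:
            fits.append(
                fit_dose_response(s.doses, s.internal_concentrations, s.drug_id)
            )
        except ZfqsarError as exc:
            raise type(exc)(f"{s.drug_id}: {exc}") from exc
    return fits


def compare_to_reference(
    fits: Iterable[KValueFit], reference: Mapping[str, KReference]
) -> list[dict]:
    """Tabulate fitted vs published k with relative deviation and flags."""
    rows = []
    for fit in fits:
        ref = reference.get(fit.drug_id)
        rows.append(
            {
                "drug_id": fit.drug_id,
                "k": fit.k,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "k_reference": ref.k if ref else None,
                "rel_deviation": (abs(fit.k - ref.k) / abs(ref.k)) if ref else None,
                "reference_discrepant": ref.discrepant if ref else None,
            }
        )
    return rows
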