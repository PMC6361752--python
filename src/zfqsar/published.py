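"""The published five-descriptor absorption model, frozen as printed.

k = -30.23
    - 2.0167  * HBD_Count
    - 0.03463 * Jurs_WPSA_1
    + 1.6392  * Num_AliphaticSingleBonds
    + 0.72925 * Num_AromaticBonds
    + 18.652  * QED_MW

Higher aliphatic-bond and aromatic-bond counts and a more drug-like
molecular weight raise the predicted uptake; more hydrogen-bond donors
and a larger positively charged accessible surface lower it. Drugs with
k > 5 are classified as readily absorbed by zebrafish larvae.

Descriptor values computed by this package follow this package's own
conventions (see :mod:`zfqsar.descriptors`), which are not guaranteed to
match the proprietary engine the model was originally trained on;
predictions from locally computed descriptors carry a provenance warning.
"""

from __future__ import annotations

import math
import warnings
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .errors import DomainError

PUBLISHED_INTERCEPT: float = -30.23

#: Slope per descriptor, in k-value units per descriptor unit.
PUBLISHED_COEFFICIENTS: Mapping[str, float] = MappingProxyType(
    {
        "HBD_Count": -2.0167,
        "Jurs_WPSA_1": -0.03463,
        "Num_AliphaticSingleBonds": 1.6392,
        "Num_AromaticBonds": 0.72925,
        "QED_MW": 18.652,
    }
)

#: k-values strictly above this are classified as readily absorbed.
ABSORPTION_THRESHOLD: float = 5.0

READILY_ABSORBED = "readily_absorbed"
POORLY_ABSORBED = "poorly_absorbed"


class DescriptorProvenanceWarning(UserWarning):
    """Predicting from locally computed descriptors: conventions differ
    from the engine the published coefficients were trained on."""


def predict_k(descriptors: DescriptorVector | Mapping[str, float]) -> float:
    """Evaluate the frozen linear model for one compound."""
    if isinstance(descriptors, DescriptorVector):
        values = dict(zip(DESCRIPTOR_NAMES, descriptors.as_array()))
    else:
        values = {name: float(descriptors[name]) for name in DESCRIPTOR_NAMES}
    if not all(math.isfinite(v) for v in values.values()):
        raise DomainError(f"non-finite descriptor value in {values}")
    return PUBLISHED_INTERCEPT + sum(
        PUBLISHED_COEFFICIENTS[name] * values[name] for name in DESCRIPTOR_NAMES
    )


def classify_absorption(k: float) -> str:
    """Readily absorbed iff k > 5 (strict); exactly 5 is poorly absorbed."""
    if not math.isfinite(k):
        raise DomainError(f"k must be finite, got {k}")
    return READILY_ABSORBED if k > ABSORPTION_THRESHOLD else POORLY_ABSORBED


def predict_frame(
    frame: pd.DataFrame, locally_computed: bool = False
) -> pd.DataFrame:
    """Predict k and absorption class for a descriptor table.

    ``frame`` needs the five model descriptor columns; the index carries
    compound identifiers. Set ``locally_computed=True`` when the
    descriptors came from this package's own calculators to emit the
    provenance warning.
    """
    missing = [c for c in DESCRIPTOR_NAMES if c not in frame.columns]
    if missing:
        raise DomainError(f"descriptor table is missing columns {missing}")
    if locally_computed:
        warnings.warn(
            "descriptor conventions differ from the engine the published "
            "coefficients were trained on; predicted k-values are "
            "convention-sensitive",
            DescriptorProvenanceWarning,
            stacklevel=2,
        )
    X = frame[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise DomainError("non-finite descriptor values in table")
    beta = np.array([PUBLISHED_COEFFICIENTS[n] for n in DESCRIPTOR_NAMES])
    k = PUBLISHED_INTERCEPT + X @ beta
    return pd.DataFrame(
        {
            "predicted_k": k,
            "absorption": [classify_absorption(v) for v in k],
        },
        index=frame.index,
    )
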