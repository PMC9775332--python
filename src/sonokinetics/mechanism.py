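"""Transport-mechanism interpretation of fitted coefficients.

For spherical carriers such as liposomes the Korsmeyer-Peppas release
exponent ``n`` diagnoses the transport regime: Fickian diffusion and slower
regimes up to n = 0.43, anomalous transport (diffusion and polymer
relaxation of comparable magnitude) for 0.43 < n < 0.85, and super case II
transport (relaxation-limited) for n > 0.85.  The Weibull shape parameter
``b`` only describes curve geometry: exponential/parabolic for b <= 1,
sigmoid with an inflection point for b > 1.

Thresholds are applied as strict inequalities, so an exponent landing exactly
on 0.43 or 0.85 is assigned to the lower class and flagged as a boundary hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .exceptions import DomainError, EmptySelectionError

__all__ = [
    "MechanismCall",
    "KP_LOWER",
    "KP_UPPER",
    "classify_kp",
    "classify_weibull",
    "summarize_exponent_range",
    "annotate_mechanism",
]

KP_LOWER = 0.43
KP_UPPER = 0.85
WEIBULL_SHAPE_THRESHOLD = 1.0


@dataclass(frozen=True)
class MechanismCall:
    """Pure classification of one fitted coefficient."""

    model_name: str
    coefficient: str
    value: float
    label: str
    thresholds_used: tuple[float, ...]
    boundary: bool = False  # value fell exactly on a threshold


def classify_kp(n: float, geometry: str = "sphere") -> MechanismCall:
    """Classify a Korsmeyer-Peppas exponent for spherical geometry.

    Labels: ``fickian_or_below`` (n <= 0.43), ``anomalous``
    (0.43 < n < 0.85), ``super_case_II`` (n > 0.85).
    """
    if geometry != "sphere":
        raise DomainError(f"only sphere thresholds are defined, got {geometry!r}")
    if not math.isfinite(n) or n < 0:
        raise DomainError(f"release exponent must be finite and >= 0, got {n}")
    if n > KP_UPPER:
        label = "super_case_II"
    elif n > KP_LOWER:
        label = "anomalous"
    else:
        label = "fickian_or_below"
    return MechanismCall(
        model_name="korsmeyer_peppas",
        coefficient="n",
        value=float(n),
        label=label,
        thresholds_used=(KP_LOWER, KP_UPPER),
        boundary=n in (KP_LOWER, KP_UPPER),
    )


def classify_weibull(b: float) -> MechanismCall:
    """Classify a Weibull shape parameter as exponential/parabolic or sigmoid."""
    if not math.isfinite(b) or b <= 0:
        raise DomainError(f"Weibull shape must be finite and > 0, got {b}")
    label = "sigmoid" if b > WEIBULL_SHAPE_THRESHOLD else "exponential_parabolic"
    return MechanismCall(
        model_name="weibull",
        coefficient="b",
        value=float(b),
        label=label,
        thresholds_used=(WEIBULL_SHAPE_THRESHOLD,),
        boundary=b == WEIBULL_SHAPE_THRESHOLD,
    )


def summarize_exponent_range(
    study, exclude: Optional[Sequence[str]] = None
) -> tuple[float, float]:
    """Min and max Korsmeyer-Peppas exponent across a study.

    Spans every (moiety, power density, replicate) entry carrying a
    Korsmeyer-Peppas fit, after dropping the moieties listed in ``exclude``.
    Permutation-invariant by construction.
    """
    exclude = set(exclude or ())
    values = [
        entry.fit["n"]
        for entry in study.entries
        if entry.fit.model_name == "korsmeyer_peppas" and entry.moiety not in exclude
    ]
    if not values:
        raise EmptySelectionError(
            "no Korsmeyer-Peppas exponents remain after exclusion"
        )
    return (min(values), max(values))


def annotate_mechanism(results):
    """Append mechanism/shape columns to a tidy results DataFrame.

    Adds ``mechanism`` (Korsmeyer-Peppas rows, from ``coef_n``) and
    ``curve_shape`` (Weibull rows, from ``coef_b``); other rows get empty
    strings.  Returns a copy.
    """
    df = results.copy()
    mech, shape = [], []
    for _, row in df.iterrows():
        m, s = "", ""
        try:
            if row["model"] == "korsmeyer_peppas" and math.isfinite(row.get("coef_n", float("nan"))):
                m = classify_kp(float(row["coef_n"])).label
            elif row["model"] == "weibull" and math.isfinite(row.get("coef_b", float("nan"))):
                s = classify_weibull(float(row["coef_b"])).label
        except DomainError:
            pass
        mech.append(m)
        shape.append(s)
    df["mechanism"] = mech
    df["curve_shape"] = shape
    return df
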