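"""Kinetic release models for ultrasound-triggered liposomal drug delivery.

Each model is a :class:`ModelSpec` giving the cumulative fractional release
(CFR) as a function of insonation time ``t`` (seconds).  The catalog holds the
ten classical dissolution/release laws commonly applied to nanocarrier release
data (zero-order, first-order, Higuchi, Hixson-Crowell, Korsmeyer-Peppas,
Baker-Lonsdale, Weibull, Gompertz, Hopfenberg, Lu-Hagen) plus an empirical
cubic polynomial used as a physically uninterpreted benchmark.

Two models, Hixson-Crowell and Baker-Lonsdale, are fitted after a linearizing
transform of the response rather than directly in CFR space; their specs carry
the transform and the linear-in-time prediction it is regressed against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import DomainError, ParameterArityError, UnsupportedTransformError

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "list_models",
    "get_model",
    "evaluate_cfr",
    "transform_response",
    "export_registry",
]

#: Clamp applied to CFR values at or above 1 before a linearizing transform.
CLAMP_EPS = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """A fittable kinetic release model.

    Parameters
    ----------
    name
        Stable identifier used in result tables and heatmaps.
    param_names
        Ordered coefficient symbols.
    cfr_form
        ``f(params, t) -> CFR`` evaluated on a time grid in seconds.
    fit_mode
        ``"direct"`` (nonlinear least squares in CFR space) or
        ``"linearized"`` (least squares on a transformed response).
    transform
        For linearized models, maps observed CFR to the transformed response.
    transform_model
        For linearized models, ``g(params, t)`` predicting the transformed
        response (linear in ``t``).
    default_lower, default_upper, default_start
        Per-parameter fit bounds and initial guesses.
    singular_at_zero
        True if the functional form is undefined at ``t = 0`` (Gompertz,
        whose ``t**b`` term diverges for negative shape ``b``).
    """

    name: str
    param_names: tuple[str, ...]
    cfr_form: Callable[[np.ndarray, np.ndarray], np.ndarray]
    fit_mode: str = "direct"
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None
    transform_model: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    default_lower: tuple[float, ...] = ()
    default_upper: tuple[float, ...] = ()
    default_start: tuple[float, ...] = ()
    singular_at_zero: bool = False
    description: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError(f"duplicate parameter symbols in {self.name}")
        linearized = self.fit_mode == "linearized"
        has_transforms = self.transform is not None and self.transform_model is not None
        if linearized != has_transforms:
            raise ValueError(
                f"{self.name}: fit_mode='linearized' iff transform and "
                "transform_model are both defined"
            )


def _as_params(model: ModelSpec, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if p.shape != (model.n_params,):
        raise ParameterArityError(
            f"{model.name} expects {model.n_params} coefficients "
            f"({', '.join(model.param_names)}), got shape {p.shape}"
        )
    return p


# ---------------------------------------------------------------------------
# functional forms
# ---------------------------------------------------------------------------

def _zero_order(p, t):
    return p[0] * t


def _first_order(p, t):
    # Saturating exponential A*(1 - exp(-k1*t)) with fitted amplitude A.
    k1, amp = p
    return amp * (1.0 - np.exp(-k1 * t))


def _higuchi(p, t):
    return p[0] * np.sqrt(t)


def _hixson_crowell(p, t):
    # (1 - CFR)^(1/3) = 1 - k*t  =>  CFR = 1 - (1 - k*t)^3
    return 1.0 - (1.0 - p[0] * t) ** 3


def _korsmeyer_peppas(p, t):
    k, n = p
    return k * np.power(t, n)


def _bl_lhs(cfr):
    # (3/2)*(1 - (1 - CFR)^(2/3)) - CFR, monotone from 0 (CFR=0) to 1/2 (CFR=1)
    return 1.5 * (1.0 - np.power(1.0 - cfr, 2.0 / 3.0)) - cfr


def _baker_lonsdale(p, t):
    y = np.asarray(p[0] * t, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    out = np.empty_like(y)
    for i, yi in enumerate(y):
        if yi <= 0.0:
            out[i] = 0.0
        elif yi >= 0.5:
            out[i] = 1.0
        else:
            out[i] = brentq(lambda f: _bl_lhs(f) - yi, 0.0, 1.0, xtol=1e-14)
    return out[0] if scalar else out


def _weibull(p, t):
    a, b = p
    return 1.0 - np.exp(-a * np.power(t, b))


def _gompertz(p, t):
    # kg * exp(-c * t**b); with c > 0 and b < 0 this rises sigmoidally
    # (in log time) from 0 toward the plateau kg.
    kg, c, b = p
    return kg * np.exp(-c * np.power(t, b))


def _hopfenberg(p, t):
    # 1 - (1 - k*t)^b, valid while k*t < 1; saturated at 1 beyond.
    k, b = p
    kt = np.minimum(k * np.asarray(t, dtype=float), 1.0)
    return 1.0 - np.power(1.0 - kt, b)


def _lu_hagen(p, t):
    k1, k2 = p
    return k1 * k2 * t / (1.0 + k2 * t)


def _cubic(p, t):
    p1, p2, p3, p4 = p
    return ((p1 * t + p2) * t + p3) * t + p4


def _hc_transform(cfr):
    return np.power(1.0 - np.minimum(cfr, 1.0 - CLAMP_EPS), 1.0 / 3.0)


def _hc_transform_model(p, t):
    return 1.0 - p[0] * t


def _bl_transform(cfr):
    return _bl_lhs(np.minimum(cfr, 1.0 - CLAMP_EPS))


def _bl_transform_model(p, t):
    return p[0] * t


# Default bounds/starts by coefficient role.  The Hixson-Crowell slope keeps
# the wide symmetric [-100, 100] window with start 1; other rate constants use
# [0, 100] with start 0.01, exponents [0, 5] with start 0.7, and amplitude
# ratios [0, 1.5] with start 0.9.  The Gompertz shape is sign-unconstrained
# because release-like (rising) curves require b < 0 in this parameterization.
_RATE = (0.0, 100.0, 0.01)
_EXPONENT = (0.0, 5.0, 0.7)
_AMPLITUDE = (0.0, 1.5, 0.9)


def _bounds(*roles):
    lower, upper, start = zip(*roles)
    return dict(default_lower=lower, default_upper=upper, default_start=start)


_CATALOG: tuple[ModelSpec, ...] = (
    ModelSpec(
        name="zero_order",
        param_names=("k0f",),
        cfr_form=_zero_order,
        description="constant-rate release, CFR = k0f*t",
        **_bounds(_RATE),
    ),
    ModelSpec(
        name="first_order",
        param_names=("k1", "amplitude"),
        cfr_form=_first_order,
        description="concentration-dependent release, CFR = A*(1 - exp(-k1*t))",
        **_bounds(_RATE, _AMPLITUDE),
    ),
    ModelSpec(
        name="higuchi",
        param_names=("kh",),
        cfr_form=_higuchi,
        description="matrix diffusion, CFR = kh*sqrt(t)",
        **_bounds(_RATE),
    ),
    ModelSpec(
        name="hixson_crowell",
        param_names=("khc",),
        cfr_form=_hixson_crowell,
        fit_mode="linearized",
        transform=_hc_transform,
        transform_model=_hc_transform_model,
        description="shrinking-particle dissolution, (1-CFR)^(1/3) = 1 - khc*t",
        default_lower=(-100.0,),
        default_upper=(100.0,),
        default_start=(1.0,),
    ),
    ModelSpec(
        name="korsmeyer_peppas",
        param_names=("kkp", "n"),
        cfr_form=_korsmeyer_peppas,
        description="power law, CFR = kkp*t^n; n diagnoses the transport mechanism",
        **_bounds(_RATE, _EXPONENT),
    ),
    ModelSpec(
        name="baker_lonsdale",
        param_names=("kbl",),
        cfr_form=_baker_lonsdale,
        fit_mode="linearized",
        transform=_bl_transform,
        transform_model=_bl_transform_model,
        description="spherical-matrix diffusion, (3/2)*(1-(1-CFR)^(2/3)) - CFR = kbl*t",
        **_bounds(_RATE),
    ),
    ModelSpec(
        name="weibull",
        param_names=("a", "b"),
        cfr_form=_weibull,
        description="empirical, CFR = 1 - exp(-a*t^b); b sets the curve shape",
        **_bounds(_RATE, _EXPONENT),
    ),
    ModelSpec(
        name="gompertz",
        param_names=("kg", "c", "b"),
        cfr_form=_gompertz,
        singular_at_zero=True,
        description="CFR = kg*exp(-c*t^b); rising release curves need b < 0",
        default_lower=(0.0, 0.0, -5.0),
        default_upper=(1.5, 100.0, 5.0),
        default_start=(0.9, 0.01, -0.7),
    ),
    ModelSpec(
        name="hopfenberg",
        param_names=("khf", "b"),
        cfr_form=_hopfenberg,
        description="surface erosion, CFR = 1 - (1 - khf*t)^b while khf*t < 1",
        **_bounds(_RATE, _EXPONENT),
    ),
    ModelSpec(
        name="lu_hagen",
        param_names=("klh1", "klh2"),
        cfr_form=_lu_hagen,
        description="Laplace-pressure driven release, CFR = klh1*klh2*t/(1+klh2*t)",
        **_bounds(_AMPLITUDE, _RATE),
    ),
    ModelSpec(
        name="cubic",
        param_names=("p1", "p2", "p3", "p4"),
        cfr_form=_cubic,
        description="third-order polynomial benchmark without physical meaning",
        default_lower=(-np.inf,) * 4,
        default_upper=(np.inf,) * 4,
        default_start=(0.0, 0.0, 0.0, 0.0),
    ),
)

MODEL_NAMES: tuple[str, ...] = tuple(m.name for m in _CATALOG)
_BY_NAME = {m.name: m for m in _CATALOG}


def list_models() -> list[ModelSpec]:
    """Return the full model catalog in stable (tie-breaking) order."""
    return list(_CATALOG)


def get_model(name: str) -> ModelSpec:
    """Look up a catalog model by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {', '.join(MODEL_NAMES)}") from None


def evaluate_cfr(model: ModelSpec, params: Sequence[float], t) -> np.ndarray:
    """Evaluate a model's CFR on a time grid.

    Returns the raw model output without clipping; a Hopfenberg curve past its
    domain saturates at 1 by construction, all other forms are returned as-is.

    Raises
    ------
    ParameterArityError
        If ``params`` does not match the model's parameter count.
    DomainError
        If ``t`` contains negative times, or non-positive times for a model
        singular at zero.
    """
    p = _as_params(model, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError(f"{model.name}: negative times are outside the model domain")
    if model.singular_at_zero and np.any(t <= 0):
        raise DomainError(f"{model.name} is singular at t <= 0; drop those samples")
    return model.cfr_form(p, t)


def transform_response(model: ModelSpec, cfr) -> np.ndarray:
    """Apply a linearized model's response transform to observed CFR values.

    CFR values at or above 1 (possible under measurement noise) are clamped to
    ``1 - 1e-9`` so the fractional powers stay real; the fit engine counts the
    clamped samples.
    """
    if model.fit_mode != "linearized" or model.transform is None:
        raise UnsupportedTransformError(
            f"{model.name} is fitted directly and defines no response transform"
        )
    return model.transform(np.asarray(cfr, dtype=float))


def export_registry() -> pd.DataFrame:
    """Machine-readable catalog: one row per (model, coefficient).

    Columns: model, fit_mode, parameter, lower, upper, start.  Intended for
    documentation dumps (``DataFrame.to_csv``).
    """
    rows = []
    for m in _CATALOG:
        for sym, lo, hi, st in zip(
            m.param_names, m.default_lower, m.default_upper, m.default_start
        ):
            rows.append(
                {
                    "model": m.name,
                    "fit_mode": m.fit_mode,
                    "parameter": sym,
                    "lower": lo,
                    "upper": hi,
                    "start": st,
                }
            )
    return pd.DataFrame(rows)
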