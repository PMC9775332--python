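"""Model fitting and SSE scoring for release profiles.

Direct models are fitted by bounded trust-region nonlinear least squares in
CFR space.  Hixson-Crowell and Baker-Lonsdale are fitted in their linearized
response space (the transformed observation regressed on a linear-in-time
prediction), after which both the fit-space SSE and the back-transformed
CFR-space SSE are reported; the CFR-space value is the one comparable across
models.  The cubic benchmark is an ordinary least-squares solve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DataSizeError, DegenerateDesignError
from .models import ModelSpec, evaluate_cfr, list_models, transform_response
from .preprocess import ReleaseProfile

__all__ = ["FitResult", "sse", "fit_model", "fit_polynomial", "fit_all"]

_log = logging.getLogger(__name__)


def sse(y, y_hat) -> float:
    """Sum of squared errors between observations and predictions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sum((y - y_hat) ** 2))


@dataclass
class FitResult:
    """Outcome of fitting one model to one release profile.

    ``sse_fit_space`` is the residual sum of squares in the space the
    regression ran in (transformed response for linearized models, CFR
    otherwise); ``sse_cfr_space`` always scores back-transformed predictions
    against observed CFR, so it is comparable across models.  The two
    coincide for direct fits.
    """

    model_name: str
    param_names: tuple[str, ...]
    params: np.ndarray
    sse_fit_space: float
    sse_cfr_space: float
    n_points: int
    converged: bool
    clamp_count: int = 0
    n_dropped: int = 0
    message: str = ""
    options_used: dict = field(default_factory=dict)

    @property
    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(self.params, dtype=float)))

    def __getitem__(self, symbol: str) -> float:
        return self.params_dict[symbol]


def _failed_result(model: ModelSpec, n_points: int, message: str) -> FitResult:
    return FitResult(
        model_name=model.name,
        param_names=model.param_names,
        params=np.full(model.n_params, np.nan),
        sse_fit_space=np.inf,
        sse_cfr_space=np.inf,
        n_points=n_points,
        converged=False,
        message=message,
    )


def _prepare(profile: ReleaseProfile, model: ModelSpec, truncate_release):
    t = np.asarray(profile.t_us, dtype=float)
    y = np.asarray(profile.cfr, dtype=float)
    if truncate_release is not None:
        # keep the leading portion of the curve up to the first crossing of
        # the release fraction (conventional power-law practice is 60%)
        above = np.nonzero(y > truncate_release)[0]
        if above.size:
            t, y = t[: above[0]], y[: above[0]]
    n_dropped = 0
    if model.singular_at_zero:
        keep = t > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            _log.info(
                "%s: dropped %d sample(s) at t <= 0 (model singular at zero)",
                model.name,
                n_dropped,
            )
        t, y = t[keep], y[keep]
    min_pts = max(5, 2 * model.n_params)
    if t.size < min_pts:
        raise DataSizeError(
            f"{model.name} needs >= {min_pts} points, profile has {t.size}"
        )
    return t, y, n_dropped


def _multi_starts(model: ModelSpec, lower, upper, start, k: int, seed: int):
    """The documented start plus k-1 uniform draws inside finite bounds."""
    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, dtype=float)]
    lo = np.where(np.isfinite(lower), lower, -10.0)
    hi = np.where(np.isfinite(upper), upper, 10.0)
    for _ in range(k - 1):
        starts.append(rng.uniform(lo, hi))
    return starts


def fit_model(
    profile: ReleaseProfile,
    model: ModelSpec,
    lower: Optional[Sequence[float]] = None,
    upper: Optional[Sequence[float]] = None,
    start: Optional[Sequence[float]] = None,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    gtol: float = 1e-10,
    max_nfev: Optional[int] = None,
    multi_start: int = 0,
    multi_start_seed: int = 0,
    truncate_release: Optional[float] = None,
) -> FitResult:
    """Fit one kinetic model to one release profile.

    Bounds and the initial guess default to the model's catalog values.
    ``multi_start > 1`` adds seeded random restarts inside the bounds and
    keeps the best fit-space SSE — useful for the flat likelihoods of
    Gompertz and Hopfenberg, off by default.  ``truncate_release`` restricts
    the fit to the leading portion of the curve below that CFR fraction
    (e.g. 0.6 for the conventional power-law window); default is the full
    profile.

    Non-convergence is reported through ``converged=False``, never raised;
    only structural problems (too few points) raise.
    """
    if model.name == "cubic":
        return fit_polynomial(profile, truncate_release=truncate_release)

    t, y, n_dropped = _prepare(profile, model, truncate_release)
    lower = np.asarray(model.default_lower if lower is None else lower, dtype=float)
    upper = np.asarray(model.default_upper if upper is None else upper, dtype=float)
    start = np.asarray(model.default_start if start is None else start, dtype=float)

    clamp_count = 0
    if model.fit_mode == "linearized":
        clamp_count = int(np.sum(y >= 1.0))
        y_fit = transform_response(model, y)

        def residual(p):
            return model.transform_model(p, t) - y_fit

    else:
        y_fit = y

        def residual(p):
            return model.cfr_form(p, t) - y_fit

    options = {
        "lower": lower.tolist(),
        "upper": upper.tolist(),
        "start": start.tolist(),
        "multi_start": multi_start,
        "truncate_release": truncate_release,
    }

    best = None
    starts = (
        _multi_starts(model, lower, upper, start, multi_start, multi_start_seed)
        if multi_start > 1
        else [start]
    )
    message = ""
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # benign overflow in trial steps
                res = least_squares(
                    residual,
                    x0=np.clip(x0, lower, upper),
                    bounds=(lower, upper),
                    method="trf",
                    ftol=ftol,
                    xtol=xtol,
                    gtol=gtol,
                    max_nfev=max_nfev,
                )
        except Exception as exc:  # pragma: no cover - defensive
            message = str(exc)
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        out = _failed_result(model, t.size, message or "optimizer failed")
        out.options_used = options
        return out

    params = best.x
    sse_fit = float(2.0 * best.cost)
    with np.errstate(over="ignore", invalid="ignore"):
        cfr_pred = model.cfr_form(params, t)
    sse_cfr = sse(y, cfr_pred) if model.fit_mode == "linearized" else sse_fit
    return FitResult(
        model_name=model.name,
        param_names=model.param_names,
        params=params,
        sse_fit_space=sse_fit,
        sse_cfr_space=sse_cfr,
        n_points=int(t.size),
        converged=bool(best.status > 0),
        clamp_count=clamp_count,
        n_dropped=n_dropped,
        message=best.message,
        options_used=options,
    )


def fit_polynomial(
    profile: ReleaseProfile, truncate_release: Optional[float] = None
) -> FitResult:
    """Ordinary least squares for the cubic CFR polynomial.

    Coefficients are returned highest order first, ``(p1, p2, p3, p4)`` for
    ``p1*t^3 + p2*t^2 + p3*t + p4``.  The solve runs on time rescaled to
    [0, 1] for conditioning and the coefficients are mapped back.
    """
    from .models import get_model

    model = get_model("cubic")
    t = np.asarray(profile.t_us, dtype=float)
    y = np.asarray(profile.cfr, dtype=float)
    if truncate_release is not None:
        above = np.nonzero(y > truncate_release)[0]
        if above.size:
            t, y = t[: above[0]], y[: above[0]]
    if t.size < 4:
        raise DataSizeError(f"cubic fit needs >= 4 points, profile has {t.size}")

    scale = max(float(np.max(np.abs(t))), 1.0)
    u = t / scale
    design = np.vander(u, 4)  # columns u^3, u^2, u, 1
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 4:
        raise DegenerateDesignError(
            "cubic design matrix is rank deficient (duplicated or too few "
            "distinct times)"
        )
    params = coef / scale ** np.array([3.0, 2.0, 1.0, 0.0])
    residual_sse = sse(y, design @ coef)
    return FitResult(
        model_name="cubic",
        param_names=model.param_names,
        params=params,
        sse_fit_space=residual_sse,
        sse_cfr_space=residual_sse,
        n_points=int(t.size),
        converged=True,
        options_used={"truncate_release": truncate_release},
    )


def fit_all(
    profile: ReleaseProfile,
    catalog: Optional[Sequence[ModelSpec]] = None,
    options_map: Optional[dict[str, dict]] = None,
) -> list[FitResult]:
    """Fit every catalog model to a profile; one result per model.

    Per-model failures (too few points, optimizer breakdown) are recorded in
    flagged results rather than raised, so a study over many runs never
    aborts on one bad cell.  ``options_map`` overrides ``fit_model`` keyword
    arguments per model name.
    """
    catalog = list(list_models() if catalog is None else catalog)
    options_map = options_map or {}
    results = []
    for model in catalog:
        opts = options_map.get(model.name, {})
        try:
            results.append(fit_model(profile, model, **opts))
        except Exception as exc:
            results.append(_failed_result(model, profile.n_points, str(exc)))
    return results
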