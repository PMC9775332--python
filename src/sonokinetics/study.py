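"""Study-level aggregation: replicate statistics, log10-SSE heatmaps, and
best-model selection across a moiety x power-density x replicate grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SonokineticsError
from .fitting import FitResult
from .models import MODEL_NAMES, get_model

__all__ = ["StudyEntry", "StudyTable", "heatmap_matrix", "best_model", "replicate_summary", "render_heatmap"]

#: Floor applied to log10 of an SSE cell that is exactly zero.
LOG10_FLOOR = float(np.log10(np.finfo(float).eps))


@dataclass(frozen=True)
class StudyEntry:
    """One fitted model on one replicate run."""

    moiety: str
    frequency: float  # kHz
    power_density: float  # mW/cm^2
    replicate: int
    fit: FitResult

    @property
    def key(self) -> tuple:
        return (self.moiety, self.frequency, self.power_density, self.replicate, self.fit.model_name)


@dataclass
class StudyTable:
    """Collection of per-replicate fits for a whole release study."""

    entries: list[StudyEntry] = field(default_factory=list)
    design: dict = field(default_factory=dict)  # e.g. expected replicate counts

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (moiety, frequency, power, replicate, model) keys")

    def add(self, entry: StudyEntry) -> None:
        if any(entry.key == e.key for e in self.entries):
            raise ValueError(f"duplicate study key {entry.key}")
        self.entries.append(entry)

    @property
    def moieties(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.moiety, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (run, model), coefficients as coef_* columns."""
        rows = []
        for e in self.entries:
            row = {
                "moiety": e.moiety,
                "frequency": e.frequency,
                "power_density": e.power_density,
                "replicate": e.replicate,
                "model": e.fit.model_name,
                "sse_fit_space": e.fit.sse_fit_space,
                "sse_cfr_space": e.fit.sse_cfr_space,
                "n_points": e.fit.n_points,
                "converged": e.fit.converged,
                "clamp_count": e.fit.clamp_count,
            }
            for sym, val in e.fit.params_dict.items():
                row[f"coef_{sym}"] = val
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_coefficients(
        cls,
        coefficients: pd.DataFrame,
        model_name: str = "korsmeyer_peppas",
        frequency: float = 20.0,
    ) -> "StudyTable":
        """Wrap a published coefficient table (columns moiety, power_density,
        a, b) as a study of coefficient-only entries with undefined SSE."""
        model = get_model(model_name)
        entries = []
        for _, row in coefficients.iterrows():
            fit = FitResult(
                model_name=model.name,
                param_names=model.param_names,
                params=np.array([row["a"], row["b"]], dtype=float),
                sse_fit_space=np.nan,
                sse_cfr_space=np.nan,
                n_points=0,
                converged=True,
                message="imported coefficients",
            )
            entries.append(
                StudyEntry(
                    moiety=str(row["moiety"]),
                    frequency=frequency,
                    power_density=float(row["power_density"]),
                    replicate=0,
                    fit=fit,
                )
            )
        return cls(entries=entries)


def _sse_column(sse_space: str) -> str:
    if sse_space not in ("cfr", "fit"):
        raise ValueError("sse_space must be 'cfr' or 'fit'")
    return f"sse_{sse_space}_space"


def _select(study: StudyTable, frequency, power_density) -> list[StudyEntry]:
    return [
        e
        for e in study.entries
        if (frequency is None or e.frequency == frequency)
        and (power_density is None or e.power_density == power_density)
    ]


def heatmap_matrix(
    study: StudyTable,
    frequency: Optional[float] = None,
    power_density: Optional[float] = None,
    sse_space: str = "cfr",
    cell_stat: str = "mean-then-log",
) -> pd.DataFrame:
    """log10-SSE matrix with moiety rows and model columns (lower = better).

    The default cell statistic is log10 of the arithmetic mean SSE over
    replicates; ``cell_stat="log-then-mean"`` averages log10(SSE) instead.
    A cell whose SSE is exactly zero is floored at log10(machine epsilon)
    with a warning.
    """
    entries = _select(study, frequency, power_density)
    if not entries:
        raise SonokineticsError("no study entries match the requested slice")
    col = _sse_column(sse_space)
    df = StudyTable(entries=entries).to_frame()
    models_present = [m for m in MODEL_NAMES if m in set(df["model"])]
    models_present += [m for m in df["model"].unique() if m not in models_present]
    moieties = list(dict.fromkeys(df["moiety"]))

    out = pd.DataFrame(index=moieties, columns=models_present, dtype=float)
    for moiety in moieties:
        for model in models_present:
            cell = df[(df["moiety"] == moiety) & (df["model"] == model)][col]
            if cell.empty:
                warnings.warn(f"no replicates for ({moiety}, {model})", stacklevel=2)
                continue
            if cell_stat == "mean-then-log":
                mean_sse = float(cell.mean())
                if mean_sse == 0.0:
                    warnings.warn(
                        f"SSE exactly zero for ({moiety}, {model}); flooring cell",
                        stacklevel=2,
                    )
                    out.loc[moiety, model] = LOG10_FLOOR
                else:
                    out.loc[moiety, model] = np.log10(mean_sse)
            elif cell_stat == "log-then-mean":
                vals = np.maximum(cell.to_numpy(), np.finfo(float).eps)
                out.loc[moiety, model] = float(np.mean(np.log10(vals)))
            else:
                raise ValueError("cell_stat must be 'mean-then-log' or 'log-then-mean'")
    out.index.name = "moiety"
    return out


def best_model(
    study: StudyTable,
    moiety: str,
    frequency: Optional[float] = None,
    power_density: Optional[float] = None,
    include_polynomial: bool = False,
    sse_space: str = "cfr",
) -> str:
    """Model with minimal replicate-mean SSE for one moiety/condition cell.

    ``include_polynomial=False`` restricts the choice to the physically
    interpretable models (the cubic benchmark fits best almost by
    construction but carries no mechanism).  Ties break toward fewer
    parameters, then catalog order.
    """
    entries = [
        e for e in _select(study, frequency, power_density) if e.moiety == moiety
    ]
    if not include_polynomial:
        entries = [e for e in entries if e.fit.model_name != "cubic"]
    if not entries:
        raise SonokineticsError(f"no fits for moiety {moiety!r} in this slice")
    col = _sse_column(sse_space)
    df = StudyTable(entries=entries).to_frame()
    means = df.groupby("model")[col].mean()

    def rank(name: str):
        order = MODEL_NAMES.index(name) if name in MODEL_NAMES else len(MODEL_NAMES)
        try:
            n_par = get_model(name).n_params
        except KeyError:
            n_par = np.inf
        return (means[name], n_par, order)

    return min(means.index, key=rank)


def replicate_summary(
    study: StudyTable,
    by: Sequence[str] = ("moiety", "power_density", "model"),
) -> pd.DataFrame:
    """Descriptive statistics (mean/SD/min/max) of SSE and coefficients.

    The grouping must include ``"model"``: averaging coefficients across
    different models is meaningless and is refused.  Groups with no entries
    are simply absent from the output.
    """
    if "model" not in by:
        raise SonokineticsError(
            "replicate_summary refuses to aggregate coefficients across "
            "models; include 'model' in the grouping"
        )
    df = study.to_frame()
    value_cols = ["sse_fit_space", "sse_cfr_space"] + [
        c for c in df.columns if c.startswith("coef_")
    ]
    agg = df.groupby(list(by))[value_cols].agg(["mean", "std", "min", "max"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()


def render_heatmap(matrix: pd.DataFrame, png_path, csv_path=None, title: str = ""):
    """Render a log10-SSE matrix as a blue-to-red heatmap PNG (blue = better
    fit); optionally dump the matrix itself as CSV (the testable artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if csv_path is not None:
        matrix.to_csv(csv_path)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.8 * matrix.shape[1], 1.0 + 0.5 * matrix.shape[0])
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap="coolwarm", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    fig.colorbar(im, ax=ax, label="log10(SSE)")
    if title:
        ax.set_title(title)
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
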