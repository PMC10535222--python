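"""Local-vs-systemic BE discordance classification and heatmaps.

A formulation that is bioequivalent in plasma need not be bioequivalent at
the site of action inside the gut.  Each (formulation, gut site, metric) cell
is classified from the pair of plasma and local decisions:

    plasma BE,  local BE  -> true_positive   (plasma verdict transfers)
    plasma NBE, local NBE -> true_negative
    plasma BE,  local NBE -> false_positive  (substandard product passes PK BE)
    plasma NBE, local BE  -> false_negative  (usable product rejected)

The heatmap rows are formulations (ordered by dissolution similarity f2, pH
variants last), columns are plasma plus the eight gut segments; every cell
carries its category and the incidence of BE across trials.  All semantics
live in the exported CSV — the rendered figure encodes local NBE as hatching
so no information exists only in styling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .pbpk_core import GUT_SEGMENTS

__all__ = [
    "HeatmapCell",
    "classify_discordance",
    "combine_metrics",
    "build_heatmap",
    "heatmap_cells",
    "write_heatmap_csv",
    "read_heatmap_csv",
    "CATEGORIES",
]

CATEGORIES = ("true_positive", "true_negative", "false_positive", "false_negative")

_CELL_COLORS = {
    "true_positive": "#2e8b57",   # flat green
    "true_negative": "#a8d5a2",   # light green
    "false_positive": "#c23b22",  # red
    "false_negative": "#f4a6b8",  # pink
}


def classify_discordance(plasma_be: bool, local_be: bool) -> str:
    """Concordance category of a (plasma, local) BE decision pair."""
    if plasma_be and local_be:
        return "true_positive"
    if not plasma_be and not local_be:
        return "true_negative"
    if plasma_be and not local_be:
        return "false_positive"
    return "false_negative"


def combine_metrics(auc_be: bool, cmax_be: bool) -> bool:
    """Combined BE verdict: BE only when both AUC and C_max conclude BE."""
    return bool(auc_be and cmax_be)


@dataclass(frozen=True)
class HeatmapCell:
    """One heatmap cell: a formulation x gut-site x metric decision pair."""

    formulation: str
    site: str
    metric: str
    layer: str
    plasma_be: bool
    local_be: bool
    incidence: float
    f2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError("incidence must be in [0, 1]")

    @property
    def category(self) -> str:
        return classify_discordance(self.plasma_be, self.local_be)


def heatmap_cells(
    decisions: pd.DataFrame,
    layer: str = "enterocyte",
    metric: str = "combined",
) -> list[HeatmapCell]:
    """Build cells from a stacked decision table.

    ``decisions`` needs columns formulation, site, layer, metric, be,
    incidence (one row per decision; plasma rows use layer 'plasma') and
    optionally f2.  Raises if any formulation is missing the plasma decision
    or any of the eight gut segments for the requested layer/metric.
    """
    required = {"formulation", "site", "layer", "metric", "be", "incidence"}
    if not required.issubset(decisions.columns):
        raise ValueError(f"decision table must have columns {sorted(required)}")
    cells = []
    for form, grp in decisions.groupby("formulation", sort=False):
        sel = grp[grp["metric"] == metric]
        plasma = sel[sel["site"] == "plasma"]
        if plasma.empty:
            raise ValueError(f"{form}: missing plasma decision for metric {metric!r}")
        plasma_be = bool(plasma["be"].iloc[0])
        f2 = grp["f2"].iloc[0] if "f2" in grp.columns else None
        local = sel[(sel["layer"] == layer)]
        missing = set(GUT_SEGMENTS) - set(local["site"])
        if missing:
            raise ValueError(f"{form}: missing decisions for sites {sorted(missing)}")
        for seg in GUT_SEGMENTS:
            row = local[local["site"] == seg].iloc[0]
            cells.append(HeatmapCell(
                formulation=form, site=seg, metric=metric, layer=layer,
                plasma_be=plasma_be, local_be=bool(row["be"]),
                incidence=float(row["incidence"]),
                f2=None if f2 is None or pd.isna(f2) else float(f2),
            ))
    return cells


def _cells_frame(cells: Sequence[HeatmapCell]) -> pd.DataFrame:
    return pd.DataFrame([
        {"formulation": c.formulation, "f2": c.f2, "site": c.site, "layer": c.layer,
         "metric": c.metric, "plasma_be": c.plasma_be, "local_be": c.local_be,
         "category": c.category, "incidence": c.incidence}
        for c in cells
    ])


def _row_order(df: pd.DataFrame) -> list[str]:
    # descending f2 (most similar first); trigger-pH variants (no f2) last
    meta = df[["formulation", "f2"]].drop_duplicates("formulation")
    with_f2 = meta.dropna(subset=["f2"]).sort_values("f2", ascending=False)
    without = meta[meta["f2"].isna()]
    return [*with_f2["formulation"], *without["formulation"]]


def build_heatmap(
    decisions: pd.DataFrame,
    layer: str = "enterocyte",
    metric: str = "combined",
    csv_path=None,
    figure_path=None,
):
    """Heatmap table + rendered figure for one layer and metric.

    Returns ``(cells_df, figure)``.  Cell colour encodes the concordance
    category, hatching marks local NBE, and the printed percentage is the
    BE incidence across trials.  Optionally writes the lossless CSV and the
    figure file.
    """
    cells = heatmap_cells(decisions, layer=layer, metric=metric)
    df = _cells_frame(cells)
    order = _row_order(df)
    n_rows, n_cols = len(order), len(GUT_SEGMENTS)

    fig, ax = plt.subplots(figsize=(1.3 * n_cols + 2, 0.6 * n_rows + 1.5))
    for r, form in enumerate(order):
        sub = df[df["formulation"] == form].set_index("site")
        for ccol, seg in enumerate(GUT_SEGMENTS):
            cell = sub.loc[seg]
            hatch = "" if cell["local_be"] else "///"
            ax.add_patch(plt.Rectangle(
                (ccol, n_rows - 1 - r), 1, 1,
                facecolor=_CELL_COLORS[cell["category"]],
                hatch=hatch, edgecolor="white",
            ))
            ax.text(ccol + 0.5, n_rows - 1 - r + 0.5, f"{cell['incidence']:.0%}",
                    ha="center", va="center", fontsize=8, color="black")
    ax.set_xlim(0, n_cols)
    ax.set_ylim(0, n_rows)
    ax.set_xticks(np.arange(n_cols) + 0.5, GUT_SEGMENTS, rotation=30, ha="right")
    plasma_flags = {
        form: "Y" if df[df["formulation"] == form]["plasma_be"].iloc[0] else "N"
        for form in order
    }
    ax.set_yticks(np.arange(n_rows) + 0.5,
                  [f"{f} [plasma {plasma_flags[f]}]" for f in reversed(order)])
    ax.set_title(f"Local vs systemic BE — {layer} layer, {metric}")
    ax.legend(handles=[Patch(facecolor=v, label=k) for k, v in _CELL_COLORS.items()],
              loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=8)
    fig.tight_layout()

    if csv_path is not None:
        write_heatmap_csv(csv_path, df)
    if figure_path is not None:
        fig.savefig(figure_path, dpi=150)
    return df, fig


_CSV_COLS = ["formulation", "f2", "site", "layer", "metric",
             "plasma_be", "local_be", "category", "incidence"]


def write_heatmap_csv(path, cells_df: pd.DataFrame) -> None:
    cells_df.to_csv(path, index=False, columns=_CSV_COLS)


def read_heatmap_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"heatmap CSV missing columns {sorted(missing)}")
    return df
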