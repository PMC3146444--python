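"""Admixture-bin calibration and hybrid-class assignment.

Individuals are assigned to hybrid categories by where their posterior-mean
*elegans* ancestry q falls among named intervals calibrated on simulated
crosses. The default bins follow the conservative assignment groups defined
from the artificial-hybrid panels: pure *elegans* (q ≥ 0.90), *elegans*
backcrosses (0.68–0.89), a mixed F1/F2/backcross group (0.21–0.67),
*graellsii* backcrosses (0.11–0.20) and pure *graellsii* (q ≤ 0.10). The
published integer-percent bounds leave gaps between bins (e.g. 0.89 vs
0.90); boundaries are placed at the gap midpoints so the bins partition
[0, 1], and the exact cut points are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hybrids import CrossType

__all__ = ["AdmixtureBins", "classify_q", "summarize_assignments", "calibrate_bins"]

DEFAULT_BIN_LABELS = (
    "pure_graellsii",
    "graellsii_backcross",
    "mixed_F1_F2_BC",
    "elegans_backcross",
    "pure_elegans",
)


@dataclass(frozen=True)
class AdmixtureBins:
    """Ordered partition of [0, 1] into named ancestry intervals.

    ``cuts`` are the interior boundaries; interval i is
    [cut_{i-1}, cut_i) except the last, which is closed at 1. With the
    default cuts the pure-*elegans* bin is [0.90, 1], i.e. q = 0.90 counts
    as pure (the interval below it is right-open).
    """

    cuts: tuple[float, ...] = (0.105, 0.205, 0.675, 0.90)
    labels: tuple[str, ...] = DEFAULT_BIN_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cut points")
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cut points must be strictly increasing")
        if self.cuts and (self.cuts[0] <= 0.0 or self.cuts[-1] >= 1.0):
            raise ValueError("cut points must lie strictly inside (0, 1)")


def classify_q(q_elegans: float, bins: AdmixtureBins | None = None) -> str:
    """Bin label for one posterior-mean *elegans* ancestry value.

    Total on [0, 1]: every valid q maps to exactly one bin; values outside
    [0, 1] are an error.
    """
    if bins is None:
        bins = AdmixtureBins()
    q = float(q_elegans)
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"admixture proportion must lie in [0, 1], got {q}")
    idx = int(np.searchsorted(bins.cuts, q, side="right"))
    return bins.labels[idx]


def summarize_assignments(
    q_table: pd.DataFrame,
    grouping: str | pd.Series = "group",
    q_column: str = "q_elegans",
    bins: AdmixtureBins | None = None,
) -> pd.DataFrame:
    """Per-group bin counts (the population-summary report shape).

    ``q_table`` has one row per individual with the *elegans* ancestry in
    ``q_column``; ``grouping`` is a column name in the table or an aligned
    Series of labels. Output rows carry N and one count column per bin;
    counts sum to N by construction.
    """
    if bins is None:
        bins = AdmixtureBins()
    labels = (
        q_table[grouping] if isinstance(grouping, str) else pd.Series(
            list(grouping), index=q_table.index
        )
    )
    assigned = q_table[q_column].map(lambda q: classify_q(q, bins))
    out = (
        pd.crosstab(labels, assigned)
        .reindex(columns=list(bins.labels), fill_value=0)
        .astype(int)
    )
    out.insert(0, "N", out.sum(axis=1))
    out.index.name = "group"
    return out


def calibrate_bins(
    cross_panel_q: pd.DataFrame,
    bins: AdmixtureBins | None = None,
    cross_column: str = "cross",
    q_column: str = "q_elegans",
) -> pd.DataFrame:
    """Per-cross ancestry ranges and bin occupancy from simulated panels.

    ``cross_panel_q`` holds one row per simulated individual with its cross
    label and posterior-mean *elegans* ancestry. The report gives, per
    cross, min/mean/max q plus bin counts — the calibration table from
    which assignment groups are read off.
    """
    if bins is None:
        bins = AdmixtureBins()
    if cross_panel_q.empty:
        raise ValueError("empty cross panel")
    for col in (cross_column, q_column):
        if col not in cross_panel_q.columns:
            raise ValueError(f"missing column {col!r}")
    order = [c.value for c in CrossType if c.value in set(cross_panel_q[cross_column])]
    extra = [c for c in pd.unique(cross_panel_q[cross_column]) if c not in order]
    counts = summarize_assignments(
        cross_panel_q, grouping=cross_column, q_column=q_column, bins=bins
    )
    stats = cross_panel_q.groupby(cross_column)[q_column].agg(["min", "mean", "max"])
    stats.columns = ["q_min", "q_mean", "q_max"]
    out = stats.join(counts).reindex(order + extra)
    out.index.name = "cross"
    return out
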