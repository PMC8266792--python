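"""ATP, ROS and viability assay summaries for L/M/S strain groups.

Event tables come from flow cytometry exported to plain TSV/CSV (one
row per event) with named channels: a cell-size signal, a stain
fluorescence channel (FITC-like, oxidative-stress dye) and a
viability-dye channel (PE-like, propidium iodide). Gating to single
intact cells is accepted as boolean flags on the events; instrument
gating geometry is out of scope.

Strain-level summaries (the units of all statistics) are averaged over
replicate preparations, and groups are compared pairwise with a
rank-based test by default.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "atp_per_cell",
    "gate_events",
    "ros_score",
    "dead_fraction",
    "compare_groups",
    "summarize_replicates",
]

#: Expected event-table columns.
SIZE_COL = "size"
STAIN_COL = "stain"
DYE_COL = "dye"
GATE_COLS = ("singlet", "intact")


def atp_per_cell(luminescence: float, n_cells: float) -> float:
    """Luminescence reading divided by the number of assayed cells.

    Units are arbitrary luminescence per cell; the ratio is invariant
    to rescaling both inputs.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return luminescence / n_cells


def gate_events(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep single intact cells; gate columns absent means pre-gated."""
    out = frame
    for col in GATE_COLS:
        if col in out.columns:
            out = out[out[col].astype(bool)]
    return out


def ros_score(
    stained: pd.DataFrame,
    unstained_control: pd.DataFrame,
    autofluorescence_quantile: float = 0.99,
) -> float:
    """Oxidative-stress score of one strain from stained events.

    Autofluorescence is handled by discarding stained events whose
    stain signal does not exceed a high quantile (default 0.99) of the
    unstained, size-matched control; the score is the median stain
    fluorescence of the remaining events divided by the mean cell size
    of all gated events of the strain, normalizing out cell-size
    differences between groups.

    Returns NaN (with a logged note) when no event clears the
    autofluorescence cutoff — no net signal, not an error.
    """
    if not 0 < autofluorescence_quantile <= 1:
        raise ValueError("autofluorescence_quantile must be in (0, 1]")
    stained = gate_events(stained)
    control = gate_events(unstained_control)
    if stained.empty or control.empty:
        raise ValueError("gated event tables must be non-empty")
    cutoff = float(control[STAIN_COL].quantile(autofluorescence_quantile))
    net = stained[stained[STAIN_COL] > cutoff]
    if net.empty:
        logger.info("no events above autofluorescence cutoff %.3g; score is NaN",
                    cutoff)
        return float("nan")
    return float(net[STAIN_COL].median() / stained[SIZE_COL].mean())


def dead_fraction(frame: pd.DataFrame, dye_cutoff: float) -> float:
    """Fraction of gated events whose viability-dye signal exceeds the
    cutoff (dye-permeable, i.e. dead, cells)."""
    frame = gate_events(frame)
    if frame.empty:
        raise ValueError("empty event table")
    return float((frame[DYE_COL] > dye_cutoff).mean())


def summarize_replicates(replicate_values: pd.DataFrame) -> pd.Series:
    """Mean per strain over replicate measurements.

    ``replicate_values`` has columns (strain, value); strains are
    averaged over exactly their available replicates.
    """
    return replicate_values.groupby("strain")["value"].mean()


def compare_groups(
    summaries: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Pairwise two-sided tests between strain groups on one metric.

    Strains, not cells, are the experimental units: each row of
    ``summaries`` is one strain with its replicate-averaged metric and
    group label (L/M/S). The default test is the two-sided
    Mann-Whitney U; ``test="ttest"`` switches to Welch's t. Pairs where
    a group has fewer than two strains are skipped with a note.
    """
    if metric not in summaries.columns:
        raise ValueError(f"metric column {metric!r} not found")
    if test not in ("mannwhitney", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    groups = sorted(summaries[group_col].dropna().unique())
    for a, b in combinations(groups, 2):
        xa = summaries.loc[summaries[group_col] == a, metric].dropna()
        xb = summaries.loc[summaries[group_col] == b, metric].dropna()
        if len(xa) < 2 or len(xb) < 2:
            logger.info("pair (%s, %s) skipped: <2 strains in a group", a, b)
            continue
        if test == "mannwhitney":
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        else:
            res = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"group1": a, "group2": b, "n1": len(xa), "n2": len(xb),
                     "statistic": float(res.statistic),
                     "pvalue": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2",
                                       "statistic", "pvalue"])
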