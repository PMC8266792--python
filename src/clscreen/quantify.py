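"""Relative chronological-lifespan quantification.

The estimand: for every strain, in each environment and replicate
flask, the linear trend over starvation time of its frequency among
alive cells, after the variance-stabilizing angular (arcsine square
root) transformation. Frequencies of a strain that outlives the pool
average rise, so a positive slope reads as an extended relative
chronological lifespan.

Pipeline: counts -> per-sample frequencies -> angular transform
(degrees) -> per-replicate OLS slope against days -> average slope per
environment (mean of the four replicate slopes) -> combined slope
(mean of all eight replicate slopes) -> L/M/S strain classes and the
H-vs-G overlap statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import AmplificationCallSet, CountTensor

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyMatrix",
    "SlopeTable",
    "StrainClassLabels",
    "OverlapStats",
    "angular_transform",
    "compute_frequencies",
    "fit_strain_slopes",
    "classify_strains",
    "overlap_stats",
    "expected_overlap",
]


def angular_transform(p, degrees: bool = True):
    """Angular (arcsine square-root) transform of proportions.

    theta = arcsin(sqrt(p)), reported in degrees by default so that
    p = 0, 0.5, 1 map to 0, 45 and 90 degrees. Defined at the
    boundaries; no pseudocount is applied here.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    theta = np.arcsin(np.sqrt(p))
    return np.degrees(theta) if degrees else theta


@dataclass
class FrequencyMatrix:
    """Per-sample strain frequencies and their angular transform.

    ``freq`` and ``theta`` have the tensor shape (strain, environment,
    replicate, timepoint); ``theta`` is in degrees.
    """

    freq: np.ndarray
    theta: np.ndarray
    strains: list[str]
    environments: list[str]
    replicates: list[int]
    timepoints: list[float]


def compute_frequencies(
    tensor: CountTensor, anscombe: bool = False
) -> FrequencyMatrix:
    """Per-sample frequencies p = count / sample total, transformed.

    With ``anscombe=True`` the variance-stabilizing variant
    p' = (x + 3/8) / (n + 3/4) is used instead of the raw proportion
    (a sensitivity-analysis option; the default applies no correction,
    so zero counts map to exactly 0 degrees).

    Raises
    ------
    ValueError
        If any sample has zero total reads (frequencies undefined),
        naming the offending sample.
    """
    totals = tensor.sample_totals().astype(float)
    if np.any(totals == 0):
        bad = np.argwhere(totals == 0)[0]
        env = tensor.environments[bad[0]]
        rep = tensor.replicates[bad[1]]
        tp = tensor.timepoints[bad[2]]
        raise ValueError(
            f"sample (environment={env}, replicate={rep}, timepoint={tp}) "
            "has zero total reads"
        )
    x = tensor.counts.astype(float)
    if anscombe:
        p = (x + 0.375) / (totals[None, ...] + 0.75)
    else:
        p = x / totals[None, ...]
    theta = angular_transform(p)
    return FrequencyMatrix(p, theta, list(tensor.strains), list(tensor.environments),
                           list(tensor.replicates), list(tensor.timepoints))


@dataclass
class SlopeTable:
    """Per-strain regression slopes (degrees/day).

    Attributes
    ----------
    replicate_slopes
        Array (strain, environment, replicate) of per-replicate OLS
        slopes; NaN marks a replicate series with <2 finite points.
    replicate_intercepts
        Matching OLS intercepts (kept for plotting; classification
        never uses them).
    average_slopes
        (strain, environment): mean of the finite replicate slopes.
    combined_slopes
        (strain,): mean over all replicate slopes of both environments
        (the "mean of eight slopes" when the design is 2 x 4).
    """

    replicate_slopes: np.ndarray
    replicate_intercepts: np.ndarray
    average_slopes: np.ndarray
    combined_slopes: np.ndarray
    strains: list[str]
    environments: list[str]
    replicates: list[int]

    def average_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.average_slopes,
            index=pd.Index(self.strains, name="strain"),
            columns=self.environments,
        )

    def combined_series(self) -> pd.Series:
        return pd.Series(self.combined_slopes,
                         index=pd.Index(self.strains, name="strain"),
                         name="combined_slope")

    def to_frame(self) -> pd.DataFrame:
        """Long summary table: one row per strain."""
        out = {"strain": self.strains}
        for j, env in enumerate(self.environments):
            for r, rep in enumerate(self.replicates):
                out[f"slope_{env}_{rep}"] = self.replicate_slopes[:, j, r]
            out[f"average_slope_{env}"] = self.average_slopes[:, j]
        out["combined_slope"] = self.combined_slopes
        return pd.DataFrame(out)


def _ols_slopes(theta: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-series OLS of theta against t along the last axis.

    NaN observations are dropped per series; series with <2 finite
    points (or no time spread) get NaN slope and intercept.
    """
    mask = np.isfinite(theta)
    y = np.where(mask, theta, 0.0)
    tt = np.broadcast_to(t, theta.shape)
    tv = np.where(mask, tt, 0.0)
    n = mask.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = tv.sum(axis=-1) / n
        y_mean = y.sum(axis=-1) / n
        t_c = np.where(mask, tt - t_mean[..., None], 0.0)
        y_c = np.where(mask, theta - y_mean[..., None], 0.0)
        sxx = (t_c ** 2).sum(axis=-1)
        sxy = (t_c * y_c).sum(axis=-1)
        slope = sxy / sxx
        intercept = y_mean - slope * t_mean
    bad = (n < 2) | (sxx == 0)
    slope = np.where(bad, np.nan, slope)
    intercept = np.where(bad, np.nan, intercept)
    return slope, intercept


def fit_strain_slopes(freqs: FrequencyMatrix, timepoints=None) -> SlopeTable:
    """Per-replicate OLS slopes of transformed frequency over time.

    Each (strain, environment, replicate) series of theta values is
    regressed against its sampling days by ordinary least squares. The
    average slope per environment is the arithmetic mean of the finite
    replicate slopes; the combined slope averages the replicate slopes
    of all environments. Replicate series with fewer than two finite
    points are excluded from the means with a logged note.
    """
    t = np.asarray(freqs.timepoints if timepoints is None else timepoints,
                   dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct timepoints")
    if t.shape[0] != freqs.theta.shape[-1]:
        raise ValueError("timepoints length does not match frequency grid")
    slope, intercept = _ols_slopes(freqs.theta, t)
    n_missing = int(np.isnan(slope).sum())
    if n_missing:
        logger.info("%d replicate series had <2 finite points; excluded from means",
                    n_missing)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(slope, axis=2)
        flat = slope.reshape(slope.shape[0], -1)
        combined = np.nanmean(flat, axis=1)
    return SlopeTable(slope, intercept, avg, combined, list(freqs.strains),
                      list(freqs.environments), list(freqs.replicates))


@dataclass
class StrainClassLabels:
    """L / M / S / unclassified assignment per strain.

    labels: Series indexed by strain over the dual-passing set.
    ranks: combined-slope ascending rank (1 = most negative) among the
    dual-passing strains, used to pick S; |combined| picks M.
    """

    labels: pd.Series
    ranks: pd.Series
    combined: pd.Series

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def classify_strains(
    slopes: SlopeTable,
    calls: AmplificationCallSet,
    n_S: int = 66,
    n_M: int = 13,
) -> StrainClassLabels:
    """Assign L / M / S labels among dual-environment filter passers.

    - L (long-lived): positive average slope in every environment.
    - S (short-lived): among strains with negative average slopes in
      every environment, the ``n_S`` with the most negative combined
      slope.
    - M (medium): among the remaining (non-L, non-S) strains, the
      ``n_M`` with combined slope closest to zero.

    Strains failing the read filter in either environment are not
    classifiable and are absent from the result. Group sizes default to
    the realized assay-cohort sizes (66 short-lived, 13 medium).
    """
    if n_S < 0 or n_M < 0:
        raise ValueError("group sizes must be non-negative")
    avg = slopes.average_frame()
    combined = slopes.combined_series()
    dual = [s for s in calls.dual_passing() if s in avg.index]
    if not dual:
        raise ValueError("no strain passes the filter in both environments")
    avg = avg.loc[dual]
    combined = combined.loc[dual]

    labels = pd.Series("unclassified", index=avg.index, name="label")
    is_L = (avg > 0).all(axis=1)
    labels[is_L] = "L"

    is_double_neg = (avg < 0).all(axis=1)
    neg_candidates = combined[is_double_neg].sort_values(kind="stable")
    if n_S > len(neg_candidates):
        raise ValueError(
            f"n_S={n_S} exceeds the {len(neg_candidates)} double-negative strains"
        )
    s_ids = list(neg_candidates.index[:n_S])
    labels[s_ids] = "S"

    remaining = labels.index[(labels != "L") & (labels != "S")]
    by_abs = combined.loc[remaining].abs().sort_values(kind="stable")
    if n_M > len(by_abs):
        raise ValueError(f"n_M={n_M} exceeds the {len(by_abs)} remaining strains")
    labels[list(by_abs.index[:n_M])] = "M"

    ranks = combined.rank(method="first").astype(int)
    return StrainClassLabels(labels=labels, ranks=ranks, combined=combined)


@dataclass
class OverlapStats:
    """H/G amplification overlap bookkeeping."""

    nH: int
    nG: int
    N: int
    observed_overlap: int
    expected_overlap: float
    n_double_positive: int


def expected_overlap(nH: int, nG: int, N: int) -> float:
    """Expected overlap of two independent draws of sizes nH, nG from N.

    The overlap of a fixed set of size nH with a uniform random set of
    size nG is hypergeometric with mean nH * nG / N.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= nH <= N and 0 <= nG <= N):
        raise ValueError("set sizes must lie in [0, N]")
    return nH * nG / N


def overlap_stats(calls: AmplificationCallSet, slopes: SlopeTable) -> OverlapStats:
    """Observed vs expected overlap of well-amplified sets, and the
    number of strains with positive average slopes in both environments."""
    envs = calls.passes.columns
    if len(envs) != 2:
        raise ValueError("overlap statistics need exactly two environments")
    eH, eG = envs
    nH = int(calls.passes[eH].sum())
    nG = int(calls.passes[eG].sum())
    N = int(len(calls.passes))
    dual = calls.dual_passing()
    avg = slopes.average_frame()
    dual_in = [s for s in dual if s in avg.index]
    n_pos = int((avg.loc[dual_in] > 0).all(axis=1).sum()) if dual_in else 0
    return OverlapStats(
        nH=nH, nG=nG, N=N,
        observed_overlap=len(dual),
        expected_overlap=expected_overlap(nH, nG, N),
        n_double_positive=n_pos,
    )
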