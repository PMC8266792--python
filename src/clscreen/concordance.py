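"""Fold-change concordance between two test strains and a common control.

Operates on a gene x sample count matrix with a design mapping samples
to strains (two test strains plus a control, typically three replicates
each). Counts are library-size normalized to counts per million (CPM),
replicates are averaged, and per-gene log2 fold changes of each test
strain against the control are compared: their Pearson and Spearman
correlation over genes, and the overlap of the gene sets exceeding
fourfold (|log2FC| >= 2) and sixteenfold (|log2FC| >= 4) shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_cpm",
    "log_fold_changes",
    "concordance",
    "ConcordanceResult",
]

FOURFOLD_LOG2 = 2.0
SIXTEENFOLD_LOG2 = 4.0


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to counts per million.

    Raises on all-zero samples (library size undefined). No
    log-transform or pseudocount here; those belong to the fold-change
    step.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return counts * 1e6 / totals


def log_fold_changes(
    cpm: pd.DataFrame,
    design: pd.Series,
    test_strain: str,
    control_strain: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change of a test strain versus the control.

    Replicate CPM values are averaged per strain; the fold change is
    log2(mean test CPM + pseudocount) - log2(mean control CPM +
    pseudocount). The pseudocount (default 0.5 CPM) keeps zero-count
    genes finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for strain in (test_strain, control_strain):
        if not (design == strain).any():
            raise ValueError(f"no samples for strain {strain!r}")
    test_mean = cpm.loc[:, design.index[design == test_strain]].mean(axis=1)
    ctrl_mean = cpm.loc[:, design.index[design == control_strain]].mean(axis=1)
    lfc = np.log2(test_mean + pseudocount) - np.log2(ctrl_mean + pseudocount)
    lfc.name = f"log2fc_{test_strain}_vs_{control_strain}"
    return lfc


@dataclass
class ConcordanceResult:
    """Concordance of two log2 fold-change vectors over a shared gene set."""

    per_gene: pd.DataFrame
    pearson: float
    spearman: float
    n_genes: int
    fourfold_overlap: int
    fourfold_union: int
    sixteenfold_overlap: int
    sixteenfold_union: int

    @property
    def fourfold_jaccard(self) -> float:
        return self.fourfold_overlap / self.fourfold_union if self.fourfold_union else float("nan")

    @property
    def sixteenfold_jaccard(self) -> float:
        return (self.sixteenfold_overlap / self.sixteenfold_union
                if self.sixteenfold_union else float("nan"))


def concordance(
    fc1: pd.Series,
    fc2: pd.Series,
    fourfold_log2: float = FOURFOLD_LOG2,
    sixteenfold_log2: float = SIXTEENFOLD_LOG2,
) -> ConcordanceResult:
    """Compare two per-gene log2 fold-change vectors.

    Correlations (Pearson and Spearman) are computed over genes finite
    in both vectors; per-gene flags mark genes beyond the fourfold and
    sixteenfold thresholds in each strain. Symmetric in its arguments
    up to flag labelling.
    """
    genes = fc1.index.intersection(fc2.index)
    merged = pd.DataFrame({"fc1": fc1.loc[genes], "fc2": fc2.loc[genes]})
    merged = merged[np.isfinite(merged).all(axis=1)]
    if len(merged) < 3:
        raise ValueError("need at least 3 shared finite genes")
    pearson = float(stats.pearsonr(merged["fc1"], merged["fc2"]).statistic)
    spearman = float(stats.spearmanr(merged["fc1"], merged["fc2"]).statistic)
    four1 = merged["fc1"].abs() >= fourfold_log2
    four2 = merged["fc2"].abs() >= fourfold_log2
    six1 = merged["fc1"].abs() >= sixteenfold_log2
    six2 = merged["fc2"].abs() >= sixteenfold_log2
    per_gene = merged.assign(fourfold_1=four1, fourfold_2=four2,
                             sixteenfold_1=six1, sixteenfold_2=six2)
    return ConcordanceResult(
        per_gene=per_gene,
        pearson=pearson,
        spearman=spearman,
        n_genes=len(merged),
        fourfold_overlap=int((four1 & four2).sum()),
        fourfold_union=int((four1 | four2).sum()),
        sixteenfold_overlap=int((six1 & six2).sum()),
        sixteenfold_union=int((six1 | six2).sum()),
    )
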