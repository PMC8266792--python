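"""Ranked-list term enrichment via the minimum-hypergeometric statistic.

Given strains ranked by their relative-lifespan slope (best or worst
survivors first) and a term -> gene annotation, the minimum
hypergeometric (mHG) statistic asks whether a term's members crowd the
top of the list without fixing a cutoff in advance: it is the minimum,
over every list prefix, of the hypergeometric upper-tail probability
of the member count seen in that prefix. Because the minimum is taken
over many dependent tests, the statistic itself is not a p-value; an
exact p-value is obtained by dynamic programming over the lattice of
(prefix length, members seen) states, counting the probability that a
uniformly random placement of the members reaches any state at least
as extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .counts import AmplificationCallSet
from .quantify import SlopeTable

logger = logging.getLogger(__name__)

__all__ = [
    "TermAnnotation",
    "EnrichmentResult",
    "rank_strains",
    "hypergeom_tail_table",
    "mhg_statistic",
    "mhg_pvalue",
    "enrich",
]


@dataclass
class TermAnnotation:
    """Mapping term id -> set of annotated gene/strain ids."""

    terms: dict[str, set[str]]

    @classmethod
    def from_tsv(cls, path) -> "TermAnnotation":
        """Two-column TSV: term_id <tab> gene_id (no header required)."""
        frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                            names=["term", "gene"], dtype=str)
        terms: dict[str, set[str]] = {}
        for term, gene in zip(frame["term"], frame["gene"]):
            terms.setdefault(term, set()).add(gene)
        return cls(terms)

    @classmethod
    def from_gaf(cls, path) -> "TermAnnotation":
        """GAF 2.x association file: gene from column 2, term from
        column 5; qualifiers and evidence codes are ignored."""
        terms: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 5:
                    continue
                terms.setdefault(fields[4], set()).add(fields[1])
        return cls(terms)


def rank_strains(
    slopes: SlopeTable,
    calls: AmplificationCallSet,
    environment: str,
    direction: str = "best-first",
) -> list[str]:
    """Order filter-passing strains by average slope in one environment.

    ``best-first`` places the highest (most lifespan-extending) slopes
    on top; ``worst-first`` the most negative. Ties are broken
    lexicographically by strain id so the ranking is a deterministic
    strict total order.
    """
    if direction not in ("best-first", "worst-first"):
        raise ValueError(f"unknown direction {direction!r}")
    avg = slopes.average_frame()
    if environment not in avg.columns:
        raise ValueError(f"unknown environment {environment!r}")
    ids = [s for s in calls.passing(environment) if s in avg.index]
    if not ids:
        raise ValueError("no strains pass the filter in this environment")
    vals = avg.loc[ids, environment]
    ascending = direction == "worst-first"
    order = sorted(ids, key=lambda s: ((vals[s] if ascending else -vals[s]), s))
    return order


def hypergeom_tail_table(N: int, B: int) -> np.ndarray:
    """Upper-tail table T[n, b] = P(X >= b), X ~ Hypergeom(N, B, n).

    Shape (N + 1, B + 1); rows index the prefix length n, columns the
    member count b. Cells with b > min(n, B) are structurally
    unreachable and hold the tail value anyway (0 beyond support).
    """
    n_grid, b_grid = np.meshgrid(np.arange(N + 1), np.arange(B + 1), indexing="ij")
    return hypergeom.sf(b_grid - 1, N, B, n_grid)


def mhg_statistic(
    membership: np.ndarray, table: np.ndarray | None = None
) -> tuple[float, int, int]:
    """Minimum-hypergeometric statistic of a binary membership vector.

    Parameters
    ----------
    membership
        0/1 vector along the ranking, length N with B ones.
    table
        Optional precomputed :func:`hypergeom_tail_table` (reused
        across calls when N and B are fixed).

    Returns
    -------
    (stat, n_star, b_star)
        The minimum over prefixes n in {1..N-1} of P(X >= b_n), the
        minimizing prefix length, and the member count at it.
    """
    membership = np.asarray(membership, dtype=int)
    if membership.ndim != 1 or not np.isin(membership, (0, 1)).all():
        raise ValueError("membership must be a binary vector")
    N = membership.size
    B = int(membership.sum())
    if B == 0 or B == N:
        raise ValueError("statistic undefined for empty or full membership")
    if table is None:
        table = hypergeom_tail_table(N, B)
    b_cum = np.cumsum(membership)[: N - 1]  # prefixes n = 1 .. N-1
    n_arr = np.arange(1, N)
    tails = table[n_arr, b_cum]
    i = int(np.argmin(tails))
    return float(tails[i]), int(n_arr[i]), int(b_cum[i])


def mhg_pvalue(stat: float, B: int, N: int,
               table: np.ndarray | None = None) -> float:
    """Exact p-value of an observed mHG statistic.

    The probability, under uniform random placement of the B members
    among N ranks, that the mHG statistic is <= ``stat``. Computed by
    the O(N*B) lattice dynamic program: propagate the probability of
    the hypergeometric random walk over states (n, b), zeroing every
    state whose upper-tail probability already reaches ``stat`` (the
    walk has "rejected"); one minus the surviving mass at n = N is the
    p-value.
    """
    if not (0 < B < N):
        raise ValueError("need 0 < B < N")
    if table is None:
        table = hypergeom_tail_table(N, B)
    # pi[b]: probability of being at (n, b) without having rejected yet.
    pi = np.zeros(B + 1)
    pi[0] = 1.0
    for n in range(1, N + 1):
        new = np.zeros(B + 1)
        b_hi = min(n, B)
        b = np.arange(0, b_hi + 1)
        # step with a member: from (n-1, b-1); without: from (n-1, b)
        from_member = np.zeros(B + 1)
        from_member[1:b_hi + 1] = pi[:b_hi] * (B - (b[1:] - 1)) / (N - (n - 1))
        from_non = np.zeros(B + 1)
        from_non[:b_hi + 1] = pi[:b_hi + 1] * (
            (N - B) - ((n - 1) - b)
        ) / (N - (n - 1))
        # unreachable "without" transitions have negative remaining
        # non-members; clip them (their pi mass is zero anyway).
        np.clip(from_non, 0.0, None, out=from_non)
        new = from_member + from_non
        if n <= N - 1:  # the statistic only scans prefixes 1..N-1
            new[table[n, : B + 1] <= stat] = 0.0
        pi = new
    return float(min(1.0, max(0.0, 1.0 - pi.sum())))


@dataclass
class EnrichmentResult:
    """Per-term ranked-enrichment outcome."""

    term: str
    B: int
    N: int
    mhg: float
    cutoff: int
    b_at_cutoff: int
    fold: float
    pvalue: float
    adjusted_pvalue: float = field(default=np.nan)


def enrich(
    ranking: list[str],
    annotation: TermAnnotation,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotation term for crowding at the top of a ranking.

    Terms with no member, or with every ranked id as a member, carry no
    signal and are skipped with a logged note. P-values are adjusted
    across the tested terms with Benjamini-Hochberg; results are
    returned sorted by p-value (ties by term id).
    """
    if not annotation.terms:
        raise ValueError("empty annotation")
    if not ranking:
        raise ValueError("empty ranking")
    N = len(ranking)
    index = {g: i for i, g in enumerate(ranking)}
    results: list[EnrichmentResult] = []
    tables: dict[int, np.ndarray] = {}
    for term, genes in sorted(annotation.terms.items()):
        members = genes & index.keys()
        B = len(members)
        if B == 0 or B == N:
            logger.info("term %s skipped (B=%d of N=%d)", term, B, N)
            continue
        membership = np.zeros(N, dtype=int)
        membership[[index[g] for g in members]] = 1
        if B not in tables:
            tables[B] = hypergeom_tail_table(N, B)
        stat, n_star, b_star = mhg_statistic(membership, tables[B])
        p = mhg_pvalue(stat, B, N, tables[B])
        fold = (b_star / n_star) / (B / N)
        results.append(EnrichmentResult(term, B, N, stat, n_star, b_star, fold, p))
    if results:
        _, adj, _, _ = multipletests([r.pvalue for r in results], alpha=alpha,
                                     method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_pvalue = float(a)
    results.sort(key=lambda r: (r.pvalue, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
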