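"""Count-tensor assembly for pooled-screen sequencing data.

The screen design is a complete grid of samples: two starvation
environments (H = water, G = water + galactose), several replicate
flasks per environment, and weekly sampling time points. Each sample
yields one per-strain read-count file (e.g. ``samtools idxstats``
output). This module reads those files, assembles them into a single
labelled 4-D tensor and applies the per-environment read-total
inclusion filter that decides which strains were amplified well enough
to be analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTensor",
    "AmplificationCallSet",
    "read_count_file",
    "assemble_tensor",
    "call_amplified",
    "DEFAULT_READ_THRESHOLD",
]

#: Minimum per-environment read total for a strain to be retained.
#: Strains with a total strictly lower than this are discarded.
DEFAULT_READ_THRESHOLD = 160

_LONG_COLUMNS = ["strain", "environment", "replicate", "timepoint", "count"]


@dataclass
class CountTensor:
    """Read counts on a (strain, environment, replicate, timepoint) grid.

    Attributes
    ----------
    counts
        Integer array of shape ``(n_strains, n_envs, n_replicates,
        n_timepoints)``. Strains absent from a sample file carry 0.
    strains, environments, replicates, timepoints
        Axis labels. ``timepoints`` are days since the start of
        starvation; ``replicates`` are integer flask indices.
    """

    counts: np.ndarray
    strains: list[str]
    environments: list[str]
    replicates: list[int]
    timepoints: list[float]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (
            len(self.strains),
            len(self.environments),
            len(self.replicates),
            len(self.timepoints),
        )
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match labels {expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts are not allowed")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain ids must be unique")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample, shape (n_envs, n_replicates, n_timepoints)."""
        return self.counts.sum(axis=0)

    def env_totals(self) -> pd.DataFrame:
        """Per-strain read totals summed over replicates and timepoints.

        Returns a frame indexed by strain with one column per environment.
        """
        totals = self.counts.sum(axis=(2, 3))
        return pd.DataFrame(totals, index=pd.Index(self.strains, name="strain"),
                            columns=self.environments)

    def to_long(self) -> pd.DataFrame:
        """Long-format view: one row per (strain, env, replicate, timepoint)."""
        idx = pd.MultiIndex.from_product(
            [self.strains, self.environments, self.replicates, self.timepoints],
            names=_LONG_COLUMNS[:4],
        )
        return pd.DataFrame({"count": self.counts.ravel()}, index=idx).reset_index()

    def to_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "CountTensor":
        missing = [c for c in _LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"long-format frame lacks columns: {missing}")
        strains = sorted(frame["strain"].astype(str).unique())
        envs = sorted(frame["environment"].astype(str).unique())
        reps = sorted(int(r) for r in frame["replicate"].unique())
        tps = sorted(float(t) for t in frame["timepoint"].unique())
        shape = (len(strains), len(envs), len(reps), len(tps))
        counts = np.zeros(shape, dtype=np.int64)
        s_ix = {s: i for i, s in enumerate(strains)}
        e_ix = {e: i for i, e in enumerate(envs)}
        r_ix = {r: i for i, r in enumerate(reps)}
        t_ix = {t: i for i, t in enumerate(tps)}
        seen: set[tuple] = set()
        for row in frame.itertuples(index=False):
            key = (str(row.strain), str(row.environment), int(row.replicate),
                   float(row.timepoint))
            if key in seen:
                raise ValueError(f"duplicate entry for {key}")
            seen.add(key)
            counts[s_ix[key[0]], e_ix[key[1]], r_ix[key[2]], t_ix[key[3]]] = int(row.count)
        return cls(counts, strains, envs, reps, tps)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTensor":
        return cls.from_long(pd.read_csv(path, sep="\t"))


@dataclass
class AmplificationCallSet:
    """Per-(strain, environment) amplification pass/fail calls.

    ``passes`` holds booleans (strain × environment); a strain passes in
    an environment iff its total reads there are >= ``threshold``.
    """

    totals: pd.DataFrame
    passes: pd.DataFrame
    threshold: int = DEFAULT_READ_THRESHOLD
    environments: list[str] = field(default_factory=list)

    def passing(self, environment: str) -> list[str]:
        """Strain ids passing the filter in one environment."""
        mask = self.passes[environment]
        return list(mask.index[mask])

    def dual_passing(self) -> list[str]:
        """Strain ids passing the filter in every environment."""
        mask = self.passes.all(axis=1)
        return list(mask.index[mask])


def read_count_file(
    path: str | Path,
    format: str = "idxstats",
    *,
    name_col: int = 0,
    count_col: int | None = None,
) -> dict[str, int]:
    """Read one per-sample strain-count file into a strain -> count map.

    Parameters
    ----------
    path
        Input file.
    format
        ``"idxstats"``: whitespace-delimited columns
        (name, length, mapped, [unmapped]) as printed by
        ``samtools idxstats``; the mapped-read column is column 2 unless
        ``count_col`` overrides it, and a ``*`` summary row is dropped.
        ``"long-tsv"``: two tab-separated columns (strain, count) with
        an optional header.
    name_col, count_col
        Zero-based column positions; ``count_col`` defaults to 2 for
        idxstats and 1 for long-tsv.

    Returns
    -------
    dict mapping strain id to read count.
    """
    path = Path(path)
    if format not in ("idxstats", "long-tsv"):
        raise ValueError(f"unknown format {format!r}")
    if count_col is None:
        count_col = 2 if format == "idxstats" else 1
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and format == "long-tsv" and not _is_int(fields[-1]):
                continue  # header row
            if len(fields) <= max(name_col, count_col):
                raise ValueError(f"{path}:{lineno}: expected at least "
                                 f"{max(name_col, count_col) + 1} columns")
            name = fields[name_col].strip()
            if name == "*":
                logger.info("%s:%d: dropping '*' summary row", path, lineno)
                continue
            raw = fields[count_col].strip()
            if not _is_int(raw):
                raise ValueError(f"{path}:{lineno}: non-integer count {raw!r}")
            if name in counts:
                raise ValueError(f"{path}:{lineno}: duplicate strain {name!r}")
            counts[name] = int(raw)
    return counts


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def assemble_tensor(
    samples: Iterable[tuple[Mapping[str, int], str, int, float]],
) -> CountTensor:
    """Assemble per-sample count maps into a :class:`CountTensor`.

    Parameters
    ----------
    samples
        Iterable of ``(counts, environment, replicate, timepoint)``
        tuples, one per sequenced sample. The strain universe is the
        union over samples; a strain absent from a sample gets count 0.

    Raises
    ------
    ValueError
        If two samples carry the same (environment, replicate,
        timepoint) tag.
    """
    tagged: dict[tuple[str, int, float], Mapping[str, int]] = {}
    for counts, env, rep, tp in samples:
        key = (str(env), int(rep), float(tp))
        if key in tagged:
            raise ValueError(f"duplicate sample tag {key}")
        tagged[key] = counts
    if not tagged:
        raise ValueError("no samples provided")
    strains = sorted({s for c in tagged.values() for s in c})
    envs = sorted({k[0] for k in tagged})
    reps = sorted({k[1] for k in tagged})
    tps = sorted({k[2] for k in tagged})
    arr = np.zeros((len(strains), len(envs), len(reps), len(tps)), dtype=np.int64)
    s_ix = {s: i for i, s in enumerate(strains)}
    for (env, rep, tp), counts in tagged.items():
        e, r, t = envs.index(env), reps.index(rep), tps.index(tp)
        for strain, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for strain {strain!r}")
            arr[s_ix[strain], e, r, t] = n
    return CountTensor(arr, strains, envs, reps, tps)


def assemble_from_design(design: pd.DataFrame, format: str = "idxstats") -> CountTensor:
    """Assemble a tensor from a design table with columns
    (path, environment, replicate, timepoint)."""
    needed = {"path", "environment", "replicate", "timepoint"}
    if not needed.issubset(design.columns):
        raise ValueError(f"design table needs columns {sorted(needed)}")
    samples = [
        (read_count_file(row.path, format=format), row.environment,
         int(row.replicate), float(row.timepoint))
        for row in design.itertuples(index=False)
    ]
    return assemble_tensor(samples)


def call_amplified(
    tensor: CountTensor,
    threshold: int = DEFAULT_READ_THRESHOLD,
    timepoints: Sequence[float] | None = None,
) -> AmplificationCallSet:
    """Apply the per-environment read-total inclusion filter.

    A strain is retained in an environment iff its reads summed over all
    replicates and the selected timepoints reach ``threshold``; totals
    strictly below the threshold are discarded.

    Parameters
    ----------
    tensor
        Assembled count tensor.
    threshold
        Minimum total; default 160 reads per environment.
    timepoints
        Optional subset of timepoint days to include in the total
        (defaults to all sampled timepoints).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if timepoints is None:
        t_sel = slice(None)
    else:
        t_sel = [tensor.timepoints.index(float(t)) for t in timepoints]
    sub = tensor.counts[:, :, :, t_sel]
    totals = pd.DataFrame(
        sub.sum(axis=(2, 3)),
        index=pd.Index(tensor.strains, name="strain"),
        columns=tensor.environments,
    )
    passes = totals >= threshold
    return AmplificationCallSet(totals=totals, passes=passes, threshold=threshold,
                                environments=list(tensor.environments))
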