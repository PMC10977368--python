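"""Count-level CPM filtering upstream of differential-expression tools.

Only the filtering stage lives here: genes are kept when their average
counts-per-million across samples exceeds a threshold (default 5), and a
log2CPM matrix (pseudo-count 0.5) is emitted for downstream model fitting,
which is out of scope for this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_AVG_CPM = 5.0
LOG2_PSEUDOCOUNT = 0.5


class CountsError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts with group labels."""

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise CountsError("counts must be nonnegative")
        if not np.issubdtype(self.counts.values.dtype, np.number):
            raise CountsError("counts must be numeric")
        zero = self.library_sizes[self.library_sizes == 0]
        if len(zero):
            raise CountsError(
                f"zero library size for sample(s): {list(zero.index)}"
            )
        unknown = set(self.groups) - set(self.counts.columns)
        if unknown:
            raise CountsError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_tsv(cls, text_or_path, metadata: str | None = None) -> "CountMatrix":
        """Counts as tab-delimited with a header of sample ids; optional
        2-column metadata text mapping sample -> group."""
        from io import StringIO

        src = (
            StringIO(text_or_path)
            if isinstance(text_or_path, str) and "\t" in text_or_path
            else text_or_path
        )
        counts = pd.read_csv(src, sep="\t", index_col=0)
        groups = {}
        if metadata:
            for ln in metadata.splitlines():
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                sample, group = ln.split("\t")[:2]
                groups[sample] = group
        return cls(counts=counts, groups=groups)

    def to_tsv(self) -> str:
        return self.counts.to_csv(sep="\t")


def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    return m.counts / m.library_sizes * 1e6


def cpm_filter(
    m: CountMatrix,
    min_avg_cpm: float = DEFAULT_MIN_AVG_CPM,
    per_group: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain genes whose mean CPM exceeds ``min_avg_cpm`` (strict >).

    By default the mean is taken across all samples; ``per_group`` keeps a
    gene when *any* group's mean passes.  Returns the filtered matrix and the
    log2CPM (log2(CPM + 0.5)) of the retained genes.
    """
    cpm_mat = cpm(m)
    if per_group:
        if not m.groups:
            raise CountsError("per_group filtering requires group labels")
        keep = pd.Series(False, index=cpm_mat.index)
        for group in set(m.groups.values()):
            cols = [s for s, g in m.groups.items() if g == group]
            keep |= cpm_mat[cols].mean(axis=1) > min_avg_cpm
    else:
        keep = cpm_mat.mean(axis=1) > min_avg_cpm
    filtered = CountMatrix(counts=m.counts.loc[keep], groups=dict(m.groups))
    log2cpm = np.log2(cpm_mat.loc[keep] + LOG2_PSEUDOCOUNT)
    logger.info(
        "CPM filter (> %g): retained %d / %d genes",
        min_avg_cpm, filtered.n_genes, m.n_genes,
    )
    return filtered, log2cpm
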