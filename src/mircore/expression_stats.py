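"""Expression-level ranking and binomial enrichment of gene sets.

Transcripts of an expression matrix (RPKM-like values, transcripts ×
samples) are summarised by their median, first and third quartile across
samples.  Expression *variance* is quantified as the Q3/Q1 ratio, which is
defined whenever Q1 > 0 and is ranking-equivalent to the interquartile
range of log-scaled values.  Whether a gene set (e.g. the network core) is
unusually concentrated in the top or bottom stratum of a ranking is tested
with an exact upper-tail binomial probability: under the null each set
member lands in a fraction-``q`` stratum independently with probability
``q``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_expression_matrix",
    "summarize_transcripts",
    "stratum_membership",
    "binomial_upper_tail",
    "enrichment_test",
    "variance_half_filter",
    "EnrichmentTestResult",
]

_STATISTICS = ("median", "q1", "q3", "variance_ratio")


@dataclass(frozen=True)
class EnrichmentTestResult:
    """Outcome of a stratum-membership binomial test.

    ``k`` of the ``n`` scored set members fall in the stratum that holds a
    fraction ``stratum_fraction`` of all transcripts; ``p_value`` is the
    exact binomial upper tail P(X >= k), X ~ Binomial(n, stratum_fraction).
    ``missing`` lists set members absent from the matrix (excluded from n).
    """

    k: int
    n: int
    stratum_fraction: float
    p_value: float
    missing: tuple[str, ...] = ()


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a delimited transcripts × samples matrix (header = sample ids)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: expression matrix contains non-finite values")
    df.index = df.index.astype(str).str.upper()
    return df


def summarize_transcripts(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript median, Q1, Q3 and Q3/Q1 variance ratio.

    Quartiles use linear interpolation between order statistics.  The
    variance ratio is NaN where Q1 <= 0 (undefined).
    """
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("expression matrix must have at least one transcript and one sample")
    values = mat.to_numpy(dtype=float)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], axis=1)
    ratio = np.where(q1 > 0, q3 / np.where(q1 > 0, q1, 1.0), np.nan)
    return pd.DataFrame(
        {"median": med, "q1": q1, "q3": q3, "variance_ratio": ratio},
        index=pd.Index(mat.index, name="transcript"),
    )


def stratum_membership(
    summaries: pd.DataFrame,
    gene_set: Iterable[str],
    statistic: str = "median",
    stratum: float = 0.25,
    direction: str = "top",
) -> tuple[int, int, tuple[str, ...]]:
    """Count gene-set members in the extreme stratum of a ranking.

    Transcripts are ranked by ``statistic`` (descending for ``top``,
    ascending for ``bottom``; ties receive their average rank) and the
    stratum holds the first ``floor(stratum * total)`` ranks.  Members of
    ``gene_set`` missing from the matrix are reported and excluded.

    Returns ``(k, n, missing)``.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {_STATISTICS}")
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if not 0 < stratum < 1:
        raise ValueError("stratum must be a fraction in (0, 1)")
    col = summaries[statistic].dropna()
    genes = {str(g).upper() for g in gene_set}
    present = sorted(genes & set(col.index))
    missing = tuple(sorted(genes - set(col.index)))
    if not present:
        raise ValueError("no gene-set member is present in the summarised matrix")
    ranks = col.rank(ascending=(direction == "bottom"), method="average")
    cutoff = int(np.floor(stratum * len(col)))
    k = int((ranks.loc[present] <= cutoff).sum())
    return k, len(present), missing


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0 < p < 1:
        raise ValueError(f"p={p} outside (0, 1)")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def enrichment_test(
    summaries: pd.DataFrame,
    gene_set: Iterable[str],
    statistic: str = "median",
    stratum: float = 0.25,
    direction: str = "top",
) -> EnrichmentTestResult:
    """Stratum membership of a gene set plus its exact binomial p-value."""
    k, n, missing = stratum_membership(summaries, gene_set, statistic, stratum, direction)
    return EnrichmentTestResult(k, n, stratum, binomial_upper_tail(k, n, stratum), missing)


def variance_half_filter(summaries: pd.DataFrame) -> pd.DataFrame:
    """Drop low-expression transcripts before variance ranking.

    Keeps the upper half of transcripts ranked by Q1 (cutoff
    ``floor(total / 2)``), then additionally requires Q1 > 0 so that the
    Q3/Q1 variance ratio is defined for every retained transcript.
    """
    ranks = summaries["q1"].rank(ascending=False, method="first")
    keep = ranks <= len(summaries) // 2
    out = summaries.loc[keep & (summaries["q1"] > 0)].copy()
    return out
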