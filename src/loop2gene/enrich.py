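"""Contingency-table and gene-set enrichment statistics, with FDR utilities.

The driver-gene style analysis is a 2x2 Fisher's exact test; the odds ratio
is reported as the sample cross-product a*d/(b*c), and the 95% CI is the
log-normal (Woolf) interval.  Gene-set over-representation uses the
upper-tail hypergeometric with a Bonferroni multiplier over tested sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ScoredRecord",
    "GeneSetResult",
    "fisher_exact",
    "bh_fdr",
    "threshold_fdr",
    "read_gmt",
    "geneset_enrichment",
    "overrepresentation",
]


class ZeroMarginError(ValueError):
    """Raised when a 2x2 table has an empty row or column (OR undefined)."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows in-set/not, columns outcome/not.

    Layout::

                outcome   not-outcome
        in-set     a           b
        not        c           d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_sets(cls, in_set: set, outcome: set, universe: set) -> "ContingencyTable":
        if not (in_set <= universe and outcome <= universe):
            raise ValueError("in_set and outcome must be subsets of the universe")
        a = len(in_set & outcome)
        b = len(in_set - outcome)
        c = len(outcome - in_set)
        d = len(universe) - a - b - c
        return cls(a, b, c, d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class ScoredRecord:
    """An id with a functional-similarity score, its p-value and FDR."""

    id: str
    score: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must be in [0, 1]")


def fisher_exact(table: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The odds ratio is the sample cross-product (a*d)/(b*c), infinite when
    b*c == 0 with a*d > 0; the p-value sums hypergeometric outcomes with
    probability <= the observed table's (the standard two-sided rule); the
    95% CI is Woolf's log-normal interval (NaN when any cell is zero).
    An empty row or column raises :class:`ZeroMarginError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ZeroMarginError("odds ratio undefined: table has a zero margin")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        ci_low = odds * math.exp(-z * se)
        ci_high = odds * math.exp(z * se)
    else:
        ci_low = ci_high = math.nan
    return EnrichmentResult(odds_ratio=odds, ci_low=ci_low, ci_high=ci_high,
                            p_two_sided=float(min(p, 1.0)),
                            method="fisher_exact; cross-product OR; Woolf CI")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def threshold_fdr(records: Iterable[ScoredRecord],
                  alpha: float = 0.05) -> list[ScoredRecord]:
    """Retain records with fdr strictly below ``alpha``."""
    return [r for r in records if r.fdr < alpha]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


@dataclass(frozen=True)
class GeneSetResult:
    name: str
    set_size: int       # after intersection with the universe
    overlap: int
    p_value: float
    p_bonferroni: float


def geneset_enrichment(query: set[str],
                       collections: Mapping[str, set[str]],
                       universe: set[str]) -> list[GeneSetResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first; the upper-tail p is
    P(overlap >= observed), so a disjoint set gives p = 1 (the 0-overlap
    outcome carries the full mass).  Bonferroni multiplies by the number of
    tested sets.  Results are sorted by adjusted then raw p.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n_query = len(query)
    n_sets = len(collections)
    results = []
    for name, genes in collections.items():
        genes_u = genes & universe
        k = len(query & genes_u)
        # P(X >= k) for X ~ Hypergeom(M=m, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, m, len(genes_u), n_query))
        results.append(GeneSetResult(
            name=name, set_size=len(genes_u), overlap=k,
            p_value=min(p, 1.0), p_bonferroni=min(p * n_sets, 1.0)))
    results.sort(key=lambda r: (r.p_bonferroni, r.p_value, r.name))
    return results


def overrepresentation(target_genes: set[str], outcome_genes: set[str],
                       universe: set[str]) -> EnrichmentResult:
    """Fisher's exact over-representation of an outcome among target genes.

    Builds the 2x2 table (a = |target & outcome|, b = |target - outcome|,
    c = |outcome - target|, d = rest of the universe) and delegates to
    :func:`fisher_exact`.  The universe and genome-wide outcome list are
    explicit inputs — there is no sensible default universe.
    """
    table = ContingencyTable.from_sets(target_genes, outcome_genes, universe)
    return fisher_exact(table)
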