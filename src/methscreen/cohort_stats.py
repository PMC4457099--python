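"""Cohort-level methylation frequencies, filters and exact tests.

Aggregates per-sample categorical calls into per-gene frequencies, applies
the frequent-in-metastasis / infrequent-in-primary cutoffs (inclusive) and
tests each gene's 2x2 contingency table with a two-sided Fisher's exact
test computed by exact hypergeometric summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Iterable, Sequence

from scipy.stats import false_discovery_control

__all__ = [
    "CallRecord",
    "CallTable",
    "GeneFrequency",
    "DifferentialResult",
    "gene_frequencies",
    "apply_filters",
    "FilterResult",
    "differential_test",
    "differential_results",
    "FREQUENT_CUTOFF",
    "INFREQUENT_CUTOFF",
]

FREQUENT_CUTOFF = 50.0  # percent methylated in the metastatic cohort, >=
INFREQUENT_CUTOFF = 45.0  # percent methylated in the primary cohort, <=

CALLS = ("methylated", "unmethylated", "failed")


@dataclass(frozen=True)
class CallRecord:
    """One per-sample, per-gene categorical methylation call."""

    sample_id: str
    cohort: str
    gene: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"invalid call {self.call!r}; expected one of {CALLS}")


@dataclass
class CallTable:
    """A collection of call records; (sample_id, gene) must be unique."""

    records: list[CallRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.gene)
            if key in seen:
                raise ValueError(f"duplicate (sample_id, gene) record: {key}")
            seen.add(key)

    @property
    def cohorts(self) -> list[str]:
        return sorted({r.cohort for r in self.records})

    @property
    def genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})


@dataclass(frozen=True)
class GeneFrequency:
    """Methylation frequency of one gene in one cohort.

    ``frequency`` is a percentage of evaluable (non-failed) samples; it is
    ``None`` and ``flagged`` is True when no sample was evaluable.
    """

    gene: str
    cohort: str
    n_evaluable: int
    n_methylated: int
    frequency: float | None
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.n_methylated > self.n_evaluable:
            raise ValueError("n_methylated cannot exceed n_evaluable")
        if self.n_evaluable == 0 and not self.flagged:
            raise ValueError("zero-evaluable record must be flagged")

    @classmethod
    def from_counts(cls, gene: str, cohort: str, n_methylated: int, n_evaluable: int) -> "GeneFrequency":
        if n_evaluable == 0:
            return cls(gene, cohort, 0, 0, None, flagged=True)
        return cls(gene, cohort, n_evaluable, n_methylated, 100.0 * n_methylated / n_evaluable)


def gene_frequencies(table: CallTable) -> list[GeneFrequency]:
    """One frequency record per (gene, cohort), failed calls excluded.

    Output is ordered by gene then cohort.
    """
    if not table.records:
        raise ValueError("empty call table")
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in table.records:
        key = (rec.gene, rec.cohort)
        evaluable, methylated = counts.setdefault(key, [0, 0])
        if rec.call == "failed":
            continue
        counts[key][0] += 1
        if rec.call == "methylated":
            counts[key][1] += 1
    return [
        GeneFrequency.from_counts(gene, cohort, n_meth, n_eval)
        for (gene, cohort), (n_eval, n_meth) in sorted(counts.items())
    ]


@dataclass
class FilterResult:
    """Gene sets surviving the cohort frequency filters."""

    frequent_in_met: set[str] = field(default_factory=set)
    selected: set[str] = field(default_factory=set)
    skipped: set[str] = field(default_factory=set)


def apply_filters(
    freqs: Iterable[GeneFrequency],
    frequent_cutoff: float = FREQUENT_CUTOFF,
    infrequent_cutoff: float = INFREQUENT_CUTOFF,
    met_cohort: str = "metastasis",
    primary_cohort: str = "primary",
) -> FilterResult:
    """Partition genes by the two inclusive frequency cutoffs.

    ``frequent_in_met``: frequency >= frequent_cutoff in the metastatic
    cohort.  ``selected``: additionally frequency <= infrequent_cutoff in the
    primary cohort.  Genes missing a cohort (or flagged) are skipped with a
    warning; the met-only filter needs only the metastatic cohort.
    """
    by_gene: dict[str, dict[str, GeneFrequency]] = {}
    for f in freqs:
        by_gene.setdefault(f.gene, {})[f.cohort] = f

    result = FilterResult()
    for gene, cohorts in sorted(by_gene.items()):
        met = cohorts.get(met_cohort)
        if met is None or met.flagged:
            result.skipped.add(gene)
            continue
        if met.frequency < frequent_cutoff:
            continue
        result.frequent_in_met.add(gene)
        prim = cohorts.get(primary_cohort)
        if prim is None or prim.flagged:
            result.skipped.add(gene)
            continue
        if prim.frequency <= infrequent_cutoff:
            result.selected.add(gene)
    if result.skipped:
        warnings.warn(
            f"genes missing a cohort, excluded from the combined filter: "
            f"{sorted(result.skipped)}",
            stacklevel=2,
        )
    return result


@lru_cache(maxsize=None)
def _hypergeom_numerators(
    n1: int, n2: int, k: int
) -> tuple[int, tuple[int, ...], int]:
    """Support lower bound, exact pmf numerators C(n1,x)*C(n2,k-x), and their sum."""
    lo, hi = max(0, k - n2), min(k, n1)
    nums = tuple(comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1))
    return lo, nums, sum(nums)  # sum == C(n1+n2, k) by Vandermonde


def differential_test(
    n_met_methylated: int,
    n_met_total: int,
    n_prim_methylated: int,
    n_prim_total: int,
) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 methylation table.

    Exact hypergeometric summation in integer arithmetic: the p-value is the
    total probability of tables (at fixed margins) no more likely than the
    observed one.  No continuity or asymptotic approximation.
    """
    for count, total, label in (
        (n_met_methylated, n_met_total, "metastatic"),
        (n_prim_methylated, n_prim_total, "primary"),
    ):
        if total <= 0:
            raise ValueError(f"{label} cohort total must be positive")
        if not (0 <= count <= total):
            raise ValueError(f"{label} count {count} outside [0, {total}]")

    k = n_met_methylated + n_prim_methylated
    lo, nums, total = _hypergeom_numerators(n_met_total, n_prim_total, k)
    observed = nums[n_met_methylated - lo]
    tail = sum(n for n in nums if n <= observed)
    return min(tail / total, 1.0)


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    freq_met: float
    freq_primary: float
    p_value: float
    selected: bool
    p_adjusted: float | None = None


def differential_results(
    freqs: Iterable[GeneFrequency],
    frequent_cutoff: float = FREQUENT_CUTOFF,
    infrequent_cutoff: float = INFREQUENT_CUTOFF,
    met_cohort: str = "metastasis",
    primary_cohort: str = "primary",
    adjust: str | None = None,
) -> list[DifferentialResult]:
    """Per-gene Fisher tests plus the frequency-filter verdicts.

    ``adjust="bh"`` adds Benjamini-Hochberg adjusted p-values; no adjustment
    is applied by default.  Genes lacking either cohort are omitted.
    """
    by_gene: dict[str, dict[str, GeneFrequency]] = {}
    for f in freqs:
        by_gene.setdefault(f.gene, {})[f.cohort] = f

    filt = apply_filters(
        (f for cohorts in by_gene.values() for f in cohorts.values()),
        frequent_cutoff,
        infrequent_cutoff,
        met_cohort,
        primary_cohort,
    )

    rows: list[DifferentialResult] = []
    for gene, cohorts in sorted(by_gene.items()):
        met, prim = cohorts.get(met_cohort), cohorts.get(primary_cohort)
        if met is None or prim is None or met.flagged or prim.flagged:
            continue
        p = differential_test(
            met.n_methylated, met.n_evaluable, prim.n_methylated, prim.n_evaluable
        )
        rows.append(
            DifferentialResult(
                gene=gene,
                freq_met=met.frequency,
                freq_primary=prim.frequency,
                p_value=p,
                selected=gene in filt.selected,
            )
        )
    if adjust == "bh" and rows:
        adjusted = false_discovery_control([r.p_value for r in rows], method="bh")
        rows = [
            DifferentialResult(
                r.gene, r.freq_met, r.freq_primary, r.p_value, r.selected, float(q)
            )
            for r, q in zip(rows, adjusted)
        ]
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return rows
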