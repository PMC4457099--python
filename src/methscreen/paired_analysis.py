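"""Epimutation timing from matched primary/metastasis call pairs.

For each gene, pairs are classified into both / met_only / primary_only /
neither; a gene is an *early* epimutation when primaries of methylated
metastases are themselves commonly methylated, and *late* when the
metastasis is methylated but the matched primary is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MatchedPair",
    "TimingSummary",
    "classify_pair",
    "summarize_timing",
    "summarize_all",
    "PAIR_CATEGORIES",
]

CALLS = ("methylated", "unmethylated", "failed")
PAIR_CATEGORIES = ("both", "met_only", "primary_only", "neither", "unevaluable")

EARLY = "early"
LATE = "late"
NONE = "none"
MIXED = "mixed"


@dataclass(frozen=True)
class MatchedPair:
    """Calls for one gene in one patient's primary tumour and metastasis.

    ``normal_call`` (adjacent normal tissue) is carried through for
    reporting but never used in the timing rule.
    """

    patient_id: str
    gene: str
    primary_call: str
    metastasis_call: str
    normal_call: str | None = None

    def __post_init__(self) -> None:
        for name in ("primary_call", "metastasis_call"):
            if getattr(self, name) not in CALLS:
                raise ValueError(f"invalid {name} {getattr(self, name)!r}")
        if self.normal_call is not None and self.normal_call not in CALLS:
            raise ValueError(f"invalid normal_call {self.normal_call!r}")


@dataclass(frozen=True)
class TimingSummary:
    gene: str
    n_pairs_evaluable: int
    n_both: int
    n_met_only: int
    n_primary_only: int
    n_neither: int
    gene_timing: str

    def __post_init__(self) -> None:
        if (
            self.n_both + self.n_met_only + self.n_primary_only + self.n_neither
            != self.n_pairs_evaluable
        ):
            raise ValueError("pair category counts must sum to n_pairs_evaluable")

    @property
    def n_met_methylated(self) -> int:
        """Evaluable pairs whose metastasis is methylated."""
        return self.n_both + self.n_met_only

    @property
    def n_primary_methylated(self) -> int:
        """Evaluable pairs whose primary tumour is methylated."""
        return self.n_both + self.n_primary_only


def classify_pair(pair: MatchedPair) -> str:
    """Concordance category of one matched pair; failed calls are unevaluable."""
    if pair.primary_call == "failed" or pair.metastasis_call == "failed":
        return "unevaluable"
    met = pair.metastasis_call == "methylated"
    prim = pair.primary_call == "methylated"
    if met and prim:
        return "both"
    if met:
        return "met_only"
    if prim:
        return "primary_only"
    return "neither"


def summarize_timing(
    pairs: Sequence[MatchedPair], early_frac: float = 0.5, late_frac: float = 0.5
) -> TimingSummary:
    """Classify one gene's epimutation timing from its matched pairs.

    Among pairs with a methylated metastasis, let f be the fraction whose
    primary is also methylated.  Timing is ``early`` if f >= early_frac
    (checked first, so f exactly at both boundaries resolves to early),
    ``late`` if f <= 1 - late_frac (met_only dominating), ``none`` when no
    metastasis is methylated, ``mixed`` otherwise.  All pairs must share a
    gene.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    genes = {p.gene for p in pairs}
    if len(genes) != 1:
        raise ValueError(f"pairs span multiple genes: {sorted(genes)}")
    gene = genes.pop()

    counts = {c: 0 for c in PAIR_CATEGORIES}
    for pair in pairs:
        counts[classify_pair(pair)] += 1
    evaluable = sum(counts[c] for c in ("both", "met_only", "primary_only", "neither"))
    if evaluable == 0:
        raise ValueError(f"gene {gene}: no evaluable pairs")

    met_meth = counts["both"] + counts["met_only"]
    if met_meth == 0:
        timing = NONE
    else:
        f = counts["both"] / met_meth
        if f >= early_frac:
            timing = EARLY
        elif f <= 1.0 - late_frac:
            timing = LATE
        else:
            timing = MIXED

    return TimingSummary(
        gene=gene,
        n_pairs_evaluable=evaluable,
        n_both=counts["both"],
        n_met_only=counts["met_only"],
        n_primary_only=counts["primary_only"],
        n_neither=counts["neither"],
        gene_timing=timing,
    )


def summarize_all(
    pairs: Iterable[MatchedPair], early_frac: float = 0.5, late_frac: float = 0.5
) -> dict[str, TimingSummary]:
    """Group pairs by gene and summarise each; genes with no evaluable pair raise."""
    by_gene: dict[str, list[MatchedPair]] = {}
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = (pair.patient_id, pair.gene)
        if key in seen:
            raise ValueError(f"duplicate (patient_id, gene) pair: {key}")
        seen.add(key)
        by_gene.setdefault(pair.gene, []).append(pair)
    return {
        gene: summarize_timing(gene_pairs, early_frac, late_frac)
        for gene, gene_pairs in sorted(by_gene.items())
    }
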