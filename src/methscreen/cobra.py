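"""In-silico combined bisulfite restriction analysis (CoBRA).

Converts an amplicon given per-CpG methylation states, scans the converted
top strand for restriction sites (BstUI ``CG^CG``, TaqI ``T^CGA``; both
palindromic, so the strand choice does not change site presence on
double-stranded PCR product) and binarises the digest into a categorical
methylation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ENZYMES",
    "MethylatedSequence",
    "DigestResult",
    "bisulfite_convert",
    "digest",
    "cobra_assay",
    "overall_call",
    "pool_call",
]

#: enzyme -> (recognition site on the converted strand, cut offset within site)
ENZYMES: dict[str, tuple[str, int]] = {
    "BstUI": ("CGCG", 2),
    "TaqI": ("TCGA", 1),
}

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MethylatedSequence:
    """An amplicon with per-CpG methylation states.

    ``cpg_positions`` holds the 0-based index of the C of each CpG on the
    given strand; ``methyl_states`` is parallel, each entry ``"methylated"``
    or ``"unmethylated"``.
    """

    seq: str
    cpg_positions: tuple[int, ...]
    methyl_states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        object.__setattr__(self, "methyl_states", tuple(self.methyl_states))
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        if len(self.cpg_positions) != len(self.methyl_states):
            raise ValueError("cpg_positions and methyl_states must be parallel")
        for state in self.methyl_states:
            if state not in (METHYLATED, UNMETHYLATED):
                raise ValueError(f"invalid methylation state {state!r}")
        for p in self.cpg_positions:
            if not (0 <= p < len(self.seq) - 1) or self.seq[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG in the sequence")

    @property
    def methylated_positions(self) -> frozenset[int]:
        return frozenset(
            p
            for p, s in zip(self.cpg_positions, self.methyl_states)
            if s == METHYLATED
        )


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one converted amplicon with one enzyme."""

    enzyme: str
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]
    call: str

    def __post_init__(self) -> None:
        if sum(self.fragment_lengths) and self.call not in (METHYLATED, UNMETHYLATED):
            raise ValueError(f"invalid call {self.call!r}")
        expected = METHYLATED if self.cut_positions else UNMETHYLATED
        if self.call != expected:
            raise ValueError("call must be methylated iff cut_positions non-empty")


def bisulfite_convert(
    ms: MethylatedSequence,
    conversion_error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Deaminate unprotected cytosines: C -> T unless at a methylated CpG.

    The default models complete conversion.  ``conversion_error_rate`` is the
    per-base probability that an unprotected C escapes conversion (requires
    ``rng`` when non-zero), for simulation realism only.
    """
    if conversion_error_rate and rng is None:
        raise ValueError("rng required when conversion_error_rate > 0")
    protected = ms.methylated_positions
    out = []
    for i, base in enumerate(ms.seq):
        if base != "C" or i in protected:
            out.append(base)
        elif conversion_error_rate and rng.random() < conversion_error_rate:
            out.append("C")
        else:
            out.append("T")
    return "".join(out)


def digest(converted: str, enzyme: str) -> DigestResult:
    """Predict restriction fragments of the converted top strand.

    All site occurrences are counted, including overlapping ones; the call
    is ``methylated`` iff at least one cut is made.
    """
    if not converted:
        raise ValueError("cannot digest an empty sequence")
    converted = converted.upper()
    bad = set(converted) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    try:
        site, offset = ENZYMES[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}") from None

    cuts = sorted(
        {
            i + offset
            for i in range(len(converted) - len(site) + 1)
            if converted[i : i + len(site)] == site
        }
    )
    bounds = [0, *cuts, len(converted)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
    return DigestResult(
        enzyme=enzyme,
        cut_positions=tuple(cuts),
        fragment_lengths=fragments,
        call=METHYLATED if cuts else UNMETHYLATED,
    )


def cobra_assay(
    ms: MethylatedSequence, enzymes: Iterable[str] = ("BstUI", "TaqI")
) -> dict[str, DigestResult]:
    """Convert once, digest with each enzyme; see :func:`overall_call`."""
    converted = bisulfite_convert(ms)
    return {enzyme: digest(converted, enzyme) for enzyme in sorted(set(enzymes))}


def overall_call(results: Mapping[str, DigestResult]) -> str:
    """Methylated if any enzyme cut the amplicon."""
    if not results:
        raise ValueError("no digest results")
    return (
        METHYLATED
        if any(r.call == METHYLATED for r in results.values())
        else UNMETHYLATED
    )


def pool_call(allele_cut: Sequence[bool], min_cut_fraction: float = 0.25) -> str:
    """Semi-quantitative call over a pool of alleles.

    The gel readout is qualitative; the pool is scored methylated when the
    fraction of cut alleles exceeds ``min_cut_fraction`` (strict).
    """
    flags = list(allele_cut)
    if not flags:
        raise ValueError("empty allele pool")
    fraction = sum(bool(f) for f in flags) / len(flags)
    return METHYLATED if fraction > min_cut_fraction else UNMETHYLATED
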