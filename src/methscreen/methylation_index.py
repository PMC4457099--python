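"""Methylation index (MI) from clone bisulfite-sequencing matrices.

MI is a micro-average: the total number of methylated CpG dinucleotides over
all clones, as a percentage of all informative CpGs, pooled across clones and
positions.  Bands: MI >= 60 methylated, MI < 40 unmethylated, [40, 60)
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CloneMatrix",
    "MIResult",
    "AllMissingError",
    "compute_mi",
    "classify_mi",
    "mi_concordance",
    "MI_METHYLATED_MIN",
    "MI_UNMETHYLATED_MAX",
]

MI_METHYLATED_MIN = 60.0  # MI >= this -> methylated
MI_UNMETHYLATED_MAX = 40.0  # MI < this -> unmethylated

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"


class AllMissingError(ValueError):
    """Raised when a clone matrix carries no informative states."""


@dataclass
class CloneMatrix:
    """Clones x CpG-position states for one amplicon in one sample.

    ``states`` is a float matrix with 1.0 = methylated, 0.0 = unmethylated,
    NaN = missing (failed base call).
    """

    gene: str
    sample: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or 0 in self.states.shape:
            raise ValueError("states must be a non-empty 2-D clones x CpGs matrix")
        finite = self.states[~np.isnan(self.states)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("states must be 0, 1 or NaN")

    @property
    def n_clones(self) -> int:
        return self.states.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class MIResult:
    mi: float
    n_informative: int
    classification: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.mi <= 100.0):
            raise ValueError(f"MI {self.mi} outside [0, 100]")
        if self.classification != classify_mi(self.mi):
            raise ValueError(
                f"classification {self.classification!r} inconsistent with MI {self.mi}"
            )


def classify_mi(mi: float) -> str:
    """Band an MI percentage: [60,100] methylated, [40,60) ambiguous, [0,40) unmethylated."""
    if mi >= MI_METHYLATED_MIN:
        return METHYLATED
    if mi < MI_UNMETHYLATED_MAX:
        return UNMETHYLATED
    return AMBIGUOUS


def compute_mi(cm: CloneMatrix) -> MIResult:
    """Pool all clone x CpG states into one MI percentage."""
    informative = ~np.isnan(cm.states)
    n = int(informative.sum())
    if n == 0:
        raise AllMissingError(
            f"clone matrix {cm.gene}/{cm.sample} has no informative states"
        )
    n_meth = int(np.nansum(cm.states))
    mi = 100.0 * n_meth / n
    return MIResult(mi=mi, n_informative=n, classification=classify_mi(mi))


def mi_concordance(
    mi_results: Sequence[MIResult], cobra_calls: Sequence[str]
) -> float:
    """Fraction of samples where the CoBRA call matches the MI band.

    Concordant iff both are methylated or both unmethylated; an ambiguous MI
    is discordant with either CoBRA call.
    """
    if len(mi_results) != len(cobra_calls):
        raise ValueError("mi_results and cobra_calls must have equal length")
    if not mi_results:
        raise ValueError("empty input")
    agree = 0
    for mi_res, call in zip(mi_results, cobra_calls):
        if call not in (METHYLATED, UNMETHYLATED):
            raise ValueError(f"invalid CoBRA call {call!r}")
        if mi_res.classification == AMBIGUOUS:
            continue
        if mi_res.classification == call:
            agree += 1
    return agree / len(mi_results)
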