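"""Bundled reference dataset for a breast-to-brain metastasis (BBM) screen.

Desk-scale validation data: the per-gene methylation frequencies observed in
a 30-tumour metastatic cohort and a 40-tumour independent primary cohort, the
matched primary/metastasis pair calls for the three differential genes, and
clone matrices at the methylation-index values observed for CoBRA-positive
and CoBRA-negative promoters.  Frequencies are percentages of evaluable
samples; per-gene denominators are nominal cohort sizes.
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import GeneFrequency
from .methylation_index import CloneMatrix
from .paired_analysis import MatchedPair

__all__ = [
    "MET_COHORT_SIZE",
    "PRIMARY_COHORT_SIZE",
    "MET_FREQUENCIES",
    "PRIMARY_FREQUENCIES",
    "reference_frequencies",
    "reference_pairs",
    "reference_clone_matrix",
    "REFERENCE_MI_VALUES",
]

MET_COHORT_SIZE = 30
PRIMARY_COHORT_SIZE = 40

#: percent of evaluable metastatic tumours methylated, per gene (21 genes,
#: all at or above the 50% frequent cutoff)
MET_FREQUENCIES: dict[str, float] = {
    "CLDN18": 100.0,
    "KRT85": 100.0,
    "MIR127": 100.0,
    "MIR433": 100.0,
    "HOXD3": 100.0,
    "MIR23B": 92.0,
    "KRT83": 84.0,
    "HOXB13": 80.0,
    "ABCB1": 80.0,
    "PENK": 80.0,
    "MST1R": 78.0,
    "CCDC8": 73.0,
    "PCDH8": 73.0,
    "BNC1": 71.0,
    "STAT3": 67.0,
    "BVES": 64.0,
    "TNFRSF10D": 60.0,
    "CLDN6": 55.0,
    "HOXD10": 55.0,
    "GALNT9": 55.0,
    "WIF1": 53.0,
}

#: percent of evaluable independent primary tumours methylated, per gene;
#: only GALNT9, BNC1 and CCDC8 fall at or below the 45% infrequent cutoff
PRIMARY_FREQUENCIES: dict[str, float] = {
    "GALNT9": 0.0,
    "BNC1": 17.0,
    "CCDC8": 40.0,
    "HOXD3": 81.0,
    "HOXB13": 53.0,
    "ABCB1": 68.0,
    "PCDH8": 54.0,
    "PENK": 79.0,
    "STAT3": 57.0,
    "TNFRSF10D": 75.0,
    "WIF1": 55.0,
    "CLDN18": 100.0,
    "KRT85": 100.0,
    "MIR127": 100.0,
    "MIR433": 100.0,
    "MIR23B": 60.0,
    "KRT83": 100.0,
    "MST1R": 60.0,
    "BVES": 60.0,
    "CLDN6": 50.0,
    "HOXD10": 55.0,
}


def reference_frequencies() -> list[GeneFrequency]:
    """Both cohorts' per-gene frequency records.

    Exact per-gene denominators were not recorded (some assays failed per
    gene), so counts are back-computed from the nominal cohort size; the
    filters compare the ``frequency`` field itself.
    """
    out: list[GeneFrequency] = []
    for gene, pct in MET_FREQUENCIES.items():
        out.append(
            GeneFrequency(
                gene=gene,
                cohort="metastasis",
                n_evaluable=MET_COHORT_SIZE,
                n_methylated=round(pct * MET_COHORT_SIZE / 100),
                frequency=pct,
            )
        )
    for gene, pct in PRIMARY_FREQUENCIES.items():
        out.append(
            GeneFrequency(
                gene=gene,
                cohort="primary",
                n_evaluable=PRIMARY_COHORT_SIZE,
                n_methylated=round(pct * PRIMARY_COHORT_SIZE / 100),
                frequency=pct,
            )
        )
    return out


def _pairs(gene: str, spec: list[tuple[str, str]]) -> list[MatchedPair]:
    return [
        MatchedPair(f"patient_{i + 1:02d}", gene, prim, met)
        for i, (prim, met) in enumerate(spec)
    ]


def reference_pairs() -> list[MatchedPair]:
    """Matched primary/metastasis calls for the three differential genes.

    BNC1: 8 evaluable pairs, metastasis methylated in all 8, primary in 1
    (2 further pairs failed amplification).  GALNT9: 5 evaluable pairs,
    metastasis methylated in 3, primary in none (5 failed).  CCDC8: 11
    evaluable pairs, both tumours methylated in 10.
    """
    m, u, f = "methylated", "unmethylated", "failed"
    bnc1 = _pairs("BNC1", [(m, m)] + [(u, m)] * 7 + [(f, m)] * 2)
    galnt9 = _pairs("GALNT9", [(u, m)] * 3 + [(u, u)] * 2 + [(f, u)] * 5)
    ccdc8 = _pairs("CCDC8", [(m, m)] * 10 + [(u, u)])
    return bnc1 + galnt9 + ccdc8


#: MI percentages observed for CoBRA-positive (60-91) and CoBRA-negative
#: (0-36) promoters, with their expected band
REFERENCE_MI_VALUES: dict[float, str] = {
    60.0: "methylated",
    91.0: "methylated",
    0.0: "unmethylated",
    36.0: "unmethylated",
}


def reference_clone_matrix(mi_percent: float) -> CloneMatrix:
    """A 10-clone x 10-CpG matrix with exactly the requested integer MI."""
    if not float(mi_percent).is_integer() or not (0 <= mi_percent <= 100):
        raise ValueError("mi_percent must be an integer percentage in [0, 100]")
    states = np.zeros(100)
    states[: int(mi_percent)] = 1.0
    return CloneMatrix(
        gene="REF", sample=f"mi{int(mi_percent)}", states=states.reshape(10, 10)
    )
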