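"""Seeded generators for every pipeline input, with recorded ground truth.

Beta matrices are drawn from a two-component Beta mixture straddling the
screen thresholds; amplicons are GC-rich with guaranteed restriction-site
precursors; clone matrices are i.i.d. Bernoulli at a chosen true MI; paired
cohorts plant early/late/none timing structure with configurable call noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .array_screen import BetaMatrix, IslandRelation, ProbeAnnotation
from .cobra import MethylatedSequence
from .cohort_stats import CallRecord, CallTable
from .methylation_index import CloneMatrix
from .paired_analysis import MatchedPair

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_beta_matrix",
    "simulate_screen_inputs",
    "simulate_promoter",
    "simulate_clones",
    "simulate_paired_cohort",
]

MET_COHORT = "metastasis"
PRIMARY_COHORT = "primary"


def _default_planted() -> list[tuple[str, str]]:
    return [
        ("EARLY1", "early"),
        ("EARLY2", "early"),
        ("LATE1", "late"),
        ("LATE2", "late"),
        ("NONE1", "none"),
        ("NONE2", "none"),
        ("NONE3", "none"),
        ("NONE4", "none"),
    ]


@dataclass(frozen=True)
class SimConfig:
    """All knobs for the synthetic generators; the seed fixes every draw."""

    seed: int = 0
    n_probes: int = 200
    n_samples_per_cohort: dict[str, int] = field(
        default_factory=lambda: {MET_COHORT: 30, PRIMARY_COHORT: 40}
    )
    planted_genes: tuple[tuple[str, str], ...] = field(
        default_factory=lambda: tuple(_default_planted())
    )
    beta_unmeth_params: tuple[float, float] = (2.0, 8.0)
    beta_meth_params: tuple[float, float] = (8.0, 2.0)
    #: optional uniform ranges overriding the Beta components, for
    #: complete-separation experiments, e.g. (0.0, 0.15) / (0.8, 1.0)
    unmeth_range: tuple[float, float] | None = None
    meth_range: tuple[float, float] | None = None
    clone_count: int = 10
    cpg_count: int = 20
    conversion_error_rate: float = 0.0
    missing_beta_rate: float = 0.0
    call_flip_rate: float = 0.02
    pairs_per_gene: int = 10
    amplicon_length: int = 300

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_genes", tuple(map(tuple, self.planted_genes)))
        for gene, timing in self.planted_genes:
            if timing not in ("early", "late", "none"):
                raise ValueError(f"invalid planted timing {timing!r} for {gene}")

    @property
    def candidate_genes(self) -> set[str]:
        """Genes planted with differential (early or late) methylation."""
        return {g for g, t in self.planted_genes if t != "none"}

    @property
    def timing_labels(self) -> dict[str, str]:
        return dict(self.planted_genes)


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery checks."""

    probe_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    candidate_probes: set[str] = field(default_factory=set)
    candidate_genes: set[str] = field(default_factory=set)
    gene_timing: dict[str, str] = field(default_factory=dict)
    pair_calls: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    true_mi: dict[tuple[str, str], float] = field(default_factory=dict)


def _draw_beta(
    rng: np.random.Generator, methylated: bool, cfg: SimConfig, size: int
) -> np.ndarray:
    if methylated:
        if cfg.meth_range is not None:
            return rng.uniform(*cfg.meth_range, size=size)
        return rng.beta(*cfg.beta_meth_params, size=size)
    if cfg.unmeth_range is not None:
        return rng.uniform(*cfg.unmeth_range, size=size)
    return rng.beta(*cfg.beta_unmeth_params, size=size)


def _probe_layout(cfg: SimConfig) -> tuple[list[ProbeAnnotation], dict[str, dict[str, float]], set[str]]:
    """Deterministic annotation plus per-cohort methylated-sample prevalence.

    One planted promoter-island probe per candidate gene (prevalence 0 in the
    primary-like cohort, 1 in the metastatic-like cohort); background probes
    share a prevalence across cohorts so they cannot pass both screens, and a
    slice of them is non-promoter or off-island.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    candidates = sorted(cfg.candidate_genes)
    if cfg.n_probes < len(candidates) + 1:
        raise ValueError("n_probes too small for the planted genes")

    annotation: list[ProbeAnnotation] = []
    prevalence: dict[str, dict[str, float]] = {}
    planted_probes: set[str] = set()

    for i, gene in enumerate(candidates):
        probe_id = f"cg_planted_{i:04d}"
        annotation.append(
            ProbeAnnotation(
                probe_id=probe_id,
                gene_symbols=(gene,),
                tss_groups=("TSS200",),
                island_relation=IslandRelation.ISLAND,
            )
        )
        prevalence[probe_id] = {PRIMARY_COHORT: 0.0, MET_COHORT: 1.0}
        planted_probes.add(probe_id)

    groups = ("TSS200", "TSS1500", "Body", "5'UTR", "3'UTR", "1stExon")
    islands = (
        IslandRelation.ISLAND,
        IslandRelation.SHORE,
        IslandRelation.SHELF,
        IslandRelation.OPEN_SEA,
    )
    n_background = cfg.n_probes - len(candidates)
    for j in range(n_background):
        probe_id = f"cg_bg_{j:05d}"
        shared = float(rng.uniform())
        annotation.append(
            ProbeAnnotation(
                probe_id=probe_id,
                gene_symbols=(f"BG{j:05d}",),
                tss_groups=(groups[j % len(groups)],),
                island_relation=islands[j % len(islands)],
            )
        )
        prevalence[probe_id] = {PRIMARY_COHORT: shared, MET_COHORT: shared}
    return annotation, prevalence, planted_probes


def simulate_annotation(cfg: SimConfig) -> list[ProbeAnnotation]:
    return _probe_layout(cfg)[0]


def simulate_beta_matrix(
    cfg: SimConfig, cohort: str, prevalence: dict[str, float] | None = None
) -> tuple[BetaMatrix, GroundTruth]:
    """Draw one cohort's beta matrix from the planted probe layout.

    Per probe, each sample is methylated with the probe's cohort prevalence
    and its beta drawn from the corresponding mixture component.
    """
    annotation, layout_prev, planted = _probe_layout(cfg)
    if prevalence is None:
        prevalence = {p: v.get(cohort, 0.0) for p, v in layout_prev.items()}
    n_samples = cfg.n_samples_per_cohort.get(cohort)
    if n_samples is None:
        raise ValueError(f"cohort {cohort!r} not in n_samples_per_cohort")

    # string hash must be stable across processes, so not builtin hash()
    rng = np.random.default_rng((cfg.seed, zlib.crc32(cohort.encode()), 1))
    probe_ids = [a.probe_id for a in annotation]
    values = np.empty((len(probe_ids), n_samples))
    for i, probe_id in enumerate(probe_ids):
        p = prevalence[probe_id]
        meth = rng.random(n_samples) < p
        row = _draw_beta(rng, False, cfg, n_samples)
        if meth.any():
            row[meth] = _draw_beta(rng, True, cfg, int(meth.sum()))
        if cfg.missing_beta_rate:
            row[rng.random(n_samples) < cfg.missing_beta_rate] = np.nan
        values[i] = row

    matrix = BetaMatrix(
        cohort_label=cohort,
        probe_ids=probe_ids,
        sample_ids=[f"{cohort}_s{j:03d}" for j in range(n_samples)],
        values=values,
    )
    truth = GroundTruth(
        probe_prevalence={p: {cohort: prevalence[p]} for p in probe_ids},
        candidate_probes=set(planted),
        candidate_genes=set(cfg.candidate_genes),
        gene_timing=cfg.timing_labels,
    )
    return matrix, truth


def simulate_screen_inputs(
    cfg: SimConfig,
) -> tuple[list[ProbeAnnotation], dict[str, BetaMatrix], GroundTruth]:
    """Annotation plus both cohorts' beta matrices and joint ground truth."""
    annotation, layout_prev, planted = _probe_layout(cfg)
    matrices: dict[str, BetaMatrix] = {}
    for cohort in (PRIMARY_COHORT, MET_COHORT):
        matrices[cohort], _ = simulate_beta_matrix(
            cfg, cohort, {p: v[cohort] for p, v in layout_prev.items()}
        )
    truth = GroundTruth(
        probe_prevalence=layout_prev,
        candidate_probes=planted,
        candidate_genes=set(cfg.candidate_genes),
        gene_timing=cfg.timing_labels,
    )
    return annotation, matrices, truth


def simulate_promoter(
    cfg: SimConfig, mi: float = 1.0, rng: np.random.Generator | None = None
) -> MethylatedSequence:
    """A GC-rich amplicon guaranteed to contain CGCG and a TCGA site.

    Both guaranteed motifs overlap CpGs, so a fully methylated allele always
    digests and a fully unmethylated one never does.  Per-CpG states are
    Bernoulli(mi).
    """
    if not (0.0 <= mi <= 1.0):
        raise ValueError("mi must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 202)
    length = max(cfg.amplicon_length, 40)
    bases = rng.choice(list("ACGT"), size=length, p=[0.2, 0.3, 0.3, 0.2])
    seq = list("".join(bases))
    # splice guaranteed motifs away from the ends and each other
    seq[10:14] = "CGCG"
    seq[20:24] = "TCGA"
    s = "".join(seq)

    cpg_positions = tuple(i for i in range(len(s) - 1) if s[i : i + 2] == "CG")
    if mi >= 1.0:
        states = tuple("methylated" for _ in cpg_positions)
    elif mi <= 0.0:
        states = tuple("unmethylated" for _ in cpg_positions)
    else:
        draws = rng.random(len(cpg_positions)) < mi
        states = tuple("methylated" if d else "unmethylated" for d in draws)
    return MethylatedSequence(seq=s, cpg_positions=cpg_positions, methyl_states=states)


def simulate_clones(
    cfg: SimConfig,
    true_mi: float,
    missing_rate: float = 0.0,
    gene: str = "GENE",
    sample: str = "S1",
    rng: np.random.Generator | None = None,
) -> CloneMatrix:
    """Clone states i.i.d. Bernoulli(true_mi) per clone x CpG."""
    if not (0.0 <= true_mi <= 1.0):
        raise ValueError("true_mi must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 303)
    states = (
        rng.random((cfg.clone_count, cfg.cpg_count)) < true_mi
    ).astype(float)
    if missing_rate:
        mask = rng.random(states.shape) < missing_rate
        states[mask] = np.nan
    return CloneMatrix(gene=gene, sample=sample, states=states)


def _noisy(call: str, flip_rate: float, rng: np.random.Generator) -> str:
    if flip_rate and rng.random() < flip_rate:
        return "unmethylated" if call == "methylated" else "methylated"
    return call


def simulate_paired_cohort(
    cfg: SimConfig,
) -> tuple[CallTable, list[MatchedPair], GroundTruth]:
    """Call tables for both cohorts plus matched pairs with planted timing.

    Early genes are methylated in both tumours of metastasising patients,
    late genes in the metastasis only, none genes nowhere; the independent
    primary cohort is unmethylated for all planted genes.  Every call is
    flipped independently with ``call_flip_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 404)
    records: list[CallRecord] = []
    pairs: list[MatchedPair] = []
    truth = GroundTruth(
        candidate_genes=set(cfg.candidate_genes), gene_timing=cfg.timing_labels
    )

    n_met = cfg.n_samples_per_cohort.get(MET_COHORT, 30)
    n_prim = cfg.n_samples_per_cohort.get(PRIMARY_COHORT, 40)
    for gene, timing in cfg.planted_genes:
        met_base = "methylated" if timing in ("early", "late") else "unmethylated"
        for j in range(n_met):
            records.append(
                CallRecord(
                    sample_id=f"met_s{j:03d}",
                    cohort=MET_COHORT,
                    gene=gene,
                    call=_noisy(met_base, cfg.call_flip_rate, rng),
                )
            )
        for j in range(n_prim):
            records.append(
                CallRecord(
                    sample_id=f"prim_s{j:03d}",
                    cohort=PRIMARY_COHORT,
                    gene=gene,
                    call=_noisy("unmethylated", cfg.call_flip_rate, rng),
                )
            )
        for j in range(cfg.pairs_per_gene):
            true_met = met_base
            true_prim = "methylated" if timing == "early" else "unmethylated"
            truth.pair_calls[(f"patient_{j:02d}", gene)] = (true_prim, true_met)
            pairs.append(
                MatchedPair(
                    patient_id=f"patient_{j:02d}",
                    gene=gene,
                    primary_call=_noisy(true_prim, cfg.call_flip_rate, rng),
                    metastasis_call=_noisy(true_met, cfg.call_flip_rate, rng),
                )
            )
    return CallTable(records=records), pairs, truth
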