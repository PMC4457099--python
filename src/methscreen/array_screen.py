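"""Genome-wide promoter probe screen on beta-value matrices.

Filters array probes to promoter-associated groups, applies prevalence
screens (infrequently methylated in one cohort, frequently methylated in
another), intersects the surviving probe sets, collapses probes to genes
and gates candidates on CpG-island membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "IslandRelation",
    "ProbeAnnotation",
    "BetaMatrix",
    "ScreenConfig",
    "ScreenResult",
    "UnevaluableProbeError",
    "filter_promoter_probes",
    "prevalence_fraction",
    "screen_cohort",
    "intersect_and_collapse",
    "run_screen",
]

#: Manifest-style probe location groups relative to the nearest transcript.
KNOWN_TSS_GROUPS = frozenset(
    {"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "TSS"}
)

#: Loose "TSS" tokens found in some annotation exports; treated as a member
#: of either fine-grained TSS group (see ScreenConfig.accepted_tss_groups).
TSS_ALIAS = "TSS"
TSS_ALIAS_EXPANSION = frozenset({"TSS200", "TSS1500"})


class IslandRelation(str, Enum):
    """Relation of a probe to the nearest CpG island."""

    ISLAND = "Island"
    SHORE = "Shore"
    SHELF = "Shelf"
    OPEN_SEA = "OpenSea"


class UnevaluableProbeError(ValueError):
    """Raised when a probe has no informative (non-missing) beta values."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """One array probe: identity, gene mapping and genomic context.

    ``tss_groups[i]`` annotates ``gene_symbols[i]``; both lists may be empty
    for unannotated probes.
    """

    probe_id: str
    gene_symbols: tuple[str, ...] = ()
    tss_groups: tuple[str, ...] = ()
    island_relation: IslandRelation = IslandRelation.OPEN_SEA

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbols", tuple(self.gene_symbols))
        object.__setattr__(self, "tss_groups", tuple(self.tss_groups))
        if len(self.gene_symbols) != len(self.tss_groups):
            raise ValueError(
                f"probe {self.probe_id}: gene_symbols ({len(self.gene_symbols)}) "
                f"and tss_groups ({len(self.tss_groups)}) must have equal length"
            )
        if not isinstance(self.island_relation, IslandRelation):
            object.__setattr__(
                self, "island_relation", IslandRelation(self.island_relation)
            )


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions for one cohort.

    Missing values are ``NaN``; all non-missing values must lie in [0, 1].
    """

    cohort_label: str
    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe_id in beta matrix")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def subset(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        """Row-subset in the given order; unknown probes raise KeyError."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        wanted = list(probe_ids)
        missing = [p for p in wanted if p not in index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        rows = [index[p] for p in wanted]
        return BetaMatrix(
            cohort_label=self.cohort_label,
            probe_ids=wanted,
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
        )


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the two-cohort prevalence screen.

    All comparisons are inclusive: beta <= unmeth_beta_max counts as
    unmethylated, beta >= meth_beta_min as methylated, and prevalence is
    compared with >= against the sample fractions.
    """

    unmeth_beta_max: float = 0.25
    unmeth_sample_frac: float = 0.75
    meth_beta_min: float = 0.60
    meth_sample_frac: float = 0.50
    accepted_tss_groups: frozenset[str] = frozenset({"TSS200", "TSS1500"})
    require_island: bool = True
    #: probes with fewer informative samples than this fraction are dropped
    #: as unevaluable rather than screened on a biased denominator.
    min_informative_frac: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "accepted_tss_groups", frozenset(self.accepted_tss_groups)
        )
        if not (0.0 <= self.unmeth_beta_max < self.meth_beta_min <= 1.0):
            raise ValueError(
                "need 0 <= unmeth_beta_max < meth_beta_min <= 1, got "
                f"{self.unmeth_beta_max} / {self.meth_beta_min}"
            )
        for name in ("unmeth_sample_frac", "meth_sample_frac"):
            frac = getattr(self, name)
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {frac}")


@dataclass
class ScreenResult:
    """Per-stage probe/gene sets and counts for one two-cohort screen."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    unmeth_probes: set[str] = field(default_factory=set)
    meth_probes: set[str] = field(default_factory=set)
    intersect_probes: set[str] = field(default_factory=set)
    candidate_genes: set[str] = field(default_factory=set)
    dropped_no_island: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.intersect_probes <= self.unmeth_probes:
            raise ValueError("intersect_probes must be a subset of unmeth_probes")
        if not self.intersect_probes <= self.meth_probes:
            raise ValueError("intersect_probes must be a subset of meth_probes")
        if self.candidate_genes & self.dropped_no_island:
            raise ValueError("candidate_genes and dropped_no_island overlap")

    def to_dict(self) -> dict:
        return {
            "stage_counts": dict(self.stage_counts),
            "unmeth_probes": sorted(self.unmeth_probes),
            "meth_probes": sorted(self.meth_probes),
            "intersect_probes": sorted(self.intersect_probes),
            "candidate_genes": sorted(self.candidate_genes),
            "dropped_no_island": sorted(self.dropped_no_island),
        }


def _group_accepted(group: str, accepted: frozenset[str]) -> bool:
    if group == TSS_ALIAS:
        return bool(accepted & TSS_ALIAS_EXPANSION)
    return group in accepted


def filter_promoter_probes(
    annotation: Iterable[ProbeAnnotation], config: ScreenConfig | None = None
) -> set[str]:
    """Return probe ids with at least one TSS group in the accepted set.

    Unknown group strings trigger a warning and never qualify a probe.
    """
    config = config or ScreenConfig()
    annotation = list(annotation)
    if not annotation:
        raise ValueError("annotation must be non-empty")
    selected: set[str] = set()
    unknown: set[str] = set()
    for probe in annotation:
        for group in probe.tss_groups:
            if group not in KNOWN_TSS_GROUPS:
                unknown.add(group)
                continue
            if _group_accepted(group, config.accepted_tss_groups):
                selected.add(probe.probe_id)
                break
    if unknown:
        warnings.warn(
            f"unknown TSS group(s) treated as non-promoter: {sorted(unknown)}",
            stacklevel=2,
        )
    return selected


def prevalence_fraction(
    beta_row: Sequence[float] | np.ndarray, threshold: float, direction: str
) -> float:
    """Fraction of informative samples whose beta satisfies the comparison.

    ``direction`` is ``"at_most"`` (<= threshold) or ``"at_least"``
    (>= threshold); missing (NaN) values are excluded from numerator and
    denominator alike.
    """
    row = np.asarray(beta_row, dtype=float)
    informative = ~np.isnan(row)
    n = int(informative.sum())
    if n == 0:
        raise UnevaluableProbeError("all beta values missing for probe row")
    vals = row[informative]
    if direction == "at_most":
        hits = int(np.count_nonzero(vals <= threshold))
    elif direction == "at_least":
        hits = int(np.count_nonzero(vals >= threshold))
    else:
        raise ValueError(f"direction must be 'at_most' or 'at_least', got {direction!r}")
    return hits / n


def screen_cohort(
    matrix: BetaMatrix, mode: str, config: ScreenConfig | None = None
) -> set[str]:
    """Select probes passing the prevalence screen for one cohort.

    ``mode="unmethylated"``: beta <= unmeth_beta_max in >= unmeth_sample_frac
    of informative samples.  ``mode="methylated"``: beta >= meth_beta_min in
    >= meth_sample_frac.  Probes with fewer than ``min_informative_frac``
    informative samples are excluded as unevaluable.
    """
    config = config or ScreenConfig()
    if mode == "unmethylated":
        threshold, direction, frac = (
            config.unmeth_beta_max,
            "at_most",
            config.unmeth_sample_frac,
        )
    elif mode == "methylated":
        threshold, direction, frac = (
            config.meth_beta_min,
            "at_least",
            config.meth_sample_frac,
        )
    else:
        raise ValueError(f"mode must be 'unmethylated' or 'methylated', got {mode!r}")

    selected: set[str] = set()
    n_samples = matrix.n_samples
    informative_counts = (~np.isnan(matrix.values)).sum(axis=1)
    for i, probe_id in enumerate(matrix.probe_ids):
        if informative_counts[i] == 0:
            continue
        if n_samples and informative_counts[i] / n_samples < config.min_informative_frac:
            continue
        if prevalence_fraction(matrix.values[i], threshold, direction) >= frac:
            selected.add(probe_id)
    return selected


def _as_annotation_map(
    annotation: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation],
) -> dict[str, ProbeAnnotation]:
    if isinstance(annotation, Mapping):
        return dict(annotation)
    out: dict[str, ProbeAnnotation] = {}
    for probe in annotation:
        if probe.probe_id in out:
            raise ValueError(f"duplicate probe_id in annotation: {probe.probe_id}")
        out[probe.probe_id] = probe
    return out


def intersect_and_collapse(
    unmeth: set[str],
    meth: set[str],
    annotation: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation],
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Intersect cohort probe sets, fan out to genes and gate on islands.

    A probe annotating k genes contributes to all k.  When
    ``config.require_island`` a gene whose intersecting probes all sit
    outside a CpG island is moved to ``dropped_no_island``.
    """
    config = config or ScreenConfig()
    ann = _as_annotation_map(annotation)
    for probe_id in unmeth | meth:
        if probe_id not in ann:
            raise KeyError(f"probe {probe_id} absent from annotation")

    intersect = unmeth & meth
    gene_probes: dict[str, set[str]] = {}
    for probe_id in intersect:
        for gene in ann[probe_id].gene_symbols:
            gene_probes.setdefault(gene, set()).add(probe_id)

    all_genes = set(gene_probes)
    dropped: set[str] = set()
    if config.require_island:
        for gene, probes in gene_probes.items():
            if all(
                ann[p].island_relation is not IslandRelation.ISLAND for p in probes
            ):
                dropped.add(gene)
    candidates = all_genes - dropped

    result = ScreenResult(
        stage_counts={
            "unmeth_probes": len(unmeth),
            "meth_probes": len(meth),
            "intersect_probes": len(intersect),
            "genes": len(all_genes),
            "dropped_no_island": len(dropped),
            "candidate_genes": len(candidates),
        },
        unmeth_probes=set(unmeth),
        meth_probes=set(meth),
        intersect_probes=intersect,
        candidate_genes=candidates,
        dropped_no_island=dropped,
    )
    return result


def run_screen(
    annotation: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation],
    unmeth_matrix: BetaMatrix,
    meth_matrix: BetaMatrix,
    config: ScreenConfig | None = None,
) -> ScreenResult:
    """Full screen: promoter filter, two cohort screens, intersect, collapse.

    The promoter filter is applied before the prevalence screens; for audit
    the stage counts also record the prevalence-pass counts computed without
    the promoter restriction (the two orders commute on the intersection).
    """
    config = config or ScreenConfig()
    ann = _as_annotation_map(annotation)
    promoter = filter_promoter_probes(ann.values(), config)

    unmeth_all = screen_cohort(unmeth_matrix, "unmethylated", config)
    meth_all = screen_cohort(meth_matrix, "methylated", config)
    unmeth = unmeth_all & promoter
    meth = meth_all & promoter

    result = intersect_and_collapse(unmeth, meth, ann, config)
    counts = {
        "annotation_probes": len(ann),
        "promoter_probes": len(promoter),
        "unmeth_probes_unfiltered": len(unmeth_all),
        "meth_probes_unfiltered": len(meth_all),
    }
    counts.update(result.stage_counts)
    result.stage_counts = counts
    return result
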