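"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..array_screen import ScreenConfig
from ..cohort_stats import FREQUENT_CUTOFF, INFREQUENT_CUTOFF
from ..synthetic_data import SimConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]

log = logging.getLogger("methscreen")


@dataclass
class PipelineConfig:
    """Umbrella configuration for the whole pipeline."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    frequent_cutoff: float = FREQUENT_CUTOFF
    infrequent_cutoff: float = INFREQUENT_CUTOFF
    mi_methylated_min: float = 60.0
    mi_unmethylated_max: float = 40.0
    cobra_enzymes: tuple[str, ...] = ("BstUI", "TaqI")
    cobra_min_cut_fraction: float = 0.25
    early_frac: float = 0.5
    late_frac: float = 0.5
    log_level: str = "INFO"
    output_dir: str = "results"

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["screen"]["accepted_tss_groups"] = sorted(
            self.screen.accepted_tss_groups
        )
        out["sim"]["planted_genes"] = [list(pg) for pg in self.sim.planted_genes]
        out["cobra_enzymes"] = list(self.cobra_enzymes)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "screen" in data:
            screen = dict(data["screen"])
            if "accepted_tss_groups" in screen:
                screen["accepted_tss_groups"] = frozenset(screen["accepted_tss_groups"])
            data["screen"] = ScreenConfig(**screen)
        if "sim" in data:
            sim = dict(data["sim"])
            for key in ("planted_genes",):
                if key in sim:
                    sim[key] = tuple(tuple(x) for x in sim[key])
            for key in ("beta_unmeth_params", "beta_meth_params", "unmeth_range", "meth_range"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            data["sim"] = SimConfig(**sim)
        if "cobra_enzymes" in data:
            data["cobra_enzymes"] = tuple(data["cobra_enzymes"])
        return cls(**data)

    def configure_logging(self) -> None:
        logging.basicConfig(level=getattr(logging, self.log_level.upper(), logging.INFO))
        log.info(
            "thresholds: beta<=%.2f in >=%d%%, beta>=%.2f in >=%d%%, "
            "frequent>=%s%%, infrequent<=%s%%, MI bands [%s, %s)",
            self.screen.unmeth_beta_max,
            round(100 * self.screen.unmeth_sample_frac),
            self.screen.meth_beta_min,
            round(100 * self.screen.meth_sample_frac),
            self.frequent_cutoff,
            self.infrequent_cutoff,
            self.mi_unmethylated_max,
            self.mi_methylated_min,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
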