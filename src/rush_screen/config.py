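"""Schema-validated run configuration (YAML), mirroring each stage's
parameters. Unknown keys are rejected so typos cannot silently fall back to
defaults; every default is therefore auditable from the model definitions."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    k_release: float = 0.014978661367769954  # ln(20)/200 per minute
    t_lag: float = 40.0
    leak_fraction: float = 0.02
    baseline_gfp: float = 8000.0


class NoiseConfig(_Strict):
    background_level: float = 200.0
    shot_scale: float = 0.1
    read_sigma: float = 10.0
    illum_gradient: float = 0.2


class LayoutConfig(_Strict):
    height: int = 256
    width: int = 256
    n_cells: int = 50
    gfp_sigma: float = 0.25
    dna_sigma: float = 0.15


class CompoundConfig(_Strict):
    compound_id: str
    f_max: float = 1.0
    ec50: float = 1.0
    toxicity: float = 0.0


class SimulateConfig(_Strict):
    """Planted screen: explicit compounds plus bulk inactive filler."""

    compounds: list[CompoundConfig] = Field(default_factory=list)
    n_inactive: int = 0
    n_neg: int = 20
    n_pos: int = 6
    n_no_biotin: int = 6
    low_dose: float = 1.0
    high_dose: float = 10.0
    t_screen: float = 60.0
    fields_per_well: int = 1
    kinetics: KineticsConfig = KineticsConfig()
    noise: NoiseConfig = NoiseConfig()
    layout: LayoutConfig = LayoutConfig()
    write_images: bool = False


class SegmentConfig(_Strict):
    smooth_sigma: float = 1.5
    background_radius: int = 25
    min_nucleus_area: int = 20
    max_nucleus_area: int = 800
    min_seed_distance: int = 5
    cyto_max_radius: float = 12.0
    gfp_foreground_method: str = "halfmax"
    illumination_model: str = "none"
    write_masks: bool = False


class QuantifyConfig(_Strict):
    min_cells: int = 10


class ScoreConfig(_Strict):
    min_viability: float = 0.5
    reference: str = "controls"  # controls | samples


class HitsConfig(_Strict):
    K: int = 20
    z_other: float = 1.0
    rescue: bool = True
    both_mode: str = "threshold"


class RunConfig(_Strict):
    """Top-level pipeline configuration.

    ``simulate`` may be omitted when segmenting pre-existing images from
    ``images_dir`` + ``platemap``.
    """

    seed: int = 0
    out_dir: str = "results"
    images_dir: str | None = None
    platemap: str | None = None
    simulate: SimulateConfig | None = None
    segment: SegmentConfig = SegmentConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    score: ScoreConfig = ScoreConfig()
    hits: HitsConfig = HitsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)
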