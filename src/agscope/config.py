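"""Pipeline configuration.

All defaults are the study's printed analysis constants: the mean + 3*SD
activity-threshold multiplier, Pc/PL sorting thresholds of 1.1 and 6.0,
sorting accuracy 0.983 with reported SD 0.017 at 500 cells/h, enrichment
alpha 0.05 with 999 PERMANOVA permutations, and two-sided Student's
t-tests at p < 0.05.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class BandConfig(BaseModel):
    lower: float
    upper: float


class BandsConfig(BaseModel):
    cd: BandConfig = BandConfig(lower=2040.0, upper=2300.0)
    ch: BandConfig = BandConfig(lower=2800.0, upper=3100.0)
    phe: BandConfig = BandConfig(lower=990.0, upper=1015.0)
    cell_band: BandConfig = BandConfig(lower=1620.0, upper=1670.0)
    pl_ref: BandConfig = BandConfig(lower=1850.0, upper=1900.0)


class ActivityConfig(BaseModel):
    snr_min: float = 3.0
    threshold_sd_multiplier: float = 3.0
    control_condition: str = "water"
    per_donor_threshold: bool = False


class SortConfig(BaseModel):
    pc_min: float = 1.1
    pl_min: float = 6.0
    accuracy: float = Field(0.983, ge=0.0, le=1.0)
    accuracy_sd: float = 0.017
    throughput: float = Field(500.0, gt=0.0)
    cultivation_p: float = Field(0.1, ge=0.0, le=1.0)


class EnrichmentConfig(BaseModel):
    alpha: float = 0.05
    n_perm: int = 999
    treatment: str = "AG"
    timepoint: float = 6.0


class GrowthConfig(BaseModel):
    alpha: float = 0.05
    blank_correct: bool = True
    welch: bool = False


class PipelineConfig(BaseModel):
    """Aggregated stage configuration plus global seed and paths."""

    bands: BandsConfig = BandsConfig()
    activity: ActivityConfig = ActivityConfig()
    sort: SortConfig = SortConfig()
    enrichment: EnrichmentConfig = EnrichmentConfig()
    growth: GrowthConfig = GrowthConfig()
    seed: int = 0
    out_dir: str = "agscope_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def band_definitions(self):
        from .spectra import Band, BandDefinitions

        b = self.bands
        return BandDefinitions(
            cd=Band(b.cd.lower, b.cd.upper),
            ch=Band(b.ch.lower, b.ch.upper),
            phe=Band(b.phe.lower, b.phe.upper),
            cell_band=Band(b.cell_band.lower, b.cell_band.upper),
            pl_ref=Band(b.pl_ref.lower, b.pl_ref.upper),
        )
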