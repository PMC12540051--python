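"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, so each stage is
testable end to end without external data:

* Raman spectra with Gaussian C-D (2,170 cm^-1), C-H (2,950 cm^-1),
  phenylalanine (1,003 cm^-1) and amide (1,650 cm^-1) bands at a
  controllable true %CD, plus linear baseline drift and white noise.  On
  the noise-free signal the trapezoid band-integral ratio
  CD/(CD+CH) equals the requested cd_fraction_true.
* Donor-structured genus count tables: donor-specific baseline
  compositions drawn log-normally, one treated and one no-amendment
  sample per donor and timepoint sampled multinomially at fixed depth,
  with planted fold-change enrichments in treated samples only.
* Logistic OD600 growth curves with lag and noise, or a flat no-growth
  baseline.
* Log-linear qPCR dilution series (triplicate wells per level).
* Isolate census tables, defaulting to the reference study's species
  composition.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import IsolateRecord, STUDY_COMPOSITION, STUDY_TAXONOMY
from .enrichment import AbundanceTable
from .growth import GrowthCurveSet, QpcrRun
from .spectra import RamanSpectrum

__all__ = [
    "SpectrumSimSpec",
    "CommunitySimSpec",
    "GrowthSimSpec",
    "gen_spectrum",
    "gen_community",
    "gen_growth_curves",
    "gen_qpcr_series",
    "gen_isolate_census",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Gaussian band centers (cm^-1) and default FWHM (cm^-1)
_PEAKS = {
    "cd": (2170.0, 40.0),
    "ch": (2950.0, 40.0),
    "phe": (1003.0, 12.0),
    "amide": (1650.0, 30.0),
}

# every band the pipeline integrates must exist on the simulated grid
_REQUIRED_SPAN = (990.0, 3100.0)


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Ground-truth description of one simulated cell spectrum.

    cd_fraction_true is the %CD the noise-free spectrum encodes;
    total_ch_cd_area is the summed C-D + C-H band area (intensity * cm^-1)
    split between the two bands accordingly.
    """

    cd_fraction_true: float = 0.0
    total_ch_cd_area: float = 1000.0
    phe_area: float = 50.0
    amide_area: float = 100.0
    noise_sd: float = 0.0
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0
    wavenumber_range: tuple[float, float] = (400.0, 3200.0)
    step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cd_fraction_true <= 100.0:
            raise ValueError("cd_fraction_true must lie in [0, 100]")
        if self.total_ch_cd_area <= 0:
            raise ValueError("total_ch_cd_area must be positive")
        if self.phe_area < 0 or self.amide_area < 0 or self.noise_sd < 0:
            raise ValueError("areas and noise_sd must be non-negative")
        if self.step <= 0:
            raise ValueError("step must be positive")


def gen_spectrum(
    spec: SpectrumSimSpec,
    cell_id: str = "",
    donor: str = "",
    condition: str = "",
    timepoint: float = float("nan"),
) -> RamanSpectrum:
    """Simulate one cell's Raman spectrum from a ground-truth spec.

    The C-D and C-H Gaussians carry areas f * total and (1 - f) * total
    with f = cd_fraction_true / 100, so the noise-free band-integral
    ratio reproduces the true %CD.  The wavenumber range must cover
    990-3,100 cm^-1 so all analysis bands exist.
    """
    lo, hi = spec.wavenumber_range
    if lo > _REQUIRED_SPAN[0] or hi < _REQUIRED_SPAN[1]:
        missing = []
        if lo > _REQUIRED_SPAN[0]:
            missing.append("phenylalanine (~1,000 cm^-1)")
        if hi < _REQUIRED_SPAN[1]:
            missing.append("C-H stretch (2,800-3,100 cm^-1)")
        raise ValueError(
            f"wavenumber range {spec.wavenumber_range} does not cover required "
            f"band(s): {', '.join(missing)}"
        )
    wn = np.arange(lo, hi + 0.5 * spec.step, spec.step)
    f = spec.cd_fraction_true / 100.0
    areas = {
        "cd": f * spec.total_ch_cd_area,
        "ch": (1.0 - f) * spec.total_ch_cd_area,
        "phe": spec.phe_area,
        "amide": spec.amide_area,
    }
    signal = np.zeros_like(wn)
    for name, (center, fwhm) in _PEAKS.items():
        sigma = fwhm * _FWHM_TO_SIGMA
        amp = areas[name] / (sigma * np.sqrt(2.0 * np.pi))
        signal += amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2)
    baseline = spec.baseline_offset + spec.baseline_slope * wn
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, wn.size) if spec.noise_sd > 0 else 0.0
    return RamanSpectrum(
        wavenumbers=wn,
        intensities=signal + baseline + noise,
        cell_id=cell_id,
        donor=donor,
        condition=condition,
        timepoint=timepoint,
    )


@dataclass(frozen=True)
class CommunitySimSpec:
    """Design of a simulated multi-donor incubation experiment.

    One treated and one NA control sample per donor and timepoint, drawn
    multinomially at ``depth`` reads from donor-specific baseline
    proportions (log-normal around shared genus means, donor spread
    ``donor_logmean_sd``).  ``enriched_genera`` are 1-based genus indices
    whose proportions are multiplied by ``effect_multiplier`` (then
    renormalized) in treated samples only.
    """

    n_donors: int = 10
    n_genera: int = 30
    depth: int = 50_000
    donor_logmean_sd: float = 1.0
    enriched_genera: frozenset[int] = frozenset()
    effect_multiplier: float = 1.0
    treatment: str = "AG"
    timepoints: tuple[float, ...] = (6.0,)
    include_baseline: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        bad = [i for i in self.enriched_genera if not 1 <= i <= self.n_genera]
        if bad:
            raise ValueError(
                f"enriched genus indices out of range 1..{self.n_genera}: {sorted(bad)}"
            )


def gen_community(spec: CommunitySimSpec) -> AbundanceTable:
    """Simulate a donor-structured genus count table with planted effects.

    Column sums equal ``depth`` exactly for every sample.  With
    ``include_baseline`` one NA sample per donor at 0 h is added so
    baseline relative abundances exist for reporting.
    """
    rng = np.random.default_rng(spec.seed)
    genus_names = [f"g{i:03d}" for i in range(1, spec.n_genera + 1)]
    genus_logmean = rng.normal(0.0, 1.0, spec.n_genera)
    enriched_mask = np.zeros(spec.n_genera, dtype=bool)
    for i in spec.enriched_genera:
        enriched_mask[i - 1] = True

    rows, meta_rows, index = [], [], []

    def add_sample(p: np.ndarray, donor: str, treatment: str, tp: float) -> None:
        counts = rng.multinomial(spec.depth, p / p.sum())
        sid = f"{donor}_{treatment}_t{tp:g}"
        rows.append(counts)
        meta_rows.append({"donor": donor, "treatment": treatment, "timepoint": tp})
        index.append(sid)

    for d in range(1, spec.n_donors + 1):
        donor = f"D{d:02d}"
        offsets = rng.normal(0.0, spec.donor_logmean_sd, spec.n_genera)
        base = np.exp(genus_logmean + offsets)
        base /= base.sum()
        treated = base * np.where(enriched_mask, spec.effect_multiplier, 1.0)
        treated /= treated.sum()
        if spec.include_baseline:
            add_sample(base, donor, "NA", 0.0)
        for tp in spec.timepoints:
            add_sample(base, donor, "NA", float(tp))
            add_sample(treated, donor, spec.treatment, float(tp))

    counts = pd.DataFrame(rows, index=index, columns=genus_names)
    meta = pd.DataFrame(meta_rows, index=index)
    return AbundanceTable(counts=counts, sample_meta=meta)


@dataclass(frozen=True)
class GrowthSimSpec:
    """Logistic growth-curve simulation: OD(t) = K / (1 + exp(-r(t - lag)))."""

    carrying_capacity: float = 1.0  # OD600
    rate: float = 0.5  # per hour
    lag: float = 5.0  # hours
    duration: float = 48.0  # hours
    interval: float = 0.5  # hours
    noise_sd: float = 0.01  # OD600
    n_replicates: int = 3
    baseline_od: float = 0.05  # flat level when not boosted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def gen_growth_curves(
    spec: GrowthSimSpec, boosted: bool, strain: str = "strain", condition: str | None = None
) -> GrowthCurveSet:
    """Simulate replicate OD600 curves, logistic (boosted) or flat baseline."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.interval, spec.interval)
    if boosted:
        mean = spec.carrying_capacity / (1.0 + np.exp(-spec.rate * (t - spec.lag)))
    else:
        mean = np.full_like(t, spec.baseline_od)
    noise = rng.normal(0.0, spec.noise_sd, (spec.n_replicates, t.size)) if spec.noise_sd > 0 else 0.0
    od = np.broadcast_to(mean, (spec.n_replicates, t.size)) + noise
    if condition is None:
        condition = "AG" if boosted else "NA"
    return GrowthCurveSet(strain=strain, condition=condition, times=t, od600=np.atleast_2d(od))


def gen_qpcr_series(
    copies: Sequence[float],
    slope: float = -3.3219,
    intercept: float = 40.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_wells: int = 3,
) -> QpcrRun:
    """Simulate a dilution-series qPCR run: Cq = slope*log10(copies) + intercept.

    Each dilution level is measured in ``n_wells`` replicate wells with
    additive Gaussian Cq noise.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(list(copies), dtype=float)
    if (levels <= 0).any():
        raise ValueError("template copies must be positive")
    records = []
    for c in levels:
        for w in range(n_wells):
            cq = slope * np.log10(c) + intercept
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            records.append({"copies": c, "cq": cq, "replicate": w + 1})
    return QpcrRun(wells=pd.DataFrame(records))


def gen_isolate_census(
    composition: Mapping[str, int] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    n_donors: int = 10,
    seed: int = 0,
) -> list[IsolateRecord]:
    """Build isolate records from a species -> count composition.

    Defaults to the reference study's 98-strain composition and taxonomy.
    Donors are assigned round-robin; the record order is shuffled by the
    seed (ids stay attached), which leaves every census summary invariant.
    """
    composition = dict(STUDY_COMPOSITION if composition is None else composition)
    taxonomy = dict(STUDY_TAXONOMY if taxonomy is None else taxonomy)
    missing = sorted(s for s in composition if s not in taxonomy)
    if missing:
        raise ValueError(f"species without a phylum in the taxonomy: {missing}")
    records = []
    k = 0
    for species in composition:
        for _ in range(composition[species]):
            k += 1
            records.append(
                IsolateRecord(
                    isolate_id=f"I{k:03d}",
                    species=species,
                    phylum=taxonomy[species],
                    donor=f"D{(k - 1) % n_donors + 1:02d}",
                )
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]
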