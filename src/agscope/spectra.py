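"""Single-cell Raman activity scoring via deuterium incorporation.

Metabolically active cells incubated in heavy water form carbon-deuterium
bonds, which appear as a C-D stretch band (2,040-2,300 cm^-1) in the
otherwise silent region of the Raman spectrum.  The per-cell activity score
%CD is the C-D band area as a percentage of the summed C-D and C-H
(2,800-3,100 cm^-1) band areas.  Cells are called metabolically active when
their %CD exceeds a threshold fitted on water-control cells (no D2O):
mean + 3 * sample SD.

All band quantities are trapezoidal integrals of the intensity after
subtracting a straight baseline through the band's endpoint intensities,
which makes %CD invariant to intensity scaling and to any linear baseline
drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RamanSpectrum",
    "Band",
    "BandDefinitions",
    "ActivityResult",
    "ActivityThreshold",
    "integrate_band",
    "is_valid_spectrum",
    "compute_cd_fraction",
    "fit_activity_threshold",
    "classify_active",
    "compare_activity",
]


@dataclass(frozen=True)
class RamanSpectrum:
    """One cell's wavenumber/intensity trace with provenance metadata.

    Wavenumbers must be strictly increasing (cm^-1); intensities are in
    arbitrary units and must match in length.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    cell_id: str = ""
    donor: str = ""
    condition: str = ""
    timepoint: float = float("nan")

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])


@dataclass(frozen=True)
class Band:
    """A wavenumber window [lower, upper] in cm^-1."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"band lower bound must be < upper ({self.lower} >= {self.upper})")


@dataclass(frozen=True)
class BandDefinitions:
    """The spectral windows used throughout the analysis.

    cd
        C-D stretch, 2,040-2,300 cm^-1 (deuterium labeling).
    ch
        C-H stretch, 2,800-3,100 cm^-1 (total organic signal).
    phe
        Phenylalanine ring-breathing peak near 1,000 cm^-1
        (990-1,015 by default), required for a spectrum to count as cellular.
    cell_band
        1,620-1,670 cm^-1, the window the sorter integrates to detect a
        cell in the measurement volume (Pc).
    pl_ref
        1,850-1,900 cm^-1 silent reference region (PL denominator and
        noise estimation).
    """

    cd: Band = field(default_factory=lambda: Band(2040.0, 2300.0))
    ch: Band = field(default_factory=lambda: Band(2800.0, 3100.0))
    phe: Band = field(default_factory=lambda: Band(990.0, 1015.0))
    cell_band: Band = field(default_factory=lambda: Band(1620.0, 1670.0))
    pl_ref: Band = field(default_factory=lambda: Band(1850.0, 1900.0))


@dataclass
class ActivityResult:
    """Per-cell activity record: %CD plus validity and (optionally) the call."""

    cell_id: str
    cd_fraction: float
    valid: bool = True
    active: bool | None = None
    threshold_used: float | None = None
    donor: str = ""
    condition: str = ""
    timepoint: float = float("nan")


@dataclass(frozen=True)
class ActivityThreshold:
    """Water-control activity threshold: mean + 3 * sample SD of control %CD."""

    mean_control: float
    sd_control: float
    threshold: float
    n_control: int


def _band_slice(spectrum: RamanSpectrum, band: Band) -> slice:
    lo, hi = spectrum.range
    if band.lower < lo or band.upper > hi:
        raise ValueError(
            f"band [{band.lower}, {band.upper}] cm^-1 lies outside the "
            f"spectrum range [{lo}, {hi}] cm^-1"
        )
    i0 = int(np.searchsorted(spectrum.wavenumbers, band.lower, side="left"))
    i1 = int(np.searchsorted(spectrum.wavenumbers, band.upper, side="right"))
    if i1 - i0 < 2:
        raise ValueError(
            f"fewer than 2 spectral points inside band [{band.lower}, {band.upper}] cm^-1"
        )
    return slice(i0, i1)


# fraction of window points averaged at each edge to anchor the baseline;
# averaging suppresses noise that a single endpoint sample would propagate
# across the whole window
_ANCHOR_FRAC = 0.1


def _endpoint_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Straight line through the window's averaged edge regions.

    Exact for any linear input (the mean of a line over a region equals
    the line at the region's centroid), so linear drift still cancels.
    """
    k = max(1, int(round(_ANCHOR_FRAC * x.size)))
    x0, y0 = float(np.mean(x[:k])), float(np.mean(y[:k]))
    x1, y1 = float(np.mean(x[-k:])), float(np.mean(y[-k:]))
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


def integrate_band(
    spectrum: RamanSpectrum, band: Band, *, baseline: bool = True
) -> float:
    """Trapezoidal band area, optionally after endpoint-baseline correction.

    With ``baseline=True`` (the default) a straight line anchored on the
    window's averaged edge regions is subtracted and negative corrected
    intensities are clipped to zero before integration, so any constant
    offset or linear drift contributes nothing.  With ``baseline=False``
    the raw trapezoidal integral is returned (used by the sorter's
    real-time indices).
    """
    sl = _band_slice(spectrum, band)
    x = spectrum.wavenumbers[sl]
    y = spectrum.intensities[sl]
    if baseline:
        y = np.clip(y - _endpoint_baseline(x, y), 0.0, None)
    return float(np.trapezoid(y, x))


def _peak_height(spectrum: RamanSpectrum, band: Band) -> float:
    """Maximum intensity above the window's endpoint baseline."""
    sl = _band_slice(spectrum, band)
    x = spectrum.wavenumbers[sl]
    y = spectrum.intensities[sl]
    return float(np.max(y - _endpoint_baseline(x, y)))


def _noise_estimate(spectrum: RamanSpectrum, band: Band) -> float:
    """Robust noise scale: 1.4826 * MAD of endpoint-detrended residuals."""
    sl = _band_slice(spectrum, band)
    x = spectrum.wavenumbers[sl]
    y = spectrum.intensities[sl]
    resid = y - _endpoint_baseline(x, y)
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def is_valid_spectrum(
    spectrum: RamanSpectrum,
    bands: BandDefinitions | None = None,
    snr_min: float = 3.0,
) -> bool:
    """Whether a spectrum shows clear cellular signal.

    Valid means both the C-H stretch and the phenylalanine peak rise above
    the window baseline by more than ``snr_min`` times a robust noise
    estimate taken from the silent reference region.  A degenerate flat or
    all-zero spectrum is invalid (never an error).
    """
    bands = bands or BandDefinitions()
    noise = _noise_estimate(spectrum, bands.pl_ref)
    ch_h = _peak_height(spectrum, bands.ch)
    phe_h = _peak_height(spectrum, bands.phe)
    return ch_h > snr_min * noise and phe_h > snr_min * noise


def compute_cd_fraction(
    spectrum: RamanSpectrum, bands: BandDefinitions | None = None
) -> float:
    """%CD = 100 * I_CD / (I_CD + I_CH), band integrals baseline-corrected.

    Raises ValueError when both band integrals are zero (no cellular
    signal to ratio).
    """
    bands = bands or BandDefinitions()
    i_cd = integrate_band(spectrum, bands.cd)
    i_ch = integrate_band(spectrum, bands.ch)
    total = i_cd + i_ch
    if total <= 0.0:
        raise ValueError("no C-D or C-H signal: cannot compute %CD")
    return 100.0 * i_cd / total


def fit_activity_threshold(control_cds: Sequence[float]) -> ActivityThreshold:
    """Fit the activity threshold from water-control %CD values.

    threshold = mean + 3 * sample SD (n-1 denominator).  At least two
    control values are required.
    """
    vals = np.asarray(list(control_cds), dtype=float)
    if vals.size < 2:
        raise ValueError("at least 2 water-control %CD values are required")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return ActivityThreshold(
        mean_control=mean, sd_control=sd, threshold=mean + 3.0 * sd, n_control=int(vals.size)
    )


def classify_active(
    results: Sequence[ActivityResult], threshold: ActivityThreshold
) -> list[ActivityResult]:
    """Call cells active when %CD strictly exceeds the control threshold.

    Invalid spectra are excluded from classification (their ``active``
    stays None) but are retained in the output, flagged via ``valid``.
    """
    out: list[ActivityResult] = []
    for r in results:
        if not r.valid:
            out.append(replace(r, active=None, threshold_used=None))
            continue
        out.append(
            replace(
                r,
                active=r.cd_fraction > threshold.threshold,
                threshold_used=threshold.threshold,
            )
        )
    return out


def compare_activity(groups: Mapping[str, Sequence[float]]):
    """One-way ANOVA of %CD across condition groups (cells pooled over donors).

    Returns the F statistic and p-value.  Each group needs >= 2 values and
    there must be >= 2 groups.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 condition groups")
    arrays = []
    for name, vals in groups.items():
        a = np.asarray(list(vals), dtype=float)
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        arrays.append(a)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
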