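"""In-silico Raman-activated cell sorting (RACS).

The sorter measures each cell's spectrum in a microfluidic channel and
routes it to a collection or waste outlet based on two real-time indices:

* Pc (cell index) — integrated 1,620-1,670 cm^-1 signal of the cell
  spectrum relative to the surrounding medium; Pc near 1 means no cell is
  in the measurement volume.
* PL (labeling index) — ratio of the C-D stretch (2,040-2,300 cm^-1) to a
  silent reference region (1,850-1,900 cm^-1); large PL means deuterium
  labeling.

Both indices use raw (non-baseline-subtracted) trapezoidal integrals, as a
real-time sorter would, which is also what makes the control-derived
thresholds (Pc = 1.1, PL = 6.0) meaningful.  A cell is collected only when
both indices strictly exceed their thresholds.

The run simulator applies the platform's published accuracy and throughput
figures: each decided cell is misdirected independently with probability
1 - accuracy, duration is n/throughput, and each collected cell yields a
colony with a per-run cultivation probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .spectra import BandDefinitions, RamanSpectrum, integrate_band

__all__ = [
    "SortIndices",
    "SortThresholds",
    "SortRunConfig",
    "SortRunReport",
    "compute_sort_indices",
    "decide_sort",
    "simulate_sort_run",
    "cultivation_success_rate",
]

# floor for ratio denominators on degenerate spectra (intensity-area units)
_EPS = 1e-12

Decision = Literal["collect", "waste"]


@dataclass(frozen=True)
class SortIndices:
    pc: float
    pl: float
    cell_id: str = ""


@dataclass(frozen=True)
class SortThresholds:
    """Control-derived sorting thresholds (glucose, no D2O)."""

    pc_min: float = 1.1
    pl_min: float = 6.0

    def __post_init__(self) -> None:
        if self.pc_min <= 0 or self.pl_min <= 0:
            raise ValueError("sort thresholds must be positive")


@dataclass(frozen=True)
class SortRunConfig:
    """Platform model for a sorting run.

    accuracy is the probability a decided cell reaches its intended
    outlet; accuracy_sd records the reported run-to-run variability of
    that figure (carried as metadata, not applied as jitter).  throughput
    is in cells per hour.  cultivation_p is the probability a correctly
    collected cell yields a colony on the post-sort plate.
    """

    accuracy: float = 0.983
    accuracy_sd: float = 0.017
    throughput: float = 500.0
    cultivation_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy", "cultivation_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.throughput <= 0:
            raise ValueError("throughput must be positive")


@dataclass(frozen=True)
class SortRunReport:
    n_analyzed: int
    n_collected: int
    n_waste: int
    n_misdirected: int
    n_colonies: int
    duration: float  # hours
    success_rate: float  # percent; NaN when nothing was collected


def compute_sort_indices(
    cell_spectrum: RamanSpectrum,
    background_spectrum: RamanSpectrum,
    bands: BandDefinitions | None = None,
) -> SortIndices:
    """Compute Pc and PL for one cell against the medium background.

    Pc = raw cell-band integral of the cell spectrum over the same
    integral of the background; PL = raw C-D integral over the raw
    reference-region integral, both on the cell spectrum.  Denominators
    are floored at a small epsilon; a background cell-band integral that
    is non-positive even after flooring is an error (no medium signal to
    normalize against).
    """
    bands = bands or BandDefinitions()
    bg = integrate_band(background_spectrum, bands.cell_band, baseline=False)
    if bg <= 0.0:
        raise ValueError("background cell-band integral is non-positive")
    cell = integrate_band(cell_spectrum, bands.cell_band, baseline=False)
    cd = integrate_band(cell_spectrum, bands.cd, baseline=False)
    ref = integrate_band(cell_spectrum, bands.pl_ref, baseline=False)
    pc = max(cell, 0.0) / max(bg, _EPS)
    pl = max(cd, 0.0) / max(ref, _EPS)
    return SortIndices(pc=pc, pl=pl, cell_id=cell_spectrum.cell_id)


def decide_sort(indices: SortIndices, thresholds: SortThresholds | None = None) -> Decision:
    """Collect iff Pc > pc_min AND PL > pl_min (both strict)."""
    thresholds = thresholds or SortThresholds()
    if indices.pc > thresholds.pc_min and indices.pl > thresholds.pl_min:
        return "collect"
    return "waste"


def simulate_sort_run(
    decisions: Sequence[Decision], config: SortRunConfig | None = None
) -> SortRunReport:
    """Simulate one sorting run over a sequence of collect/waste decisions.

    Each decided cell is misdirected (sent to the other outlet) with
    probability 1 - accuracy, independently.  Colonies are drawn
    Binomial(n_collected, cultivation_p).  Cells are conserved:
    n_collected + n_waste = n_analyzed for every seed.
    """
    config = config or SortRunConfig()
    if len(decisions) == 0:
        raise ValueError("decisions must be non-empty")
    bad = {d for d in decisions if d not in ("collect", "waste")}
    if bad:
        raise ValueError(f"unknown decisions: {sorted(bad)!r}")
    rng = np.random.default_rng(config.seed)
    intended = np.array([d == "collect" for d in decisions], dtype=bool)
    mis = rng.random(intended.size) < (1.0 - config.accuracy)
    actual = intended ^ mis
    n_analyzed = int(intended.size)
    n_collected = int(np.count_nonzero(actual))
    n_misdirected = int(np.count_nonzero(mis))
    n_colonies = int(rng.binomial(n_collected, config.cultivation_p)) if n_collected else 0
    success = 100.0 * n_colonies / n_collected if n_collected > 0 else float("nan")
    return SortRunReport(
        n_analyzed=n_analyzed,
        n_collected=n_collected,
        n_waste=n_analyzed - n_collected,
        n_misdirected=n_misdirected,
        n_colonies=n_colonies,
        duration=n_analyzed / config.throughput,
        success_rate=success,
    )


def cultivation_success_rate(n_colonies: int, n_sorted: int) -> float:
    """Percentage of colonies recovered relative to labeled cells sorted."""
    if n_sorted <= 0:
        raise ValueError("n_sorted must be positive")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    return 100.0 * n_colonies / n_sorted
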