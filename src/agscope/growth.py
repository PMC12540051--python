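"""Substrate-dependent growth and coculture cross-feeding quantification.

Growth responses of isolates to a carbon amendment are summarized by the
AUC growth boost: the ratio of the mean area under the OD600 growth curve
in amended medium to the mean area in the no-amendment control, with a
two-sided Student's t-test on the per-replicate AUCs (n = 3 + 3 by
default).  Cross-feeding in cocultures with a polysaccharide degrader is
quantified absolutely by strain-specific qPCR against a 10-fold dilution
standard curve, reported as log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurveSet",
    "GrowthBoostResult",
    "QpcrRun",
    "QpcrStandardCurve",
    "CocultureResult",
    "auc_trapezoid",
    "growth_boost",
    "fit_standard_curve",
    "quantify",
    "l2fc",
    "coculture_analysis",
]


@dataclass
class GrowthCurveSet:
    """Replicate OD600 growth curves for one strain under one condition.

    ``times`` (hours, strictly increasing) are shared across replicates;
    ``od600`` is a replicates x timepoints array.
    """

    strain: str
    condition: str
    times: np.ndarray
    od600: np.ndarray  # shape (n_replicates, n_timepoints)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.atleast_2d(np.asarray(self.od600, dtype=float))
        if t.ndim != 1 or od.shape[1] != t.size:
            raise ValueError("od600 must be (replicates, len(times))")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)):
            raise ValueError("OD values must be finite")
        self.times = t
        self.od600 = od

    @property
    def n_replicates(self) -> int:
        return int(self.od600.shape[0])


@dataclass
class GrowthBoostResult:
    strain: str
    auc_treated: np.ndarray  # per replicate, OD*h
    auc_control: np.ndarray
    boost: float  # ratio of mean AUCs; NaN when control mean is 0
    t_stat: float
    p: float
    significant: bool


@dataclass
class QpcrRun:
    """qPCR wells: known template copies (standards) and measured Cq."""

    wells: pd.DataFrame  # columns: copies, cq, replicate


@dataclass(frozen=True)
class QpcrStandardCurve:
    """Least-squares fit Cq = slope * log10(copies) + intercept.

    A valid assay has slope < 0; amplification efficiency is
    10^(-1/slope) - 1 (1.0 = 100% for the ideal slope -3.3219).
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class CocultureResult:
    strain: str
    l2fc_co: float  # 24 h vs 0 h within the coculture arm
    l2fc_mono: float  # 24 h vs 0 h within the monoculture arm
    l2fc_co_vs_mono: float  # cross-arm, 24 h coculture vs 24 h monoculture
    t_stat: float  # coculture vs monoculture 24 h abundances
    p: float
    significant: bool
    degrader_l2fc: float | None = None  # focal degrader's own 24h-vs-0h L2FC in coculture


def auc_trapezoid(
    times: Sequence[float], values: Sequence[float], blank: float = 0.0
) -> float:
    """Trapezoidal area under an OD curve (OD*h).

    ``blank`` is subtracted first and negative corrected values are
    clipped to zero.  Requires >= 2 strictly increasing timepoints.
    """
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing without duplicates")
    corrected = np.clip(v - blank, 0.0, None)
    return float(np.trapezoid(corrected, t))


def growth_boost(
    treated: GrowthCurveSet,
    control: GrowthCurveSet,
    alpha: float = 0.05,
    blank_correct: bool = True,
    welch: bool = False,
) -> GrowthBoostResult:
    """AUC growth boost of amended vs no-amendment medium.

    boost = mean(AUC_treated) / mean(AUC_control) on per-replicate AUCs;
    significance by a two-sided Student's t-test on the replicate AUCs
    (equal-variance by default, Welch with ``welch=True``).  With
    ``blank_correct`` each replicate's first-timepoint OD is subtracted as
    its blank.  A zero mean control AUC leaves the boost NaN (flagged).
    """
    if treated.n_replicates < 2 or control.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")

    def aucs(cs: GrowthCurveSet) -> np.ndarray:
        return np.array(
            [
                auc_trapezoid(cs.times, row, blank=row[0] if blank_correct else 0.0)
                for row in cs.od600
            ]
        )

    auc_t = aucs(treated)
    auc_c = aucs(control)
    boost = float(auc_t.mean() / auc_c.mean()) if auc_c.mean() > 0 else float("nan")
    t_stat, p = stats.ttest_ind(auc_t, auc_c, equal_var=not welch)
    return GrowthBoostResult(
        strain=treated.strain,
        auc_treated=auc_t,
        auc_control=auc_c,
        boost=boost,
        t_stat=float(t_stat),
        p=float(p),
        significant=bool(p < alpha),
    )


def fit_standard_curve(run: QpcrRun) -> QpcrStandardCurve:
    """Fit the standard curve from a serial-dilution run.

    Requires >= 3 distinct dilution levels with known copies; a fitted
    slope >= 0 means the assay is invalid (Cq must fall as template
    rises).
    """
    wells = run.wells
    levels = np.unique(wells["copies"].to_numpy(dtype=float))
    if levels.size < 3:
        raise ValueError("need >= 3 dilution levels to fit a standard curve")
    if (levels <= 0).any():
        raise ValueError("standard copies must be positive")
    x = np.log10(wells["copies"].to_numpy(dtype=float))
    y = wells["cq"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"non-negative slope ({fit.slope:.3g}): invalid assay")
    return QpcrStandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify(cq, curve: QpcrStandardCurve):
    """Absolute copies from a Cq value: 10^((cq - intercept) / slope)."""
    cq_arr = np.asarray(cq, dtype=float)
    copies = 10.0 ** ((cq_arr - curve.intercept) / curve.slope)
    return float(copies) if np.isscalar(cq) else copies


def l2fc(after: float, before: float, pseudocount: float = 0.0) -> float:
    """log2((after + pseudocount) / (before + pseudocount))."""
    if after < 0 or before < 0 or pseudocount < 0:
        raise ValueError("abundances and pseudocount must be non-negative")
    num = after + pseudocount
    den = before + pseudocount
    if num <= 0 or den <= 0:
        raise ValueError("zero abundance with zero pseudocount: L2FC undefined")
    return float(np.log2(num / den))


def _default_pseudocount(*arrays: np.ndarray) -> float:
    pooled = np.concatenate([np.asarray(a, float).ravel() for a in arrays])
    positive = pooled[pooled > 0]
    return float(positive.min()) if positive.size else 1.0


def coculture_analysis(
    mono_t0: Sequence[float],
    mono_t24: Sequence[float],
    co_t0: Sequence[float],
    co_t24: Sequence[float],
    strain: str = "",
    alpha: float = 0.05,
    pseudocount: float | None = None,
    degrader_co_t0: Sequence[float] | None = None,
    degrader_co_t24: Sequence[float] | None = None,
    welch: bool = False,
) -> CocultureResult:
    """Cross-feeding test: coculture vs monoculture absolute abundances.

    Inputs are replicate copy-number quantifications of the focal strain
    at 0 and 24 h in each arm (>= 2 replicates per arm and timepoint).
    Reports the within-arm L2FC of replicate-mean abundances (24 h vs
    0 h), the cross-arm L2FC at 24 h, and a two-sided Student's t-test of
    coculture vs monoculture 24 h abundances.  When the degrader's own
    coculture quantifications are supplied, its within-coculture L2FC is
    reported too, to detect growth suppression of the degrader.  The
    pseudocount defaults to the smallest positive quantified value.
    """
    arrays = {k: np.asarray(list(v), float) for k, v in
              dict(mono_t0=mono_t0, mono_t24=mono_t24, co_t0=co_t0, co_t24=co_t24).items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"{name} needs >= 2 replicates")
        if (arr < 0).any():
            raise ValueError(f"{name} has negative abundances")
    pc = _default_pseudocount(*arrays.values()) if pseudocount is None else pseudocount
    m0, m24 = arrays["mono_t0"], arrays["mono_t24"]
    c0, c24 = arrays["co_t0"], arrays["co_t24"]
    t_stat, p = stats.ttest_ind(c24, m24, equal_var=not welch)
    degrader = None
    if degrader_co_t0 is not None and degrader_co_t24 is not None:
        d0 = np.asarray(list(degrader_co_t0), float)
        d24 = np.asarray(list(degrader_co_t24), float)
        degrader = l2fc(float(d24.mean()), float(d0.mean()), pc)
    return CocultureResult(
        strain=strain,
        l2fc_co=l2fc(float(c24.mean()), float(c0.mean()), pc),
        l2fc_mono=l2fc(float(m24.mean()), float(m0.mean()), pc),
        l2fc_co_vs_mono=l2fc(float(c24.mean()), float(m24.mean()), pc),
        t_stat=float(t_stat),
        p=float(p),
        significant=bool(p < alpha),
        degrader_l2fc=degrader,
    )
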