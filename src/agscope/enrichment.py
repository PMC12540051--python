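"""Genus-level enrichment analysis of 16S relative-abundance tables.

The prebiotic response of a gut community is quantified per genus and per
donor by the enrichment factor

    EF = 2A / (A + B) - 1,

where A and B are the genus's relative abundances in the treated and the
donor-matched no-amendment (NA) control sample at the same timepoint.  EF
is bounded in [-1, 1], antisymmetric under swapping treated/control, and
comparable across donors despite strong inter-individual differences in
baseline composition.  Genera are called significantly enriched when the
mean EF across donors is positive and the BH/FDR-adjusted p-value of a
one-sample z-test of the per-donor EFs against zero falls below alpha.

Community-level shifts are assessed with Bray-Curtis dissimilarities,
an adonis-style sequential (Type I) PERMANOVA, and classical PCoA
ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "EnrichmentResult",
    "PermanovaResult",
    "relative_abundance",
    "enrichment_factor",
    "ef_table",
    "call_enrichment",
    "benjamini_hochberg",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "pcoa",
]

# SD floor in the z statistic: unanimous per-donor EFs give a finite,
# extreme z instead of a division failure.
_SD_FLOOR = 1e-8

_META_COLS = ("donor", "treatment", "timepoint")


@dataclass
class AbundanceTable:
    """Samples x genera count table with donor/treatment/timepoint metadata.

    ``counts`` is indexed by sample id with genus-name columns;
    ``sample_meta`` is indexed identically with columns donor, treatment
    (e.g. AG / arabinose / galactose / NA) and timepoint (hours).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.reindex(self.counts.index)
        missing = [c for c in _META_COLS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta lacks columns: {missing}")
        if self.sample_meta[list(_META_COLS)].isna().any().any():
            raise ValueError("sample_meta has missing donor/treatment/timepoint entries")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        totals = self.counts.sum(axis=1)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise ValueError(f"samples with zero total counts: {empty}")

    @property
    def genus_names(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class EnrichmentResult:
    """Per-(genus, donor) EFs plus per-genus enrichment calls.

    ``ef`` is a long table (genus, donor, ef); ``calls`` (after
    :func:`call_enrichment`) has per-genus mean_ef, z, p, p_adj, enriched;
    ``baseline_ra`` is each genus's mean relative abundance in the 0 h
    samples, used for bubble sizing in reports.
    """

    treatment: str
    timepoint: float
    ef: pd.DataFrame
    baseline_ra: pd.Series
    calls: pd.DataFrame | None = None
    alpha: float | None = None


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition: per-term R2, pseudo-F and p."""

    terms: pd.DataFrame  # index: term names + "Residual"; cols r2, df, pseudo_f, p
    n_perm: int


def relative_abundance(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Counts divided by each sample's total; rows sum to 1."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    totals = counts.sum(axis=1)
    return counts.div(totals, axis=0)


def enrichment_factor(a, b):
    """EF = 2A/(A+B) - 1 for treated (a) vs control (b) relative abundances.

    Defined as 0 when a = b = 0 (no evidence of change).  Accepts scalars
    or arrays; negative inputs are an error.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if (a_arr < 0).any() or (b_arr < 0).any():
        raise ValueError("relative abundances must be non-negative")
    total = a_arr + b_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        ef = np.where(total > 0, 2.0 * a_arr / np.where(total > 0, total, 1.0) - 1.0, 0.0)
    if np.isscalar(a) and np.isscalar(b):
        return float(ef)
    return ef


def ef_table(
    table: AbundanceTable, treatment: str, timepoint: float
) -> EnrichmentResult:
    """Per-genus, per-donor EF of a treatment against donor-matched NA.

    For every donor there must be exactly one treated and one NA sample at
    the requested timepoint; EF uses the donor's own NA sample as B.
    ``baseline_ra`` is taken from the 0 h samples (NaN if none exist).
    """
    ra = relative_abundance(table)
    meta = table.sample_meta
    tp = meta["timepoint"].astype(float)
    donors = sorted(meta["donor"].unique())
    rows = []
    missing: list[str] = []
    for donor in donors:
        sel_t = meta.index[
            (meta["donor"] == donor) & (meta["treatment"] == treatment) & (tp == timepoint)
        ]
        sel_c = meta.index[
            (meta["donor"] == donor) & (meta["treatment"] == "NA") & (tp == timepoint)
        ]
        if len(sel_t) != 1 or len(sel_c) != 1:
            missing.append(str(donor))
            continue
        efs = enrichment_factor(ra.loc[sel_t[0]].to_numpy(), ra.loc[sel_c[0]].to_numpy())
        for genus, ef in zip(table.genus_names, efs):
            rows.append({"genus": genus, "donor": donor, "ef": float(ef)})
    if missing:
        raise ValueError(
            f"donors without a matched {treatment}/NA pair at {timepoint} h: {missing}"
        )
    baseline_idx = meta.index[tp == 0.0]
    if len(baseline_idx):
        baseline = ra.loc[baseline_idx].mean(axis=0)
    else:
        baseline = pd.Series(np.nan, index=table.genus_names)
    return EnrichmentResult(
        treatment=treatment,
        timepoint=float(timepoint),
        ef=pd.DataFrame(rows),
        baseline_ra=baseline,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enrichment(efs: EnrichmentResult, alpha: float = 0.05) -> EnrichmentResult:
    """Fill per-genus enrichment calls into an EF result.

    Per genus: z = mean(EF over donors) / (SD / sqrt(n)), two-sided normal
    p, BH adjustment across the genera of this (treatment, timepoint)
    stratum; enriched = mean EF > 0 and adjusted p < alpha.  Needs >= 2
    donors per genus.
    """
    grouped = efs.ef.groupby("genus")["ef"]
    n = grouped.size()
    if (n < 2).any():
        raise ValueError("need >= 2 donors per genus for the z-test")
    mean_ef = grouped.mean()
    sd = grouped.std(ddof=1).clip(lower=_SD_FLOOR)
    z = mean_ef / (sd / np.sqrt(n))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = benjamini_hochberg(p)
    calls = pd.DataFrame(
        {
            "mean_ef": mean_ef,
            "z": z,
            "p": p,
            "p_adj": p_adj,
            "enriched": (mean_ef > 0) & (p_adj < alpha),
        }
    )
    calls["baseline_ra"] = efs.baseline_ra.reindex(calls.index)
    efs.calls = calls
    efs.alpha = alpha
    return efs


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) for non-negative vectors."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("inputs must be non-negative")
    denom = float(np.sum(xa + ya))
    if denom == 0.0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(xa - ya)) / denom)


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix of sample profiles (rows = samples)."""
    dm = squareform(pdist(profiles.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dm, index=profiles.index, columns=profiles.index)


def _design_matrix(meta: pd.DataFrame, terms: Sequence[str]) -> list[np.ndarray]:
    """Cumulative design matrices: intercept, then one term added at a time."""
    n = len(meta)
    designs = [np.ones((n, 1))]
    cols = [np.ones((n, 1))]
    for term in terms:
        levels = pd.unique(meta[term])
        if len(levels) < 2:
            raise ValueError(f"term {term!r} has a single level")
        dummies = pd.get_dummies(meta[term].astype(str), drop_first=True).to_numpy(float)
        cols.append(dummies)
        designs.append(np.hstack(cols))
    return designs


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    q = q[:, keep]
    return q @ q.T


def permanova(
    dm: pd.DataFrame | np.ndarray,
    sample_meta: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA on a dissimilarity matrix.

    Partitions the Gower-centered squared-dissimilarity matrix by the
    model terms in order (adonis-style), reporting per-term R2, pseudo-F
    and a free-permutation p-value p = (1 + #{F_perm >= F_obs}) / (1 +
    n_perm).  The dissimilarity matrix must be square, symmetric and
    zero-diagonal; each term must have >= 2 levels; n_perm >= 99.
    """
    d = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity matrix must be square, symmetric, zero-diagonal")
    if len(sample_meta) != n:
        raise ValueError("metadata length does not match the matrix")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))

    designs = _design_matrix(sample_meta, terms)
    hats = [_hat(x) for x in designs]
    ranks = [int(round(np.trace(h))) for h in hats]
    df_terms = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    # SS_res of a perfectly separated design cancels to rounding error and
    # can come out negative; treat it as zero and report an infinite F
    ss_tiny = 1e-12 * max(ss_total, 1.0)

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.array([float(np.sum(h * gmat)) for h in hats])
        ss = np.diff(tr)  # per-term sequential SS
        ss_res = float(np.trace(gmat)) - tr[-1]
        if ss_res <= ss_tiny:
            f = np.where(ss > 0, np.inf, 0.0)
        else:
            f = (ss / np.array(df_terms)) / (ss_res / df_resid)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm = term_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    ss_res_obs = ss_total - float(np.sum(ss_obs))
    index = list(terms) + ["Residual"]
    out = pd.DataFrame(
        {
            "df": df_terms + [df_resid],
            "r2": list(ss_obs / ss_total) + [ss_res_obs / ss_total],
            "pseudo_f": list(f_obs) + [np.nan],
            "p": list(pvals) + [np.nan],
        },
        index=index,
    )
    return PermanovaResult(terms=out, n_perm=n_perm)


def pcoa(dm: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA (metric MDS) of a dissimilarity matrix.

    Double-centers the squared dissimilarities and eigendecomposes;
    axes with non-positive eigenvalues are dropped.  Returns coordinates
    (samples x axes, columns PCo1..) and the retained eigenvalues.
    """
    index = dm.index if isinstance(dm, pd.DataFrame) else None
    d = dm.to_numpy(dtype=float) if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(eigvals.max(), 0.0))
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    cols = [f"PCo{i + 1}" for i in range(int(keep.sum()))]
    return pd.DataFrame(coords, index=index, columns=cols), eigvals[keep]
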