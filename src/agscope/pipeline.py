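"""End-to-end orchestration of the analysis stages.

`run_pipeline` runs the configured stages on synthetic inputs generated
from the global seed (the reproducible demo): Raman activity scoring with
the water-control threshold, in-silico RACS with census accounting,
community enrichment with PERMANOVA/PCoA, and growth + coculture
quantification.  Every stage's output is written under the run directory
together with a JSON manifest of package version, seed and parameters, so
identical config + seed gives identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .census import census_summary, select_representatives
from .config import PipelineConfig
from .enrichment import bray_curtis_matrix, call_enrichment, ef_table, pcoa, permanova, relative_abundance
from .growth import coculture_analysis, fit_standard_curve, growth_boost, quantify
from .io import (
    write_abundance_table,
    write_activity_table,
    write_census,
    write_growth_curves,
    write_spectra,
)
from .simulate import (
    CommunitySimSpec,
    GrowthSimSpec,
    SpectrumSimSpec,
    gen_community,
    gen_growth_curves,
    gen_isolate_census,
    gen_qpcr_series,
    gen_spectrum,
)
from .sorting import SortRunConfig, SortThresholds, compute_sort_indices, decide_sort, simulate_sort_run
from .spectra import ActivityResult, classify_active, compare_activity, compute_cd_fraction, fit_activity_threshold, is_valid_spectrum


def _simulate_cells(cfg: PipelineConfig, rng: np.random.Generator):
    """Synthetic cohort: water controls, NA cells and AG-stimulated cells."""
    spectra = []
    specs = [
        # (condition, n, %CD mean, %CD sd)
        ("water", 30, 0.3, 0.2),
        ("NA", 40, 2.0, 1.5),
        ("AG", 40, 18.0, 6.0),
    ]
    k = 0
    for condition, n, mu, sd in specs:
        for _ in range(n):
            k += 1
            cd_true = float(np.clip(rng.normal(mu, sd), 0.0, 60.0))
            spectra.append(
                gen_spectrum(
                    SpectrumSimSpec(
                        cd_fraction_true=cd_true,
                        noise_sd=0.05,
                        baseline_slope=1e-4,
                        baseline_offset=1.0,
                        seed=int(rng.integers(2**31)),
                    ),
                    cell_id=f"cell{k:04d}",
                    donor=f"D{(k % 10) + 1:02d}",
                    condition=condition,
                    timepoint=6.0,
                )
            )
    return spectra


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run the full synthetic demo pipeline; returns the run directory."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bands = config.band_definitions()

    # --- Raman activity scoring ---------------------------------------
    spectra = _simulate_cells(config, rng)
    write_spectra(spectra, out / "spectra")
    results = []
    for s in spectra:
        valid = is_valid_spectrum(s, bands, config.activity.snr_min)
        cd = compute_cd_fraction(s, bands) if valid else float("nan")
        results.append(
            ActivityResult(
                cell_id=s.cell_id, cd_fraction=cd, valid=valid,
                donor=s.donor, condition=s.condition, timepoint=s.timepoint,
            )
        )
    control = [r.cd_fraction for r in results
               if r.valid and r.condition == config.activity.control_condition]
    threshold = fit_activity_threshold(control)
    classified = classify_active(
        [r for r in results if r.condition != config.activity.control_condition], threshold
    )
    write_activity_table(classified, out / "activity.tsv")
    groups = {}
    for r in classified:
        if r.valid:
            groups.setdefault(r.condition, []).append(r.cd_fraction)
    f_stat, anova_p = compare_activity(groups)

    # --- In-silico RACS + census --------------------------------------
    background = gen_spectrum(
        SpectrumSimSpec(cd_fraction_true=0.0, total_ch_cd_area=1e-6, phe_area=0.0,
                        amide_area=1.0, baseline_offset=0.5, seed=int(rng.integers(2**31)))
    )
    sort_rows = []
    decisions = []
    for s in spectra:
        if s.condition == config.activity.control_condition:
            continue
        idx = compute_sort_indices(s, background, bands)
        decision = decide_sort(idx, SortThresholds(config.sort.pc_min, config.sort.pl_min))
        decisions.append(decision)
        sort_rows.append({"cell_id": idx.cell_id, "pc": idx.pc, "pl": idx.pl, "decision": decision})
    pd.DataFrame(sort_rows).to_csv(out / "sort.tsv", sep="\t", index=False)
    report = simulate_sort_run(
        decisions,
        SortRunConfig(
            accuracy=config.sort.accuracy, accuracy_sd=config.sort.accuracy_sd,
            throughput=config.sort.throughput, cultivation_p=config.sort.cultivation_p,
            seed=int(rng.integers(2**31)),
        ),
    )
    census_records = gen_isolate_census(seed=int(rng.integers(2**31)))
    write_census(census_records, out / "isolates.tsv")
    census = census_summary(census_records)
    representatives = select_representatives(census_records)

    # --- Community enrichment -----------------------------------------
    community = gen_community(
        CommunitySimSpec(
            enriched_genera=frozenset({1, 2, 3}), effect_multiplier=4.0,
            treatment=config.enrichment.treatment,
            timepoints=(config.enrichment.timepoint,),
            seed=int(rng.integers(2**31)),
        )
    )
    write_abundance_table(community, out / "counts.tsv", out / "meta.tsv")
    enr = call_enrichment(
        ef_table(community, config.enrichment.treatment, config.enrichment.timepoint),
        alpha=config.enrichment.alpha,
    )
    enr.ef.to_csv(out / "ef.tsv", sep="\t", index=False)
    enr.calls.to_csv(out / "enrichment_calls.tsv", sep="\t", index_label="genus")
    ra = relative_abundance(community)
    dm = bray_curtis_matrix(ra)
    perm = permanova(
        dm, community.sample_meta, ["donor", "treatment"],
        n_perm=config.enrichment.n_perm, seed=int(rng.integers(2**31)),
    )
    perm.terms.to_csv(out / "permanova.tsv", sep="\t", index_label="term")
    coords, _ = pcoa(dm)
    coords.iloc[:, :2].to_csv(out / "pcoa.tsv", sep="\t", index_label="sample")

    # --- Growth + coculture -------------------------------------------
    gspec = GrowthSimSpec(seed=int(rng.integers(2**31)))
    treated = gen_growth_curves(gspec, boosted=True, strain="B. longum")
    ctrl = gen_growth_curves(
        GrowthSimSpec(seed=int(rng.integers(2**31))), boosted=False, strain="B. longum"
    )
    write_growth_curves([treated, ctrl], out / "growth.csv")
    boost = growth_boost(treated, ctrl, alpha=config.growth.alpha,
                         blank_correct=config.growth.blank_correct, welch=config.growth.welch)

    standards = gen_qpcr_series([10.0**k for k in range(1, 7)],
                                seed=int(rng.integers(2**31)))
    curve = fit_standard_curve(standards)
    q = lambda copies: quantify(  # noqa: E731
        curve.slope * np.log10(copies) + curve.intercept, curve
    )
    coc = coculture_analysis(
        mono_t0=[q(1e4)] * 3, mono_t24=[q(1.1e4), q(0.9e4), q(1.0e4)],
        co_t0=[q(1e4)] * 3, co_t24=[q(7.9e4), q(8.2e4), q(8.0e4)],
        strain="Alistipes shahii",
    )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.model_dump(mode="json", exclude={"out_dir"}),
        "raman": {
            "n_cells": len(classified),
            "threshold_pct_cd": threshold.threshold,
            "anova_f": f_stat,
            "anova_p": anova_p,
        },
        "sort": {
            "n_analyzed": report.n_analyzed,
            "n_collected": report.n_collected,
            "n_misdirected": report.n_misdirected,
            "duration_h": report.duration,
            "cultivation_success_pct": report.success_rate,
        },
        "census": {
            "total": census.total,
            "n_species": census.n_species,
            "phylum_counts": census.phylum_counts,
            "n_representatives": len(representatives),
        },
        "enrichment": {
            "n_enriched": int(enr.calls["enriched"].sum()),
            "permanova_r2": {t: float(perm.terms.loc[t, "r2"]) for t in ("donor", "treatment")},
        },
        "growth": {"boost": boost.boost, "p": boost.p, "significant": boost.significant},
        "coculture": {
            "strain": coc.strain, "l2fc_co": coc.l2fc_co,
            "l2fc_co_vs_mono": coc.l2fc_co_vs_mono, "p": coc.p,
            "qpcr_efficiency": curve.efficiency,
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
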