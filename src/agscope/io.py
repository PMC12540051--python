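"""Readers and writers for the pipeline's plain-text formats.

Spectra are two-column delimited text (wavenumber, intensity), one file
per cell, listed in a TSV manifest (file, cell_id, donor, condition,
timepoint).  Count tables are TSV (rows = samples, columns = genera) with
a companion metadata TSV (sample, donor, treatment, timepoint).  Growth
curves are long-format CSV; qPCR runs and standards are CSV; isolate
censuses are TSV.  Writers emit exactly what the readers consume.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import IsolateRecord
from .enrichment import AbundanceTable
from .growth import GrowthCurveSet, QpcrRun
from .spectra import ActivityResult, RamanSpectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_spectra",
    "read_manifest",
    "write_activity_table",
    "write_abundance_table",
    "read_abundance_table",
    "write_growth_curves",
    "read_growth_curves",
    "write_qpcr_run",
    "read_qpcr_run",
    "write_census",
    "read_census",
]


def write_spectrum(spectrum: RamanSpectrum, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.wavenumbers, spectrum.intensities]),
        fmt="%.6f\t%.8e",
        header="wavenumber_cm-1\tintensity",
    )


def read_spectrum(
    path: str | Path,
    cell_id: str = "",
    donor: str = "",
    condition: str = "",
    timepoint: float = float("nan"),
) -> RamanSpectrum:
    data = np.loadtxt(path)
    return RamanSpectrum(
        wavenumbers=data[:, 0],
        intensities=data[:, 1],
        cell_id=cell_id or Path(path).stem,
        donor=donor,
        condition=condition,
        timepoint=timepoint,
    )


def write_spectra(spectra: Sequence[RamanSpectrum], out_dir: str | Path) -> Path:
    """Write one file per cell plus a manifest TSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.cell_id}.txt"
        write_spectrum(s, out / fname)
        rows.append(
            {
                "file": fname,
                "cell_id": s.cell_id,
                "donor": s.donor,
                "condition": s.condition,
                "timepoint": s.timepoint,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[RamanSpectrum]:
    """Load every spectrum listed in a manifest TSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    # "NA" is a meaningful condition label (no amendment), never missingness
    df = pd.read_csv(manifest_path, sep="\t", keep_default_na=False, na_values=[""])
    spectra = []
    for _, row in df.iterrows():
        spectra.append(
            read_spectrum(
                manifest_path.parent / row["file"],
                cell_id=str(row["cell_id"]),
                donor=str(row.get("donor", "")),
                condition=str(row.get("condition", "")),
                timepoint=float(row.get("timepoint", float("nan"))),
            )
        )
    return spectra


def write_activity_table(results: Iterable[ActivityResult], path: str | Path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "donor": r.donor,
            "condition": r.condition,
            "timepoint": r.timepoint,
            "cd_fraction": r.cd_fraction,
            "valid": r.valid,
            "active": r.active,
            "threshold": r.threshold_used,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_abundance_table(
    table: AbundanceTable, counts_path: str | Path, meta_path: str | Path
) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample")
    table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_abundance_table(counts_path: str | Path, meta_path: str | Path) -> AbundanceTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
    # treatment "NA" means no amendment, not a missing value
    meta = pd.read_csv(
        meta_path, sep="\t", index_col="sample", keep_default_na=False, na_values=[""]
    )
    return AbundanceTable(counts=counts, sample_meta=meta)


def write_growth_curves(curve_sets: Sequence[GrowthCurveSet], path: str | Path) -> None:
    rows = []
    for cs in curve_sets:
        for rep in range(cs.n_replicates):
            for t, od in zip(cs.times, cs.od600[rep]):
                rows.append(
                    {
                        "time_h": t,
                        "strain": cs.strain,
                        "condition": cs.condition,
                        "replicate": rep + 1,
                        "od600": od,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurveSet]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    sets = []
    for (strain, condition), grp in df.groupby(["strain", "condition"], sort=True):
        reps = sorted(grp["replicate"].unique())
        times = np.sort(grp["time_h"].unique())
        od = np.empty((len(reps), times.size))
        for i, rep in enumerate(reps):
            sub = grp[grp["replicate"] == rep].sort_values("time_h")
            if not np.array_equal(sub["time_h"].to_numpy(dtype=float), times):
                raise ValueError(
                    f"replicate {rep} of {strain}/{condition} has mismatched timepoints"
                )
            od[i] = sub["od600"].to_numpy(dtype=float)
        sets.append(GrowthCurveSet(strain=str(strain), condition=str(condition), times=times, od600=od))
    return sets


def write_qpcr_run(run: QpcrRun, path: str | Path) -> None:
    run.wells.to_csv(path, index=False)


def read_qpcr_run(path: str | Path) -> QpcrRun:
    return QpcrRun(wells=pd.read_csv(path))


def write_census(records: Iterable[IsolateRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"isolate_id": r.isolate_id, "species": r.species, "phylum": r.phylum, "donor": r.donor}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> list[IsolateRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[]).fillna("")
    return [
        IsolateRecord(
            isolate_id=str(r["isolate_id"]),
            species=str(r["species"]),
            phylum=str(r["phylum"]),
            donor=str(r["donor"]),
        )
        for _, r in df.iterrows()
    ]
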