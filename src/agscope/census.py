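"""Isolate census accounting for RACS-recovered strains.

Tabulates species- and phylum-level counts of sorted-and-cultivated
isolates and selects one representative isolate per species for
downstream physiology.  Ships the species-to-phylum taxonomy of the 16
arabinogalactan-responsive gut species recovered in the reference study;
users can extend the mapping via TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "IsolateRecord",
    "IsolateCensus",
    "STUDY_COMPOSITION",
    "STUDY_TAXONOMY",
    "census_summary",
    "select_representatives",
]

# Species composition of the 98 RACS-recovered isolates and their phyla.
STUDY_COMPOSITION: dict[str, int] = {
    "Bifidobacterium longum": 45,
    "Collinsella aerofaciens": 26,
    "Alistipes shahii": 5,
    "Alistipes senegalensis": 1,
    "Alistipes putredinis": 2,
    "Alistipes onderdonkii": 3,
    "Bacteroides uniformis": 2,
    "Bacteroides stercoris": 1,
    "Catenibacterium mitsuokai": 6,
    "Dysosmobacter welbionis": 1,
    "Eggerthella lenta": 1,
    "Faecalibacterium prausnitzii": 1,
    "Parabacteroides merdae": 1,
    "Phascolarctobacterium faecium": 1,
    "Phocaeicola coprocola": 1,
    "Ruminococcus bicirculans": 1,
}

STUDY_TAXONOMY: dict[str, str] = {
    "Bifidobacterium longum": "Actinomycetota",
    "Collinsella aerofaciens": "Actinomycetota",
    "Eggerthella lenta": "Actinomycetota",
    "Alistipes shahii": "Bacteroidota",
    "Alistipes senegalensis": "Bacteroidota",
    "Alistipes putredinis": "Bacteroidota",
    "Alistipes onderdonkii": "Bacteroidota",
    "Bacteroides uniformis": "Bacteroidota",
    "Bacteroides stercoris": "Bacteroidota",
    "Parabacteroides merdae": "Bacteroidota",
    "Phocaeicola coprocola": "Bacteroidota",
    "Catenibacterium mitsuokai": "Bacillota",
    "Dysosmobacter welbionis": "Bacillota",
    "Faecalibacterium prausnitzii": "Bacillota",
    "Phascolarctobacterium faecium": "Bacillota",
    "Ruminococcus bicirculans": "Bacillota",
}


@dataclass(frozen=True)
class IsolateRecord:
    isolate_id: str
    species: str
    phylum: str
    donor: str = ""


@dataclass
class IsolateCensus:
    """Census summary: per-species and per-phylum counts with fractions."""

    records: list[IsolateRecord]
    species_counts: dict[str, int] = field(default_factory=dict)
    phylum_counts: dict[str, int] = field(default_factory=dict)
    species_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(self.species_counts)


def census_summary(records: Iterable[IsolateRecord]) -> IsolateCensus:
    """Tabulate species/phylum counts and species fractions of the total.

    Every record must carry a phylum; offenders are listed in the error.
    """
    recs = list(records)
    if not recs:
        raise ValueError("census requires at least one isolate record")
    orphans = sorted({r.species for r in recs if not r.phylum})
    if orphans:
        raise ValueError(f"species without a phylum assignment: {orphans}")
    clash = sorted(
        {r.species for r in recs}
        & {s for s in {r.species for r in recs}
           if len({q.phylum for q in recs if q.species == s}) > 1}
    )
    if clash:
        raise ValueError(f"species mapped to multiple phyla: {clash}")
    species_counts: dict[str, int] = {}
    phylum_counts: dict[str, int] = {}
    for r in recs:
        species_counts[r.species] = species_counts.get(r.species, 0) + 1
        phylum_counts[r.phylum] = phylum_counts.get(r.phylum, 0) + 1
    total = len(recs)
    fractions = {s: c / total for s, c in species_counts.items()}
    return IsolateCensus(
        records=recs,
        species_counts=species_counts,
        phylum_counts=phylum_counts,
        species_fractions=fractions,
    )


def select_representatives(records: Iterable[IsolateRecord]) -> list[IsolateRecord]:
    """One representative isolate per distinct species.

    Deterministic tie-break: the lexicographically lowest isolate_id per
    species wins.  Output is ordered by species name.
    """
    best: dict[str, IsolateRecord] = {}
    for r in records:
        cur = best.get(r.species)
        if cur is None or r.isolate_id < cur.isolate_id:
            best[r.species] = r
    return [best[s] for s in sorted(best)]
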