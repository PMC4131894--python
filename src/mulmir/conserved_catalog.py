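"""Conserved-miRNA catalog: identification by exact match against a mature
reference, family grouping and naming, per-tissue presence, and the
cross-species conservation profile (++ exact / + 1-3 mismatches / -
otherwise).

The published mulberry catalog (85 conserved miRNAs with per-tissue read
counts and seven-species conservation symbols) ships as package data and is
the fixture for catalog statistics; the per-library sequencing totals ship
alongside it.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib import resources

import edlib
import pandas as pd

from .preprocess import ReadLibrary
from .seqio import MatureRecord, parse_family_label, to_dna

PROFILE_SPECIES = ("ath", "gma", "mdm", "ptc", "rco", "osa", "zma")

# conservation symbols by best edit distance to the species' mature set
SYM_EXACT, SYM_NEAR, SYM_ABSENT = "++", "+", "-"
NEAR_MAX_DISTANCE = 3


def load_catalog() -> pd.DataFrame:
    """The published conserved-miRNA catalog (85 records)."""
    path = resources.files("mulmir.data").joinpath("conserved_catalog.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_library_totals() -> dict:
    """Per-tissue clean-read totals of the three sequencing libraries."""
    path = resources.files("mulmir.data").joinpath("library_totals.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["tissue"], df["clean_reads"]))


def catalog_records(df: pd.DataFrame | None = None) -> list[MatureRecord]:
    """Catalog rows as MatureRecords with per-tissue counts."""
    if df is None:
        df = load_catalog()
    recs = []
    for _, row in df.iterrows():
        recs.append(
            MatureRecord(
                name=row["name"],
                seq=row["sequence"],
                species=row["name"].split("-", 1)[0],
                family=row["family"],
                ref_name=row["ref_name"],
                counts={
                    "leaf": int(row["leaf"]),
                    "bark": int(row["bark"]),
                    "male_flower": int(row["male_flower"]),
                },
            )
        )
    return recs


def identify_conserved(libs: dict, mature_ref: list) -> list[MatureRecord]:
    """Reads identical (full length, exact) to a reference mature become
    conserved-miRNA records with per-tissue counts.

    ``libs`` maps tissue label -> ReadLibrary.  Records are deduplicated by
    sequence; the matched reference name and its family label are carried
    over.  Naming is applied separately by :func:`name_conserved`.
    """
    by_seq: dict[str, MatureRecord] = {}
    ref_by_seq = {}
    for m in mature_ref:
        ref_by_seq.setdefault(m.seq, m)
    for tissue, lib in libs.items():
        for seq, count in lib.unique_reads.items():
            ref = ref_by_seq.get(seq)
            if ref is None:
                continue
            rec = by_seq.get(seq)
            if rec is None:
                rec = MatureRecord(
                    name="",
                    seq=seq,
                    family=parse_family_label(ref.name),
                    ref_name=ref.name,
                    counts={t: 0 for t in libs},
                )
                by_seq[seq] = rec
            rec.counts[tissue] = rec.counts.get(tissue, 0) + count
    return sorted(by_seq.values(), key=lambda r: (-r.total_count(), r.seq))


def _letter_suffix(i: int) -> str:
    letters = string.ascii_lowercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


def name_conserved(records: list, species_code: str = "mno") -> list:
    """Assign family-wise letter suffixes in descending total-count order.

    Single-member families get suffix "a"; beyond 26 members, double
    letters (aa, ab, ...) follow.
    """
    by_family: dict[str, list[MatureRecord]] = {}
    for rec in records:
        by_family.setdefault(rec.family, []).append(rec)
    for family, members in by_family.items():
        members.sort(key=lambda r: (-r.total_count(), r.seq))
        for i, rec in enumerate(members):
            rec.name = f"{species_code}-{family}{_letter_suffix(i)}"
    return records


def edit_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions and 1-cost indels)."""
    return edlib.align(to_dna(a), to_dna(b))["editDistance"]


def conservation_profile(rec: MatureRecord, species_sets: dict) -> dict:
    """Per-species conservation symbol from the best edit distance.

    0 -> "++", 1-3 -> "+", >3 or empty species set -> "-".
    """
    profile = {}
    for species, matures in species_sets.items():
        dists = [edit_distance(rec.seq, m.seq) for m in matures]
        best = min(dists) if dists else None
        if best == 0:
            profile[species] = SYM_EXACT
        elif best is not None and best <= NEAR_MAX_DISTANCE:
            profile[species] = SYM_NEAR
        else:
            profile[species] = SYM_ABSENT
    return profile


@dataclass
class CatalogStats:
    n_mirnas: int
    n_families: int
    presence: dict            # tissue -> number with count > 0
    n_common_all: int
    length_histogram: dict    # length -> count
    family_species_span: dict  # family -> number of species with + or ++

    @property
    def fraction_length(self) -> dict:
        return {L: n / self.n_mirnas for L, n in self.length_histogram.items()}

    def n_families_in_at_most(self, k: int) -> int:
        return sum(1 for span in self.family_species_span.values() if span <= k)


def catalog_stats(df: pd.DataFrame | None = None,
                  tissues=("leaf", "bark", "male_flower")) -> CatalogStats:
    """Summary statistics of a conserved catalog table.

    Presence in a tissue means count > 0; "common" means present in every
    tissue.  A family is counted as found in a species when any member is
    "+" or "++" there.
    """
    if df is None:
        df = load_catalog()
    presence = {t: int((df[t] > 0).sum()) for t in tissues}
    common = (df[list(tissues)] > 0).all(axis=1)
    lengths = df["sequence"].str.len()
    hist = lengths.value_counts().sort_index().to_dict()
    span: dict[str, set] = {}
    species_cols = [s for s in PROFILE_SPECIES if s in df.columns]
    for _, row in df.iterrows():
        found = span.setdefault(row["family"], set())
        for sp in species_cols:
            if row[sp] in (SYM_EXACT, SYM_NEAR):
                found.add(sp)
    return CatalogStats(
        n_mirnas=len(df),
        n_families=df["family"].nunique(),
        presence=presence,
        n_common_all=int(common.sum()),
        length_histogram=hist,
        family_species_span={fam: len(s) for fam, s in span.items()},
    )


def records_to_frame(records: list, species_profiles: dict | None = None,
                     tissues=("leaf", "bark", "male_flower")) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "family": rec.family,
            "name": rec.name,
            "ref_name": rec.ref_name,
            "sequence": rec.seq,
            "length": rec.length,
        }
        for t in tissues:
            row[t] = rec.counts.get(t, 0)
        if species_profiles and rec.seq in species_profiles:
            row.update(species_profiles[rec.seq])
        rows.append(row)
    return pd.DataFrame(rows)
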