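"""Classify unique reads into annotation categories by a priority cascade.

The cascade mirrors the workflow of removing structural ncRNA first (Rfam
pass), then assigning known miRNAs, then repeats and gene-derived
degradation fragments; whatever remains is "unannotated" and feeds novel
miRNA discovery.  Order (first hit wins):

    rRNA > tRNA > snRNA > snoRNA > miRNA > repeat >
    exon_sense > exon_antisense > intron_sense > intron_antisense >
    unannotated
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import ReadLibrary
from .seqio import Locus, revcomp

NCRNA_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "unannotated",
)


@dataclass
class AnnotationDB:
    """User-supplied reference sets, one list of SequenceRecord each."""

    rRNA: list = field(default_factory=list)
    tRNA: list = field(default_factory=list)
    snRNA: list = field(default_factory=list)
    snoRNA: list = field(default_factory=list)
    repeat: list = field(default_factory=list)
    exon: list = field(default_factory=list)
    intron: list = field(default_factory=list)
    genome: list = field(default_factory=list)


@dataclass
class AnnotationResult:
    labels: dict  # sequence -> category
    library: ReadLibrary

    def summary(self) -> pd.DataFrame:
        """Per-category unique and total read counts (Table-1-style)."""
        rows = []
        for cat in CATEGORIES:
            seqs = [s for s, c in self.labels.items() if c == cat]
            rows.append(
                {
                    "category": cat,
                    "unique_reads": len(seqs),
                    "total_reads": sum(self.library.unique_reads[s] for s in seqs),
                }
            )
        return pd.DataFrame(rows)

    def reads_in(self, category: str) -> list:
        return [s for s, c in self.labels.items() if c == category]


def match_genome(lib: ReadLibrary, genome: list) -> dict:
    """Exact full-length ungapped matches of each unique read against both
    genome strands.  Reverse-strand hits are located by searching the
    read's reverse complement on the forward strand and reported with
    strand "-".  Returns sequence -> list of Locus.
    """
    hits: dict[str, list[Locus]] = {s: [] for s in lib.unique_reads}
    for contig in genome:
        text = contig.seq
        for seq in lib.unique_reads:
            for query, strand in ((seq, "+"), (revcomp(seq), "-")):
                start = text.find(query)
                while start >= 0:
                    hits[seq].append(
                        Locus(chrom=contig.id, start=start,
                              end=start + len(query), strand=strand)
                    )
                    start = text.find(query, start + 1)
    return hits


def _hits_any(seq: str, refs: list, orientation_aware: bool = False):
    """Exact-substring hit of a read in a reference set (either
    orientation).  With ``orientation_aware`` returns "sense"/"antisense"/
    None, else True/False."""
    rc = revcomp(seq)
    for ref in refs:
        if seq in ref.seq:
            return "sense" if orientation_aware else True
        if rc in ref.seq:
            return "antisense" if orientation_aware else True
    return None if orientation_aware else False


def classify(lib: ReadLibrary, db: AnnotationDB, mature_ref=None) -> AnnotationResult:
    """Assign every unique read its first matching category.

    ncRNA matching is exact-substring in either orientation.  miRNA means
    full-length identity with a reference mature sequence.  Exon/intron
    matches carry sense/antisense according to which orientation of the
    read matches the annotated transcript sequence.
    """
    mature_seqs = set()
    if mature_ref:
        mature_seqs = {m.seq for m in mature_ref}
    labels = {}
    for seq in lib.unique_reads:
        label = "unannotated"
        for cat in NCRNA_CATEGORIES:
            if _hits_any(seq, getattr(db, cat)):
                label = cat
                break
        else:
            if seq in mature_seqs:
                label = "miRNA"
            elif _hits_any(seq, db.repeat):
                label = "repeat"
            else:
                for feature in ("exon", "intron"):
                    orient = _hits_any(seq, getattr(db, feature),
                                       orientation_aware=True)
                    if orient:
                        label = f"{feature}_{orient}"
                        break
        labels[seq] = label
    return AnnotationResult(labels=labels, library=lib)


def unannotated_library(result: AnnotationResult) -> ReadLibrary:
    """Sub-library of reads left unannotated (input to novel discovery)."""
    lib = result.library
    out = ReadLibrary(label=lib.label, min_len=lib.min_len, max_len=lib.max_len)
    out.unique_reads = {
        s: lib.unique_reads[s] for s, c in result.labels.items() if c == "unannotated"
    }
    out.total_raw = lib.total_raw
    return out


def db_from_fastas(paths: dict) -> AnnotationDB:
    """Build an AnnotationDB from a mapping category -> FASTA path."""
    from .seqio import read_fasta

    db = AnnotationDB()
    for cat, path in paths.items():
        if not hasattr(db, cat):
            raise ValueError(f"unknown annotation category {cat!r}")
        setattr(db, cat, read_fasta(path))
    return db
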