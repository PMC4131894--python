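"""Readers and writers for the external formats the pipeline touches.

All sequence data are held internally in the DNA alphabet (T, never U);
conversion to U happens only at display or folding boundaries.  Coordinates
are 0-based half-open internally and 1-based inclusive in GFF3 output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

VALID_CHARS = set("ACGTUN")
FASTA_WRAP = 70

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def to_dna(seq: str) -> str:
    """Uppercase and normalize U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and normalize T -> U (display/folding boundary only)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        self.seq = to_dna(self.seq)
        if not self.seq:
            raise ParseError(f"record {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_CHARS
        if bad:
            raise ParseError(f"record {self.id!r} has invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MatureRecord:
    """A named mature miRNA with optional per-tissue counts.

    ``species`` is the text before the first "-" of a miRBase-style name
    (e.g. "gma" in "gma-miR156f"); ``family`` strips letter and arm
    suffixes ("miR156" from "gma-miR156f" or "zma-miR156g-3p").
    """

    name: str
    seq: str
    species: str = "unknown"
    family: str = ""
    ref_name: str = ""
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = to_dna(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def total_count(self) -> int:
        return sum(self.counts.values())


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (DNA alphabet, uppercased).

    An empty file yields an empty list; a record with an empty sequence is
    a parse error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, rna: bool = False) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            seq = to_rna(rec.seq) if rna else rec.seq
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_fastq(path) -> list[tuple[SequenceRecord, str]]:
    """Read 4-line FASTQ; returns (record, quality string) pairs.

    Sequence/quality length mismatches raise ParseError naming the record.
    """
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith("@"):
                raise ParseError(f"{path}: expected '@' header, got {header.strip()!r}")
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            rid = header[1:].split()[0] if len(header) > 1 else ""
            if not plus.startswith("+"):
                raise ParseError(f"{path}: record {rid!r} missing '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {rid!r} sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})"
                )
            out.append((SequenceRecord(id=rid, seq=seq), qual))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, seq, qual) triples as 4-line FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


_MIR_NAME = re.compile(r"miR[a-zA-Z]*(\d+)", re.IGNORECASE)


def parse_family_label(name: str) -> str:
    """Family = "miR" + the leading integer after the miR token.

    "gma-miR156f" -> "miR156"; "zma-miR156g-3p" -> "miR156";
    "mtr-miR4414a-5p" -> "miR4414".
    """
    m = _MIR_NAME.search(name)
    if not m:
        raise ValueError(f"no miR token in name {name!r}")
    return "miR" + m.group(1)


def read_mature_reference(path) -> list[MatureRecord]:
    """Read a miRBase-style mature FASTA (species-prefixed names).

    Names without a "-" are kept with species "unknown".
    """
    import warnings

    matures = []
    for rec in read_fasta(path):
        if "-" in rec.id:
            species = rec.id.split("-", 1)[0]
        else:
            species = "unknown"
            warnings.warn(f"mature name {rec.id!r} has no species prefix")
        try:
            family = parse_family_label(rec.id)
        except ValueError:
            family = ""
        matures.append(
            MatureRecord(name=rec.id, seq=rec.seq, species=species, family=family)
        )
    return matures


@dataclass
class Locus:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.id!r}: start {self.start} > end {self.end}")


def write_loci_gff(loci: Iterable[Locus], path, source: str = "mulmir",
                   feature_type: str = "miRNA_primary_transcript") -> None:
    """Write loci as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = dict(loc.attributes)
            if loc.id:
                attrs = {"ID": loc.id, **attrs}
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        source,
                        feature_type,
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def read_loci_gff(path) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: malformed GFF3 line: {line.strip()!r}")
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = parts
            attr_d = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_d[k] = v
            loci.append(
                Locus(
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    id=attr_d.pop("ID", ""),
                    attributes=attr_d,
                )
            )
    return loci


def read_ct_table(path) -> pd.DataFrame:
    """Read a tab-separated Ct table with columns assay, sample, replicate, Ct.

    Replicate groups are validated: Ct finite, no duplicated
    (assay, sample, replicate) keys.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"assay", "sample", "replicate", "Ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    ct = pd.to_numeric(df["Ct"], errors="coerce")
    bad = df.index[ct.isna()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric or missing Ct in row {bad[0] + 2}")
    df["Ct"] = ct
    dup = df.duplicated(subset=["assay", "sample", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicated key ({row['assay']}, {row['sample']}, "
            f"{row['replicate']})"
        )
    return df


def read_count_table(path) -> pd.DataFrame:
    """Collapsed-library TSV: columns sequence, count."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns or "count" not in df.columns:
        raise ParseError(f"{path}: expected columns 'sequence' and 'count'")
    if (df["count"] < 0).any():
        raise ParseError(f"{path}: negative counts")
    df["sequence"] = df["sequence"].map(to_dna)
    return df


def _ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
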