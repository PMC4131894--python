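"""Raw-read cleaning: quality filter, 3' adapter trimming, length window,
and collapsing to a unique-sequence library with counts."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import to_dna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_MEAN_QUALITY = 20.0
ADAPTER_MIN_OVERLAP = 6
ADAPTER_MAX_MISMATCH = 1


@dataclass
class ReadLibrary:
    """A collapsed, length-filtered small-RNA library for one tissue."""

    label: str
    unique_reads: dict = field(default_factory=dict)  # sequence -> count
    total_raw: int = 0
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    @property
    def total_clean(self) -> int:
        return sum(self.unique_reads.values())

    @property
    def n_unique(self) -> int:
        return len(self.unique_reads)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sequence": list(self.unique_reads), "count": list(self.unique_reads.values())}
        )
        return df.sort_values(["count", "sequence"], ascending=[False, True]).reset_index(
            drop=True
        )

    @classmethod
    def from_counts(cls, label: str, counts: dict, **kw) -> "ReadLibrary":
        lib = cls(label=label, **kw)
        lib.unique_reads = {to_dna(s): int(c) for s, c in counts.items() if c > 0}
        lib.total_raw = lib.total_clean
        return lib


def mean_quality(qual: str, offset: int = 33) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - offset for c in qual) / len(qual)


def find_adapter(seq: str, adapter: str,
                 min_overlap: int = ADAPTER_MIN_OVERLAP,
                 max_mismatch: int = ADAPTER_MAX_MISMATCH) -> int:
    """Locate the 3' adapter: the earliest position where a prefix of the
    adapter matches the read suffix with at most ``max_mismatch``
    mismatches over an overlap of at least ``min_overlap`` (or reaching the
    read end).  Returns the insert length, or -1 when no adapter is found.
    """
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - start)
        mism = 0
        for k in range(overlap):
            if seq[start + k] != adapter[k]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return -1


def clean_reads(raw, label: str = "", adapter3: str | None = None,
                min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN,
                min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY) -> ReadLibrary:
    """Clean and collapse raw reads.

    ``raw`` is an iterable of (seq, quality) pairs (quality may be ""
    for pre-collapsed input, which skips the quality filter).  Reads with
    mean Phred below ``min_mean_quality``, containing N, or whose trimmed
    insert falls outside [min_len, max_len] are discarded.  Reads without a
    recognizable adapter are kept untrimmed when their full length is
    already inside the window.
    """
    lib = ReadLibrary(label=label, min_len=min_len, max_len=max_len)
    n_raw = 0
    for seq, qual in raw:
        n_raw += 1
        if qual and mean_quality(qual) < min_mean_quality:
            continue
        seq = to_dna(seq)
        if adapter3:
            pos = find_adapter(seq, to_dna(adapter3))
            if pos >= 0:
                seq = seq[:pos]
        if "N" in seq:
            continue
        if not (min_len <= len(seq) <= max_len):
            continue
        lib.unique_reads[seq] = lib.unique_reads.get(seq, 0) + 1
    lib.total_raw = n_raw
    return lib


def length_distribution(lib: ReadLibrary) -> dict:
    """Fraction of total (not unique) clean reads per length."""
    total = lib.total_clean
    if total == 0:
        raise ValueError(f"library {lib.label!r} is empty")
    hist: dict[int, int] = {}
    for seq, count in lib.unique_reads.items():
        hist[len(seq)] = hist.get(len(seq), 0) + count
    return {length: n / total for length, n in sorted(hist.items())}


def modal_length(dist: dict) -> int:
    """Arg-max of a length distribution; ties break to the smaller length."""
    if not dist:
        raise ValueError("empty length distribution")
    return min(sorted(dist), key=lambda length: (-dist[length], length))
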