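"""Novel miRNA discovery from unannotated genome-mapped reads.

A read that maps to the genome seeds up to two precursor windows (mature on
the 5' or the 3' arm).  Each window is folded, trimmed to the hairpin plus
flanks, refolded, and judged against the discovery criteria:

Structural (Mireap-style) filters, never rescued:
    len_mature        every supporting read is 18-25 nt
    len_ref           the representative (most abundant) read is 20-23 nt
    max_copies        the mature maps to at most 20 accepted loci
    precursor_mfe     precursor MFE strictly below -18 kcal/mol
    star_space        gap between mature and miRNA* at most 300 nt
    duplex_pairs      at least 16 mature positions paired with the star
    duplex_bulge      largest asymmetric bulge at most 4 nt
    duplex_asymmetry  |unpaired mature side - unpaired star side| at most 4
    flank             at least 20 nt of precursor beyond the duplex ends

Manual filters, rescued when the predicted miRNA* is itself observed in a
library (within a 2-nt end-shift tolerance):
    mfei              MFEI at least 0.85
    manual_bulges     fewer than 3 asymmetric bulges in the duplex
    manual_mismatches fewer than 4 mismatches between miRNA and miRNA*

The miRNA* is predicted from the fold with the Dicer 2-nt 3'-overhang
convention.  ``star_observed`` is recorded on every candidate as a fact;
it is the rescue condition, not a filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import match_genome
from .preprocess import ReadLibrary
from .rnafold import FoldResult, fold, mfei
from .seqio import Locus, revcomp

MIREAP_CRITERIA = (
    "len_mature", "len_ref", "max_copies", "precursor_mfe", "star_space",
    "duplex_pairs", "duplex_bulge", "duplex_asymmetry", "flank",
)
MANUAL_CRITERIA = ("mfei", "manual_bulges", "manual_mismatches")
ALL_CRITERIA = MIREAP_CRITERIA + MANUAL_CRITERIA


@dataclass
class DiscoveryParams:
    mirna_len: tuple = (18, 25)
    ref_len: tuple = (20, 23)
    max_copies: int = 20
    max_precursor_mfe: float = -18.0   # MFE must be strictly below this
    max_star_space: int = 300
    min_duplex_pairs: int = 16
    max_duplex_bulge: int = 4
    max_duplex_asymmetry: int = 4
    flank: int = 20
    min_mfei: float = 0.85
    max_manual_bulges: int = 2         # "less than 3"
    max_manual_mismatches: int = 3     # "fewer than 4"
    star_shift_tolerance: int = 2


@dataclass
class HairpinCandidate:
    locus: Locus                      # mature locus on the genome
    precursor_start: int              # window-relative start of trimmed precursor
    precursor_seq: str = ""
    fold: FoldResult | None = None
    mature_seq: str = ""
    mature_span: tuple = (0, 0)       # within precursor
    arm: str = ""                     # "5p" or "3p"
    star_seq: str = ""
    star_span: tuple = (0, 0)
    duplex_stats: dict = field(default_factory=dict)
    mfei: float = 0.0
    star_observed: bool = False
    criteria_ledger: dict = field(default_factory=dict)
    rejected_reason: str = ""
    counts: dict = field(default_factory=dict)  # tissue -> mature count

    @property
    def mireap_pass(self) -> bool:
        return all(self.criteria_ledger.get(c, False) for c in MIREAP_CRITERIA)

    @property
    def manual_pass(self) -> bool:
        return all(self.criteria_ledger.get(c, False) for c in MANUAL_CRITERIA)

    def failing(self) -> list:
        return [c for c in ALL_CRITERIA if self.criteria_ledger.get(c) is False]


@dataclass
class NovelCatalogEntry:
    name: str
    mature_seq: str
    loci: list
    counts: dict
    star_counts: dict
    star_observed: bool
    precursors: list

    def total_count(self) -> int:
        return sum(self.counts.values())


def candidate_precursors(locus: Locus, genome: dict, params: DiscoveryParams):
    """Up to two precursor windows for a mature locus.

    ``genome`` maps contig id -> sequence.  Windows are returned in the
    read's orientation as (window_start_on_contig, window_seq,
    mature_offset, clipped_left, clipped_right); minus-strand windows are
    reverse-complemented so the mature always reads 5'->3' within them.
    """
    contig = genome[locus.chrom]
    read_len = locus.end - locus.start
    # a small margin beyond the star-space bound keeps boundary violations
    # observable instead of silently truncating the search window
    reach = params.max_star_space + params.flank + 40
    windows = []
    # (upstream extension, downstream extension) in contig coordinates;
    # which arm that corresponds to depends on the strand
    extents = [(params.flank, reach), (reach, params.flank)]
    for up, down in extents:
        w0 = max(0, locus.start - up)
        w1 = min(len(contig), locus.end + down)
        if w1 - w0 < read_len + 2 * params.flank:
            continue
        seq = contig[w0:w1]
        offset = locus.start - w0
        clip_left = (locus.start - w0) < up
        clip_right = (w1 - locus.end) < down
        if locus.strand == "-":
            seq = revcomp(seq)
            offset = len(seq) - (offset + read_len)
            clip_left, clip_right = clip_right, clip_left
        windows.append((w0, seq, offset, clip_left, clip_right))
    return windows


def _projected_partner(pairs, pos, lo, hi):
    """Partner of ``pos`` extrapolated from the nearest paired position in
    [lo, hi)."""
    for d in range(hi - lo):
        for q in (pos - d, pos + d):
            if lo <= q < hi and pairs[q] >= 0:
                return pairs[q] - (pos - q)
    return None


def predict_star(pairs: list, m0: int, m1: int) -> tuple | None:
    """Predicted miRNA* interval (2-nt 3' overhangs on both strands)."""
    s0 = _projected_partner(pairs, m1 - 3, m0, m1)
    s1p = _projected_partner(pairs, m0, m0, m1)
    if s0 is None or s1p is None or s1p < s0:
        return None
    return (s0, s1p + 3)


def duplex_stats_from_fold(pairs: list, m0: int, m1: int, s0: int, s1: int) -> dict:
    """miRNA:miRNA* duplex statistics read off the precursor fold.

    mismatches: symmetric unpaired positions (per mature side), terminal
    unpaired 5' positions included, up to 2 nt of 3' overhang excluded.
    bulges: asymmetric events; bulge size is the asymmetric excess of one
    event, asymmetry the net excess over the duplex.
    """
    idx = [i for i in range(m0, m1) if pairs[i] >= 0 and s0 <= pairs[i] < s1]
    if not idx:
        return {"pairs": 0, "mismatches": m1 - m0, "n_asym_bulges": 0,
                "max_bulge": 0, "asymmetry": 0}
    mism = 0
    n_events = 0
    max_bulge = 0
    gm_total = gs_total = 0
    for a, b in zip(idx, idx[1:]):
        g_m = b - a - 1
        g_s = max(0, pairs[a] - pairs[b] - 1)
        mism += min(g_m, g_s)
        if g_m != g_s:
            n_events += 1
            max_bulge = max(max_bulge, abs(g_m - g_s))
        gm_total += g_m
        gs_total += g_s
    mism += (idx[0] - m0) + max(0, (m1 - 1 - idx[-1]) - 2)
    return {
        "pairs": len(idx),
        "mismatches": mism,
        "n_asym_bulges": n_events,
        "max_bulge": max_bulge,
        "asymmetry": abs(gm_total - gs_total),
    }


def _star_in_libraries(precursor: str, s0: int, s1: int, libs: dict,
                       tolerance: int) -> tuple:
    """Counts of reads matching the predicted star within the end-shift
    tolerance.  Returns (observed, per-tissue counts)."""
    counts = {t: 0 for t in libs}
    seen = set()
    for ds in range(-tolerance, tolerance + 1):
        for de in range(-tolerance, tolerance + 1):
            a, b = s0 + ds, s1 + de
            if a < 0 or b > len(precursor) or b - a < 15:
                continue
            var = precursor[a:b]
            if var in seen:
                continue
            seen.add(var)
            for tissue, lib in libs.items():
                counts[tissue] += lib.unique_reads.get(var, 0)
    return any(v > 0 for v in counts.values()), counts


def evaluate_candidate(window_seq: str, mature_offset: int, read: str,
                       libs: dict, params: DiscoveryParams,
                       locus: Locus | None = None,
                       clipped: tuple = (False, False)) -> HairpinCandidate:
    """Fold a window, excise the precursor, and fill the criteria ledger.

    ``libs`` maps tissue -> unannotated ReadLibrary (used for supporting
    reads and miRNA* observation).  The returned candidate carries a
    pass/fail ledger over the twelve filter criteria plus the
    ``star_observed`` fact; ``rejected_reason`` is set for structural
    rejections (loop-spanning reads, unfoldable windows) that never reach
    the ledger.
    """
    locus = locus or Locus(chrom="?", start=0, end=len(read), strand="+")
    cand = HairpinCandidate(locus=locus, precursor_start=0)
    cand.mature_seq = read
    L = len(read)

    def reject(reason: str) -> HairpinCandidate:
        cand.rejected_reason = reason
        return cand

    first = fold(window_seq)
    m0, m1 = mature_offset, mature_offset + L
    partners = [first.pairs[i] for i in range(m0, m1) if first.pairs[i] >= 0]
    if not partners:
        return reject("unpaired")
    if any(m0 <= p < m1 for p in partners):
        return reject("loop-spanning")
    star0 = predict_star(first.pairs, m0, m1)
    if star0 is None:
        return reject("unpaired")

    # excise: duplex extent plus flanks, then refold
    lo = max(0, min(m0, star0[0]) - params.flank)
    hi = min(len(window_seq), max(m1, star0[1]) + params.flank)
    precursor = window_seq[lo:hi]
    cand.precursor_start = lo
    cand.precursor_seq = precursor
    m0, m1 = m0 - lo, m1 - lo
    res = fold(precursor)
    cand.fold = res
    cand.mature_span = (m0, m1)

    partners = [res.pairs[i] for i in range(m0, m1) if res.pairs[i] >= 0]
    if not partners:
        return reject("unpaired")
    if any(m0 <= p < m1 for p in partners):
        return reject("loop-spanning")
    star = predict_star(res.pairs, m0, m1)
    if star is None:
        return reject("unpaired")
    s0, s1 = max(0, star[0]), min(len(precursor), star[1])
    if s1 <= s0 or (s0 < m1 and m0 < s1):
        return reject("star-overlap")
    cand.star_span = (s0, s1)
    cand.star_seq = precursor[s0:s1]
    cand.arm = "5p" if m0 < s0 else "3p"

    stats = duplex_stats_from_fold(res.pairs, m0, m1, s0, s1)
    cand.duplex_stats = stats
    cand.mfei = mfei(precursor, res.mfe)

    # supporting reads: library reads occurring in the precursor and
    # overlapping the mature interval
    support = {}
    for tissue, lib in libs.items():
        for seq, count in lib.unique_reads.items():
            pos = precursor.find(seq)
            while pos >= 0:
                if pos < m1 and m0 < pos + len(seq):
                    support[seq] = support.get(seq, 0) + count
                pos = precursor.find(seq, pos + 1)
    if read not in support:
        support[read] = sum(l.unique_reads.get(read, 0) for l in libs.values())
    representative = max(support, key=lambda s: (support[s], s == read, s))

    space = s0 - m1 if m0 < s0 else m0 - s1
    left_flank = min(m0, s0)
    right_flank = len(precursor) - max(m1, s1)

    ledger = cand.criteria_ledger
    ledger["len_mature"] = all(
        params.mirna_len[0] <= len(s) <= params.mirna_len[1] for s in support
    )
    ledger["len_ref"] = (
        params.ref_len[0] <= len(representative) <= params.ref_len[1]
    )
    ledger["max_copies"] = True  # finalized at catalog level
    ledger["precursor_mfe"] = res.mfe < params.max_precursor_mfe
    ledger["star_space"] = space <= params.max_star_space
    ledger["duplex_pairs"] = stats["pairs"] >= params.min_duplex_pairs
    ledger["duplex_bulge"] = stats["max_bulge"] <= params.max_duplex_bulge
    ledger["duplex_asymmetry"] = (
        stats["asymmetry"] <= params.max_duplex_asymmetry
    )
    ledger["flank"] = (
        left_flank >= params.flank and right_flank >= params.flank
    )
    ledger["mfei"] = cand.mfei >= params.min_mfei
    ledger["manual_bulges"] = stats["n_asym_bulges"] <= params.max_manual_bulges
    ledger["manual_mismatches"] = (
        stats["mismatches"] <= params.max_manual_mismatches
    )

    observed, star_counts = _star_in_libraries(
        precursor, s0, s1, libs, params.star_shift_tolerance
    )
    cand.star_observed = observed
    cand.duplex_stats["star_counts"] = star_counts
    cand.counts = {
        t: lib.unique_reads.get(read, 0) for t, lib in libs.items()
    }
    return cand


def manual_filter(cand: HairpinCandidate, params: DiscoveryParams) -> tuple:
    """Accept/reject decision with its reason.

    Accept when all Mireap filters pass AND (all manual filters pass OR
    the predicted miRNA* is observed).  Mireap failures are never rescued.
    """
    if cand.rejected_reason:
        return False, cand.rejected_reason
    if not cand.mireap_pass:
        return False, "mireap:" + ",".join(
            c for c in MIREAP_CRITERIA if not cand.criteria_ledger[c]
        )
    if cand.manual_pass:
        return True, "manual-criteria"
    if cand.star_observed:
        return True, "star-rescue"
    return False, "manual:" + ",".join(
        c for c in MANUAL_CRITERIA if not cand.criteria_ledger[c]
    )


def _absorb_star_arms(accepted: list, params: DiscoveryParams) -> list:
    """Drop candidates whose mature is another accepted candidate's
    predicted miRNA* (the duplex partner seeded its own candidate); the
    more abundant strand keeps the entry."""
    keep = []
    tol = params.star_shift_tolerance
    for cand in accepted:
        absorbed = False
        for other in accepted:
            if other is cand:
                continue
            if len(cand.mature_seq) < 15 or not other.star_seq:
                continue
            pos = other.precursor_seq.find(cand.mature_seq)
            o_s0, o_s1 = other.star_span
            if pos >= 0 and abs(pos - o_s0) <= tol and abs(
                pos + len(cand.mature_seq) - o_s1
            ) <= tol:
                c_total = sum(cand.counts.values())
                o_total = sum(other.counts.values())
                if (o_total, other.mature_seq) > (c_total, cand.mature_seq):
                    absorbed = True
                    break
        if not absorbed:
            keep.append(cand)
    return keep


def build_novel_catalog(accepted: list, params: DiscoveryParams,
                        name_prefix: str = "mno-miRn") -> list:
    """Group accepted candidates by mature sequence into catalog entries.

    Matures at more than ``max_copies`` loci are dropped entirely (their
    candidates' ledgers record the max_copies failure).  Entries are named
    <prefix>1, <prefix>2, ... in descending total-count order.
    """
    accepted = _absorb_star_arms(accepted, params)
    by_mature: dict[str, list[HairpinCandidate]] = {}
    for cand in accepted:
        by_mature.setdefault(cand.mature_seq, []).append(cand)
    entries = []
    for mature, cands in by_mature.items():
        loci = [c.locus for c in cands]
        if len(loci) > params.max_copies:
            for c in cands:
                c.criteria_ledger["max_copies"] = False
            continue
        counts = dict(cands[0].counts)
        star_counts = {t: 0 for t in counts}
        for c in cands:
            for t, v in c.duplex_stats.get("star_counts", {}).items():
                star_counts[t] = max(star_counts[t], v)
        entries.append(
            NovelCatalogEntry(
                name="", mature_seq=mature, loci=loci, counts=counts,
                star_counts=star_counts,
                star_observed=any(c.star_observed for c in cands),
                precursors=cands,
            )
        )
    entries.sort(key=lambda e: (-e.total_count(), e.mature_seq))
    for i, e in enumerate(entries, start=1):
        e.name = f"{name_prefix}{i}"
    return entries


def star_expression_compare(entry: NovelCatalogEntry) -> dict:
    """Per-tissue (miRNA count, star count, star_dominant) comparison;
    the star dominates only on a strictly greater count."""
    out = {}
    for tissue, n in entry.counts.items():
        star_n = entry.star_counts.get(tissue, 0)
        out[tissue] = (n, star_n, star_n > n)
    return out


def discover_novel(libs: dict, genome: list, params: DiscoveryParams | None = None):
    """Full discovery pass over unannotated tissue libraries.

    Returns (catalog entries, all evaluated candidates).  ``libs`` maps
    tissue -> ReadLibrary of unannotated reads; ``genome`` is a list of
    SequenceRecord contigs.
    """
    params = params or DiscoveryParams()
    genome_map = {c.id: c.seq for c in genome}

    pooled = ReadLibrary(label="pooled")
    for lib in libs.values():
        for seq, count in lib.unique_reads.items():
            pooled.unique_reads[seq] = pooled.unique_reads.get(seq, 0) + count
    hits = match_genome(pooled, genome)

    candidates = []
    accepted = []
    for seq in sorted(pooled.unique_reads):
        for locus in hits[seq]:
            best = None
            for w0, wseq, offset, cl, cr in candidate_precursors(
                locus, genome_map, params
            ):
                cand = evaluate_candidate(
                    wseq, offset, seq, libs, params, locus=locus,
                    clipped=(cl, cr),
                )
                ok, reason = manual_filter(cand, params)
                cand.duplex_stats["decision"] = reason
                if ok:
                    best = cand
                    break
                if best is None or (
                    best.rejected_reason and not cand.rejected_reason
                ):
                    best = cand
            if best is not None:
                candidates.append(best)
                ok, _ = manual_filter(best, params)
                if ok:
                    accepted.append(best)
    entries = build_novel_catalog(accepted, params)
    return entries, candidates
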