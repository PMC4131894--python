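"""Transcriptome-wide miRNA target-site scan under position-weighted
complementarity rules (Allen/Schwab-style).

Every length-|miRNA| window of a transcript is scored as an ungapped
antiparallel duplex.  Positions are numbered 1..L from the miRNA 5' end;
G:U wobbles count 0.5 toward mismatch totals and count as mismatch
*positions* for the adjacency and position-10/11 rules (strict reading;
switchable via ``gu_blocks_positions``).  The six acceptance rules, checked
in order:

1. weighted mismatch total <= 4 (G:U = 0.5);
2. no run of more than 2 consecutive mismatch positions;
3. no two adjacent mismatch positions with both indices in 2..12;
4. positions 10 and 11 both Watson-Crick;
5. weighted mismatch total over positions 1..12 <= 2.5;
6. duplex energy >= 75% of the miRNA's perfect-complement energy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rnafold import DuplexAlignment, duplex, perfect_complement_energy
from .seqio import to_dna

MAX_WEIGHTED_TOTAL = 4.0
MAX_CONSECUTIVE_MM = 2
SEED_REGION = (2, 12)      # 1-based inclusive positions for rule 3
CLEAVAGE_POSITIONS = (10, 11)
MAX_SEED_WEIGHTED = 2.5
MIN_ENERGY_RATIO = 0.75
RULE_IDS = (1, 2, 3, 4, 5, 6)


@dataclass
class TargetSite:
    transcript_id: str
    start: int                 # 0-based half-open on the transcript
    end: int
    duplex: DuplexAlignment
    weighted_total: float
    seed_weighted_total: float
    energy_ratio: float
    accepted: bool
    first_violated: int | None  # rule number, None when accepted
    rule_pass: dict             # rule number -> bool


def _mismatch_positions(classes: list, gu_blocks: bool) -> list:
    """1-based positions counted as mismatch positions."""
    bad = {"MM", "GU"} if gu_blocks else {"MM"}
    return [i + 1 for i, c in enumerate(classes) if c in bad]


def score_site(mirna: str, window: str, transcript_id: str = "",
               start: int = 0, gu_blocks_positions: bool = True,
               perfect_energy: float | None = None) -> TargetSite:
    """Score one window against the six rules.

    ``perfect_energy`` caches perfect_complement_energy(mirna) across a
    scan.  ``gu_blocks_positions=False`` relaxes rules 2-4 to full
    mismatches only.
    """
    mirna = to_dna(mirna)
    window = to_dna(window)
    dup = duplex(mirna, window)
    L = len(mirna)
    weighted = dup.weighted_mismatches
    lo, hi = SEED_REGION
    seed_weighted = sum(
        1.0 if c == "MM" else 0.5 if c == "GU" else 0.0
        for c in dup.classes[: min(12, L)]
    )
    mm_pos = set(_mismatch_positions(dup.classes, gu_blocks_positions))

    # longest run of consecutive mismatch positions
    run = best_run = 0
    for p in range(1, L + 1):
        run = run + 1 if p in mm_pos else 0
        best_run = max(best_run, run)

    adjacent_in_seed = any(
        p in mm_pos and p + 1 in mm_pos and lo <= p and p + 1 <= hi
        for p in range(1, L)
    )
    if perfect_energy is None:
        perfect_energy = perfect_complement_energy(mirna)
    ratio = dup.energy / perfect_energy if perfect_energy < 0 else 0.0

    rule_pass = {
        1: weighted <= MAX_WEIGHTED_TOTAL,
        2: best_run <= MAX_CONSECUTIVE_MM,
        3: not adjacent_in_seed,
        4: all(p not in mm_pos for p in CLEAVAGE_POSITIONS),
        5: seed_weighted <= MAX_SEED_WEIGHTED,
        6: ratio >= MIN_ENERGY_RATIO,
    }
    first = next((r for r in RULE_IDS if not rule_pass[r]), None)
    return TargetSite(
        transcript_id=transcript_id, start=start, end=start + L, duplex=dup,
        weighted_total=weighted, seed_weighted_total=seed_weighted,
        energy_ratio=ratio, accepted=first is None, first_violated=first,
        rule_pass=rule_pass,
    )


def scan(mirna: str, transcript, gu_blocks_positions: bool = True) -> list:
    """All accepted sites of a miRNA on one transcript (sense strand),
    sorted by weighted total then energy ratio (best first).

    ``transcript`` is a SequenceRecord or any object with .id and .seq.
    """
    mirna = to_dna(mirna)
    seq = to_dna(transcript.seq)
    if len(seq) < len(mirna):
        raise ValueError(
            f"transcript {transcript.id!r} shorter than miRNA ({len(seq)} < {len(mirna)})"
        )
    pe = perfect_complement_energy(mirna)
    sites = []
    for start in range(0, len(seq) - len(mirna) + 1):
        site = score_site(
            mirna, seq[start : start + len(mirna)], transcript_id=transcript.id,
            start=start, gu_blocks_positions=gu_blocks_positions,
            perfect_energy=pe,
        )
        if site.accepted:
            sites.append(site)
    sites.sort(key=lambda s: (s.weighted_total, -s.energy_ratio, s.start))
    return sites


def annotate_targets(mirnas: dict, transcripts: list,
                     descriptions: dict | None = None,
                     gu_blocks_positions: bool = True) -> list:
    """Per-miRNA report of distinct target transcripts with the best site.

    ``mirnas`` maps name -> sequence.  Returns a list of dicts with keys
    miRNA, transcript, description, start, end, weighted_mismatches,
    energy_ratio, alignment.
    """
    descriptions = descriptions or {}
    report = []
    for name in sorted(mirnas):
        seq = mirnas[name]
        for tr in transcripts:
            sites = scan(seq, tr, gu_blocks_positions=gu_blocks_positions)
            if not sites:
                continue
            best = sites[0]
            report.append(
                {
                    "miRNA": name,
                    "transcript": tr.id,
                    "description": descriptions.get(tr.id, "NA"),
                    "start": best.start,
                    "end": best.end,
                    "weighted_mismatches": best.weighted_total,
                    "energy_ratio": round(best.energy_ratio, 3),
                    "alignment": best.duplex.alignment_string(),
                }
            )
    return report
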