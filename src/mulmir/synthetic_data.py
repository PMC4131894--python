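"""Synthetic study generator with machine-readable ground truth.

Emulates the structure of a three-tissue plant small-RNA experiment:

* a toy genome carrying planted miRNA hairpins that satisfy every
  discovery criterion, plus knockout decoys each violating exactly one
  criterion (the decoy proves the corresponding filter is live);
* three tissue read libraries (leaf, bark, male_flower) with 18-30 nt
  inserts, 21/24-nt-dominated length profiles, planted conserved miRNAs
  with controlled tissue bias, ncRNA/degradation decoys and random
  background, written as adapter-carrying FASTQ;
* a multi-species mature reference emitting per-species variants at
  controlled edit distance (0 / 2 / 5) so conservation profiles are known;
* transcripts with planted target sites of controlled rule budgets and
  single-rule knockouts;
* a triplicate Ct table generated from known relative quantities.

Every generator validates its own truth with the corresponding evaluator
before writing (up to 100 attempts per construct) and is deterministic for
a given seed: one child RNG stream per artifact, drawn in fixed order.

The planted effect size for tissue-biased families is 3x (the bias call
uses a 2x boundary; at the default depth of 50,000 reads per library the
binomial sampling noise stays well inside the margin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .novel_discovery import (
    DiscoveryParams,
    candidate_precursors,
    evaluate_candidate,
    manual_filter,
)
from .preprocess import ReadLibrary
from .seqio import Locus, SequenceRecord, revcomp, write_fasta, write_fastq
from .target_pred import score_site
from .conserved_catalog import edit_distance

TISSUES = ("leaf", "bark", "male_flower")
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter
READ_LEN = 40
MAX_ATTEMPTS = 100

KNOCKOUT_IDS = (
    "len_mature", "len_ref", "max_copies", "precursor_mfe", "star_space",
    "duplex_pairs", "duplex_bulge", "duplex_asymmetry", "flank",
    "mfei", "manual_bulges", "manual_mismatches",
)
RESCUE_ID = "star_rescue"

BASES = "ACGT"


class GenerationError(RuntimeError):
    """A construct could not satisfy its criteria within the attempt cap."""


def _rand_seq(rng, n: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(p)))


def _spacer(rng, n: int) -> str:
    # A/C-skewed background: low self-complementarity, low GC
    return _rand_seq(rng, n, p=(0.55, 0.3, 0.05, 0.1))


def _gc_seq(rng, n: int, gc: float) -> str:
    p_gc = gc / 2
    p_at = (1 - gc) / 2
    return _rand_seq(rng, n, p=(p_at, p_gc, p_gc, p_at))


_NONPAIR = {
    "A": "ACG",  # anything but T (A:T WC; A has no wobble partner)
    "C": "ACT",  # anything but G
    "G": "AG",   # not C (WC) and not T (G:U wobble)
    "T": "CT",   # not A (WC) and not G (wobble)
}


def _mismatch_base(rng, mature_base: str) -> str:
    return rng.choice(list(_NONPAIR[mature_base]))


@dataclass
class HairpinSpec:
    """Recipe for one planted hairpin block."""

    mature_len: int = 21
    mature_gc: float = 0.6
    mature_bases: str = ""       # override composition (e.g. AT-only)
    loop_len: int = 8
    subs: tuple = ()             # mature positions given a non-pairing star base
    dels: tuple = ()             # mature positions left unpaired (star deletion)
    star_ins: tuple = ()         # (after mature position, length) star-side bulges
    del_base: str = ""           # force the deleted mature stretch to this base
    sub_base: str = ""           # force the mismatched mature positions
    sub_star_base: str = ""      # force the star base facing a mismatch
    ins_base: str = "A"          # star-side bulge filler
    mature_no_a: bool = False    # A-free mature: forced bulges cannot re-pair
    n_gu: int = 2                # G:U wobbles in the stem (breaks palindromy so
                                 # the mature cannot re-map to the star arm)
    low_gc_context: bool = False  # near-GC-free loop and flanks (keeps MFEI
                                  # high around a deliberately weak stem)
    ext_helix: int = 0           # extra stem bp outside the duplex
    left_flank: int = 20
    right_flank: int = 20
    arm: str = "5p"
    long_arm_ext: int = 0        # extend the mature arm (star-space design)


@dataclass
class PlantedHairpin:
    mature: str
    star: str
    block: str
    mature_offset: int           # within block
    violated: str | None
    contig: str = ""
    start: int = 0               # mature locus on the contig
    strand: str = "+"
    extra_reads: dict = field(default_factory=dict)  # seq -> count weight


def _build_block(rng, spec: HairpinSpec) -> tuple[str, str, int]:
    """Assemble a hairpin block; returns (block, mature, mature_offset)."""
    if spec.mature_bases:
        mature = "".join(rng.choice(list(spec.mature_bases), size=spec.mature_len))
    elif spec.mature_no_a:
        p_gc = spec.mature_gc / 2
        mature = "".join(
            rng.choice(["T", "C", "G"], size=spec.mature_len,
                       p=[1 - spec.mature_gc, p_gc, p_gc])
        )
    else:
        mature = _gc_seq(rng, spec.mature_len, spec.mature_gc)
    if spec.del_base:
        mature = "".join(
            spec.del_base if i in spec.dels else b for i, b in enumerate(mature)
        )
    if spec.sub_base:
        mature = "".join(
            spec.sub_base if i in spec.subs else b for i, b in enumerate(mature)
        )
    wobble = {"G": "T", "T": "G"}
    if spec.long_arm_ext:
        arm1 = mature + _gc_seq(rng, spec.long_arm_ext, 0.55)
        arm2 = list(revcomp(arm1))
        eligible = [j for j, b in enumerate(arm1) if b in wobble]
        for j in rng.choice(eligible, size=min(spec.n_gu, len(eligible)),
                            replace=False):
            arm2[len(arm1) - 1 - j] = wobble[arm1[j]]
        loop = _spacer(rng, spec.loop_len)
        block = (
            _spacer(rng, spec.left_flank) + arm1 + loop + "".join(arm2)
            + _spacer(rng, spec.right_flank)
        )
        return block, mature, spec.left_flank
    # star strand: complement of the mature walked 3'->5'
    star_parts = []
    ins_map = dict(spec.star_ins)
    comp = dict(zip("ACGT", "TGCA"))
    eligible = [
        i for i, b in enumerate(mature)
        if b in wobble and i not in spec.dels and i not in spec.subs
    ]
    gu_at = set(
        int(j) for j in rng.choice(
            eligible, size=min(spec.n_gu, len(eligible)), replace=False
        )
    )
    for i in range(spec.mature_len - 1, -1, -1):
        if i in spec.dels:
            pass
        elif i in spec.subs:
            star_parts.append(spec.sub_star_base
                              or _mismatch_base(rng, mature[i]))
        elif i in gu_at:
            star_parts.append(wobble[mature[i]])
        else:
            star_parts.append(comp[mature[i]])
        if i in ins_map:
            star_parts.append(spec.ins_base * ins_map[i])
    star_core = "".join(star_parts)
    ext5 = _gc_seq(rng, spec.ext_helix, 0.7) if spec.ext_helix else ""

    def ctx(n):
        if spec.low_gc_context:
            return _rand_seq(rng, n, p=(0.7, 0.15, 0.0, 0.15))
        return _spacer(rng, n)

    loop = ctx(spec.loop_len)
    lf = ctx(spec.left_flank)
    rf = ctx(spec.right_flank)
    if spec.arm == "5p":
        block = lf + ext5 + mature + loop + star_core + revcomp(ext5) + rf
        offset = len(lf) + len(ext5)
    else:
        block = lf + ext5 + star_core + loop + mature + revcomp(ext5) + rf
        offset = len(lf) + len(ext5) + len(star_core) + len(loop)
    return block, mature, offset


# knockout recipes: each decoy must fail exactly the named criterion
_RECIPES = {
    None: HairpinSpec(),
    "len_ref": HairpinSpec(mature_len=24),
    "len_mature": HairpinSpec(),   # plus a planted 26-nt supporting read
    "precursor_mfe": HairpinSpec(mature_bases="AT", mature_len=20, loop_len=8,
                                 low_gc_context=True),
    "star_space": HairpinSpec(long_arm_ext=151),
    "duplex_pairs": HairpinSpec(subs=(8, 9, 10), dels=(14, 15, 16),
                                ext_helix=12, mature_gc=0.7, mature_no_a=True,
                                del_base="A", sub_base="G", sub_star_base="A"),
    "duplex_bulge": HairpinSpec(mature_len=23, dels=(4, 5, 6, 7, 8),
                                star_ins=((17, 2),), ext_helix=10,
                                mature_gc=0.65, mature_no_a=True, del_base="A"),
    "duplex_asymmetry": HairpinSpec(mature_len=23, dels=(4, 5, 6, 15, 16),
                                    ext_helix=8, mature_gc=0.65,
                                    mature_no_a=True, del_base="A"),
    "manual_bulges": HairpinSpec(dels=(5, 11, 16), ext_helix=16, mature_gc=0.75,
                                 mature_no_a=True, del_base="A"),
    "manual_mismatches": HairpinSpec(mature_len=23, subs=(5, 9, 13, 17),
                                     ext_helix=16, mature_gc=0.75,
                                     mature_no_a=True, sub_base="G",
                                     sub_star_base="A"),
    "mfei": HairpinSpec(loop_len=110),
    "flank": HairpinSpec(left_flank=5),
    RESCUE_ID: HairpinSpec(loop_len=110),
}


def _evaluate_in_contig(contig: str, locus: Locus, mature: str,
                        read_counts: dict, params: DiscoveryParams) -> tuple:
    """Run the discovery evaluator for one locus in an explicit contig;
    returns (candidate, accepted, reason)."""
    lib = ReadLibrary.from_counts("probe", {mature: 50, **read_counts})
    best = None
    for _w0, wseq, woff, cl, cr in candidate_precursors(
        locus, {locus.chrom: contig}, params
    ):
        cand = evaluate_candidate(wseq, woff, mature, {"probe": lib}, params,
                                  locus=locus, clipped=(cl, cr))
        ok, reason = manual_filter(cand, params)
        if ok:
            return cand, True, reason
        if best is None or (best[0].rejected_reason and not cand.rejected_reason):
            best = (cand, False, reason)
    return best if best else (None, False, "no-window")


def _probe_block(block: str, mature: str, offset: int, params: DiscoveryParams,
                 extra_reads: dict | None = None,
                 edge: bool = False) -> tuple:
    """Evaluate a block in a generic genome context; returns
    (candidate, decision, reason)."""
    rng = np.random.default_rng(12345)  # fixed probe context
    left = "" if edge else _spacer(rng, 420)
    contig = left + block + _spacer(rng, 420)
    locus = Locus(chrom="probe", start=len(left) + offset,
                  end=len(left) + offset + len(mature), strand="+")
    return _evaluate_in_contig(contig, locus, mature, extra_reads or {},
                               params)


def _expected_ok(violated, cand, ok, reason) -> bool:
    if cand is None or cand.rejected_reason:
        return False
    failing = cand.failing()
    if violated is None:
        return ok and not failing and bool(cand.star_seq)
    if violated == RESCUE_ID:
        return (not ok) and failing == ["mfei"] and bool(cand.star_seq)
    return (not ok) and failing == [violated]


def make_hairpin(rng, violated: str | None,
                 params: DiscoveryParams | None = None) -> PlantedHairpin:
    """Draw hairpins until the evaluator confirms the intended signature."""
    params = params or DiscoveryParams()
    spec = _RECIPES[RESCUE_ID if violated == RESCUE_ID else violated]
    for _ in range(MAX_ATTEMPTS):
        block, mature, offset = _build_block(rng, spec)
        extra = {}
        if violated == "len_mature":
            sup = block[offset - 2 : offset + 24]
            if len(sup) != 26:
                continue
            extra = {sup: 2}
        cand, ok, reason = _probe_block(
            block, mature, offset, params, extra_reads=extra,
            edge=(violated == "flank"),
        )
        if violated == "precursor_mfe" and cand is not None and (
            cand.fold is None or cand.fold.mfe > -4.0
        ):
            continue  # want a real (just too weak) hairpin, not an unfolded one
        if _expected_ok(violated, cand, ok, reason):
            return PlantedHairpin(
                mature=mature, star=cand.star_seq, block=block,
                mature_offset=offset, violated=violated, extra_reads=extra,
            )
    raise GenerationError(
        f"could not construct hairpin for criterion {violated!r} "
        f"in {MAX_ATTEMPTS} attempts"
    )


@dataclass
class TruthSet:
    seed: int
    conserved: list = field(default_factory=list)
    hairpins: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    bias_truth: dict = field(default_factory=dict)
    profile_truth: dict = field(default_factory=dict)  # name -> species -> symbol
    rq_truth: dict = field(default_factory=dict)       # assay -> sample -> RQ
    class_fractions: dict = field(default_factory=dict)
    depth: int = 0

    def true_matures(self) -> list:
        return sorted(
            {h["mature"] for h in self.hairpins if h["violated"] is None}
        )

    def knockout(self, criterion: str) -> dict:
        return next(h for h in self.hairpins if h["violated"] == criterion)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


def make_genome(seed: int, n_true: int = 10,
                knockouts: tuple = KNOCKOUT_IDS + (RESCUE_ID,),
                params: DiscoveryParams | None = None,
                spacing: int = 500):
    """Toy genome with planted and knockout hairpins plus gene models.

    Returns (list of SequenceRecord contigs, TruthSet, gene dict).  True
    hairpins all satisfy the discovery criteria (verified by running the
    evaluator at generation time); each knockout violates exactly its
    named criterion.  Hairpins are separated by >= ``spacing`` nt of
    low-complexity background.
    """
    params = params or DiscoveryParams()
    rng = np.random.default_rng(seed)
    truth = TruthSet(seed=seed)

    def record(contig_name, start, mature, star, violated, strand, extra):
        truth.hairpins.append(
            {"mature": mature, "star": star, "violated": violated,
             "contig": contig_name, "start": start,
             "end": start + len(mature), "strand": strand,
             "extra_reads": extra}
        )

    def plant_verified(parts, contig_name, violated, strand="+",
                       spec_override=None, record_as="__same__"):
        """Draw blocks until the evaluator confirms the intended signature
        IN SITU (real left context and the spacer that will follow)."""
        next_spacer = _spacer(rng, spacing)
        left = "".join(parts)
        ctx = left[-420:]
        recipe = spec_override or _RECIPES[
            RESCUE_ID if violated == RESCUE_ID else violated
        ]
        for _ in range(MAX_ATTEMPTS):
            block, mature, off = _build_block(rng, recipe)
            extra = {}
            if violated == "len_mature":
                sup = block[off - 2 : off + 24]
                if len(sup) != 26:
                    continue
                extra = {sup: 2}
            oriented = block if strand == "+" else revcomp(block)
            m_off = (off if strand == "+"
                     else len(block) - off - len(mature))
            test = ctx + oriented + next_spacer
            locus = Locus(chrom=contig_name, start=len(ctx) + m_off,
                          end=len(ctx) + m_off + len(mature), strand=strand)
            cand, ok, reason = _evaluate_in_contig(test, locus, mature,
                                                   extra, params)
            if violated == "precursor_mfe" and cand is not None and (
                cand.fold is None or cand.fold.mfe > -4.0
            ):
                continue  # want a weak real hairpin, not an unfolded one
            if not _expected_ok(violated, cand, ok, reason):
                continue
            vrec = violated if record_as == "__same__" else record_as
            record(contig_name, len(left) + m_off, mature, cand.star_seq,
                   vrec, strand, extra)
            parts += [oriented, next_spacer]
            return block, mature, off
        raise GenerationError(
            f"could not construct hairpin for criterion {violated!r} "
            f"in {MAX_ATTEMPTS} attempts"
        )

    def replant_copy(parts, contig_name, block, mature, off):
        """Re-plant an already-verified block at a fresh locus, redrawing
        the following spacer until the evaluator accepts it there too."""
        left = "".join(parts)
        ctx = left[-420:]
        for _ in range(MAX_ATTEMPTS):
            next_spacer = _spacer(rng, spacing)
            test = ctx + block + next_spacer
            locus = Locus(chrom=contig_name, start=len(ctx) + off,
                          end=len(ctx) + off + len(mature), strand="+")
            cand, ok, reason = _evaluate_in_contig(test, locus, mature, {},
                                                   params)
            if _expected_ok(None, cand, ok, reason):
                record(contig_name, len(left) + off, mature, cand.star_seq,
                       "max_copies", "+", {})
                parts += [block, next_spacer]
                return
        raise GenerationError("could not re-plant copy-number decoy")

    # chr1: true hairpins (one 3'-arm mature, one minus-strand)
    parts = [_spacer(rng, spacing)]
    for i in range(n_true):
        spec = None
        if i == 1:
            spec = HairpinSpec(**{**asdict(_RECIPES[None]), "arm": "3p"})
        strand = "-" if i == 2 else "+"
        plant_verified(parts, "chr1", None, strand=strand, spec_override=spec)
    chr1 = "".join(parts)

    # chr2: knockout decoys (and the copy-number decoy's 21 loci)
    parts = [_spacer(rng, spacing)]
    for violated in knockouts:
        if violated == "flank":
            continue  # gets its own contig edge
        if violated == "max_copies":
            block, mature, off = plant_verified(
                parts, "chr2", None, record_as="max_copies"
            )
            for _ in range(params.max_copies):
                replant_copy(parts, "chr2", block, mature, off)
            continue
        plant_verified(parts, "chr2", violated)
    chr2 = "".join(parts)

    # chrEdge: the flank decoy hugs the contig start
    if "flank" in knockouts:
        parts = []
        plant_verified(parts, "chrEdge", "flank")
        chredge = "".join(parts)
    else:
        chredge = _spacer(rng, spacing)

    # chr3: gene models feeding the annotation decoy classes
    genes = {
        "rRNA": _rand_seq(rng, 400), "tRNA": _rand_seq(rng, 160),
        "snRNA": _rand_seq(rng, 140), "snoRNA": _rand_seq(rng, 120),
        "repeat": _rand_seq(rng, 250),
        "exon": _rand_seq(rng, 500), "intron": _rand_seq(rng, 400),
    }
    chr3 = _spacer(rng, 200) + "".join(
        genes[k] + _spacer(rng, 120) for k in sorted(genes)
    )

    contigs = [
        SequenceRecord(id="chr1", seq=chr1),
        SequenceRecord(id="chr2", seq=chr2),
        SequenceRecord(id="chrEdge", seq=chredge),
        SequenceRecord(id="chr3", seq=chr3),
    ]
    return contigs, truth, genes


# ---------------------------------------------------------------- conserved

FAMILY_IDS = (901, 902, 903, 904, 905, 906, 907, 908)
PROFILE_SPECIES = ("aca", "bcb", "ccc", "dcd", "ece")
_PROFILE_CLASSES = {0: "++", 2: "+", 5: "-"}


def make_conserved(seed: int, truth: TruthSet) -> list:
    """Planted conserved miRNAs: one per family, with a reference-exact
    entry and per-species variants at controlled edit distance."""
    rng = np.random.default_rng(seed + 1)
    labels = (["leaf-biased"] * 2 + ["bark-biased"] * 2
              + ["male_flower-biased"] * 2 + ["unbiased"] * 2)
    for fam_id, label in zip(FAMILY_IDS, labels):
        family = f"miR{fam_id}"
        for _ in range(MAX_ATTEMPTS):
            seq = _rand_seq(rng, 21)
            if all(seq != c["seq"] for c in truth.conserved):
                break
        base = 3.0 if label == "unbiased" else 1.0
        weights = {t: base for t in TISSUES}
        if label != "unbiased":
            weights[label.replace("-biased", "")] = 3.0
        truth.conserved.append(
            {"seq": seq, "family": family, "ref_name": f"gma-{family}",
             "weights": weights, "label": label}
        )
        truth.bias_truth[family] = label
    return truth.conserved


def make_species_reference(truth: TruthSet, seed: int) -> list:
    """Multi-species mature FASTA records with known conservation classes.

    For every planted conserved miRNA each toy species carries a variant
    at edit distance 0 ("++"), 2 ("+") or 5 ("-" -- emitted as a distant
    decoy so absence is still exercised against a non-empty set).
    """
    rng = np.random.default_rng(seed + 2)
    records = []
    for entry in truth.conserved:
        family = entry["family"]
        records.append(SequenceRecord(id=entry["ref_name"], seq=entry["seq"]))
        profile = {}
        for i, species in enumerate(PROFILE_SPECIES):
            dist = (0, 2, 5)[(FAMILY_IDS.index(int(family[3:])) + i) % 3]
            for _ in range(MAX_ATTEMPTS):
                var = _mutate(rng, entry["seq"], dist)
                if edit_distance(var, entry["seq"]) == dist:
                    break
            else:
                raise GenerationError("variant distance not achieved")
            profile[species] = _PROFILE_CLASSES[dist]
            records.append(
                SequenceRecord(id=f"{species}-{family}{'abc'[i % 3]}", seq=var)
            )
        truth.profile_truth[entry["ref_name"]] = profile
    return records


def _mutate(rng, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != seq[p]])
    return "".join(out)


# ---------------------------------------------------------------- libraries

DEFAULT_CLASS_FRACTIONS = {
    "conserved": 0.12, "novel": 0.06, "star": 0.01,
    "rRNA": 0.10, "tRNA": 0.05, "snRNA": 0.01, "snoRNA": 0.01,
    "repeat": 0.03, "exon": 0.06, "intron": 0.04,
    "background": 0.51,
}
LENGTH_PROFILES = {
    "leaf": {"mode": 24},
    "bark": {"mode": 24},
    "male_flower": {"mode": 21},
}


def _length_probs(mode: int) -> tuple:
    lengths = np.arange(18, 31)
    probs = np.full(len(lengths), 0.02)
    probs[lengths == mode] = 0.52
    probs[lengths == (21 if mode == 24 else 24)] = 0.10
    probs[lengths == 22] = 0.08
    probs[lengths == 23] = 0.06
    probs = probs / probs.sum()
    return lengths, probs


def make_libraries(truth: TruthSet, seed: int, genes: dict,
                   depth: int = 50_000,
                   class_fractions: dict | None = None,
                   outdir=None) -> dict:
    """Sample three tissue libraries; optionally write FASTQ files.

    Returns tissue -> list of (read id, full read with adapter, quality).
    Class counts are multinomial at ``depth``; within the conserved class
    the planted tissue weights set the bias (3x for biased families).
    A sprinkle of low-quality and N-containing reads exercises cleaning.
    """
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, not 1")
    truth.class_fractions = fractions
    truth.depth = depth
    classes = sorted(fractions)
    rng = np.random.default_rng(seed + 3)

    novel_templates = []
    star_templates = []
    for h in truth.hairpins:
        w = float(rng.uniform(0.5, 2.0))
        if h["violated"] is None:
            novel_templates.append((h["mature"], w))
            star_templates.append((h["star"], w * 0.12))
        elif h["violated"] == RESCUE_ID:
            novel_templates.append((h["mature"], w * 0.3))
            star_templates.append((h["star"], w * 0.1))
        elif h["violated"] == "max_copies":
            if all(t[0] != h["mature"] for t in novel_templates):
                novel_templates.append((h["mature"], w * 0.3))
        else:
            novel_templates.append((h["mature"], w * 0.3))
        for seq, n in h.get("extra_reads", {}).items():
            novel_templates.append((seq, 0.05))

    libraries = {}
    for tissue in TISSUES:
        lengths, lprobs = _length_probs(LENGTH_PROFILES[tissue]["mode"])
        n_per_class = rng.multinomial(depth, [fractions[c] for c in classes])
        reads = []
        for cls, n in zip(classes, n_per_class):
            if cls == "conserved":
                weights = np.array(
                    [c["weights"][tissue] for c in truth.conserved]
                )
                picks = rng.multinomial(n, weights / weights.sum())
                for entry, k in zip(truth.conserved, picks):
                    reads += [entry["seq"]] * int(k)
            elif cls in ("novel", "star"):
                templates = novel_templates if cls == "novel" else star_templates
                if not templates:
                    continue
                weights = np.array([w for _, w in templates])
                picks = rng.multinomial(n, weights / weights.sum())
                for (seq, _), k in zip(templates, picks):
                    reads += [seq] * int(k)
            elif cls == "background":
                for _ in range(n):
                    L = int(rng.choice(lengths, p=lprobs))
                    reads.append(_rand_seq(rng, L))
            else:  # fragment classes from the gene models
                gene = genes[cls]
                for _ in range(n):
                    L = int(rng.choice(lengths, p=lprobs))
                    start = int(rng.integers(0, len(gene) - L + 1))
                    frag = gene[start : start + L]
                    if cls in ("exon", "intron") and rng.random() < 0.3:
                        frag = revcomp(frag)
                    reads.append(frag)
        rng.shuffle(reads)
        fastq = []
        for i, insert in enumerate(reads):
            seq = (insert + ADAPTER3 + _spacer(rng, READ_LEN))[:READ_LEN]
            fastq.append((f"{tissue}_{i}", seq, "I" * READ_LEN))
        # reads the cleaner must discard
        n_junk = max(1, depth // 200)
        for j in range(n_junk):
            seq = _rand_seq(rng, READ_LEN)
            fastq.append((f"{tissue}_lowq_{j}", seq, "#" * READ_LEN))
            withn = list(_rand_seq(rng, 22) + ADAPTER3)[:READ_LEN]
            withn[int(rng.integers(0, 20))] = "N"
            fastq.append(
                (f"{tissue}_n_{j}", "".join(withn).ljust(READ_LEN, "A")[:READ_LEN],
                 "I" * min(READ_LEN, len(withn)))
            )
        libraries[tissue] = fastq
        if outdir is not None:
            write_fastq(fastq, Path(outdir) / f"lib_{tissue}.fastq")
    return libraries


# ---------------------------------------------------------------- targets

SITE_RECIPES = {
    None: [("perfect", ()), ("two_gu", ()), ("mixed", ())],
    "rule1": [("rule1", ())], "rule2": [("rule2", ())],
    "rule3": [("rule3", ())], "rule4": [("rule4", ())],
    "rule5": [("rule5", ())], "rule6": [("rule6", ())],
}


def _rule_mirna(rng, recipe: str) -> str:
    """Design a 21-nt miRNA whose composition confines the recipe's damage
    to weak (A:U) stacks, so only the named rule is violated -- except for
    the energy-rule decoy, which is GC-rich so its mismatches are costly."""

    def gc(n):
        return _rand_seq(rng, n, p=(0.1, 0.4, 0.4, 0.1))

    def at(n):
        return _rand_seq(rng, n, p=(0.5, 0.0, 0.0, 0.5))

    if recipe == "rule1":
        # mm at 13/15/17/19, G:U at 21 (0-based 12,14,16,18 = A; 20 = T)
        tail = "".join(
            "A" if i % 2 == 0 else at(1) for i in range(8)
        ) + "T"
        return gc(12) + tail
    if recipe == "rule2":
        return gc(12) + "AAA" + gc(6)
    if recipe == "rule3":
        return gc(4) + "TAAT" + gc(13)
    if recipe == "rule4":
        return gc(9) + "T" + gc(11)
    if recipe == "rule5":
        return at(2) + "A" + at(1) + "A" + at(1) + "T" + at(1) + "T" + gc(12)
    if recipe == "rule6":
        return gc(21)
    return _rand_seq(rng, 21)


def _site_window(rng, mirna: str, recipe: str) -> str | None:
    """Mutate the perfect-complement window per recipe; None = retry."""
    L = len(mirna)
    window = list(revcomp(mirna))

    def set_mm(pos1):  # 1-based miRNA position
        window[L - pos1] = _mismatch_base(rng, mirna[pos1 - 1])

    def set_gu(pos1):
        if not 1 <= pos1 <= L:
            return False
        b = mirna[pos1 - 1]
        if b == "G":
            window[L - pos1] = "T"
        elif b == "T":
            window[L - pos1] = "G"
        else:
            return False
        return True

    gu_ok_positions = [p for p in range(13, L + 1) if mirna[p - 1] in "GT"]
    if recipe == "perfect":
        pass
    elif recipe == "two_gu":
        if len(gu_ok_positions) < 2:
            return None
        for p in gu_ok_positions[:2]:
            set_gu(p)
    elif recipe == "mixed":
        if not gu_ok_positions:
            return None
        set_mm(15)
        set_gu(gu_ok_positions[-1])
        if gu_ok_positions[-1] == 15:
            return None
    elif recipe == "rule1":
        for p in (13, 15, 17, 19):
            set_mm(p)
        if not set_gu(21 if L >= 21 and mirna[20] in "GT" else -1):
            return None
    elif recipe == "rule2":
        for p in (13, 14, 15):
            set_mm(p)
    elif recipe == "rule3":
        set_mm(6)
        set_mm(7)
    elif recipe == "rule4":
        if not set_gu(10):
            set_mm(10)
    elif recipe == "rule5":
        for p in (3, 5):
            set_mm(p)
        gu = [p for p in (7, 9, 12) if mirna[p - 1] in "GT"]
        if len(gu) < 2:
            return None
        for p in gu[:2]:
            set_gu(p)
    elif recipe == "rule6":
        for p in (14, 16, 18):
            set_mm(p)
    return "".join(window)


def make_transcripts(truth: TruthSet, seed: int, n_decoys: int = 4,
                     n_compliant: int = 4) -> list:
    """Transcripts with planted compliant and single-rule-knockout sites.

    Compliant sites satisfy all six rules; each knockout violates exactly
    its named rule (verified with the scorer at generation time).  Decoys
    are low-complexity sequence that accepts no site.
    """
    rng = np.random.default_rng(seed + 4)
    mirnas = [c["seq"] for c in truth.conserved][: max(4, n_compliant)]
    transcripts = []
    recipes = []
    for i in range(n_compliant):
        recipes.append((mirnas[i % len(mirnas)], ("perfect", "two_gu", "mixed")[i % 3], None))
    for rule in ("rule1", "rule2", "rule3", "rule4", "rule5", "rule6"):
        recipes.append((None, rule, rule))

    for idx, (mirna, recipe, violated) in enumerate(recipes):
        for attempt in range(MAX_ATTEMPTS):
            if violated is not None:
                m = _rule_mirna(rng, recipe)
            elif mirna is not None and attempt < MAX_ATTEMPTS // 2:
                m = mirnas[(idx + attempt) % len(mirnas)]
            else:
                m = _rand_seq(rng, 21)
            window = _site_window(rng, m, recipe)
            if window is None:
                continue
            site = score_site(m, window)
            if violated is None:
                if not site.accepted:
                    continue
            else:
                want = int(violated[4:])
                if site.rule_pass[want] or any(
                    not site.rule_pass[r] for r in site.rule_pass if r != want
                ):
                    continue
            backbone = _spacer(rng, 240)
            pos = 100
            tid = f"tx{idx + 1:03d}"
            seq = backbone[:pos] + window + backbone[pos:]
            # the planted window must stay the best-matching one
            transcripts.append(SequenceRecord(id=tid, seq=seq))
            truth.sites.append(
                {"transcript": tid, "mirna": m, "pos": pos,
                 "violated": violated, "recipe": recipe}
            )
            break
        else:
            raise GenerationError(f"could not plant site for {recipe}")
    for d in range(n_decoys):
        transcripts.append(
            SequenceRecord(id=f"decoy{d + 1:02d}", seq=_spacer(rng, 300))
        )
    return transcripts


# ---------------------------------------------------------------- qRT-PCR

REFERENCE_ASSAYS = ("rRNA5.8S", "RPL15")


def make_ct_table(truth: TruthSet, seed: int, noise_sd: float = 0.05):
    """Triplicate Ct table generated from known relative quantities.

    Reference assays sit near Ct 16; target dCt in the calibrator (leaf)
    is 5 cycles; RQ truth spans two orders of magnitude.
    """
    import pandas as pd

    rng = np.random.default_rng(seed + 5)
    assays = {"miR901": {"leaf": 1.0, "bark": 0.5, "male_flower": 4.0},
              "miR903": {"leaf": 1.0, "bark": 8.0, "male_flower": 0.25},
              "miRn1": {"leaf": 1.0, "bark": 1.0, "male_flower": 10.0}}
    truth.rq_truth = assays
    rows = []
    for sample in TISSUES:
        for ref in REFERENCE_ASSAYS:
            for rep in (1, 2, 3):
                rows.append((ref, sample, rep,
                             16.0 + rng.normal(0, noise_sd)))
        for assay, rqs in assays.items():
            base = 16.0 + 5.0 - np.log2(rqs[sample])
            for rep in (1, 2, 3):
                rows.append((assay, sample, rep,
                             base + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["assay", "sample", "replicate", "Ct"])


# ---------------------------------------------------------------- bundle

def simulate(seed: int, outdir, depth: int = 50_000, n_true: int = 10,
             knockouts: tuple = KNOCKOUT_IDS + (RESCUE_ID,)) -> TruthSet:
    """Generate the full fixture bundle into ``outdir``.

    Writes genome.fa, annotation reference FASTAs, a conserved mature
    reference, the multi-species reference, three FASTQ libraries,
    transcripts.fa, ct.tsv and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, truth, genes = make_genome(seed, n_true=n_true, knockouts=knockouts)
    write_fasta(contigs, outdir / "genome.fa")
    for cat, seq in genes.items():
        write_fasta([SequenceRecord(id=f"{cat}_gene1", seq=seq)],
                    outdir / f"{cat}.fa")
    make_conserved(seed, truth)
    species_ref = make_species_reference(truth, seed)
    write_fasta(species_ref, outdir / "matures_species.fa")
    write_fasta(
        [SequenceRecord(id=c["ref_name"], seq=c["seq"]) for c in truth.conserved],
        outdir / "matures_ref.fa",
    )
    make_libraries(truth, seed, genes, depth=depth, outdir=outdir)
    transcripts = make_transcripts(truth, seed)
    write_fasta(transcripts, outdir / "transcripts.fa")
    ct = make_ct_table(truth, seed)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return truth
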