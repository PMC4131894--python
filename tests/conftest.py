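"""Session fixtures: one synthetic world at full depth, one pipeline run
over it, and one discovery pass with per-candidate ledgers."""

import pytest

from mulmir.novel_discovery import discover_novel
from mulmir.pipeline_cli import RunConfig, run_all
from mulmir.preprocess import ReadLibrary
from mulmir.seqio import read_fasta
from mulmir.synthetic_data import (
    ADAPTER3,
    REFERENCE_ASSAYS,
    RESCUE_ID,
    simulate,
)

SEED = 7
DEPTH = 50_000
ANNOT_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """Full synthetic fixture bundle (genome, libraries, references, truth)."""
    out = tmp_path_factory.mktemp("world")
    truth = simulate(SEED, out, depth=DEPTH)
    return out, truth


@pytest.fixture(scope="session")
def pipeline(world):
    """End-to-end pipeline run over the synthetic world."""
    out, truth = world
    cfg = RunConfig(
        tissues={t: str(out / f"lib_{t}.fastq")
                 for t in ("leaf", "bark", "male_flower")},
        genome=str(out / "genome.fa"),
        mature_ref=str(out / "matures_ref.fa"),
        outdir=str(out / "run"),
        adapter=ADAPTER3,
        annotation={c: str(out / f"{c}.fa") for c in ANNOT_CATEGORIES},
        species_ref=str(out / "matures_species.fa"),
        transcripts=str(out / "transcripts.fa"),
        ct_table=str(out / "ct.tsv"),
        reference_assays=list(REFERENCE_ASSAYS),
        calibrator="leaf",
    )
    report = run_all(cfg)
    return out, truth, report


@pytest.fixture(scope="session")
def discovery(world):
    """Discovery pass with candidate-level ledgers, on truth-derived reads
    (every planted mature at a fixed count, stars for the true and
    rescue hairpins)."""
    out, truth = world
    genome = read_fasta(out / "genome.fa")
    counts = {t: {} for t in ("leaf", "bark", "male_flower")}
    for h in truth.hairpins:
        for t in counts:
            counts[t][h["mature"]] = counts[t].get(h["mature"], 0) + 30
        if h["violated"] in (None, RESCUE_ID):
            counts["bark"][h["star"]] = counts["bark"].get(h["star"], 0) + 4
        for seq, c in h.get("extra_reads", {}).items():
            counts["leaf"][seq] = c
    libs = {t: ReadLibrary.from_counts(t, c) for t, c in counts.items()}
    entries, candidates = discover_novel(libs, genome)
    return truth, entries, candidates
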