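import numpy as np
import pytest

from mulmir.seqio import SequenceRecord, revcomp
from mulmir.target_pred import annotate_targets, scan, score_site


def brute_force_scan(mirna: str, transcript: str) -> list:
    """Independent window evaluation of the six duplex rules, written from
    the rule definitions rather than the scanner's code path."""
    from mulmir.rnafold import duplex, perfect_complement_energy

    L = len(mirna)
    accepted = []
    pe = perfect_complement_energy(mirna)
    for start in range(len(transcript) - L + 1):
        window = transcript[start : start + L]
        d = duplex(mirna, window)
        weights = [1.0 if c == "MM" else 0.5 if c == "GU" else 0.0
                   for c in d.classes]
        mm_pos = [i + 1 for i, c in enumerate(d.classes) if c != "WC"]
        ok = sum(weights) <= 4
        run, longest = 0, 0
        for p in range(1, L + 1):
            run = run + 1 if p in mm_pos else 0
            longest = max(longest, run)
        ok &= longest <= 2
        ok &= not any(p in mm_pos and p + 1 in mm_pos
                      for p in range(2, 12))
        ok &= 10 not in mm_pos and 11 not in mm_pos
        ok &= sum(weights[:12]) <= 2.5
        ok &= pe < 0 and d.energy / pe >= 0.75
        if ok:
            accepted.append(start)
    return accepted


class TestScoreSite:
    MIRNA = "TGGAGAAGCAGGGCACGTGCA"

    def test_perfect_complement_accepted(self):
        site = score_site(self.MIRNA, revcomp(self.MIRNA))
        assert site.accepted
        assert site.weighted_total == 0
        assert site.energy_ratio == pytest.approx(1.0)

    def _with_mm(self, positions, gu=()):
        L = len(self.MIRNA)
        window = list(revcomp(self.MIRNA))
        nonpair = {"A": "C", "C": "A", "G": "A", "T": "C"}
        for p in positions:
            window[L - p] = nonpair[self.MIRNA[p - 1]]
        for p in gu:
            b = self.MIRNA[p - 1]
            window[L - p] = {"G": "T", "T": "G"}[b]
        return "".join(window)

    def test_mismatch_at_position_10_rejected_by_rule4(self):
        site = score_site(self.MIRNA, self._with_mm([10]))
        assert not site.accepted and site.first_violated == 4

    def test_gu_at_position_11_also_disqualifies(self):
        # position 11 of the miRNA is G -> wobble available
        assert self.MIRNA[10] == "G"
        site = score_site(self.MIRNA, self._with_mm([], gu=[11]))
        assert not site.accepted and site.first_violated == 4
        relaxed = score_site(self.MIRNA, self._with_mm([], gu=[11]),
                             gu_blocks_positions=False)
        assert relaxed.rule_pass[4]

    def test_five_scattered_mismatches_rejected_by_rule1(self):
        site = score_site(self.MIRNA, self._with_mm([1, 13, 15, 17, 19]))
        assert not site.accepted and site.first_violated == 1

    def test_weighted_four_and_a_half_rejected(self):
        assert self.MIRNA[16] == "G"  # wobble available at position 17
        site = score_site(self.MIRNA, self._with_mm([1, 13, 15, 19], gu=[17]))
        assert site.weighted_total == 4.5
        assert site.first_violated == 1

    def test_three_consecutive_mismatches_rejected_by_rule2(self):
        site = score_site(self.MIRNA, self._with_mm([14, 15, 16]))
        assert not site.accepted and site.first_violated == 2

    def test_adjacent_seed_mismatches_rejected_by_rule3(self):
        site = score_site(self.MIRNA, self._with_mm([6, 7]))
        assert not site.accepted and site.first_violated == 3

    def test_seed_weight_over_2_5_rejected_by_rule5(self):
        site = score_site(self.MIRNA, self._with_mm([2, 4, 6]))
        assert site.seed_weighted_total == 3.0
        assert not site.accepted and site.first_violated == 5

    def test_monotone_weight_under_added_mismatch(self):
        base = score_site(self.MIRNA, self._with_mm([15]))
        more = score_site(self.MIRNA, self._with_mm([15, 17]))
        assert more.weighted_total >= base.weighted_total

    def test_repairing_a_mismatch_keeps_acceptance(self):
        damaged = score_site(self.MIRNA, self._with_mm([15]))
        repaired = score_site(self.MIRNA, revcomp(self.MIRNA))
        assert damaged.accepted and repaired.accepted


class TestScan:
    def test_embedded_perfect_site_found(self):
        m = "TGGAGAAGCAGGGCACGTGCA"
        tx = SequenceRecord(id="t", seq="A" * 30 + revcomp(m) + "C" * 30)
        sites = scan(m, tx)
        assert sites and sites[0].start == 30 and sites[0].weighted_total == 0

    def test_transcript_shorter_than_mirna_is_error(self):
        with pytest.raises(ValueError):
            scan("TGGAGAAGCAGGGCACGTGCA", SequenceRecord(id="t", seq="ACGT"))

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_transcripts(self, seed):
        rng = np.random.default_rng(seed)
        m = "".join(rng.choice(list("ACGT"), size=21))
        # half random windows, half mutated complements to hit near-misses
        parts = ["".join(rng.choice(list("ACGT"), size=30))]
        site = list(revcomp(m))
        for _ in range(int(rng.integers(0, 4))):
            site[int(rng.integers(0, 21))] = str(rng.choice(list("ACGT")))
        parts.append("".join(site))
        parts.append("".join(rng.choice(list("ACGT"), size=28)))
        tx = "".join(parts)[:100]
        got = sorted(s.start for s in scan(m, SequenceRecord(id="t", seq=tx)))
        assert got == brute_force_scan(m, tx)


class TestAnnotateTargets:
    def test_best_site_per_transcript(self):
        m = "TGGAGAAGCAGGGCACGTGCA"
        tx = SequenceRecord(
            id="t1", seq="A" * 10 + revcomp(m) + "T" * 10 + revcomp(m)
        )
        report = annotate_targets({"miR-x": m}, [tx])
        assert len(report) == 1
        assert report[0]["transcript"] == "t1"
        assert report[0]["weighted_mismatches"] == 0

    def test_no_sites_empty_report(self):
        report = annotate_targets(
            {"miR-x": "TGGAGAAGCAGGGCACGTGCA"},
            [SequenceRecord(id="t", seq="A" * 60)],
        )
        assert report == []

    def test_missing_description_is_na(self):
        m = "TGGAGAAGCAGGGCACGTGCA"
        tx = SequenceRecord(id="t1", seq=revcomp(m))
        report = annotate_targets({"miR-x": m}, [tx], descriptions={})
        assert report[0]["description"] == "NA"


class TestPlantedSites:
    def test_compliant_sites_accepted_at_planted_positions(self, world):
        _out, truth = world
        for site in truth.sites:
            if site["violated"] is not None:
                continue
            from mulmir.seqio import read_fasta

            tx = {r.id: r for r in read_fasta(_out / "transcripts.fa")}
            found = scan(site["mirna"], tx[site["transcript"]])
            assert any(s.start == site["pos"] for s in found), site["recipe"]

    def test_each_rule_knockout_rejected_by_exactly_its_rule(self, world):
        _out, truth = world
        from mulmir.seqio import read_fasta

        tx = {r.id: r.seq for r in read_fasta(_out / "transcripts.fa")}
        for site in truth.sites:
            if site["violated"] is None:
                continue
            want = int(site["violated"][4:])
            window = tx[site["transcript"]][site["pos"]:site["pos"] + 21]
            scored = score_site(site["mirna"], window)
            assert not scored.accepted
            failing = [r for r, ok in scored.rule_pass.items() if not ok]
            assert failing == [want], site["violated"]

    def test_decoy_transcripts_accept_nothing(self, world):
        _out, truth = world
        from mulmir.seqio import read_fasta

        decoys = [r for r in read_fasta(_out / "transcripts.fa")
                  if r.id.startswith("decoy")]
        assert decoys
        for site in truth.sites[:4]:
            for d in decoys:
                assert scan(site["mirna"], d) == []
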