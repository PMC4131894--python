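import pytest

from mulmir.conserved_catalog import (
    catalog_records,
    catalog_stats,
    conservation_profile,
    edit_distance,
    identify_conserved,
    load_catalog,
    name_conserved,
)
from mulmir.preprocess import ReadLibrary
from mulmir.seqio import MatureRecord


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(nm) Levenshtein, the oracle for the edlib-backed path."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestIdentifyConserved:
    REF = [MatureRecord(name="gma-miR156m", seq="TTGACAGAAGATAGAGAGCAC",
                        species="gma", family="miR156")]

    def test_counts_summed_per_tissue(self):
        libs = {
            "leaf": ReadLibrary.from_counts("leaf", {self.REF[0].seq: 12787}),
            "bark": ReadLibrary.from_counts("bark", {self.REF[0].seq: 117270}),
            "male_flower": ReadLibrary.from_counts(
                "male_flower", {self.REF[0].seq: 768488}),
        }
        (rec,) = identify_conserved(libs, self.REF)
        assert rec.counts == {"leaf": 12787, "bark": 117270,
                              "male_flower": 768488}
        assert rec.family == "miR156" and rec.ref_name == "gma-miR156m"

    def test_one_mismatch_is_not_conserved(self):
        libs = {"leaf": ReadLibrary.from_counts(
            "leaf", {"TTGACAGAAGATAGAGAGCAA": 10})}
        assert identify_conserved(libs, self.REF) == []

    def test_same_sequence_three_libraries_one_record(self):
        libs = {t: ReadLibrary.from_counts(t, {self.REF[0].seq: 1})
                for t in ("leaf", "bark", "male_flower")}
        records = identify_conserved(libs, self.REF)
        assert len(records) == 1
        assert all(v == 1 for v in records[0].counts.values())


class TestNaming:
    def _recs(self, counts):
        return [
            MatureRecord(name="", seq=f"ACGT{i:017d}".replace("0", "A"),
                         family="miR1", counts={"leaf": c})
            for i, c in enumerate(counts)
        ]

    def test_descending_abundance_gets_early_letters(self):
        recs = name_conserved(self._recs([10, 100]))
        by_count = {r.counts["leaf"]: r.name for r in recs}
        assert by_count[100] == "mno-miR1a" and by_count[10] == "mno-miR1b"

    def test_single_member_family_gets_a(self):
        (rec,) = name_conserved(self._recs([5]))
        assert rec.name == "mno-miR1a"

    def test_27_members_roll_to_double_letters(self):
        recs = name_conserved(self._recs(list(range(27, 0, -1))))
        assert recs[-1].name.endswith("aa")


class TestConservationProfile:
    def test_exact_match_is_plus_plus(self):
        rec = MatureRecord(name="x", seq="TGCCTGGCTCCCTGTATGCCA")
        sets = {"ath": [MatureRecord(name="a", seq=rec.seq)]}
        assert conservation_profile(rec, sets) == {"ath": "++"}

    @pytest.mark.parametrize("dist,symbol", [(1, "+"), (2, "+"), (3, "+"),
                                             (4, "-")])
    def test_distance_boundaries(self, dist, symbol):
        seq = "TGCCTGGCTCCCTGTATGCCA"
        var = "A" * dist + seq[dist:]
        assert edit_distance(seq, var) == dist
        rec = MatureRecord(name="x", seq=seq)
        sets = {"sp": [MatureRecord(name="v", seq=var)]}
        assert conservation_profile(rec, sets)["sp"] == symbol

    def test_empty_species_set_is_absent(self):
        rec = MatureRecord(name="x", seq="TGCCTGGCTCCCTGTATGCCA")
        assert conservation_profile(rec, {"osa": []}) == {"osa": "-"}

    def test_edlib_agrees_with_dp_oracle(self):
        import numpy as np

        rng = np.random.default_rng(3)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 25))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 25))))
            assert edit_distance(a, b) == dp_edit_distance(a, b)

    def test_unequal_lengths_use_indels(self):
        assert edit_distance("ACGTACGT", "ACGACGT") == 1


class TestPublishedCatalog:
    """Statistics recomputed from the published 85-miRNA catalog."""

    def test_catalog_size_and_families(self):
        st = catalog_stats()
        assert st.n_mirnas == 85
        assert st.n_families == 31

    def test_per_tissue_presence(self):
        st = catalog_stats()
        assert st.presence == {"leaf": 77, "bark": 70, "male_flower": 70}

    def test_common_to_all_three_tissues(self):
        assert catalog_stats().n_common_all == 57

    def test_length_peak_at_21(self):
        st = catalog_stats()
        assert st.length_histogram[21] == 72
        assert st.fraction_length[21] * 100 == pytest.approx(84.7, abs=0.05)

    def test_seven_families_in_at_most_two_species(self):
        st = catalog_stats()
        assert st.n_families_in_at_most(2) == 7
        less_conserved = {f for f, s in st.family_species_span.items() if s <= 2}
        assert less_conserved == {"miR482", "miR529", "miR858", "miR4376",
                                  "miR4414", "miR4995", "miR5523"}

    def test_presence_ordering_invariant(self):
        st = catalog_stats()
        assert st.n_common_all <= min(st.presence.values()) <= st.n_mirnas

    def test_records_carry_lengths(self):
        for rec in catalog_records():
            assert rec.length == len(rec.seq)

    def test_fully_conserved_members(self):
        """Catalog members whose profile is ++ in all seven species."""
        df = load_catalog()
        species = ["ath", "gma", "mdm", "ptc", "rco", "osa", "zma"]
        fully = set(df[(df[species] == "++").all(axis=1)]["name"])
        # the extremely conserved core families are all represented
        assert {"mno-miR160b", "mno-miR164a", "mno-miR167a", "mno-miR169a",
                "mno-miR390"} <= fully
        assert fully <= {"mno-miR160b", "mno-miR164a", "mno-miR167a",
                         "mno-miR169a", "mno-miR390", "mno-miR393b",
                         "mno-miR396c"}


def test_profile_recovery_on_synthetic_reference(pipeline):
    """Every planted per-species variant maps back to its intended
    conservation symbol through the full pipeline."""
    import pandas as pd

    out, truth, _report = pipeline
    catalog = pd.read_csv(out / "run" / "conserved_catalog.tsv", sep="\t")
    assert len(catalog) == len(truth.conserved)
    by_ref = catalog.set_index("ref_name")
    for ref_name, expected in truth.profile_truth.items():
        row = by_ref.loc[ref_name]
        for species, symbol in expected.items():
            assert row[species] == symbol, (ref_name, species)
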