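import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mulmir.conserved_catalog import load_catalog, load_library_totals
from mulmir.expression import (
    biased_units,
    call_bias,
    ddct,
    family_aggregate,
    to_rpm,
)

TISSUES = ["leaf", "bark", "male_flower"]


def _matrix(rows: dict, totals=None):
    counts = pd.DataFrame(rows, index=TISSUES).T
    return to_rpm(counts, totals or {t: 1_000_000 for t in TISSUES})


class TestRpm:
    def test_count_per_million(self):
        m = _matrix({"x": [100, 0, 50]})
        assert m.rpm.loc["x", "leaf"] == 100.0
        assert m.rpm.loc["x", "bark"] == 0.0

    def test_published_mir390_rpm(self):
        totals = load_library_totals()
        m = to_rpm(pd.DataFrame({"leaf": [4275], "bark": [489],
                                 "male_flower": [1153]}, index=["miR390"]),
                   totals)
        assert m.rpm.loc["miR390"].round(1).tolist() == [388.9, 43.4, 113.8]

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            to_rpm(pd.DataFrame({"leaf": [1]}), {"leaf": 0})


class TestFamilyAggregate:
    def test_member_counts_summed(self):
        counts = pd.DataFrame({"leaf": [10, 20], "bark": [0, 1],
                               "male_flower": [2, 3]}, index=["a", "b"])
        fam = family_aggregate(counts, {"a": "f1", "b": "f1"})
        assert fam.loc["f1"].tolist() == [30, 1, 5]

    def test_single_member_is_identity(self):
        counts = pd.DataFrame({"leaf": [7], "bark": [8], "male_flower": [9]},
                              index=["a"])
        fam = family_aggregate(counts, {"a": "f"})
        assert fam.loc["f"].tolist() == [7, 8, 9]

    def test_published_mir172_leaf_total(self):
        df = load_catalog().set_index("name")
        fam = family_aggregate(df[TISSUES], df["family"].to_dict())
        assert fam.loc["miR172", "leaf"] == 19438

    def test_unmapped_unit_is_error(self):
        counts = pd.DataFrame({"leaf": [1], "bark": [1], "male_flower": [1]},
                              index=["a"])
        with pytest.raises(ValueError):
            family_aggregate(counts, {})


class TestBiasCalls:
    def test_inclusive_twofold_boundary(self):
        calls = call_bias(_matrix({"x": [10, 4, 5]}))
        assert calls[0].label == "leaf-biased"

    def test_exact_tie_at_boundary_still_biased(self):
        calls = call_bias(_matrix({"x": [10, 5, 5]}))
        assert calls[0].label == "leaf-biased"

    def test_below_boundary_unbiased(self):
        calls = call_bias(_matrix({"x": [10, 6, 5]}))
        assert calls[0].label == "unbiased"

    def test_all_zero_unbiased(self):
        calls = call_bias(_matrix({"x": [0, 0, 0]}))
        assert calls[0].label == "unbiased" and calls[0].specific_to is None

    def test_specific_when_only_one_tissue(self):
        calls = call_bias(_matrix({"x": [5, 0, 0]}))
        assert calls[0].label == "leaf-biased"
        assert calls[0].specific_to == "leaf"

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_invariant_to_uniform_library_rescaling(self, factor):
        counts = pd.DataFrame(
            {"leaf": [40, 7], "bark": [10, 9], "male_flower": [3, 20]},
            index=["a", "b"],
        )
        base = {t: 1e6 for t in TISSUES}
        scaled = {t: v * factor for t, v in base.items()}
        labels = [c.label for c in call_bias(to_rpm(counts, base))]
        assert labels == [c.label for c in call_bias(to_rpm(counts, scaled))]

    def test_at_most_one_biased_label(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, size=(30, 3)),
                              columns=TISSUES)
        calls = call_bias(to_rpm(counts, {t: 1e6 for t in TISSUES}))
        assert all(c.label.count("biased") <= 1 for c in calls)


@pytest.fixture(scope="module")
def calls():
    df = load_catalog().set_index("name")
    fam = family_aggregate(df[TISSUES], df["family"].to_dict())
    return call_bias(to_rpm(fam, load_library_totals()))


class TestPublishedFamilyBias:
    """Tissue-biased conserved families recomputed from the published
    catalog with the per-library clean-read totals."""

    def test_five_leaf_biased_families(self, calls):
        assert biased_units(calls, "leaf") == [
            "miR172", "miR390", "miR4995", "miR827", "miR828"
        ]

    def test_five_bark_biased_families(self, calls):
        assert biased_units(calls, "bark") == [
            "miR319", "miR393", "miR395", "miR396", "miR535"
        ]

    def test_mir390_is_leaf_biased(self, calls):
        assert next(c for c in calls if c.unit == "miR390").label == "leaf-biased"


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["assay", "sample", "replicate", "Ct"])


class TestDdct:
    def _table(self, target_cts: dict, ref_ct: float = 16.0):
        rows = []
        for sample, ct in target_cts.items():
            for rep in (1, 2, 3):
                rows.append(("ref", sample, rep, ref_ct))
                rows.append(("tgt", sample, rep, ct))
        return _ct_frame(rows)

    def test_calibrator_rq_is_one(self):
        table = self._table({"leaf": 21.0, "bark": 21.0})
        results = {r.sample: r for r in ddct(table, "tgt", ["ref"], "leaf")}
        assert results["leaf"].rq == pytest.approx(1.0)
        assert results["bark"].rq == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles_rq(self):
        table = self._table({"leaf": 21.0, "bark": 20.0})
        results = {r.sample: r for r in ddct(table, "tgt", ["ref"], "leaf")}
        assert results["bark"].delta_delta_ct == pytest.approx(-1.0)
        assert results["bark"].rq == pytest.approx(2.0)

    def test_tenfold_down_is_3_32_cycles(self):
        table = self._table({"leaf": 21.0, "bark": 21.0 + np.log2(10)})
        results = {r.sample: r for r in ddct(table, "tgt", ["ref"], "leaf")}
        assert results["bark"].rq == pytest.approx(0.1)

    def test_two_reference_genes_averaged(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [("r1", "leaf", rep, 15.0), ("r2", "leaf", rep, 17.0),
                     ("tgt", "leaf", rep, 21.0),
                     ("r1", "bark", rep, 15.0), ("r2", "bark", rep, 17.0),
                     ("tgt", "bark", rep, 20.0)]
        results = {r.sample: r
                   for r in ddct(_ct_frame(rows), "tgt", ["r1", "r2"], "leaf")}
        assert results["leaf"].ct_reference == pytest.approx(16.0)
        assert results["bark"].rq == pytest.approx(2.0)

    def test_missing_replicates_error_names_assay(self):
        table = self._table({"leaf": 21.0})
        with pytest.raises(ValueError, match="other"):
            ddct(table, "other", ["ref"], "leaf")


def test_bias_truth_recovered_through_pipeline(pipeline):
    """Planted 3x tissue effects come back as the intended family labels."""
    _out, truth, report = pipeline
    called = {}
    for label, families in report["bias"].items():
        for fam in families:
            called[fam] = label
    assert called == truth.bias_truth


def test_rq_truth_recovered_through_pipeline(pipeline):
    """2^-ddCt estimates land within 15% of the generating quantities."""
    _out, truth, report = pipeline
    for assay, samples in truth.rq_truth.items():
        for sample, rq in samples.items():
            got = report["ddct"][f"{assay}:{sample}"]
            assert got == pytest.approx(rq, rel=0.15), (assay, sample)
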