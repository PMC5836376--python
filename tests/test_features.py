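"""Cleavage classification, lengths, hydrophobicity, allele assignment and
positional enrichment."""

import numpy as np
import pandas as pd
import pytest

from ligandq import (
    PredictionTable,
    ValidationError,
    assign_alleles,
    classify_cterm,
    hydrophobicity_score,
    length_distribution,
    peptides_by_allele,
    position_enrichment,
)
from ligandq.io import AMINO_ACIDS


class TestClassifyCterm:
    def test_partition_is_2_7_11(self):
        classes = {aa: classify_cterm("AAA" + aa + "AAAA" + aa) for aa in AMINO_ACIDS}
        by_class = pd.Series(classes).value_counts()
        assert by_class["tryptic"] == 2
        assert by_class["chymotryptic"] == 7
        assert by_class["other"] == 11
        assert {aa for aa, c in classes.items() if c == "tryptic"} == {"K", "R"}
        assert {aa for aa, c in classes.items() if c == "chymotryptic"} == set("AFILMVY")

    @pytest.mark.parametrize(
        "seq,expected",
        [("SPRWWPTCL", "chymotryptic"), ("KVANKGYSR", "tryptic"), ("ACDEFGHW", "other")],
    )
    def test_examples(self, seq, expected):
        assert classify_cterm(seq) == expected

    def test_empty_sequence_raises(self):
        with pytest.raises(ValidationError):
            classify_cterm("")


class TestLengthDistribution:
    def test_fractions(self):
        sets = {"ctrl": ["AAAAAAAAK", "CCCCCCCCR", "AAAAAAAAAL", "AAAAAAAAAAAK"]}
        out = length_distribution(sets)
        overall = out[(out["condition"] == "ctrl") & (out["cleavage_class"] == "all")]
        assert dict(zip(overall["length"], overall["fraction"])) == {
            9: 0.5, 10: 0.25, 12: 0.25,
        }

    def test_identical_sets_give_identical_histograms(self):
        peps = ["AAAAAAAAK", "AAAAAAAAL"]
        out = length_distribution({"a": peps, "b": peps})
        a = out[out["condition"] == "a"].drop(columns="condition").reset_index(drop=True)
        b = out[out["condition"] == "b"].drop(columns="condition").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_stratified_counts_sum_to_unstratified(self):
        peps = ["AAAAAAAAK", "AAAAAAAAL", "AAAAAAAAW", "CCCCCCCCR", "DDDDDDDDF"]
        out = length_distribution({"c": peps})
        total = out[out["cleavage_class"] == "all"]["count"].sum()
        strat = out[out["cleavage_class"] != "all"]["count"].sum()
        assert total == strat == len(peps)

    def test_empty_set_warns(self):
        with pytest.warns(UserWarning):
            out = length_distribution({"empty": []})
        assert out.empty


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAA", 1.8), ("KKK", -3.9), ("ILV", (4.5 + 3.8 + 4.2) / 3)],
    )
    def test_kyte_doolittle_means(self, seq, expected):
        assert hydrophobicity_score(seq) == pytest.approx(expected)

    def test_unknown_residue_raises(self):
        with pytest.raises(ValidationError, match="X"):
            hydrophobicity_score("AAX", scale={"A": 1.0})


class TestAssignAlleles:
    def _preds(self, rows):
        return PredictionTable(
            pd.DataFrame(rows, columns=["sequence", "allele", "rank_pct", "affinity_nm"])
        )

    def test_statuses(self):
        preds = self._preds(
            [("PEPTIDEA", "A*03:01", 0.5, 50.0), ("PEPTIDEA", "B*07:02", 12.0, 9000.0),
             ("PEPTIDEB", "A*03:01", 0.5, 60.0), ("PEPTIDEB", "B*07:02", 1.0, 300.0),
             ("PEPTIDEC", "A*03:01", 5.0, 5000.0), ("PEPTIDEC", "B*07:02", 8.0, 7000.0)]
        )
        out = assign_alleles(["PEPTIDEA", "PEPTIDEB", "PEPTIDEC", "PEPTIDED"], preds)
        status = dict(zip(out["sequence"], out["status"]))
        assert status == {
            "PEPTIDEA": "assigned", "PEPTIDEB": "multi_binder",
            "PEPTIDEC": "non_binder", "PEPTIDED": "unpredicted",
        }
        assigned = out[out["sequence"] == "PEPTIDEA"].iloc[0]
        assert assigned["allele"] == "A*03:01" and assigned["rank_pct"] == 0.5

    def test_statuses_partition_peptides(self):
        preds = self._preds([("PEPTIDEA", "A*03:01", 0.5, 50.0)])
        out = assign_alleles(["PEPTIDEA", "PEPTIDEB"], preds)
        assert out["status"].notna().all() and len(out) == 2
        assert peptides_by_allele(out) == {"A*03:01": ["PEPTIDEA"]}


class TestPositionEnrichment:
    def test_fixed_anchor_is_enriched(self):
        rng = np.random.default_rng(0)
        aas = list(AMINO_ACIDS)
        ref = ["".join(rng.choice(aas, 9)) for _ in range(400)]
        exp = ["".join(rng.choice(aas, 9)) for _ in range(100)]
        exp = [p[0] + "P" + p[2:] for p in exp]  # all P at position 2
        res = position_enrichment(exp, ref, length=9, cutoff=0.01)
        hit = res.table[(res.table["position"] == 2) & (res.table["residue"] == "P")]
        assert hit.iloc[0]["p_value"] < 0.01
        assert hit.iloc[0]["direction"] == "enriched"

    def test_identical_sets_flag_nothing(self):
        rng = np.random.default_rng(1)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(50)]
        res = position_enrichment(peps, peps)
        assert (res.table["direction"] == "none").all()

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        aas = list(AMINO_ACIDS)
        a = ["".join(rng.choice(aas, 9)) for _ in range(60)]
        b = [p[0] + "L" + p[2:] for p in ("".join(rng.choice(aas, 9)) for _ in range(60))]
        fwd = position_enrichment(a, b).table.set_index(["position", "residue"])
        rev = position_enrichment(b, a).table.set_index(["position", "residue"])
        common = fwd.index.intersection(rev.index)
        np.testing.assert_allclose(
            fwd.loc[common, "p_value"], rev.loc[common, "p_value"], rtol=1e-10
        )
        flips = {"enriched": "depleted", "depleted": "enriched", "none": "none"}
        assert (fwd.loc[common, "direction"].map(flips) == rev.loc[common, "direction"]).all()

    def test_frequencies_sum_to_one_per_position(self):
        rng = np.random.default_rng(3)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), 9)) for _ in range(30)]
        res = position_enrichment(peps, peps)
        np.testing.assert_allclose(res.pfm_experiment.sum(axis=1), 1.0)

    def test_empty_after_length_filter_raises(self):
        with pytest.raises(ValidationError):
            position_enrichment(["AAAAAAAA"], ["AAAAAAAAK"], length=10)
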