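"""Nested-pair detection, the Delta statistic, transition tests and
cleavage-context windows."""

import numpy as np
import pandas as pd
import pytest

from ligandq import (
    NestedPair,
    ValidationError,
    cleavage_context,
    compute_delta,
    compute_deltas,
    detect_nested_pairs,
    group_and_test,
    group_means,
)
from conftest import TOY_PROTEIN, make_design, make_table


def _coord_table(windows, protein=TOY_PROTEIN, name="P1"):
    """windows: list of (start, length) 1-based cuts from the toy protein."""
    rows = []
    seen = set()
    for start, length in windows:
        seq = protein[start - 1 : start - 1 + length]
        if seq in seen:
            continue
        seen.add(seq)
        rows.append((seq, name, start, {"S1": 1.0}))
    return make_table(rows, ["S1"])


def brute_force_pairs(table, max_ext=5):
    """Independent O(n^2) all-pairs oracle on coordinates + substrings."""
    found = set()
    rows = [
        r for r in table.frame.itertuples(index=False)
        if r.mapped and pd.notna(r.start)
    ]
    for a in rows:
        for b in rows:
            if a.sequence == b.sequence or a.leading_protein != b.leading_protein:
                continue
            ext = len(b.sequence) - len(a.sequence)
            if not 1 <= ext <= max_ext:
                continue
            if int(a.start) == int(b.start) and b.sequence.startswith(a.sequence):
                found.add((a.sequence, b.sequence, "C", ext))
            elif int(a.end) == int(b.end) and b.sequence.endswith(a.sequence):
                found.add((a.sequence, b.sequence, "N", ext))
    return found


class TestDetectNestedPairs:
    def test_c_side_pair_with_transition(self):
        table = _coord_table([(4, 9), (4, 12)])  # AYIAKQRQI / AYIAKQRQISFV
        pairs, report = detect_nested_pairs(table)
        assert len(pairs) == 1 and report["skipped_unmapped"] == 0
        p = pairs[0]
        assert (p.short, p.long) == ("AYIAKQRQI", "AYIAKQRQISFV")
        assert p.side == "C" and p.ext_len == 3
        assert p.transition == "C->C"  # I -> V

    def test_n_side_pair(self):
        table = _coord_table([(9, 8), (7, 10)])  # QRQISFVK / AKQRQISFVK
        pairs, _ = detect_nested_pairs(table)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.side == "N" and p.ext_len == 2 and p.transition == "n/a"

    def test_extension_beyond_five_is_not_paired(self):
        table = _coord_table([(4, 8), (4, 14)])  # ext 6
        pairs, _ = detect_nested_pairs(table)
        assert pairs == []

    def test_unmapped_peptides_are_skipped_and_counted(self):
        table = make_table(
            [("AYIAKQRQI", "P1", 4, {"S1": 1.0}), ("WWWWWWWW", "", None, {"S1": 1.0})],
            ["S1"],
        )
        _, report = detect_nested_pairs(table)
        assert report["skipped_unmapped"] == 1

    def test_matches_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(99)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        proteins = {f"P{i}": "".join(rng.choice(aas, 120)) for i in range(5)}
        rows, seen = [], set()
        for _ in range(200):
            name = f"P{rng.integers(5)}"
            length = int(rng.integers(8, 15))
            start = int(rng.integers(1, 120 - length))
            seq = proteins[name][start - 1 : start - 1 + length]
            if seq in seen:
                continue
            seen.add(seq)
            rows.append((seq, name, start, {"S1": 1.0}))
        table = make_table(rows, ["S1"])
        got = {(p.short, p.long, p.side, p.ext_len) for p in detect_nested_pairs(table)[0]}
        assert got == brute_force_pairs(table)


class TestDelta:
    def _pair(self):
        return NestedPair("SHORTPEPK", "SHORTPEPKAL", "P1", "C", 2, 1, 9, 1, 11)

    def _means(self, cl, tl, cs, ts):
        return pd.DataFrame(
            {"ctrl": [cl, cs], "ifng": [tl, ts]}, index=["SHORTPEPKAL", "SHORTPEPK"]
        )

    def test_all_equal_means_give_zero(self):
        assert compute_delta(self._pair(), self._means(20, 20, 20, 20)) == 0.0

    def test_treated_long_shift_passes_through(self):
        assert compute_delta(self._pair(), self._means(20, 21, 20, 20)) == 1.0

    def test_direct_arithmetic(self):
        # long (ctrl 20, treated 21), short (ctrl 20.0, treated 20.2)
        assert compute_delta(self._pair(), self._means(20, 21, 20.0, 20.2)) == pytest.approx(0.8)

    def test_antisymmetric_under_group_swap(self):
        means = self._means(20.0, 21.3, 19.5, 20.0)
        fwd = compute_delta(self._pair(), means, groups=("ctrl", "ifng"))
        rev = compute_delta(self._pair(), means, groups=("ifng", "ctrl"))
        assert fwd == pytest.approx(-rev)

    def test_missing_mean_raises(self):
        with pytest.raises(ValidationError):
            compute_delta(self._pair(), self._means(np.nan, 21, 20, 20))

    def test_group_means_from_matrix(self, two_group_design):
        data = pd.DataFrame(
            np.arange(8.0).reshape(1, 8), columns=two_group_design.samples,
            index=["PEPTIDEX"],
        )
        means = group_means(data, two_group_design)
        assert means.loc["PEPTIDEX", "ctrl"] == 1.5
        assert means.loc["PEPTIDEX", "ifng"] == 5.5


class TestGroupAndTest:
    def _pairs(self, deltas, side="C", transition="C->C"):
        return [
            NestedPair(f"S{i}AAAAAAA", f"S{i}AAAAAAAL", "P1", side, 1, 1, 8, 1, 9,
                       transition=transition, delta=d)
            for i, d in enumerate(deltas)
        ]

    def test_large_positive_shift_is_detected(self):
        rng = np.random.default_rng(4)
        pairs = self._pairs(rng.normal(0.5, 0.1, size=40))
        out = group_and_test(pairs).set_index(["side", "transition"])
        assert out.loc[("C", "all"), "p"] < 0.01
        assert out.loc[("C", "C->C"), "stars"] == "***"

    def test_zero_variance_group_reported_without_p(self):
        out = group_and_test(self._pairs([0.0, 0.0, 0.0])).set_index(["side", "transition"])
        assert np.isnan(out.loc[("C", "all"), "p"])
        assert out.loc[("C", "all"), "n"] == 3

    def test_transition_group_sizes_partition_c_side(self):
        pairs = (self._pairs([0.1, 0.2], transition="T->T")
                 + self._pairs([0.3], transition="C->T")
                 + self._pairs([0.4, 0.5, 0.6], transition="C->C"))
        out = group_and_test(pairs).set_index(["side", "transition"])
        trans_n = out.loc[[("C", t) for t in ("T->T", "C->C", "C->T", "T->C")], "n"].sum()
        assert trans_n == out.loc[("C", "all"), "n"] == 6

    def test_small_group_reported_without_p(self):
        out = group_and_test(self._pairs([0.5])).set_index(["side", "transition"])
        assert out.loc[("C", "all"), "n"] == 1 and np.isnan(out.loc[("C", "all"), "p"])


class TestCleavageContext:
    def test_window_indexing(self, toy_protein):
        pair = NestedPair("AYIAKQRQI", "AYIAKQRQISFV", "P1", "C", 3, 4, 12, 4, 15)
        ctx = cleavage_context(pair, {"P1": toy_protein})
        assert ctx["p_side"] == "QISFV"
        assert ctx["p_prime"] == "KSHFS"

    def test_protein_end_pads_with_gaps(self, toy_protein):
        pair = NestedPair("VKSHFSR", "VKSHFSRQ", "P1", "C", 1, 15, 21, 15, 22)
        ctx = cleavage_context(pair, {"P1": toy_protein})
        assert ctx["p_prime"] == "-----"

    def test_n_side_pair_rejected(self, toy_protein):
        pair = NestedPair("QRQISFVK", "AKQRQISFVK", "P1", "N", 2, 9, 16, 7, 16)
        with pytest.raises(ValidationError):
            cleavage_context(pair, {"P1": toy_protein})
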