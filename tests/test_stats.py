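"""Normalization, frequency tables, fidelity and yield statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nerpeseq import (
    MATCH,
    DegenerateControlError,
    EmptyTableError,
    NormalizationFactors,
    PairMatrix,
    TrimerTable,
    compute_normalization,
    error_frequency,
    mean_base_frequency,
    mismatch_spectrum,
    pair_weight,
    positional_frequencies,
    product_class_fractions,
    trimer_frequencies,
    yield_and_lengths,
)
from nerpeseq.stats import TRIMERS, TRIMER_WINDOW_123, TRIMER_WINDOW_456

from conftest import make_pair

BASES = "ACGU"


def uniform_control(T=4):
    """Control pair set whose templates show each base equally at each position."""
    rotations = ["".join(BASES[(i + k) % 4] for i in range(T)) for k in range(4)]
    return [make_pair(t, "") for t in rotations]


def random_pairs(rng, n=200, T=6, p_ext=0.7, err=0.2):
    pairs = []
    for k in range(n):
        template = "".join(rng.choice(list(BASES), T))
        if rng.random() < p_ext:
            L = int(rng.integers(1, T + 1))
            prod = []
            for i in range(L):
                comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[template[i]]
                if rng.random() < err:
                    prod.append(rng.choice([b for b in BASES if b != comp]))
                else:
                    prod.append(comp)
            product = "".join(prod)
        else:
            product = ""
        pairs.append(make_pair(template, product, source_id=f"p{k}"))
    return pairs


class TestNormalization:
    def test_uniform_control_gives_unit_factors(self):
        norm = compute_normalization(uniform_control())
        assert norm.is_uniform

    def test_factors_from_skewed_control(self):
        # position 1: A at frequency 1/2, the others 1/6 each
        tails = ["ACG", "CGU", "GUA", "UAC", "ACG", "CGU"]
        templates = [h + t for h, t in zip("AAACGU", tails)]
        norm = compute_normalization([make_pair(t, "") for t in templates])
        assert norm.factor(1, "A") == pytest.approx(0.5)
        for b in "CGU":
            assert norm.factor(1, b) == pytest.approx(1.5)

    def test_degenerate_control_raises(self):
        pairs = [make_pair("AAAA", ""), make_pair("CCCC", "")]
        with pytest.raises(DegenerateControlError):
            compute_normalization(pairs)

    def test_pair_weight_is_product_of_factors(self):
        w = np.ones((4, 4))
        w[0, 0] = 0.5  # position 1, base A
        w[1, 1] = 2.0  # position 2, base C
        norm = NormalizationFactors(w)
        pair = make_pair("ACGU", "UGCA")
        assert pair_weight(pair, norm, [1]) == pytest.approx(0.5)
        assert pair_weight(pair, norm, [1, 2]) == pytest.approx(1.0)
        assert pair_weight(pair, NormalizationFactors.uniform(4), [1, 2, 3]) == 1.0


class TestPositionalFrequencies:
    def test_single_complementary_product(self):
        table = positional_frequencies([make_pair("CGAU", "GC")])
        assert table.F.loc[1, "G"] == 1.0
        assert table.F.loc[2, "C"] == 1.0
        assert table.n_eff.loc[1] == 1.0

    def test_two_products_split_evenly(self):
        pairs = [make_pair("UAAA", "A"), make_pair("UAAA", "G")]
        table = positional_frequencies(pairs)
        assert table.F.loc[1, "A"] == 0.5
        assert table.F.loc[1, "G"] == 0.5

    def test_uncovered_positions_flagged_empty(self):
        table = positional_frequencies([make_pair("ACGU", "U")])
        assert table.n_eff.loc[2] == 0.0
        assert table.F.loc[2].isna().all()

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        table = positional_frequencies(random_pairs(rng))
        covered = table.n_eff > 0
        sums = table.F[covered.values].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (table.F[covered.values].values >= 0).all()

    def test_mean_base_frequency(self):
        pairs = [make_pair("AAAA", "UU"), make_pair("AAAA", "UG")]
        table = positional_frequencies(pairs)
        # F(1,U)=1.0, F(2,U)=0.5
        assert mean_base_frequency(table, "U", [1, 2]) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            mean_base_frequency(table, "U", [])
        with pytest.raises(ValueError):
            mean_base_frequency(table, "U", [1, 2, 3])  # position 3 uncovered

    def test_complementary_class_excludes_mismatched(self):
        pairs = [make_pair("CGAU", "GC"), make_pair("CGAU", "GG")]
        table = positional_frequencies(pairs, product_class="complementary")
        assert table.F.loc[2, "C"] == 1.0


class TestTrimerTable:
    def test_uniform_usage_gives_ideal_frequency(self):
        pairs = [make_pair("".join({"A": "U", "U": "A", "G": "C", "C": "G"}[b]
                                   for b in tri), tri) for tri in TRIMERS]
        table = trimer_frequencies(pairs)
        assert np.allclose(table.freq.values, 1 / 64)
        assert table.median == pytest.approx(1 / 64)

    def test_single_product_dominates_and_median_zero(self):
        table = trimer_frequencies([make_pair("CCC", "GGG")])
        assert table.freq["GGG"] == 1.0
        assert table.median == 0.0
        assert table.summary()["n_unrepresented"] == 63

    def test_window_456_requires_length_six(self):
        pairs = [make_pair("A" * 6, "U" * 6), make_pair("A" * 6, "U" * 3)]
        table = trimer_frequencies(pairs, window=TRIMER_WINDOW_456)
        assert table.n_products == 1
        with pytest.raises(EmptyTableError):
            trimer_frequencies([make_pair("A" * 6, "U" * 3)], window=TRIMER_WINDOW_456)

    def test_mismatched_products_excluded(self):
        with pytest.raises(EmptyTableError):
            trimer_frequencies([make_pair("AAA", "UUG")])

    def test_printed_fold_differences(self):
        # fold differences computed from the extreme frequencies, zeros excluded
        filler = (1 - 0.111 - 0.00013) / 62
        freq = {t: filler for t in TRIMERS}
        freq["CCC"], freq["UAA"] = 0.111, 0.00013
        assert TrimerTable.from_frequencies(freq).max_min_ratio == 854

        filler = (1 - 0.057 - 0.003) / 62
        freq = {t: filler for t in TRIMERS}
        freq["GGG"], freq["UUU"] = 0.057, 0.003
        assert TrimerTable.from_frequencies(freq).max_min_ratio == 19

    def test_brute_force_oracle_weighted(self):
        """Vectorized trimer table equals a per-pair dict enumeration."""
        rng = np.random.default_rng(42)
        pairs = random_pairs(rng, n=400, T=8, err=0.1)
        w = rng.uniform(0.5, 2.0, size=(8, 4))
        norm = NormalizationFactors(w)

        table = trimer_frequencies(pairs, norm)
        expected = {t: 0.0 for t in TRIMERS}
        for p in pairs:
            if p.is_complementary and p.length >= 3:
                expected[p.product[:3]] += pair_weight(p, norm, [1, 2, 3])
        total = sum(expected.values())
        for t in TRIMERS:
            assert table.freq[t] == pytest.approx(expected[t] / total, abs=1e-12)


class TestFidelity:
    def test_all_complementary_is_zero(self):
        assert error_frequency([make_pair("ACG", "UGC")]) == 0.0

    def test_counts_per_base(self):
        pairs = [make_pair("AAAAAA", "UUUG"), make_pair("AAAAAA", "UUUUUU")]
        assert error_frequency(pairs) == pytest.approx(1 / 10)

    def test_requires_extended_products(self):
        with pytest.raises(EmptyTableError):
            error_frequency([make_pair("ACG", "")])

    def test_single_mismatch_spectrum_cell(self):
        spec = mismatch_spectrum([make_pair("AAAA", "G")])
        assert spec.M.loc["A:G", 1] == 1.0
        assert spec.M.values.sum() == 1.0

    def test_two_mismatches_split(self):
        pairs = [make_pair("AGAA", "UUU"), make_pair("AAUA", "UUG")]
        spec = mismatch_spectrum(pairs)
        assert spec.M.loc["G:U", 2] == 0.5
        assert spec.M.loc["U:G", 3] == 0.5
        assert spec.position_marginal.loc[2] == 0.5

    def test_all_zero_spectrum_allowed(self):
        spec = mismatch_spectrum([make_pair("ACG", "UGC")])
        assert spec.n_mismatches == 0
        assert (spec.M.values == 0).all()

    def test_spectrum_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pairs = random_pairs(rng, n=500, T=6, err=0.3)
        spec = mismatch_spectrum(pairs)
        counts = {}
        total = 0
        for p in pairs:
            for i, c in enumerate(p.calls, start=1):
                if c != MATCH:
                    counts[(c, i)] = counts.get((c, i), 0) + 1
                    total += 1
        for (lbl, pos), cnt in counts.items():
            assert spec.M.loc[lbl, pos] == cnt / total  # exact: integer ratios
        assert spec.n_mismatches == total


class TestProductClasses:
    def test_terminal_mismatch_fraction_one(self):
        pairs = [make_pair("AAAA", "UUG"), make_pair("AAAA", "UUUG")]
        fr = product_class_fractions(pairs)
        assert fr["terminal_mismatch_fraction"] == 1.0

    def test_multi_mismatch_fraction(self):
        pairs = [make_pair("AAAA", "UUUG")] * 6 + [make_pair("AAAA", "UUGG")] * 4
        fr = product_class_fractions(pairs)
        assert fr["multi_mismatch_fraction"] == pytest.approx(0.4)

    def test_undefined_conditionals_are_none(self):
        fr = product_class_fractions([make_pair("ACG", "UGC")])
        assert fr["complementary_fraction"] == 1.0
        assert fr["multi_mismatch_fraction"] is None
        assert fr["terminal_mismatch_fraction"] is None


class TestYieldAndLengths:
    def test_worked_example(self):
        pairs = [
            make_pair("AAA", ""),
            make_pair("AAA", ""),
            make_pair("AAA", "U"),
            make_pair("AAA", "UUU"),
        ]
        out = yield_and_lengths(pairs)
        assert out["yield_fraction"] == 0.5
        cum = out["cumulative_incorporation"]
        assert cum.loc[1, "total"] == 0.5
        assert cum.loc[2, "total"] == 0.25
        assert out["length_distribution"].loc[0] == 0.5
        assert out["length_distribution"].sum() == pytest.approx(1.0)

    def test_all_unextended(self):
        out = yield_and_lengths([make_pair("AAA", "")] * 3)
        assert out["yield_fraction"] == 0.0
        assert (out["cumulative_incorporation"]["total"] == 0).all()

    def test_cumulative_monotone_and_starts_at_yield(self):
        rng = np.random.default_rng(1)
        pairs = random_pairs(rng, n=300)
        out = yield_and_lengths(pairs)
        tot = out["cumulative_incorporation"]["total"].values
        assert (np.diff(tot) <= 1e-15).all()
        assert tot[0] == out["yield_fraction"]
        cum = out["cumulative_incorporation"]
        assert np.allclose(cum["correct"] + cum["incorrect"], cum["total"])


def test_uniform_control_normalization_is_identity():
    """Statistics under a uniform control equal the unnormalized statistics."""
    rng = np.random.default_rng(9)
    pairs = random_pairs(rng, n=300, T=5, err=0.15)
    uniform = NormalizationFactors.uniform(5)
    raw = positional_frequencies(pairs, norm=None)
    normed = positional_frequencies(pairs, norm=uniform)
    pd.testing.assert_frame_equal(raw.F, normed.F)
    t_raw = trimer_frequencies(pairs, norm=None)
    t_norm = trimer_frequencies(pairs, norm=uniform)
    assert (t_raw.freq == t_norm.freq).all()
    assert error_frequency(pairs) == error_frequency(pairs, uniform)


def test_pair_matrix_round_trip_consistency():
    rng = np.random.default_rng(3)
    pairs = random_pairs(rng, n=100, T=5)
    pm = PairMatrix.from_pairs(pairs)
    assert pm.n == 100
    assert [int(x) for x in pm.length] == [p.length for p in pairs]
    assert [int(x) for x in pm.n_mismatches] == [p.n_mismatches for p in pairs]
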