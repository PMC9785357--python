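"""Expression transforms, 2^-ddCt, fruit-shape statistics."""

import numpy as np
import pandas as pd
import pytest

from iq67kit import quant


def make_ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "ct"])


class TestHeatmapMatrix:
    def test_log2p1(self):
        out = quant.heatmap_matrix(pd.DataFrame([[0.0, 3.0]]))
        assert out.to_numpy().tolist() == [[0.0, 2.0]]

    def test_constant_row_zscore(self):
        out = quant.heatmap_matrix(pd.DataFrame([[1.0, 1.0, 1.0]]), "log2p1_zscore")
        assert out.to_numpy().tolist() == [[0.0, 0.0, 0.0]]

    def test_zscore_rows_standardized(self):
        out = quant.heatmap_matrix(
            pd.DataFrame([[0, 1, 4, 9], [2, 2, 8, 30]], dtype=float), "log2p1_zscore")
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            quant.heatmap_matrix(pd.DataFrame([[-1.0]]))


class TestDeltaDeltaCt:
    def _closed_form_table(self):
        rows = []
        for sample, ct_t in (("trt", 25.0), ("cal", 28.0)):
            for bio in (1, 2):
                rows.append((sample, "target", bio, 1, ct_t))
                rows.append((sample, "reference", bio, 1, 20.0))
        return make_ct_table(rows)

    def test_closed_form_fold_eight(self):
        """dCt 5 vs calibrator dCt 8 -> ddCt = -3 -> fold 8."""
        res = {r.sample: r for r in
               quant.delta_delta_ct(self._closed_form_table(), "reference", "cal")}
        assert res["trt"].delta_delta_ct == pytest.approx(-3.0)
        assert res["trt"].fold == pytest.approx(8.0)

    def test_calibrator_fold_is_one(self):
        res = {r.sample: r for r in
               quant.delta_delta_ct(self._closed_form_table(), "reference", "cal")}
        assert res["cal"].fold == pytest.approx(1.0)

    def test_technical_replicates_averaged_first(self):
        rows = [("s", "target", 1, t, ct) for t, ct in ((1, 25.1), (2, 24.9), (3, 25.0))]
        rows += [("s", "reference", 1, 1, 20.0)]
        res = quant.delta_delta_ct(make_ct_table(rows), "reference", "s")
        assert res[0].delta_ct == pytest.approx(5.0)

    def test_ct_shift_doubles_fold(self):
        """Subtracting one cycle from the target Ct doubles the fold change."""
        base = self._closed_form_table()
        shifted = base.copy()
        mask = (shifted["sample"] == "trt") & (shifted["gene"] == "target")
        shifted.loc[mask, "ct"] -= 1.0
        f0 = {r.sample: r for r in quant.delta_delta_ct(base, "reference", "cal")}
        f1 = {r.sample: r for r in quant.delta_delta_ct(shifted, "reference", "cal")}
        assert f1["trt"].fold == pytest.approx(2 * f0["trt"].fold)

    def test_missing_reference_errors(self):
        tbl = make_ct_table([("s", "target", 1, 1, 25.0)])
        with pytest.raises(ValueError, match="reference"):
            quant.delta_delta_ct(tbl, "reference", "s")


class TestFsiArithmetic:
    @pytest.mark.parametrize("v,h,expected", [(10, 8, 1.25), (7, 7, 1.0)])
    def test_fsi(self, v, h, expected):
        assert quant.fsi(v, h) == pytest.approx(expected)

    def test_fsi_scale_invariance(self):
        assert quant.fsi(3 * 1.7, 3 * 1.3) == pytest.approx(quant.fsi(1.7, 1.3))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            quant.fsi(0, 1)

    def test_line_average(self):
        assert (1.23 + 1.21) / 2 == pytest.approx(1.22)

    @pytest.mark.parametrize("t,c,expected", [
        (1.22, 1.09, 11.9),
        (1.18, 1.09, 8.3),
        (5.0, 5.0, 0.0),
    ])
    def test_percent_increase(self, t, c, expected):
        assert quant.percent_increase(t, c) == expected


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "v": [1.0, 2, 3, 4] * 2})
        out = quant.compare_groups(df, "v", "g")
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "stars"] == "ns"

    def test_strong_separation_four_stars(self, rng):
        df = pd.DataFrame({
            "g": ["a"] * 50 + ["b"] * 50,
            "v": np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
        })
        out = quant.compare_groups(df, "v", "g")
        assert out.loc[0, "p"] < 1e-4
        assert out.loc[0, "stars"] == "****"

    @pytest.mark.parametrize("p,stars", [
        (0.03, "*"), (0.004, "**"), (0.0005, "***"), (5e-5, "****"),
        (0.05, "ns"), (0.2, "ns"),
    ])
    def test_star_mapping_strictly_below(self, p, stars):
        assert quant.star_code(p) == stars

    def test_degenerate_group_errors(self):
        df = pd.DataFrame({"g": ["a", "b", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            quant.compare_groups(df, "v", "g")


class TestSignificanceLetters:
    def test_outlier_group_separated(self, rng):
        groups = {
            "A": rng.normal(10, 1, 30),
            "B": rng.normal(0, 1, 30),
            "C": rng.normal(0, 1, 30),
        }
        letters = quant.significance_letters(groups)
        assert letters["A"] == "a"
        assert letters["B"] == letters["C"] == "b"

    def test_identical_groups_share_letter(self):
        g = {k: [1.0, 2.0, 3.0, 4.0] for k in "ABC"}
        assert set(quant.significance_letters(g).values()) == {"a"}

    def test_letters_consistent_with_pairwise_matrix(self, rng):
        """CLD oracle: groups share a letter iff not significantly different."""
        groups = {f"g{i}": rng.normal(mu, 1, 25)
                  for i, mu in enumerate([0, 0.3, 4, 4.2, 12])}
        letters = quant.significance_letters(groups)
        sig = quant.pairwise_significance(
            {k: np.asarray(v) for k, v in groups.items()})
        for (a, b), different in sig.items():
            shared = set(letters[a]) & set(letters[b])
            assert bool(shared) == (not different), (a, b, letters)

    def test_letter_count_bounded_by_groups(self, rng):
        groups = {f"g{i}": rng.normal(i * 3.0, 1, 20) for i in range(5)}
        letters = quant.significance_letters(groups)
        assert len(set("".join(letters.values()))) <= len(groups)


class TestRegression:
    def test_perfect_line(self):
        slope, intercept, r2 = quant.expression_fsi_regression(
            [1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
        assert (slope, intercept, r2) == (pytest.approx(2.0), pytest.approx(0.0),
                                          pytest.approx(1.0))

    def test_independent_noise_r2_near_zero(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        *_, r2 = quant.expression_fsi_regression(x, y)
        assert r2 < 0.01

    def test_affine_invariance_of_r2(self, rng):
        x = rng.normal(0, 1, 50)
        y = 1.1 + 0.3 * x + rng.normal(0, 0.2, 50)
        *_, r2a = quant.expression_fsi_regression(x, y)
        *_, r2b = quant.expression_fsi_regression(5.0 + 2.0 * x, y)
        assert r2a == pytest.approx(r2b)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            quant.expression_fsi_regression([1, 1, 1], [1, 2, 3])


class TestFruitStats:
    def test_planted_effect_recovered(self):
        from iq67kit import synth_data
        cfg = synth_data.SynthConfig(seed=17)
        fruit, truth = synth_data.generate_fruit_table(cfg)
        res = {r.line: r for r in quant.fruit_stats(fruit, "WT", "mature")}
        assert res["WT"].mean_fsi == pytest.approx(1.09, abs=0.03)
        oe = [res["Oe-L1"], res["Oe-L2"]]
        assert np.mean([r.mean_fsi for r in oe]) == pytest.approx(1.22, abs=0.03)
        for r in oe:
            assert r.p_vs_control < 1e-4
            assert r.stars == "****"

    def test_missing_control_errors(self):
        df = pd.DataFrame({"line": ["X"] * 3, "fruit_id": list("abc"),
                           "stage": ["mature"] * 3,
                           "vertical": [1.0, 1.1, 1.2], "horizontal": [1.0] * 3})
        with pytest.raises(ValueError, match="control"):
            quant.fruit_stats(df, control_line="WT")
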