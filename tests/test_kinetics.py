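"""Michaelis-Menten fitting, modulator series, dose-response and statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from abatune import (
    KineticsDataset,
    MMSpec,
    anova2_tukey,
    biphasic_test,
    compact_letter_display,
    fit_mm,
    gen_mm,
    modulator_series,
    to_rate,
    welch_t,
)
from abatune.kinetics import UM

from oracles import welch_from_formulas

GRID_M = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0]) * UM


class TestToRate:
    @pytest.mark.parametrize(
        "product, time, mass, expected",
        [(119.0, 20.0, 5.0, 1.19), (0.0, 20.0, 5.0, 0.0), (50.0, 10.0, 10.0, 0.5)],
    )
    def test_rate_arithmetic(self, product, time, mass, expected):
        assert to_rate(product, time, mass) == pytest.approx(expected)

    @pytest.mark.parametrize("time, mass", [(0.0, 5.0), (-1.0, 5.0), (20.0, 0.0)])
    def test_nonpositive_divisors_error(self, time, mass):
        with pytest.raises(ValueError):
            to_rate(10.0, time, mass)


class TestFitMM:
    def test_noise_free_exact_recovery(self):
        v = 1.19 * GRID_M / (5.21e-6 + GRID_M)
        fit = fit_mm(S=GRID_M, v=v)
        assert fit.converged
        assert fit.vmax == pytest.approx(1.19, rel=1e-6)
        assert fit.km == pytest.approx(5.21e-6, rel=1e-6)

    def test_vmax_scaling_km_invariance(self):
        v = 1.19 * GRID_M / (5.21e-6 + GRID_M)
        full = fit_mm(S=GRID_M, v=v)
        half = fit_mm(S=GRID_M, v=v / 2.0)
        assert half.vmax == pytest.approx(full.vmax / 2.0, rel=1e-6)
        assert half.km == pytest.approx(full.km, rel=1e-6)

    def test_control_condition_recovery_with_noise(self):
        ds, _ = gen_mm(MMSpec(seed=0))
        fit = fit_mm(ds.at_level(0.0))
        assert fit.vmax == pytest.approx(1.19, rel=0.10)
        assert fit.km_uM == pytest.approx(5.21, rel=0.20)

    def test_recovery_over_100_seeded_simulations(self):
        """Median relative error: Vmax <= 5%, KM <= 15% at 2% noise."""
        ev, ek = [], []
        for seed in range(100):
            ds, _ = gen_mm(MMSpec(seed=seed))
            fit = fit_mm(ds.at_level(0.0))
            ev.append(abs(fit.vmax - 1.19) / 1.19)
            ek.append(abs(fit.km - 5.21e-6) / 5.21e-6)
        assert np.median(ev) <= 0.05
        assert np.median(ek) <= 0.15

    def test_too_few_substrate_levels_error(self):
        S = np.array([1.0, 2.0, 5.0]) * UM
        with pytest.raises(ValueError, match="4 distinct substrate"):
            fit_mm(S=S, v=np.ones_like(S))

    def test_km_identifiability_warning_on_saturating_grid(self):
        km = 5.21e-6
        S = np.array([60.0, 100.0, 150.0, 200.0]) * UM  # all >= ~10x KM
        v = 1.19 * S / (km + S)
        fit = fit_mm(S=S, v=v)
        assert any("KM" in w for w in fit.warnings)


class TestModulatorSeries:
    def test_percent_changes_at_printed_parameters(self):
        ds, _ = gen_mm(
            MMSpec(
                seed=0,
                levels={
                    0.0: (1.19, 5.21e-6),
                    2e-9: (1.58, 5.21e-6),
                    50e-9: (0.75, 5.21e-6),
                },
                noise_frac=0.0,
            )
        )
        series = modulator_series(ds)
        assert series.percent_vmax_change[2e-9] == pytest.approx(32.77, abs=0.01)
        assert series.percent_vmax_change[50e-9] == pytest.approx(-36.97, abs=0.01)
        assert series.percent_vmax_change[0.0] == 0.0

    def test_missing_control_error(self):
        ds, _ = gen_mm(MMSpec(seed=1, levels={2e-9: (1.58, 5.21e-6)}))
        with pytest.raises(ValueError, match="control"):
            modulator_series(ds)

    def test_csv_round_trip_with_raw_product_columns(self, tmp_path):
        rows = []
        for s_um in (1, 5, 20, 100):
            v = 1.19 * s_um / (5.21 + s_um)
            rows.append(
                {
                    "substrate_conc_uM": s_um,
                    "modulator_conc_nM": 0.0,
                    "replicate": 1,
                    "product_pmol": v * 20.0 * 5.0,
                    "time_min": 20.0,
                    "protein_ug": 5.0,
                }
            )
        path = tmp_path / "assay.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        ds = KineticsDataset.from_csv(path)
        fit = fit_mm(ds.at_level(0.0))
        assert fit.vmax == pytest.approx(1.19, rel=1e-6)


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_textbook_formulas(self):
        a, b = [2.0, 2.1, 1.9], [3.0, 3.1, 2.9]
        res = welch_t(a, b)
        t_expect, df_expect = welch_from_formulas(a, b)
        assert res.statistic == pytest.approx(t_expect, rel=1e-12)
        assert res.df == pytest.approx(df_expect, rel=1e-12)
        assert res.pvalue < 0.001

    def test_antisymmetry(self):
        a, b = [2.0, 2.1, 1.9], [3.0, 3.2, 2.9]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_distinct_constant_groups(self):
        res = welch_t([1.0, 1.0], [2.0, 2.0])
        assert res.pvalue == 0.0

    def test_single_value_group_error(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestBiphasic:
    @staticmethod
    def _profile(effects, cv, seed, n=3, control=1.0):
        rng = np.random.default_rng(seed)
        out = {0.0: (control + rng.normal(0, cv * control, n)).tolist()}
        for lvl, eff in effects.items():
            mean = control * (1 + eff)
            out[lvl] = (mean + rng.normal(0, cv * mean, n)).tolist()
        return out

    def test_hormetic_profile_classified_biphasic(self):
        prof = self._profile({2e-9: 0.30, 10e-9: 0.15, 50e-9: -0.30}, 0.05, seed=0)
        assert biphasic_test(prof).classification == "biphasic"

    def test_flat_profile(self):
        prof = self._profile({2e-9: 0.0, 10e-9: 0.0, 50e-9: 0.0}, 0.05, seed=1)
        assert biphasic_test(prof).classification == "flat"

    def test_monotonic_up(self):
        prof = self._profile({2e-9: 0.3, 10e-9: 0.6, 50e-9: 0.9}, 0.02, seed=2, n=5)
        assert biphasic_test(prof).classification == "monotonic_up"

    def test_monotonic_down(self):
        prof = self._profile({2e-9: -0.3, 10e-9: -0.5, 50e-9: -0.7}, 0.02, seed=3, n=5)
        assert biphasic_test(prof).classification == "monotonic_down"

    def test_control_relative_activity_is_unity(self):
        prof = self._profile({2e-9: 0.3, 10e-9: 0.1, 50e-9: -0.3}, 0.05, seed=4)
        result = biphasic_test(prof)
        assert result.relative_activity[0.0] == 1.0

    def test_single_replicate_error(self):
        prof = {0.0: [1.0, 1.1], 1e-9: [1.2], 2e-9: [1.0, 1.1], 3e-9: [1.0, 0.9]}
        with pytest.raises(ValueError, match="single replicate"):
            biphasic_test(prof)

    def test_missing_control_error(self):
        with pytest.raises(ValueError, match="control"):
            biphasic_test({1e-9: [1, 2], 2e-9: [1, 2], 3e-9: [1, 2]})

    def test_raw_and_adjusted_decisions_reported(self):
        prof = self._profile({2e-9: 0.30, 10e-9: 0.15, 50e-9: -0.30}, 0.05, seed=5)
        table = biphasic_test(prof).tests
        assert {"p_raw", "p_adj", "significant_raw", "significant"} <= set(table.columns)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()


class TestCompactLetterDisplay:
    @staticmethod
    def _consistent(groups, sig_pairs, letters):
        for g1, g2 in itertools.combinations(groups, 2):
            shared = bool(set(letters[g1]) & set(letters[g2]))
            significant = frozenset((g1, g2)) in sig_pairs
            if shared == significant:
                return False
        return True

    def test_exhaustive_consistency_up_to_four_groups(self):
        """Every significance pattern on <= 4 groups yields a consistent display."""
        groups = ["a", "b", "c", "d"]
        pairs = list(itertools.combinations(groups, 2))
        for bits in itertools.product([0, 1], repeat=len(pairs)):
            sig = {frozenset(p) for p, b in zip(pairs, bits) if b}
            letters = compact_letter_display(groups, sig)
            assert self._consistent(groups, sig, letters)

    def test_random_six_group_patterns(self, rng):
        groups = list("uvwxyz")
        pairs = list(itertools.combinations(groups, 2))
        for _ in range(200):
            sig = {frozenset(p) for p in pairs if rng.random() < 0.4}
            letters = compact_letter_display(groups, sig)
            assert self._consistent(groups, sig, letters)

    def test_all_different_all_distinct_letters(self):
        groups = ["a", "b", "c"]
        sig = {frozenset(p) for p in itertools.combinations(groups, 2)}
        letters = compact_letter_display(groups, sig)
        assert len({letters[g] for g in groups}) == 3


class TestAnova2Tukey:
    @staticmethod
    def _table(rng, shift_variant=None, shift=0.0, sd=1.0, n=3):
        rows = []
        for variant in ("WT", "E657A", "Y678A"):
            for level in (0.0, 2.0, 10.0, 50.0):
                mu = 10.0 + (shift if variant == shift_variant else 0.0)
                for r in range(n):
                    rows.append(
                        {
                            "variant": variant,
                            "level": level,
                            "rate": mu + rng.normal(0, sd),
                        }
                    )
        return pd.DataFrame(rows)

    def test_shifted_variant_gets_distinct_letter(self, rng):
        table = self._table(rng, shift_variant="WT", shift=10.0)  # 10 SD apart
        res = anova2_tukey(table)
        for level, letters in res.letters.items():
            assert set(letters["WT"]).isdisjoint(set(letters["E657A"]))
            assert set(letters["WT"]).isdisjoint(set(letters["Y678A"]))
        assert res.pvalue is not None

    def test_null_tables_mostly_share_letters(self):
        """Under the null, per-level letter splits occur at roughly rate alpha."""
        split = total = 0
        for seed in range(40):
            table = self._table(np.random.default_rng(seed))
            res = anova2_tukey(table)
            for level, letters in res.letters.items():
                total += 1
                if len(set(letters.values())) > 1:
                    split += 1
        assert split / total <= 0.15  # ~5% expected familywise per level

    def test_letters_consistent_with_pairwise_matrix(self, rng):
        table = self._table(rng, shift_variant="Y678A", shift=3.0)
        res = anova2_tukey(table)
        for level, ptab in res.pairwise.items():
            letters = res.letters[level]
            for _, row in ptab.iterrows():
                shared = bool(set(letters[row["group1"]]) & set(letters[row["group2"]]))
                assert shared != bool(row["reject"])

    def test_two_group_special_case_matches_pooled_t(self, rng):
        """With k = 2 the Tukey p equals the pooled two-sample t-test p."""
        from scipy import stats

        rows = []
        for variant, mu in (("A", 10.0), ("B", 11.0)):
            for r in range(6):
                rows.append(
                    {"variant": variant, "level": 0.0, "rate": mu + rng.normal(0, 1)}
                )
            for r in range(6):
                rows.append(
                    {"variant": variant, "level": 2.0, "rate": mu + rng.normal(0, 1)}
                )
        table = pd.DataFrame(rows)
        res = anova2_tukey(table)
        for level in (0.0, 2.0):
            sub = table[table["level"] == level]
            t_p = stats.ttest_ind(
                sub[sub["variant"] == "A"]["rate"],
                sub[sub["variant"] == "B"]["rate"],
                equal_var=True,
            ).pvalue
            tukey_p = float(res.pairwise[level]["p-adj"].iloc[0])
            assert tukey_p == pytest.approx(t_p, abs=2e-3)

    def test_empty_cell_error_names_cell(self, rng):
        table = self._table(rng)
        table = table[~((table["variant"] == "WT") & (table["level"] == 2.0))]
        with pytest.raises(ValueError, match="empty design cells"):
            anova2_tukey(table)

    def test_single_replicate_cell_error(self, rng):
        table = self._table(rng)
        drop = table[(table["variant"] == "WT") & (table["level"] == 2.0)].index[1:]
        with pytest.raises(ValueError, match="single replicate"):
            anova2_tukey(table.drop(index=drop))
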