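"""Mixed-model trend fitting, cell contrasts, TANOVA and t-maps."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_meta_frame, simulate_descriptor_table
from somnostate.core import DesignError
from somnostate.stats import (
    ModelSpec,
    channel_t_map,
    contrast_slopes,
    contrast_table,
    fit_lmm,
    predicted_trajectories,
    prepare_table,
    tanova,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestFitLmm:
    def test_constant_response_gives_zero_slopes(self):
        rng = np.random.default_rng(0)
        table = simulate_descriptor_table(10, 4, rng)
        table["sigma"] = 7.0
        res = fit_lmm(table, ModelSpec("sigma", "descriptor"))
        assert res.coefficients.loc["Intercept", "estimate"] == pytest.approx(7.0, abs=1e-6)
        slopes = res.coefficients.drop("Intercept")["estimate"]
        assert slopes.abs().max() < 1e-6

    def test_known_slopes_recovered(self):
        rng = np.random.default_rng(1)
        slopes = {
            (False, False): 0.00,
            (False, True): 0.02,
            (True, False): -0.02,
            (True, True): 0.06,
        }
        table = simulate_descriptor_table(40, 8, rng, slopes=slopes, sd_within=0.3)
        res = fit_lmm(table, ModelSpec("sigma", "descriptor"))
        covered = 0
        for cell, want in slopes.items():
            c = contrast_slopes(res, pod=cell[0], suppression=cell[1])
            covered += c["ci_low"] <= want <= c["ci_high"]
            assert c["estimate"] == pytest.approx(want, abs=0.01)
        # individual 95% CIs may miss occasionally; most cells must cover
        assert covered >= 3

    def test_single_patient_refused(self):
        rng = np.random.default_rng(2)
        table = simulate_descriptor_table(10, 4, rng)
        single = table[table["patient_id"] == "P000"]
        with pytest.raises(DesignError):
            fit_lmm(single, ModelSpec("sigma", "descriptor"))

    def test_empty_interaction_cell_refused(self):
        rng = np.random.default_rng(3)
        table = simulate_descriptor_table(10, 4, rng)
        # remove every suppression interval of POD patients
        broken = table[~((table["pod"] == 1) & (table["suppression"] == 1))]
        with pytest.raises(DesignError):
            fit_lmm(broken, ModelSpec("sigma", "descriptor"))


class TestContrastSlopes:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(4)
        table = simulate_descriptor_table(25, 6, rng, slopes={(True, True): 0.05})
        return fit_lmm(table, ModelSpec("sigma", "descriptor"))

    def test_reference_cell_equals_bare_duration_coefficient(self, fitted):
        c = contrast_slopes(fitted, pod=False, suppression=False)
        assert c["estimate"] == fitted.coefficients.loc["anaesthesia_duration", "estimate"]
        assert c["se"] == pytest.approx(
            fitted.coefficients.loc["anaesthesia_duration", "se"]
        )

    def test_full_cell_sums_four_coefficients(self, fitted):
        c = contrast_slopes(fitted, pod=True, suppression=True)
        coefs = fitted.coefficients["estimate"]
        manual = (
            coefs["anaesthesia_duration"]
            + coefs["anaesthesia_duration:suppression"]
            + coefs["anaesthesia_duration:pod"]
            + coefs["anaesthesia_duration:suppression:pod"]
        )
        assert c["estimate"] == pytest.approx(manual)

    def test_descriptor_model_refuses_class_argument(self, fitted):
        with pytest.raises(ValueError):
            contrast_slopes(fitted, pod=False, suppression=False, microstate="A")

    def test_contrast_table_covers_all_cells(self, fitted):
        t = contrast_table(fitted)
        assert len(t) == 4
        assert set(zip(t["pod"], t["suppression"])) == {
            (False, False), (False, True), (True, False), (True, True)
        }


class TestQuantifierModel:
    @pytest.fixture(scope="class")
    def quant_table(self):
        rng = np.random.default_rng(5)
        meta = make_meta_frame(20, 7, rng)
        rows = []
        for i in range(20):
            pod = bool(meta.loc[i, "pod"])
            b = rng.normal(0, 0.5)
            for j in range(8):
                t = 15.0 + 30.0 * j
                supp = bool(j % 2)
                for k, ms in enumerate("ABCD"):
                    slope = 0.08 if (pod and supp and ms == "C") else 0.0
                    rows.append(
                        dict(
                            patient_id=f"P{i:03d}", mean_time=t, suppression=supp,
                            class_index=k,
                            duration_ms=100 + b + slope * t + rng.normal(0, 2),
                        )
                    )
        return prepare_table(pd.DataFrame(rows), meta)

    def test_four_way_model_and_class_contrast(self, quant_table):
        res = fit_lmm(quant_table, ModelSpec("duration_ms", "quantifier"))
        inter = [
            n for n in res.coefficients.index
            if n.count(":") == 3 and "anaesthesia_duration" in n
        ]
        assert len(inter) == 3  # one per non-reference class
        c_c = contrast_slopes(res, pod=True, suppression=True, microstate="C")
        c_a = contrast_slopes(res, pod=True, suppression=True, microstate="A")
        # the class-C-only injection separates the two class slopes by 0.08
        assert c_c["estimate"] - c_a["estimate"] == pytest.approx(0.08, abs=0.03)
        assert c_a["ci_low"] <= 0.0 <= c_a["ci_high"]

    def test_quantifier_contrast_requires_class(self, quant_table):
        res = fit_lmm(quant_table, ModelSpec("duration_ms", "quantifier"))
        with pytest.raises(ValueError):
            contrast_slopes(res, pod=False, suppression=False)


class TestPredictedTrajectories:
    def test_flat_model_flat_trajectories_and_intercept_at_zero(self):
        rng = np.random.default_rng(6)
        table = simulate_descriptor_table(15, 5, rng, sd_within=0.01, sd_between=0.01)
        table["sigma"] = 5.0
        spec = ModelSpec("sigma", "descriptor", covariates=())
        res = fit_lmm(table, spec)
        out = predicted_trajectories(res, np.array([0.0, 60.0, 120.0]), table)
        assert out["predicted"].std() < 1e-6
        ref = out[
            (out["pod"] == 0) & (out["suppression"] == 0)
            & (out["anaesthesia_duration"] == 0.0)
        ]
        assert ref["predicted"].iloc[0] == pytest.approx(
            res.coefficients.loc["Intercept", "estimate"]
        )

    def test_bands_widen_away_from_centroid_and_extrapolation_flagged(self):
        rng = np.random.default_rng(7)
        table = simulate_descriptor_table(15, 5, rng)
        res = fit_lmm(table, ModelSpec("sigma", "descriptor", covariates=()))
        centre = table["anaesthesia_duration"].mean()
        grid = np.array([centre, centre + 100, centre + 500])
        out = predicted_trajectories(res, grid, table)
        cell = out[(out["pod"] == 0) & (out["suppression"] == 0)]
        widths = (cell["ci_high"] - cell["ci_low"]).values
        assert widths[0] < widths[1] < widths[2]
        assert bool(cell["extrapolated"].iloc[-1])
        assert not bool(cell["extrapolated"].iloc[0])


class TestTanova:
    def test_minimum_attainable_p_with_19_permutations(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(0, 1, (10, 4, 2, 19))
        pod = np.array([True] * 5 + [False] * 5)
        res = tanova(maps, pod, n_permutations=19, seed=0)
        assert (res.table["p"] >= 1 / 20).all()
        assert res.table["p"].min() >= 0.05

    def test_group_specific_class_map_detected(self, template_maps):
        rng = np.random.default_rng(9)
        maps = rng.normal(0, 0.05, (16, 4, 2, 19))
        maps += template_maps[None, :, None, :]
        pod = np.array([True] * 8 + [False] * 8)
        # give the POD group a distinct class-D topography (high SNR)
        maps[pod, 3] += 2.0 * template_maps[0]
        res = tanova(maps, pod, n_permutations=199, seed=1)
        row = res.table.set_index("effect")
        assert row.loc["class x pod", "p"] <= 0.01

    def test_too_small_group_refused(self):
        rng = np.random.default_rng(10)
        maps = rng.normal(0, 1, (6, 4, 2, 19))
        pod = np.array([True] + [False] * 5)
        with pytest.raises(DesignError):
            tanova(maps, pod, n_permutations=19)


class TestChannelTMap:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (8, 19))
        np.testing.assert_allclose(channel_t_map(a, a.copy()), 0.0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")  # near-zero variance is the point
    def test_single_electrode_offset_matches_hand_formula(self):
        rng = np.random.default_rng(12)
        n = 12
        a = rng.normal(0, 1.0, (n, 19))
        b = a.copy()
        b[:, 4] -= 0.8  # constant offset on one electrode
        t = channel_t_map(a, b, paired=True)
        d = a[:, 4] - b[:, 4]
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(n)) if d.std(ddof=1) > 0 else np.inf
        # constant difference: statsmodels/scipy convention gives huge t; check sign+magnitude
        assert t[4] > 10 or np.isinf(expected)
        others = np.delete(t, 4)
        assert np.abs(others).max() < 1e-6

    def test_noisy_offset_matches_paired_formula(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1.0, (15, 19))
        b = a + rng.normal(0.3, 0.5, (15, 19))
        t = channel_t_map(a, b, paired=True)
        d = a - b
        expected = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(15))
        np.testing.assert_allclose(t, expected, rtol=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, (9, 19))
        b = rng.normal(0.2, 1, (9, 19))
        np.testing.assert_allclose(
            channel_t_map(a, b), -channel_t_map(b, a), rtol=1e-10
        )

    def test_single_pair_refused(self):
        with pytest.raises(DesignError):
            channel_t_map(np.zeros((1, 19)), np.ones((1, 19)))
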