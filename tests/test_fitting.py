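"""Least-squares fitting, model selection and uncertainty estimates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import girkfit as gf
from girkfit.fitting import GirkTitrationModel

GIRK4 = gf.get_variant("GIRK4")
P4 = gf.REFERENCE_PARAMETERS["GIRK4"]


def _single_point_dataset(mean, sem=0.02, variant="GIRK4"):
    return gf.TitrationDataset(
        pd.DataFrame(
            {
                "variant": [variant],
                "na_mM": [0.0],
                "ni_nta_fraction": [0.001],
                "normalized_current_mean": [mean],
                "sem": [sem],
                "n_rep": [3],
            }
        )
    )


class TestResidualVector:
    def test_noiseless_data_gives_zero_residuals(self, variant_name, ref_params):
        ds = gf.simulate_dataset(
            ref_params, variant_name, gf.make_design(noise_sd=0.0, seed=0)
        )
        r = gf.residual_vector(ref_params, ds)
        assert np.allclose(r, 0.0, atol=1e-14)

    def test_unweighted_residual_is_plain_gap(self):
        pred = gf.predicted_activity(0.001, 0.0, P4, GIRK4)
        ds = _single_point_dataset(pred + 0.2)
        r = gf.residual_vector(P4, ds)
        assert r[0] == pytest.approx(0.2, abs=1e-12)

    def test_sem_weighting_divides_by_sem(self):
        pred = gf.predicted_activity(0.001, 0.0, P4, GIRK4)
        ds = _single_point_dataset(pred + 0.2, sem=0.02)
        r = gf.residual_vector(P4, ds, weighting="sem_weighted")
        assert r[0] == pytest.approx(10.0, abs=1e-9)

    def test_sem_floor_guards_tiny_sems(self):
        pred = gf.predicted_activity(0.001, 0.0, P4, GIRK4)
        ds = _single_point_dataset(pred + 0.2, sem=1e-9)
        r = gf.residual_vector(P4, ds, weighting="sem_weighted")
        assert r[0] == pytest.approx(0.2 / 0.005, abs=1e-6)

    def test_mixed_variant_dataset_rejected(self):
        df = pd.concat(
            [
                _single_point_dataset(0.1, variant="GIRK4").frame,
                _single_point_dataset(0.1, variant="GIRK1_4").frame,
            ]
        )
        ds = gf.TitrationDataset(df)
        with pytest.raises(ValueError, match="mix"):
            gf.residual_vector(P4, ds)


class TestAdjustedR2:
    def _dataset(self, n=24):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "variant": "GIRK4",
                "na_mM": 0.0,
                "ni_nta_fraction": np.linspace(0, 0.015, n),
                "normalized_current_mean": rng.uniform(0, 1, n),
                "sem": 0.02,
                "n_rep": 3,
            }
        )
        return gf.TitrationDataset(df)

    def test_perfect_fit_gives_one(self):
        assert gf.adjusted_r2(0.0, self._dataset(), 6) == pytest.approx(1.0)

    def test_fit_no_better_than_mean_is_nonpositive(self):
        ds = self._dataset()
        y = ds.mean_activity
        sst = float(np.sum((y - y.mean()) ** 2))
        assert gf.adjusted_r2(sst, ds, 6) <= 0.0

    def test_penalty_formula(self):
        # n=24, n_free=6, R^2=0.95: 1 - 0.05*23/17
        ds = self._dataset(24)
        y = ds.mean_activity
        sst = float(np.sum((y - y.mean()) ** 2))
        val = gf.adjusted_r2(0.05 * sst, ds, 6)
        assert val == pytest.approx(1 - 0.05 * 23 / 17, abs=1e-12)

    def test_degenerate_zero_variance_signalled(self):
        df = self._dataset().frame.copy()
        df["normalized_current_mean"] = 0.5
        with pytest.raises(ValueError, match="zero variance"):
            gf.adjusted_r2(0.1, gf.TitrationDataset(df), 6)


class TestZeroNoiseIdentifiability:
    def test_recovery_to_machine_precision(self, variant_name, ref_params):
        """Noiseless data on the full design grid pin every free parameter."""
        variant = gf.get_variant(variant_name)
        ds = gf.simulate_dataset(
            ref_params, variant_name, gf.make_design(noise_sd=0.0, seed=3)
        )
        res = gf.fit_variant(ds, n_starts=16, seed=0)
        truth = {
            "k_db": ref_params.k_db,
            "k_dn": ref_params.k_dn,
            "b": ref_params.b,
            "eta": ref_params.eta,
        }
        truth.update(
            {
                f"theta_{i}_4": ref_params.theta[i]
                for i in variant.free_theta_indices
            }
        )
        for name, est in res.free_estimates.items():
            assert est == pytest.approx(truth[name], rel=1e-6), name
        assert res.ssr < 1e-20
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-12)


class TestFixedParameters:
    def test_n217d_protocol_holds_b_and_theta44(self):
        """The N217D fit carries b and theta(4) over from the GIRK1/4 fit."""
        p = gf.REFERENCE_PARAMETERS["GIRK1N217D_4"]
        ds = gf.simulate_dataset(
            p, "GIRK1N217D_4", gf.make_design(noise_sd=0.03, seed=21)
        )
        res = gf.fit_variant(
            ds, fixed={"b": 0.6, "theta_4_4": 1.1}, n_starts=12, seed=0
        )
        assert res.fixed == {"b": 0.6, "theta_4_4": 1.1}
        assert res.params.b == 0.6
        assert res.params.theta[4] == 1.1
        assert set(res.free_estimates) == {"k_db", "k_dn", "eta", "theta_0_4"}
        assert res.n_free == 4

    def test_unknown_fixed_name_rejected(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.0, seed=0))
        with pytest.raises(ValueError, match="not in"):
            GirkTitrationModel(ds, fixed={"theta_3_4": 1.0})


class TestFitDiagnostics:
    def test_fit_is_deterministic_given_seed(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.03, seed=9))
        r1 = gf.fit_variant(ds, n_starts=8, seed=5)
        r2 = gf.fit_variant(ds, n_starts=8, seed=5)
        assert r1.free_estimates == r2.free_estimates
        assert r1.ssr == r2.ssr

    def test_standard_errors_finite_and_positive(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.03, seed=9))
        res = gf.fit_variant(ds, n_starts=12, seed=0)
        for name, se in res.bse.items():
            assert np.isfinite(se) and se > 0, name

    def test_summary_lists_all_parameters(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.02, seed=2))
        res = gf.fit_variant(ds, n_starts=8, seed=0)
        text = res.summary()
        for name in GIRK4.parameter_names:
            assert name in text
        assert "adjusted R2" in text

    def test_results_roundtrip_to_dict(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.02, seed=2))
        res = gf.fit_variant(ds, n_starts=8, seed=0)
        d = res.to_dict()
        assert d["variant"] == "GIRK4"
        assert set(d["estimates"]) == set(GIRK4.parameter_names)
        assert d["n_points"] == 27
        assert d["fixed_map"] == {}

    def test_underdetermined_dataset_rejected(self):
        ds = _single_point_dataset(0.1)
        with pytest.raises(ValueError, match="free parameters"):
            GirkTitrationModel(ds)


class TestOpenStoichiometrySelection:
    def test_noiseless_data_identify_four_gbg(self):
        """Data generated with 4 conducting Gbg give SSR 0 only at k=4."""
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.0, seed=0))
        tab = gf.select_open_stoichiometry(ds, seed=0, n_starts=6)
        tab = tab.set_index("j_open")
        assert tab["ssr"][4] < 1e-15
        for k in (1, 2, 3):
            assert tab["ssr"][k] > 1e-4

    def test_self_consistency_for_two_gbg_generator(self):
        """Symmetric check: data generated with 2 conducting Gbg select k=2."""
        xs = np.concatenate([[0.0], np.geomspace(2e-4, 0.015, 8)])
        rows = []
        for na in (0.0, 8.0, 32.0):
            a = gf.predicted_activity(
                xs, np.full_like(xs, na), P4, GIRK4, j_open=2
            )
            for x, mean in zip(xs, np.atleast_1d(a)):
                rows.append(
                    {
                        "variant": "GIRK4",
                        "na_mM": na,
                        "ni_nta_fraction": x,
                        "normalized_current_mean": mean,
                        "sem": 0.0,
                        "n_rep": 3,
                    }
                )
        ds = gf.TitrationDataset(pd.DataFrame(rows))
        tab = gf.select_open_stoichiometry(ds, seed=0, n_starts=6)
        assert int(tab["j_open"].iloc[0]) == 2

    def test_empty_candidates_rejected(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.0, seed=0))
        with pytest.raises(ValueError, match="non-empty"):
            gf.select_open_stoichiometry(ds, j_open_candidates=())


class TestBootstrap:
    def test_zero_noise_bootstrap_spread_vanishes(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.0, seed=0))
        res = gf.fit_variant(ds, n_starts=8, seed=0)
        with pytest.warns(UserWarning, match="small"):
            tab = res.bootstrap(n_boot=10, seed=0)
        assert (tab["boot_sd"] < 1e-6).all()

    def test_bootstrap_sd_same_order_as_curvature_se(self):
        ds = gf.simulate_dataset(P4, "GIRK4", gf.make_design(noise_sd=0.03, seed=4))
        res = gf.fit_variant(ds, n_starts=12, seed=0)
        tab = res.bootstrap(n_boot=60, seed=1)
        ratio = tab.loc["k_dn", "boot_sd"] / res.bse["k_dn"]
        assert 0.1 < ratio < 10
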