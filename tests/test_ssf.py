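import warnings

import numpy as np
import pandas as pd
import pytest

import lionhab.ssf as ssf
from lionhab.design import ModelFit


def _strata(rng, n_strata, k, beta, n_cov=2, animal="a"):
    """Simulate conditional-logit strata with known slopes."""
    rows = []
    for s in range(n_strata):
        X = rng.normal(0, 1, (k + 1, n_cov))
        w = np.exp(X @ beta)
        used = rng.choice(k + 1, p=w / w.sum())
        for j in range(k + 1):
            row = {"stratum_id": f"{animal}_{s}", "animal_id": animal, "case": int(j == used)}
            row |= {f"c{v}": X[j, v] for v in range(n_cov)}
            rows.append(row)
    return pd.DataFrame(rows)


class TestExactCLogit:
    def test_symmetric_strata_give_zero(self):
        # used covariate equals the mean of its availables in every stratum
        rows = []
        for s in range(60):
            vals = [0.0, -1.0 + 0.1 * s % 1, 1.0 - 0.1 * s % 1]
            for j, v in enumerate(vals):
                rows.append({"stratum_id": s, "animal_id": "a", "case": int(j == 0), "c0": v})
        data = pd.DataFrame(rows)
        fit = ssf.fit_clogit_exact(data, ["c0"])
        assert fit.estimates["c0"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_one_covariate(self):
        rng = np.random.default_rng(0)
        data = _strata(rng, 80, 8, np.array([0.6]), n_cov=1)
        fit = ssf.fit_clogit_exact(data, ["c0"])
        grid = np.linspace(-2, 2, 4001)
        X = data["c0"].to_numpy()
        y = data["case"].to_numpy()
        codes = pd.factorize(data["stratum_id"])[0]
        lls = []
        for b in grid:
            eta = b * X
            m = pd.Series(eta).groupby(codes).max().to_numpy()
            denom = pd.Series(np.exp(eta - m[codes])).groupby(codes).sum().to_numpy()
            lls.append(y @ eta - (np.log(denom) + m).sum())
        assert fit.estimates["c0"] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_separation_flagged(self):
        rows = []
        for s in range(40):
            for j, v in enumerate([2.0, 1.0, 0.0, -1.0]):  # used always strictly largest
                rows.append({"stratum_id": s, "animal_id": "a", "case": int(j == 0), "c0": v})
        fit = ssf.fit_clogit_exact(pd.DataFrame(rows), ["c0"])
        assert not fit.converged
        assert "separation_suspected" in fit.flags


class TestPoissonFormulation:
    def test_matches_exact_oracle(self):
        rng = np.random.default_rng(3)
        data = _strata(rng, 150, 10, np.array([0.8, -0.5]))
        p = ssf.fit_ssf_poisson(data, ["c0", "c1"])
        e = ssf.fit_clogit_exact(data, ["c0", "c1"])
        for t in ("c0", "c1"):
            assert p.estimates[t] == pytest.approx(e.estimates[t], abs=1e-2)
            assert p.se[t] == pytest.approx(e.se[t], rel=0.05)

    def test_within_stratum_constant_covariate_rejected(self):
        rng = np.random.default_rng(4)
        data = _strata(rng, 40, 5, np.array([0.5]), n_cov=1)
        data["flat"] = data.groupby("stratum_id")["c0"].transform("mean")
        with pytest.raises(ValueError, match="constant within"):
            ssf.fit_ssf_poisson(data, ["flat"])

    def test_stratum_constant_shift_leaves_oracle_unchanged(self):
        """The exact conditional likelihood is invariant to per-stratum
        covariate shifts; the fixed-variance Poisson device tracks it closely."""
        rng = np.random.default_rng(5)
        data = _strata(rng, 100, 8, np.array([0.7, -0.2]))
        fit1 = ssf.fit_clogit_exact(data, ["c0", "c1"])
        shifted = data.copy()
        offsets = {sid: rng.normal(0, 3) for sid in shifted["stratum_id"].unique()}
        shifted["c0"] = shifted["c0"] + shifted["stratum_id"].map(offsets)
        fit2 = ssf.fit_clogit_exact(shifted, ["c0", "c1"])
        assert fit2.estimates["c0"] == pytest.approx(fit1.estimates["c0"], abs=1e-6)
        fit3 = ssf.fit_ssf_poisson(shifted, ["c0", "c1"])
        assert fit3.estimates["c0"] == pytest.approx(fit1.estimates["c0"], abs=0.05)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(6)
        data = _strata(rng, 60, 6, np.array([0.4, 0.1]))
        fit1 = ssf.fit_ssf_poisson(data, ["c0", "c1"])
        fit2 = ssf.fit_ssf_poisson(data.sample(frac=1.0, random_state=1), ["c0", "c1"])
        for t in ("c0", "c1"):
            assert fit2.estimates[t] == pytest.approx(fit1.estimates[t], abs=1e-8)

    def test_too_few_strata_rejected(self):
        rng = np.random.default_rng(7)
        data = _strata(rng, 10, 5, np.array([0.5]), n_cov=1)
        with pytest.raises(ValueError, match="strata"):
            ssf.fit_ssf_poisson(data, ["c0"])

    def test_random_slopes_dropped_below_animal_minimum(self):
        rng = np.random.default_rng(8)
        data = _strata(rng, 60, 6, np.array([0.5]), n_cov=1)
        with pytest.warns(UserWarning, match="dropping random slopes"):
            fit = ssf.fit_ssf_poisson(data, ["c0"], random_slopes=["c0"])
        assert "animal_slope:c0" not in fit.random_effects

    def test_random_slopes_estimated_with_enough_animals(self):
        rng = np.random.default_rng(9)
        parts = []
        for a in range(4):
            slope = 0.6 + [-0.3, -0.1, 0.1, 0.3][a]
            parts.append(_strata(rng, 40, 6, np.array([slope]), n_cov=1, animal=f"a{a}"))
        data = pd.concat(parts, ignore_index=True)
        fit = ssf.fit_ssf_poisson(data, ["c0"], random_slopes=["c0"])
        re = fit.random_effects["animal_slope:c0"]
        assert not re["fixed"] and re["variance"] > 0
        assert fit.n_params == 2  # slope + one estimated variance


class TestAvailableSteps:
    def test_stratum_sizes_and_determinism(self, ssf_dataset):
        sizes = ssf_dataset.groupby("stratum_id").size()
        assert (sizes == 21).all()  # 1 used + 20 available
        used = ssf_dataset.groupby("stratum_id")["case"].sum()
        assert (used == 1).all()

    def test_same_seed_identical(self, stack, kernel):
        import lionhab as lh
        import lionhab.trajectory as tj

        coeffs = lh.SelectionCoefficients(beta={"cover": 0.5})
        track = lh.simulate_ssf_track(stack, kernel, coeffs, (10_000, 10_000), 60, seed=2)
        steps = tj.build_steps(track, 1.0, 30.0)
        a = ssf.sample_available_steps(steps, kernel, stack, k=10, seed=4)
        b = ssf.sample_available_steps(steps, kernel, stack, k=10, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_available_lengths_follow_fitted_gamma(self, stack, kernel):
        from scipy import stats as st

        import lionhab as lh
        import lionhab.trajectory as tj

        coeffs = lh.SelectionCoefficients(beta={"cover": 0.0})
        track = lh.simulate_ssf_track(stack, kernel, coeffs, (10_000, 10_000), 120, seed=3)
        steps = tj.build_steps(track, 1.0, 30.0)
        data = ssf.sample_available_steps(steps, kernel, stack, k=50, seed=5)
        avail = data[data["case"] == 0]
        starts = steps.set_index("stratum_id")
        lengths = np.hypot(
            avail["x"].to_numpy() - avail["stratum_id"].map(starts["x_start"]).to_numpy(),
            avail["y"].to_numpy() - avail["stratum_id"].map(starts["y_start"]).to_numpy(),
        )
        ref = np.maximum(np.random.default_rng(9).gamma(kernel.gamma_shape, kernel.gamma_scale, 5000), 1.0)
        assert st.ks_2samp(lengths, ref).pvalue > 0.01


class TestModelSet:
    def test_exactly_six_models_with_expected_terms(self):
        models = ssf.candidate_model_set()
        assert len(models) == 6
        by_name = {m.name: set(m.terms) for m in models}
        assert by_name["cover_only"] == {"cover"}
        assert "cover" not in by_name["habitat_no_cover"]
        assert by_name["full_interaction"] - by_name["full"] == {"cover:dist_human", "cover:dens_human"}
        assert by_name["human_only"] == {"dist_human", "dens_human"}


class TestAICRanking:
    def _fit(self, name, loglik, k):
        return ModelFit(
            terms=[f"t{i}" for i in range(k)],
            estimates={f"t{i}": 0.0 for i in range(k)},
            se={f"t{i}": 1.0 for i in range(k)},
            loglik=loglik,
            n_obs=100,
        )

    def test_formula_and_ordering(self):
        table = ssf.rank_by_aic({"a": self._fit("a", -100.0, 5), "b": self._fit("b", -90.0, 5)})
        assert table["aic"].iloc[0] == pytest.approx(190.0)
        assert list(table["model"]) == ["b", "a"]
        assert table["delta_aic"].iloc[0] == 0.0

    def test_tie_broken_by_fewer_parameters(self):
        table = ssf.rank_by_aic({"big": self._fit("big", -99.0, 4), "small": self._fit("small", -100.0, 3)})
        assert table["aic"].iloc[0] == table["aic"].iloc[1]
        assert table["model"].iloc[0] == "small"

    def test_nonconverged_excluded_with_warning(self):
        bad = self._fit("bad", -50.0, 2)
        bad.converged = False
        with pytest.warns(UserWarning, match="non-converged"):
            table = ssf.rank_by_aic({"good": self._fit("good", -100.0, 2), "bad": bad})
        assert list(table["model"]) == ["good"]


class TestRadiusSelection:
    def test_single_radius_returned(self, ssf_dataset):
        r, table = ssf.select_density_radius(ssf_dataset.assign(dens_human_3km=ssf_dataset["dens_human"]), [3.0], terms=["cover", "dens_human"])
        assert r == 3.0 and len(table) == 1

    def test_identical_layers_tie_to_smallest(self):
        rng = np.random.default_rng(11)
        data = _strata(rng, 60, 6, np.array([0.5]), n_cov=1).rename(columns={"c0": "cover"})
        rng2 = np.random.default_rng(12)
        dens = rng2.normal(0, 1, len(data))
        for r in (1, 3, 5):
            data[f"dens_human_{r}km"] = dens
        radius, table = ssf.select_density_radius(data, (1.0, 3.0, 5.0), terms=["cover", "dens_human"])
        assert radius == 1.0
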