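"""Robust noise-model fitting and the residual/AF calling rules."""

import math

import numpy as np
import pandas as pd
import pytest

from ampcall.noise import (
    NoiseModelFit,
    call_mutations,
    fit_noise_model,
    logit_af,
)


class TestLogitAF:
    def test_symmetry_point(self):
        assert logit_af(500, 1000) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # log(0.0225 / 0.9775) evaluated directly
        assert logit_af(225, 10000) == pytest.approx(math.log(0.0225 / 0.9775))
        assert logit_af(225, 10000) == pytest.approx(-3.77148, abs=1e-4)

    def test_fixed_allele_clamped(self):
        # count == depth clamps a to (depth - 0.5)/depth -> log(999.5/0.5)
        assert logit_af(1000, 1000) == pytest.approx(math.log(999.5 / 0.5))
        assert logit_af(1000, 1000) == pytest.approx(7.6004, abs=1e-3)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            logit_af(0, 1000)


def _plane_obs(n_positions=40, samples=("S1", "S2", "S3"), beta0=-6.9, beta1=0.01,
               effects=None, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    effects = effects or {s: 0.0 for s in samples}
    rows = []
    for s in samples:
        for off in range(1, n_positions + 1):
            y = beta0 + beta1 * off + effects[s]
            if noise is not None:
                y += noise(rng)
            rows.append({"sample": s, "offset": off, "af": 1 / (1 + np.exp(-y)),
                         "amplicon": "AMP", "depth": 10_000})
    return pd.DataFrame(rows)


class TestFit:
    def test_noise_free_plane_recovered_exactly(self):
        obs = _plane_obs(effects={"S1": 0.0, "S2": 0.3, "S3": -0.2})
        fit = fit_noise_model(obs)
        assert fit.converged and not fit.unfittable
        assert fit.beta0 == pytest.approx(-6.9, abs=1e-6)
        assert fit.beta1 == pytest.approx(0.01, abs=1e-8)
        assert fit.beta_sample["S2"] == pytest.approx(0.3, abs=1e-6)
        assert fit.beta_sample["S3"] == pytest.approx(-0.2, abs=1e-6)
        assert np.allclose(fit.residuals, 0.0, atol=1e-6)

    def test_huber_equals_ols_without_outliers(self):
        """On outlier-free data the Huber IRLS solution is the OLS solution.

        Residuals alternate +/-c, so every |residual| is well inside the
        Huber corner (1.345 * MAD/0.6745 ~ 2c) and all IRLS weights are 1.
        """
        import statsmodels.api as sm

        c = 0.01
        obs = _plane_obs(
            n_positions=8,
            samples=("S1", "S2"),
            noise=None,
        )
        y_extra = np.array([c if i % 2 == 0 else -c for i in range(len(obs))])
        logit = np.log(obs["af"] / (1 - obs["af"])) + y_extra
        obs = obs.assign(af=1 / (1 + np.exp(-logit)))
        assert len(obs) <= 30
        fit = fit_noise_model(obs)
        X = np.column_stack(
            [np.ones(len(obs)), obs["offset"], (obs["sample"] == "S2").astype(float)]
        )
        ols = np.asarray(sm.OLS(np.asarray(logit), X).fit().params)
        assert fit.beta0 == pytest.approx(ols[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(ols[1], abs=1e-6)
        assert fit.beta_sample["S2"] == pytest.approx(ols[2], abs=1e-6)

    def test_single_sample_degenerate_design(self):
        obs = _plane_obs(samples=("only",))
        fit = fit_noise_model(obs)
        assert fit.converged and not fit.unfittable
        assert fit.beta_sample == {"only": 0.0}
        assert fit.beta1 == pytest.approx(0.01, abs=1e-8)

    def test_underdetermined_design_flagged(self):
        obs = _plane_obs(n_positions=1, samples=("S1", "S2", "S3"))[:3]
        fit = fit_noise_model(obs)
        assert fit.unfittable
        calls = call_mutations(fit, obs)
        assert (calls["reason"] == "insufficient-data").all()

    def test_sample_relabeling_changes_no_residual_or_call(self):
        rng_noise = lambda rng: rng.normal(0, 0.3)
        obs = _plane_obs(samples=("S1", "S2", "S3"), noise=rng_noise, seed=42)
        fit = fit_noise_model(obs)
        calls = call_mutations(fit, obs)
        relabel = {"S1": "zz", "S2": "aa", "S3": "mm"}
        obs2 = obs.assign(sample=obs["sample"].map(relabel))
        fit2 = fit_noise_model(obs2)
        calls2 = call_mutations(fit2, obs2)
        assert np.allclose(np.sort(fit.residuals), np.sort(fit2.residuals), atol=1e-8)
        assert (calls["status"].to_numpy() == calls2["status"].to_numpy()).all()

    def test_beta1_recovery_within_2se(self):
        """Fitted position slope covers the generating value (spec of the
        generator: 150 positions x 10 samples, slope 0.005, noise 0.3)."""
        from ampcall.experiments import beta1_recovery

        rec = beta1_recovery(n_seeds=20, seed=3)
        assert rec["converged"].all()
        assert rec["beta1_within_2se"].mean() >= 0.9


class TestCalling:
    def _fit_with_residuals(self, resid):
        resid = np.asarray(resid, float)
        return NoiseModelFit(
            amplicon="A",
            beta0=0.0,
            beta1=0.0,
            residuals=resid,
            obs_index=np.arange(resid.size),
            residual_median=float(np.median(resid)),
            residual_sd=float(np.std(resid, ddof=1)),
            n_obs=resid.size,
            converged=True,
        )

    def _obs(self, afs):
        return pd.DataFrame(
            {
                "sample": "S",
                "amplicon": "A",
                "offset": np.arange(1, len(afs) + 1),
                "af": afs,
                "count": (np.asarray(afs) * 10000).astype(int),
                "depth": 10000,
            }
        )

    def test_residual_and_af_rules(self):
        resid = np.concatenate([np.random.default_rng(0).normal(0, 1, 97),
                                [4.0, 4.0, 2.0]])
        fit = self._fit_with_residuals(resid)
        med, sd = fit.residual_median, fit.residual_sd
        fit.residuals[-3:] = [med + 4 * sd, med + 4 * sd, med + 2 * sd]
        afs = [0.001] * 97 + [0.02, 0.004, 0.05]
        calls = call_mutations(fit, self._obs(afs))
        assert calls["status"].iloc[-3] == "called"
        assert calls["status"].iloc[-2] == "rejected"
        assert calls["reason"].iloc[-2] == "below-min-AF"
        assert calls["status"].iloc[-1] == "rejected"
        assert calls["reason"].iloc[-1] == "within-noise"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        resid = rng.normal(0, 1, 200)
        fit = self._fit_with_residuals(resid)
        afs = np.full(200, 0.01)
        none_called = call_mutations(fit, self._obs(afs), sd_threshold=np.inf)
        assert (none_called["status"] == "rejected").all()
        all_above = call_mutations(fit, self._obs(afs), sd_threshold=0.0)
        expected = fit.residuals >= fit.residual_median
        assert ((all_above["status"] == "called").to_numpy() == expected).all()

    def test_injected_variant_recovered_against_noise_plane(self):
        """A 2% MAF variant at one position in one of 10 samples stands out
        from the fitted position/sample noise plane."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            obs = _plane_obs(
                n_positions=150,
                samples=tuple(f"S{i}" for i in range(10)),
                beta0=-6.9,
                beta1=0.005,
                effects={f"S{i}": e for i, e in
                         enumerate(np.random.default_rng(seed).normal(0, 0.2, 10))},
                noise=lambda r: r.normal(0, 0.3),
                seed=2000 + seed,
            )
            idx = obs.index[(obs["sample"] == "S4") & (obs["offset"] == 75)][0]
            obs.loc[idx, "af"] = 0.02
            fit = fit_noise_model(obs)
            calls = call_mutations(fit, obs)
            hits += calls.loc[idx, "status"] == "called"
        assert hits >= int(0.99 * n_seeds)
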