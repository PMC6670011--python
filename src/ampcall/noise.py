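"""Per-amplicon robust noise model of logit allele frequencies.

The central idea: almost all non-reference alleles observed in deep amplicon
sequencing are PCR or sequencing errors, not mutations.  Under the working
assumptions that (a) errors dominate the observations, (b) PCR error rates
depend on position within an amplicon but are otherwise stable, and (c)
sequencing error at a given position is equally likely in every sample, the
error structure is captured by a linear model on the logit scale

    log(a / (1 - a)) = beta0 + beta1 * offset + beta_sample[s] + eps

with ``a`` the allele frequency, ``offset`` the 1-based position of the
variant on its amplicon and ``s`` the sample (a categorical factor,
reference-coded).  The model is fit per amplicon with a Huber M-estimator so
that the rare true mutations - large positive outliers - do not drag the fit.
The fit is the noise model: an observation is called a true mutation when its
residual exceeds the median residual by at least ``sd_threshold`` standard
deviations and its allele frequency is at least ``min_af``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["NoiseModelFit", "logit_af", "fit_noise_model", "call_mutations", "fit_and_call"]

#: Huber tuning constant, 95% efficiency at the Gaussian model
HUBER_T = 1.345

#: machine-readable rejection reasons
REASON_WITHIN_NOISE = "within-noise"
REASON_BELOW_MIN_AF = "below-min-AF"
REASON_INSUFFICIENT = "insufficient-data"
REASON_NOT_IN_CATALOGUE = "not-in-catalogue"
REASON_SNP = "snp"


def logit_af(count: int, depth: int) -> float:
    """Logit-transformed allele frequency, finite for count == depth.

    ``a = count / depth`` is clamped to at most ``(depth - 0.5) / depth`` so
    a fixed (homozygous-looking) allele still maps to a finite logit.
    Zero counts are rejected: non-variant positions are not observations.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if count < 1:
        raise ValueError("count must be >= 1; non-variant positions are not observations")
    a = min(count / depth, (depth - 0.5) / depth)
    return math.log(a / (1.0 - a))


@dataclass
class NoiseModelFit:
    """Robust per-amplicon regression result (the noise model)."""

    amplicon: str
    beta0: float = float("nan")
    beta1: float = float("nan")
    beta_sample: dict[str, float] = field(default_factory=dict)
    residuals: Optional[np.ndarray] = None  # aligned with obs_index
    obs_index: Optional[np.ndarray] = None
    residual_median: float = float("nan")
    residual_sd: float = float("nan")
    n_obs: int = 0
    converged: bool = False
    n_iter: int = 0
    reference_sample: Optional[str] = None
    bse: Optional[dict[str, float]] = None
    unfittable: bool = False

    def predict(self, offset: np.ndarray, sample: pd.Series) -> np.ndarray:
        eff = sample.map(lambda s: self.beta_sample.get(s, 0.0)).to_numpy(float)
        return self.beta0 + self.beta1 * np.asarray(offset, float) + eff


_MIN_RESIDUAL_SD = 1e-8


def _residual_scale(res: np.ndarray, how: str) -> float:
    if how == "mad":
        sd = float(sm.robust.scale.mad(res, center=np.median(res)))
    else:
        sd = float(np.std(res, ddof=1)) if res.size > 1 else 0.0
    return max(sd, _MIN_RESIDUAL_SD)


def fit_noise_model(
    obs: pd.DataFrame,
    amplicon: Optional[str] = None,
    loss: str = "huber",
    residual_scale: str = "sd",
    maxiter: int = 50,
    tol: float = 1e-8,
) -> NoiseModelFit:
    """Fit the robust noise model for one amplicon's observations.

    ``obs`` must contain columns ``offset``, ``sample`` and either ``af`` or
    (``count``, ``depth``); it should hold every observation of one amplicon
    across all samples of the run.  The sample factor is reference-coded
    against the lexicographically first sample and dropped entirely for
    single-sample designs.  Estimation is iteratively reweighted least
    squares under a Huber loss (scale re-estimated each iteration as
    MAD / 0.6745), converging when the coefficients change by less than
    ``tol``.

    Underdetermined or rank-deficient designs yield an ``unfittable`` result;
    callers downstream reject the amplicon's observations with reason
    "insufficient-data".
    """
    if amplicon is None:
        amps = obs["amplicon"].unique() if "amplicon" in obs else ["?"]
        if len(amps) > 1:
            raise ValueError("fit_noise_model expects observations of a single amplicon")
        amplicon = str(amps[0])
    n = len(obs)
    samples = sorted(obs["sample"].astype(str).unique()) if n else []
    n_params = 2 + max(len(samples) - 1, 0)
    fit = NoiseModelFit(amplicon=amplicon, n_obs=n)
    if n < n_params or n == 0:
        fit.unfittable = True
        return fit

    if "af" in obs.columns:
        a = obs["af"].to_numpy(float)
        depth = obs["depth"].to_numpy(float) if "depth" in obs.columns else None
        if depth is not None:
            a = np.minimum(a, (depth - 0.5) / depth)
        else:
            a = np.minimum(a, 1.0 - 1e-12)
        y = np.log(a / (1.0 - a))
    else:
        y = np.array(
            [logit_af(c, d) for c, d in zip(obs["count"], obs["depth"])], float
        )

    offset = obs["offset"].to_numpy(float)
    cols = [np.ones(n), offset]
    names = ["const", "offset"]
    sample_series = obs["sample"].astype(str)
    for s in samples[1:]:
        cols.append((sample_series == s).to_numpy(float))
        names.append(f"sample[{s}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        fit.unfittable = True
        return fit

    norm = (
        sm.robust.norms.TukeyBiweight()
        if loss == "tukey"
        else sm.robust.norms.HuberT(t=HUBER_T)
    )
    model = sm.RLM(y, X, M=norm)
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs", scale_est="mad")
    params = dict(zip(names, res.params))
    resid = np.asarray(res.resid, float)

    fit.beta0 = params["const"]
    fit.beta1 = params["offset"]
    fit.beta_sample = {samples[0]: 0.0} if samples else {}
    for s in samples[1:]:
        fit.beta_sample[s] = params[f"sample[{s}]"]
    fit.reference_sample = samples[0] if samples else None
    fit.residuals = resid
    fit.obs_index = obs.index.to_numpy()
    fit.residual_median = float(np.median(resid))
    fit.residual_sd = _residual_scale(resid, residual_scale)
    fit.n_iter = int(res.fit_history.get("iteration", 0))
    fit.converged = fit.n_iter < maxiter
    fit.bse = dict(zip(names, np.asarray(res.bse, float)))
    return fit


def call_mutations(
    fit: NoiseModelFit,
    obs: pd.DataFrame,
    sd_threshold: float = 3.0,
    min_af: float = 0.005,
    residual_center: Optional[float] = None,
    residual_sd: Optional[float] = None,
) -> pd.DataFrame:
    """Classify each observation of an amplicon against its noise model.

    Adds ``residual``, ``z_excess``, ``passed_af``, ``status`` and ``reason``
    columns.  An observation is ``called`` iff its residual exceeds the
    residual median by at least ``sd_threshold`` residual standard deviations
    and its allele frequency is at least ``min_af`` (the clinical-relevance
    floor).  ``residual_center``/``residual_sd`` override the per-amplicon
    statistics for the pooled-residual mode.
    """
    out = obs.copy()
    if "af" not in out.columns:
        out["af"] = out["count"] / out["depth"]
    if fit.unfittable or fit.residuals is None:
        out["residual"] = np.nan
        out["z_excess"] = np.nan
        out["passed_af"] = out["af"] >= min_af
        out["status"] = "rejected"
        out["reason"] = REASON_INSUFFICIENT
        return out
    center = fit.residual_median if residual_center is None else residual_center
    sd = fit.residual_sd if residual_sd is None else max(residual_sd, _MIN_RESIDUAL_SD)
    resid = pd.Series(fit.residuals, index=fit.obs_index).reindex(out.index)
    out["residual"] = resid.to_numpy(float)
    out["z_excess"] = (out["residual"] - center) / sd
    out["passed_af"] = out["af"] >= min_af
    called = (out["z_excess"] >= sd_threshold) & out["passed_af"]
    out["status"] = np.where(called, "called", "rejected")
    out["reason"] = np.where(
        called,
        "",
        np.where(out["z_excess"] >= sd_threshold, REASON_BELOW_MIN_AF, REASON_WITHIN_NOISE),
    )
    return out


def fit_and_call(
    observations: pd.DataFrame,
    sd_threshold: float = 3.0,
    min_af: float = 0.005,
    loss: str = "huber",
    residual_scale: str = "sd",
    pool_residuals: bool = False,
) -> tuple[dict[str, NoiseModelFit], pd.DataFrame]:
    """Fit the noise model for every amplicon and call mutations.

    With ``pool_residuals`` the median and SD of the residuals are computed
    over the pooled residual vector of all amplicons instead of per amplicon
    (the per-amplicon default matches fitting the model "for each amplicon").
    Returns the fits keyed by amplicon plus the concatenated call table.
    """
    fits: dict[str, NoiseModelFit] = {}
    pieces = []
    groups = list(observations.groupby("amplicon", sort=True))
    for amp, group in groups:
        fits[str(amp)] = fit_noise_model(
            group, amplicon=str(amp), loss=loss, residual_scale=residual_scale
        )
    center = sd = None
    if pool_residuals:
        pooled = np.concatenate(
            [f.residuals for f in fits.values() if f.residuals is not None]
            or [np.array([])]
        )
        if pooled.size:
            center = float(np.median(pooled))
            sd = _residual_scale(pooled, residual_scale)
    for amp, group in groups:
        pieces.append(
            call_mutations(
                fits[str(amp)],
                group,
                sd_threshold=sd_threshold,
                min_af=min_af,
                residual_center=center,
                residual_sd=sd,
            )
        )
    calls = (
        pd.concat(pieces).sort_index()
        if pieces
        else observations.assign(
            residual=np.nan, z_excess=np.nan, passed_af=False, status="rejected", reason=""
        )
    )
    return fits, calls


def fit_diagnostics(fits: dict[str, NoiseModelFit]) -> pd.DataFrame:
    """Per-amplicon fit summary table (coefficients, residual stats, convergence)."""
    rows = []
    for amp, f in sorted(fits.items()):
        rows.append(
            {
                "amplicon": amp,
                "n_obs": f.n_obs,
                "beta0": f.beta0,
                "beta1": f.beta1,
                "residual_median": f.residual_median,
                "residual_sd": f.residual_sd,
                "converged": f.converged,
                "n_iter": f.n_iter,
                "unfittable": f.unfittable,
            }
        )
    return pd.DataFrame(rows)
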