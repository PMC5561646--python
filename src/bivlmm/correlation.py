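"""Correlation summaries derived from a fitted bivariate linear mixed model.

Three summaries are provided:

* association of evolution — the correlations between the two outcomes'
  random intercepts and random slopes,
      rho_intercept = cov(a0, b0) / sqrt(var(a0) var(b0)),
      rho_slope     = cov(a1, b1) / sqrt(var(a1) var(b1));

* evolution of association — the marginal correlation between the outcomes
  as a function of time,
      rho(t) = (cov(a0,b0) + t cov(a0,b1) + t cov(a1,b0) + t^2 cov(a1,b1)
                [+ sigma_12])
               / sqrt(var(a0) + 2 t cov(a0,a1) + t^2 var(a1) + sigma_1^2)
               / sqrt(var(b0) + 2 t cov(b0,b1) + t^2 var(b1) + sigma_2^2),
  with sigma_12 present only under the correlated-error model;

* conditional correlation — the same marginal correlation restricted to the
  subpopulation whose outcome-1 trajectory has level gamma0 > c1 and slope
  gamma1 > c2, estimated by parametric bootstrap from the joint normal law of
  (Y1(t), Y2(t), gamma0, gamma1).

A naive pointwise Pearson estimator and a clustered (subject-resampling)
empirical bootstrap round out the toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DegenerateInputError, LongitudinalDataset
from .model import BLMMFit, RandomEffectsCov

__all__ = [
    "CorrelationEstimates",
    "CorrelationCurve",
    "ConditionalQuery",
    "ConditionalEstimate",
    "BootstrapCI",
    "re_correlations",
    "marginal_correlation",
    "marginal_curve",
    "joint_moments",
    "conditional_correlation",
    "conditional_curve",
    "pointwise_pearson",
    "pointwise_pearson_curve",
    "empirical_bootstrap_ci",
    "default_time_grid",
]


def default_time_grid(stop: float = 7.5, step: float = 0.25) -> np.ndarray:
    """Default evaluation grid for correlation curves: 0 to 7.5 by 0.25 years."""
    return np.arange(0.0, stop + 1e-9, step)


@dataclass
class CorrelationEstimates:
    """Random-effect correlations (association of evolution)."""

    rho_intercept: float
    rho_slope: float
    ci_intercept: tuple | None = None
    ci_slope: tuple | None = None
    method: str = "plugin"

    def __post_init__(self) -> None:
        for v in (self.rho_intercept, self.rho_slope):
            if abs(v) > 1 + 1e-12:
                raise ValueError("correlation outside [-1, 1]")


@dataclass
class CorrelationCurve:
    """rho(t) on a time grid, with optional pointwise 95% bands."""

    times: np.ndarray
    rho: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    flavor: str = "marginal"
    n_eff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        finite = np.isfinite(self.rho)
        if np.any(np.abs(self.rho[finite]) > 1 + 1e-9):
            raise ValueError("|rho| must not exceed 1")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.times)
        return pd.DataFrame({
            "time": self.times,
            "rho": self.rho,
            "ci_lower": self.ci_lower if self.ci_lower is not None else np.full(n, np.nan),
            "ci_upper": self.ci_upper if self.ci_upper is not None else np.full(n, np.nan),
            "flavor": self.flavor,
            "n_eff": self.n_eff if self.n_eff is not None else np.full(n, np.nan),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ConditionalQuery:
    """Settings for the conditional-correlation parametric bootstrap.

    ``c1`` thresholds the outcome-1 trajectory level at the index date
    (gamma0 > c1) and ``c2`` its slope (gamma1 > c2); e.g. -5 dB and
    -0.5 dB/year select the clinically stable subpopulation in the glaucoma
    setting.  ``covariate_profiles`` is an optional (n_subjects, q) array of
    baseline covariates giving each simulated subject its own mean; when
    empty the model must be covariate-free.
    """

    c1: float = -5.0
    c2: float = -0.5
    n_subjects: int = 269
    n_boot: int = 10_000
    covariate_profiles: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if self.covariate_profiles is not None:
            self.covariate_profiles = np.atleast_2d(np.asarray(self.covariate_profiles, dtype=float))
            if self.covariate_profiles.shape[0] != self.n_subjects:
                raise ValueError("covariate_profiles must have one row per simulated subject")


@dataclass
class ConditionalEstimate:
    estimate: float
    ci: tuple
    n_replicates: int
    n_dropped: int
    unreliable: bool
    replicates: np.ndarray | None = None


# -- association of evolution ---------------------------------------------


def re_correlations(re_cov: RandomEffectsCov) -> CorrelationEstimates:
    """Plug-in correlations between the two outcomes' random effects."""
    S = re_cov.Sigma
    v = np.diag(S)
    if np.any(v <= 0):
        raise DegenerateInputError("zero random-effect variance; correlations undefined")
    rho_int = S[0, 1] / np.sqrt(v[0] * v[1])
    rho_slope = S[2, 3] / np.sqrt(v[2] * v[3])
    return CorrelationEstimates(
        rho_intercept=float(np.clip(rho_int, -1, 1)),
        rho_slope=float(np.clip(rho_slope, -1, 1)),
        method="plugin",
    )


# -- evolution of association ---------------------------------------------


def marginal_correlation(fit: BLMMFit, t) -> float | np.ndarray:
    """Marginal correlation between the two outcomes at time ``t`` (years).

    Under the correlated-error model the same-time residual covariance
    sigma_12 enters the numerator.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    S = fit.re_cov.Sigma
    e = fit.err
    num = S[0, 1] + t * S[0, 3] + t * S[1, 2] + t**2 * S[2, 3]
    if fit.error_model == "correlated":
        num = num + e.sigma12
    d1 = S[0, 0] + 2 * t * S[0, 2] + t**2 * S[2, 2] + e.sigma1_sq
    d2 = S[1, 1] + 2 * t * S[1, 3] + t**2 * S[3, 3] + e.sigma2_sq
    rho = num / np.sqrt(d1 * d2)
    return float(rho) if rho.ndim == 0 else rho


def marginal_curve(fit: BLMMFit, times=None) -> CorrelationCurve:
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    return CorrelationCurve(times=times, rho=marginal_correlation(fit, times), flavor="marginal")


# -- conditional correlation -----------------------------------------------


def joint_moments(fit: BLMMFit, z=None, t: float = 0.0):
    """Mean and covariance of (Y1(t), Y2(t), gamma0, gamma1) for one profile.

    gamma0 = Z alpha_z + alpha0 + a0 is the subject's outcome-1 level at the
    index date and gamma1 = alpha1 + a1 its slope.  The covariance does not
    depend on the covariate profile; the mean does.
    """
    S = fit.re_cov.Sigma
    e = fit.err
    f = fit.fixed
    if z is None:
        z = np.zeros(len(f.alpha_z))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if len(z) != len(f.alpha_z):
        raise ValueError(f"profile length {len(z)} does not match model ({len(f.alpha_z)} covariates)")
    za = float(z @ f.alpha_z) if len(z) else 0.0
    zb = float(z @ f.beta_z) if len(z) else 0.0
    mean = np.array([
        za + f.alpha0 + f.alpha1 * t,
        zb + f.beta0 + f.beta1 * t,
        za + f.alpha0,
        f.alpha1,
    ])
    v11 = S[0, 0] + t**2 * S[2, 2] + 2 * t * S[0, 2] + e.sigma1_sq
    v22 = S[1, 1] + t**2 * S[3, 3] + 2 * t * S[1, 3] + e.sigma2_sq
    v12 = S[0, 1] + t * S[0, 3] + t * S[1, 2] + t**2 * S[2, 3]
    if fit.error_model == "correlated":
        v12 += e.sigma12
    v13 = S[0, 0] + t * S[0, 2]
    v14 = S[0, 2] + t * S[2, 2]
    v23 = S[0, 1] + t * S[0, 3]
    v24 = S[1, 2] + t * S[2, 3]
    v33 = S[0, 0]
    v34 = S[0, 2]
    v44 = S[2, 2]
    cov = np.array([
        [v11, v12, v13, v14],
        [v12, v22, v23, v24],
        [v13, v23, v33, v34],
        [v14, v24, v34, v44],
    ])
    return mean, cov


def conditional_correlation(fit: BLMMFit, query: ConditionalQuery, t: float) -> ConditionalEstimate:
    """Parametric-bootstrap estimate of rho(Y1(t), Y2(t) | gamma0 > c1, gamma1 > c2).

    Each replicate draws ``n_subjects`` 4-vectors from the joint normal of
    (Y1, Y2, gamma0, gamma1) — one per covariate profile when profiles are
    supplied — and computes the Pearson correlation of (Y1, Y2) among draws
    meeting both thresholds.  The estimate is the replicate mean; the 95% CI
    is the 2.5/97.5 percentile band.  Replicates with fewer than 3 qualifying
    draws are dropped and counted; if more than half drop the result is
    flagged unreliable.
    """
    if query.covariate_profiles is None and len(fit.fixed.alpha_z):
        raise ValueError("model has covariates; covariate_profiles must be supplied")
    rng = np.random.default_rng(query.seed)
    n, B = query.n_subjects, query.n_boot

    if query.covariate_profiles is None:
        mean, cov = joint_moments(fit, None, t)
        means = np.broadcast_to(mean, (n, 4))
    else:
        _, cov = joint_moments(fit, query.covariate_profiles[0], t)
        means = np.array([joint_moments(fit, z, t)[0] for z in query.covariate_profiles])

    L = np.linalg.cholesky(cov + 1e-12 * np.eye(4))
    # draws: (B, n, 4); each replicate uses every profile exactly once
    draws = means[None, :, :] + rng.standard_normal((B, n, 4)) @ L.T

    ok = (draws[:, :, 2] > query.c1) & (draws[:, :, 3] > query.c2)
    y1 = np.where(ok, draws[:, :, 0], np.nan)
    y2 = np.where(ok, draws[:, :, 1], np.nan)
    m = ok.sum(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu1 = np.nanmean(y1, axis=1)
        mu2 = np.nanmean(y2, axis=1)
        d1 = y1 - mu1[:, None]
        d2 = y2 - mu2[:, None]
        sxy = np.nansum(d1 * d2, axis=1)
        sxx = np.nansum(d1 * d1, axis=1)
        syy = np.nansum(d2 * d2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = sxy / np.sqrt(sxx * syy)

    valid = (m >= 3) & np.isfinite(r)
    n_dropped = int(B - valid.sum())
    unreliable = n_dropped > 0.5 * B
    if valid.sum() == 0:
        return ConditionalEstimate(np.nan, (np.nan, np.nan), 0, n_dropped, True)
    rv = r[valid]
    return ConditionalEstimate(
        estimate=float(np.mean(rv)),
        ci=(float(np.percentile(rv, 2.5)), float(np.percentile(rv, 97.5))),
        n_replicates=int(valid.sum()),
        n_dropped=n_dropped,
        unreliable=unreliable,
        replicates=rv,
    )


def conditional_curve(fit: BLMMFit, query: ConditionalQuery, times=None) -> CorrelationCurve:
    """Conditional correlation over a time grid, with percentile bands.

    Per-time replicate streams are spawned from ``query.seed`` so the curve
    is reproducible and the points are independent.
    """
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    master = np.random.default_rng(query.seed)
    seeds = master.integers(0, 2**31 - 1, size=len(times))
    rho = np.empty(len(times))
    lo = np.empty(len(times))
    hi = np.empty(len(times))
    neff = np.empty(len(times))
    for i, (t, s) in enumerate(zip(times, seeds)):
        q = ConditionalQuery(
            c1=query.c1, c2=query.c2, n_subjects=query.n_subjects,
            n_boot=query.n_boot, covariate_profiles=query.covariate_profiles,
            seed=int(s),
        )
        est = conditional_correlation(fit, q, float(t))
        rho[i], (lo[i], hi[i]), neff[i] = est.estimate, est.ci, est.n_replicates
    return CorrelationCurve(times=times, rho=rho, ci_lower=lo, ci_upper=hi,
                            flavor="conditional", n_eff=neff)


# -- naive pointwise Pearson ----------------------------------------------


def pointwise_pearson(
    data: LongitudinalDataset, t: float, window: float = 0.25, min_n: int = 30
) -> float | None:
    """Cross-sectional Pearson correlation near time ``t``, or None.

    For each subject the nearest observation of each outcome within
    ``|time - t| <= window`` is taken; subjects contributing both outcomes
    form the sample.  Returns None when fewer than ``min_n`` subjects
    qualify (the visit is too sparse for a trustworthy naive estimate).
    """
    pairs = _paired_values(data, t, window)
    if pairs.shape[0] < min_n or pairs.shape[0] < 2:
        return None
    x, y = pairs[:, 0], pairs[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def _paired_values(data: LongitudinalDataset, t: float, window: float) -> np.ndarray:
    rows = []
    obs = data.obs
    near = obs[np.abs(obs["time"] - t) <= window + 1e-12]
    for sid, g in near.groupby("subject_id"):
        vals = {}
        for oc in (data.outcome1, data.outcome2):
            go = g[g["outcome"] == oc]
            if len(go):
                idx = (go["time"] - t).abs().idxmin()
                vals[oc] = go.loc[idx, "value"]
        if len(vals) == 2:
            rows.append((vals[data.outcome1], vals[data.outcome2]))
    return np.array(rows, dtype=float).reshape(-1, 2)


def pointwise_pearson_curve(
    data: LongitudinalDataset, times=None, window: float = 0.25, min_n: int = 30
) -> CorrelationCurve:
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    rho = np.array([
        np.nan if (v := pointwise_pearson(data, float(t), window, min_n)) is None else v
        for t in times
    ])
    neff = np.array([_paired_values(data, float(t), window).shape[0] for t in times], dtype=float)
    return CorrelationCurve(times=times, rho=rho, flavor="pointwise-pearson", n_eff=neff)


# -- clustered empirical bootstrap ----------------------------------------


@dataclass
class BootstrapCI:
    estimate: float
    ci: tuple
    n_effective: int
    n_failed: int
    flagged: bool
    replicates: np.ndarray = field(default_factory=lambda: np.zeros(0))


def empirical_bootstrap_ci(
    data: LongitudinalDataset,
    estimator,
    B: int = 500,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile CI by resampling whole subjects with replacement.

    ``estimator`` maps a LongitudinalDataset to a scalar (typically: fit the
    BLMM and return one correlation).  Trajectories are kept intact; a
    subject drawn twice enters as two distinct subjects.  Resamples on which
    the estimator raises or returns a non-finite value are dropped and
    counted; more than 20% failures flags the result.
    """
    rng = np.random.default_rng(seed)
    subjects = np.array(data.subjects, dtype=object)
    n = len(subjects)
    values = []
    n_failed = 0
    obs_by_subject = dict(tuple(data.obs.groupby("subject_id")))
    for b in range(B):
        chosen = subjects[rng.integers(0, n, size=n)]
        frames = []
        cov_rows = []
        new_ids = []
        for k, sid in enumerate(chosen):
            g = obs_by_subject[sid].copy()
            nid = f"{sid}~{k}"
            g["subject_id"] = nid
            frames.append(g)
            cov_rows.append(data.covariates.loc[sid])
            new_ids.append(nid)
        obs = pd.concat(frames, ignore_index=True)
        cov = pd.DataFrame(cov_rows)
        cov.index = pd.Index(new_ids, name="subject_id")
        resample = LongitudinalDataset.from_frames(obs, data.outcome1, data.outcome2, covariates=cov)
        try:
            v = float(estimator(resample))
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(v):
            n_failed += 1
            continue
        values.append(v)
    values = np.array(values)
    flagged = n_failed > 0.2 * B
    if flagged:
        warnings.warn(f"empirical bootstrap: {n_failed}/{B} resamples failed")
    if len(values) == 0:
        return BootstrapCI(np.nan, (np.nan, np.nan), 0, n_failed, True)
    return BootstrapCI(
        estimate=float(np.mean(values)),
        ci=(float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))),
        n_effective=len(values),
        n_failed=n_failed,
        flagged=flagged,
        replicates=values,
    )
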