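"""Bivariate linear mixed model (BLMM): specification and ML estimation.

Two outcome-specific linear mixed models, each with a random intercept and a
random time slope, are linked through a joint zero-mean normal distribution of
the four random effects.  With the random-effect vector ordered as
(a0, b0, a1, b1) = (outcome-1 intercept, outcome-2 intercept, outcome-1 slope,
outcome-2 slope) and covariance Sigma, a subject's stacked observation vector
is marginally normal with covariance Z_i Sigma Z_i' + R_i, where R_i is
diagonal under the independent-error model and gains a cross-outcome
covariance sigma_12 for same-time observation pairs under the correlated-error
model.

Estimation maximizes the marginal likelihood.  Fixed effects are profiled out
by generalized least squares at each variance-parameter value; Sigma is kept
positive semidefinite through a log-Cholesky parameterization.  Subjects
sharing an identical design (visit grids and covariate values) are pooled into
sufficient statistics, which makes balanced simulated designs cheap to fit
regardless of the number of subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .data import LongitudinalDataset

__all__ = [
    "FixedEffects",
    "RandomEffectsCov",
    "ErrorCov",
    "BLMMFit",
    "LRTResult",
    "SubjectDesign",
    "NumericalError",
    "build_subject_design",
    "marginal_loglik",
    "fit_blmm",
    "lrt_error_correlation",
]

RE_ORDER = ("a0", "b0", "a1", "b1")

_TRIL = np.tril_indices(4)


class NumericalError(RuntimeError):
    """Raised when a marginal covariance matrix is numerically singular."""


# -- parameter containers --------------------------------------------------


@dataclass
class FixedEffects:
    """Population-level coefficients of the two linear mean trajectories.

    ``alpha_*`` belong to outcome 1, ``beta_*`` to outcome 2.  ``alpha_z`` /
    ``beta_z`` are coefficients of baseline covariates on the intercept;
    ``alpha_tz`` / ``beta_tz`` are optional covariate-by-time interaction
    coefficients (covariate effects on the slope).
    """

    alpha0: float
    alpha1: float
    beta0: float
    beta1: float
    alpha_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha_tz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_tz: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("alpha_z", "beta_z", "alpha_tz", "beta_tz"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.alpha_z.shape != self.beta_z.shape:
            raise ValueError("alpha_z and beta_z must have equal length")
        if self.alpha_tz.shape != self.beta_tz.shape:
            raise ValueError("alpha_tz and beta_tz must have equal length")


@dataclass
class RandomEffectsCov:
    """4x4 covariance of the random effects, ordered (a0, b0, a1, b1)."""

    Sigma: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (4, 4):
            raise ValueError("Sigma must be 4x4")
        if not np.allclose(S, S.T, atol=1e-10 * (1 + np.abs(S).max())):
            raise ValueError("Sigma must be symmetric")
        w = np.linalg.eigvalsh(S)
        if w.min() < -1e-8 * max(np.trace(S), 1.0):
            raise ValueError(f"Sigma is not positive semidefinite (min eigenvalue {w.min():.3g})")
        self.Sigma = 0.5 * (S + S.T)

    # named accessors ------------------------------------------------------
    @property
    def var_a0(self) -> float:  # outcome-1 intercept variance
        return float(self.Sigma[0, 0])

    @property
    def var_b0(self) -> float:  # outcome-2 intercept variance
        return float(self.Sigma[1, 1])

    @property
    def var_a1(self) -> float:  # outcome-1 slope variance
        return float(self.Sigma[2, 2])

    @property
    def var_b1(self) -> float:  # outcome-2 slope variance
        return float(self.Sigma[3, 3])

    @property
    def cov_a0b0(self) -> float:
        return float(self.Sigma[0, 1])

    @property
    def cov_a0a1(self) -> float:
        return float(self.Sigma[0, 2])

    @property
    def cov_a0b1(self) -> float:
        return float(self.Sigma[0, 3])

    @property
    def cov_a1b0(self) -> float:
        return float(self.Sigma[1, 2])

    @property
    def cov_b0b1(self) -> float:
        return float(self.Sigma[1, 3])

    @property
    def cov_a1b1(self) -> float:
        return float(self.Sigma[2, 3])


@dataclass
class ErrorCov:
    """Residual (measurement-error) covariance of the two outcomes."""

    sigma1_sq: float
    sigma2_sq: float
    sigma12: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma1_sq <= 0 or self.sigma2_sq <= 0:
            raise ValueError("residual variances must be positive")
        bound = np.sqrt(self.sigma1_sq * self.sigma2_sq)
        if abs(self.sigma12) > bound * (1 + 1e-10):
            raise ValueError("|sigma12| exceeds sqrt(sigma1_sq * sigma2_sq)")

    @property
    def rho(self) -> float:
        return float(self.sigma12 / np.sqrt(self.sigma1_sq * self.sigma2_sq))


@dataclass
class BLMMFit:
    """A fitted bivariate linear mixed model."""

    fixed: FixedEffects
    re_cov: RandomEffectsCov
    err: ErrorCov
    loglik: float
    n_subjects: int
    error_model: str
    converged: bool
    param_names: list[str] = field(default_factory=list)
    param_cov: np.ndarray | None = None
    n_iter: int = 0
    message: str = ""
    covariate_names: list[str] = field(default_factory=list)
    slope_covariate_names: list[str] = field(default_factory=list)

    def standard_errors(self) -> pd.Series | None:
        if self.param_cov is None:
            return None
        se = np.sqrt(np.clip(np.diag(self.param_cov), 0.0, None))
        return pd.Series(se, index=self.param_names)

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "error_model": self.error_model,
            "loglik": self.loglik,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
            "covariate_names": self.covariate_names,
            "slope_covariate_names": self.slope_covariate_names,
            "fixed": {
                "alpha0": self.fixed.alpha0,
                "alpha1": self.fixed.alpha1,
                "beta0": self.fixed.beta0,
                "beta1": self.fixed.beta1,
                "alpha_z": self.fixed.alpha_z.tolist(),
                "beta_z": self.fixed.beta_z.tolist(),
                "alpha_tz": self.fixed.alpha_tz.tolist(),
                "beta_tz": self.fixed.beta_tz.tolist(),
            },
            # row-major 4x4; random-effect order (a0, b0, a1, b1) =
            # (outcome-1 intercept, outcome-2 intercept, outcome-1 slope, outcome-2 slope)
            "Sigma_order": list(RE_ORDER),
            "Sigma": self.re_cov.Sigma.ravel().tolist(),
            "err": {
                "sigma1_sq": self.err.sigma1_sq,
                "sigma2_sq": self.err.sigma2_sq,
                "sigma12": self.err.sigma12,
            },
            "param_names": self.param_names,
            "param_cov": None if self.param_cov is None else np.asarray(self.param_cov).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BLMMFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        f = payload["fixed"]
        fixed = FixedEffects(
            alpha0=f["alpha0"], alpha1=f["alpha1"], beta0=f["beta0"], beta1=f["beta1"],
            alpha_z=np.array(f["alpha_z"]), beta_z=np.array(f["beta_z"]),
            alpha_tz=np.array(f["alpha_tz"]), beta_tz=np.array(f["beta_tz"]),
        )
        Sigma = np.array(payload["Sigma"], dtype=float).reshape(4, 4)
        err = ErrorCov(**payload["err"])
        pc = payload.get("param_cov")
        return cls(
            fixed=fixed,
            re_cov=RandomEffectsCov(Sigma),
            err=err,
            loglik=payload["loglik"],
            n_subjects=payload["n_subjects"],
            error_model=payload["error_model"],
            converged=payload["converged"],
            param_names=payload.get("param_names", []),
            param_cov=None if pc is None else np.array(pc),
            n_iter=payload.get("n_iter", 0),
            message=payload.get("message", ""),
            covariate_names=payload.get("covariate_names", []),
            slope_covariate_names=payload.get("slope_covariate_names", []),
        )


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


# -- design construction ---------------------------------------------------


@dataclass
class SubjectDesign:
    """Stacked per-subject design: outcome-1 rows first, then outcome-2."""

    y: np.ndarray          # response, length n1 + n2
    X: np.ndarray          # fixed-effect design
    Z: np.ndarray          # random-effect design, 4 columns (a0, b0, a1, b1)
    n1: int
    n2: int
    pairs: np.ndarray      # (k, 2) row indices of same-time cross-outcome pairs
    times1: np.ndarray
    times2: np.ndarray


def _design_matrices(t1: np.ndarray, t2: np.ndarray, z: np.ndarray, z_slope: np.ndarray):
    """Fixed and random designs for one subject given visit times and covariates."""
    n1, n2 = len(t1), len(t2)
    q, qs = len(z), len(z_slope)
    k_half = 2 + q + qs
    X = np.zeros((n1 + n2, 2 * k_half))
    # outcome-1 block: [1, t, z, t*z]
    X[:n1, 0] = 1.0
    X[:n1, 1] = t1
    if q:
        X[:n1, 2:2 + q] = z
    if qs:
        X[:n1, 2 + q:k_half] = t1[:, None] * z_slope
    # outcome-2 block
    X[n1:, k_half + 0] = 1.0
    X[n1:, k_half + 1] = t2
    if q:
        X[n1:, k_half + 2:k_half + 2 + q] = z
    if qs:
        X[n1:, k_half + 2 + q:] = t2[:, None] * z_slope

    Z = np.zeros((n1 + n2, 4))
    Z[:n1, 0] = 1.0
    Z[:n1, 2] = t1
    Z[n1:, 1] = 1.0
    Z[n1:, 3] = t2

    # same-time cross-outcome pairs (for the correlated-error residual pattern)
    pairs = []
    for j, tv in enumerate(t1):
        hits = np.nonzero(np.abs(t2 - tv) < 1e-8)[0]
        for h in hits:
            pairs.append((j, n1 + h))
    return X, Z, np.array(pairs, dtype=int).reshape(-1, 2)


def build_subject_design(
    data: LongitudinalDataset,
    subject,
    covariate_names: list[str] | None = None,
    slope_covariate_names: list[str] | None = None,
) -> SubjectDesign:
    """Stack a single subject's two outcome equations into one design.

    The response places outcome-1 observations first.  The random-effect
    design has columns (a0, b0, a1, b1); outcome-1 rows are zero in the b
    columns and vice versa.  ``pairs`` marks rows observed at the same time on
    both outcomes, which is where the correlated-error model places sigma_12.
    """
    covariate_names = list(covariate_names or [])
    slope_covariate_names = list(slope_covariate_names or [])
    o1 = data.subject_obs(subject, data.outcome1)
    o2 = data.subject_obs(subject, data.outcome2)
    if len(o1) + len(o2) == 0:
        raise KeyError(f"subject {subject!r} has no observations")
    t1 = o1["time"].to_numpy(dtype=float)
    t2 = o2["time"].to_numpy(dtype=float)
    z = data.covariates.loc[subject, covariate_names].to_numpy(dtype=float) if covariate_names else np.zeros(0)
    zs = data.covariates.loc[subject, slope_covariate_names].to_numpy(dtype=float) if slope_covariate_names else np.zeros(0)
    X, Z, pairs = _design_matrices(t1, t2, z, zs)
    y = np.concatenate([o1["value"].to_numpy(dtype=float), o2["value"].to_numpy(dtype=float)])
    return SubjectDesign(y=y, X=X, Z=Z, n1=len(t1), n2=len(t2), pairs=pairs, times1=t1, times2=t2)


class _DesignGroups:
    """Subjects pooled by identical (visit grids, covariates) design.

    Within a group all subjects share X, Z and the residual pattern, so the
    likelihood needs only the group mean response and scatter matrix.
    """

    def __init__(self, data: LongitudinalDataset, covariate_names, slope_covariate_names):
        self.covariate_names = list(covariate_names or [])
        self.slope_covariate_names = list(slope_covariate_names or [])
        obs = data.obs
        buckets: dict = {}
        cov = data.covariates
        grouped = {(sid, oc): g for (sid, oc), g in obs.groupby(["subject_id", "outcome"])}
        for sid in obs["subject_id"].unique():
            g1 = grouped.get((sid, data.outcome1))
            g2 = grouped.get((sid, data.outcome2))
            t1 = g1["time"].to_numpy(dtype=float) if g1 is not None else np.zeros(0)
            t2 = g2["time"].to_numpy(dtype=float) if g2 is not None else np.zeros(0)
            y1 = g1["value"].to_numpy(dtype=float) if g1 is not None else np.zeros(0)
            y2 = g2["value"].to_numpy(dtype=float) if g2 is not None else np.zeros(0)
            z = cov.loc[sid, self.covariate_names].to_numpy(dtype=float) if self.covariate_names else np.zeros(0)
            zs = cov.loc[sid, self.slope_covariate_names].to_numpy(dtype=float) if self.slope_covariate_names else np.zeros(0)
            key = (tuple(np.round(t1, 9)), tuple(np.round(t2, 9)),
                   tuple(np.round(z, 12)), tuple(np.round(zs, 12)))
            buckets.setdefault(key, {"t1": t1, "t2": t2, "z": z, "zs": zs, "ys": [], "sids": []})
            buckets[key]["ys"].append(np.concatenate([y1, y2]))
            buckets[key]["sids"].append(sid)

        self.groups = []
        self.n_subjects = 0
        self.n_fixed = None
        for b in buckets.values():
            X, Z, pairs = _design_matrices(b["t1"], b["t2"], b["z"], b["zs"])
            Y = np.array(b["ys"])
            m = Y.shape[0]
            ybar = Y.mean(axis=0)
            dev = Y - ybar
            S = dev.T @ dev
            self.groups.append({
                "X": X, "Z": Z, "pairs": pairs, "m": m, "ybar": ybar, "S": S,
                "n1": len(b["t1"]), "n2": len(b["t2"]), "p": X.shape[0],
                "sids": b["sids"],
            })
            self.n_subjects += m
            self.n_fixed = X.shape[1]

    def residual_cov(self, g, s1sq, s2sq, s12):
        p, n1 = g["p"], g["n1"]
        R = np.zeros((p, p))
        R[np.arange(n1), np.arange(n1)] = s1sq
        R[np.arange(n1, p), np.arange(n1, p)] = s2sq
        if s12 != 0.0 and len(g["pairs"]):
            i, j = g["pairs"][:, 0], g["pairs"][:, 1]
            R[i, j] = s12
            R[j, i] = s12
        return R


# -- likelihood ------------------------------------------------------------


def _group_loglik_terms(groups: _DesignGroups, Sigma, s1sq, s2sq, s12):
    """Per-group Cholesky pieces; raises NumericalError on a singular V."""
    out = []
    for g in groups.groups:
        V = g["Z"] @ Sigma @ g["Z"].T + groups.residual_cov(g, s1sq, s2sq, s12)
        try:
            cho = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular marginal covariance for subjects {g['sids'][:3]}..."
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vi = cho_solve(cho, np.eye(g["p"]))
        out.append((g, Vi, logdet))
    return out


def _loglik_given_all(groups: _DesignGroups, beta, Sigma, s1sq, s2sq, s12):
    terms = _group_loglik_terms(groups, Sigma, s1sq, s2sq, s12)
    ll = 0.0
    for g, Vi, logdet in terms:
        r = g["ybar"] - g["X"] @ beta
        quad = float(np.einsum("ij,ij->", Vi, g["S"])) + g["m"] * float(r @ Vi @ r)
        ll += -0.5 * (g["m"] * (g["p"] * np.log(2 * np.pi) + logdet) + quad)
    return ll


def _profile_beta_and_loglik(groups: _DesignGroups, Sigma, s1sq, s2sq, s12, reml=False):
    terms = _group_loglik_terms(groups, Sigma, s1sq, s2sq, s12)
    k = groups.n_fixed
    A = np.zeros((k, k))
    b = np.zeros(k)
    for g, Vi, _ in terms:
        ViX = Vi @ g["X"]
        A += g["m"] * (g["X"].T @ ViX)
        b += g["m"] * (ViX.T @ g["ybar"])
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("rank-deficient fixed-effect design") from exc
    ll = 0.0
    for g, Vi, logdet in terms:
        r = g["ybar"] - g["X"] @ beta
        quad = float(np.einsum("ij,ij->", Vi, g["S"])) + g["m"] * float(r @ Vi @ r)
        ll += -0.5 * (g["m"] * (g["p"] * np.log(2 * np.pi) + logdet) + quad)
    if reml:
        sign, ld = np.linalg.slogdet(A)
        ll += -0.5 * ld + 0.5 * k * np.log(2 * np.pi)
    return beta, ll


def marginal_loglik(
    fixed: FixedEffects,
    re_cov: RandomEffectsCov,
    err: ErrorCov,
    data: LongitudinalDataset,
    covariate_names: list[str] | None = None,
    slope_covariate_names: list[str] | None = None,
) -> float:
    """Marginal log-likelihood: sum over subjects of the MVN log-density with
    mean X_i theta and covariance Z_i Sigma Z_i' + R_i."""
    groups = _DesignGroups(data, covariate_names, slope_covariate_names)
    beta = _pack_beta(fixed)
    if len(beta) != groups.n_fixed:
        raise ValueError(
            f"fixed-effect vector length {len(beta)} does not match design ({groups.n_fixed} columns)"
        )
    return _loglik_given_all(groups, beta, re_cov.Sigma, err.sigma1_sq, err.sigma2_sq, err.sigma12)


# -- parameter packing -----------------------------------------------------


def _pack_beta(fixed: FixedEffects) -> np.ndarray:
    return np.concatenate([
        [fixed.alpha0, fixed.alpha1], fixed.alpha_z, fixed.alpha_tz,
        [fixed.beta0, fixed.beta1], fixed.beta_z, fixed.beta_tz,
    ])


def _unpack_beta(beta: np.ndarray, q: int, qs: int) -> FixedEffects:
    k_half = 2 + q + qs
    a, b = beta[:k_half], beta[k_half:]
    return FixedEffects(
        alpha0=float(a[0]), alpha1=float(a[1]),
        alpha_z=a[2:2 + q], alpha_tz=a[2 + q:],
        beta0=float(b[0]), beta1=float(b[1]),
        beta_z=b[2:2 + q], beta_tz=b[2 + q:],
    )


def _theta_to_cov(theta: np.ndarray, error_model: str):
    """Variance parameters from the unconstrained vector.

    First 10 entries: log-Cholesky of Sigma (diagonal on the log scale), then
    log residual variances, then (correlated model only) atanh of the residual
    correlation.
    """
    L = np.zeros((4, 4))
    vals = theta[:10].copy()
    L[_TRIL] = vals
    diag = np.arange(4)
    L[diag, diag] = np.exp(np.clip(np.diag(L), -20, 20))
    Sigma = L @ L.T
    s1sq = float(np.exp(np.clip(theta[10], -20, 20)))
    s2sq = float(np.exp(np.clip(theta[11], -20, 20)))
    if error_model == "correlated":
        rho = float(np.tanh(theta[12]))
        s12 = rho * np.sqrt(s1sq * s2sq)
    else:
        s12 = 0.0
    return Sigma, s1sq, s2sq, s12


def _cov_to_theta(Sigma: np.ndarray, s1sq: float, s2sq: float, s12: float, error_model: str) -> np.ndarray:
    w, U = np.linalg.eigh(Sigma)
    w = np.clip(w, 1e-6 * max(np.trace(Sigma), 1.0) / 4, None)
    Sigma_pd = U @ np.diag(w) @ U.T
    L = np.linalg.cholesky(Sigma_pd)
    vals = L[_TRIL].copy()
    # diagonal entries stored as logs
    pos = np.cumsum([1, 2, 3, 4]) - 1  # positions of diagonal in tril order
    vals[pos] = np.log(vals[pos])
    theta = [*vals, np.log(s1sq), np.log(s2sq)]
    if error_model == "correlated":
        rho = np.clip(s12 / np.sqrt(s1sq * s2sq), -0.999, 0.999)
        theta.append(np.arctanh(rho))
    return np.array(theta, dtype=float)


# -- initialization --------------------------------------------------------


def _moment_init(data: LongitudinalDataset, outcome1: str, outcome2: str):
    """Moment-based starting values from per-subject OLS lines.

    Each subject-outcome trajectory with at least two distinct visits is fit
    by least squares; the empirical covariance of the (intercept, slope)
    estimates seeds Sigma, and pooled squared residuals seed the error
    variances.  Crude but in the right basin for a local optimizer.
    """
    coefs = {oc: {} for oc in (outcome1, outcome2)}
    resid_ss = {outcome1: [0.0, 0], outcome2: [0.0, 0]}
    for (sid, oc), g in data.obs.groupby(["subject_id", "outcome"]):
        t = g["time"].to_numpy(dtype=float)
        y = g["value"].to_numpy(dtype=float)
        if len(t) >= 2 and np.ptp(t) > 0:
            A = np.column_stack([np.ones_like(t), t])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            coefs[oc][sid] = coef
            if len(t) > 2:
                r = y - A @ coef
                resid_ss[oc][0] += float(r @ r)
                resid_ss[oc][1] += len(t) - 2
        elif len(t) >= 1:
            coefs[oc][sid] = np.array([float(np.mean(y)), np.nan])

    frame = {}
    for oc, tag in ((outcome1, "1"), (outcome2, "2")):
        d = pd.DataFrame.from_dict(coefs[oc], orient="index", columns=[f"i{tag}", f"s{tag}"])
        frame[tag] = d
    df = frame["1"].join(frame["2"], how="outer")[["i1", "i2", "s1", "s2"]]  # order (a0, b0, a1, b1)
    C = df.cov().to_numpy()
    C = np.where(np.isfinite(C), C, 0.0)
    # shrink toward the diagonal and floor eigenvalues so the start is PD
    C = 0.9 * C + 0.1 * np.diag(np.clip(np.diag(C), 1e-2, None))
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    w = np.clip(w, 1e-3 * max(np.trace(C), 1.0) / 4, None)
    Sigma0 = U @ np.diag(w) @ U.T

    s_init = []
    for oc in (outcome1, outcome2):
        ss, dof = resid_ss[oc]
        s_init.append(ss / dof if dof > 0 else 1.0)
    s1sq = max(s_init[0], 1e-2)
    s2sq = max(s_init[1], 1e-2)
    return Sigma0, s1sq, s2sq


# -- fitting ---------------------------------------------------------------


def _param_names(covariate_names, slope_covariate_names, error_model):
    names = ["alpha0", "alpha1"]
    names += [f"alpha_{c}" for c in covariate_names]
    names += [f"alpha_t_{c}" for c in slope_covariate_names]
    names += ["beta0", "beta1"]
    names += [f"beta_{c}" for c in covariate_names]
    names += [f"beta_t_{c}" for c in slope_covariate_names]
    tril_names = []
    labels = RE_ORDER
    canonical = {"cov_b0a1": "cov_a1b0"}  # conventional index order
    for i in range(4):
        for j in range(i + 1):
            name = f"var_{labels[i]}" if i == j else f"cov_{labels[j]}{labels[i]}"
            tril_names.append(canonical.get(name, name))
    names += tril_names + ["sigma1_sq", "sigma2_sq"]
    if error_model == "correlated":
        names.append("sigma12")
    return names


def _natural_vector(beta, Sigma, s1sq, s2sq, s12, error_model):
    v = [*beta, *Sigma[_TRIL], s1sq, s2sq]
    if error_model == "correlated":
        v.append(s12)
    return np.array(v, dtype=float)


def _nll_natural(phi, groups, error_model, k):
    beta = phi[:k]
    Sigma = np.zeros((4, 4))
    Sigma[_TRIL] = phi[k:k + 10]
    Sigma = Sigma + np.tril(Sigma, -1).T
    s1sq, s2sq = phi[k + 10], phi[k + 11]
    s12 = phi[k + 12] if error_model == "correlated" else 0.0
    if s1sq <= 0 or s2sq <= 0:
        return np.inf
    try:
        return -_loglik_given_all(groups, beta, Sigma, s1sq, s2sq, s12)
    except NumericalError:
        return np.inf


def _observed_information_cov(phi_hat, groups, error_model, k):
    """Parameter covariance from a central-difference observed information."""
    n = len(phi_hat)
    h = 1e-4 * (1.0 + np.abs(phi_hat))
    H = np.zeros((n, n))
    f0 = _nll_natural(phi_hat, groups, error_model, k)
    if not np.isfinite(f0):
        return None
    evals = {}

    def f(idx_steps):
        key = tuple(idx_steps)
        if key not in evals:
            phi = phi_hat.copy()
            for i, s in idx_steps:
                phi[i] += s * h[i]
            evals[key] = _nll_natural(phi, groups, error_model, k)
        return evals[key]

    for i in range(n):
        H[i, i] = (f(((i, 1),)) - 2 * f0 + f(((i, -1),))) / h[i] ** 2
    for i in range(n):
        for j in range(i):
            H[i, j] = H[j, i] = (
                f(((i, 1), (j, 1))) - f(((i, 1), (j, -1))) - f(((i, -1), (j, 1))) + f(((i, -1), (j, -1)))
            ) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) < -1e-8):
        return None
    return 0.5 * (cov + cov.T)


def fit_blmm(
    data: LongitudinalDataset,
    covariate_names: list[str] | None = None,
    error_model: str = "independent",
    slope_covariate_names: list[str] | None = None,
    init: BLMMFit | tuple | None = None,
    reml: bool = False,
    compute_se: bool = True,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> BLMMFit:
    """Maximum-likelihood fit of the bivariate linear mixed model.

    Parameters
    ----------
    data
        Validated long-format dataset with two outcomes.
    covariate_names
        Baseline covariates entering both outcomes' intercepts.  ``None``
        means all covariates present in the dataset; pass ``[]`` for none.
    error_model
        ``"independent"`` (diagonal residual covariance) or ``"correlated"``
        (same-time cross-outcome residual covariance sigma_12 estimated).
    slope_covariate_names
        Covariates additionally interacted with time (effects on the slope).
    init
        Optional warm start: a previous :class:`BLMMFit` or a tuple
        ``(Sigma, sigma1_sq, sigma2_sq, sigma12)``.
    reml
        Use the REML criterion instead of plain ML.  ML is the default so
        that likelihood-ratio tests between nested error models are valid.
    compute_se
        Compute the parameter covariance from the observed information
        (numerical Hessian).  Disable for speed in large simulation sweeps.

    Notes
    -----
    Fixed effects are profiled out by GLS, so the optimizer only searches the
    variance parameters (log-Cholesky of Sigma, log error variances, and
    atanh residual correlation under the correlated model).  Non-convergence
    is reported through ``converged``/``message``, not an exception.
    """
    if error_model not in ("independent", "correlated"):
        raise ValueError(f"unknown error_model {error_model!r}")
    if covariate_names is None:
        covariate_names = list(data.covariate_names)
    slope_covariate_names = list(slope_covariate_names or [])
    if data.n_subjects < 2:
        raise ValueError("need at least 2 subjects to fit the BLMM")

    groups = _DesignGroups(data, covariate_names, slope_covariate_names)

    if init is None:
        Sigma0, s1sq0, s2sq0 = _moment_init(data, data.outcome1, data.outcome2)
        s120 = 0.0
    elif isinstance(init, BLMMFit):
        Sigma0, s1sq0, s2sq0, s120 = init.re_cov.Sigma, init.err.sigma1_sq, init.err.sigma2_sq, init.err.sigma12
    else:
        Sigma0, s1sq0, s2sq0, s120 = init
    theta0 = _cov_to_theta(np.asarray(Sigma0, dtype=float), s1sq0, s2sq0, s120, error_model)

    def objective(theta):
        Sigma, s1sq, s2sq, s12 = _theta_to_cov(theta, error_model)
        try:
            _, ll = _profile_beta_and_loglik(groups, Sigma, s1sq, s2sq, s12, reml=reml)
        except NumericalError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12, "maxfun": 50000},
    )

    Sigma, s1sq, s2sq, s12 = _theta_to_cov(res.x, error_model)
    beta, ll = _profile_beta_and_loglik(groups, Sigma, s1sq, s2sq, s12, reml=False)
    q, qs = len(covariate_names), len(slope_covariate_names)
    fixed = _unpack_beta(beta, q, qs)
    re_cov = RandomEffectsCov(Sigma)
    err = ErrorCov(sigma1_sq=s1sq, sigma2_sq=s2sq, sigma12=s12)
    names = _param_names(covariate_names, slope_covariate_names, error_model)

    param_cov = None
    if compute_se:
        phi_hat = _natural_vector(beta, Sigma, s1sq, s2sq, s12, error_model)
        param_cov = _observed_information_cov(phi_hat, groups, error_model, len(beta))
        if param_cov is None:
            warnings.warn("observed information is not invertible; standard errors unavailable")

    return BLMMFit(
        fixed=fixed,
        re_cov=re_cov,
        err=err,
        loglik=float(ll),
        n_subjects=groups.n_subjects,
        error_model=error_model,
        converged=bool(res.success),
        param_names=names,
        param_cov=param_cov,
        n_iter=int(res.nit),
        message=str(res.message),
        covariate_names=list(covariate_names),
        slope_covariate_names=slope_covariate_names,
    )


# -- likelihood ratio test -------------------------------------------------


def lrt_error_correlation(fit_indep: BLMMFit, fit_corr: BLMMFit) -> LRTResult:
    """Likelihood ratio test of correlated vs independent residuals.

    The models are nested (sigma_12 = 0 versus free), so the statistic
    2 * (loglik_corr - loglik_indep), clipped at zero, is referred to a
    chi-square distribution with 1 degree of freedom.
    """
    if fit_indep.error_model != "independent" or fit_corr.error_model != "correlated":
        raise ValueError("expected (independent, correlated) fits, in that order")
    if fit_indep.n_subjects != fit_corr.n_subjects:
        raise ValueError("fits are not on the same data")
    raw = 2.0 * (fit_corr.loglik - fit_indep.loglik)
    if raw < -1e-6:
        warnings.warn(
            f"correlated-error fit has lower likelihood than the nested model (2*diff={raw:.3g}); "
            "one of the fits likely failed to converge"
        )
    stat = max(raw, 0.0)
    return LRTResult(statistic=stat, df=1, pvalue=float(chi2.sf(stat, 1)))
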