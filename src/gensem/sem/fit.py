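"""ML covariance-structure estimation with robust corrections.

Estimation minimizes the normal-theory discrepancy F_ML by Fisher
scoring (expected-information Newton steps with Armijo halving), with an
L-BFGS fallback if scoring stalls.  The test statistic is
T = (n - 1) F_ML at the optimum.  Naive standard errors come from the
inverse expected information; robust (sandwich) standard errors and the
mean-scaled test statistic use the empirical fourth-moment matrix of the
observations (Satorra-Bentler-type correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import SemModel, fml
from .spec import SemModelSpec, parse_model_spec

__all__ = [
    "SemFit",
    "fit_ml",
    "robust_corrections",
    "fit_indices",
    "classify_fit",
    "srmr",
]

_PHANTOM = "~"


# --------------------------------------------------------------------------
# vech machinery
# --------------------------------------------------------------------------

def _vech_pairs(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1)]


def _duplication(p: int) -> np.ndarray:
    pairs = _vech_pairs(p)
    idx = {pair: k for k, pair in enumerate(pairs)}
    D = np.zeros((p * p, len(pairs)))
    for a in range(p):
        for b in range(p):
            D[a * p + b, idx[(max(a, b), min(a, b))]] = 1.0
    return D


def _vech(M: np.ndarray) -> np.ndarray:
    p = M.shape[0]
    return np.array([M[i, j] for i, j in _vech_pairs(p)])


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

def _safe_fml(model: SemModel, S: np.ndarray, theta: np.ndarray) -> float:
    try:
        return fml(S, model.implied_covariance(theta))
    except np.linalg.LinAlgError:
        return np.inf


def _gradient_info(model: SemModel, S: np.ndarray, theta: np.ndarray):
    """Gradient of F_ML and the expected-information matrix H (H_ij =
    tr(Sigma^-1 dSigma_i Sigma^-1 dSigma_j))."""
    Sig = model.implied_covariance(theta)
    Sinv = np.linalg.inv(Sig)
    dS = model.dsigma(theta)
    R = Sinv @ (Sig - S) @ Sinv
    g = np.einsum("ij,aji->a", R, dS)
    SdS = np.einsum("ij,ajk->aik", Sinv, dS)
    H = np.einsum("aij,bji->ab", SdS, SdS)
    return g, H, Sig, Sinv, dS


def _optimize(model: SemModel, S: np.ndarray, theta0: np.ndarray, gtol: float, maxiter: int):
    theta = theta0.copy()
    F = _safe_fml(model, S, theta)
    if not np.isfinite(F):
        # jitter start toward larger residual variances until admissible
        for p_idx, p in enumerate(model.free_params):
            if p.log_scale:
                theta[p_idx] += 1.0
        F = _safe_fml(model, S, theta)
        if not np.isfinite(F):
            raise np.linalg.LinAlgError("no admissible start value found")
    grad_norm = np.inf
    it = 0
    for it in range(1, maxiter + 1):
        g, H, *_ = _gradient_info(model, S, theta)
        grad_norm = float(np.max(np.abs(g)))
        if grad_norm < gtol:
            return theta, F, grad_norm, it, True
        ridge = 1e-8 * max(1.0, float(np.trace(H)) / max(H.shape[0], 1))
        try:
            step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), -g)
        except np.linalg.LinAlgError:
            step = -g
        slope = float(g @ step)
        if slope >= 0:  # not a descent direction; fall back to gradient
            step, slope = -g, float(-g @ g)
        alpha, improved = 1.0, False
        for _ in range(40):
            F_new = _safe_fml(model, S, theta + alpha * step)
            if np.isfinite(F_new) and F_new <= F + 1e-4 * alpha * slope:
                theta = theta + alpha * step
                F = F_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
    # scoring stalled: polish with quasi-Newton on the same objective
    def fun(t):
        f = _safe_fml(model, S, t)
        if not np.isfinite(f):
            return 1e10, np.zeros_like(t)
        g, *_ = _gradient_info(model, S, t)
        return f, g

    res = minimize(fun, theta, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol / 10})
    if np.isfinite(res.fun) and res.fun <= F:
        theta, F = res.x, float(res.fun)
    g, *_ = _gradient_info(model, S, theta)
    grad_norm = float(np.max(np.abs(g)))
    return theta, F, grad_norm, it, grad_norm < gtol


# --------------------------------------------------------------------------
# fit indices
# --------------------------------------------------------------------------

def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Root mean squared standardized residual over unique (i, j) pairs."""
    p = S.shape[0]
    num, cnt = 0.0, 0
    for i in range(p):
        for j in range(i + 1):
            num += ((S[i, j] - Sigma[i, j]) / math.sqrt(S[i, i] * S[j, j])) ** 2
            cnt += 1
    return math.sqrt(num / cnt)


def fit_indices(T: float, df: int, baseline_T: float, baseline_df: int,
                n: int, S: np.ndarray | None = None,
                Sigma: np.ndarray | None = None) -> dict[str, float]:
    """CFI, RMSEA and (when S, Sigma given) SRMR.

    RMSEA is undefined at df = 0 and reported as NaN.
    """
    d = max(T - df, 0.0)
    denom = max(baseline_T - baseline_df, d, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - d / denom
    rmsea = float("nan") if df == 0 else math.sqrt(d / (df * (n - 1)))
    out = {"cfi": float(np.clip(cfi, 0.0, 1.0)), "rmsea": rmsea}
    if S is not None and Sigma is not None:
        out["srmr"] = srmr(S, Sigma)
    return out


def classify_fit(indices: dict[str, float]) -> dict[str, str]:
    """Label CFI/RMSEA/SRMR as good / acceptable / poor by the
    conventional cutoffs (CFI 0.95/0.90, RMSEA 0.06/0.10, SRMR 0.08/0.10)."""
    labels = {}
    if "cfi" in indices:
        c = indices["cfi"]
        labels["cfi"] = "good" if c >= 0.95 else "acceptable" if c >= 0.90 else "poor"
    if "rmsea" in indices:
        r = indices["rmsea"]
        if math.isnan(r):
            labels["rmsea"] = "undefined"
        else:
            labels["rmsea"] = "good" if r <= 0.06 else "acceptable" if r <= 0.10 else "poor"
    if "srmr" in indices:
        s = indices["srmr"]
        labels["srmr"] = "good" if s <= 0.08 else "acceptable" if s < 0.10 else "poor"
    return labels


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def _standardized_all(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Standardized value of every parameter (free and fixed), in
    ``model.params`` order."""
    Lam, B, Gam, Th, Ps, Ph = model.matrices(theta)
    A = np.linalg.inv(np.eye(model.m) - B)
    G = A @ (Gam @ Ph @ Gam.T + Ps) @ A.T
    sd_l = np.sqrt(np.clip(np.diag(G), 1e-300, None))
    sd_y = np.sqrt(np.clip(np.diag(Lam @ G @ Lam.T + Th), 1e-300, None))
    sd_x = np.sqrt(np.clip(np.diag(Ph), 1e-300, None)) if model.q else np.zeros(0)
    vals = model.value_dict(theta)
    out = np.empty(len(model.params))
    for k, p in enumerate(model.params):
        v = vals[p.label]
        if p.matrix == "lam":
            out[k] = v * sd_l[p.j] / sd_y[p.i]
        elif p.matrix == "beta":
            out[k] = v * sd_l[p.j] / sd_l[p.i]
        elif p.matrix == "gam":
            out[k] = v * sd_x[p.j] / sd_l[p.i]
        elif p.matrix == "theta":
            out[k] = v / (sd_y[p.i] * sd_y[p.j])
        elif p.matrix == "psi":
            out[k] = v / (sd_l[p.i] * sd_l[p.j])
        else:  # phi
            out[k] = v / (sd_x[p.i] * sd_x[p.j])
    return out


def _std_jacobian(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Numerical Jacobian of the standardized vector wrt transformed theta."""
    t = theta.size
    base_h = 1e-6
    J = np.zeros((len(model.params), t))
    for k in range(t):
        h = base_h * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (_standardized_all(model, tp) - _standardized_all(model, tm)) / (2 * h)
    return J


# --------------------------------------------------------------------------
# the fit object
# --------------------------------------------------------------------------

@dataclass
class SemFit:
    """Everything estimated for one model on one sample."""

    model: SemModel
    S: np.ndarray
    n: int
    theta: np.ndarray  # transformed scale
    params: pd.DataFrame
    F_min: float
    T: float
    df: int
    baseline_T: float
    baseline_df: int
    converged: bool
    grad_norm: float
    n_iter: int
    admissible: bool
    Sigma_hat: np.ndarray
    rsquare: pd.Series
    scaling_c: float = float("nan")
    T_scaled: float = float("nan")
    baseline_T_scaled: float = float("nan")
    robust: bool = False

    @property
    def spec(self) -> SemModelSpec:
        return self.model.spec

    @property
    def indices(self) -> dict[str, float]:
        """Fit indices from the unscaled statistic."""
        return fit_indices(self.T, self.df, self.baseline_T, self.baseline_df,
                           self.n, self.S, self.Sigma_hat)

    @property
    def indices_scaled(self) -> dict[str, float]:
        """Fit indices recomputed from the mean-scaled statistic (SRMR is
        unaffected by scaling)."""
        if not self.robust or not np.isfinite(self.T_scaled):
            return self.indices
        return fit_indices(self.T_scaled, self.df, self.baseline_T_scaled,
                           self.baseline_df, self.n, self.S, self.Sigma_hat)

    @property
    def fit_labels(self) -> dict[str, str]:
        return classify_fit(self.indices)

    def param_values(self) -> dict[str, float]:
        return self.model.value_dict(self.theta)

    def standardized(self) -> pd.Series:
        return self.params.set_index("label")["std_estimate"]

    def to_table(self) -> str:
        cols = ["label", "class", "free", "estimate", "se", "robust_se",
                "std_estimate", "std_se", "std_robust_se"]
        lines = ["\t".join(cols)]
        for _, r in self.params.iterrows():
            lines.append("\t".join([
                str(r["label"]), str(r["class"]), str(int(r["free"])),
                *(f"{r[c]:.6g}" if np.isfinite(r[c]) else "NA"
                  for c in cols[3:]),
            ]))
        idx = self.indices
        idx_s = self.indices_scaled
        lines.append("")
        lines.append("\t".join(["n", "T", "df", "T_scaled", "CFI", "RMSEA", "SRMR",
                                "CFI_scaled", "RMSEA_scaled", "converged"]))
        lines.append("\t".join([
            str(self.n), f"{self.T:.6g}", str(self.df),
            f"{self.T_scaled:.6g}" if np.isfinite(self.T_scaled) else "NA",
            f"{idx['cfi']:.4f}", f"{idx['rmsea']:.4f}" if np.isfinite(idx["rmsea"]) else "NA",
            f"{idx['srmr']:.4f}",
            f"{idx_s['cfi']:.4f}", f"{idx_s['rmsea']:.4f}" if np.isfinite(idx_s["rmsea"]) else "NA",
            str(int(self.converged)),
        ]))
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _sample_cov(data: pd.DataFrame, obs: list[str]) -> tuple[np.ndarray, int]:
    missing = [v for v in obs if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks modeled variables: {missing}")
    Z = data[obs].to_numpy(dtype=float)
    Z = Z[~np.isnan(Z).any(axis=1)]  # listwise deletion
    n = Z.shape[0]
    if n <= len(obs):
        raise ValueError(f"n = {n} too small for {len(obs)} modeled variables")
    return np.cov(Z, rowvar=False, ddof=1), n


def fit_ml(
    data: pd.DataFrame | None = None,
    spec: SemModelSpec | str | None = None,
    *,
    sample_cov: np.ndarray | None = None,
    n: int | None = None,
    robust: bool | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    ridge: float = 0.0,
    stat_multiplier: str = "n-1",
) -> SemFit:
    """Fit a SEM by maximum likelihood.

    Provide either ``data`` (raw observations, DataFrame with the modeled
    variables as columns) or ``sample_cov`` + ``n``.  Robust corrections
    require raw data and default to on when data is available.
    ``stat_multiplier`` selects the T = c * F convention, ``"n-1"``
    (default) or ``"n"``.
    """
    if isinstance(spec, str):
        spec = parse_model_spec(spec)
    if spec is None:
        raise ValueError("a model spec is required")
    model = SemModel(spec)
    if data is not None:
        S, n = _sample_cov(data, model.observed_vars)
    else:
        if sample_cov is None or n is None:
            raise ValueError("need data, or sample_cov together with n")
        S = np.asarray(sample_cov, dtype=float)
        if S.shape != (model.pstar, model.pstar):
            raise ValueError(f"sample_cov must be {model.pstar}x{model.pstar}")
    if ridge > 0.0:
        S = S + ridge * np.eye(S.shape[0])
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "sample covariance not positive definite; consider the ridge option"
        ) from None
    if robust is None:
        robust = data is not None
    if robust and data is None:
        raise ValueError("robust corrections require raw data")

    theta0 = model.start_values(S)
    theta, F, grad_norm, n_iter, converged = _optimize(model, S, theta0, gtol, maxiter)
    if not converged:
        warnings.warn(
            f"SEM did not converge (max |grad| = {grad_norm:.3g}); "
            "estimates returned with converged=False",
            RuntimeWarning,
        )
    mult = (n - 1) if stat_multiplier == "n-1" else n
    T = mult * F
    pstar = model.pstar
    n_moments = pstar * (pstar + 1) // 2
    df = n_moments - model.n_free
    if df < 0:
        raise ValueError(f"model has more free parameters ({model.n_free}) than moments ({n_moments})")

    # baseline (independence) model: closed form
    baseline_F = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    baseline_T = mult * baseline_F
    baseline_df = n_moments - pstar

    # naive covariance of estimates
    g, H, Sig, Sinv, dS = _gradient_info(model, S, theta)
    info = H / 2.0
    try:
        acov_t = np.linalg.inv(info) / mult
    except np.linalg.LinAlgError:
        warnings.warn("information matrix singular; SEs from pseudo-inverse", RuntimeWarning)
        acov_t = np.linalg.pinv(info) / mult
    raw = model.raw_values(theta)
    jac_nat = np.array([raw[k] if p.log_scale else 1.0 for k, p in enumerate(model.free_params)])
    se_nat = np.sqrt(np.clip(np.diag(acov_t), 0.0, None)) * np.abs(jac_nat)

    # admissibility: free variances collapsing to the boundary
    scale = float(np.mean(np.diag(S)))
    admissible = all(
        raw[k] > 1e-8 * scale
        for k, p in enumerate(model.free_params)
        if p.log_scale and p.matrix in ("theta", "psi")
    )

    # standardized solution + delta-method SEs
    std_all = _standardized_all(model, theta)
    J_std = _std_jacobian(model, theta)
    std_se = np.sqrt(np.clip(np.diag(J_std @ acov_t @ J_std.T), 0.0, None))

    rows = []
    vals = model.value_dict(theta)
    free_ix = {p.label: k for k, p in enumerate(model.free_params)}
    for k, p in enumerate(model.params):
        fk = free_ix.get(p.label)
        rows.append({
            "label": p.label.replace(_PHANTOM, ""),
            "class": p.pclass,
            "matrix": p.matrix,
            "free": p.free,
            "estimate": vals[p.label],
            "se": se_nat[fk] if fk is not None else 0.0,
            "robust_se": np.nan,
            "std_estimate": std_all[k],
            "std_se": std_se[k],
            "std_robust_se": np.nan,
        })
    table = pd.DataFrame(rows)

    # R^2 for endogenous variables
    Lam, B, Gam, Th, Ps, Ph = model.matrices(theta)
    A = np.linalg.inv(np.eye(model.m) - model.matrices(theta)[1])
    G = A @ (Gam @ Ph @ Gam.T + Ps) @ A.T
    Syy = Lam @ G @ Lam.T + Th
    r2 = {}
    for i, name in enumerate(model.latents):
        if model.spec._is_endogenous(name):
            disp = name.lstrip(_PHANTOM)
            if G[i, i] > 0:
                r2[disp] = 1.0 - Ps[i, i] / G[i, i]
    for i, v in enumerate(model.y_vars):
        if v not in r2 and v not in model.spec.observed_endogenous:
            if Syy[i, i] > 0 and Th[i, i] >= 0:
                r2[v] = 1.0 - Th[i, i] / Syy[i, i]
    rsquare = pd.Series(r2, name="rsquare")

    fit = SemFit(
        model=model, S=S, n=n, theta=theta, params=table, F_min=F, T=T, df=df,
        baseline_T=baseline_T, baseline_df=baseline_df, converged=converged,
        grad_norm=grad_norm, n_iter=n_iter, admissible=admissible,
        Sigma_hat=model.implied_covariance(theta), rsquare=rsquare,
    )
    if robust:
        robust_corrections(data, fit, acov_naive_t=acov_t, J_std=J_std)
    return fit


def robust_corrections(
    data: pd.DataFrame,
    fit: SemFit,
    *,
    acov_naive_t: np.ndarray | None = None,
    J_std: np.ndarray | None = None,
) -> SemFit:
    """Attach sandwich SEs and the mean-scaled test statistic to a fit.

    Uses the empirical fourth-moment covariance of vech((z - mean)(z -
    mean)') as the asymptotic covariance of the sample moments. Mutates
    and returns ``fit``.
    """
    model = fit.model
    Z = data[model.observed_vars].to_numpy(dtype=float)
    Z = Z[~np.isnan(Z).any(axis=1)]
    n = Z.shape[0]
    Zc = Z - Z.mean(axis=0)
    pairs = _vech_pairs(model.pstar)
    Bmat = np.column_stack([Zc[:, i] * Zc[:, j] for i, j in pairs])
    Gamma = np.cov(Bmat, rowvar=False, ddof=1)

    Sinv = np.linalg.inv(fit.Sigma_hat)
    D = _duplication(model.pstar)
    W = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    dS = model.dsigma(fit.theta)
    Delta = np.column_stack([_vech(d) for d in dS])
    mult = fit.n - 1

    try:
        bread = np.linalg.inv(Delta.T @ W @ Delta)
        meat = Delta.T @ W @ Gamma @ W @ Delta
        acov_rob_t = bread @ meat @ bread / mult
        U = W - W @ Delta @ bread @ Delta.T @ W
        c = float(np.trace(U @ Gamma)) / fit.df if fit.df > 0 else float("nan")
        ok = (fit.df == 0) or (np.isfinite(c) and c > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        warnings.warn(
            "fourth-moment matrix rank-deficient; robust corrections "
            "unavailable, falling back to naive SEs",
            RuntimeWarning,
        )
        fit.robust = False
        return fit

    raw = model.raw_values(fit.theta)
    jac_nat = np.array([raw[k] if p.log_scale else 1.0 for k, p in enumerate(model.free_params)])
    rob_se = np.sqrt(np.clip(np.diag(acov_rob_t), 0.0, None)) * np.abs(jac_nat)
    free_ix = {p.label.replace(_PHANTOM, ""): k for k, p in enumerate(model.free_params)}
    fit.params["robust_se"] = [
        rob_se[free_ix[l]] if l in free_ix else 0.0 for l in fit.params["label"]
    ]
    if J_std is None:
        J_std = _std_jacobian(model, fit.theta)
    fit.params["std_robust_se"] = np.sqrt(
        np.clip(np.diag(J_std @ acov_rob_t @ J_std.T), 0.0, None)
    )

    fit.scaling_c = c
    fit.T_scaled = fit.T / c if fit.df > 0 else fit.T

    # scaled baseline statistic for scaled CFI
    if fit.baseline_df > 0:
        Sb = np.diag(np.diag(fit.S))
        Sb_inv = np.linalg.inv(Sb)
        Wb = 0.5 * D.T @ np.kron(Sb_inv, Sb_inv) @ D
        diag_cols = []
        for i in range(model.pstar):
            E = np.zeros((model.pstar, model.pstar))
            E[i, i] = 1.0
            diag_cols.append(_vech(E))
        Db = np.column_stack(diag_cols)
        breadb = np.linalg.inv(Db.T @ Wb @ Db)
        Ub = Wb - Wb @ Db @ breadb @ Db.T @ Wb
        cb = float(np.trace(Ub @ Gamma)) / fit.baseline_df
        fit.baseline_T_scaled = fit.baseline_T / cb if cb > 0 else float("nan")
    fit.robust = True
    return fit
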