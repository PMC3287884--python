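"""Independent reference SEM implementation used as a cross-check oracle.

Deliberately shares no code, parameterization or optimizer with the
package: model matrices are given explicitly as numpy pattern arrays
(np.nan marks a free entry), the discrepancy is assembled from scratch,
and estimation uses scipy's derivative-free / finite-difference
optimizers on the untransformed parameters.  Only suitable for the small
fixture models it is used on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

_PENALTY = 1e8


@dataclass
class RefModel:
    """Pattern matrices: numeric entries are fixed, np.nan entries are free.

    Symmetric matrices (theta, psi, phi) are read from the lower
    triangle.  ``gam``/``phi`` may be None for models without exogenous
    covariates.
    """

    lam: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    psi: np.ndarray
    gam: np.ndarray | None = None
    phi: np.ndarray | None = None

    def free_entries(self):
        entries = []
        for name in ("lam", "beta", "gam", "theta", "psi", "phi"):
            M = getattr(self, name)
            if M is None:
                continue
            symmetric = name in ("theta", "psi", "phi")
            for i in range(M.shape[0]):
                cols = range(i + 1) if symmetric else range(M.shape[1])
                for j in cols:
                    if np.isnan(M[i, j]):
                        entries.append((name, i, j, symmetric))
        return entries


def _assemble(ref: RefModel, x: np.ndarray):
    mats = {}
    for name in ("lam", "beta", "gam", "theta", "psi", "phi"):
        M = getattr(ref, name)
        mats[name] = None if M is None else M.copy()
    for value, (name, i, j, symmetric) in zip(x, ref.free_entries()):
        mats[name][i, j] = value
        if symmetric and i != j:
            mats[name][j, i] = value
    for name in ("theta", "psi", "phi"):
        if mats[name] is not None:
            M = mats[name]
            ii, jj = np.tril_indices(M.shape[0], -1)
            M[jj, ii] = M[ii, jj]
    return mats


def _implied(ref: RefModel, x: np.ndarray) -> np.ndarray:
    m = _assemble(ref, x)
    lam, beta, psi, theta = m["lam"], m["beta"], m["psi"], m["theta"]
    nl = beta.shape[0]
    inv = np.linalg.inv(np.eye(nl) - beta)
    if m["gam"] is not None:
        gam, phi = m["gam"], m["phi"]
        latent_cov = inv @ (gam @ phi @ gam.T + psi) @ inv.T
        syy = lam @ latent_cov @ lam.T + theta
        syx = lam @ inv @ gam @ phi
        top = np.hstack([syy, syx])
        bottom = np.hstack([syx.T, phi])
        return np.vstack([top, bottom])
    latent_cov = inv @ psi @ inv.T
    return lam @ latent_cov @ lam.T + theta


def _discrepancy(ref: RefModel, x: np.ndarray, S: np.ndarray) -> float:
    try:
        sigma = _implied(ref, x)
    except np.linalg.LinAlgError:
        return _PENALTY
    p = S.shape[0]
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY + float(np.sum(x ** 2))
    sign, logdet = np.linalg.slogdet(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def _starts(ref: RefModel, S: np.ndarray) -> np.ndarray:
    p = ref.lam.shape[0]
    x0 = []
    for name, i, j, _sym in ref.free_entries():
        if name == "lam":
            x0.append(0.7)
        elif name in ("beta", "gam"):
            x0.append(0.1)
        elif name == "theta":
            x0.append(0.5 * S[i, i] if i == j else 0.0)
        elif name == "psi":
            x0.append(0.5 * np.mean(np.diag(S)[:p]) if i == j else 0.0)
        else:  # phi
            q = ref.phi.shape[0]
            x0.append(S[-q + i, -q + j])
    return np.array(x0)


def fit_reference(ref: RefModel, S: np.ndarray, n: int) -> dict:
    """Minimize the ML discrepancy and report estimates and fit measures."""
    S = np.asarray(S, dtype=float)
    x0 = _starts(ref, S)
    obj = lambda x: _discrepancy(ref, x, S)
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"maxiter": 40000, "maxfev": 40000,
                            "xatol": 1e-12, "fatol": 1e-14})
    res = minimize(obj, res.x, method="BFGS",
                   options={"maxiter": 5000, "gtol": 1e-10})
    res = minimize(obj, res.x, method="Nelder-Mead",
                   options={"maxiter": 40000, "maxfev": 40000,
                            "xatol": 1e-13, "fatol": 1e-15})
    F = obj(res.x)
    p = S.shape[0]
    n_free = len(ref.free_entries())
    df = p * (p + 1) // 2 - n_free
    T = (n - 1) * F
    # independence baseline
    F_b = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    T_b = (n - 1) * F_b
    df_b = p * (p + 1) // 2 - p
    d = max(T - df, 0.0)
    denom = max(T_b - df_b, d, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - d / denom
    rmsea = float("nan") if df == 0 else np.sqrt(d / (df * (n - 1)))
    sigma = _implied(ref, res.x)
    resid = 0.0
    cnt = 0
    for i in range(p):
        for j in range(i + 1):
            resid += ((S[i, j] - sigma[i, j]) / np.sqrt(S[i, i] * S[j, j])) ** 2
            cnt += 1
    srmr = float(np.sqrt(resid / cnt))
    return {
        "x": res.x,
        "matrices": _assemble(ref, res.x),
        "F": F,
        "T": T,
        "df": df,
        "cfi": cfi,
        "rmsea": rmsea,
        "srmr": srmr,
        "Sigma": sigma,
    }
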