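"""Model matrices, implied covariance, and analytic derivatives.

The joint covariance of the modeled observed vector (y first, then x) is

    Sigma_yy = Lambda A (Gamma Phi Gamma' + Psi) A' Lambda' + Theta
    Sigma_yx = Lambda A Gamma Phi
    Sigma_xx = Phi,        with A = (I - B)^{-1}.

Free variances are optimized as log-variances so they stay positive;
derivatives carry the chain-rule factor.
"""

from __future__ import annotations

import math

import numpy as np

from .spec import Param, SemModelSpec

__all__ = ["SemModel", "fml", "simulate_data"]


def fml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Non-negative, zero iff S == Sigma. Raises on non-positive-definite
    input.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Sigma must be square and conformable")
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("S and Sigma must be positive definite")
    np.linalg.cholesky(Sigma)  # reject indefinite matrices with positive determinant
    np.linalg.cholesky(S)
    return float(logdet_m + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


class SemModel:
    """A :class:`SemModelSpec` compiled to numeric matrices.

    The free-parameter vector ``theta`` is ordered as the free entries of
    ``spec.parameters()``; log-scale entries hold log-variances.
    """

    def __init__(self, spec: SemModelSpec):
        self.spec = spec
        self.params: list[Param] = spec.parameters()
        self.free_params: list[Param] = [p for p in self.params if p.free]
        self.y_vars = spec.y_vars
        self.x_vars = spec.x_vars
        self.latents = spec.all_latents
        self.observed_vars = spec.observed_vars
        self.p = len(self.y_vars)
        self.q = len(self.x_vars)
        self.m = len(self.latents)
        self.pstar = self.p + self.q

    # ----- theta handling ----------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def free_labels(self) -> list[str]:
        return [p.label for p in self.free_params]

    def raw_values(self, theta: np.ndarray) -> np.ndarray:
        """Transformed theta -> natural-scale parameter values."""
        out = np.asarray(theta, dtype=float).copy()
        for k, p in enumerate(self.free_params):
            if p.log_scale:
                out[k] = math.exp(out[k])
        return out

    def to_theta(self, raw: np.ndarray) -> np.ndarray:
        out = np.asarray(raw, dtype=float).copy()
        for k, p in enumerate(self.free_params):
            if p.log_scale:
                if out[k] <= 0:
                    raise ValueError(f"{p.label}: variance must be positive")
                out[k] = math.log(out[k])
        return out

    def value_dict(self, theta: np.ndarray) -> dict[str, float]:
        """All parameter values (free and fixed) on the natural scale."""
        raw = self.raw_values(theta)
        out = {p.label: p.value for p in self.params if not p.free}
        out.update(zip(self.free_labels, raw))
        return out

    # ----- matrices ----------------------------------------------------------

    def matrices(self, theta: np.ndarray):
        raw = self.raw_values(theta)
        Lam = np.zeros((self.p, self.m))
        B = np.zeros((self.m, self.m))
        Gam = np.zeros((self.m, self.q))
        Th = np.zeros((self.p, self.p))
        Ps = np.zeros((self.m, self.m))
        Ph = np.zeros((self.q, self.q))
        store = {"lam": Lam, "beta": B, "gam": Gam, "theta": Th, "psi": Ps, "phi": Ph}
        it = iter(raw)
        for p in self.params:
            v = next(it) if p.free else p.value
            M = store[p.matrix]
            M[p.i, p.j] = v
            if p.matrix in ("theta", "psi", "phi") and p.i != p.j:
                M[p.j, p.i] = v
        return Lam, B, Gam, Th, Ps, Ph

    def implied_covariance(self, theta: np.ndarray) -> np.ndarray:
        Lam, B, Gam, Th, Ps, Ph = self.matrices(theta)
        I = np.eye(self.m)
        try:
            A = np.linalg.inv(I - B)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"I - B singular at theta={np.round(np.asarray(theta, float), 4)}"
            ) from exc
        C = Gam @ Ph @ Gam.T + Ps
        G = A @ C @ A.T
        Syy = Lam @ G @ Lam.T + Th
        Sig = np.empty((self.pstar, self.pstar))
        Sig[: self.p, : self.p] = Syy
        if self.q:
            Syx = Lam @ A @ Gam @ Ph
            Sig[: self.p, self.p :] = Syx
            Sig[self.p :, : self.p] = Syx.T
            Sig[self.p :, self.p :] = Ph
        return (Sig + Sig.T) / 2.0

    def dsigma(self, theta: np.ndarray) -> np.ndarray:
        """(t, p*, p*) array of dSigma/dtheta_k (transformed scale)."""
        raw = self.raw_values(theta)
        Lam, B, Gam, Th, Ps, Ph = self.matrices(theta)
        A = np.linalg.inv(np.eye(self.m) - B)
        C = Gam @ Ph @ Gam.T + Ps
        G = A @ C @ A.T
        LamA = Lam @ A
        GamPh = Gam @ Ph
        AGamPh = A @ GamPh
        GLt = G @ Lam.T
        out = np.zeros((self.n_free, self.pstar, self.pstar))
        py = self.p
        free_idx = 0
        raw_it = iter(raw)
        for p in self.params:
            if not p.free:
                continue
            v = next(raw_it)
            d = out[free_idx]
            if p.matrix == "lam":
                i, j = p.i, p.j
                dyy = np.zeros((py, py))
                dyy[i, :] += GLt[j, :]
                dyy[:, i] += GLt[j, :]
                d[:py, :py] = dyy
                if self.q:
                    d[i, py:] += AGamPh[j, :]
                    d[py:, i] += AGamPh[j, :]
            elif p.matrix == "beta":
                E = np.zeros((self.m, self.m))
                E[p.i, p.j] = 1.0
                dA = A @ E @ A
                dG = dA @ C @ A.T
                dG = dG + dG.T
                d[:py, :py] = Lam @ dG @ Lam.T
                if self.q:
                    dyx = Lam @ dA @ GamPh
                    d[:py, py:] += dyx
                    d[py:, :py] += dyx.T
            elif p.matrix == "gam":
                E = np.zeros((self.m, self.q))
                E[p.i, p.j] = 1.0
                dC = E @ GamPh.T + GamPh @ E.T
                d[:py, :py] = LamA @ dC @ LamA.T
                dyx = LamA @ E @ Ph
                d[:py, py:] += dyx
                d[py:, :py] += dyx.T
            elif p.matrix == "theta":
                d[p.i, p.j] += 1.0
                if p.i != p.j:
                    d[p.j, p.i] += 1.0
            elif p.matrix == "psi":
                E = np.zeros((self.m, self.m))
                E[p.i, p.j] = 1.0
                if p.i != p.j:
                    E[p.j, p.i] = 1.0
                d[:py, :py] = LamA @ E @ LamA.T
            elif p.matrix == "phi":
                E = np.zeros((self.q, self.q))
                E[p.i, p.j] = 1.0
                if p.i != p.j:
                    E[p.j, p.i] = 1.0
                dC = Gam @ E @ Gam.T
                d[:py, :py] = LamA @ dC @ LamA.T
                dyx = LamA @ Gam @ E
                d[:py, py:] += dyx
                d[py:, :py] += dyx.T
                d[py:, py:] = E
            if p.log_scale:
                d *= v
            free_idx += 1
        return out

    # ----- start values ------------------------------------------------------

    def start_values(self, S: np.ndarray) -> np.ndarray:
        """Marker-scaled moment-based starts (natural scale -> transformed)."""
        obs_var = np.diag(S)
        yi = {v: k for k, v in enumerate(self.y_vars)}
        markers: dict[int, int] = {}  # latent index -> marker y index
        for p in self.params:
            if p.matrix == "lam" and not p.free and p.value == 1.0 and p.j not in markers:
                markers[p.j] = p.i
        raw = []
        for p in self.free_params:
            if p.matrix == "lam":
                mk = markers.get(p.j)
                if mk is not None and S[mk, mk] > 0:
                    raw.append(float(np.clip(S[p.i, mk] / S[mk, mk], -2.0, 2.0)) or 0.5)
                else:
                    raw.append(0.7)
            elif p.matrix in ("beta", "gam"):
                raw.append(0.0)
            elif p.matrix == "theta":
                raw.append(max(0.5 * obs_var[p.i], 1e-4) if p.i == p.j else 0.0)
            elif p.matrix == "psi":
                if p.i == p.j:
                    mk = markers.get(p.i)
                    base = obs_var[mk] if mk is not None else 1.0
                    raw.append(max(0.5 * base, 1e-4))
                else:
                    mi, mj = markers.get(p.i), markers.get(p.j)
                    raw.append(0.5 * S[mi, mj] if mi is not None and mj is not None else 0.0)
            elif p.matrix == "phi":
                a, b = self.p + p.i, self.p + p.j
                raw.append(S[a, b] if p.i != p.j else max(S[a, a], 1e-4))
        return self.to_theta(np.array(raw))


def simulate_data(
    model: SemModel | SemModelSpec,
    values: dict[str, float],
    n: int,
    rng: int | np.random.Generator,
) -> "np.ndarray":
    """Draw n observations (columns ordered y then x) from the model at
    the given parameter values.

    ``values`` must assign every free parameter by label (fixed
    parameters keep their fixed values). Returns a pandas DataFrame.
    """
    import pandas as pd

    if isinstance(model, SemModelSpec):
        model = SemModel(model)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    missing = [l for l in model.free_labels if l not in values]
    if missing:
        raise ValueError(f"values missing for free parameters: {missing[:5]}")
    theta = model.to_theta(np.array([values[l] for l in model.free_labels]))
    Lam, B, Gam, Th, Ps, Ph = model.matrices(theta)
    A = np.linalg.inv(np.eye(model.m) - B)

    def draw(cov: np.ndarray, size: int) -> np.ndarray:
        if cov.shape[0] == 0:
            return np.zeros((size, 0))
        w, V = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 0.0, None)
        return rng.standard_normal((size, cov.shape[0])) @ (V * np.sqrt(w)).T

    x = draw(Ph, n)
    zeta = draw(Ps, n)
    eta = (A @ (Gam @ x.T + zeta.T)).T
    eps = draw(Th, n)
    y = eta @ Lam.T + eps
    data = np.hstack([y, x])
    return pd.DataFrame(data, columns=model.observed_vars)
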