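"""Gaussian-process binary classification with a probit likelihood.

The classifier places a zero-mean GP prior with a *linear* covariance

    k(x, x') = s * <x, x'> / d + b,        s = exp(log_signal),
                                           b = exp(log_bias),

over a latent function f (d is the feature dimension; the 1/d
normalisation keeps hyperparameter scales dimension-independent), squashes
f through the probit link Phi, and approximates the non-Gaussian posterior
over the n latent training values by expectation propagation (EP): one
Gaussian site factor per data point, refined by iterated moment matching.
Hyperparameters are chosen by maximising the EP approximation of the log
marginal likelihood (type-II maximum likelihood).

Because n << d in imaging applications, all computations are carried out
in the dual: only the n x n kernel matrix is ever formed.  Features are
centred by the training mean before the dot product; the bias
hyperparameter then absorbs any class offset.

The EP recursions and the marginal-likelihood expression follow the
standard formulation for binary GP classification (site updates by
matching cavity-times-likelihood moments; posterior refreshed from the
site parameters through a Cholesky factorisation of
B = I + S^(1/2) K S^(1/2)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, optimize
from scipy.special import log_ndtr, ndtr

__all__ = [
    "Hyperparams",
    "EPState",
    "GPModel",
    "linear_kernel",
    "ep_inference",
    "fit",
    "predict_probability",
    "predict_latent",
    "save_model",
    "load_model",
]

JITTER_SCALE = 1e-8
EP_TOL = 1e-4
EP_MAX_SWEEPS = 60
HYPER_BOUNDS = (-10.0, 10.0)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Hyperparams:
    """Log-scale kernel hyperparameters (signal scale s and bias b)."""

    log_signal: float = 0.0
    log_bias: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log_signal) and np.isfinite(self.log_bias)):
            raise ValueError("hyperparameters must be finite")


def linear_kernel(
    A: np.ndarray,
    B: np.ndarray,
    h: Hyperparams,
    d_normalize: bool = True,
) -> np.ndarray:
    """Linear covariance K[i, j] = s <A_i, B_j> / d + b.

    ``A`` and ``B`` are rows of (already centred) features with a common
    column count d; ``d_normalize=False`` drops the 1/d factor.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    d = A.shape[1] if d_normalize else 1
    return np.exp(h.log_signal) * (A @ B.T) / d + np.exp(h.log_bias)


@dataclass
class EPState:
    """Converged EP site parameters and posterior moments.

    ``site_precisions`` (tau >= 0) and ``site_means`` (nu, natural-parameter
    scale) define the local Gaussian approximations; ``mu`` and ``Sigma``
    are the resulting approximate posterior moments of the latent values,
    and ``log_marginal`` the EP estimate of the log evidence.
    """

    site_precisions: np.ndarray
    site_means: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    log_marginal: float
    converged: bool
    n_sweeps: int
    K: np.ndarray = field(repr=False, default=None)  # jittered kernel


def _probit_moments(y: float, mu_cav: float, s2_cav: float) -> tuple[float, float, float]:
    """log Z, mean and variance of N(f; mu_cav, s2_cav) * Phi(y f)."""
    denom = np.sqrt(1.0 + s2_cav)
    z = y * mu_cav / denom
    log_z = log_ndtr(z)
    # ratio phi(z)/Phi(z), computed in log space for tail robustness
    ratio = np.exp(-0.5 * z * z - 0.5 * _LOG_2PI - log_z)
    mu_hat = mu_cav + y * s2_cav * ratio / denom
    s2_hat = s2_cav - s2_cav**2 * ratio * (z + ratio) / (1.0 + s2_cav)
    return log_z, mu_hat, s2_hat


def _posterior_from_sites(
    K: np.ndarray, tau: np.ndarray, nu: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recompute (Sigma, mu, L) from site parameters.

    L is the Cholesky factor of B = I + S^(1/2) K S^(1/2).
    """
    n = K.shape[0]
    srt = np.sqrt(tau)
    B = np.eye(n) + (srt[:, None] * K) * srt[None, :]
    L = linalg.cholesky(B, lower=True)
    V = linalg.solve_triangular(L, srt[:, None] * K, lower=True)
    Sigma = K - V.T @ V
    mu = Sigma @ nu
    return Sigma, mu, L


def _ep_log_marginal(
    K: np.ndarray,
    y: np.ndarray,
    tau: np.ndarray,
    nu: np.ndarray,
    Sigma: np.ndarray,
    mu: np.ndarray,
    L: np.ndarray,
) -> float:
    """EP approximation of the log marginal likelihood (zero prior mean)."""
    diag = np.diag(Sigma)
    tau_cav = 1.0 / diag - tau
    nu_cav = mu / diag - nu
    mu_cav = nu_cav / tau_cav
    s2_cav = 1.0 / tau_cav
    lZ = log_ndtr(y * mu_cav / np.sqrt(1.0 + s2_cav))
    nlZ = (
        np.sum(np.log(np.diag(L)))
        - np.sum(lZ)
        - 0.5 * nu @ Sigma @ nu
        - 0.5 * nu_cav @ ((tau / tau_cav * nu_cav - 2.0 * nu) / (tau + tau_cav))
        + 0.5 * np.sum(nu**2 / (tau_cav + tau))
        - 0.5 * np.sum(np.log1p(tau / tau_cav))
    )
    return float(-nlZ)


def ep_inference(
    K: np.ndarray,
    y: np.ndarray,
    max_sweeps: int = EP_MAX_SWEEPS,
    tol: float = EP_TOL,
    jitter_scale: float = JITTER_SCALE,
) -> EPState:
    """Run EP to convergence on a PSD kernel and binary labels.

    Sites are updated in fixed ascending index order; an update that
    would drive a site precision negative is damped by 0.5 and, if still
    negative, clipped at 0.  Convergence is declared when the largest
    absolute site-parameter change in a sweep falls below ``tol``
    (default 1e-4), with a hard cap of ``max_sweeps`` sweeps.
    """
    K = np.asarray(K, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = K.shape[0]
    if K.shape != (n, n) or len(y) != n:
        raise ValueError("K must be square and match the length of y")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1/-1")
    K = K + jitter_scale * float(np.mean(np.diag(K))) * np.eye(n)

    tau = np.zeros(n)
    nu = np.zeros(n)
    Sigma = K.copy()
    mu = np.zeros(n)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for i in range(n):
            s2_i = Sigma[i, i]
            tau_cav = 1.0 / s2_i - tau[i]
            nu_cav = mu[i] / s2_i - nu[i]
            if tau_cav <= 0:
                # pathological cavity; skip this site for the sweep
                continue
            _, mu_hat, s2_hat = _probit_moments(y[i], nu_cav / tau_cav, 1.0 / tau_cav)
            tau_new = 1.0 / s2_hat - tau_cav
            nu_new = mu_hat / s2_hat - nu_cav
            if tau_new < 0:
                tau_new = 0.5 * tau_new + 0.5 * tau[i]
                nu_new = 0.5 * nu_new + 0.5 * nu[i]
                if tau_new < 0:
                    tau_new = 0.0
            d_tau = tau_new - tau[i]
            max_delta = max(max_delta, abs(d_tau), abs(nu_new - nu[i]))
            tau[i], nu[i] = tau_new, nu_new
            # rank-1 refresh of the posterior moments
            si = Sigma[:, i].copy()
            Sigma -= (d_tau / (1.0 + d_tau * s2_i)) * np.outer(si, si)
            mu = Sigma @ nu
        try:
            Sigma, mu, L = _posterior_from_sites(K, tau, nu)
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise linalg.LinAlgError(
                f"EP posterior refresh failed (indefinite kernel after jitter): {exc}"
            ) from exc
        if max_delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"EP did not converge in {max_sweeps} sweeps (last max delta {max_delta:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    log_marginal = _ep_log_marginal(K, y, tau, nu, Sigma, mu, L)
    return EPState(
        site_precisions=tau,
        site_means=nu,
        mu=mu,
        Sigma=Sigma,
        log_marginal=log_marginal,
        converged=converged,
        n_sweeps=sweeps,
        K=K,
    )


@dataclass
class GPModel:
    """A trained GP classifier: hyperparameters, EP state, training data."""

    hyperparams: Hyperparams
    ep_state: EPState
    X_centered: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    train_mean: np.ndarray = field(repr=False)

    @property
    def log_marginal(self) -> float:
        return self.ep_state.log_marginal


def _neg_evidence(theta: np.ndarray, G: np.ndarray, y: np.ndarray, d: int) -> float:
    h = Hyperparams(log_signal=float(theta[0]), log_bias=float(theta[1]))
    K = np.exp(h.log_signal) * G / d + np.exp(h.log_bias)
    return -ep_inference(K, y).log_marginal


def fit(
    X: np.ndarray,
    y: np.ndarray,
    optimize_hyperparams: bool = True,
    start: Hyperparams = Hyperparams(0.0, 0.0),
    bounds: tuple[float, float] = HYPER_BOUNDS,
) -> GPModel:
    """Train the classifier, optionally with type-II maximum likelihood.

    Features are centred by the training mean (stored for prediction).
    When ``optimize_hyperparams`` is true, (log_signal, log_bias) are
    tuned by bounded L-BFGS-B with numerical gradients on the negative EP
    evidence, from the fixed default start — a deterministic procedure.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1.0, 1.0]):
        raise ValueError(f"training labels must contain both classes, got {classes}")

    train_mean = X.mean(axis=0)
    Xc = X - train_mean
    d = Xc.shape[1]
    G = Xc @ Xc.T  # Gram matrix, reused across evidence evaluations

    h = start
    if optimize_hyperparams:
        x0 = np.array([start.log_signal, start.log_bias])
        f0 = _neg_evidence(x0, G, y, d)
        res = optimize.minimize(
            _neg_evidence,
            x0=x0,
            args=(G, y, d),
            method="L-BFGS-B",
            bounds=[bounds, bounds],
        )
        # monotone-improvement contract: never return worse than the start
        if res.fun <= f0:
            h = Hyperparams(float(res.x[0]), float(res.x[1]))
    K = np.exp(h.log_signal) * G / d + np.exp(h.log_bias)
    state = ep_inference(K, y)
    return GPModel(hyperparams=h, ep_state=state, X_centered=Xc, y=y, train_mean=train_mean)


def predict_latent(m: GPModel, X_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive latent mean and variance at new points."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=np.float64))
    if X_star.shape[1] != m.X_centered.shape[1]:
        raise ValueError(
            f"test feature dimension {X_star.shape[1]} does not match training "
            f"{m.X_centered.shape[1]}"
        )
    Xs = X_star - m.train_mean
    h = m.hyperparams
    Kstar = linear_kernel(m.X_centered, Xs, h)  # n x m
    d = m.X_centered.shape[1]
    kss = np.exp(h.log_signal) * np.einsum("ij,ij->i", Xs, Xs) / d + np.exp(h.log_bias)

    tau = m.ep_state.site_precisions
    nu = m.ep_state.site_means
    K = m.ep_state.K
    srt = np.sqrt(tau)
    n = K.shape[0]
    B = np.eye(n) + (srt[:, None] * K) * srt[None, :]
    L = linalg.cholesky(B, lower=True)
    # z = (K + S~^-1)^-1 mu~ in a form valid for tau -> 0
    w = linalg.cho_solve((L, True), srt * (K @ nu))
    z = nu - srt * w
    mu_star = Kstar.T @ z
    V = linalg.solve_triangular(L, srt[:, None] * Kstar, lower=True)
    var_star = kss - np.einsum("ij,ij->j", V, V)
    var_star = np.maximum(var_star, 1e-12)
    return mu_star, var_star


def predict_probability(m: GPModel, X_star: np.ndarray) -> np.ndarray:
    """Probability of class +1: Phi(mu* / sqrt(1 + var*)), in (0, 1)."""
    mu_star, var_star = predict_latent(m, X_star)
    p = ndtr(mu_star / np.sqrt(1.0 + var_star))
    eps = np.finfo(np.float64).tiny
    return np.clip(p, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# serialization: JSON header + npz array bundle
# ---------------------------------------------------------------------------

def save_model(m: GPModel, out_dir: str | Path) -> Path:
    """Persist a model as model.json + arrays.npz inside ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {
        "log_signal": m.hyperparams.log_signal,
        "log_bias": m.hyperparams.log_bias,
        "log_marginal": m.log_marginal,
        "converged": bool(m.ep_state.converged),
        "n_sweeps": int(m.ep_state.n_sweeps),
        "n_samples": int(m.X_centered.shape[0]),
        "n_features": int(m.X_centered.shape[1]),
    }
    (out_dir / "model.json").write_text(json.dumps(header, indent=2))
    np.savez(
        out_dir / "arrays.npz",
        X_centered=m.X_centered,
        y=m.y,
        train_mean=m.train_mean,
        site_precisions=m.ep_state.site_precisions,
        site_means=m.ep_state.site_means,
        mu=m.ep_state.mu,
        Sigma=m.ep_state.Sigma,
        K=m.ep_state.K,
    )
    return out_dir


def load_model(in_dir: str | Path) -> GPModel:
    in_dir = Path(in_dir)
    header = json.loads((in_dir / "model.json").read_text())
    arrays = np.load(in_dir / "arrays.npz")
    state = EPState(
        site_precisions=arrays["site_precisions"],
        site_means=arrays["site_means"],
        mu=arrays["mu"],
        Sigma=arrays["Sigma"],
        log_marginal=float(header["log_marginal"]),
        converged=bool(header["converged"]),
        n_sweeps=int(header["n_sweeps"]),
        K=arrays["K"],
    )
    return GPModel(
        hyperparams=Hyperparams(header["log_signal"], header["log_bias"]),
        ep_state=state,
        X_centered=arrays["X_centered"],
        y=arrays["y"],
        train_mean=arrays["train_mean"],
    )
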