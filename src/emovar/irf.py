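"""Impulse-response analysis: moving-average coefficients, orthogonalized
one-standard-deviation shock responses, and bootstrap confidence bands.

The MA representation of a stable VAR(p) gives Psi_0 = I and
Psi_h = sum_{j=1..min(h,p)} A_j Psi_{h-j}.  Orthogonalized responses use
the lower-triangular Cholesky factor P of the residual covariance
(Sigma = P P'): Theta_h = Psi_h P, so column k of Theta_h is the
horizon-h response to a one-SD orthogonal shock in variable k (the
decomposition — hence the result — depends on the variable ordering).
Confidence bands come from a recursive-design residual bootstrap with
pointwise percentile intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, StabilityError
from .panel import WeeklyPanel
from .var import VARModel, check_stability, fit_var, _lagged_design, _ols_system

__all__ = ["IRFResult", "ma_coefficients", "orthogonalized_irf",
           "bootstrap_irf_bands", "irf_frame"]


@dataclass(frozen=True)
class IRFResult:
    """Point impulse responses, optionally with pointwise bands.

    ``theta[h, i, k]`` is the horizon-h response of variable i to a
    shock in variable k, in the model's original variable order.
    """

    names: tuple[str, ...]
    horizon: int
    theta: np.ndarray                 # (H+1, K, K)
    lower: np.ndarray | None = None   # same shape, level alpha/2
    upper: np.ndarray | None = None   # level 1 - alpha/2
    alpha: float = 0.05
    shock: str = "orthogonalized-one-SD"  # or "unit-shock"
    ordering: tuple[str, ...] = ()
    band_method: str | None = None
    n_boot: int | None = None
    seed: int | None = None

    def response(self, response: str, shock: str) -> np.ndarray:
        i = self.names.index(response)
        k = self.names.index(shock)
        return self.theta[:, i, k]


def ma_coefficients(model: VARModel, H: int) -> np.ndarray:
    """MA matrices Psi_0..Psi_H of the fitted VAR, shape (H+1, K, K)."""
    if H < 0:
        raise ValueError(f"horizon must be >= 0, got {H}")
    K, p = model.K, model.p
    psi = np.zeros((H + 1, K, K))
    psi[0] = np.eye(K)
    for h in range(1, H + 1):
        acc = np.zeros((K, K))
        for j in range(1, min(h, p) + 1):
            acc += model.A[j - 1] @ psi[h - j]
        psi[h] = acc
    return psi


def _cholesky_factor(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise EstimationError(
            "residual covariance is not positive definite") from None


def _theta_matrices(
    A: np.ndarray, sigma: np.ndarray, H: int, perm: np.ndarray,
    unit_shock: bool = False,
) -> np.ndarray:
    """Orthogonalized responses in the *original* variable order."""
    p, K, _ = A.shape
    inv = np.argsort(perm)
    sig_p = sigma[np.ix_(perm, perm)]
    P = _cholesky_factor(sig_p)
    if unit_shock:
        P = P / np.diag(P)
    # MA recursion in permuted space with permuted lag matrices
    A_p = A[:, perm][:, :, perm]
    theta = np.zeros((H + 1, K, K))
    psis = [np.eye(K)]
    theta[0] = P
    for h in range(1, H + 1):
        acc = np.zeros((K, K))
        for j in range(1, min(h, p) + 1):
            acc += A_p[j - 1] @ psis[h - j]
        psis.append(acc)
        theta[h] = acc @ P
    return theta[:, inv][:, :, inv]


def orthogonalized_irf(
    model: VARModel,
    H: int,
    ordering: tuple[str, ...] | None = None,
    unit_shock: bool = False,
) -> IRFResult:
    """Point responses to orthogonalized (Cholesky) shocks.

    ``ordering`` is a permutation of the model's variables defining the
    recursive identification; it defaults to the model's own order.
    With ``unit_shock=True`` the shock columns are rescaled so the
    impact response of each shocked variable is one unit instead of one
    standard deviation.
    """
    if H < 0:
        raise ValueError(f"horizon must be >= 0, got {H}")
    names = model.names
    if ordering is None:
        ordering = names
    if sorted(ordering) != sorted(names):
        raise ValueError(f"ordering {ordering} is not a permutation of {names}")
    perm = np.array([names.index(v) for v in ordering])
    theta = _theta_matrices(model.A, model.sigma, H, perm, unit_shock)
    return IRFResult(
        names=names, horizon=H, theta=theta,
        shock="unit-shock" if unit_shock else "orthogonalized-one-SD",
        ordering=tuple(ordering),
    )


def _fit_arrays(y: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lean per-equation OLS on a raw array; returns (c, A, sigma_ml)."""
    T, K = y.shape
    Y, X = _lagged_design(y, p, p)
    B, E = _ols_system(Y, X)
    c = B[0].copy()
    A = np.empty((p, K, K))
    for j in range(p):
        A[j] = B[1 + j * K: 1 + (j + 1) * K].T
    sigma = (E.T @ E) / (T - p)
    return c, A, sigma


def bootstrap_irf_bands(
    panel: WeeklyPanel,
    p: int,
    H: int,
    ordering: tuple[str, ...] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    unit_shock: bool = False,
) -> IRFResult:
    """Orthogonalized IRF with pointwise percentile bootstrap bands.

    Recursive-design residual bootstrap: center the fitted residuals,
    resample their rows with replacement, regenerate the T panel rows
    from the first p observed rows using the fitted coefficients, refit,
    and recompute the responses.  Bands are the alpha/2 and 1 - alpha/2
    pointwise quantiles over B replicates; the draw stream is fixed by
    ``seed``.  Refuses to run when the point estimate is unstable.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 bootstrap replicates, got {B}")
    if seed is None:
        raise ValueError("bootstrap bands require an explicit seed")
    model = fit_var(panel, p)
    stab = check_stability(model)
    if not stab.is_stable:
        raise StabilityError(
            f"point estimate unstable (max root modulus {stab.max_modulus:.4f})")
    names = model.names
    if ordering is None:
        ordering = names
    if sorted(ordering) != sorted(names):
        raise ValueError(f"ordering {ordering} is not a permutation of {names}")
    perm = np.array([names.index(v) for v in ordering])

    point = _theta_matrices(model.A, model.sigma, H, perm, unit_shock)
    y = panel.data.to_numpy(dtype=float)
    T, K = y.shape
    E = model.residuals.to_numpy()
    E = E - E.mean(axis=0)
    T_eff = T - p
    rng = np.random.default_rng(seed)
    c, A = model.c, model.A

    draws = np.empty((B, H + 1, K, K))
    ystar = np.empty_like(y)
    for b in range(B):
        idx = rng.integers(0, T_eff, size=T_eff)
        ystar[:p] = y[:p]
        eps = E[idx]
        for t in range(p, T):
            acc = c + eps[t - p]
            for j in range(1, p + 1):
                acc = acc + A[j - 1] @ ystar[t - j]
            ystar[t] = acc
        cb, Ab, sigb = _fit_arrays(ystar, p)
        draws[b] = _theta_matrices(Ab, sigb, H, perm, unit_shock)

    lower = np.quantile(draws, alpha / 2.0, axis=0)
    upper = np.quantile(draws, 1.0 - alpha / 2.0, axis=0)
    return IRFResult(
        names=names, horizon=H, theta=point, lower=lower, upper=upper,
        alpha=alpha,
        shock="unit-shock" if unit_shock else "orthogonalized-one-SD",
        ordering=tuple(ordering),
        band_method="recursive-design residual bootstrap, percentile",
        n_boot=B, seed=seed,
    )


def irf_frame(result: IRFResult) -> pd.DataFrame:
    """Long-format table: h, response, shock, point [, lower, upper]."""
    rows = []
    for h in range(result.horizon + 1):
        for i, resp in enumerate(result.names):
            for k, shk in enumerate(result.names):
                row = {"h": h, "response": resp, "shock": shk,
                       "point": result.theta[h, i, k]}
                if result.lower is not None:
                    row["lower"] = result.lower[h, i, k]
                    row["upper"] = result.upper[h, i, k]
                rows.append(row)
    return pd.DataFrame(rows)


def plot_irf_grid(result: IRFResult, path: str) -> None:
    """K x K grid of response curves with shaded pointwise bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = len(result.names)
    h = np.arange(result.horizon + 1)
    fig, axes = plt.subplots(K, K, figsize=(3 * K, 2.2 * K),
                             sharex=True, squeeze=False)
    for i, resp in enumerate(result.names):
        for k, shk in enumerate(result.names):
            ax = axes[i][k]
            if result.lower is not None:
                ax.fill_between(h, result.lower[:, i, k],
                                result.upper[:, i, k],
                                color="0.8", label="95% band")
            ax.plot(h, result.theta[:, i, k], color="C0")
            ax.axhline(0.0, color="k", lw=0.5)
            ax.set_title(f"{resp} ← {shk} shock", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
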