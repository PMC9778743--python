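"""Vector autoregression estimation, lag selection, stability diagnostics
and Granger causality tests.

A VAR(p) writes each of K weekly series as a linear function of an
intercept and p lags of all K series:

    y_t = c + A_1 y_{t-1} + ... + A_p y_{t-p} + e_t,   e_t ~ WN(0, Sigma)

Each equation is estimated by ordinary least squares on rows p+1..T;
Sigma uses the maximum-likelihood scaling (divide by the effective
sample size).  Granger non-causality of one variable for another is
tested by a block F-test excluding the cause's p lags from the effect's
equation, by default inside the full K-variable system.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .panel import WeeklyPanel

__all__ = [
    "VARModel",
    "LagSelection",
    "StabilityReport",
    "GrangerResult",
    "fit_var",
    "select_lag",
    "companion_matrix",
    "check_stability",
    "granger_test",
    "granger_matrix",
]


@dataclass(frozen=True)
class VARModel:
    """A fitted VAR(p): intercepts, lag matrices, residual covariance."""

    names: tuple[str, ...]
    p: int
    c: np.ndarray            # (K,)
    A: np.ndarray            # (p, K, K); A[j][i, k]: equation i, variable k, lag j+1
    sigma: np.ndarray        # (K, K), ML scaling
    residuals: pd.DataFrame  # (T_effective, K)
    rss: np.ndarray          # (K,) per-equation residual sum of squares
    T_effective: int
    standardized_input: bool = False

    @property
    def K(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "p": self.p,
            "c": self.c.tolist(),
            "A": self.A.tolist(),
            "sigma": self.sigma.tolist(),
            "T_effective": self.T_effective,
            "standardized_input": self.standardized_input,
        }


def _lagged_design(y: np.ndarray, p: int, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Regressand rows start..T-1 and regressors [1, y_{t-1}, ..., y_{t-p}]."""
    T, K = y.shape
    Y = y[start:]
    n = T - start
    X = np.empty((n, 1 + K * p))
    X[:, 0] = 1.0
    for j in range(1, p + 1):
        X[:, 1 + (j - 1) * K: 1 + j * K] = y[start - j: T - j]
    return Y, X


def _ols_system(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (n_reg x K) and residuals for Y = X B + E."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise EstimationError(
            f"rank-deficient regressor matrix (rank {rank} < {X.shape[1]})")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ B
    return B, E


def fit_var(panel: WeeklyPanel, p: int) -> VARModel:
    """Estimate a VAR(p) on the panel by per-equation least squares."""
    if p < 1:
        raise EstimationError(f"lag order must be >= 1, got {p}")
    y = panel.data.to_numpy(dtype=float)
    T, K = y.shape
    if T < K * p + p + 2:
        raise EstimationError(
            f"insufficient rows: T={T} < {K * p + p + 2} needed for K={K}, p={p}")
    Y, X = _lagged_design(y, p, p)
    B, E = _ols_system(Y, X)
    T_eff = T - p
    c = B[0].copy()
    A = np.empty((p, K, K))
    for j in range(p):
        # B rows 1+jK .. 1+(j+1)K hold lag-(j+1) coefficients, variable-major
        A[j] = B[1 + j * K: 1 + (j + 1) * K].T
    sigma = (E.T @ E) / T_eff
    resid = pd.DataFrame(E, columns=panel.data.columns)
    return VARModel(
        names=tuple(panel.data.columns), p=p, c=c, A=A, sigma=sigma,
        residuals=resid, rss=(E ** 2).sum(axis=0), T_effective=T_eff,
        standardized_input=panel.standardized,
    )


@dataclass(frozen=True)
class LagSelection:
    """AIC/BIC over candidate orders 1..p_max on a common estimation sample."""

    candidates: tuple[int, ...]
    aic: dict[int, float]
    bic: dict[int, float]
    selected_aic: int
    selected_bic: int
    common_sample: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aic": [self.aic[p] for p in self.candidates],
             "bic": [self.bic[p] for p in self.candidates]},
            index=pd.Index(self.candidates, name="lag"),
        )


def select_lag(panel: WeeklyPanel, p_max: int) -> LagSelection:
    """Choose the lag order by AIC and BIC.

    All candidates are fitted on the common sample (rows p_max+1..T), so
    their criteria are comparable:

        AIC(p) = ln det Sigma_p + 2 (K^2 p + K) / T_c
        BIC(p) = ln det Sigma_p + ln(T_c) (K^2 p + K) / T_c

    with Sigma_p the ML residual covariance and T_c = T - p_max.  Ties
    break toward the smaller order.
    """
    if p_max < 1:
        raise EstimationError(f"p_max must be >= 1, got {p_max}")
    y = panel.data.to_numpy(dtype=float)
    T, K = y.shape
    T_c = T - p_max
    if T_c < K * p_max + 2:
        raise EstimationError(
            f"insufficient rows for p_max={p_max}: common sample {T_c}")
    aic: dict[int, float] = {}
    bic: dict[int, float] = {}
    for p in range(1, p_max + 1):
        Y, X = _lagged_design(y, p, p_max)
        _, E = _ols_system(Y, X)
        sigma = (E.T @ E) / T_c
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise EstimationError(f"singular residual covariance at p={p}")
        k_params = K * K * p + K
        aic[p] = float(logdet + 2.0 * k_params / T_c)
        bic[p] = float(logdet + np.log(T_c) * k_params / T_c)
    candidates = tuple(range(1, p_max + 1))
    sel_aic = min(candidates, key=lambda p: (aic[p], p))
    sel_bic = min(candidates, key=lambda p: (bic[p], p))
    return LagSelection(candidates=candidates, aic=aic, bic=bic,
                        selected_aic=sel_aic, selected_bic=sel_bic)


def companion_matrix(model: VARModel) -> np.ndarray:
    """Stacked first-order (companion) form: top block row [A_1 ... A_p],
    identity blocks on the subdiagonal, zeros elsewhere."""
    K, p = model.K, model.p
    F = np.zeros((K * p, K * p))
    for j in range(p):
        F[:K, j * K:(j + 1) * K] = model.A[j]
    if p > 1:
        F[K:, :K * (p - 1)] = np.eye(K * (p - 1))
    return F


@dataclass(frozen=True)
class StabilityReport:
    """Companion eigenvalue moduli; the VAR is stable iff all are < 1."""

    moduli: np.ndarray  # sorted descending
    is_stable: bool
    tolerance: float = 0.0

    @property
    def max_modulus(self) -> float:
        return float(self.moduli[0])


def check_stability(model: VARModel, tolerance: float = 0.0) -> StabilityReport:
    """Eigenvalue moduli of the companion matrix; stable iff max < 1 (strict)."""
    eig = np.linalg.eigvals(companion_matrix(model))
    moduli = np.sort(np.abs(eig))[::-1]
    return StabilityReport(
        moduli=moduli,
        is_stable=bool(moduli[0] < 1.0 - tolerance),
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class GrangerResult:
    """Block F-test of Granger non-causality of `cause` for `effect`."""

    cause: str
    effect: str
    lag: int
    F: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    reject: bool


def granger_test(
    panel: WeeklyPanel,
    cause: str,
    effect: str,
    p: int,
    alpha: float = 0.05,
    bivariate: bool = False,
) -> GrangerResult:
    """Test whether `cause` Granger-causes `effect` at lag order p.

    The unrestricted model is the effect's equation from the full
    K-variable VAR(p); the restricted model removes the cause's p lags.
    F = ((RSS_r - RSS_u)/p) / (RSS_u / df_den) with
    df_den = T_eff - (K p + 1).  With ``bivariate=True`` the system is
    first reduced to the two columns involved.
    """
    if cause == effect:
        raise ValueError("cause and effect must differ")
    for c in (cause, effect):
        if c not in panel.data.columns:
            raise KeyError(f"column {c!r} not in panel")
    data = panel.data
    if bivariate:
        data = data[[cause, effect]]
    y = data.to_numpy(dtype=float)
    T, K = y.shape
    if T < K * p + p + 2:
        raise EstimationError(
            f"insufficient rows: T={T} for K={K}, p={p}")
    names = list(data.columns)
    i_eff = names.index(effect)
    i_cause = names.index(cause)
    Y, X = _lagged_design(y, p, p)
    _, E_u = _ols_system(Y[:, [i_eff]], X)
    rss_u = float((E_u ** 2).sum())
    keep = [0] + [
        1 + j * K + k
        for j in range(p) for k in range(K) if k != i_cause
    ]
    _, E_r = _ols_system(Y[:, [i_eff]], X[:, keep])
    rss_r = float((E_r ** 2).sum())
    T_eff = T - p
    df_num = p
    df_den = T_eff - (K * p + 1)
    if df_den < 1:
        raise EstimationError("no residual degrees of freedom for the F test")
    F = max(0.0, (rss_r - rss_u) / df_num / (rss_u / df_den))
    p_value = float(stats.f.sf(F, df_num, df_den))
    return GrangerResult(
        cause=cause, effect=effect, lag=p, F=float(F),
        df_num=df_num, df_den=df_den, p_value=p_value,
        alpha=alpha, reject=bool(p_value < alpha),
    )


def granger_matrix(
    panel: WeeklyPanel,
    p: int,
    alpha: float = 0.05,
    behavior_name: str = "behavior",
    bivariate: bool = False,
) -> list[GrangerResult]:
    """Directed tests between each emotion and the behavior column.

    Emits, in panel column order, every emotion -> behavior test
    followed by every behavior -> emotion test (2 x n_emotions results).
    """
    if behavior_name not in panel.data.columns:
        raise KeyError(f"behavior column {behavior_name!r} not in panel")
    emotions = [c for c in panel.data.columns if c != behavior_name]
    if not emotions:
        raise ValueError("panel has no emotion columns")
    out = [granger_test(panel, m, behavior_name, p, alpha, bivariate) for m in emotions]
    out += [granger_test(panel, behavior_name, m, p, alpha, bivariate) for m in emotions]
    return out


def granger_frame(results: list[GrangerResult]) -> pd.DataFrame:
    """Long-format table: cause, effect, lag, F, dfs, p_value, reject."""
    return pd.DataFrame(
        [{
            "cause": r.cause, "effect": r.effect, "lag": r.lag, "F": r.F,
            "df_num": r.df_num, "df_den": r.df_den,
            "p_value": r.p_value, "reject": r.reject,
        } for r in results]
    )
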