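"""Limited-information goodness of fit for binary 2PL models.

The M2 statistic compares observed first- and second-order response margins
(item proportions and pairwise joint proportions) with their model-implied
values.  With s = k + k(k-1)/2 margins and q free parameters, the quadratic
form in the marginal residuals is weighted through an orthogonal complement
of the margin Jacobian, which makes it asymptotically chi-square with
s - q degrees of freedom for any root-n-consistent estimator; for a k-item
2PL, q = 2k.  RMSEA and CFI analogues are derived from M2 exactly as their
full-information counterparts are derived from the chi-square statistic,
with the independence model (free item proportions, zero association) as
the CFI baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, null_space

from .irt import CalibratedForm, ThetaGrid, _logistic_terms, _validate_matrix, default_grid

__all__ = [
    "FitIndices",
    "m2_statistic",
    "m2_independence",
    "rmsea_from_m2",
    "cfi_from_m2",
    "fit_indices",
    "m2_df",
    "categorical_cfa_df",
    "delta_df_unit_correlations",
]


@dataclass
class FitIndices:
    """M2-based fit summary for one calibrated form."""

    m2: float
    df: int
    rmsea: float
    cfi: float
    n_persons: int
    m2_baseline: float = np.nan
    df_baseline: int = 0


def m2_df(n_items: int) -> int:
    """Degrees of freedom of M2 for a k-item 2PL: (k + k(k-1)/2) - 2k."""
    k = int(n_items)
    return k + k * (k - 1) // 2 - 2 * k


def _margin_sets(k: int) -> list[tuple[int, ...]]:
    return [(i,) for i in range(k)] + list(combinations(range(k), 2))


def _membership(sets: list[tuple[int, ...]], k: int) -> np.ndarray:
    m = np.zeros((len(sets), k))
    for r, s in enumerate(sets):
        m[r, list(s)] = 1.0
    return m


def _sample_margins(X: np.ndarray) -> np.ndarray:
    n, k = X.shape
    Xf = X.astype(float)
    uni = Xf.mean(axis=0)
    cross = (Xf.T @ Xf) / n
    biv = np.array([cross[i, j] for i, j in combinations(range(k), 2)])
    return np.concatenate([uni, biv])


def _model_margin_machinery(form: CalibratedForm, grid: ThetaGrid):
    """Model-implied margins pi, their covariance Xi, and Jacobian Delta."""
    k = form.n_items
    nodes = grid.nodes
    w = grid.normal_weights(form.prior_mean, form.prior_sd)
    _, p, logp, _ = _logistic_terms(form.a_hat, form.b_hat, nodes)

    sets = _margin_sets(k)
    memb = _membership(sets, k)  # s x k
    g = memb @ logp  # log prod_{i in S} P_i(theta), s x Q
    pi = np.exp(g) @ w  # s

    # covariance of the margin indicators: pi_{A u B} - pi_A pi_B
    inter = np.einsum("ri,ti,iq->rtq", memb, memb, logp)  # log prod over A ^ B
    log_union = g[:, None, :] + g[None, :, :] - inter
    pi_union = np.exp(log_union) @ w
    xi = pi_union - np.outer(pi, pi)

    # Jacobian of margins wrt (a_1..a_k, b_1..b_k)
    e = np.exp(g) * w[None, :]  # s x Q, weight-folded products
    da_kernel = (nodes[None, :] - form.b_hat[:, None]) * (1.0 - p)  # k x Q
    db_kernel = -form.a_hat[:, None] * (1.0 - p)
    d_a = memb * np.einsum("sq,iq->si", e, da_kernel)
    d_b = memb * np.einsum("sq,iq->si", e, db_kernel)
    delta = np.concatenate([d_a, d_b], axis=1)  # s x 2k
    return pi, xi, delta


def _quadratic_form(resid: np.ndarray, xi: np.ndarray, delta: np.ndarray, n: int) -> float:
    comp = null_space(delta.T)
    if comp.shape[1] == 0:
        raise ValueError("margin Jacobian leaves no residual degrees of freedom")
    middle = comp.T @ xi @ comp
    rhs = comp.T @ resid
    try:
        chol = cho_factor(middle)
    except LinAlgError as exc:
        raise ValueError(
            "singular limited-information weighting matrix; "
            "use a larger sample or fewer items"
        ) from exc
    return float(n * rhs @ cho_solve(chol, rhs))


def m2_statistic(
    form: CalibratedForm, responses, grid: ThetaGrid | None = None
) -> tuple[float, int]:
    """M2 statistic and its degrees of freedom for a fitted 2PL form."""
    X = _validate_matrix(responses)
    k = X.shape[1]
    if k != form.n_items:
        raise ValueError("responses do not match the calibrated form")
    if k < 4:
        raise ValueError("M2 for the 2PL needs at least 4 items for positive df")
    grid = grid if grid is not None else default_grid()
    pi, xi, delta = _model_margin_machinery(form, grid)
    resid = _sample_margins(X) - pi
    m2 = _quadratic_form(resid, xi, delta, X.shape[0])
    return max(m2, 0.0), m2_df(k)


def m2_independence(responses) -> tuple[float, int]:
    """M2 of the independence baseline (free proportions, zero association)."""
    X = _validate_matrix(responses)
    n, k = X.shape
    p = X.mean(axis=0)
    sets = _margin_sets(k)
    memb = _membership(sets, k)
    logp = np.log(np.clip(p, 1e-12, 1 - 1e-12))
    pi = np.exp(memb @ logp)
    inter = np.einsum("ri,ti,i->rt", memb, memb, logp)
    pi_union = np.exp((memb @ logp)[:, None] + (memb @ logp)[None, :] - inter)
    xi = pi_union - np.outer(pi, pi)
    # d pi_S / d p_i = [i in S] * prod_{j in S \ i} p_j
    delta = memb * np.exp((memb @ logp)[:, None] - memb * logp[None, :])
    resid = _sample_margins(X) - pi
    m2 = _quadratic_form(resid, xi, delta, n)
    return max(m2, 0.0), len(sets) - k


def rmsea_from_m2(m2: float, df: int, n_persons: int) -> float:
    """RMSEA analogue: sqrt(max(M2 - df, 0) / (df * (n - 1)))."""
    if df <= 0:
        raise ValueError("df must be positive")
    if n_persons <= 1:
        raise ValueError("n_persons must exceed 1")
    return float(np.sqrt(max(m2 - df, 0.0) / (df * (n_persons - 1))))


def cfi_from_m2(m2: float, df: int, m2_baseline: float, df_baseline: int) -> float:
    """CFI analogue from target and independence-baseline M2 statistics."""
    excess = max(m2 - df, 0.0)
    denom = max(m2 - df, m2_baseline - df_baseline, 0.0)
    if denom == 0.0:
        return 1.0
    return float(np.clip(1.0 - excess / denom, 0.0, 1.0))


def fit_indices(
    form: CalibratedForm, responses, grid: ThetaGrid | None = None
) -> FitIndices:
    """Convenience: M2, independence baseline, RMSEA and CFI in one pass."""
    X = _validate_matrix(responses)
    m2, df = m2_statistic(form, X, grid)
    m2_0, df_0 = m2_independence(X)
    n = X.shape[0]
    return FitIndices(
        m2=m2,
        df=df,
        rmsea=rmsea_from_m2(m2, df, n),
        cfi=cfi_from_m2(m2, df, m2_0, df_0),
        n_persons=n,
        m2_baseline=m2_0,
        df_baseline=df_0,
    )


# ---------------------------------------------------------------------------
# analytic degrees of freedom for categorical CFA

def categorical_cfa_df(
    n_indicators_per_factor, n_factors: int | None = None, correlated: bool = True
) -> int:
    """df of a simple-structure CFA with binary indicators.

    Sample statistics are T thresholds plus T(T-1)/2 polychoric
    correlations; free parameters are T loadings, T thresholds and (if
    ``correlated``) the factor correlations.  Thresholds appear in both
    counts and cancel, so df = T(T-1)/2 - T - C.
    """
    if np.isscalar(n_indicators_per_factor):
        if n_factors is None:
            raise ValueError("n_factors required with a scalar indicator count")
        counts = [int(n_indicators_per_factor)] * int(n_factors)
    else:
        counts = [int(c) for c in n_indicators_per_factor]
        if n_factors is not None and n_factors != len(counts):
            raise ValueError("n_factors disagrees with the indicator counts")
    if any(c <= 0 for c in counts) or not counts:
        raise ValueError("indicator counts must be positive")
    t = sum(counts)
    f = len(counts)
    n_corr = f * (f - 1) // 2 if correlated else 0
    stats = t + t * (t - 1) // 2
    params = t + t + n_corr
    return stats - params


def delta_df_unit_correlations(n_factors: int) -> int:
    """df gained by constraining all factor correlations to unity."""
    if n_factors < 2:
        raise ValueError("need at least two factors")
    return n_factors * (n_factors - 1) // 2
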