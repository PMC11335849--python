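"""Unidimensional 2PL estimation and derived quantities.

The two-parameter logistic model gives the probability of a correct response
as ``P(X=1 | theta) = logistic(a * (theta - b))`` with discrimination ``a``
and difficulty ``b`` (logistic metric, no 1.7 scaling constant).  Item
parameters are estimated by marginal maximum likelihood with an EM
algorithm: the latent ability is integrated out on a fixed quadrature grid
with a standard-normal prior, expected counts are accumulated in the E-step,
and each item's parameters are updated by a damped Newton ascent of the
expected complete-data log-likelihood in the M-step (a generalized EM step,
so the marginal log-likelihood never decreases).  Cycles are accelerated by
a safeguarded squared extrapolation (SQUAREM family) that falls back to the
plain double EM step whenever extrapolation does not improve the
likelihood, preserving monotone ascent.

Also provided: expected-a-posteriori (EAP) ability scores and the EAP
reliability, test characteristic curves (TCC), test information functions
(TIF), and the summed squared pairwise curve differences used to match
parallel forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .bank import ResponseData

__all__ = [
    "ThetaGrid",
    "CalibratedForm",
    "CurveSet",
    "TwoParameterLogistic",
    "default_grid",
    "fit_2pl",
    "eap_scores",
    "eap_reliability",
    "tcc",
    "tif",
    "item_probabilities",
    "curve_sqsum",
    "NonConvergenceWarning",
]


def _row_logsumexp(m: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp without scipy call overhead."""
    mx = m.max(axis=1)
    return mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))


class NonConvergenceWarning(UserWarning):
    """EM stopped at the iteration cap before meeting the tolerance."""


@dataclass(frozen=True)
class ThetaGrid:
    """Quadrature support for all integrals over the latent ability.

    ``nodes`` are strictly increasing ability values; ``weights`` are
    nonnegative and sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.nodes.ndim != 1 or self.nodes.size < 2:
            raise ValueError("grid needs at least two 1-D nodes")
        if not np.all(np.diff(self.nodes) > 0):
            raise ValueError("grid nodes must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("grid weights must be nonnegative")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"grid weights must sum to 1 (got {s})")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def spec(self) -> dict:
        """Serializable description used to detect grid mismatches."""
        return {
            "n_nodes": int(self.n_nodes),
            "lo": float(self.nodes[0]),
            "hi": float(self.nodes[-1]),
        }

    def normal_weights(self, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        """Renormalized N(mean, sd) density weights on these nodes."""
        w = norm.pdf(self.nodes, loc=mean, scale=sd)
        return w / w.sum()


def default_grid(n_nodes: int = 61, lo: float = -6.0, hi: float = 6.0) -> ThetaGrid:
    """Equally spaced nodes with renormalized standard-normal weights."""
    nodes = np.linspace(lo, hi, n_nodes)
    w = norm.pdf(nodes)
    return ThetaGrid(nodes, w / w.sum())


def grid_from_spec(spec: dict) -> ThetaGrid:
    return default_grid(int(spec["n_nodes"]), float(spec["lo"]), float(spec["hi"]))


@dataclass
class CalibratedForm:
    """Estimated 2PL parameters for one test form."""

    item_ids: list[str]
    a_hat: np.ndarray
    b_hat: np.ndarray
    loglik: float
    converged: bool
    n_persons: int
    n_iter: int = 0
    prior_mean: float = 0.0
    prior_sd: float = 1.0

    def __post_init__(self) -> None:
        self.a_hat = np.atleast_1d(np.asarray(self.a_hat, dtype=float))
        self.b_hat = np.atleast_1d(np.asarray(self.b_hat, dtype=float))
        if not (len(self.item_ids) == self.a_hat.size == self.b_hat.size):
            raise ValueError("item_ids, a_hat and b_hat must have equal length")
        if not np.all(np.isfinite(self.a_hat)):
            raise ValueError("a_hat must be finite")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass
class CurveSet:
    """One curve per form, evaluated on a shared theta grid."""

    grid: ThetaGrid
    values_per_form: list[np.ndarray]
    kind: str  # "tcc" or "tif"

    def __post_init__(self) -> None:
        if self.kind not in ("tcc", "tif"):
            raise ValueError("kind must be 'tcc' or 'tif'")
        self.values_per_form = [np.asarray(v, dtype=float) for v in self.values_per_form]
        for v in self.values_per_form:
            if v.shape != self.grid.nodes.shape:
                raise ValueError("every curve must match the grid length")


# ---------------------------------------------------------------------------
# probability helpers

def _logistic_terms(a: np.ndarray, b: np.ndarray, nodes: np.ndarray):
    """z, P, logP, log(1-P) for all items x nodes."""
    z = np.asarray(a)[:, None] * (nodes[None, :] - np.asarray(b)[:, None])
    p = expit(z)
    logp = -np.logaddexp(0.0, -z)
    log1mp = -np.logaddexp(0.0, z)
    return z, p, logp, log1mp


def item_probabilities(form: CalibratedForm, grid: ThetaGrid) -> np.ndarray:
    """Matrix of P_i(theta_q), shape (n_items, n_nodes)."""
    return expit(form.a_hat[:, None] * (grid.nodes[None, :] - form.b_hat[:, None]))


def _validate_matrix(X) -> np.ndarray:
    if isinstance(X, ResponseData):
        X = X.responses
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("responses must be a persons x items matrix")
    if not np.isin(np.unique(X), [0, 1]).all():
        raise ValueError("responses must be binary (0/1)")
    return X.astype(np.int8)


# ---------------------------------------------------------------------------
# EM internals

def _mstep_item_objective(a, c, x, rbar, nbar):
    z = a[:, None] * x[None, :] + c[:, None]
    return (rbar * (-np.logaddexp(0.0, -z)) + (nbar - rbar) * (-np.logaddexp(0.0, z))).sum(axis=1)


def _mstep_newton(a, b, x, rbar, nbar, a_bounds, b_bounds, free, n_newton=8):
    """Damped Newton ascent of the expected complete-data log-likelihood.

    Parametrized as z = a*x + c with c = -a*b; ascent per item with step
    halving so the objective never decreases, then parameters are clipped to
    the stability box.
    """
    a0, b0 = a.copy(), b.copy()
    a = a.copy()
    c = -a * b
    obj = _mstep_item_objective(a, c, x, rbar, nbar)
    obj0 = obj.copy()
    for _ in range(n_newton):
        z = a[:, None] * x[None, :] + c[:, None]
        p = expit(z)
        resid = rbar - nbar * p
        g_a = resid @ x
        g_c = resid.sum(axis=1)
        w = nbar * p * (1.0 - p)
        h_aa = w @ (x * x)
        h_ac = w @ x
        h_cc = w.sum(axis=1)
        det = h_aa * h_cc - h_ac**2
        det = np.where(det < 1e-12, 1e-12, det)
        da = (h_cc * g_a - h_ac * g_c) / det
        dc = (h_aa * g_c - h_ac * g_a) / det
        step = np.where(free, 1.0, 0.0)
        for _ in range(30):  # halving
            a_new = a + step * da
            c_new = c + step * dc
            obj_new = _mstep_item_objective(a_new, c_new, x, rbar, nbar)
            worse = obj_new < obj - 1e-12
            if not worse.any():
                break
            step = np.where(worse, step / 2.0, step)
        else:  # halving exhausted: keep the old point where still worse
            a_new = np.where(worse, a, a_new)
            c_new = np.where(worse, c, c_new)
            obj_new = np.where(worse, obj, obj_new)
        a, c, obj = a_new, c_new, obj_new
        if np.max(np.abs(np.concatenate([g_a[free], g_c[free]])), initial=0.0) < 1e-7:
            break
    a_clip = np.clip(a, *a_bounds)
    b_clip = np.clip(-c / a_clip, *b_bounds)
    # the box projection may cost likelihood; never accept a downhill move
    obj_clip = _mstep_item_objective(a_clip, -a_clip * b_clip, x, rbar, nbar)
    worse = obj_clip < obj0
    a_out = np.where(worse, a0, a_clip)
    b_out = np.where(worse, b0, b_clip)
    return a_out, b_out


class TwoParameterLogistic(BaseEstimator):
    """Marginal maximum-likelihood 2PL estimator (EM on a quadrature grid).

    Parameters
    ----------
    grid : ThetaGrid, optional
        Quadrature support; defaults to 61 equally spaced nodes on [-6, 6]
        with renormalized standard-normal weights.
    tol : float
        Convergence tolerance on the maximum absolute parameter change.
    ll_tol : float
        Secondary convergence rule: a per-cycle log-likelihood gain below
        this declares convergence even while parameters drift on a
        quasi-unidentified ridge (all derived quantities are stable there).
    max_iter : int
        Cap on EM-map evaluations; hitting it leaves ``converged_ = False``.
    a_bounds, b_bounds : tuple
        Stability boxes applied in each M-step.
    estimate_prior : bool
        If True, update the latent mean/SD each cycle from the posterior
        moments (used by anchored multigroup calibration); otherwise the
        prior stays N(0, 1).

    Attributes
    ----------
    a_, b_ : per-item estimates; loglik_ : marginal log-likelihood at the
    solution; converged_ ; n_iter_ ; prior_mean_, prior_sd_ ;
    loglik_path_ : per-cycle marginal log-likelihood (non-decreasing).
    """

    def __init__(
        self,
        grid: ThetaGrid | None = None,
        tol: float = 1e-4,
        ll_tol: float = 1e-6,
        max_iter: int = 500,
        a_bounds: tuple = (0.05, 8.0),
        b_bounds: tuple = (-8.0, 8.0),
        estimate_prior: bool = False,
    ):
        self.grid = grid
        self.tol = tol
        self.ll_tol = ll_tol
        self.max_iter = max_iter
        self.a_bounds = a_bounds
        self.b_bounds = b_bounds
        self.estimate_prior = estimate_prior

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None, item_ids=None, fixed: dict | None = None, start=None):
        """Fit the 2PL to a binary persons x items matrix.

        ``fixed`` maps item column indices to (a, b) pairs held constant
        (anchor items in multigroup calibration); ``start`` optionally warm
        starts the EM with (a, b) arrays.
        """
        if isinstance(X, ResponseData) and item_ids is None:
            item_ids = list(X.item_ids)
        X = _validate_matrix(X)
        n, k = X.shape
        if k < 2:
            raise ValueError("at least 2 items are required")
        props = X.mean(axis=0)
        degenerate = np.where((props == 0) | (props == 1))[0]
        if degenerate.size:
            ids = item_ids or [f"item{j}" for j in range(k)]
            names = [ids[j] for j in degenerate]
            raise ValueError(
                f"zero-variance items (all 0 or all 1): {names}; "
                "2PL parameters are not identified for them"
            )
        grid = self.grid if self.grid is not None else default_grid()
        x, w0 = grid.nodes, grid.weights

        patterns, counts = np.unique(X, axis=0, return_counts=True)
        patterns = patterns.astype(float)
        counts = counts.astype(float)

        # starting values: warm start, or normal-ogive style heuristics
        if start is not None:
            a = np.clip(np.asarray(start[0], dtype=float).copy(), *self.a_bounds)
            b = np.clip(np.asarray(start[1], dtype=float).copy(), *self.b_bounds)
        else:
            q = norm.ppf(np.clip(props, 1e-3, 1 - 1e-3))
            a = np.full(k, 1.0)
            b = np.clip(-q, -4, 4)
        free = np.ones(k, dtype=bool)
        if fixed:
            for j, (fa, fb) in fixed.items():
                a[j], b[j] = fa, fb
                free[j] = False

        k_par = k  # items
        fixed_a = a.copy()
        fixed_b = b.copy()

        def pack(a, b, mean, sd):
            v = np.concatenate([a, b])
            if self.estimate_prior:
                v = np.concatenate([v, [mean, sd]])
            return v

        def unpack(v):
            a = v[:k_par]
            b = v[k_par : 2 * k_par]
            if self.estimate_prior:
                mean, sd = v[-2], v[-1]
            else:
                mean, sd = 0.0, 1.0
            return a, b, mean, sd

        def project(v):
            """Clip to the stability box and restore fixed/anchored entries."""
            a, b, mean, sd = unpack(v)
            a = np.clip(a, *self.a_bounds)
            b = np.clip(b, *self.b_bounds)
            a = np.where(free, a, fixed_a)
            b = np.where(free, b, fixed_b)
            return pack(a, b, float(np.clip(mean, -4, 4)), float(max(sd, 1e-3)))

        n_em = 0

        def em_map(v):
            """One EM cycle; returns the updated vector and the log-likelihood at v."""
            nonlocal n_em
            n_em += 1
            a, b, mean, sd = unpack(v)
            w = w0 if not self.estimate_prior else grid.normal_weights(mean, sd)
            _, p, logp, log1mp = _logistic_terms(a, b, x)
            ll_mat = patterns @ logp + (1.0 - patterns) @ log1mp + np.log(w)[None, :]
            lse = _row_logsumexp(ll_mat)
            loglik = float(counts @ lse)
            post = np.exp(ll_mat - lse[:, None])
            nbar = counts @ post  # expected persons per node
            rbar = (patterns * counts[:, None]).T @ post  # expected correct per item/node
            a_new, b_new = _mstep_newton(
                a, b, x, rbar, nbar, self.a_bounds, self.b_bounds, free
            )
            if self.estimate_prior:
                total = nbar.sum()
                mean = float(nbar @ x / total)
                sd = max(float(np.sqrt(nbar @ (x - mean) ** 2 / total)), 1e-3)
            return project(pack(a_new, b_new, mean, sd)), loglik

        # EM with safeguarded squared (SQUAREM-style) acceleration: each cycle
        # takes two EM steps, extrapolates, and keeps the plain double step
        # whenever the extrapolated point does not improve the marginal
        # log-likelihood, so the recorded path stays non-decreasing.
        v0 = pack(a, b, 0.0, 1.0)
        loglik_path: list[float] = []
        converged = False
        delta = np.inf
        while n_em < self.max_iter:
            v1, ll0 = em_map(v0)
            loglik_path.append(ll0)
            delta = float(np.max(np.abs(v1 - v0)))
            if delta < self.tol:
                v0 = v1
                converged = True
                break
            if n_em >= self.max_iter:
                v0 = v1
                break
            v2, ll1 = em_map(v1)
            loglik_path.append(ll1)
            delta = float(np.max(np.abs(v2 - v1)))
            # converged when parameters settle, or when the likelihood is flat
            # (quasi-unidentified ridges let parameters drift at numerically
            # constant likelihood; every downstream quantity is stable there)
            if delta < self.tol or ll1 - ll0 < self.ll_tol:
                v0 = v2
                converged = True
                break
            r = v1 - v0
            q = v2 - v1 - r
            qn = float(np.linalg.norm(q))
            if qn < 1e-12 or n_em >= self.max_iter:
                v0 = v2
                continue
            alpha = -max(float(np.linalg.norm(r)) / qn, 1.0)
            v_acc = project(v0 - 2.0 * alpha * r + alpha**2 * q)
            v3, ll_acc = em_map(v_acc)  # stabilization EM step at the candidate
            if ll_acc >= ll1:
                loglik_path.append(ll_acc)
                v0 = v3
            else:
                v0 = v2
        # final log-likelihood at the solution
        a, b, mean, sd = unpack(v0)
        w = w0 if not self.estimate_prior else grid.normal_weights(mean, sd)
        _, _, logp, log1mp = _logistic_terms(a, b, x)
        ll_mat = patterns @ logp + (1.0 - patterns) @ log1mp + np.log(w)[None, :]
        loglik_path.append(float(counts @ _row_logsumexp(ll_mat)))
        it = n_em
        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} cycles "
                f"(last max parameter change {delta:.2e})",
                NonConvergenceWarning,
            )
        if np.any(a <= self.a_bounds[0]) or np.any(a >= self.a_bounds[1]):
            warnings.warn("discrimination estimate at stability bound", NonConvergenceWarning)

        self.item_ids_ = list(item_ids) if item_ids is not None else [f"item{j}" for j in range(k)]
        self.a_, self.b_ = a, b
        self.loglik_ = loglik_path[-1]
        self.loglik_path_ = np.asarray(loglik_path)
        self.converged_ = converged
        self.n_iter_ = it
        self.prior_mean_, self.prior_sd_ = mean, sd
        self.grid_ = grid
        self.n_persons_ = n
        return self

    # -- derived quantities -------------------------------------------------
    def form_(self) -> CalibratedForm:
        return CalibratedForm(
            item_ids=self.item_ids_,
            a_hat=self.a_,
            b_hat=self.b_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_persons=self.n_persons_,
            n_iter=self.n_iter_,
            prior_mean=self.prior_mean_,
            prior_sd=self.prior_sd_,
        )

    def transform(self, X):
        """EAP ability scores (posterior means), shape (n_persons,)."""
        scores, _ = eap_scores(self.form_(), X, self.grid_)
        return scores

    def score(self, X, y=None):
        """Mean marginal log-likelihood per person of new data."""
        X = _validate_matrix(X)
        grid = self.grid_
        w = grid.normal_weights(self.prior_mean_, self.prior_sd_)
        _, _, logp, log1mp = _logistic_terms(self.a_, self.b_, grid.nodes)
        ll = X @ logp + (1 - X) @ log1mp + np.log(w)[None, :]
        return float(np.mean(_row_logsumexp(ll)))


def fit_2pl(
    responses,
    grid: ThetaGrid | None = None,
    item_ids=None,
    tol: float = 1e-4,
    max_iter: int = 500,
    **kwargs,
) -> CalibratedForm:
    """Functional wrapper around :class:`TwoParameterLogistic`."""
    est = TwoParameterLogistic(grid=grid, tol=tol, max_iter=max_iter, **kwargs)
    est.fit(responses, item_ids=item_ids)
    return est.form_()


# ---------------------------------------------------------------------------
# EAP scores and reliability

def eap_scores(form: CalibratedForm, responses, grid: ThetaGrid):
    """Posterior mean and SD of theta per person under the form's prior.

    Returns (scores, posterior_sds), each shape (n_persons,).
    """
    if isinstance(responses, ResponseData):
        if list(responses.item_ids) != list(form.item_ids):
            raise ValueError("response columns do not match the calibrated form's items")
        X = responses.responses
    else:
        X = responses
    X = _validate_matrix(X)
    if X.shape[1] != form.n_items:
        raise ValueError(
            f"responses have {X.shape[1]} columns but the form has {form.n_items} items"
        )
    x = grid.nodes
    w = grid.normal_weights(form.prior_mean, form.prior_sd)
    _, _, logp, log1mp = _logistic_terms(form.a_hat, form.b_hat, x)
    ll = X @ logp + (1 - X) @ log1mp + np.log(w)[None, :]
    post = np.exp(ll - _row_logsumexp(ll)[:, None])
    scores = post @ x
    second = post @ (x**2)
    var = np.maximum(second - scores**2, 0.0)
    return scores, np.sqrt(var)


def eap_reliability(scores: np.ndarray, posterior_sds: np.ndarray) -> float:
    """EAP (empirical) reliability: var(EAP) / (var(EAP) + mean(SE^2))."""
    scores = np.asarray(scores, dtype=float)
    posterior_sds = np.asarray(posterior_sds, dtype=float)
    if scores.size < 2:
        raise ValueError("at least two persons are required")
    v = float(np.var(scores, ddof=1))
    err = float(np.mean(posterior_sds**2))
    if v == 0.0:
        if err == 0.0:
            return 1.0
        warnings.warn("EAP scores have zero variance; reliability set to 0")
        return 0.0
    return v / (v + err)


# ---------------------------------------------------------------------------
# curves

def tcc(form: CalibratedForm, grid: ThetaGrid) -> np.ndarray:
    """Test characteristic curve: expected raw score at each grid node."""
    return item_probabilities(form, grid).sum(axis=0)


def tif(form: CalibratedForm, grid: ThetaGrid) -> np.ndarray:
    """Test information function: sum of a_i^2 P_i (1 - P_i) at each node."""
    p = item_probabilities(form, grid)
    return (form.a_hat[:, None] ** 2 * p * (1.0 - p)).sum(axis=0)


def curve_set(forms: list[CalibratedForm], grid: ThetaGrid, kind: str) -> CurveSet:
    fn = {"tcc": tcc, "tif": tif}[kind]
    return CurveSet(grid, [fn(f, grid) for f in forms], kind)


def curve_sqsum(curves: CurveSet) -> float:
    """Summed squared differences over all unordered form pairs and nodes.

    Zero iff all curves coincide on the grid; this is the quantity whose
    thresholds govern equal-difficulty (TCC) and equal-precision (TIF)
    matching of parallel forms.
    """
    vals = curves.values_per_form
    if len(vals) < 2:
        raise ValueError("curve_sqsum needs at least two forms")
    total = 0.0
    for j in range(len(vals)):
        for l in range(j + 1, len(vals)):
            d = vals[j] - vals[l]
            total += float(d @ d)
    return total
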