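"""Partial credit model: probabilities, item calibration, person measurement.

The partial credit model (PCM) is the unrestricted Rasch model for ordered
polytomous responses.  For an item with categories 0..m and thresholds
tau_1..tau_m, the probability of category x given person location theta is

    P(X = x | theta) ∝ exp( sum_{k<=x} (theta - tau_k) ),

the empty sum for x = 0 being zero.  A threshold tau_k is the point on the
latent continuum where categories k-1 and k are equally likely; the item
location delta is the mean of the thresholds.

Calibration uses marginal maximum likelihood: an EM algorithm with
Gauss-Hermite quadrature over a latent normal whose mean and variance are
re-estimated each cycle.  The latent-scale translation indeterminacy is
resolved by centring item locations to mean zero after the fit.  Person
measurement offers maximum likelihood (MLE) and Warm's weighted likelihood
(WLE); WLE is finite at extreme raw scores and is the default everywhere
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.special import logsumexp

MISSING = -1  # internal missing marker in response matrices

DEFAULT_SEED = 20140201


# ---------------------------------------------------------------------------
# Model probabilities and moments
# ---------------------------------------------------------------------------

def pcm_category_probs(theta, thresholds) -> np.ndarray:
    """Category probabilities of the PCM.

    Parameters
    ----------
    theta : float or array of shape (n,)
        Person location(s) in logits.
    thresholds : array of shape (m,)
        Item thresholds tau_1..tau_m in logits (unrestricted order).

    Returns
    -------
    probs : array of shape (..., m+1)
        Probabilities over categories 0..m; rows sum to 1.
    """
    tau = np.asarray(thresholds, dtype=float)
    th = np.asarray(theta, dtype=float)
    m = tau.shape[-1]
    x = np.arange(m + 1)
    # eta_x = x*theta - cumsum(tau)_x, eta_0 = 0
    ctau = np.concatenate([[0.0], np.cumsum(tau)])
    eta = th[..., None] * x - ctau
    eta -= eta.max(axis=-1, keepdims=True)
    w = np.exp(eta)
    return w / w.sum(axis=-1, keepdims=True)


def pcm_expected_score(theta, thresholds) -> np.ndarray | float:
    """Expected category E[X | theta]; strictly increasing in theta."""
    p = pcm_category_probs(theta, thresholds)
    x = np.arange(p.shape[-1])
    out = (p * x).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def pcm_moments(theta, thresholds, order: int = 2):
    """Central moments (E, var[, mu3[, mu4]]) of the category distribution."""
    p = pcm_category_probs(theta, thresholds)
    x = np.arange(p.shape[-1])
    e = (p * x).sum(axis=-1)
    d = x - e[..., None]
    out = [e, (p * d**2).sum(axis=-1)]
    if order >= 3:
        out.append((p * d**3).sum(axis=-1))
    if order >= 4:
        out.append((p * d**4).sum(axis=-1))
    return tuple(out)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ItemCalibration:
    """Calibrated item: thresholds, location (their mean) and standard errors."""

    item_id: str
    thresholds: np.ndarray
    se_thresholds: np.ndarray | None = None
    se_location: float | None = None
    null_categories: tuple[int, ...] = ()

    @property
    def location(self) -> float:
        return float(np.mean(self.thresholds))

    def ordered(self) -> bool:
        t = np.asarray(self.thresholds)
        return bool(np.all(np.diff(t) > 0))


@dataclass
class PersonEstimate:
    respondent_id: object
    theta: float
    se: float
    method: str
    raw_score: int
    max_score: int
    extreme_flag: bool


@dataclass
class ConvergenceReport:
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    latent_mean: float = 0.0
    latent_sd: float = 1.0
    warnings: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


class CalibrationError(RuntimeError):
    """Raised when the EM algorithm fails to converge."""

    def __init__(self, msg, report=None):
        super().__init__(msg)
        self.report = report


# ---------------------------------------------------------------------------
# Marginal maximum likelihood calibration (EM + Gauss-Hermite)
# ---------------------------------------------------------------------------

def _log_prob_table(taus: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """log P(x | node) for every item: shape (n_items, n_nodes, m+1)."""
    n_items, m = taus.shape
    x = np.arange(m + 1)
    ctau = np.concatenate([np.zeros((n_items, 1)), np.cumsum(taus, axis=1)], axis=1)
    eta = nodes[None, :, None] * x[None, None, :] - ctau[:, None, :]
    return eta - logsumexp(eta, axis=2, keepdims=True)


def _init_thresholds(data: np.ndarray, n_cat: int) -> np.ndarray:
    """Start values from adjacent-category log odds of the margins."""
    n_items = data.shape[1]
    taus = np.zeros((n_items, n_cat - 1))
    for i in range(n_items):
        col = data[:, i]
        counts = np.bincount(col[col >= 0], minlength=n_cat).astype(float) + 0.5
        taus[i] = np.log(counts[:-1] / counts[1:])
    return taus


def calibrate_items(
    data: np.ndarray,
    item_ids: list[str] | None = None,
    n_cat: int = 5,
    n_quad: int = 49,
    max_iter: int = 500,
    tol: float = 1e-6,
    compute_se: bool = True,
) -> tuple[list[ItemCalibration], ConvergenceReport]:
    """Calibrate PCM items by marginal maximum likelihood.

    Parameters
    ----------
    data : int array (n_persons, n_items)
        Categories 0..n_cat-1; ``MISSING`` (-1) marks unobserved cells.
        Rows with no observed response are dropped.
    n_quad : int
        Gauss-Hermite nodes for the latent normal (re-centred adaptively).
    tol : float
        Absolute marginal log-likelihood change declaring convergence.

    Returns
    -------
    (calibrations, report)
        Item locations are centred (mean location = 0).  Items with a
        response category never observed are flagged (structural zero) and
        a warning is recorded; calibration still proceeds.
    """
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need a persons x items matrix with >= 2 items")
    keep = (data >= 0).any(axis=1)
    data = data[keep]
    n, n_items = data.shape
    if item_ids is None:
        item_ids = [f"item{i + 1}" for i in range(n_items)]

    warnings_: list[str] = []
    null_cats: dict[int, tuple[int, ...]] = {}
    for i in range(n_items):
        col = data[:, i]
        counts = np.bincount(col[col >= 0], minlength=n_cat)
        zeros = tuple(int(c) for c in np.nonzero(counts == 0)[0])
        if zeros:
            null_cats[i] = zeros
            warnings_.append(
                f"item {item_ids[i]}: no observations in categories {zeros} "
                "(structural zero); estimates for adjacent thresholds are weakly identified"
            )

    # probabilist's Hermite quadrature: nodes ~ N(0,1) after weighting
    z_nodes, z_w = hermegauss(n_quad)
    z_logw = np.log(z_w / np.sqrt(2 * np.pi))

    taus = _init_thresholds(data, n_cat)
    mu, sigma = 0.0, 2.0
    obs = data >= 0
    dat0 = np.where(obs, data, 0)

    loglik_trace: list[float] = []
    converged = False
    x_ge = np.arange(1, n_cat)  # threshold indices 1..m

    for it in range(max_iter):
        nodes = mu + sigma * z_nodes
        logw = z_logw  # importance weights cancel: nodes ARE the prior grid
        logp = _log_prob_table(taus, nodes)  # (I, Q, C)

        # person-node log likelihood
        ll_nq = np.zeros((n, n_quad))
        for i in range(n_items):
            m_i = obs[:, i]
            ll_nq[m_i] += logp[i][:, dat0[m_i, i]].T
        ll_nq += logw
        norm = logsumexp(ll_nq, axis=1)
        loglik = float(norm.sum())
        W = np.exp(ll_nq - norm[:, None])  # posterior weights (n, Q)

        loglik_trace.append(loglik)
        if it > 0 and abs(loglik_trace[-1] - loglik_trace[-2]) < tol:
            converged = True
            break

        # latent distribution update
        e1 = W @ nodes
        e2 = W @ nodes**2
        mu = float(e1.mean())
        sigma = float(np.sqrt(max(e2.mean() - mu**2, 1e-6)))

        # M-step: one Newton step per item on expected-count tables
        p = np.exp(logp)  # (I, Q, C)
        p_ge = np.cumsum(p[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]  # P(X>=k), (I,Q,m)
        for i in range(n_items):
            m_i = obs[:, i]
            r = np.zeros((n_cat, n_quad))
            np.add.at(r, dat0[m_i, i], W[m_i])
            n_q = r.sum(axis=0)  # (Q,)
            c_k = np.cumsum(r[::-1], axis=0)[::-1][1:]  # counts with x>=k, (m, Q)
            pg = p_ge[i]  # (Q, m)
            g = (pg * n_q[:, None]).sum(axis=0) - c_k.sum(axis=1)
            # H_kl = sum_q n_q (P(>=k)P(>=l) - P(>=max(k,l)))
            pmax = np.minimum(pg[:, :, None], pg[:, None, :])  # P(>=max(k,l))
            H = np.einsum("q,qkl->kl", n_q, pg[:, :, None] * pg[:, None, :] - pmax)
            try:
                step = np.linalg.solve(H - 1e-8 * np.eye(n_cat - 1), g)
            except np.linalg.LinAlgError:
                step = g / (np.diag(H) - 1e-6)
            nrm = np.linalg.norm(step)
            if nrm > 2.0:
                step *= 2.0 / nrm
            taus[i] = np.clip(taus[i] - step, -12, 12)

    report = ConvergenceReport(
        converged=converged,
        n_iter=len(loglik_trace),
        loglik_trace=loglik_trace,
        latent_mean=mu,
        latent_sd=sigma,
        warnings=warnings_,
    )
    if not converged:
        raise CalibrationError(
            f"EM did not converge in {max_iter} iterations", report=report
        )

    # centre item locations (translation identification)
    shift = float(np.mean(taus))
    taus -= shift
    report.latent_mean = mu - shift

    se_tau = np.full_like(taus, np.nan)
    se_loc = np.full(n_items, np.nan)
    if compute_se:
        se_tau, se_loc = _mml_standard_errors(data, taus, report, n_quad, n_cat)

    cals = [
        ItemCalibration(
            item_id=item_ids[i],
            thresholds=taus[i].copy(),
            se_thresholds=se_tau[i],
            se_location=float(se_loc[i]),
            null_categories=null_cats.get(i, ()),
        )
        for i in range(n_items)
    ]
    return cals, report


def _mml_standard_errors(data, taus, report, n_quad, n_cat):
    """SEs from the empirical cross-product of marginal score vectors."""
    n, n_items = data.shape
    m = n_cat - 1
    z_nodes, z_w = hermegauss(n_quad)
    nodes = report.latent_mean + report.latent_sd * z_nodes
    logw = np.log(z_w / np.sqrt(2 * np.pi))
    logp = _log_prob_table(taus, nodes)
    obs = data >= 0
    dat0 = np.where(obs, data, 0)
    ll_nq = np.zeros((n, n_quad))
    for i in range(n_items):
        m_i = obs[:, i]
        ll_nq[m_i] += logp[i][:, dat0[m_i, i]].T
    ll_nq += logw
    W = np.exp(ll_nq - logsumexp(ll_nq, axis=1, keepdims=True))

    p = np.exp(logp)
    p_ge = np.cumsum(p[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]  # (I, Q, m)
    S = np.zeros((n, n_items * m))
    for i in range(n_items):
        m_i = obs[:, i]
        post_ge = W[m_i] @ p_ge[i]  # (n_i, m) posterior E[P(X>=k)]
        ind = (dat0[m_i, i][:, None] >= np.arange(1, n_cat)).astype(float)
        S[m_i, i * m:(i + 1) * m] = post_ge - ind
    info = S.T @ S
    try:
        cov = np.linalg.inv(info + 1e-10 * np.eye(info.shape[0]))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se_tau = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(n_items, m)
    se_loc = np.empty(n_items)
    for i in range(n_items):
        block = cov[i * m:(i + 1) * m, i * m:(i + 1) * m]
        se_loc[i] = math.sqrt(max(block.sum() / m**2, 0.0))
    return se_tau, se_loc


# ---------------------------------------------------------------------------
# Person measurement
# ---------------------------------------------------------------------------

def _score_info(theta: float, taus: list[np.ndarray], order: int = 2):
    """Sum of expected scores / information terms across items."""
    e = v = j = 0.0
    for t in taus:
        mom = pcm_moments(theta, t, order=order)
        e += float(mom[0])
        v += float(mom[1])
        if order >= 3:
            j += float(mom[2])
    return (e, v, j) if order >= 3 else (e, v)


def _solve_theta(raw: int, taus: list[np.ndarray], method: str, lo=-15.0, hi=15.0):
    if method == "MLE":
        def f(th):
            e, _ = _score_info(th, taus, order=2)
            return raw - e
    else:  # WLE: score eq. + I'/(2I), I' = sum of third central moments
        def f(th):
            e, v, j = _score_info(th, taus, order=3)
            return raw - e + j / (2.0 * max(v, 1e-300))
    flo, fhi = f(lo), f(hi)
    if flo <= 0:
        return lo
    if fhi >= 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10)


def estimate_person(
    responses: np.ndarray,
    calibrations: list[ItemCalibration],
    method: str = "WLE",
    respondent_id=None,
) -> PersonEstimate:
    """Measure one person given calibrated items.

    ``responses`` uses internal 0..m coding with MISSING (-1) allowed; only
    observed items enter the likelihood.  MLE is infinite at extreme raw
    scores (returned clamped at the search bound with ``extreme_flag``);
    WLE stays finite.
    """
    responses = np.asarray(responses)
    obs = responses >= 0
    if not obs.any():
        raise ValueError("all responses missing; person not measurable")
    taus = [np.asarray(c.thresholds, float) for c, o in zip(calibrations, obs) if o]
    raw = int(responses[obs].sum())
    max_score = int(sum(t.shape[0] for t in taus))
    theta = _solve_theta(raw, taus, method)
    _, info = _score_info(theta, taus, order=2)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    return PersonEstimate(
        respondent_id=respondent_id,
        theta=float(theta),
        se=float(se),
        method=method,
        raw_score=raw,
        max_score=max_score,
        extreme_flag=raw in (0, max_score),
    )


def estimate_persons(
    data: np.ndarray,
    calibrations: list[ItemCalibration],
    method: str = "WLE",
    respondent_ids=None,
) -> list[PersonEstimate]:
    """Measure every row of a response matrix.

    Exploits raw-score sufficiency: rows sharing a missingness pattern and a
    raw score share one root-finding solve.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if respondent_ids is None:
        respondent_ids = list(range(n))
    obs = data >= 0
    raws = np.where(obs, data, 0).sum(axis=1)
    pat_keys = [o.tobytes() for o in obs]
    cache: dict[tuple[bytes, int], tuple[float, float, int]] = {}
    out: list[PersonEstimate] = []
    for r in range(n):
        if not obs[r].any():
            raise ValueError(f"row {r}: all responses missing")
        key = (pat_keys[r], int(raws[r]))
        if key not in cache:
            taus = [np.asarray(c.thresholds, float)
                    for c, o in zip(calibrations, obs[r]) if o]
            theta = _solve_theta(int(raws[r]), taus, method)
            _, info = _score_info(theta, taus, order=2)
            se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
            cache[key] = (theta, se, int(sum(t.shape[0] for t in taus)))
        theta, se, mx = cache[key]
        out.append(PersonEstimate(
            respondent_id=respondent_ids[r], theta=theta, se=se, method=method,
            raw_score=int(raws[r]), max_score=mx,
            extreme_flag=int(raws[r]) in (0, mx),
        ))
    return out
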