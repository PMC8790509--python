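"""Concurrent multiple-group MML-EM calibration for IRT and testlet models.

The estimator maximises the marginal likelihood of a stacked two-group
response matrix (NEAT design) over item parameters, per-testlet
random-effect variances (testlet families only) and the new group's ability
mean and variance; the base group is fixed at N(0, 1) for identification.
Anchor items occupy a single shared column, so concurrent calibration links
the two forms without a post-hoc transformation.

Latent-trait integration uses a fixed rectangular grid for theta.  For the
testlet families the random effect is written as ``gamma = s_d * z`` with
``z ~ N(0,1)`` integrated on a Gauss-Hermite grid; because every item loads
on theta plus at most one testlet effect (with the same slope), the
conditional likelihood factors over testlets given theta and the
integration cost is (theta nodes) x (z nodes) per testlet rather than
exponential in the number of testlets — the standard bifactor dimension
reduction.

The M-step performs batched Fisher-scoring updates of all items at once
(one conditional-maximisation pass per EM cycle, with per-item step halving
so the expected complete-data log-likelihood never decreases), then a
bounded 1-D maximisation of each testlet's ``s_d`` and a closed-form moment
update of the new group's prior.  This makes the whole procedure a
generalised ECM whose marginal log-likelihood is non-decreasing across
cycles up to quadrature round-off.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .models import (
    MISSING,
    TESTLET_FAMILIES,
    DichotomousItemParams,
    ItemParams,
    PolytomousItemParams,
)
from .simulate import FormPair, ResponseMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12
_LOGA_BOUNDS = (np.log(0.05), np.log(8.0))
_B_BOUND = 7.0


@dataclass(frozen=True)
class CalibrationConfig:
    """Estimation settings for :class:`ConcurrentCalibrator`."""

    model_family: str = "2PLM"
    quad_points_theta: int = 21
    theta_range: tuple[float, float] = (-5.0, 5.0)
    quad_points_testlet: int = 11
    convergence_tol: float = 1e-4
    max_cycles: int = 500
    estimate_new_group: bool = True
    s_max: float = 3.0

    def __post_init__(self) -> None:
        if self.quad_points_theta < 5 or self.quad_points_testlet < 5:
            raise ValueError("quadrature grids need at least 5 points")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class CalibrationResult:
    """Fitted parameters and diagnostics of one concurrent calibration."""

    model_family: str
    item_estimates: dict[str, ItemParams]
    testlet_variances: dict[str, float]
    group_params: dict[str, float]  # new-group mean/var; base fixed at (0, 1)
    log_likelihood: float
    n_cycles: int
    converged: bool
    excluded_items: tuple[str, ...] = ()

    def to_json(self) -> str:
        def enc(it: ItemParams) -> dict:
            d = {"item_id": it.item_id, "a": it.a, "testlet_id": it.testlet_id}
            if isinstance(it, DichotomousItemParams):
                d["b"] = it.b
            else:
                d["boundaries"] = list(it.boundaries)
            return d

        payload = {
            "model_family": self.model_family,
            "items": [enc(v) for v in self.item_estimates.values()],
            "testlet_variances": self.testlet_variances,
            "group_params": self.group_params,
            "log_likelihood": self.log_likelihood,
            "n_cycles": self.n_cycles,
            "converged": self.converged,
            "excluded_items": list(self.excluded_items),
        }
        return json.dumps(payload, indent=2)


def _as_testlet_map(
    structure: FormPair | Mapping[str, str] | None,
) -> dict[str, str]:
    """item_id -> testlet_id map from either a FormPair or a plain mapping."""
    if structure is None:
        return {}
    if isinstance(structure, FormPair):
        out: dict[str, str] = {}
        for spec in structure.all_testlets().values():
            for iid in spec.item_ids:
                out[iid] = spec.testlet_id
        return out
    return {k: v for k, v in structure.items() if v is not None}


# ---------------------------------------------------------------------------
# Probability tables and their derivatives (graded parameterisation; a
# dichotomous item is the K=2 special case with a single boundary).
# ---------------------------------------------------------------------------

def _unpack(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(J, npar) packed params -> (a, boundaries); boundaries cumulative."""
    a = np.exp(p[:, 0])
    ncat_m1 = p.shape[1] - 1
    B = np.empty((p.shape[0], ncat_m1))
    B[:, 0] = p[:, 1]
    for x in range(1, ncat_m1):
        B[:, x] = B[:, x - 1] + np.exp(p[:, x + 1])
    return a, B


def _pack(a: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = np.empty((len(a), 1 + B.shape[1]))
    p[:, 0] = np.log(a)
    p[:, 1] = B[:, 0]
    if B.shape[1] > 1:
        p[:, 2:] = np.log(np.maximum(np.diff(B, axis=1), 1e-4))
    return p


def _cat_probs(a: np.ndarray, B: np.ndarray, TT: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (J, C, N) from nodes TT (J, N)."""
    eta = a[:, None, None] * (TT[:, None, :] - B[:, :, None])
    Pstar = expit(eta)
    J, _, N = Pstar.shape
    full = np.concatenate(
        [np.ones((J, 1, N)), Pstar, np.zeros((J, 1, N))], axis=1
    )
    return full[:, :-1] - full[:, 1:]


def _expected_loglik(p: np.ndarray, TT: np.ndarray, R: np.ndarray) -> np.ndarray:
    a, B = _unpack(p)
    P = _cat_probs(a, B, TT)
    return np.einsum("jcn,jcn->j", R, np.log(np.clip(P, _EPS, None)))


def _fisher_step(p: np.ndarray, TT: np.ndarray, R: np.ndarray) -> np.ndarray:
    """One batched Fisher-scoring update with per-item step halving.

    ``TT`` (J, N) effective-trait nodes, ``R`` (J, C, N) expected response
    counts.  Guarantees the per-item expected log-likelihood does not
    decrease (items that cannot improve keep their parameters).
    """
    J, npar = p.shape
    C = R.shape[1]
    a, B = _unpack(p)
    eta = a[:, None, None] * (TT[:, None, :] - B[:, :, None])  # (J, C-1, N)
    Pstar = expit(eta)
    q = Pstar * (1.0 - Pstar)

    deta = np.zeros((J, C - 1, npar, TT.shape[1]))
    deta[:, :, 0, :] = eta
    deta[:, :, 1, :] = -a[:, None, None]
    for y in range(2, npar):
        # increment exp(p_y) shifts boundaries with index >= y-1
        inc = np.exp(p[:, y])
        deta[:, y - 1:, y, :] = (-a * inc)[:, None, None]
    dPstar = q[:, :, None, :] * deta
    N = TT.shape[1]
    zero = np.zeros((J, 1, npar, N))
    dfull = np.concatenate([zero, dPstar, zero], axis=1)
    dP = dfull[:, :-1] - dfull[:, 1:]  # (J, C, npar, N)

    full = np.concatenate(
        [np.ones((J, 1, N)), Pstar, np.zeros((J, 1, N))], axis=1
    )
    P = np.clip(full[:, :-1] - full[:, 1:], _EPS, None)
    nT = R.sum(axis=1)  # (J, N)

    grad = np.einsum("jcn,jcpn->jp", R / P, dP)
    w = nT[:, None, :] / P
    info = np.einsum("jcpn,jcqn->jpq", dP * w[:, :, None, :], dP)
    info += 1e-8 * np.eye(npar)
    try:
        step = np.linalg.solve(info, grad[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        step = grad / np.einsum("jpp->jp", info)

    e_old = _expected_loglik(p, TT, R)
    alpha = np.ones(J)
    p_new = p.copy()
    remaining = np.ones(J, dtype=bool)
    for _ in range(8):
        if not remaining.any():
            break
        trial = p + alpha[:, None] * step
        trial[:, 0] = np.clip(trial[:, 0], *_LOGA_BOUNDS)
        trial[:, 1] = np.clip(trial[:, 1], -_B_BOUND, _B_BOUND)
        if npar > 2:
            trial[:, 2:] = np.clip(trial[:, 2:], np.log(1e-3), np.log(8.0))
        e_new = _expected_loglik(trial, TT, R)
        ok = remaining & (e_new >= e_old - 1e-10)
        p_new[ok] = trial[ok]
        remaining &= ~ok
        alpha[remaining] *= 0.5
    return p_new


# ---------------------------------------------------------------------------
# The EM engine
# ---------------------------------------------------------------------------

class _Engine:
    """Precomputed data layout + E-step/M-step kernels for one matrix."""

    def __init__(
        self,
        matrix: ResponseMatrix,
        testlet_map: Mapping[str, str],
        config: CalibrationConfig,
        use_testlets: bool,
    ) -> None:
        self.config = config
        codes = np.asarray(matrix.codes)
        self.item_ids = list(matrix.item_ids)
        observed = codes != MISSING
        if not observed.any():
            raise ValueError("response matrix contains no observed responses")

        # items with zero observed response variance cannot be calibrated
        self.excluded: list[str] = []
        keep = []
        for j, iid in enumerate(self.item_ids):
            vals = codes[observed[:, j], j]
            if len(vals) == 0 or np.all(vals == vals[0]):
                self.excluded.append(iid)
                logger.warning("item %s has zero observed variance; excluded from fit", iid)
            else:
                keep.append(j)
        self.keep_ids = [self.item_ids[j] for j in keep]
        codes = codes[:, keep]
        observed = observed[:, keep]

        self.codes = codes
        self.n, self.J = codes.shape
        self.C = int(codes[observed].max()) + 1
        if self.C < 2:
            raise ValueError("need at least two observed response categories")

        self.group_is_new = np.asarray(matrix.groups) == "new"
        self.has_new = bool(self.group_is_new.any())

        # testlet structure over kept columns; a testlet needs at least two
        # items for its random-effect variance to be identified — singleton
        # testlets are treated as locally independent (sigma2 fixed at 0)
        tmap = dict(testlet_map) if use_testlets else {}
        counts: dict[str, int] = {}
        for iid in self.keep_ids:
            if iid in tmap:
                counts[tmap[iid]] = counts.get(tmap[iid], 0) + 1
        for tid, c in counts.items():
            if c < 2:
                logger.info("testlet %s has a single calibrated item; treated as independent", tid)
        tids = sorted(t for t, c in counts.items() if c >= 2)
        self.testlet_ids = tids
        self.t_cols: list[np.ndarray] = [
            np.array([k for k, iid in enumerate(self.keep_ids) if tmap.get(iid) == tid])
            for tid in tids
        ]
        in_testlet = np.zeros(self.J, dtype=bool)
        for cols in self.t_cols:
            in_testlet[cols] = True
        self.ind_cols = np.where(~in_testlet)[0]

        # quadrature grids
        K = config.quad_points_theta
        lo, hi = config.theta_range
        self.theta = np.linspace(lo, hi, K)
        self.dtheta = self.theta[1] - self.theta[0]
        z, wz = np.polynomial.hermite_e.hermegauss(config.quad_points_testlet)
        self.z = z
        self.wz = wz / np.sqrt(2.0 * np.pi)

        # indicator tensor (n, J, C): 1 where y_ij == c, 0 elsewhere/missing
        ind = np.zeros((self.n, self.J, self.C))
        ii, jj = np.nonzero(observed)
        ind[ii, jj, codes[ii, jj]] = 1.0
        self.I_ind = ind[:, self.ind_cols, :].reshape(self.n, -1)
        self.I_t = [ind[:, cols, :].reshape(self.n, -1) for cols in self.t_cols]
        self._ind_flat_cols = self.ind_cols
        del ind

        # column index -> packed-parameter row
        self.npar = 1 + (self.C - 1)

    # -- parameter helpers ---------------------------------------------------

    def start_values(self) -> tuple[np.ndarray, np.ndarray, float, float]:
        """(packed item params (J, npar), s (T,), mu_new, var_new)."""
        p = np.zeros((self.J, self.npar))
        obs = self.codes != MISSING
        for j in range(self.J):
            vals = self.codes[obs[:, j], j]
            # cumulative share scoring >= x  ->  boundary at theta = 0, a = 1
            qs = np.array([(vals >= x).mean() for x in range(1, self.C)])
            qs = np.clip(qs, 0.02, 0.98)
            b = -np.log(qs / (1.0 - qs))
            b = np.maximum.accumulate(b)
            b += 0.05 * np.arange(self.C - 1)  # enforce strict increase
            p[j] = _pack(np.array([1.0]), b[None, :])[0]
        s = np.full(len(self.testlet_ids), np.sqrt(0.5))
        return p, s, 0.0, 1.0

    def _prior_logw(self, mu: float, var: float) -> np.ndarray:
        """(n, K) log prior weights per person (rectangular rule, unnormalised)."""
        sd = np.sqrt(var)
        logw_base = norm.logpdf(self.theta, 0.0, 1.0) + np.log(self.dtheta)
        logw_new = norm.logpdf(self.theta, mu, sd) + np.log(self.dtheta)
        return np.where(self.group_is_new[:, None], logw_new[None, :], logw_base[None, :])

    def _node_grids(self, s: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Effective-trait node grids for independent items and per testlet."""
        TT_ind = np.broadcast_to(self.theta, (len(self.ind_cols), len(self.theta)))
        TT_t = [
            (self.theta[:, None] - s_d * self.z[None, :]).reshape(-1)
            for s_d in s
        ]
        return TT_ind, TT_t

    # -- E-step --------------------------------------------------------------

    def e_step(self, p: np.ndarray, s: np.ndarray, mu: float, var: float, need_counts: bool = True):
        """Posterior quantities at the current parameters.

        Returns (loglik, post, R_ind, R_t) where ``post`` is the (n, K)
        posterior over theta (testlet effects integrated out), ``R_ind`` the
        (J_ind, C, K) expected counts and ``R_t`` a list of (m_d, C, K*L)
        expected counts on each testlet's joint grid.
        """
        K = len(self.theta)
        L = len(self.z)
        a, B = _unpack(p)
        TT_ind, TT_t = self._node_grids(s)

        total = self._prior_logw(mu, var).copy()
        if len(self.ind_cols):
            P = _cat_probs(a[self.ind_cols], B[self.ind_cols], np.ascontiguousarray(TT_ind))
            logP_ind = np.log(np.clip(P, _EPS, None))
            total += self.I_ind @ logP_ind.reshape(-1, K)
        conds = []
        for d, cols in enumerate(self.t_cols):
            P = _cat_probs(a[cols], B[cols], np.broadcast_to(TT_t[d], (len(cols), K * L)))
            logP = np.log(np.clip(P, _EPS, None))
            logM = self.I_t[d] @ logP.reshape(-1, K * L)
            # bounded below by (items per testlet) * log(eps) > -750: exp is safe
            Mw = np.exp(logM).reshape(self.n, K, L)
            Mw *= self.wz  # fold quadrature weights in once
            T = Mw.sum(axis=2)
            total += np.log(T)
            if need_counts:
                # joint weight over z-nodes, conditional on (person, theta-node)
                Mw /= T[:, :, None]
                conds.append(Mw)
            else:
                conds.append(None)

        mtot = total.max(axis=1, keepdims=True)
        post = np.exp(total - mtot)
        marg = post.sum(axis=1)
        loglik = float((mtot[:, 0] + np.log(marg)).sum())
        post /= marg[:, None]

        if not need_counts:
            return loglik, post, None, None

        R_ind = None
        if len(self.ind_cols):
            R_ind = (self.I_ind.T @ post).reshape(len(self.ind_cols), self.C, K)
        R_t = []
        for d, cols in enumerate(self.t_cols):
            u = (post[:, :, None] * conds[d]).reshape(self.n, K * L)
            R_t.append((self.I_t[d].T @ u).reshape(len(cols), self.C, K * L))
        return loglik, post, R_ind, R_t

    # -- M-step --------------------------------------------------------------

    def m_step(
        self,
        p: np.ndarray,
        s: np.ndarray,
        mu: float,
        var: float,
        post: np.ndarray,
        R_ind,
        R_t,
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        K = len(self.theta)
        L = len(self.z)
        p_new = p.copy()
        TT_ind, TT_t = self._node_grids(s)

        if len(self.ind_cols):
            p_new[self.ind_cols] = _fisher_step(
                p[self.ind_cols], np.ascontiguousarray(TT_ind), R_ind
            )
        if self.t_cols:
            cols_all = np.concatenate(self.t_cols)
            TT_stack = np.concatenate(
                [np.broadcast_to(TT_t[d], (len(c), K * L)) for d, c in enumerate(self.t_cols)]
            )
            R_stack = np.concatenate(R_t)
            p_new[cols_all] = _fisher_step(p[cols_all], TT_stack, R_stack)

        # conditional maximisation of each testlet's s given updated items
        s_new = s.copy()
        a, B = _unpack(p_new)
        for d, cols in enumerate(self.t_cols):
            s_new[d] = self._update_s(float(s[d]), a[cols], B[cols], R_t[d])

        # new-group prior: closed-form moment update
        mu_new, var_new = mu, var
        if self.has_new and self.config.estimate_new_group:
            pw = post[self.group_is_new]
            person_mean = pw @ self.theta
            person_m2 = pw @ self.theta**2
            mu_new = float(person_mean.mean())
            var_new = float(person_m2.mean() - mu_new**2)
            var_new = max(var_new, 0.05)
        return p_new, s_new, mu_new, var_new

    def _update_s(self, s0: float, a: np.ndarray, B: np.ndarray, R_d: np.ndarray) -> float:
        """Safeguarded Newton (Fisher-scoring) update of one testlet's s >= 0."""
        K, L = len(self.theta), len(self.z)
        zrep = np.broadcast_to(self.z, (K, L)).reshape(-1)  # z value at each joint node

        def e_and_derivs(s_val: float, derivs: bool = True):
            TT = (self.theta[:, None] - s_val * self.z[None, :]).reshape(-1)
            TTb = np.broadcast_to(TT, (len(a), K * L))
            eta = a[:, None, None] * (TTb[:, None, :] - B[:, :, None])
            Pstar = expit(eta)
            J = len(a)
            full = np.concatenate(
                [np.ones((J, 1, K * L)), Pstar, np.zeros((J, 1, K * L))], axis=1
            )
            P = np.clip(full[:, :-1] - full[:, 1:], _EPS, None)
            e_val = float(np.einsum("jcn,jcn->", R_d, np.log(P)))
            if not derivs:
                return e_val, 0.0, 1.0
            q = Pstar * (1.0 - Pstar)
            dPstar = q * (-a[:, None, None] * zrep)  # d eta / d s = -a z
            zero = np.zeros((J, 1, K * L))
            dfull = np.concatenate([zero, dPstar, zero], axis=1)
            dP = dfull[:, :-1] - dfull[:, 1:]
            grad = float(np.einsum("jcn,jcn->", R_d / P, dP))
            nT = R_d.sum(axis=1)
            info = float(np.einsum("jcn,jcn->", dP * (nT[:, None, :] / P), dP))
            return e_val, grad, max(info, 1e-8)

        s_val = s0
        e_old, grad, info = e_and_derivs(s_val)
        for _ in range(3):
            step = grad / info
            if abs(step) < 1e-6:
                break
            alpha = 1.0
            for _ in range(8):
                cand = float(np.clip(s_val + alpha * step, 0.0, self.config.s_max))
                e_new, g_new, i_new = e_and_derivs(cand)
                if e_new >= e_old - 1e-10:
                    s_val, e_old, grad, info = cand, e_new, g_new, i_new
                    break
                alpha *= 0.5
            else:
                break
        return s_val

    def eap(self, post: np.ndarray) -> np.ndarray:
        """Posterior-mean abilities; all-missing persons fall back to the prior mean."""
        n_blank = int((~(self.codes != MISSING).any(axis=1)).sum())
        if n_blank:
            logger.warning("%d person(s) with no observed responses scored at the prior mean", n_blank)
        return post @ self.theta


class ConcurrentCalibrator(BaseEstimator):
    """Multiple-group MML-EM calibration of 2PLM / 2PTM / GRM / GRTM.

    Parameters
    ----------
    model_family:
        One of ``"2PLM"``, ``"2PTM"``, ``"GRM"``, ``"GRTM"``.  The testlet
        families estimate one random-effect variance per testlet with the
        constraint that the slope on the testlet effect equals the item's
        discrimination.
    quad_points_theta, theta_range:
        Rectangular quadrature grid for the general trait.
    quad_points_testlet:
        Gauss-Hermite nodes for each standardised testlet effect.
    convergence_tol:
        EM stops when the largest absolute parameter change falls below this.
    max_cycles:
        Cycle cap; non-convergence yields ``converged_ = False`` plus a warning.
    estimate_new_group:
        Estimate the new group's ability mean/variance (base fixed at 0, 1).

    Attributes (after ``fit``)
    --------------------------
    item_estimates_ : dict[str, ItemParams]
    testlet_variances_ : dict[str, float]
    group_params_ : dict  with keys ``new_mean`` and ``new_var``
    log_likelihood_ : float
    loglik_path_ : ndarray of per-cycle marginal log-likelihoods
    n_cycles_ : int
    converged_ : bool
    excluded_items_ : tuple[str, ...]
    """

    def __init__(
        self,
        model_family: str = "2PLM",
        quad_points_theta: int = 21,
        theta_range: tuple[float, float] = (-5.0, 5.0),
        quad_points_testlet: int = 11,
        convergence_tol: float = 1e-4,
        max_cycles: int = 500,
        estimate_new_group: bool = True,
        s_max: float = 3.0,
    ) -> None:
        self.model_family = model_family
        self.quad_points_theta = quad_points_theta
        self.theta_range = theta_range
        self.quad_points_testlet = quad_points_testlet
        self.convergence_tol = convergence_tol
        self.max_cycles = max_cycles
        self.estimate_new_group = estimate_new_group
        self.s_max = s_max

    # ------------------------------------------------------------------

    def _config(self) -> CalibrationConfig:
        return CalibrationConfig(
            model_family=self.model_family,
            quad_points_theta=self.quad_points_theta,
            theta_range=tuple(self.theta_range),
            quad_points_testlet=self.quad_points_testlet,
            convergence_tol=self.convergence_tol,
            max_cycles=self.max_cycles,
            estimate_new_group=self.estimate_new_group,
            s_max=self.s_max,
        )

    def fit(
        self,
        X: ResponseMatrix,
        y: None = None,
        structure: FormPair | Mapping[str, str] | None = None,
        init_items: Mapping[str, ItemParams] | None = None,
    ) -> "ConcurrentCalibrator":
        """Run the EM to convergence on one concurrent response matrix."""
        if self.model_family not in ("2PLM", "2PTM", "GRM", "GRTM"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        use_testlets = self.model_family in TESTLET_FAMILIES
        if use_testlets and structure is None:
            raise ValueError("testlet families require a structure (FormPair or testlet map)")
        config = self._config()
        tmap = _as_testlet_map(structure)
        eng = _Engine(X, tmap, config, use_testlets)
        self._engine_ = eng

        p, s, mu, var = eng.start_values()
        if init_items:
            for j, iid in enumerate(eng.keep_ids):
                it = init_items.get(iid)
                if it is None:
                    continue
                bs = (
                    np.array([it.b])
                    if isinstance(it, DichotomousItemParams)
                    else np.array(it.boundaries)
                )
                if len(bs) == eng.C - 1:
                    p[j] = _pack(np.array([it.a]), bs[None, :])[0]

        path = []
        converged = False
        n_cycles = 0
        for cycle in range(1, config.max_cycles + 1):
            n_cycles = cycle
            loglik, post, R_ind, R_t = eng.e_step(p, s, mu, var)
            path.append(loglik)
            p_new, s_new, mu_new, var_new = eng.m_step(p, s, mu, var, post, R_ind, R_t)
            a_old, B_old = _unpack(p)
            a_new, B_new = _unpack(p_new)
            delta = max(
                np.abs(a_new - a_old).max(),
                np.abs(B_new - B_old).max(),
                np.abs(s_new - s).max() if len(s) else 0.0,
                abs(mu_new - mu),
                abs(var_new - var),
            )
            p, s, mu, var = p_new, s_new, mu_new, var_new
            if delta < config.convergence_tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"EM did not converge in {config.max_cycles} cycles "
                f"(model {self.model_family})",
                RuntimeWarning,
            )
        final_loglik, post, _, _ = eng.e_step(p, s, mu, var, need_counts=False)
        path.append(final_loglik)

        a, B = _unpack(p)
        items: dict[str, ItemParams] = {}
        for j, iid in enumerate(eng.keep_ids):
            tid = tmap.get(iid) if use_testlets else None
            if eng.C == 2:
                items[iid] = DichotomousItemParams(iid, float(a[j]), float(B[j, 0]), tid)
            else:
                items[iid] = PolytomousItemParams(
                    iid, float(a[j]), tuple(float(x) for x in B[j]), tid
                )
        self.item_estimates_ = items
        self.testlet_variances_ = {
            tid: float(s_d**2) for tid, s_d in zip(eng.testlet_ids, s)
        }
        self.group_params_ = {"new_mean": float(mu), "new_var": float(var)}
        self.log_likelihood_ = final_loglik
        self.loglik_path_ = np.asarray(path)
        self.n_cycles_ = n_cycles
        self.converged_ = converged
        self.excluded_items_ = tuple(eng.excluded)
        self._p_, self._s_, self._mu_, self._var_ = p, s, mu, var
        return self

    def predict(self, X: ResponseMatrix | None = None) -> np.ndarray:
        """EAP ability scores (posterior means, testlet effects integrated out)."""
        if not hasattr(self, "item_estimates_"):
            raise RuntimeError("calibrator is not fitted")
        if X is None:
            eng = self._engine_
            _, post, _, _ = eng.e_step(self._p_, self._s_, self._mu_, self._var_, need_counts=False)
            return eng.eap(post)
        tmap = {
            iid: it.testlet_id
            for iid, it in self.item_estimates_.items()
            if it.testlet_id is not None
        }
        eng = _Engine(X, tmap, self._config(), self.model_family in TESTLET_FAMILIES)
        p = np.zeros((eng.J, eng.npar))
        for j, iid in enumerate(eng.keep_ids):
            it = self.item_estimates_[iid]
            bs = (
                np.array([it.b])
                if isinstance(it, DichotomousItemParams)
                else np.array(it.boundaries)
            )
            p[j] = _pack(np.array([it.a]), bs[None, :])[0]
        s = np.array(
            [np.sqrt(self.testlet_variances_[tid]) for tid in eng.testlet_ids]
        )
        _, post, _, _ = eng.e_step(
            p, s, self.group_params_["new_mean"], self.group_params_["new_var"],
            need_counts=False,
        )
        return eng.eap(post)

    def result(self) -> CalibrationResult:
        if not hasattr(self, "item_estimates_"):
            raise RuntimeError("calibrator is not fitted")
        return CalibrationResult(
            model_family=self.model_family,
            item_estimates=dict(self.item_estimates_),
            testlet_variances=dict(self.testlet_variances_),
            group_params=dict(self.group_params_),
            log_likelihood=self.log_likelihood_,
            n_cycles=self.n_cycles_,
            converged=self.converged_,
            excluded_items=self.excluded_items_,
        )


def eap_rmse_floor(
    items: Sequence[ItemParams],
    n: int = 20_000,
    rng: np.random.Generator | None = None,
    grid_points: int = 401,
) -> float:
    """Lower bound on EAP ability RMSE for a test form.

    Simulates locally independent responses from the *true* item parameters
    (no testlet noise, no estimation error) for ``n`` N(0,1) examinees and
    scores them with true-parameter EAP on a dense grid.  No pipeline that
    also carries testlet noise and item-estimation error can beat this
    value, so it bounds what ability-recovery statistics are achievable
    with a given form.
    """
    from .simulate import PersonSample, generate_responses
    from dataclasses import replace as _replace

    rng = rng or np.random.default_rng(0)
    free = [
        _replace(it, testlet_id=None) for it in items
    ]  # strip testlet membership: locally independent generation
    thetas = rng.normal(0.0, 1.0, size=n)
    persons = PersonSample("base", thetas, {})
    codes = generate_responses(tuple(free), persons, rng)
    matrix = ResponseMatrix(
        codes=codes,
        item_ids=tuple(it.item_id for it in free),
        groups=np.array(["base"] * n),
    )
    config = CalibrationConfig(model_family="2PLM", quad_points_theta=grid_points)
    result = CalibrationResult(
        model_family="GRM" if isinstance(free[0], PolytomousItemParams) else "2PLM",
        item_estimates={it.item_id: it for it in free},
        testlet_variances={}, group_params={"new_mean": 0.0, "new_var": 1.0},
        log_likelihood=0.0, n_cycles=0, converged=True,
    )
    scores = eap_score(matrix, result, config)
    return float(np.sqrt(np.mean((scores - thetas) ** 2)))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_concurrent(
    matrix: ResponseMatrix,
    structure: FormPair | Mapping[str, str] | None,
    config: CalibrationConfig | None = None,
    init_items: Mapping[str, ItemParams] | None = None,
) -> CalibrationResult:
    """Fit one model family to a concurrent matrix and return the result bundle."""
    config = config or CalibrationConfig()
    cal = ConcurrentCalibrator(**asdict(config))
    cal.fit(matrix, structure=structure, init_items=init_items)
    return cal.result()


def eap_score(
    matrix: ResponseMatrix,
    result: CalibrationResult,
    config: CalibrationConfig | None = None,
) -> np.ndarray:
    """EAP ability estimates for every row of ``matrix`` under fitted parameters."""
    config = config or CalibrationConfig(model_family=result.model_family)
    cal = ConcurrentCalibrator(**{**asdict(config), "model_family": result.model_family})
    cal.item_estimates_ = dict(result.item_estimates)
    cal.testlet_variances_ = dict(result.testlet_variances)
    cal.group_params_ = dict(result.group_params)
    return cal.predict(matrix)


def marginal_loglik(
    matrix: ResponseMatrix,
    items: Mapping[str, ItemParams],
    testlet_variances: Mapping[str, float],
    group_params: Mapping[str, float],
    config: CalibrationConfig,
) -> float:
    """Quadrature-approximated marginal log-likelihood at fixed parameters."""
    use_testlets = config.model_family in TESTLET_FAMILIES
    tmap = {
        iid: it.testlet_id for iid, it in items.items() if it.testlet_id is not None
    }
    eng = _Engine(matrix, tmap if use_testlets else {}, config, use_testlets)
    p = np.zeros((eng.J, eng.npar))
    for j, iid in enumerate(eng.keep_ids):
        it = items[iid]
        bs = (
            np.array([it.b])
            if isinstance(it, DichotomousItemParams)
            else np.array(it.boundaries)
        )
        if len(bs) != eng.C - 1:
            raise ValueError(f"item {iid}: boundary count does not match data categories")
        p[j] = _pack(np.array([it.a]), bs[None, :])[0]
    s = np.array([np.sqrt(testlet_variances[tid]) for tid in eng.testlet_ids])
    mu = float(group_params.get("new_mean", 0.0))
    var = float(group_params.get("new_var", 1.0))
    loglik, _, _, _ = eng.e_step(p, s, mu, var, need_counts=False)
    return loglik
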