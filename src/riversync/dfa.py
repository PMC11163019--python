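"""Dynamic factor analysis of multivariate time series with missing data.

Model
-----
Observations ``y_t`` (one value per river, NaN = missing) are linear
combinations of ``m`` latent random-walk trends plus structured noise::

    y_t = Z x_t + a + D d_t + v_t,   v_t ~ MVN(0, R)
    x_t = x_{t-1} + w_t,             w_t ~ MVN(0, I_m)

The trend innovation covariance is fixed at the identity and the entries of
``Z`` above the diagonal are constrained to zero during estimation — the
standard identifiability convention; loadings carry the scale.  The initial
state ``x_0`` is a fixed parameter with zero prior variance, so the joint
distribution of the stacked observations is an ordinary multivariate normal
and can be evaluated directly (see :func:`loglik_exact`), which pins down
the absolute log-likelihood convention used throughout.

Estimation is by EM: the E-step runs a Kalman filter/smoother that drops
the missing components of the observation vector at each time step; the
M-step updates the loadings/covariate coefficients from weighted normal
equations (free entries of ``[Z | a | D]`` solved jointly) and the
observation covariance per structure:

``diagonal_unequal``
    series-specific variances, no covariance (closed form);
``diagonal_equal``
    one shared variance (closed form);
``equalvarcov``
    compound symmetry ``R = sigma^2 I + c (J - I)`` — under arbitrary
    missing-data patterns this has no closed-form M-step, so the two
    parameters are updated by an inner numerical maximization started at
    the current values (a generalized-EM step that preserves monotone
    likelihood ascent).

Interpretation aids: varimax rotation of loadings and trends (fitted
values invariant), fitted values with delta-method confidence bands, and
AICc with the small-sample correction evaluated at ``n`` = number of
non-missing observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from riversync.panel import LengthPanel

__all__ = [
    "DFAModelSpec",
    "DynamicFactorAnalysis",
    "DFAResults",
    "FittedIntervals",
    "fit_dfa",
    "fit_dfa_covariate",
    "varimax",
    "varimax_rotate",
    "loglik_exact",
    "aicc",
]

R_STRUCTURES = ("diagonal_equal", "equalvarcov", "diagonal_unequal")

_R_VARIANCE_FLOOR = 1e-10


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """AICc = -2 logL + 2 K n / (n - K - 1)."""
    denom = n_obs - n_params - 1
    if denom <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * n_params * n_obs / denom


@dataclass
class DFAModelSpec:
    """Configuration of one dynamic factor model.

    ``m`` latent trends (1 to S-1), one of three observation-error
    structures, optional year-indexed covariates (columns of a DataFrame,
    complete over the panel years), and EM controls.
    """

    m: int = 1
    r_structure: str = "diagonal_equal"
    covariates: pd.DataFrame | None = None
    max_iter: int = 50_000
    tol: float = 1e-6
    estimate_offsets: bool = False
    aicc_n: str = "observations"  # or "cells" (S*T)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_structure not in R_STRUCTURES:
            raise ValueError(f"unknown r_structure {self.r_structure!r}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.aicc_n not in {"observations", "cells"}:
            raise ValueError("aicc_n must be 'observations' or 'cells'")

    @classmethod
    def from_file(cls, path) -> "DFAModelSpec":
        """Load a spec from a YAML/JSON mapping, e.g.
        ``{m: 3, R: equalvarcov, tol: 1e-6, max_iter: 50000}``."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "R" in raw:
            raw["r_structure"] = raw.pop("R")
        return cls(**raw)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class _Params:
    Z: np.ndarray          # (S, m), upper triangle zero
    a: np.ndarray          # (S,)
    D: np.ndarray          # (S, p)
    pi: np.ndarray         # (m,) initial state
    sigma2: np.ndarray     # (S,) variances (equal structures keep S copies)
    cov: float             # off-diagonal covariance (equalvarcov only)

    def R(self) -> np.ndarray:
        S = len(self.sigma2)
        R = np.full((S, S), self.cov)
        np.fill_diagonal(R, self.sigma2)
        return R


def _r_inverse_subset(params: _Params, idx: np.ndarray, structure: str) -> np.ndarray:
    """Inverse of R restricted to observed rows, exploiting structure."""
    k = len(idx)
    if structure == "equalvarcov":
        s2 = params.sigma2[0]
        c = params.cov
        # compound symmetry: (s2 - c) I + c J
        alpha = 1.0 / (s2 - c)
        beta = -c / ((s2 - c) * (s2 + (k - 1) * c))
        return alpha * np.eye(k) + beta * np.ones((k, k))
    return np.diag(1.0 / params.sigma2[idx])


# ---------------------------------------------------------------------------
# Kalman filter / RTS smoother with observation-vector reduction


def _kalman_filter(
    y: np.ndarray,
    obs_idx: list[np.ndarray],
    params: _Params,
    d: np.ndarray | None,
    want_states: bool = True,
):
    """Filter pass; returns loglik and (optionally) the filtering moments."""
    S, T = y.shape
    m = params.Z.shape[1]
    R = params.R()
    Im = np.eye(m)

    x_prev = params.pi.copy()
    P_prev = np.zeros((m, m))
    ll = 0.0
    if want_states:
        x_pred = np.empty((T, m))
        P_pred = np.empty((T, m, m))
        x_filt = np.empty((T, m))
        P_filt = np.empty((T, m, m))

    for t in range(T):
        xp = x_prev
        Pp = P_prev + Im
        o = obs_idx[t]
        if len(o) > 0:
            Zo = params.Z[o]
            mean = Zo @ xp + params.a[o]
            if d is not None:
                mean = mean + params.D[o] @ d[:, t]
            v = y[o, t] - mean
            F = Zo @ Pp @ Zo.T + R[np.ix_(o, o)]
            F = 0.5 * (F + F.T)
            L = np.linalg.cholesky(F)
            alpha = np.linalg.solve(L, v)
            ll += -0.5 * (
                len(o) * np.log(2.0 * np.pi)
                + 2.0 * np.sum(np.log(np.diag(L)))
                + alpha @ alpha
            )
            K = Pp @ Zo.T @ np.linalg.solve(F, np.eye(len(o)))
            xf = xp + K @ v
            IKZ = Im - K @ Zo
            # Joseph form for numerical symmetry
            Pf = IKZ @ Pp @ IKZ.T + K @ R[np.ix_(o, o)] @ K.T
        else:
            xf, Pf = xp, Pp
        if want_states:
            x_pred[t], P_pred[t] = xp, Pp
            x_filt[t], P_filt[t] = xf, 0.5 * (Pf + Pf.T)
        x_prev, P_prev = xf, 0.5 * (Pf + Pf.T)

    if not want_states:
        return ll
    return ll, x_pred, P_pred, x_filt, P_filt


def _kalman_smooth(y, obs_idx, params, d):
    """Filter + RTS smoother.

    Returns loglik, smoothed means ``xs`` (T, m), covariances ``Vs``
    (T, m, m) and lag-one covariances ``Vlag[t] = Cov(x_{t-1}, x_t | Y)``
    for t >= 1 (Vlag[0] is zero: x_0 is fixed).
    """
    ll, x_pred, P_pred, x_filt, P_filt = _kalman_filter(y, obs_idx, params, d)
    T, m = x_filt.shape
    xs = np.empty((T, m))
    Vs = np.empty((T, m, m))
    Vlag = np.zeros((T, m, m))
    xs[-1], Vs[-1] = x_filt[-1], P_filt[-1]
    for t in range(T - 2, -1, -1):
        J = P_filt[t] @ np.linalg.solve(P_pred[t + 1], np.eye(m))
        xs[t] = x_filt[t] + J @ (xs[t + 1] - x_pred[t + 1])
        Vs[t] = P_filt[t] + J @ (Vs[t + 1] - P_pred[t + 1]) @ J.T
        Vs[t] = 0.5 * (Vs[t] + Vs[t].T)
        # smoothing distribution is Markov with slope J
        Vlag[t + 1] = J @ Vs[t + 1]
    return ll, xs, Vs, Vlag


# ---------------------------------------------------------------------------
# EM


def _free_mask(S: int, m: int, p: int, estimate_offsets: bool) -> np.ndarray:
    """Boolean (S, q) mask of free entries of Gamma = [Z | a | D]."""
    q = m + 1 + p
    mask = np.zeros((S, q), dtype=bool)
    for i in range(S):
        mask[i, : min(i + 1, m)] = True  # lower-triangular loadings
    if estimate_offsets:
        mask[:, m] = True
    mask[:, m + 1:] = True
    return mask


class DynamicFactorAnalysis:
    """Dynamic factor model for a centered river x year panel.

    Parameters
    ----------
    panel : LengthPanel
        Must be centered (fitted on deviations from river means).
    m : int
        Number of latent random-walk trends (1 <= m < number of rivers).
    r_structure : str
        Observation-error structure: ``"diagonal_equal"``,
        ``"equalvarcov"`` or ``"diagonal_unequal"``.
    covariates : DataFrame, optional
        Year-indexed, centered-and-scaled covariates; must be complete
        (no NaN) over the panel years.  One regression coefficient per
        river per covariate is estimated jointly with the factor model.

    Examples
    --------
    >>> model = DynamicFactorAnalysis(panel, m=3, r_structure="equalvarcov")
    >>> res = model.fit()
    >>> res.AICc, res.converged
    """

    def __init__(
        self,
        panel: LengthPanel,
        m: int = 1,
        r_structure: str = "diagonal_equal",
        covariates: pd.DataFrame | None = None,
        estimate_offsets: bool = False,
        aicc_n: str = "observations",
    ) -> None:
        spec = DFAModelSpec(
            m=m,
            r_structure=r_structure,
            covariates=covariates,
            estimate_offsets=estimate_offsets,
            aicc_n=aicc_n,
        )
        self._validate(panel, spec)
        self.panel = panel
        self.spec = spec
        self.y = panel.values
        self.S, self.T = self.y.shape
        self.obs_idx = [np.flatnonzero(np.isfinite(self.y[:, t])) for t in range(self.T)]
        if covariates is not None:
            cov = covariates.reindex(panel.years)
            if cov.isna().any().any():
                raise ValueError("covariates must be complete over the panel years")
            self.d = cov.to_numpy(dtype=float).T  # (p, T)
            self.covariate_names = list(cov.columns)
        else:
            self.d = None
            self.covariate_names = []
        self.p = 0 if self.d is None else self.d.shape[0]

    @staticmethod
    def _validate(panel: LengthPanel, spec: DFAModelSpec) -> None:
        S = panel.n_rivers
        if spec.m >= S:
            raise ValueError(f"m={spec.m} must be < number of series ({S})")
        if not panel.centered:
            raise ValueError("panel must be centered (LengthPanel.center())")
        all_missing = ~np.isfinite(panel.values)
        if all_missing.all(axis=1).any():
            bad = [r for r, row in zip(panel.rivers, all_missing) if row.all()]
            raise ValueError(f"rivers with no observations: {bad}")

    # -- parameter bookkeeping ------------------------------------------

    @property
    def n_params(self) -> int:
        m, S, p = self.spec.m, self.S, self.p
        k = S * m - m * (m - 1) // 2          # free loadings
        k += m                                 # initial state
        k += {"diagonal_equal": 1, "equalvarcov": 2, "diagonal_unequal": S}[
            self.spec.r_structure
        ]
        k += S * p                             # covariate coefficients
        if self.spec.estimate_offsets:
            k += S
        return k

    def _init_params(self) -> _Params:
        y0 = np.nan_to_num(self.y, nan=0.0)
        m = self.spec.m
        U, s, _ = np.linalg.svd(y0, full_matrices=False)
        Z = U[:, :m] * (s[:m] / np.sqrt(self.T))
        # guard against a structurally zero start, then impose the
        # triangular identifiability constraint
        Z[np.abs(Z) < 1e-3] += 1e-3
        if m > 1:
            Z = np.tril(Z)
        var = np.nanvar(self.y, axis=1)
        var = np.where(var > 0, var, 1.0)
        if self.spec.r_structure == "diagonal_unequal":
            sigma2 = 0.5 * var
        else:
            sigma2 = np.full(self.S, 0.5 * float(np.mean(var)))
        return _Params(
            Z=Z,
            a=np.zeros(self.S),
            D=np.zeros((self.S, self.p)),
            pi=np.zeros(m),
            sigma2=np.maximum(sigma2, _R_VARIANCE_FLOOR),
            cov=0.0,
        )

    # -- M-step pieces ---------------------------------------------------

    def _patterns(self):
        """Group time steps by missing-data pattern."""
        groups: dict[tuple, list[int]] = {}
        for t, o in enumerate(self.obs_idx):
            groups.setdefault(tuple(o), []).append(t)
        return [(np.array(k, dtype=int), np.array(v, dtype=int)) for k, v in groups.items()]

    def _update_gamma(self, params: _Params, xs, Vs, patterns) -> _Params:
        """Solve the weighted normal equations for the free entries of
        Gamma = [Z | a | D] jointly (weights from the current R)."""
        S, m, p = self.S, self.spec.m, self.p
        q = m + 1 + p
        mask = _free_mask(S, m, p, self.spec.estimate_offsets).flatten(order="F")

        # E[u_t u_t'] with u = [x; 1; d]
        U_mean = np.zeros((q, self.T))
        U_mean[:m] = xs.T
        U_mean[m] = 1.0
        if p:
            U_mean[m + 1:] = self.d

        A = np.zeros((S * q, S * q))
        b = np.zeros((S, q))
        for o, ts in patterns:
            if len(o) == 0:
                continue
            Rinv = _r_inverse_subset(params, o, self.spec.r_structure)
            W = np.zeros((S, S))
            W[np.ix_(o, o)] = Rinv
            Suu = U_mean[:, ts] @ U_mean[:, ts].T
            Suu[:m, :m] += Vs[ts].sum(axis=0)
            A += np.kron(Suu, W)
            cy = np.zeros((S, len(ts)))
            cy[o] = Rinv @ self.y[np.ix_(o, ts)]
            b += cy @ U_mean[:, ts].T
        bf = b.flatten(order="F")
        gamma = np.zeros(S * q)
        gamma[mask] = np.linalg.solve(A[np.ix_(mask, mask)], bf[mask])
        G = gamma.reshape((S, q), order="F")
        return replace(
            params, Z=G[:, :m], a=G[:, m], D=G[:, m + 1:].reshape(S, p)
        )

    def _residual_scatter(self, params: _Params, xs, Vs, patterns):
        """Per-pattern expected residual outer products at current Gamma."""
        out = []
        for o, ts in patterns:
            if len(o) == 0:
                continue
            Zo = params.Z[o]
            mean = Zo @ xs[ts].T + params.a[o][:, None]
            if self.d is not None:
                mean = mean + params.D[o] @ self.d[:, ts]
            r = self.y[np.ix_(o, ts)] - mean
            W = r @ r.T + Zo @ Vs[ts].sum(axis=0) @ Zo.T
            out.append((o, len(ts), W))
        return out

    def _update_r(self, params: _Params, scatter) -> _Params:
        struct = self.spec.r_structure
        if struct == "diagonal_unequal":
            num = np.zeros(self.S)
            cnt = np.zeros(self.S)
            for o, n_t, W in scatter:
                num[o] += np.diag(W)
                cnt[o] += n_t
            sigma2 = np.where(cnt > 0, num / np.maximum(cnt, 1), params.sigma2)
            return replace(params, sigma2=np.maximum(sigma2, _R_VARIANCE_FLOOR))
        if struct == "diagonal_equal":
            num = sum(np.trace(W) for _, _, W in scatter)
            cnt = sum(len(o) * n_t for o, n_t, _ in scatter)
            s2 = max(num / cnt, _R_VARIANCE_FLOOR)
            return replace(params, sigma2=np.full(self.S, s2))
        return self._update_r_equalvarcov(params, scatter)

    def _update_r_equalvarcov(self, params: _Params, scatter) -> _Params:
        """Inner 2-parameter maximization for compound-symmetry R.

        The expected complete-data objective decomposes over missing-data
        patterns via the compound-symmetry eigenstructure; it is maximized
        numerically starting from the current (sigma2, c), so the step never
        decreases the objective (generalized EM).
        """
        stats_ = [
            (len(o), n_t, float(np.trace(W)), float(W.sum())) for o, n_t, W in scatter
        ]
        S = self.S

        def neg_obj(theta):
            s2 = np.exp(theta[0])
            # correlation in (-1/(S-1), 1)
            rho = (1.0 + 1.0 / (S - 1)) / (1.0 + np.exp(-theta[1])) - 1.0 / (S - 1)
            c = rho * s2
            total = 0.0
            for k, n_t, trW, sumW in stats_:
                lam2 = s2 - c
                lam1 = s2 + (k - 1) * c
                if lam2 <= 0 or lam1 <= 0:
                    return 1e300
                logdet = (k - 1) * np.log(lam2) + np.log(lam1)
                alpha = 1.0 / lam2
                beta = -c / (lam2 * lam1)
                tr_inv_W = alpha * trW + beta * sumW
                total += -0.5 * (n_t * logdet + tr_inv_W)
            return -total

        s2_cur = float(params.sigma2[0])
        rho_cur = np.clip(
            params.cov / s2_cur, -1.0 / (S - 1) + 1e-6, 1.0 - 1e-6
        )
        u = (rho_cur + 1.0 / (S - 1)) / (1.0 + 1.0 / (S - 1))
        theta0 = np.array([np.log(s2_cur), np.log(u / (1.0 - u))])
        res = optimize.minimize(neg_obj, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
        theta = res.x if res.fun <= neg_obj(theta0) else theta0
        s2 = float(np.exp(theta[0]))
        rho = (1.0 + 1.0 / (S - 1)) / (1.0 + np.exp(-theta[1])) - 1.0 / (S - 1)
        return replace(
            params,
            sigma2=np.full(S, max(s2, _R_VARIANCE_FLOOR)),
            cov=float(rho * s2),
        )

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        max_iter: int | None = None,
        tol: float | None = None,
        track_loglik: bool = False,
    ) -> "DFAResults":
        """Run EM to (local) maximum likelihood.

        Returns a :class:`DFAResults`; a fit that hits ``max_iter`` before
        the log-likelihood change drops below ``tol`` is returned with
        ``converged=False`` rather than raising.
        """
        max_iter = self.spec.max_iter if max_iter is None else max_iter
        tol = self.spec.tol if tol is None else tol
        params = self._init_params()
        patterns = self._patterns()

        ll_prev = -np.inf
        ll_path: list[float] = []
        converged = False
        n_iter = 0
        xs = Vs = None
        for n_iter in range(1, max_iter + 1):
            ll, xs, Vs, _ = _kalman_smooth(self.y, self.obs_idx, params, self.d)
            if track_loglik:
                ll_path.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
            params = replace(params, pi=xs[0].copy())
            params = self._update_gamma(params, xs, Vs, patterns)
            scatter = self._residual_scatter(params, xs, Vs, patterns)
            params = self._update_r(params, scatter)

        # moments and likelihood at the final parameter values
        ll, xs, Vs, _ = _kalman_smooth(self.y, self.obs_idx, params, self.d)
        n = self.panel.n_obs if self.spec.aicc_n == "observations" else self.S * self.T
        return DFAResults(
            model=self,
            params=params,
            x=xs.T.copy(),
            x_cov=Vs.copy(),
            loglik=float(ll),
            n_params=self.n_params,
            n_obs_used=n,
            AICc=aicc(float(ll), self.n_params, n),
            converged=converged,
            n_iter=n_iter,
            loglik_path=np.array(ll_path) if track_loglik else None,
        )


# ---------------------------------------------------------------------------
# results


@dataclass
class FittedIntervals:
    """Per-river fitted series with symmetric normal-approximation bands."""

    fitted: pd.DataFrame   # rivers x years
    lower: pd.DataFrame
    upper: pd.DataFrame
    level: float


@dataclass
class DFAResults:
    """Estimates from a fitted dynamic factor model.

    Attributes
    ----------
    x : (m, T) array
        Smoothed trend estimates; ``x_cov`` holds the (T, m, m) smoothed
        state covariances.
    loglik, AICc : float
        Maximized log-likelihood and small-sample-corrected AIC using
        ``n_obs_used`` observations and ``n_params`` parameters.
    rotated : bool
        Whether a varimax rotation has been applied (see :meth:`rotate`).
    """

    model: DynamicFactorAnalysis
    params: _Params
    x: np.ndarray
    x_cov: np.ndarray
    loglik: float
    n_params: int
    n_obs_used: int
    AICc: float
    converged: bool
    n_iter: int
    rotated: bool = False
    rotation: np.ndarray | None = None
    loglik_path: np.ndarray | None = field(default=None, repr=False)
    _D_se: np.ndarray | None = field(default=None, repr=False)

    # -- convenience accessors ------------------------------------------

    @property
    def Z(self) -> np.ndarray:
        return self.params.Z

    @property
    def a(self) -> np.ndarray:
        return self.params.a

    @property
    def D(self) -> np.ndarray:
        return self.params.D

    @property
    def m(self) -> int:
        return self.model.spec.m

    @property
    def r_structure(self) -> str:
        return self.model.spec.r_structure

    def fittedvalues(self) -> np.ndarray:
        """(S, T) model-implied observation means Z x + a (+ D d)."""
        fit = self.params.Z @ self.x + self.params.a[:, None]
        if self.model.d is not None:
            fit = fit + self.params.D @ self.model.d
        return fit

    # -- rotation ---------------------------------------------------------

    def rotate(self) -> "DFAResults":
        """Varimax-rotate loadings and trends; fitted values unchanged."""
        Zr, H = varimax(self.params.Z)
        xr = H.T @ self.x
        Vr = np.einsum("ij,tjk,kl->til", H.T, self.x_cov, H)
        return replace(
            self,
            params=replace(self.params, Z=Zr),
            x=xr,
            x_cov=Vr,
            rotated=True,
            rotation=H,
        )

    # -- intervals --------------------------------------------------------

    def fitted_with_ci(self, level: float = 0.95) -> FittedIntervals:
        """Fitted values with delta-method confidence bands.

        The band for river s at year t is ``Z_s x_t +- z * sqrt(Z_s V_t
        Z_s')``: only trend uncertainty is propagated (offsets are fixed by
        centering), so a zero-loading river has zero band width.
        """
        z = stats.norm.ppf(0.5 + level / 2.0)
        fit = self.fittedvalues()
        se = np.sqrt(
            np.einsum("sj,tjk,sk->st", self.params.Z, self.x_cov, self.params.Z)
        )
        rivers, years = self.model.panel.rivers, self.model.panel.years
        return FittedIntervals(
            fitted=pd.DataFrame(fit, index=rivers, columns=years),
            lower=pd.DataFrame(fit - z * se, index=rivers, columns=years),
            upper=pd.DataFrame(fit + z * se, index=rivers, columns=years),
            level=level,
        )

    # -- covariate inference ----------------------------------------------

    def covariate_se(self) -> np.ndarray:
        """Standard errors for the covariate coefficients D.

        D enters the observation mean linearly, so with the remaining
        parameters held at their MLEs the observed information for D is
        exact: ``I = X' Sigma^{-1} X`` over the stacked non-missing
        observations, with Sigma the model-implied joint covariance.
        Cached after the first call.
        """
        if self.model.p == 0:
            return np.zeros((self.model.S, 0))
        if self._D_se is None:
            Sigma, cells = _implied_covariance(self.model, self.params)
            n = len(cells)
            p = self.model.p
            X = np.zeros((n, self.model.S * p))
            for k, (i, t) in enumerate(cells):
                for j in range(p):
                    X[k, i * p + j] = self.model.d[j, t]
            info = X.T @ np.linalg.solve(Sigma, X)
            cov = np.linalg.inv(info)
            self._D_se = np.sqrt(np.diag(cov)).reshape(self.model.S, p)
        return self._D_se

    def covariate_table(self, level: float = 0.95) -> pd.DataFrame:
        """Per-river covariate coefficients, CIs and significance flags."""
        se = self.covariate_se()
        z = stats.norm.ppf(0.5 + level / 2.0)
        rows = []
        for j, name in enumerate(self.model.covariate_names):
            for i, river in enumerate(self.model.panel.rivers):
                est = self.params.D[i, j]
                lo, hi = est - z * se[i, j], est + z * se[i, j]
                rows.append(
                    {
                        "covariate": name,
                        "river": river,
                        "coef": est,
                        "se": se[i, j],
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "significant": bool(lo > 0 or hi < 0),
                    }
                )
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Dynamic Factor Analysis Results",
            "=" * 46,
            f"Series (rivers):      {self.model.S}",
            f"Time points (years):  {self.model.T}",
            f"Observations:         {self.model.panel.n_obs}",
            f"Common trends (m):    {spec.m}",
            f"R structure:          {spec.r_structure}",
            f"Covariates:           {', '.join(self.model.covariate_names) or 'none'}",
            f"Log-likelihood:       {self.loglik:.2f}",
            f"Parameters (K):       {self.n_params}",
            f"AICc:                 {self.AICc:.2f}",
            f"Converged:            {self.converged} ({self.n_iter} EM iterations)",
            f"Varimax rotated:      {self.rotated}",
            "-" * 46,
            "Loadings (Z):",
        ]
        zfmt = pd.DataFrame(
            self.params.Z,
            index=self.model.panel.rivers,
            columns=[f"trend_{j + 1}" for j in range(spec.m)],
        )
        lines.append(zfmt.round(3).to_string())
        if self.model.p:
            lines.append("-" * 46)
            lines.append("Covariate coefficients (D) with 95% CI:")
            lines.append(self.covariate_table().round(3).to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "m": self.m,
            "r_structure": self.r_structure,
            "Z": self.params.Z.tolist(),
            "a": self.params.a.tolist(),
            "D": self.params.D.tolist(),
            "x": self.x.tolist(),
            "pi": self.params.pi.tolist(),
            "sigma2": self.params.sigma2.tolist(),
            "cov": self.params.cov,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "AICc": self.AICc,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "rotated": self.rotated,
        }


# ---------------------------------------------------------------------------
# functional wrappers matching the pipeline vocabulary


def fit_dfa(panel: LengthPanel, spec: DFAModelSpec) -> DFAResults:
    """Fit a dynamic factor model described by ``spec`` to ``panel``."""
    model = DynamicFactorAnalysis(
        panel,
        m=spec.m,
        r_structure=spec.r_structure,
        covariates=spec.covariates,
        estimate_offsets=spec.estimate_offsets,
        aicc_n=spec.aicc_n,
    )
    return model.fit(max_iter=spec.max_iter, tol=spec.tol)


def fit_dfa_covariate(
    panel: LengthPanel, spec: DFAModelSpec, covariate: pd.Series | pd.DataFrame
) -> DFAResults:
    """Fit the model with one or more annual covariates added (y = Zx + a + Dd + v)."""
    if isinstance(covariate, pd.Series):
        covariate = covariate.to_frame(covariate.name or "covariate")
    return fit_dfa(panel, replace(spec, covariates=covariate))


def varimax_rotate(fit: DFAResults) -> DFAResults:
    return fit.rotate()


def fitted_with_ci(fit: DFAResults, level: float = 0.95) -> FittedIntervals:
    return fit.fitted_with_ci(level)


# ---------------------------------------------------------------------------
# varimax


def varimax(
    loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser criterion, raw loadings).

    Returns ``(rotated, H)`` with ``rotated = loadings @ H`` and H
    orthogonal; for a single factor H is the identity.
    """
    L = np.asarray(loadings, dtype=float)
    S, m = L.shape
    H = np.eye(m)
    if m == 1:
        return L.copy(), H
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ H
        B = L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / S)
        U, s, Vt = np.linalg.svd(B)
        H = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1.0 + tol):
            break
        d_old = d
    return L @ H, H


# ---------------------------------------------------------------------------
# brute-force likelihood oracle


def _implied_covariance(model: DynamicFactorAnalysis, params: _Params):
    """Joint covariance of the stacked non-missing observations.

    With x_0 fixed, ``Cov(x_t, x_s) = min(t, s) I_m`` (t, s counted from 1),
    so ``Cov(y_it, y_js) = min(t, s) Z_i . Z_j + R_ij [t = s]``.
    """
    R = params.R()
    cells = [(i, t) for t in range(model.T) for i in model.obs_idx[t]]
    n = len(cells)
    Sigma = np.empty((n, n))
    for aix, (i, t) in enumerate(cells):
        for bix, (j, s) in enumerate(cells):
            v = (min(t, s) + 1.0) * (params.Z[i] @ params.Z[j])
            if t == s:
                v += R[i, j]
            Sigma[aix, bix] = v
    return Sigma, cells


def loglik_exact(panel: LengthPanel, fit: DFAResults) -> float:
    """Exact joint-normal log-likelihood of the panel at the fitted
    parameters, computed without the Kalman filter.

    Stacks all non-missing observations, builds the model-implied mean
    (``Z pi + a + D d_t``) and covariance directly, and evaluates the
    multivariate normal log-density.  Intended as an independent check of
    the filter on small panels (<= ~200 observations).
    """
    model = fit.model
    if panel is not model.panel:
        model = DynamicFactorAnalysis(
            panel,
            m=model.spec.m,
            r_structure=model.spec.r_structure,
            covariates=None
            if model.d is None
            else pd.DataFrame(model.d.T, index=panel.years, columns=model.covariate_names),
            estimate_offsets=model.spec.estimate_offsets,
        )
    if panel.n_obs > 2000:
        raise ValueError("panel too large for the direct-stacking oracle")
    Sigma, cells = _implied_covariance(model, fit.params)
    mu = np.empty(len(cells))
    yv = np.empty(len(cells))
    for k, (i, t) in enumerate(cells):
        mu[k] = fit.params.Z[i] @ fit.params.pi + fit.params.a[i]
        if model.d is not None:
            mu[k] += fit.params.D[i] @ model.d[:, t]
        yv[k] = panel.values[i, t]
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance is not positive definite")
    r = yv - mu
    return float(
        -0.5 * (len(cells) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(Sigma, r))
    )
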