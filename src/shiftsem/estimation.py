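"""Normal-theory maximum-likelihood estimation of the longitudinal factor model.

The model-implied moments are fitted to a sample covariance matrix ``S`` and
mean vector ``xbar`` by minimizing the ML discrepancy

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - PT + (xbar - mu)' Sigma^-1 (xbar - mu)

over the free parameters of a :class:`~shiftsem.model_core.ParameterTable`,
honouring equality groups.  The chi-square statistic is ``(n - 1) * F_min``
(the sample covariance uses the n - 1 denominator, and the test statistic is
scaled consistently).  Gradients are analytic; optimization is L-BFGS-B with
box bounds keeping variances positive, followed by Newton polishing with a
finite-difference Hessian, which also supplies the observed-information
standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
from scipy import stats

from .model_core import (
    Entry,
    ImpliedMoments,
    ParameterTable,
    n_sample_moments,
)

__all__ = [
    "SampleMoments",
    "FittedModel",
    "ModificationCandidate",
    "FitOptions",
    "NonAdmissibleError",
    "compute_moments",
    "ml_discrepancy",
    "fit",
    "saturated_fit",
    "independence_fit",
    "modification_indices",
    "wald_test",
]

_VAR_FLOOR = 1e-6
_BARRIER = 1e10


class NonAdmissibleError(ValueError):
    """Implied covariance matrix is singular or not positive definite."""


# ---------------------------------------------------------------------------
# sample moments


@dataclass
class SampleMoments:
    """Observed covariance matrix (denominator n-1), mean vector and n."""

    S: np.ndarray
    xbar: np.ndarray
    n: int
    names: tuple[str, ...] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        self.S = (S + S.T) / 2.0
        self.xbar = np.asarray(self.xbar, dtype=float)
        if self.xbar.shape != (S.shape[0],):
            raise ValueError("xbar length must match S")
        ev = np.linalg.eigvalsh(self.S)
        if ev[0] <= 1e-10 * max(ev[-1], 1.0):
            raise ValueError("sample covariance matrix is singular or nearly so")

    @property
    def p(self) -> int:
        return self.S.shape[0]


def compute_moments(data: pd.DataFrame, columns: Sequence[str] | None = None) -> SampleMoments:
    """Sample covariance (denominator n-1) and means with listwise deletion.

    Rows containing any missing value are dropped; the count of dropped rows
    is recorded on the result.
    """
    if columns is not None:
        missing = [c for c in columns if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing expected columns: {missing}")
        data = data[list(columns)]
    values = data.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    values = values[complete]
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 complete rows to form a covariance, got {n}")
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = data.columns[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance column: {bad!r}")
    if n <= values.shape[1]:
        warnings.warn(
            f"sample size n={n} does not exceed the number of observed variables "
            f"({values.shape[1]}); estimates will be unstable",
            stacklevel=2,
        )
    S = np.atleast_2d(np.cov(values, rowvar=False, ddof=1))
    xbar = values.mean(axis=0)
    return SampleMoments(S=S, xbar=xbar, n=n, names=tuple(data.columns), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# compiled model: fast scatter/gather between parameter vector and matrices


class _Compiled:
    """Index structure mapping a flat free-parameter vector to model matrices."""

    def __init__(self, table: ParameterTable):
        self.table = table
        pat = table.pattern
        P, Q, T = pat.n_indicators, pat.n_factors, pat.n_occasions
        self.P, self.Q, self.T = P, Q, T
        iocc = {o: t for t, o in enumerate(pat.occasions)}
        iind = {v: i for i, v in enumerate(pat.indicators)}
        ifac = {v: i for i, v in enumerate(pat.factors)}
        self._iocc, self._iind, self._ifac = iocc, iind, ifac

        self.slot_names: list[str] = []
        slot_of: dict[str, int] = {}
        self.slot_is_variance: list[bool] = []
        # per matrix: row idx, col idx, slot idx (free); base matrices for fixed
        idx: dict[str, list[list[int]]] = {m: [] for m in ("lambda", "phi", "theta")}
        vec_idx: dict[str, list[list[int]]] = {m: [] for m in ("tau", "kappa")}
        self.base_lam = np.zeros((P * T, Q * T))
        self.base_phi = np.zeros((Q * T, Q * T))
        self.base_theta = np.zeros((P * T, P * T))
        self.base_tau = np.zeros(P * T)
        self.base_kappa = np.zeros(Q * T)

        def cell(e: Entry) -> tuple[int, int]:
            if e.matrix == "lambda":
                return iocc[e.occ_row] * P + iind[e.row], iocc[e.occ_row] * Q + ifac[e.col]
            if e.matrix == "phi":
                return iocc[e.occ_row] * Q + ifac[e.row], iocc[e.occ_col] * Q + ifac[e.col]
            if e.matrix == "theta":
                return iocc[e.occ_row] * P + iind[e.row], iocc[e.occ_col] * P + iind[e.col]
            if e.matrix == "tau":
                return iocc[e.occ_row] * P + iind[e.row], 0
            return iocc[e.occ_row] * Q + ifac[e.row], 0

        self.cell_of: dict[str, tuple[str, int, int]] = {}
        for e in table.entries.values():
            r, c = cell(e)
            self.cell_of[e.ref] = (e.matrix, r, c)
            if e.is_free:
                key = e.group if e.group is not None else e.ref
                if key not in slot_of:
                    slot_of[key] = len(self.slot_names)
                    self.slot_names.append(key)
                    self.slot_is_variance.append(
                        e.matrix in ("phi", "theta") and r == c
                    )
                s = slot_of[key]
                if e.matrix in ("lambda", "phi", "theta"):
                    idx[e.matrix].append([r, c, s])
                else:
                    vec_idx[e.matrix].append([r, s])
            else:
                v = float(e.value)
                if e.matrix == "lambda":
                    self.base_lam[r, c] = v
                elif e.matrix == "phi":
                    self.base_phi[r, c] = self.base_phi[c, r] = v
                elif e.matrix == "theta":
                    self.base_theta[r, c] = self.base_theta[c, r] = v
                elif e.matrix == "tau":
                    self.base_tau[r] = v
                else:
                    self.base_kappa[r] = v
        self.slot_of = slot_of
        self.q = len(self.slot_names)
        self._idx = {
            m: np.array(v, dtype=int).reshape(-1, 3) for m, v in idx.items()
        }
        self._vec_idx = {
            m: np.array(v, dtype=int).reshape(-1, 2) for m, v in vec_idx.items()
        }

    def cell_for(self, e: Entry) -> tuple[str, int, int]:
        """Matrix cell of an entry (also for entries not present in the table)."""
        P, Q = self.P, self.Q
        if e.matrix == "lambda":
            return e.matrix, self._iocc[e.occ_row] * P + self._iind[e.row], \
                self._iocc[e.occ_row] * Q + self._ifac[e.col]
        if e.matrix == "phi":
            return e.matrix, self._iocc[e.occ_row] * Q + self._ifac[e.row], \
                self._iocc[e.occ_col] * Q + self._ifac[e.col]
        if e.matrix == "theta":
            return e.matrix, self._iocc[e.occ_row] * P + self._iind[e.row], \
                self._iocc[e.occ_col] * P + self._iind[e.col]
        if e.matrix == "tau":
            return e.matrix, self._iocc[e.occ_row] * P + self._iind[e.row], 0
        return e.matrix, self._iocc[e.occ_row] * Q + self._ifac[e.row], 0

    # -- vector <-> matrices ------------------------------------------------

    def assemble(self, x: np.ndarray):
        lam = self.base_lam.copy()
        phi = self.base_phi.copy()
        theta = self.base_theta.copy()
        tau = self.base_tau.copy()
        kappa = self.base_kappa.copy()
        li = self._idx["lambda"]
        lam[li[:, 0], li[:, 1]] = x[li[:, 2]]
        pi = self._idx["phi"]
        phi[pi[:, 0], pi[:, 1]] = x[pi[:, 2]]
        phi[pi[:, 1], pi[:, 0]] = x[pi[:, 2]]
        ti = self._idx["theta"]
        theta[ti[:, 0], ti[:, 1]] = x[ti[:, 2]]
        theta[ti[:, 1], ti[:, 0]] = x[ti[:, 2]]
        vi = self._vec_idx["tau"]
        tau[vi[:, 0]] = x[vi[:, 1]]
        ki = self._vec_idx["kappa"]
        kappa[ki[:, 0]] = x[ki[:, 1]]
        return lam, phi, theta, tau, kappa

    def slot_for(self, ref: str) -> int:
        e = self.table[ref]
        key = e.group if e.group is not None else e.ref
        try:
            return self.slot_of[key]
        except KeyError:
            raise KeyError(f"{ref} is not a free parameter of this model") from None

    def start_values(self, moments: SampleMoments) -> np.ndarray:
        """Heuristic interior starting point; table values take precedence."""
        x = np.empty(self.q)
        diag_s = np.diag(moments.S)
        P = self.P
        for key, s in self.slot_of.items():
            members = (
                self.table.groups()[key]
                if key.startswith("eq:") or key in self.table.groups()
                else [self.table[key]]
            )
            vals = [m.value for m in members if m.value is not None and np.isfinite(m.value)]
            if vals:
                x[s] = float(np.mean(vals))
                continue
            e = members[0]
            m, r, c = self.cell_of[e.ref]
            if m == "lambda":
                x[s] = 0.7
            elif m == "phi":
                x[s] = 1.0 if r == c else 0.3
            elif m == "theta":
                x[s] = 0.5 * diag_s[r] if r == c else 0.0
            elif m == "tau":
                rows = [self.cell_of[mm.ref][1] for mm in members]
                x[s] = float(np.mean(moments.xbar[rows]))
            else:
                x[s] = 0.0
        return x

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [
            (_VAR_FLOOR, None) if v else (None, None) for v in self.slot_is_variance
        ]

    # -- objective ----------------------------------------------------------

    def fg(
        self,
        x: np.ndarray,
        moments: SampleMoments,
        extra: Sequence[tuple[str, int, int, float]] = (),
    ):
        """ML discrepancy, its gradient, and gradients for extra cell offsets.

        ``extra`` entries are ``(matrix, row, col, delta)`` additive offsets
        applied on top of the assembled matrices (symmetric matrices get both
        mirror cells); used for score tests of fixed/tied parameters.
        """
        lam, phi, theta, tau, kappa = self.assemble(x)
        for m, r, c, dv in extra:
            if m == "lambda":
                lam[r, c] += dv
            elif m == "phi":
                phi[r, c] += dv
                if r != c:
                    phi[c, r] += dv
            elif m == "theta":
                theta[r, c] += dv
                if r != c:
                    theta[c, r] += dv
            elif m == "tau":
                tau[r] += dv
            else:
                kappa[r] += dv
        S, xbar, p = moments.S, moments.xbar, moments.p
        lp = lam @ phi
        sigma = lp @ lam.T + theta
        sigma = (sigma + sigma.T) / 2.0
        try:
            cf = sla.cho_factor(sigma, check_finite=False)
        except sla.LinAlgError:
            return _BARRIER, np.zeros(self.q), np.zeros(len(extra))
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        if not np.isfinite(logdet):
            return _BARRIER, np.zeros(self.q), np.zeros(len(extra))
        sigma_inv = sla.cho_solve(cf, np.eye(p), check_finite=False)
        mu = tau + lam @ kappa
        d = xbar - mu
        sid = sigma_inv @ d
        sign_S, logdet_S = np.linalg.slogdet(S)
        f = (
            logdet
            - logdet_S
            + float((S * sigma_inv).sum())
            - p
            + float(d @ sid)
        )
        # gradient: A = Sigma^-1 - Sigma^-1 (S + dd') Sigma^-1
        Msi = sigma_inv @ (S @ sigma_inv)
        A = sigma_inv - Msi - np.outer(sid, sid)
        ALP = A @ lp  # p x qT
        LAL = lam.T @ (A @ lam)  # qT x qT
        g = np.zeros(self.q)
        li = self._idx["lambda"]
        if len(li):
            np.add.at(
                g,
                li[:, 2],
                2.0 * ALP[li[:, 0], li[:, 1]] - 2.0 * sid[li[:, 0]] * kappa[li[:, 1]],
            )
        pi = self._idx["phi"]
        if len(pi):
            w = np.where(pi[:, 0] == pi[:, 1], 1.0, 2.0)
            np.add.at(g, pi[:, 2], w * LAL[pi[:, 0], pi[:, 1]])
        ti = self._idx["theta"]
        if len(ti):
            w = np.where(ti[:, 0] == ti[:, 1], 1.0, 2.0)
            np.add.at(g, ti[:, 2], w * A[ti[:, 0], ti[:, 1]])
        vi = self._vec_idx["tau"]
        if len(vi):
            np.add.at(g, vi[:, 1], -2.0 * sid[vi[:, 0]])
        ki = self._vec_idx["kappa"]
        if len(ki):
            lsd = lam.T @ sid
            np.add.at(g, ki[:, 1], -2.0 * lsd[ki[:, 0]])
        eg = np.zeros(len(extra))
        if extra:
            lsd = lam.T @ sid
            for k, (m, r, c, _dv) in enumerate(extra):
                if m == "lambda":
                    eg[k] = 2.0 * ALP[r, c] - 2.0 * sid[r] * kappa[c]
                elif m == "phi":
                    eg[k] = (1.0 if r == c else 2.0) * LAL[r, c]
                elif m == "theta":
                    eg[k] = (1.0 if r == c else 2.0) * A[r, c]
                elif m == "tau":
                    eg[k] = -2.0 * sid[r]
                else:
                    eg[k] = -2.0 * lsd[r]
        return f, g, eg


# ---------------------------------------------------------------------------
# public discrepancy


def ml_discrepancy(table: ParameterTable, moments: SampleMoments) -> float:
    """ML discrepancy of a fully valued table against sample moments."""
    from .model_core import implied_moments as _implied

    imp = _implied(table)
    return _discrepancy_from_moments(imp.sigma, imp.mu, moments)


def _discrepancy_from_moments(
    sigma: np.ndarray, mu: np.ndarray, moments: SampleMoments
) -> float:
    S, xbar, p = moments.S, moments.xbar, moments.p
    try:
        cf = sla.cho_factor(sigma)
    except sla.LinAlgError as exc:
        raise NonAdmissibleError("implied covariance matrix is not positive definite") from exc
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    sigma_inv = sla.cho_solve(cf, np.eye(p))
    d = xbar - mu
    _, logdet_S = np.linalg.slogdet(S)
    return float(
        logdet - logdet_S + (S * sigma_inv).sum() - p + d @ sigma_inv @ d
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    """Optimizer controls for :func:`fit`."""

    gtol: float = 1e-6
    max_iter: int = 1000
    restarts: int = 5
    jitter: float = 0.2
    seed: int = 0
    compute_se: bool = True


@dataclass
class FittedModel:
    """One maximum-likelihood fit of a parameter table to sample moments."""

    table: ParameterTable | None
    moments: SampleMoments
    discrepancy: float
    chi_square: float
    df: int
    converged: bool
    gradient_norm: float
    n: int
    param_names: list[str] = field(default_factory=list)
    estimates: np.ndarray | None = None
    cov_params: np.ndarray | None = None
    hessian: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    n_restarts_used: int = 0
    log: list[str] = field(default_factory=list)
    n_params: int = 0

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def _slot(self, ref: str) -> int:
        e = self.table[ref]
        key = e.group if e.group is not None else e.ref
        try:
            return self.param_names.index(key)
        except ValueError:
            raise KeyError(f"{ref} is not a free parameter of this fit") from None

    def estimate(self, ref: str) -> float:
        return float(self.estimates[self._slot(ref)])

    def se(self, ref: str) -> float:
        if self.cov_params is None:
            raise ValueError("standard errors unavailable (fit not converged or singular information)")
        return float(np.sqrt(self.cov_params[self._slot(ref), self._slot(ref)]))

    @property
    def standard_errors(self) -> dict[str, float] | None:
        if self.cov_params is None:
            return None
        ses = np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))
        return dict(zip(self.param_names, ses))

    def implied(self) -> ImpliedMoments:
        from .model_core import implied_moments as _implied

        return _implied(self.table)


def _numeric_hessian(comp: _Compiled, x: np.ndarray, moments: SampleMoments) -> np.ndarray:
    """Forward-difference Hessian of the discrepancy from analytic gradients."""
    q = comp.q
    _, g0, _ = comp.fg(x, moments)
    H = np.empty((q, q))
    for j in range(q):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += h
        _, gp, _ = comp.fg(xp, moments)
        H[:, j] = (gp - g0) / h
    return (H + H.T) / 2.0


def _projected_grad_inf(x, g, bounds_lo):
    """Max |gradient| ignoring coordinates pinned at their lower bound."""
    g = g.copy()
    at_lo = (bounds_lo is not None) & (x <= bounds_lo + 1e-12) & (g > 0)
    g[at_lo] = 0.0
    return float(np.max(np.abs(g))) if len(g) else 0.0


def fit(
    table: ParameterTable,
    moments: SampleMoments,
    options: FitOptions | None = None,
) -> FittedModel:
    """Minimize the ML discrepancy over the free parameters of ``table``.

    Equality groups are honoured (one underlying parameter per group), so all
    group members carry identical estimates afterwards.  Standard errors come
    from the inverse observed information of ``(n-1)/2`` times the
    discrepancy at the optimum.  When the gradient tolerance is not reached,
    the fit is retried from jittered starting points; a still-unconverged fit
    is returned with ``converged=False`` and no standard errors.
    """
    opts = options or FitOptions()
    from .model_core import degrees_of_freedom as _df

    comp = _Compiled(table)
    df = _df(table)
    n = moments.n
    log: list[str] = []
    if comp.q == 0:
        f = ml_discrepancy(table, moments)
        return FittedModel(
            table=table.copy(), moments=moments, discrepancy=f,
            chi_square=max(0.0, (n - 1) * f), df=df, converged=True,
            gradient_norm=0.0, n=n, log=["no free parameters"], n_params=0,
        )
    bounds = comp.bounds()
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    rng = np.random.default_rng(opts.seed)
    x0 = np.clip(comp.start_values(moments), lo, None)
    best = None
    for attempt in range(opts.restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(0.0, opts.jitter, size=comp.q)
        xs = np.maximum(xs, np.where(np.isfinite(lo), lo + 1e-4, -np.inf))
        res = scipy.optimize.minimize(
            lambda x: comp.fg(x, moments)[:2],
            xs,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.max_iter, "ftol": 1e-14, "gtol": 1e-8},
        )
        x = np.maximum(res.x, np.where(np.isfinite(lo), lo, -np.inf))
        # Newton polish with Levenberg damping
        H = None
        for _ in range(40):
            f, g, _ = comp.fg(x, moments)
            if _projected_grad_inf(x, g, lo) < opts.gtol:
                break
            H = _numeric_hessian(comp, x, moments)
            lam_reg = 0.0
            for _inner in range(8):
                try:
                    step = np.linalg.solve(
                        H + lam_reg * np.eye(comp.q), -g
                    )
                except np.linalg.LinAlgError:
                    lam_reg = max(10 * lam_reg, 1e-6)
                    continue
                xn = np.maximum(x + step, np.where(np.isfinite(lo), lo, -np.inf))
                fn, gn, _ = comp.fg(xn, moments)
                if fn <= f + 1e-12:
                    break
                lam_reg = max(10 * lam_reg, 1e-6)
            else:
                break
            if np.max(np.abs(xn - x)) < 1e-14:
                break
            x = xn
        f, g, _ = comp.fg(x, moments)
        gnorm = _projected_grad_inf(x, g, lo)
        log.append(
            f"attempt {attempt}: discrepancy={f:.6g}, max|grad|={gnorm:.3g}, "
            f"lbfgs_iters={res.nit}"
        )
        if best is None or f < best[0] - 1e-12 or (
            abs(f - best[0]) <= 1e-12 and gnorm < best[2]
        ):
            best = (f, x, gnorm, attempt)
        if best[2] < opts.gtol:
            break
    f, x, gnorm, attempt = best
    converged = gnorm < opts.gtol and f < _BARRIER / 2
    # write estimates back into a copy of the table
    fitted_table = table.copy()
    for e in fitted_table.entries.values():
        if e.is_free:
            key = e.group if e.group is not None else e.ref
            e.value = float(x[comp.slot_of[key]])
    warns: list[str] = []
    theta_at_floor = [
        comp.slot_names[s]
        for s in range(comp.q)
        if comp.slot_is_variance[s] and x[s] <= _VAR_FLOOR * 1.001
    ]
    if theta_at_floor:
        warns.append(
            "Heywood case: variance estimate(s) at lower bound: "
            + ", ".join(theta_at_floor)
        )
    cov = None
    H = None
    if converged and opts.compute_se:
        H = _numeric_hessian(comp, x, moments)
        try:
            cov = np.linalg.inv((n - 1) / 2.0 * H)
            if (np.diag(cov) <= 0).any():
                warns.append("observed information not positive definite; no standard errors")
                cov = None
        except np.linalg.LinAlgError:
            warns.append("observed information singular; no standard errors")
            cov = None
    return FittedModel(
        table=fitted_table,
        moments=moments,
        discrepancy=f,
        chi_square=max(0.0, (n - 1) * f),
        df=df,
        converged=converged,
        gradient_norm=gnorm,
        n=n,
        param_names=list(comp.slot_names),
        estimates=x.copy(),
        cov_params=cov,
        hessian=H,
        warnings=warns,
        n_restarts_used=attempt,
        log=log,
        n_params=comp.q,
    )


# ---------------------------------------------------------------------------
# reference fits with closed forms


def saturated_fit(moments: SampleMoments) -> FittedModel:
    """The saturated model: Sigma = S, mu = xbar; zero discrepancy, df = 0."""
    f = _discrepancy_from_moments(moments.S, moments.xbar, moments)
    return FittedModel(
        table=None, moments=moments, discrepancy=f, chi_square=0.0, df=0,
        converged=True, gradient_norm=0.0, n=moments.n,
        log=["saturated model (closed form)"],
        n_params=n_sample_moments(moments.p, 1),
    )


def independence_fit(moments: SampleMoments) -> FittedModel:
    """The independence (null) baseline: free variances and means, zero covariances.

    The ML solution is available in closed form (variances equal the sample
    variances, means the sample means), giving discrepancy
    ``sum(ln s_ii) - ln|S|``.
    """
    diag = np.diag(moments.S).copy()
    _, logdet_S = np.linalg.slogdet(moments.S)
    f = float(np.log(diag).sum() - logdet_S)
    m = moments.p
    df = n_sample_moments(m, 1) - 2 * m
    return FittedModel(
        table=None, moments=moments, discrepancy=f,
        chi_square=max(0.0, (moments.n - 1) * f), df=df, converged=True,
        gradient_norm=0.0, n=moments.n,
        log=["independence model (closed form)"],
        n_params=2 * m,
    )


# ---------------------------------------------------------------------------
# score (modification index) and Wald machinery


@dataclass
class ModificationCandidate:
    """Score-test approximation for freeing one constrained/fixed parameter."""

    ref: str
    mod_index: float
    epc: float


def _candidate_cells(
    table: ParameterTable, comp: _Compiled, ref: str
) -> list[tuple[str, int, int]]:
    """The matrix cells an offset parameter would touch when freeing ``ref``.

    For an equality group, freeing is a split of the last occasion's member
    out of the group, so the offset applies to that member's cell(s).  For a
    fixed or not-yet-existing entry (a pattern-zero loading or an excluded
    residual covariance) the offset applies to its own cell.
    """
    groups = table.groups()
    if ref in groups:
        occ = table.pattern.occasions[-1]
        cells = [comp.cell_of[m.ref] for m in groups[ref] if m.occ_row == occ]
        if not cells:
            raise ValueError(f"group {ref} has no member at the last occasion")
        return cells
    if ref not in table.entries:
        from .model_core import parse_ref

        return [comp.cell_for(parse_ref(ref, table.pattern))]
    e = table[ref]
    if e.is_free and e.group is None:
        raise ValueError(f"{ref} is already free")
    if e.role == "identification":
        raise ValueError(f"{ref} is an identification restriction")
    return [comp.cell_of[ref]]


def modification_indices(
    fitted: FittedModel, candidates: Iterable[str]
) -> list[ModificationCandidate]:
    """Expected 1-df chi-square improvement from freeing each candidate.

    Uses the score-test approximation: with score ``s`` and the Schur
    complement ``h`` of the candidate's Hessian block against the free
    parameters, MI = (n-1) s^2 / (2 h) and the expected parameter change is
    ``-s / h``.  Results are sorted by decreasing index.
    """
    if not fitted.converged:
        raise ValueError("modification indices require a converged fit")
    table = fitted.table
    comp = _Compiled(table)
    x = fitted.estimates
    moments = fitted.moments
    H_ff = fitted.hessian
    if H_ff is None:
        H_ff = _numeric_hessian(comp, x, moments)
    out: list[ModificationCandidate] = []
    _, g0, _ = comp.fg(x, moments)
    for ref in candidates:
        cells = [(m, r, c, 0.0) for (m, r, c) in _candidate_cells(table, comp, ref)]
        _, _, eg0 = comp.fg(x, moments, extra=cells)
        s = float(eg0.sum())
        eps = 1e-6
        cells_eps = [(m, r, c, eps) for (m, r, c, _d) in cells]
        _, g1, eg1 = comp.fg(x, moments, extra=cells_eps)
        h_cf = (g1 - g0) / eps
        h_cc = float((eg1.sum() - s) / eps)
        try:
            schur = h_cc - h_cf @ np.linalg.solve(H_ff, h_cf)
        except np.linalg.LinAlgError:
            schur = h_cc
        if schur <= 1e-12:
            mi, epc = 0.0, 0.0
        else:
            mi = (fitted.n - 1) * s * s / (2.0 * schur)
            epc = -s / schur
        out.append(ModificationCandidate(ref=ref, mod_index=max(mi, 0.0), epc=epc))
    out.sort(key=lambda c: -c.mod_index)
    return out


def wald_test(fitted: FittedModel, ref: str | tuple[str, str]) -> tuple[float, float]:
    """Wald chi-square(1) test of one free parameter (or of a difference).

    For a single reference the null is ``param = 0``; for a pair the null is
    equality of the two parameters, with the variance of the difference taken
    from the parameter covariance matrix.
    """
    if fitted.cov_params is None:
        raise ValueError("Wald test requires standard errors")
    if isinstance(ref, tuple):
        i, j = fitted._slot(ref[0]), fitted._slot(ref[1])
        est = fitted.estimates[i] - fitted.estimates[j]
        var = (
            fitted.cov_params[i, i]
            + fitted.cov_params[j, j]
            - 2.0 * fitted.cov_params[i, j]
        )
    else:
        i = fitted._slot(ref)
        est = fitted.estimates[i]
        var = fitted.cov_params[i, i]
    if var <= 0:
        raise ValueError("non-positive variance in Wald test")
    stat = float(est * est / var)
    return stat, float(stats.chi2.sf(stat, 1))
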