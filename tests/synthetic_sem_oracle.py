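"""Synthetic stand-in for an external SEM engine (independent cross-check).

This is a deliberately separate, minimal implementation of normal-theory ML
covariance-and-mean-structure estimation, written without any shiftsem
machinery: it builds its own flat parameter list for the canonical
3-factor / 9-indicator / 2-occasion longitudinal model (Step-1 or Step-2
restrictions), assembles the implied moments with plain loops, and minimizes
the discrepancy with scipy's L-BFGS-B using finite-difference gradients and
a simple self-contained Newton polish.  It shares no code path with the
package and is used only as the reference implementation in tests.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize


class OracleLongitudinalCFA:
    """Independent ML fitter for the canonical two-occasion 3x3 factor model.

    Parameters are named with the same reference strings the package uses so
    tests can compare estimates one-for-one, but the internal bookkeeping is
    a flat list built here from scratch.
    """

    def __init__(self, indicators, factors, assignment, occasions=("T1", "T2"),
                 step=1):
        assert len(occasions) == 2
        self.indicators = list(indicators)
        self.factors = list(factors)
        self.assignment = dict(assignment)  # indicator -> factor
        self.occasions = list(occasions)
        self.step = step
        self.P = len(self.indicators)
        self.Q = len(self.factors)
        self.names: list[str] = []
        self._build()

    def _build(self):
        P, Q = self.P, self.Q
        o1, o2 = self.occasions
        names = []
        if self.step == 1:
            for occ in self.occasions:
                for ind in self.indicators:
                    names.append(f"lambda[{ind},{self.assignment[ind]}]@{occ}")
        else:
            for ind in self.indicators:
                names.append(f"eq:lambda[{ind},{self.assignment[ind]}]")
        # phi off-diagonals within occasions; diagonals fixed 1 except step2 T2
        for occ in self.occasions:
            for i in range(Q):
                for j in range(i + 1, Q):
                    names.append(f"phi[{self.factors[i]}@{occ},{self.factors[j]}@{occ}]")
        if self.step == 2:
            for f in self.factors:
                names.append(f"phi[{f}@{o2},{f}@{o2}]")
        for fi in self.factors:
            for fj in self.factors:
                names.append(f"phi[{fi}@{o1},{fj}@{o2}]")
        for occ in self.occasions:
            for ind in self.indicators:
                names.append(f"theta[{ind}@{occ},{ind}@{occ}]")
        for ind in self.indicators:
            names.append(f"theta[{ind}@{o1},{ind}@{o2}]")
        if self.step == 1:
            for occ in self.occasions:
                for ind in self.indicators:
                    names.append(f"tau[{ind}]@{occ}")
        else:
            for ind in self.indicators:
                names.append(f"eq:tau[{ind}]")
            for f in self.factors:
                names.append(f"kappa[{f}]@{o2}")
        self.names = names

    # -- model-implied moments --------------------------------------------

    def implied(self, x):
        P, Q = self.P, self.Q
        o1, o2 = self.occasions
        v = dict(zip(self.names, x))
        lam = np.zeros((2 * P, 2 * Q))
        for t, occ in enumerate(self.occasions):
            for i, ind in enumerate(self.indicators):
                fac = self.assignment[ind]
                j = self.factors.index(fac)
                if self.step == 1:
                    val = v[f"lambda[{ind},{fac}]@{occ}"]
                else:
                    val = v[f"eq:lambda[{ind},{fac}]"]
                lam[t * P + i, t * Q + j] = val
        phi = np.eye(2 * Q)
        if self.step == 2:
            for j, f in enumerate(self.factors):
                phi[Q + j, Q + j] = v[f"phi[{f}@{o2},{f}@{o2}]"]
        for t, occ in enumerate(self.occasions):
            for i in range(Q):
                for j in range(i + 1, Q):
                    val = v[f"phi[{self.factors[i]}@{occ},{self.factors[j]}@{occ}]"]
                    phi[t * Q + i, t * Q + j] = phi[t * Q + j, t * Q + i] = val
        for i, fi in enumerate(self.factors):
            for j, fj in enumerate(self.factors):
                val = v[f"phi[{fi}@{o1},{fj}@{o2}]"]
                phi[i, Q + j] = phi[Q + j, i] = val
        theta = np.zeros((2 * P, 2 * P))
        for t, occ in enumerate(self.occasions):
            for i, ind in enumerate(self.indicators):
                theta[t * P + i, t * P + i] = v[f"theta[{ind}@{occ},{ind}@{occ}]"]
        for i, ind in enumerate(self.indicators):
            val = v[f"theta[{ind}@{o1},{ind}@{o2}]"]
            theta[i, P + i] = theta[P + i, i] = val
        sigma = lam @ phi @ lam.T + theta
        mu = np.zeros(2 * P)
        for t, occ in enumerate(self.occasions):
            for i, ind in enumerate(self.indicators):
                if self.step == 1:
                    mu[t * P + i] = v[f"tau[{ind}]@{occ}"]
                else:
                    mu[t * P + i] = v[f"eq:tau[{ind}]"]
        if self.step == 2:
            for i, ind in enumerate(self.indicators):
                fac = self.assignment[ind]
                j = self.factors.index(fac)
                mu[P + i] += lam[P + i, Q + j] * v[f"kappa[{fac}]@{o2}"]
        return sigma, mu

    def discrepancy(self, x, S, xbar):
        sigma, mu = self.implied(x)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e9
        logdet = 2 * np.log(np.diag(c)).sum()
        sigma_inv = np.linalg.inv(sigma)
        d = xbar - mu
        _, logdet_S = np.linalg.slogdet(S)
        val = logdet - logdet_S + (S * sigma_inv).sum() - len(xbar) + d @ sigma_inv @ d
        return float(val)

    def start(self, S, xbar):
        x = np.empty(len(self.names))
        for k, name in enumerate(self.names):
            if name.startswith(("lambda", "eq:lambda")):
                x[k] = 0.5
            elif name.startswith("phi["):
                a, b = name[4:-1].split(",")
                x[k] = 0.9 if a == b else 0.2
            elif name.startswith("theta["):
                a, b = name[6:-1].split(",")
                x[k] = 0.6 if a == b else 0.05
            elif name.startswith("tau[") or name.startswith("eq:tau"):
                x[k] = float(np.mean(xbar))
            else:
                x[k] = 0.0
        return x

    def fit(self, S, xbar, n):
        """Minimize the ML discrepancy; returns (estimates dict, chi_square)."""
        x0 = self.start(S, xbar)
        obj = lambda x: self.discrepancy(x, S, xbar)
        res = scipy.optimize.minimize(
            obj, x0, method="L-BFGS-B", jac=None,
            options={"maxiter": 4000, "maxfun": 200000, "ftol": 1e-15, "gtol": 1e-9},
        )
        x = res.x
        # Newton polish with finite-difference derivatives, self-contained
        q = len(x)
        for _ in range(15):
            g = scipy.optimize.approx_fprime(x, obj, 1.49e-8)
            if np.max(np.abs(g)) < 1e-8:
                break
            H = np.empty((q, q))
            for j in range(q):
                xp = x.copy()
                h = 1e-5 * max(1.0, abs(x[j]))
                xp[j] += h
                gp = scipy.optimize.approx_fprime(xp, obj, 1.49e-8)
                H[:, j] = (gp - g) / h
            H = (H + H.T) / 2
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(q), -g)
            except np.linalg.LinAlgError:
                break
            f0 = obj(x)
            t = 1.0
            while t > 1e-6 and obj(x + t * step) > f0:
                t /= 2
            if t <= 1e-6:
                break
            x = x + t * step
        estimates = dict(zip(self.names, x))
        chi2 = (n - 1) * obj(x)
        return estimates, chi2
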