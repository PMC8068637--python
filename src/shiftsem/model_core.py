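"""Longitudinal common-factor measurement model as an explicit parameter ledger.

The model for indicators observed at T occasions is the covariance/mean
structure

    Sigma = Lambda Phi Lambda' + Theta        mu = tau + Lambda kappa

assembled from occasion blocks: ``Lambda`` is block-diagonal over occasions
(no cross-occasion loadings), ``Phi`` holds within- and cross-occasion factor
(co)variances, ``Theta`` is diagonal within occasions with cross-occasion
covariances only between the residuals of the same indicator, ``tau`` stacks
the intercepts and ``kappa`` the factor means per occasion.  Vectors and
matrices are stored occasion-major: all occasion-1 indicators first, then all
occasion-2 indicators, and so on.

Every scalar parameter is one :class:`Entry` in a :class:`ParameterTable`,
addressed by name (matrix, indicator/factor labels, occasion) rather than by
position.  The table is the single source of truth for which parameters are
free, fixed, or tied into across-occasion equality groups; estimation,
hypothesis testing and simulation all operate on it.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "ModelPattern",
    "Entry",
    "ParameterTable",
    "ImpliedMoments",
    "parse_model_config",
    "build_parameter_table",
    "apply_identification",
    "impose_invariance",
    "implied_moments",
    "degrees_of_freedom",
    "n_sample_moments",
    "release_parameter",
    "parse_ref",
]


class ConfigError(ValueError):
    """Invalid model configuration."""


# ---------------------------------------------------------------------------
# pattern


@dataclass(frozen=True)
class ModelPattern:
    """Which indicator loads on which factor, replicated over occasions.

    Parameters
    ----------
    indicators : ordered indicator names (length P).
    factors : ordered factor names (length Q).
    loading_pattern : (P, Q) binary array; 1 marks an allowed loading.
    occasions : ordered occasion labels (length T >= 2).
    """

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    loading_pattern: np.ndarray
    occasions: tuple[str, ...]

    def __post_init__(self) -> None:
        pat = np.asarray(self.loading_pattern, dtype=int)
        object.__setattr__(self, "loading_pattern", pat)
        P, Q = len(self.indicators), len(self.factors)
        if len(set(self.indicators)) != P:
            raise ConfigError("factors: duplicate indicator names")
        if len(set(self.factors)) != Q:
            raise ConfigError("factors: duplicate factor names")
        if pat.shape != (P, Q):
            raise ConfigError(f"loading_pattern must be {P}x{Q}")
        if P < Q:
            raise ConfigError("more factors than indicators")
        if len(self.occasions) < 2:
            raise ConfigError("occasions: at least two measurement occasions required")
        if len(set(self.occasions)) != len(self.occasions):
            raise ConfigError("occasions: duplicate occasion labels")
        if (pat.sum(axis=1) == 0).any():
            bad = self.indicators[int(np.argmax(pat.sum(axis=1) == 0))]
            raise ConfigError(f"factors: indicator '{bad}' loads on no factor")
        if (pat.sum(axis=0) == 0).any():
            bad = self.factors[int(np.argmax(pat.sum(axis=0) == 0))]
            raise ConfigError(f"factors: factor '{bad}' has no indicators")

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    def column_names(self) -> list[str]:
        """Expected data columns, occasion-major (``ind_occ``)."""
        return [f"{ind}_{occ}" for occ in self.occasions for ind in self.indicators]


def parse_model_config(config_text: str | Mapping) -> ModelPattern:
    """Parse a YAML/JSON model configuration into a :class:`ModelPattern`.

    The configuration declares ``factors`` (mapping of factor name to its
    indicator list), ``occasions`` (list of labels) and optionally
    ``options`` (passed through to the procedure layer, ignored here).
    Indicator order is first-appearance order across the declared factors;
    an indicator listed under two factors cross-loads on both.
    """
    if isinstance(config_text, Mapping):
        cfg = dict(config_text)
    else:
        try:
            cfg = yaml.safe_load(config_text)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ConfigError(f"could not parse model config: {exc}") from exc
    if not isinstance(cfg, Mapping):
        raise ConfigError("model config must be a mapping with keys 'factors' and 'occasions'")
    if "factors" not in cfg:
        raise ConfigError("factors: key missing from model config")
    if "occasions" not in cfg:
        raise ConfigError("occasions: key missing from model config")
    factors_cfg = cfg["factors"]
    if not isinstance(factors_cfg, Mapping) or not factors_cfg:
        raise ConfigError("factors: must be a non-empty mapping factor -> [indicators]")
    factor_names = [str(f) for f in factors_cfg]
    indicators: list[str] = []
    for fac, inds in factors_cfg.items():
        if not inds:
            raise ConfigError(f"factors: factor '{fac}' has no indicators")
        seen_here: set[str] = set()
        for ind in inds:
            ind = str(ind)
            if ind in seen_here:
                raise ConfigError(f"factors: duplicate indicator '{ind}' under factor '{fac}'")
            seen_here.add(ind)
            if ind not in indicators:
                indicators.append(ind)
    occasions = [str(o) for o in cfg["occasions"]]
    pattern = np.zeros((len(indicators), len(factor_names)), dtype=int)
    for j, fac in enumerate(factors_cfg):
        for ind in factors_cfg[fac]:
            pattern[indicators.index(str(ind)), j] = 1
    return ModelPattern(
        indicators=tuple(indicators),
        factors=tuple(factor_names),
        loading_pattern=pattern,
        occasions=tuple(occasions),
    )


# ---------------------------------------------------------------------------
# parameter table


FREE = "free"
FIXED = "fixed"

MATRICES = ("lambda", "phi", "theta", "tau", "kappa")


@dataclass
class Entry:
    """One scalar model parameter.

    ``row``/``col`` are indicator or factor labels; ``occ_row``/``occ_col``
    the occasion of each margin (symmetric matrices carry two, vectors and
    loadings one, with ``occ_col`` mirroring ``occ_row``).  ``group`` names
    an across-occasion equality group; ``role`` tags entries fixed for
    identification so they are never offered for release.
    """

    ref: str
    matrix: str
    row: str
    col: str | None
    occ_row: str
    occ_col: str
    status: str = FREE
    value: float | None = None
    group: str | None = None
    role: str | None = None

    @property
    def is_free(self) -> bool:
        return self.status == FREE


def _lambda_ref(ind: str, fac: str, occ: str) -> str:
    return f"lambda[{ind},{fac}]@{occ}"


def _phi_ref(f1: str, o1: str, f2: str, o2: str) -> str:
    return f"phi[{f1}@{o1},{f2}@{o2}]"


def _theta_ref(i1: str, o1: str, i2: str, o2: str) -> str:
    return f"theta[{i1}@{o1},{i2}@{o2}]"


def _tau_ref(ind: str, occ: str) -> str:
    return f"tau[{ind}]@{occ}"


def _kappa_ref(fac: str, occ: str) -> str:
    return f"kappa[{fac}]@{occ}"


@dataclass
class ParameterTable:
    """Ledger of all parameters of one longitudinal measurement model."""

    pattern: ModelPattern
    entries: dict[str, Entry] = field(default_factory=dict)
    identification: str | None = None

    # -- basic bookkeeping -------------------------------------------------

    def copy(self) -> "ParameterTable":
        return copy.deepcopy(self)

    def __getitem__(self, ref: str) -> Entry:
        try:
            return self.entries[ref]
        except KeyError:
            raise KeyError(f"no such parameter entry: {ref!r}") from None

    def __contains__(self, ref: str) -> bool:
        return ref in self.entries

    def groups(self) -> dict[str, list[Entry]]:
        out: dict[str, list[Entry]] = {}
        for e in self.entries.values():
            if e.group is not None:
                out.setdefault(e.group, []).append(e)
        return out

    def free_entries(self) -> list[Entry]:
        return [e for e in self.entries.values() if e.is_free]

    def n_free_parameters(self) -> int:
        """Distinct free parameters; an equality group counts once."""
        seen_groups: set[str] = set()
        n = 0
        for e in self.entries.values():
            if not e.is_free:
                continue
            if e.group is None:
                n += 1
            elif e.group not in seen_groups:
                seen_groups.add(e.group)
                n += 1
        return n

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        for gid, members in self.groups().items():
            if len(members) < 2:
                raise ValueError(f"equality group {gid!r} has fewer than 2 members")
            if len({m.matrix for m in members}) != 1:
                raise ValueError(f"equality group {gid!r} mixes matrix types")
        pat = self.pattern
        for o1 in pat.occasions:
            for o2 in pat.occasions:
                if o1 == o2:
                    continue
                for i1 in pat.indicators:
                    for i2 in pat.indicators:
                        if i1 != i2:
                            ref = _theta_ref(i1, o1, i2, o2)
                            if ref in self.entries:
                                raise ValueError(
                                    "cross-occasion residual covariances exist only "
                                    f"between the same indicator; found {ref}"
                                )

    # -- values ------------------------------------------------------------

    def set_value(self, ref: str, value: float) -> None:
        e = self[ref]
        e.value = float(value)
        if e.group is not None:
            for m in self.groups()[e.group]:
                m.value = float(value)

    def to_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Assemble stacked (Lambda, Phi, Theta, tau, kappa), occasion-major.

        All entries must carry finite numeric values.
        """
        pat = self.pattern
        P, Q, T = pat.n_indicators, pat.n_factors, pat.n_occasions
        lam = np.zeros((P * T, Q * T))
        phi = np.zeros((Q * T, Q * T))
        theta = np.zeros((P * T, P * T))
        tau = np.zeros(P * T)
        kappa = np.zeros(Q * T)
        iocc = {o: t for t, o in enumerate(pat.occasions)}
        iind = {v: i for i, v in enumerate(pat.indicators)}
        ifac = {v: i for i, v in enumerate(pat.factors)}
        for e in self.entries.values():
            v = e.value
            if v is None or not np.isfinite(v):
                raise ValueError(f"entry {e.ref} has no finite value")
            if e.matrix == "lambda":
                r = iocc[e.occ_row] * P + iind[e.row]
                c = iocc[e.occ_row] * Q + ifac[e.col]
                lam[r, c] = v
            elif e.matrix == "phi":
                r = iocc[e.occ_row] * Q + ifac[e.row]
                c = iocc[e.occ_col] * Q + ifac[e.col]
                phi[r, c] = phi[c, r] = v
            elif e.matrix == "theta":
                r = iocc[e.occ_row] * P + iind[e.row]
                c = iocc[e.occ_col] * P + iind[e.col]
                theta[r, c] = theta[c, r] = v
            elif e.matrix == "tau":
                tau[iocc[e.occ_row] * P + iind[e.row]] = v
            elif e.matrix == "kappa":
                kappa[iocc[e.occ_row] * Q + ifac[e.row]] = v
            else:  # pragma: no cover
                raise ValueError(f"unknown matrix {e.matrix}")
        return lam, phi, theta, tau, kappa

    def to_frame(self):
        """Long-format view of the table (one row per entry) as a DataFrame."""
        import pandas as pd

        rows = []
        for e in self.entries.values():
            rows.append(
                {
                    "ref": e.ref,
                    "matrix": e.matrix,
                    "row": e.row,
                    "col": e.col,
                    "occ_row": e.occ_row,
                    "occ_col": e.occ_col,
                    "status": e.status,
                    "group": e.group,
                    "role": e.role,
                    "value": e.value,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied covariance matrix and mean vector (occasion-major)."""

    sigma: np.ndarray
    mu: np.ndarray


# ---------------------------------------------------------------------------
# construction


def build_parameter_table(pattern: ModelPattern) -> ParameterTable:
    """Create the full unrestricted parameter table for a pattern.

    Per occasion: one free loading per allowed pattern cell, a full symmetric
    factor covariance block, diagonal residual variances, P intercepts and Q
    factor means.  Across each occasion pair: a fully free factor-covariance
    block and same-indicator residual covariances.  No identification
    restrictions are imposed here.
    """
    t = ParameterTable(pattern=pattern)
    pat = pattern

    def add(e: Entry) -> None:
        t.entries[e.ref] = e

    for occ in pat.occasions:
        for ind_i, ind in enumerate(pat.indicators):
            for fac_j, fac in enumerate(pat.factors):
                if pat.loading_pattern[ind_i, fac_j]:
                    add(Entry(_lambda_ref(ind, fac, occ), "lambda", ind, fac, occ, occ))
    # phi: within-occasion lower triangles (incl. diagonal), then cross blocks
    for occ in pat.occasions:
        for i, f1 in enumerate(pat.factors):
            for j in range(i + 1):
                f2 = pat.factors[j]
                add(Entry(_phi_ref(f2, occ, f1, occ), "phi", f2, f1, occ, occ))
    for a, o1 in enumerate(pat.occasions):
        for o2 in pat.occasions[a + 1 :]:
            for f1 in pat.factors:
                for f2 in pat.factors:
                    add(Entry(_phi_ref(f1, o1, f2, o2), "phi", f1, f2, o1, o2))
    # theta: within-occasion diagonal; cross-occasion same-indicator only
    for occ in pat.occasions:
        for ind in pat.indicators:
            add(Entry(_theta_ref(ind, occ, ind, occ), "theta", ind, ind, occ, occ))
    for a, o1 in enumerate(pat.occasions):
        for o2 in pat.occasions[a + 1 :]:
            for ind in pat.indicators:
                add(Entry(_theta_ref(ind, o1, ind, o2), "theta", ind, ind, o1, o2))
    for occ in pat.occasions:
        for ind in pat.indicators:
            add(Entry(_tau_ref(ind, occ), "tau", ind, None, occ, occ))
    for occ in pat.occasions:
        for fac in pat.factors:
            add(Entry(_kappa_ref(fac, occ), "kappa", fac, None, occ, occ))
    return t


def apply_identification(table: ParameterTable, step: str) -> ParameterTable:
    """Impose identification restrictions for a procedure step, in place.

    ``step='step1'`` fixes every occasion's factor variances to 1 and factor
    means to 0 (each occasion's measurement scale set separately).  With the
    across-occasion equality restrictions of later steps, fixing only the
    first occasion suffices, so ``step='step2'`` (also used for Steps 3-4)
    frees the later occasions' factor variances and means.  Re-application in
    the same mode is a no-op; switching modes first reverts the previous
    identification fixes.
    """
    if step not in ("step1", "step2"):
        raise ValueError(f"unknown identification step tag: {step!r}")
    # revert previous identification fixes
    for e in table.entries.values():
        if e.role == "identification":
            e.status = FREE
            e.role = None
            e.value = None
    pat = table.pattern
    occs = pat.occasions if step == "step1" else pat.occasions[:1]
    for occ in occs:
        for fac in pat.factors:
            e = table[_phi_ref(fac, occ, fac, occ)]
            e.status, e.value, e.role, e.group = FIXED, 1.0, "identification", None
            e2 = table[_kappa_ref(fac, occ)]
            e2.status, e2.value, e2.role, e2.group = FIXED, 0.0, "identification", None
    table.identification = step
    return table


def impose_invariance(table: ParameterTable) -> ParameterTable:
    """Tie all loadings and intercepts into across-occasion equality groups.

    This is the Step-2 (no response shift) restriction: every allowed loading
    and every intercept is constrained equal over occasions.  Loadings freed
    from zero at a single occasion only (reconceptualization moves) have no
    counterpart and are left untouched.
    """
    pat = table.pattern
    for ind_i, ind in enumerate(pat.indicators):
        for fac_j, fac in enumerate(pat.factors):
            refs = [
                _lambda_ref(ind, fac, occ)
                for occ in pat.occasions
                if _lambda_ref(ind, fac, occ) in table
            ]
            if len(refs) == len(pat.occasions):
                gid = f"eq:lambda[{ind},{fac}]"
                for ref in refs:
                    table[ref].group = gid
        gid = f"eq:tau[{ind}]"
        for occ in pat.occasions:
            table[_tau_ref(ind, occ)].group = gid
    return table


def implied_moments(table: ParameterTable) -> ImpliedMoments:
    """Model-implied ``Sigma = Lambda Phi Lambda' + Theta``, ``mu = tau + Lambda kappa``."""
    lam, phi, theta, tau, kappa = table.to_matrices()
    sigma = lam @ phi @ lam.T + theta
    sigma = (sigma + sigma.T) / 2.0
    mu = tau + lam @ kappa
    return ImpliedMoments(sigma=sigma, mu=mu)


def n_sample_moments(P: int, T: int) -> int:
    """Number of distinct observed moments: PT(PT+1)/2 covariances + PT means."""
    m = P * T
    return m * (m + 1) // 2 + m


def degrees_of_freedom(table: ParameterTable, P: int | None = None, T: int | None = None) -> int:
    """Moment count minus distinct free parameters (equality groups count once)."""
    if P is None:
        P = table.pattern.n_indicators
    if T is None:
        T = table.pattern.n_occasions
    df = n_sample_moments(P, T) - table.n_free_parameters()
    if df < 0:
        raise ValueError(
            f"model has more free parameters ({table.n_free_parameters()}) than "
            f"sample moments ({n_sample_moments(P, T)}): not identified by counting rule"
        )
    return df


_REF_PATTERNS = (
    ("lambda", re.compile(r"^lambda\[([^,\]]+),([^,\]]+)\]@(.+)$")),
    ("phi", re.compile(r"^phi\[([^@,\]]+)@([^,\]]+),([^@,\]]+)@([^\]]+)\]$")),
    ("theta", re.compile(r"^theta\[([^@,\]]+)@([^,\]]+),([^@,\]]+)@([^\]]+)\]$")),
    ("tau", re.compile(r"^tau\[([^\]]+)\]@(.+)$")),
    ("kappa", re.compile(r"^kappa\[([^\]]+)\]@(.+)$")),
)


def parse_ref(ref: str, pattern: ModelPattern) -> Entry:
    """Parse an entry reference string into an (unvalued, free) :class:`Entry`.

    Used to address parameters that do not yet exist in a table: pattern-zero
    loadings and within-occasion residual covariances, which can be created
    by :func:`release_parameter`.
    """
    for matrix, rx in _REF_PATTERNS:
        m = rx.match(ref)
        if not m:
            continue
        if matrix == "lambda":
            ind, fac, occ = m.groups()
            if ind not in pattern.indicators or fac not in pattern.factors:
                raise ValueError(f"unknown indicator/factor in {ref!r}")
            if occ not in pattern.occasions:
                raise ValueError(f"unknown occasion in {ref!r}")
            return Entry(ref, "lambda", ind, fac, occ, occ)
        if matrix in ("phi", "theta"):
            r1, o1, r2, o2 = m.groups()
            names = pattern.factors if matrix == "phi" else pattern.indicators
            if r1 not in names or r2 not in names:
                raise ValueError(f"unknown label in {ref!r}")
            if o1 not in pattern.occasions or o2 not in pattern.occasions:
                raise ValueError(f"unknown occasion in {ref!r}")
            return Entry(ref, matrix, r1, r2, o1, o2)
        lbl, occ = m.groups()
        names = pattern.indicators if matrix == "tau" else pattern.factors
        if lbl not in names or occ not in pattern.occasions:
            raise ValueError(f"unknown label/occasion in {ref!r}")
        return Entry(ref, matrix, lbl, None, occ, occ)
    raise ValueError(f"cannot parse parameter reference {ref!r}")


def release_parameter(table: ParameterTable, ref: str, occasion: str | None = None) -> ParameterTable:
    """Return a copy of the table with exactly one constraint removed.

    ``ref`` may name an across-occasion equality group (split one occasion's
    member out of the group; default the last occasion), a fixed entry other
    than an identification restriction (freed), or a structurally excluded
    parameter that is addressable by reference — a pattern-zero loading at
    one occasion or a within-occasion residual covariance — which is added to
    the table as a new free entry.  The number of distinct free parameters
    increases by exactly one, so model degrees of freedom drop by one.
    """
    new = table.copy()
    groups = new.groups()
    if ref not in new.entries and ref not in groups:
        e = parse_ref(ref, new.pattern)
        if e.matrix == "lambda":
            pass  # pattern-zero loading freed at a single occasion
        elif e.matrix == "theta":
            if e.occ_row != e.occ_col:
                raise ValueError(
                    "cross-occasion residual covariances other than same-indicator "
                    f"ones are not allowed: {ref}"
                )
            if e.row == e.col:
                raise ValueError(f"{ref} duplicates an existing variance entry")
        else:
            raise ValueError(f"{ref} cannot be added to the model")
        e.status = FREE
        e.value = None
        new.entries[e.ref] = e
        return new
    if ref in groups:
        members = groups[ref]
        if occasion is None:
            occasion = new.pattern.occasions[-1]
        split = [m for m in members if m.occ_row == occasion]
        if not split:
            raise ValueError(f"group {ref!r} has no member at occasion {occasion!r}")
        for m in split:
            m.group = None
        remaining = [m for m in members if m.occ_row != occasion]
        if len(remaining) == 1:
            remaining[0].group = None
        return new
    e = new[ref]
    if e.role == "identification":
        raise ValueError(f"{ref} is an identification restriction and cannot be released")
    if e.is_free and e.group is None:
        raise ValueError(f"{ref} is already a free parameter")
    if e.group is not None:
        # releasing a grouped member directly: split it from its group
        gid = e.group
        e.group = None
        remaining = [m for m in new.groups().get(gid, [])]
        if len(remaining) == 1:
            remaining[0].group = None
        return new
    e.status = FREE
    e.value = None
    return new
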