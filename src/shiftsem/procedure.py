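"""The four-step response-shift detection procedure.

Step 1 establishes the longitudinal measurement model (the configured factor
structure at every occasion, cross-occasion factor covariances, and
same-indicator residual covariances).  Step 2 is the omnibus invariance
test: all loadings and intercepts are constrained equal over occasions and
the restricted model is compared against Step 1; a significant deterioration
signals response shift somewhere.  Step 3 searches for the specific shifts
by releasing one invariance constraint at a time — the release with the
largest significant likelihood-ratio improvement is incorporated, classified
as recalibration (intercept), reprioritization (loading value) or
reconceptualization (loading pattern) — until the stopping rule fires.
Step 4 reads 'true' change from the factor means of the final model and
contrasts it with the naive (no-shift) Step-2 estimates; observed mean
change is decomposed exactly into recalibration, reprioritization/
reconceptualization and true-change components.

Because near-equivalent releases are common, ties (candidates within a
chi-square tolerance of the best) are always recorded, and
:func:`explore_sequences` forks the search at every tie to show which
findings recur across alternative specification sequences.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    FitOptions,
    FittedModel,
    SampleMoments,
    compute_moments,
    fit,
    modification_indices,
    wald_test,
)
from .fit_indices import ComparisonResult, FitIndexSet, compare_nested, overall_fit
from .model_core import (
    ModelPattern,
    ParameterTable,
    apply_identification,
    build_parameter_table,
    impose_invariance,
    release_parameter,
)

__all__ = [
    "ProcedureOptions",
    "ShiftFinding",
    "SearchTrace",
    "TrueChangeResult",
    "DecompositionRow",
    "PipelineResult",
    "step1_establish_lmm",
    "step2_omnibus",
    "step3_search",
    "explore_sequences",
    "step4_true_change",
    "decompose_change",
    "effect_sizes",
    "run_pipeline",
]


@dataclass
class ProcedureOptions:
    """Tunable controls of the detection procedure.

    alpha_omnibus : significance level of the Step-2 omnibus test and of the
        model-level (final vs measurement model) stopping comparison.
    alpha_step : per-candidate significance level in the Step-3 search.
    bonferroni : divide ``alpha_step`` by the candidate count per iteration.
    tie_tolerance : two candidates whose chi-square improvements differ by
        less than this are treated as statistically equivalent.
    stop_rule : 'candidates' (stop when no candidate is individually
        significant), 'omnibus' (stop when the current model no longer
        differs significantly from the measurement model), or 'both'
        (default; stop only when both conditions hold, so the search can
        continue past individually non-significant releases while the
        model-level gap remains significant).
    allow_reconceptualization : include pattern-zero loadings at follow-up
        occasions in the candidate set.
    auto_modify : let Step 1 free top-ranked residual covariances or
        cross-loadings (at most ``max_modifications``) when the measurement
        model fits poorly.
    decomposition : 'baseline' weights true change by baseline loadings and
        the pattern/value component by follow-up factor means;
        'followup' is the mirrored convention.
    """

    alpha_omnibus: float = 0.05
    alpha_step: float = 0.05
    bonferroni: bool = False
    tie_tolerance: float = 0.5
    stop_rule: str = "both"
    allow_reconceptualization: bool = False
    auto_modify: bool = False
    max_modifications: int = 3
    rmsea_adequate: float = 0.08
    max_iterations: int = 20
    max_branches: int = 8
    prescreen_threshold: int = 24
    prescreen_top: int = 12
    decomposition: str = "baseline"
    effect_size_bands: tuple[float, float, float] = (0.2, 0.5, 0.8)
    seed: int = 0
    restarts: int = 5

    def __post_init__(self) -> None:
        if self.stop_rule not in ("candidates", "omnibus", "both"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.decomposition not in ("baseline", "followup"):
            raise ValueError(f"unknown decomposition convention {self.decomposition!r}")
        for name in ("alpha_omnibus", "alpha_step"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be >= 0")


@dataclass
class ShiftFinding:
    """One detected response shift."""

    indicator: str
    occasions: tuple[str, str]
    shift_type: str
    ref: str
    estimate_t1: float
    estimate_t2: float
    delta: float
    delta_chi_square: float
    p: float
    sequence: int
    factor: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occasions"] = list(self.occasions)
        return d


@dataclass
class SearchTrace:
    """Full record of a Step-3 specification search."""

    branch: str = "A"
    iterations: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    stopped_because: str = ""

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "iterations": self.iterations,
            "skipped": self.skipped,
            "stopped_because": self.stopped_because,
        }


@dataclass
class TrueChangeRow:
    factor: str
    occasion: str
    estimate: float
    se: float | None
    wald: float | None
    p: float | None
    estimate_no_shift: float
    se_no_shift: float | None
    p_no_shift: float | None
    shift_impact: float


@dataclass
class TrueChangeResult:
    """Factor-mean change with and without accounting for response shift."""

    rows: list[TrueChangeRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


@dataclass
class DecompositionRow:
    """Per-indicator split of model-implied observed mean change."""

    indicator: str
    occasion: str
    observed_change: float
    recalibration: float
    reprioritization_reconceptualization: float
    true_change: float


# ---------------------------------------------------------------------------
# steps 1 and 2


def _fit_opts(options: ProcedureOptions, compute_se: bool = True) -> FitOptions:
    return FitOptions(seed=options.seed, restarts=options.restarts, compute_se=compute_se)


def step1_establish_lmm(
    moments: SampleMoments,
    pattern: ModelPattern,
    options: ProcedureOptions | None = None,
) -> FittedModel:
    """Fit the longitudinal measurement model (Step 1).

    When overall fit is inadequate (RMSEA at or above the configured bound),
    ranked modification candidates — within-occasion residual covariances and
    cross-loadings — are attached as ``modification_candidates``; with
    ``auto_modify`` the top candidate is freed and the model refitted, at
    most ``max_modifications`` times, each application logged.
    """
    options = options or ProcedureOptions()
    table = apply_identification(build_parameter_table(pattern), "step1")
    fitted = fit(table, moments, _fit_opts(options))
    applied: list[str] = []
    while fitted.converged:
        fi = overall_fit(fitted)
        adequate = fi.rmsea is None or fi.rmsea < options.rmsea_adequate
        fitted.fit_indices = fi  # type: ignore[attr-defined]
        cands = _measurement_candidates(fitted.table)
        if adequate or not cands:
            fitted.modification_candidates = []  # type: ignore[attr-defined]
            break
        mods = modification_indices(fitted, cands)
        fitted.modification_candidates = mods  # type: ignore[attr-defined]
        if not options.auto_modify or len(applied) >= options.max_modifications:
            break
        top = mods[0]
        applied.append(top.ref)
        fitted = fit(release_parameter(fitted.table, top.ref), moments, _fit_opts(options))
        fitted.log.append(f"auto-modify: freed {top.ref} (MI={top.mod_index:.2f})")
    fitted.modifications_applied = applied  # type: ignore[attr-defined]
    return fitted


def _measurement_candidates(table: ParameterTable) -> list[str]:
    """Residual-covariance and cross-loading candidates for Step-1 respecification."""
    pat = table.pattern
    cands: list[str] = []
    for occ in pat.occasions:
        for i, a in enumerate(pat.indicators):
            for b in pat.indicators[i + 1 :]:
                ref = f"theta[{a}@{occ},{b}@{occ}]"
                if ref not in table:
                    cands.append(ref)
        for i, ind in enumerate(pat.indicators):
            for j, fac in enumerate(pat.factors):
                if pat.loading_pattern[i, j] == 0:
                    ref = f"lambda[{ind},{fac}]@{occ}"
                    if ref not in table:
                        cands.append(ref)
    return cands


def step2_omnibus(
    lmm: FittedModel, options: ProcedureOptions | None = None
) -> tuple[FittedModel, ComparisonResult]:
    """Fit the full-invariance model and run the omnibus response-shift test.

    All across-occasion loading and intercept equalities are imposed on top
    of the measurement model; identification switches to the Step-2 mode in
    which follow-up factor variances and means are free.  The returned
    comparison's ``significant`` flag is the omnibus verdict: response shift
    is present somewhere iff the restrictions significantly worsen fit.
    """
    options = options or ProcedureOptions()
    if not lmm.converged:
        raise ValueError("Step 2 requires a converged measurement model")
    table = lmm.table.copy()
    impose_invariance(table)
    apply_identification(table, "step2")
    # warm start for the newly freed follow-up factor variances and means
    for e in table.entries.values():
        if e.value is None:
            e.value = 1.0 if e.matrix == "phi" else 0.0
    fitted = fit(table, lmm.moments, _fit_opts(options))
    comparison = compare_nested(lmm, fitted, alpha=options.alpha_omnibus)
    return fitted, comparison


# ---------------------------------------------------------------------------
# step 3: specification search


def _type_rank(ref: str) -> int:
    if ref.startswith("eq:tau["):
        return 0
    if ref.startswith("eq:lambda["):
        return 1
    return 2


def _ref_indicator(ref: str, pattern: ModelPattern) -> str:
    inner = ref.split("[", 1)[1]
    return inner.split(",", 1)[0].split("]", 1)[0]


def _indicator_rank(ref: str, pattern: ModelPattern) -> int:
    ind = _ref_indicator(ref, pattern)
    return pattern.indicators.index(ind) if ind in pattern.indicators else 99


def _factors_of(pattern: ModelPattern, indicator: str) -> list[str]:
    i = pattern.indicators.index(indicator)
    return [f for j, f in enumerate(pattern.factors) if pattern.loading_pattern[i, j]]


def _shift_candidates(table: ParameterTable, options: ProcedureOptions) -> list[str]:
    """Releasable invariance constraints, with an identifiability guard.

    Releasing is disallowed when it would leave a factor without any
    invariant loading (its follow-up variance would lose its scale) or any
    invariant intercept among its indicators (its follow-up mean would be
    unidentified).
    """
    pat = table.pattern
    groups = table.groups()

    def intact_tau(ind: str) -> bool:
        return f"eq:tau[{ind}]" in groups

    def intact_lambda(ind: str, fac: str) -> bool:
        return f"eq:lambda[{ind},{fac}]" in groups

    cands: list[str] = []
    for ind in pat.indicators:
        gid = f"eq:tau[{ind}]"
        if gid not in groups:
            continue
        ok = all(
            any(intact_tau(other) for other in pat.indicators
                if other != ind and fac in _factors_of(pat, other))
            for fac in _factors_of(pat, ind)
        )
        if ok:
            cands.append(gid)
    for ind in pat.indicators:
        for fac in _factors_of(pat, ind):
            gid = f"eq:lambda[{ind},{fac}]"
            if gid not in groups:
                continue
            others = [
                o for o in pat.indicators
                if o != ind and fac in _factors_of(pat, o) and intact_lambda(o, fac)
            ]
            if others:
                cands.append(gid)
    if options.allow_reconceptualization:
        for occ in pat.occasions[1:]:
            for i, ind in enumerate(pat.indicators):
                for j, fac in enumerate(pat.factors):
                    if pat.loading_pattern[i, j] == 0:
                        ref = f"lambda[{ind},{fac}]@{occ}"
                        if ref not in table:
                            cands.append(ref)
    return cands


@dataclass
class _CandidateResult:
    ref: str
    delta_chi_square: float
    p: float
    fitted: FittedModel


def _evaluate_candidates(
    current: FittedModel,
    cands: Sequence[str],
    options: ProcedureOptions,
    trace: SearchTrace,
    iteration: int,
) -> list[_CandidateResult]:
    if len(cands) > options.prescreen_threshold:
        mis = modification_indices(current, cands)
        keep = {m.ref for m in mis[: options.prescreen_top]}
        cands = [c for c in cands if c in keep]
    results: list[_CandidateResult] = []
    for ref in cands:
        tbl = release_parameter(current.table, ref)
        fm = fit(tbl, current.moments, _fit_opts(options, compute_se=False))
        if not fm.converged:
            trace.skipped.append({"iteration": iteration, "ref": ref, "reason": "non-convergence"})
            continue
        dchi = max(current.chi_square - fm.chi_square, 0.0)
        results.append(
            _CandidateResult(ref, dchi, float(stats.chi2.sf(dchi, 1)), fm)
        )
    pat = current.table.pattern
    results.sort(
        key=lambda r: (-r.delta_chi_square, _type_rank(r.ref), _indicator_rank(r.ref, pat), r.ref)
    )
    return results


def _classify(ref: str, table: ParameterTable) -> tuple[str, str, str | None, float, float]:
    """(indicator, shift_type, factor, estimate at baseline, at follow-up)."""
    pat = table.pattern
    t1, t2 = pat.occasions[0], pat.occasions[-1]
    if ref.startswith("eq:tau["):
        ind = ref[len("eq:tau[") : -1]
        return ind, "recalibration", None, table[f"tau[{ind}]@{t1}"].value, table[f"tau[{ind}]@{t2}"].value
    if ref.startswith("eq:lambda["):
        ind, fac = ref[len("eq:lambda[") : -1].split(",")
        return (
            ind, "reprioritization", fac,
            table[f"lambda[{ind},{fac}]@{t1}"].value,
            table[f"lambda[{ind},{fac}]@{t2}"].value,
        )
    # plain entry: a loading freed from zero at a single occasion
    from .model_core import parse_ref

    e = parse_ref(ref, pat)
    other = t1 if e.occ_row != t1 else t2
    other_ref = f"lambda[{e.row},{e.col}]@{other}"
    other_val = table[other_ref].value if other_ref in table else 0.0
    if e.occ_row == t1:
        return e.row, "reconceptualization", e.col, table[ref].value if ref in table else 0.0, other_val
    return e.row, "reconceptualization", e.col, other_val, table[ref].value if ref in table else 0.0


def _finding_from(
    ref: str, fitted: FittedModel, dchi: float, p: float, seq: int
) -> ShiftFinding:
    ind, stype, fac, v1, v2 = _classify(ref, fitted.table)
    pat = fitted.table.pattern
    return ShiftFinding(
        indicator=ind,
        occasions=(pat.occasions[0], pat.occasions[-1]),
        shift_type=stype,
        ref=ref,
        estimate_t1=float(v1),
        estimate_t2=float(v2),
        delta=float(v2 - v1),
        delta_chi_square=float(dchi),
        p=float(p),
        sequence=seq,
        factor=fac,
    )


def _search_step(
    current: FittedModel,
    step1_model: FittedModel,
    options: ProcedureOptions,
    trace: SearchTrace,
    iteration: int,
    excluded: set[str],
):
    """Evaluate one search iteration.

    Returns ``(stop_reason or None, eligible, ranking, forced)`` where
    ``eligible`` is the tie set from which the next release is to be chosen.
    """
    vs1 = None
    if current.df > step1_model.df:
        try:
            vs1 = compare_nested(step1_model, current, alpha=options.alpha_omnibus)
        except ValueError:
            # a reconceptualization release can make the current model fit
            # better than the measurement model (which lacks that loading);
            # then the model-level gap is certainly not significant
            vs1 = None
    vs1_sig = vs1 is not None and vs1.significant
    cands = [c for c in _shift_candidates(current.table, options) if c not in excluded]
    if not cands:
        return "no remaining candidates", [], [], False
    results = _evaluate_candidates(current, cands, options, trace, iteration)
    if not results:
        return "all candidate refits failed", [], [], False
    alpha = options.alpha_step / len(results) if options.bonferroni else options.alpha_step
    sig = [r for r in results if r.p < alpha]
    forced = False
    if options.stop_rule == "candidates":
        if not sig:
            return "no significant candidate", [], results, False
        pool = sig
    elif options.stop_rule == "omnibus":
        if not vs1_sig:
            return "model no longer differs from measurement model", [], results, False
        pool = sig if sig else results
        forced = not sig
    else:  # both
        if not sig and not vs1_sig:
            return (
                "no significant candidate and model no longer differs "
                "from measurement model",
                [], results, False,
            )
        pool = sig if sig else results
        forced = not sig
    if forced and pool[0].delta_chi_square <= 0.0:
        return "no candidate improves fit", [], results, forced
    top = pool[0].delta_chi_square
    pat = current.table.pattern
    eligible = sorted(
        (r for r in pool if top - r.delta_chi_square <= options.tie_tolerance),
        key=lambda r: (_type_rank(r.ref), _indicator_rank(r.ref, pat), r.ref),
    )
    return None, eligible, results, forced


def _record_iteration(
    trace: SearchTrace,
    iteration: int,
    ranking: Sequence[_CandidateResult],
    chosen: str | None,
    eligible: Sequence[_CandidateResult],
    forced: bool,
    current: FittedModel,
) -> None:
    trace.iterations.append(
        {
            "iteration": iteration,
            "ranking": [
                {"ref": r.ref, "delta_chi_square": r.delta_chi_square, "p": r.p}
                for r in ranking
            ],
            "chosen": chosen,
            "tie_set": [r.ref for r in eligible],
            "forced": forced,
            "chi_square": current.chi_square,
            "df": current.df,
        }
    )


def step3_search(
    step2_model: FittedModel,
    step1_model: FittedModel,
    options: ProcedureOptions | None = None,
) -> tuple[FittedModel, list[ShiftFinding], SearchTrace]:
    """Iterative one-at-a-time release of invariance constraints (Step 3).

    Every remaining loading equality, intercept equality and (optionally)
    pattern-zero follow-up loading is refitted with exactly one release; the
    largest significant chi-square improvement is incorporated and classified
    as a :class:`ShiftFinding`.  Ties within ``tie_tolerance`` are recorded
    in the trace and broken deterministically (intercepts before loadings,
    then indicator declaration order).  A freed reconceptualization loading
    whose estimate is not significant by Wald test is rolled back.  Finding
    estimates are refreshed from the final model before returning.
    """
    options = options or ProcedureOptions()
    trace = SearchTrace(branch="A")
    current = step2_model
    findings: list[ShiftFinding] = []
    excluded: set[str] = set()
    for iteration in range(1, options.max_iterations + 1):
        stop, eligible, ranking, forced = _search_step(
            current, step1_model, options, trace, iteration, excluded
        )
        if stop is not None:
            _record_iteration(trace, iteration, ranking, None, [], forced, current)
            trace.stopped_because = stop
            break
        chosen = eligible[0]
        _record_iteration(trace, iteration, ranking, chosen.ref, eligible, forced, current)
        current, finding, rolled_back = _incorporate(
            current, chosen, options, len(findings) + 1
        )
        if rolled_back:
            excluded.add(chosen.ref)
            trace.skipped.append(
                {"iteration": iteration, "ref": chosen.ref,
                 "reason": "freed loading not significant by Wald test; rolled back"}
            )
            continue
        findings.append(finding)
    else:
        trace.stopped_because = "maximum number of iterations reached"
    final = _refresh_findings(current, findings, options)
    return final, findings, trace


def _incorporate(
    current: FittedModel,
    chosen: _CandidateResult,
    options: ProcedureOptions,
    seq: int,
) -> tuple[FittedModel, ShiftFinding | None, bool]:
    refit = fit(chosen.fitted.table, current.moments, _fit_opts(options))
    if _type_rank(chosen.ref) == 2 and refit.cov_params is not None:
        w, p_w = wald_test(refit, chosen.ref)
        if p_w >= options.alpha_step:
            return current, None, True
    finding = _finding_from(chosen.ref, refit, chosen.delta_chi_square, chosen.p, seq)
    return refit, finding, False


def _refresh_findings(
    final: FittedModel, findings: list[ShiftFinding], options: ProcedureOptions
) -> FittedModel:
    """Re-read finding magnitudes from the final model's estimates."""
    if final.cov_params is None and final.converged:
        final = fit(final.table, final.moments, _fit_opts(options))
    for f in findings:
        ind, stype, fac, v1, v2 = _classify(f.ref, final.table)
        f.estimate_t1, f.estimate_t2, f.delta = float(v1), float(v2), float(v2 - v1)
    return final


def explore_sequences(
    step2_model: FittedModel,
    step1_model: FittedModel,
    options: ProcedureOptions | None = None,
) -> list[tuple[str, list[ShiftFinding], FittedModel, SearchTrace]]:
    """Branch the Step-3 search at every statistical tie.

    Whenever two or more candidates fall within ``tie_tolerance`` of the top
    chi-square improvement, one branch per tied candidate is explored (up to
    ``max_branches`` in total; hitting the cap is recorded in the affected
    branch's trace).  Returns per-branch results; the cross-branch frequency
    of each finding is available via :func:`finding_frequencies`.
    """
    options = options or ProcedureOptions()

    @dataclass
    class _State:
        label: str
        current: FittedModel
        findings: list[ShiftFinding]
        trace: SearchTrace
        excluded: set[str]
        iteration: int

    states = [_State("A", step2_model, [], SearchTrace(branch="A"), set(), 1)]
    done: list[_State] = []
    n_total = 1
    while states:
        st = states.pop(0)
        if st.iteration > options.max_iterations:
            st.trace.stopped_because = "maximum number of iterations reached"
            done.append(st)
            continue
        stop, eligible, ranking, forced = _search_step(
            st.current, step1_model, options, st.trace, st.iteration, st.excluded
        )
        if stop is not None:
            _record_iteration(st.trace, st.iteration, ranking, None, [], forced, st.current)
            st.trace.stopped_because = stop
            done.append(st)
            continue
        fork = eligible
        if len(eligible) > 1 and n_total + len(eligible) - 1 > options.max_branches:
            fork = eligible[:1]
            st.trace.iterations.append(
                {"iteration": st.iteration, "note": "branch cap reached; deterministic choice"}
            )
        if len(fork) > 1:
            n_total += len(fork) - 1
        for k, cand in enumerate(fork):
            child = _State(
                label=st.label if len(fork) == 1 else f"{st.label}.{k + 1}",
                current=st.current,
                findings=[copy.deepcopy(f) for f in st.findings],
                trace=copy.deepcopy(st.trace),
                excluded=set(st.excluded),
                iteration=st.iteration,
            )
            child.trace.branch = child.label
            _record_iteration(
                child.trace, child.iteration, ranking, cand.ref, eligible, forced, child.current
            )
            new_model, finding, rolled_back = _incorporate(
                child.current, cand, options, len(child.findings) + 1
            )
            if rolled_back:
                child.excluded.add(cand.ref)
                child.trace.skipped.append(
                    {"iteration": child.iteration, "ref": cand.ref,
                     "reason": "freed loading not significant by Wald test; rolled back"}
                )
            else:
                child.current = new_model
                child.findings.append(finding)
            child.iteration += 1
            states.append(child)
    out = []
    for st in done:
        final = _refresh_findings(st.current, st.findings, options)
        out.append((st.label, st.findings, final, st.trace))
    out.sort(key=lambda t: t[0])
    return out


def finding_frequencies(
    branches: Sequence[tuple[str, list[ShiftFinding], FittedModel, SearchTrace]]
) -> pd.DataFrame:
    """Fraction of branches in which each (indicator, type) finding occurs."""
    counts: dict[tuple[str, str], int] = {}
    for _label, findings, _final, _trace in branches:
        for key in {(f.indicator, f.shift_type) for f in findings}:
            counts[key] = counts.get(key, 0) + 1
    nb = max(len(branches), 1)
    rows = [
        {"indicator": ind, "shift_type": st, "branches": c, "frequency": c / nb}
        for (ind, st), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["indicator", "shift_type", "branches", "frequency"])


# ---------------------------------------------------------------------------
# step 4 and interpretation


def step4_true_change(
    final: FittedModel, step2_model: FittedModel
) -> TrueChangeResult:
    """Factor-mean change from the final model vs the no-shift model (Step 4).

    Baseline factor means are fixed to zero for identification, so the free
    follow-up mean of each factor is its change since baseline.  The same
    quantity from the Step-2 (full invariance) model shows what would have
    been concluded had response shift been ignored; the per-factor difference
    is the impact of response shift on true change.
    """
    if not (final.converged and step2_model.converged):
        raise ValueError("true-change assessment requires converged models")
    pat = final.table.pattern
    rows: list[TrueChangeRow] = []
    for occ in pat.occasions[1:]:
        for fac in pat.factors:
            ref = f"kappa[{fac}]@{occ}"
            est = final.estimate(ref)
            se = w = p = None
            if final.cov_params is not None:
                se = final.se(ref)
                w, p = wald_test(final, ref)
            est0 = step2_model.estimate(ref)
            se0 = p0 = None
            if step2_model.cov_params is not None:
                se0 = step2_model.se(ref)
                _, p0 = wald_test(step2_model, ref)
            rows.append(
                TrueChangeRow(
                    factor=fac, occasion=occ, estimate=est, se=se, wald=w, p=p,
                    estimate_no_shift=est0, se_no_shift=se0, p_no_shift=p0,
                    shift_impact=est - est0,
                )
            )
    return TrueChangeResult(rows=rows)


def decompose_change(
    final: FittedModel, convention: str = "baseline"
) -> list[DecompositionRow]:
    """Split model-implied observed mean change per indicator, exactly.

    With mu = tau + Lambda kappa per occasion,

        mu_2 - mu_1 = (tau_2 - tau_1)                          recalibration
                    + (Lambda_2 - Lambda_1) kappa_w            pattern/value shift
                    + Lambda_w (kappa_2 - kappa_1)             true change

    where the 'baseline' convention takes the weights kappa_w = kappa_2 and
    Lambda_w = Lambda_1, and 'followup' takes kappa_w = kappa_1 and
    Lambda_w = Lambda_2.  Either way the three components sum to the implied
    change identically.
    """
    if convention not in ("baseline", "followup"):
        raise ValueError(f"unknown decomposition convention {convention!r}")
    pat = final.table.pattern
    P, Q = pat.n_indicators, pat.n_factors
    lam, phi, theta, tau, kappa = final.table.to_matrices()
    rows: list[DecompositionRow] = []
    lam1 = lam[0:P, 0:Q]
    tau1 = tau[0:P]
    k1 = kappa[0:Q]
    for t, occ in enumerate(pat.occasions[1:], start=1):
        lam2 = lam[t * P : (t + 1) * P, t * Q : (t + 1) * Q]
        tau2 = tau[t * P : (t + 1) * P]
        k2 = kappa[t * Q : (t + 1) * Q]
        recal = tau2 - tau1
        if convention == "baseline":
            shift = (lam2 - lam1) @ k2
            true = lam1 @ (k2 - k1)
        else:
            shift = (lam2 - lam1) @ k1
            true = lam2 @ (k2 - k1)
        observed = recal + shift + true
        for i, ind in enumerate(pat.indicators):
            rows.append(
                DecompositionRow(
                    indicator=ind, occasion=occ,
                    observed_change=float(observed[i]),
                    recalibration=float(recal[i]),
                    reprioritization_reconceptualization=float(shift[i]),
                    true_change=float(true[i]),
                )
            )
    return rows


def effect_sizes(
    final: FittedModel,
    moments: SampleMoments | None = None,
    bands: tuple[float, float, float] = (0.2, 0.5, 0.8),
    convention: str = "baseline",
) -> pd.DataFrame:
    """Standardized change and decomposition components.

    Factor rows give latent change in baseline-factor-SD units (the SD is 1
    by identification).  Indicator rows divide each decomposition component
    by the indicator's baseline observed standard deviation.  Magnitude
    labels use the conventional small/medium/large bands.
    """
    moments = moments or final.moments

    def band(v: float) -> str:
        a = abs(v)
        if a < bands[0]:
            return "trivial"
        if a < bands[1]:
            return "small"
        if a < bands[2]:
            return "medium"
        return "large"

    pat = final.table.pattern
    P = pat.n_indicators
    rows = []
    for occ in pat.occasions[1:]:
        for fac in pat.factors:
            dk = final.estimate(f"kappa[{fac}]@{occ}")
            rows.append(
                {"name": fac, "kind": "factor", "occasion": occ,
                 "component": "true_change", "effect_size": float(dk),
                 "magnitude": band(dk)}
            )
    base_sd = np.sqrt(np.diag(moments.S)[:P])
    if (base_sd == 0).any():
        raise ValueError("zero baseline standard deviation")
    for row in decompose_change(final, convention):
        i = pat.indicators.index(row.indicator)
        for comp in ("observed_change", "recalibration",
                     "reprioritization_reconceptualization", "true_change"):
            v = getattr(row, comp) / base_sd[i]
            rows.append(
                {"name": row.indicator, "kind": "indicator", "occasion": row.occasion,
                 "component": comp, "effect_size": float(v), "magnitude": band(v)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    """Artifacts of one full run of the four-step procedure."""

    pattern: ModelPattern
    moments: SampleMoments
    options: ProcedureOptions
    step1: FittedModel
    step1_fit: FitIndexSet
    step2: FittedModel
    step2_fit: FitIndexSet
    omnibus: ComparisonResult
    final: FittedModel
    final_fit: FitIndexSet | None
    findings: list[ShiftFinding]
    trace: SearchTrace | None
    true_change: TrueChangeResult | None
    decomposition: list[DecompositionRow] | None
    effect_sizes: pd.DataFrame | None

    @property
    def response_shift_detected(self) -> bool:
        return bool(self.findings)


def run_pipeline(
    data: pd.DataFrame | SampleMoments,
    pattern: ModelPattern,
    options: ProcedureOptions | None = None,
    through_step: int = 4,
) -> PipelineResult:
    """Execute Steps 1-4 on a wide-format dataset (or precomputed moments)."""
    options = options or ProcedureOptions()
    if isinstance(data, SampleMoments):
        moments = data
    else:
        moments = compute_moments(data, pattern.column_names())
    step1 = step1_establish_lmm(moments, pattern, options)
    if not step1.converged:
        raise RuntimeError(
            "the longitudinal measurement model did not converge; "
            "check the model specification and data"
        )
    step1_fit = overall_fit(step1)
    step2, omnibus = step2_omnibus(step1, options)
    step2_fit = overall_fit(step2)
    findings: list[ShiftFinding] = []
    trace: SearchTrace | None = None
    final = step2
    if through_step >= 3 and omnibus.significant:
        final, findings, trace = step3_search(step2, step1, options)
    true_change = None
    decomposition = None
    es = None
    final_fit = overall_fit(final) if final.converged else None
    if through_step >= 4 and final.converged:
        true_change = step4_true_change(final, step2)
        decomposition = decompose_change(final, options.decomposition)
        es = effect_sizes(final, moments, options.effect_size_bands, options.decomposition)
    return PipelineResult(
        pattern=pattern, moments=moments, options=options,
        step1=step1, step1_fit=step1_fit, step2=step2, step2_fit=step2_fit,
        omnibus=omnibus, final=final, final_fit=final_fit,
        findings=findings, trace=trace, true_change=true_change,
        decomposition=decomposition, effect_sizes=es,
    )
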