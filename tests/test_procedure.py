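"""The four-step detection procedure: omnibus test, specification search,
tie handling, true-change assessment, decomposition and effect sizes."""

import json

import numpy as np
import pytest

from shiftsem.estimation import SampleMoments, compute_moments
from shiftsem.model_core import (
    apply_identification,
    build_parameter_table,
    impose_invariance,
    parse_model_config,
)
from shiftsem.procedure import (
    ProcedureOptions,
    decompose_change,
    effect_sizes,
    explore_sequences,
    finding_frequencies,
    run_pipeline,
    step1_establish_lmm,
    step2_omnibus,
    step3_search,
    step4_true_change,
    _shift_candidates,
)
from shiftsem.simulate import (
    Injection,
    SimulationSpec,
    example_generating_table,
    generate_dataset,
    implied_population_moments,
)


def _population_moments(table, injections=(), n=500):
    sigma, mu = implied_population_moments(
        SimulationSpec(table=table, injections=injections, n=1, seed=0)
    )
    return SampleMoments(S=sigma, xbar=mu, n=n)


class TestStep2Omnibus:
    def test_structural_counts(self, step2_result, step1_fitted):
        """Nine loading and nine intercept equalities; delta df = 12."""
        step2, cmp_ = step2_result
        groups = step2.table.groups()
        lam_groups = [g for g in groups if g.startswith("eq:lambda")]
        tau_groups = [g for g in groups if g.startswith("eq:tau")]
        assert len(lam_groups) == 9
        assert len(tau_groups) == 9
        assert all(len(groups[g]) == 2 for g in groups)
        assert cmp_.delta_df == 12
        assert step2.df - step1_fitted.df == 12

    def test_null_data_verdict_negative(self, step2_result):
        _, cmp_ = step2_result
        assert not cmp_.significant  # fixture dataset is invariant by construction

    def test_injected_shift_flips_verdict(self, generating_table, pattern):
        mom = _population_moments(
            generating_table, (Injection("anxiety", "reprioritization", 0.3),), n=2000
        )
        s1 = step1_establish_lmm(mom, pattern)
        _, cmp_ = step2_omnibus(s1)
        assert cmp_.significant

    def test_unconverged_input_rejected(self, step1_fitted):
        import copy

        bad = copy.copy(step1_fitted)
        bad.converged = False
        with pytest.raises(ValueError, match="converged"):
            step2_omnibus(bad)


class TestStep3Search:
    def test_no_shift_in_population_yields_no_findings(self, generating_table, pattern):
        mom = _population_moments(generating_table, (), n=500)
        s1 = step1_establish_lmm(mom, pattern)
        s2, _ = step2_omnibus(s1)
        final, findings, trace = step3_search(s2, s1)
        assert findings == []
        assert final.chi_square == pytest.approx(s2.chi_square)

    def test_recalibration_recovered_from_population(self, generating_table, pattern):
        mom = _population_moments(
            generating_table, (Injection("nausea", "recalibration", 0.5),), n=500
        )
        s1 = step1_establish_lmm(mom, pattern)
        s2, _ = step2_omnibus(s1)
        final, findings, trace = step3_search(s2, s1)
        assert findings[0].indicator == "nausea"
        assert findings[0].shift_type == "recalibration"
        assert findings[0].delta == pytest.approx(0.5, abs=0.01)
        # at the population optimum the freed model absorbs the entire shift
        assert final.chi_square < s2.chi_square

    def test_reconceptualization_recovered_and_classified(self, generating_table, pattern):
        mom = _population_moments(
            generating_table,
            (Injection("work_relations", "reconceptualization", 0.4, "physical"),),
            n=500,
        )
        opts = ProcedureOptions(allow_reconceptualization=True)
        s1 = step1_establish_lmm(mom, pattern, opts)
        s2, _ = step2_omnibus(s1, opts)
        final, findings, trace = step3_search(s2, s1, opts)
        assert findings[0].indicator == "work_relations"
        assert findings[0].shift_type == "reconceptualization"
        assert findings[0].factor == "physical"
        assert findings[0].estimate_t1 == 0.0
        assert findings[0].delta == pytest.approx(0.4, abs=0.02)

    def test_search_is_deterministic(self, generating_table, pattern):
        spec = SimulationSpec(
            table=generating_table,
            injections=(Injection("nausea", "recalibration", 0.5),),
            n=400, seed=123,
        )
        mom = compute_moments(generate_dataset(spec), pattern.column_names())
        traces = []
        for _ in range(2):
            s1 = step1_establish_lmm(mom, pattern)
            s2, _ = step2_omnibus(s1)
            _, _, trace = step3_search(s2, s1)
            traces.append(json.dumps(trace.to_dict(), sort_keys=True))
        assert traces[0] == traces[1]

    def test_identifiability_guard_keeps_anchor_constraints(self, step2_result):
        step2, _ = step2_result
        opts = ProcedureOptions()
        table = step2.table
        # free two of three intercepts on the physical factor; the third must
        # no longer be offered as a candidate
        from shiftsem.model_core import release_parameter

        t = release_parameter(table, "eq:tau[nausea]")
        t = release_parameter(t, "eq:tau[pain]")
        cands = _shift_candidates(t, opts)
        assert "eq:tau[fatigue]" not in cands
        assert "eq:tau[anxiety]" in cands


@pytest.fixture(scope="module")
def tie_setup():
    pat = parse_model_config(
        {
            "factors": {
                "physical": ["nausea", "pain", "fatigue"],
                "social": ["family_relations", "friendships"],
            },
            "occasions": ["T1", "T2"],
        }
    )
    gen = example_generating_table(pattern=pat)
    mom = _population_moments(
        gen, (Injection("family_relations", "recalibration", 0.4),), n=500
    )
    return pat, mom


class TestTieHandling:
    """A two-indicator factor makes either intercept release fit exactly."""

    def test_tie_recorded_and_broken_by_declaration_order(self, tie_setup):
        pat, mom = tie_setup
        res = run_pipeline(mom, pat)
        it1 = res.trace.iterations[0]
        assert set(it1["tie_set"]) == {
            "eq:tau[family_relations]", "eq:tau[friendships]",
        }
        assert it1["chosen"] == "eq:tau[family_relations]"
        assert len(res.findings) == 1

    def test_freeing_one_renders_the_other_unnecessary(self, tie_setup):
        pat, mom = tie_setup
        res = run_pipeline(mom, pat)
        # the single release absorbs the whole invariance misfit
        assert res.final.chi_square == pytest.approx(res.step1.chi_square, abs=1e-4)

    def test_explore_sequences_branches_fifty_fifty(self, tie_setup):
        pat, mom = tie_setup
        s1 = step1_establish_lmm(mom, pat)
        s2, _ = step2_omnibus(s1)
        branches = explore_sequences(s2, s1)
        assert len(branches) == 2
        per_branch = [
            {(f.indicator, f.shift_type) for f in findings}
            for _label, findings, _final, _trace in branches
        ]
        assert {("family_relations", "recalibration")} in per_branch
        assert {("friendships", "recalibration")} in per_branch
        freq = finding_frequencies(branches)
        assert set(freq["frequency"]) == {0.5}

    def test_unique_best_candidate_gives_single_branch(self, generating_table, pattern):
        mom = _population_moments(
            generating_table, (Injection("nausea", "recalibration", 0.5),), n=500
        )
        s1 = step1_establish_lmm(mom, pattern)
        s2, _ = step2_omnibus(s1)
        branches = explore_sequences(s2, s1)
        final, findings, _ = step3_search(s2, s1)
        assert len(branches) == 1
        assert [f.ref for f in branches[0][1]] == [f.ref for f in findings]


class TestStep4TrueChange:
    def test_factor_mean_change_recovered(self, pattern):
        gen = example_generating_table(factor_means_t2=(-0.5, 0.0, 0.0))
        mom = _population_moments(gen, (), n=500)
        res = run_pipeline(mom, pattern)
        rows = {r.factor: r for r in res.true_change.rows}
        assert rows["physical"].estimate == pytest.approx(-0.5, abs=0.02)
        assert rows["mental"].estimate == pytest.approx(0.0, abs=0.02)
        assert rows["social"].estimate == pytest.approx(0.0, abs=0.02)
        assert rows["physical"].p < 0.001

    def test_no_findings_means_identical_estimates(self, step2_result):
        step2, _ = step2_result
        tc = step4_true_change(step2, step2)
        for row in tc.rows:
            assert row.shift_impact == 0.0

    def test_recalibration_confounds_naive_change(self, pattern):
        """Recalibration of two physical indicators with no latent change:
        the no-shift model misattributes the intercept shifts to the factor
        mean, while the final model attributes them correctly and leaves the
        latent change near zero.  (Shifting every indicator of a factor would
        be empirically indistinguishable from latent change, which is exactly
        why the search keeps one intercept anchored per factor.)"""
        gen = example_generating_table()
        inj = (
            Injection("nausea", "recalibration", 0.5),
            Injection("pain", "recalibration", -0.3),
        )
        mom = _population_moments(gen, inj, n=2000)
        res = run_pipeline(mom, pattern)
        rows = {r.factor: r for r in res.true_change.rows}
        assert abs(rows["physical"].estimate_no_shift) > 0.2
        assert abs(rows["physical"].estimate) < 0.03
        found = {(f.indicator, f.shift_type) for f in res.findings}
        assert found == {("nausea", "recalibration"), ("pain", "recalibration")}


class TestDecomposition:
    def test_pure_true_change(self, pattern):
        gen = example_generating_table(factor_means_t2=(0.3, 0.3, 0.3))
        mom = _population_moments(gen, (), n=500)
        res = run_pipeline(mom, pattern)
        for row in res.decomposition:
            assert row.recalibration == pytest.approx(0.0, abs=0.01)
            assert row.reprioritization_reconceptualization == pytest.approx(0.0, abs=0.01)
            assert row.true_change == pytest.approx(row.observed_change, abs=1e-10)

    def test_pure_intercept_shift(self, generating_table, pattern):
        mom = _population_moments(
            generating_table, (Injection("nausea", "recalibration", 0.5),), n=500
        )
        res = run_pipeline(mom, pattern)
        rows = {r.indicator: r for r in res.decomposition}
        assert rows["nausea"].observed_change == pytest.approx(0.5, abs=0.02)
        assert rows["nausea"].recalibration == pytest.approx(
            rows["nausea"].observed_change, abs=0.02
        )

    def test_exact_additivity_on_random_admissible_models(self, pattern):
        """Components must sum to the implied mean change to 1e-10, always."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(100):
            table = apply_identification(
                impose_invariance(build_parameter_table(pattern)), "step2"
            )
            from shiftsem.model_core import release_parameter

            table = release_parameter(table, "eq:tau[nausea]")
            table = release_parameter(table, "eq:lambda[anxiety,mental]")
            for e in table.entries.values():
                if e.value is not None:
                    continue
                if e.matrix == "lambda":
                    table.set_value(e.ref, rng.uniform(0.3, 0.9))
                elif e.matrix == "phi":
                    if e.row == e.col and e.occ_row == e.occ_col:
                        table.set_value(e.ref, rng.uniform(0.5, 1.5))
                    else:
                        table.set_value(e.ref, rng.uniform(-0.3, 0.3))
                elif e.matrix == "theta":
                    table.set_value(
                        e.ref,
                        rng.uniform(0.2, 1.0) if e.occ_row == e.occ_col else rng.uniform(-0.1, 0.1),
                    )
                else:
                    table.set_value(e.ref, rng.normal(0, 0.5))
            from shiftsem.estimation import FittedModel
            from shiftsem.model_core import implied_moments

            imp = implied_moments(table)
            fake = FittedModel(
                table=table, moments=None, discrepancy=0.0, chi_square=0.0,
                df=0, converged=True, gradient_norm=0.0, n=100,
            )
            for convention in ("baseline", "followup"):
                rows = decompose_change(fake, convention)
                P = pattern.n_indicators
                implied_delta = imp.mu[P:] - imp.mu[:P]
                for i, row in enumerate(rows):
                    total = (
                        row.recalibration
                        + row.reprioritization_reconceptualization
                        + row.true_change
                    )
                    err = abs(total - row.observed_change)
                    worst = max(worst, err)
                    assert abs(row.observed_change - implied_delta[i]) <= 1e-10
        assert worst <= 1e-10

    def test_convention_variants_reallocate_not_change_total(self, pattern, generating_table):
        mom = _population_moments(
            generating_table, (Injection("anxiety", "reprioritization", 0.3),), n=500
        )
        res = run_pipeline(mom, pattern)
        a = decompose_change(res.final, "baseline")
        b = decompose_change(res.final, "followup")
        for ra, rb in zip(a, b):
            assert ra.observed_change == pytest.approx(rb.observed_change, abs=1e-12)


class TestEffectSizes:
    def test_zero_latent_change_gives_zero_factor_effects(self, generating_table, pattern):
        mom = _population_moments(generating_table, (), n=500)
        res = run_pipeline(mom, pattern)
        es = effect_sizes(res.final, mom)
        fac = es[es.kind == "factor"]
        assert (fac.effect_size.abs() < 1e-3).all()

    def test_known_component_over_unit_sd(self, generating_table, pattern):
        mom = _population_moments(
            generating_table, (Injection("nausea", "recalibration", 0.5),), n=500
        )
        res = run_pipeline(mom, pattern)
        es = res.effect_sizes
        row = es[(es.name == "nausea") & (es.component == "recalibration")]
        # unit baseline indicator SD: effect size equals the raw component
        assert row.effect_size.iloc[0] == pytest.approx(0.5, abs=0.03)
        assert row.magnitude.iloc[0] == "medium"

    def test_scale_equivariance(self, generating_table, pattern):
        spec = SimulationSpec(
            table=generating_table,
            injections=(Injection("nausea", "recalibration", 0.5),),
            n=400, seed=321,
        )
        data = generate_dataset(spec)
        res1 = run_pipeline(data, pattern)
        res2 = run_pipeline(data * 3.0, pattern)
        es1 = res1.effect_sizes.set_index(["name", "component", "kind"]).effect_size
        es2 = res2.effect_sizes.set_index(["name", "component", "kind"]).effect_size
        common = es1.index.intersection(es2.index)
        assert len(common) > 10
        np.testing.assert_allclose(es1[common], es2[common], atol=5e-3)


class TestStep1Modification:
    def test_auto_modify_off_returns_configured_pattern(self, step1_fitted, pattern):
        assert getattr(step1_fitted, "modifications_applied") == []
        lam_entries = [e for e in step1_fitted.table.entries.values() if e.matrix == "lambda"]
        assert len(lam_entries) == 18  # exactly the configured pattern

    def test_extra_residual_covariance_ranks_first(self, pattern):
        gen = example_generating_table()
        # generating model with an extra within-occasion residual covariance
        from shiftsem.model_core import release_parameter

        gen2 = release_parameter(gen, "theta[nausea@T1,pain@T1]")
        gen2.entries["theta[nausea@T1,pain@T1]"].value = 0.18
        mom = _population_moments(gen2, (), n=500)
        opts = ProcedureOptions(rmsea_adequate=-1.0)  # force candidate ranking
        s1 = step1_establish_lmm(mom, pattern, opts)
        mods = s1.modification_candidates
        assert mods[0].ref == "theta[nausea@T1,pain@T1]"

    def test_auto_modify_applies_and_logs(self, pattern):
        gen = example_generating_table()
        from shiftsem.model_core import release_parameter

        gen2 = release_parameter(gen, "theta[nausea@T1,pain@T1]")
        gen2.entries["theta[nausea@T1,pain@T1]"].value = 0.18
        mom = _population_moments(gen2, (), n=500)
        opts = ProcedureOptions(rmsea_adequate=-1.0, auto_modify=True, max_modifications=1)
        s1 = step1_establish_lmm(mom, pattern, opts)
        assert s1.modifications_applied == ["theta[nausea@T1,pain@T1]"]
        assert "theta[nausea@T1,pain@T1]" in s1.table
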