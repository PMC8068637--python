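"""Structure of the longitudinal factor model: patterns, parameter ledger,
identification, implied moments and degree-of-freedom bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftsem.model_core import (
    ConfigError,
    apply_identification,
    build_parameter_table,
    degrees_of_freedom,
    implied_moments,
    impose_invariance,
    n_sample_moments,
    parse_model_config,
    parse_ref,
    release_parameter,
)


class TestParseModelConfig:
    def test_canonical_three_factor_model(self, pattern):
        assert pattern.n_indicators == 9
        assert pattern.n_factors == 3
        assert pattern.n_occasions == 2
        assert pattern.loading_pattern.sum() == 9  # simple structure
        assert pattern.indicators[0] == "nausea"
        assert pattern.column_names()[0] == "nausea_T1"
        assert pattern.column_names()[9] == "nausea_T2"

    def test_minimal_single_indicator_model(self):
        pat = parse_model_config({"factors": {"f": ["x"]}, "occasions": ["a", "b"]})
        assert (pat.n_indicators, pat.n_factors) == (1, 1)

    def test_cross_loading_union(self):
        pat = parse_model_config(
            {"factors": {"f": ["x", "y"], "g": ["y", "z"]}, "occasions": ["a", "b"]}
        )
        row_y = pat.loading_pattern[pat.indicators.index("y")]
        assert row_y.tolist() == [1, 1]

    def test_yaml_text_round_trip(self):
        text = "factors:\n  f: [x, y]\noccasions: [T1, T2]\n"
        pat = parse_model_config(text)
        assert pat.indicators == ("x", "y")

    @pytest.mark.parametrize(
        "cfg, key",
        [
            ({"factors": {"f": ["x", "x"]}, "occasions": ["a", "b"]}, "factors"),
            ({"factors": {"f": []}, "occasions": ["a", "b"]}, "factors"),
            ({"factors": {"f": ["x"]}, "occasions": ["a"]}, "occasions"),
            ({"occasions": ["a", "b"]}, "factors"),
            ({"factors": {"f": ["x"]}}, "occasions"),
        ],
    )
    def test_invalid_configs_name_offending_key(self, cfg, key):
        with pytest.raises(ConfigError, match=key):
            parse_model_config(cfg)


class TestBuildParameterTable:
    def test_canonical_entry_counts(self, pattern):
        table = build_parameter_table(pattern)
        by_matrix = {}
        for e in table.entries.values():
            by_matrix.setdefault(e.matrix, []).append(e)
        assert len(by_matrix["lambda"]) == 18
        assert len(by_matrix["phi"]) == 21  # 2 * (3 diag + 3 offdiag) + 9 cross
        assert len(by_matrix["theta"]) == 27  # 9 + 9 variances + 9 cross
        assert len(by_matrix["tau"]) == 18
        assert len(by_matrix["kappa"]) == 6
        cross_phi = [
            e for e in by_matrix["phi"] if e.occ_row != e.occ_col
        ]
        assert len(cross_phi) == 9 and all(e.is_free for e in cross_phi)

    def test_minimal_model_counts(self):
        pat = parse_model_config({"factors": {"f": ["x"]}, "occasions": ["a", "b"]})
        table = build_parameter_table(pat)
        counts = {}
        for e in table.entries.values():
            counts[e.matrix] = counts.get(e.matrix, 0) + 1
        assert counts == {"lambda": 2, "phi": 3, "theta": 3, "tau": 2, "kappa": 2}

    def test_cross_occasion_residuals_same_indicator_only(self, pattern):
        table = build_parameter_table(pattern)
        cross = [
            e for e in table.entries.values()
            if e.matrix == "theta" and e.occ_row != e.occ_col
        ]
        assert len(cross) == 9
        assert all(e.row == e.col for e in cross)
        table.validate()


class TestIdentification:
    def test_step1_fixes_all_factor_scales_and_means(self, pattern):
        table = apply_identification(build_parameter_table(pattern), "step1")
        fixed = [e for e in table.entries.values() if e.role == "identification"]
        phis = [e for e in fixed if e.matrix == "phi"]
        kappas = [e for e in fixed if e.matrix == "kappa"]
        assert len(phis) == 6 and all(e.value == 1.0 for e in phis)
        assert len(kappas) == 6 and all(e.value == 0.0 for e in kappas)

    def test_step2_frees_followup_scale_and_means(self, pattern):
        table = apply_identification(build_parameter_table(pattern), "step2")
        fixed = [e for e in table.entries.values() if e.role == "identification"]
        assert len([e for e in fixed if e.matrix == "phi"]) == 3
        assert len([e for e in fixed if e.matrix == "kappa"]) == 3
        assert table["phi[physical@T2,physical@T2]"].is_free
        assert table["kappa[physical]@T2"].is_free

    def test_reapplication_is_idempotent(self, pattern):
        t1 = apply_identification(build_parameter_table(pattern), "step1")
        before = [(e.ref, e.status, e.value, e.role) for e in t1.entries.values()]
        apply_identification(t1, "step1")
        after = [(e.ref, e.status, e.value, e.role) for e in t1.entries.values()]
        assert before == after

    def test_modes_differ_in_exactly_two_q_statuses(self, pattern):
        a = apply_identification(build_parameter_table(pattern), "step1")
        b = apply_identification(build_parameter_table(pattern), "step2")
        diffs = [
            ref for ref in a.entries
            if a.entries[ref].status != b.entries[ref].status
        ]
        assert len(diffs) == 2 * pattern.n_factors

    def test_unknown_step_tag(self, pattern):
        with pytest.raises(ValueError, match="step"):
            apply_identification(build_parameter_table(pattern), "step9")


def _set_all(table, value_fn):
    for e in table.entries.values():
        if e.value is None:
            e.value = value_fn(e)
    return table


class TestImpliedMoments:
    def test_identity_case(self):
        pat = parse_model_config({"factors": {"f": ["x"]}, "occasions": ["a", "b"]})
        table = build_parameter_table(pat)

        def values(e):
            if e.matrix == "lambda":
                return 1.0
            if e.matrix in ("phi", "theta"):
                return 1.0 if (e.row == e.col and e.occ_row == e.occ_col) else 0.0
            return 0.0

        imp = implied_moments(_set_all(table, values))
        # sigma = Lam Phi Lam' + Theta = I + I = 2I here with unit theta; use theta=0
        for e in table.entries.values():
            if e.matrix == "theta":
                e.value = 0.0
        imp = implied_moments(table)
        np.testing.assert_allclose(imp.sigma, np.eye(2))
        np.testing.assert_allclose(imp.mu, np.zeros(2))

    def test_single_indicator_arithmetic(self):
        pat = parse_model_config({"factors": {"f": ["x"]}, "occasions": ["a", "b"]})
        table = build_parameter_table(pat)

        def values(e):
            return {
                "lambda": 0.8,
                "phi": 1.0 if (e.row == e.col and e.occ_row == e.occ_col) else 0.0,
                "theta": 0.36 if e.occ_row == e.occ_col else 0.0,
                "tau": 2.0,
                "kappa": 0.5,
            }[e.matrix]

        imp = implied_moments(_set_all(table, values))
        assert imp.sigma[0, 0] == pytest.approx(0.8**2 * 1.0 + 0.36)
        assert imp.mu[0] == pytest.approx(2.0 + 0.8 * 0.5)

    def test_block_assembly_matches_stacked_brute_force(self, generating_table):
        """Cross-check blockwise assembly against an independent dense build."""
        table = generating_table
        pat = table.pattern
        P, Q, T = pat.n_indicators, pat.n_factors, pat.n_occasions
        lam = np.zeros((P * T, Q * T))
        phi = np.zeros((Q * T, Q * T))
        theta = np.zeros((P * T, P * T))
        tau = np.zeros(P * T)
        kappa = np.zeros(Q * T)
        occ = {o: t for t, o in enumerate(pat.occasions)}
        ind = {v: i for i, v in enumerate(pat.indicators)}
        fac = {v: i for i, v in enumerate(pat.factors)}
        for e in table.entries.values():
            if e.matrix == "lambda":
                lam[occ[e.occ_row] * P + ind[e.row], occ[e.occ_row] * Q + fac[e.col]] = e.value
            elif e.matrix == "phi":
                r, c = occ[e.occ_row] * Q + fac[e.row], occ[e.occ_col] * Q + fac[e.col]
                phi[r, c] = phi[c, r] = e.value
            elif e.matrix == "theta":
                r, c = occ[e.occ_row] * P + ind[e.row], occ[e.occ_col] * P + ind[e.col]
                theta[r, c] = theta[c, r] = e.value
            elif e.matrix == "tau":
                tau[occ[e.occ_row] * P + ind[e.row]] = e.value
            else:
                kappa[occ[e.occ_row] * Q + fac[e.row]] = e.value
        sigma_bf = lam @ phi @ lam.T + theta
        mu_bf = tau + lam @ kappa
        imp = implied_moments(table)
        np.testing.assert_allclose(imp.sigma, sigma_bf, atol=1e-10)
        np.testing.assert_allclose(imp.mu, mu_bf, atol=1e-10)
        # cross-occasion block identity: Sigma_12 = Lam1 Phi12 Lam2' + Theta12
        s12 = lam[:P, :Q] @ phi[:Q, Q:] @ lam[P:, Q:].T + theta[:P, P:]
        np.testing.assert_allclose(imp.sigma[:P, P:], s12, atol=1e-10)

    def test_sigma_exactly_symmetric(self, generating_table):
        imp = implied_moments(generating_table)
        assert np.abs(imp.sigma - imp.sigma.T).max() == 0.0

    def test_missing_value_raises(self, pattern):
        table = build_parameter_table(pattern)
        with pytest.raises(ValueError, match="finite"):
            implied_moments(table)


class TestDegreesOfFreedom:
    def test_step1_counts(self, step1_table):
        assert step1_table.n_free_parameters() == 78
        assert degrees_of_freedom(step1_table) == 111

    def test_step2_counts(self, pattern):
        table = apply_identification(
            impose_invariance(build_parameter_table(pattern)), "step2"
        )
        assert table.n_free_parameters() == 66
        assert degrees_of_freedom(table) == 123

    def test_step_delta_df(self, pattern, step1_table):
        step2 = apply_identification(
            impose_invariance(build_parameter_table(pattern)), "step2"
        )
        assert degrees_of_freedom(step2) - degrees_of_freedom(step1_table) == 12

    def test_brute_force_enumeration_agrees(self, step1_table):
        """Count distinct free parameters by direct enumeration of the ledger."""
        seen = set()
        count = 0
        for e in step1_table.entries.values():
            if not e.is_free:
                continue
            key = e.group if e.group is not None else e.ref
            if key not in seen:
                seen.add(key)
                count += 1
        m = 18
        moments = m * (m + 1) // 2 + m
        assert moments - count == degrees_of_freedom(step1_table) == 111

    @given(P=st.integers(1, 12), T=st.integers(2, 3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_moment_count_enumeration(self, P, T):
        m = P * T
        pairs = sum(1 for i in range(m) for j in range(i, m))
        assert n_sample_moments(P, T) == pairs + m


class TestReleaseParameter:
    def test_release_intercept_equality(self, pattern):
        table = apply_identification(
            impose_invariance(build_parameter_table(pattern)), "step2"
        )
        df0 = degrees_of_freedom(table)
        new = release_parameter(table, "eq:tau[nausea]")
        assert new["tau[nausea]@T1"].group is None
        assert new["tau[nausea]@T2"].group is None
        assert new["tau[nausea]@T1"].is_free and new["tau[nausea]@T2"].is_free
        assert degrees_of_freedom(new) == df0 - 1

    def test_release_pattern_zero_loading_creates_entry(self, pattern):
        table = apply_identification(
            impose_invariance(build_parameter_table(pattern)), "step2"
        )
        ref = "lambda[work_relations,physical]@T2"
        assert ref not in table
        new = release_parameter(table, ref)
        assert ref in new and new[ref].is_free
        assert degrees_of_freedom(new) == degrees_of_freedom(table) - 1
        # pattern now differs across occasions
        assert "lambda[work_relations,physical]@T1" not in new

    @pytest.mark.parametrize(
        "ref",
        ["eq:tau[pain]", "eq:lambda[anxiety,mental]", "lambda[nausea,social]@T2",
         "theta[nausea@T1,pain@T1]"],
    )
    def test_any_single_release_drops_df_by_one(self, pattern, ref):
        table = apply_identification(
            impose_invariance(build_parameter_table(pattern)), "step2"
        )
        assert degrees_of_freedom(release_parameter(table, ref)) == (
            degrees_of_freedom(table) - 1
        )

    def test_release_free_parameter_errors(self, pattern):
        table = apply_identification(build_parameter_table(pattern), "step1")
        with pytest.raises(ValueError, match="already"):
            release_parameter(table, "lambda[nausea,physical]@T1")

    def test_release_identification_restriction_refused(self, pattern):
        table = apply_identification(build_parameter_table(pattern), "step1")
        with pytest.raises(ValueError, match="identification"):
            release_parameter(table, "kappa[physical]@T1")

    def test_cross_occasion_cross_indicator_residual_refused(self, pattern):
        table = apply_identification(build_parameter_table(pattern), "step1")
        with pytest.raises(ValueError):
            release_parameter(table, "theta[nausea@T1,pain@T2]")


def test_parse_ref_round_trip(pattern):
    table = build_parameter_table(pattern)
    for ref in list(table.entries)[:20]:
        e = parse_ref(ref, pattern)
        assert e.ref == ref
        assert e.matrix == table[ref].matrix
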