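"""Markdown report rendering and artifact serialization for pipeline runs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .procedure import PipelineResult, ShiftFinding

__all__ = ["render_report", "save_artifacts"]


def _interpretation(f: ShiftFinding) -> str:
    direction = "lower" if f.delta < 0 else "higher"
    if f.shift_type == "recalibration":
        return (
            f"The intercept of '{f.indicator}' is {direction} at follow-up: the same "
            f"state on the underlying factor corresponds to {direction} scores on "
            f"'{f.indicator}' at follow-up than at baseline (recalibration)."
        )
    if f.shift_type == "reprioritization":
        more_less = "less" if f.delta < 0 else "more"
        return (
            f"The factor loading of '{f.indicator}' is "
            f"{'smaller' if f.delta < 0 else 'larger'} at follow-up: "
            f"'{f.indicator}' has become {more_less} important to the measurement "
            f"of {f.factor} (reprioritization)."
        )
    return (
        f"The loading of '{f.indicator}' on {f.factor} differs in pattern across "
        f"occasions: '{f.indicator}' has become "
        f"{'part of' if abs(f.estimate_t2) > abs(f.estimate_t1) else 'detached from'} "
        f"the measurement of {f.factor} (reconceptualization)."
    )


def _fit_table(rows: list[tuple[str, object]]) -> str:
    head = (
        "| model | chi2 | df | p | RMSEA | RMSEA 90% CI | verdict | CFI | TLI | ECVI | AIC | BIC |\n"
        "|---|---|---|---|---|---|---|---|---|---|---|---|\n"
    )
    out = head
    for name, fi in rows:
        if fi is None:
            continue
        rm = f"{fi.rmsea:.4f}" if fi.rmsea is not None else "n/a"
        ci = (
            f"[{fi.rmsea_ci[0]:.4f}, {fi.rmsea_ci[1]:.4f}]" if fi.rmsea_ci else "n/a"
        )
        out += (
            f"| {name} | {fi.chi_square:.3f} | {fi.df} | {fi.p_exact:.4f} | {rm} | {ci} "
            f"| {fi.rmsea_verdict} | {fi.cfi:.4f} | {fi.tli:.4f} | {fi.ecvi:.3f} "
            f"| {fi.aic:.1f} | {fi.bic:.1f} |\n"
        )
    return out


def render_report(result: PipelineResult, branches=None, frequency=None) -> str:
    """Human-readable Markdown account of a four-step analysis."""
    r = result
    md: list[str] = []
    md.append("# Response shift analysis report\n")
    md.append(
        f"N = {r.moments.n} persons"
        + (f" ({r.moments.n_dropped} incomplete rows dropped)" if r.moments.n_dropped else "")
        + f"; {r.pattern.n_indicators} indicators, {r.pattern.n_factors} factors, "
        f"{r.pattern.n_occasions} occasions.\n"
    )
    md.append("## Step 1: measurement model\n")
    md.append(_fit_table([("measurement model", r.step1_fit)]))
    mods = getattr(r.step1, "modifications_applied", [])
    if mods:
        md.append(
            "\nModel modifications applied while establishing the measurement "
            "model: " + ", ".join(f"`{m}`" for m in mods) + ".\n"
        )
    md.append("\n## Step 2: omnibus test of response shift\n")
    om = r.omnibus
    md.append(
        f"Constraining all loadings and intercepts equal across occasions: "
        f"&Delta;chi2({om.delta_df}) = {om.delta_chi_square:.3f}, "
        f"p = {om.p_delta:.4g}; &Delta;CFI = {om.delta_cfi:.4f}"
        f" ({'> 0.01, reject restrictions' if om.cfi_rule_reject else '<= 0.01'}); "
        f"&Delta;ECVI = {om.delta_ecvi:.4f}, &Delta;AIC = {om.delta_aic:.2f}.\n"
    )
    md.append(
        "\n**Verdict: response shift is "
        + ("present" if om.significant else "not detected")
        + ".**\n"
    )
    md.append(_fit_table([
        ("measurement model", r.step1_fit),
        ("full invariance", r.step2_fit),
        ("final (with shifts)", r.final_fit if r.final is not r.step2 else None),
    ]))
    if r.trace is not None:
        md.append("\n## Step 3: specification search\n")
        for it in r.trace.iterations:
            if "note" in it:
                md.append(f"- iteration {it['iteration']}: {it['note']}\n")
                continue
            if it["chosen"] is None:
                continue
            tie = ""
            if len(it.get("tie_set", [])) > 1:
                others = [t for t in it["tie_set"] if t != it["chosen"]]
                tie = (
                    "  **Tie:** statistically equivalent alternative(s): "
                    + ", ".join(f"`{t}`" for t in others)
                    + " — the choice between them cannot rest on statistical criteria alone."
                )
            forced = " (incorporated despite non-significance: model still differs from the measurement model)" if it.get("forced") else ""
            top = it["ranking"][0]
            md.append(
                f"- iteration {it['iteration']}: freed `{it['chosen']}` "
                f"(&Delta;chi2(1) = {top['delta_chi_square']:.2f}, p = {top['p']:.3g}){forced}{tie}\n"
            )
        md.append(f"\nSearch stopped: {r.trace.stopped_because}.\n")
    md.append("\n## Findings\n")
    if r.findings:
        md.append(
            "| # | indicator | type | baseline | follow-up | delta | dchi2 | p |\n"
            "|---|---|---|---|---|---|---|---|\n"
        )
        for f in r.findings:
            md.append(
                f"| {f.sequence} | {f.indicator} | {f.shift_type} | {f.estimate_t1:.3f} "
                f"| {f.estimate_t2:.3f} | {f.delta:.3f} | {f.delta_chi_square:.2f} "
                f"| {f.p:.3g} |\n"
            )
        md.append("\n")
        for f in r.findings:
            md.append(f"- {_interpretation(f)}\n")
    else:
        md.append(
            "No response shift was detected; true change is read from the "
            "full-invariance (Step 2) model.\n"
        )
    if r.true_change is not None:
        md.append("\n## Step 4: true change in the factor means\n")
        md.append(
            "| factor | occasion | change (with shift) | se | p | change (no shift) "
            "| impact of response shift |\n|---|---|---|---|---|---|---|\n"
        )
        for row in r.true_change.rows:
            se = f"{row.se:.3f}" if row.se is not None else "n/a"
            p = f"{row.p:.3g}" if row.p is not None else "n/a"
            md.append(
                f"| {row.factor} | {row.occasion} | {row.estimate:.3f} | {se} | {p} "
                f"| {row.estimate_no_shift:.3f} | {row.shift_impact:.3f} |\n"
            )
    if r.decomposition is not None:
        md.append("\n## Decomposition of observed change\n")
        md.append(
            "| indicator | occasion | observed change | recalibration "
            "| reprioritization/reconceptualization | true change |\n"
            "|---|---|---|---|---|---|\n"
        )
        for d in r.decomposition:
            total = d.recalibration + d.reprioritization_reconceptualization + d.true_change
            assert abs(total - d.observed_change) <= 1e-10
            md.append(
                f"| {d.indicator} | {d.occasion} | {d.observed_change:.3f} "
                f"| {d.recalibration:.3f} | {d.reprioritization_reconceptualization:.3f} "
                f"| {d.true_change:.3f} |\n"
            )
    if frequency is not None and len(frequency):
        md.append("\n## Alternative specification sequences\n")
        md.append(
            f"{len(branches)} branch(es) explored at statistical ties. Frequency of "
            "each finding across branches (frequently recurring findings are more "
            "robust to sequential decision-making than sporadic ones):\n\n"
        )
        md.append("| indicator | type | branches | frequency |\n|---|---|---|---|\n")
        for _, row in frequency.iterrows():
            md.append(
                f"| {row['indicator']} | {row['shift_type']} | {row['branches']} "
                f"| {row['frequency']:.2f} |\n"
            )
    md.append("\n## Caveats\n")
    md.append(
        "Statistical criteria alone cannot settle which model modifications to "
        "adopt: competing releases can improve fit equally, and sequential "
        "choices can change what is found later. Interpretation of the detected "
        "effects as response shift — and the decision to keep or drop any of "
        "them — requires subjective judgment informed by knowledge of the "
        "patient group, treatment and disease trajectory.\n"
    )
    return "".join(md)


def save_artifacts(result: PipelineResult, outdir) -> None:
    """Write parameter tables, fit/comparison JSON, findings, decomposition, trace."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    r = result
    r.step1.table.to_frame().to_csv(out / "parameters_step1.csv", index=False)
    r.step2.table.to_frame().to_csv(out / "parameters_step2.csv", index=False)
    r.final.table.to_frame().to_csv(out / "parameters_final.csv", index=False)
    fits = {
        "step1": r.step1_fit.to_dict(),
        "step2": r.step2_fit.to_dict(),
        "final": r.final_fit.to_dict() if r.final_fit is not None else None,
        "omnibus_comparison": r.omnibus.to_dict(),
    }
    (out / "fit_indices.json").write_text(json.dumps(fits, indent=2))
    (out / "findings.json").write_text(
        json.dumps([f.to_dict() for f in r.findings], indent=2)
    )
    if r.trace is not None:
        (out / "search_trace.json").write_text(json.dumps(r.trace.to_dict(), indent=2))
    if r.decomposition is not None:
        pd.DataFrame([asdict(d) for d in r.decomposition]).to_csv(
            out / "decomposition.csv", index=False
        )
    if r.true_change is not None:
        r.true_change.to_frame().to_csv(out / "true_change.csv", index=False)
    if r.effect_sizes is not None:
        r.effect_sizes.to_csv(out / "effect_sizes.csv", index=False)
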