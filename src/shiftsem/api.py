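"""High-level modelling interface.

:class:`ResponseShiftModel` is constructed from a wide-format dataset (one
row per person, one column per indicator-occasion) and a model
configuration; its :meth:`~ResponseShiftModel.fit` runs the four-step
detection procedure and returns a :class:`ResponseShiftResults` carrying the
fitted models, test results, findings, true-change estimates and the change
decomposition, with a ``summary()`` table in the spirit of statsmodels
results objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .estimation import SampleMoments, compute_moments
from .model_core import ModelPattern, parse_model_config
from .procedure import (
    PipelineResult,
    ProcedureOptions,
    explore_sequences,
    finding_frequencies,
    run_pipeline,
)

__all__ = ["ResponseShiftModel", "ResponseShiftResults"]


class ResponseShiftModel:
    """A longitudinal factor model for response-shift detection.

    Parameters
    ----------
    data : wide-format DataFrame; columns named ``{indicator}_{occasion}``.
    config : a :class:`ModelPattern`, or a mapping / YAML / JSON text
        declaring ``factors`` and ``occasions``.
    **options : any :class:`~shiftsem.procedure.ProcedureOptions` field.
    """

    def __init__(self, data: pd.DataFrame, config, **options):
        file_options: dict = {}
        if isinstance(config, ModelPattern):
            self.pattern = config
        else:
            if isinstance(config, str):
                import yaml

                config = yaml.safe_load(config)
            if isinstance(config, Mapping) and isinstance(config.get("options"), Mapping):
                file_options = dict(config["options"])
            self.pattern = parse_model_config(config)
        # keyword arguments (and CLI flags) override file-level options
        file_options.update(options)
        try:
            self.options = ProcedureOptions(**file_options)
        except TypeError as exc:
            from .model_core import ConfigError

            raise ConfigError(f"options: {exc}") from exc
        self.data = data
        self._moments: SampleMoments | None = None

    @classmethod
    def from_files(cls, data_path, config_path, **options) -> "ResponseShiftModel":
        data = pd.read_csv(data_path)
        config_text = Path(config_path).read_text()
        return cls(data, config_text, **options)

    @property
    def moments(self) -> SampleMoments:
        if self._moments is None:
            self._moments = compute_moments(self.data, self.pattern.column_names())
        return self._moments

    def fit(self, through_step: int = 4) -> "ResponseShiftResults":
        """Run Steps 1-4 (measurement model, omnibus test, search, true change)."""
        result = run_pipeline(self.moments, self.pattern, self.options, through_step)
        return ResponseShiftResults(self, result)


class ResponseShiftResults:
    """Results of a four-step response-shift analysis."""

    def __init__(self, model: ResponseShiftModel, result: PipelineResult):
        self.model = model
        self.result = result

    # -- convenience accessors --------------------------------------------

    @property
    def findings(self) -> pd.DataFrame:
        return pd.DataFrame(
            [f.to_dict() for f in self.result.findings],
            columns=[
                "indicator", "occasions", "shift_type", "ref", "estimate_t1",
                "estimate_t2", "delta", "delta_chi_square", "p", "sequence", "factor",
            ],
        )

    @property
    def omnibus(self):
        return self.result.omnibus

    @property
    def true_change(self) -> pd.DataFrame | None:
        tc = self.result.true_change
        return tc.to_frame() if tc is not None else None

    @property
    def decomposition(self) -> pd.DataFrame | None:
        dec = self.result.decomposition
        if dec is None:
            return None
        from dataclasses import asdict

        return pd.DataFrame([asdict(r) for r in dec])

    @property
    def effect_sizes(self) -> pd.DataFrame | None:
        return self.result.effect_sizes

    @property
    def response_shift_detected(self) -> bool:
        return self.result.response_shift_detected

    def explore_sequences(self):
        """Re-run the Step-3 search, branching at every statistical tie.

        Returns ``(branches, frequency_table)``.
        """
        branches = explore_sequences(
            self.result.step2, self.result.step1, self.result.options
        )
        return branches, finding_frequencies(branches)

    # -- rendering ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text overview of the analysis."""
        r = self.result
        lines: list[str] = []
        w = 72
        lines.append("Response shift analysis (longitudinal SEM)".center(w))
        lines.append("=" * w)
        lines.append(
            f"Indicators: {r.pattern.n_indicators}   Factors: {r.pattern.n_factors}   "
            f"Occasions: {r.pattern.n_occasions}   N: {r.moments.n}"
            + (f" ({r.moments.n_dropped} incomplete rows dropped)" if r.moments.n_dropped else "")
        )
        lines.append("-" * w)

        def fitline(name, fi):
            return (
                f"{name:<22} chi2({fi.df}) = {fi.chi_square:9.3f}  p = {fi.p_exact:.4f}  "
                f"RMSEA = {fi.rmsea if fi.rmsea is not None else float('nan'):.4f} "
                f"({fi.rmsea_verdict})  CFI = {fi.cfi:.4f}"
            )

        lines.append(fitline("Step 1 (measurement)", r.step1_fit))
        lines.append(fitline("Step 2 (invariance)", r.step2_fit))
        if r.final_fit is not None and r.final is not r.step2:
            lines.append(fitline("Step 3 (final)", r.final_fit))
        lines.append("-" * w)
        om = r.omnibus
        lines.append(
            f"Omnibus response-shift test: delta chi2({om.delta_df}) = "
            f"{om.delta_chi_square:.3f}, p = {om.p_delta:.4f} -> "
            + ("response shift present" if om.significant else "no response shift detected")
        )
        if r.findings:
            lines.append("")
            lines.append("Detected response shifts:")
            lines.append(
                f"  {'#':>2} {'indicator':<18}{'type':<20}{'T1':>8}{'T2':>8}"
                f"{'delta':>8}{'dchi2':>8}{'p':>10}"
            )
            for f in r.findings:
                lines.append(
                    f"  {f.sequence:>2} {f.indicator:<18}{f.shift_type:<20}"
                    f"{f.estimate_t1:>8.3f}{f.estimate_t2:>8.3f}{f.delta:>8.3f}"
                    f"{f.delta_chi_square:>8.2f}{f.p:>10.3g}"
                )
        if r.true_change is not None:
            lines.append("")
            lines.append("True change in factor means (baseline fixed at 0):")
            lines.append(
                f"  {'factor':<18}{'occ':<6}{'with shift':>12}{'(se)':>9}"
                f"{'p':>10}{'no shift':>12}{'impact':>9}"
            )
            for row in r.true_change.rows:
                se = f"({row.se:.3f})" if row.se is not None else "--"
                p = f"{row.p:.3g}" if row.p is not None else "--"
                lines.append(
                    f"  {row.factor:<18}{row.occasion:<6}{row.estimate:>12.3f}{se:>9}"
                    f"{p:>10}{row.estimate_no_shift:>12.3f}{row.shift_impact:>9.3f}"
                )
        lines.append("=" * w)
        lines.append(
            "Note: statistical detection is only one ingredient; deciding which"
        )
        lines.append(
            "effects are substantively meaningful requires subjective judgment."
        )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write all artifacts (CSV/JSON tables plus a Markdown report)."""
        from .report import render_report, save_artifacts

        save_artifacts(self.result, outdir)
        Path(outdir, "report.md").write_text(render_report(self.result))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n = len(self.result.findings)
        return (
            f"<ResponseShiftResults: omnibus p={self.result.omnibus.p_delta:.4g}, "
            f"{n} finding(s)>"
        )
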