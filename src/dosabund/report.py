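"""Publication-style report tables and detection-curve figures."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .abundance import AbundanceEstimate, AveragedEstimate
from .estimation import ModelSet
from .fixtures import FixtureAssumption

__all__ = [
    "model_selection_table",
    "abundance_table",
    "render_markdown_report",
    "detection_curve_figure",
]

MODEL_TABLE_COLUMNS = ["Model", "K", "AICc", "ΔAICc", "w_i"]
ABUNDANCE_TABLE_COLUMNS = ["Method", "Count", "Estimate", "SE", "LCL", "UCL"]


def model_selection_table(model_set: ModelSet, digits: int = 2) -> pd.DataFrame:
    """AICc model-selection table: Model, K, AICc, ΔAICc, w_i (2 decimals)."""
    t = model_set.table()
    for col in ("AICc", "ΔAICc", "w_i"):
        t[col] = t[col].round(digits)
    return t[MODEL_TABLE_COLUMNS]


def abundance_table(
    rows: Sequence[tuple[str, AbundanceEstimate | AveragedEstimate]],
) -> pd.DataFrame:
    """Abundance summary: Method, Count, Estimate, SE, LCL, UCL (integers)."""
    out = []
    for method, est in rows:
        if isinstance(est, AveragedEstimate):
            n_hat, se = est.N_bar, est.SE_unconditional
        else:
            n_hat, se = est.N_hat, est.SE
        out.append(
            {
                "Method": method,
                "Count": int(est.M),
                "Estimate": int(round(n_hat)),
                "SE": int(round(se)),
                "LCL": int(round(est.ci_low)),
                "UCL": int(round(est.ci_high)),
            }
        )
    return pd.DataFrame(out, columns=ABUNDANCE_TABLE_COLUMNS)


def render_markdown_report(
    model_set: ModelSet,
    abundance_rows: Sequence[tuple[str, AbundanceEstimate | AveragedEstimate]],
    assumptions: Sequence[FixtureAssumption] = (),
    seed: int | None = None,
    config_hash: str | None = None,
) -> str:
    """Markdown report with both tables, run provenance and all fixture assumptions.

    Assumptions are never silently dropped: every one attached to the input
    data appears in the report.
    """
    lines = ["# Double-observer abundance report", ""]
    lines.append("## Model selection")
    lines.append("")
    lines.append(model_selection_table(model_set).to_markdown(index=False))
    if model_set.excluded:
        lines.append("")
        lines.append("Excluded models:")
        for label, reason in model_set.excluded:
            lines.append(f"- {label}: {reason}")
    lines.append("")
    lines.append("## Abundance")
    lines.append("")
    lines.append(abundance_table(abundance_rows).to_markdown(index=False))
    lines.append("")
    n_eff_rules = sorted({m.n_eff_rule for m in model_set.models})
    lines.append(f"Effective-sample-size rule for AICc: {', '.join(n_eff_rules)}.")
    if seed is not None:
        lines.append(f"Seed: {seed}.")
    if config_hash is not None:
        lines.append(f"Config hash: {config_hash}.")
    if assumptions:
        lines.append("")
        lines.append("## Data reconstruction assumptions")
        lines.append("")
        for a in assumptions:
            lines.append(f"- [{a.fixture_name}] {a.text} (affects: {a.affects})")
    lines.append("")
    return "\n".join(lines)


def detection_curve_figure(fitted_models, sizes=None, forest_levels=(0, 1)):
    """Detection probability vs group size, one curve per forest level.

    ``fitted_models`` is a fitted :class:`~dosabund.estimation.HugginsDetectionModel`
    or a list of them.  Returns a matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    if not isinstance(fitted_models, (list, tuple)):
        fitted_models = [fitted_models]
    sizes = np.arange(1, 31) if sizes is None else np.asarray(sizes)

    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {0: "--", 1: "-"}
    for est in fitted_models:
        for forest in forest_levels:
            curve = est.predict_detection(sizes=sizes, forest=forest)
            label = f"{est.spec_.label} ({'forested' if forest else 'open'})"
            ax.plot(curve["size"], curve["p_obs1"], styles.get(forest, "-"), label=label)
    ax.set_xlabel("Group size")
    ax.set_ylabel("Detection probability (observer 1)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
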