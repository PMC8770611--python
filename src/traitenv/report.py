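"""End-to-end orchestration and report generation.

``run_pipeline`` sequences the full analysis: obtain (or simulate) the plot,
trait and occurrence tables; grid-subsample replicate modelling datasets;
standardize each replicate's covariates; fit the trait-environment model per
replicate; evaluate discrimination metrics and residual Moran's I; and
aggregate coefficients across replicates.  ``write_report`` renders the run
directory into a human-readable report (fixed-effect table with
significance stars, random-effect SD block, per-species responses,
trait-response panels) without recomputing anything.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from traitenv import __version__
from traitenv.evaluation import aggregate_fits, metric_report, morans_i, plot_residuals
from traitenv.glmm import (
    ModelData,
    ModelFit,
    PriorSpec,
    conditional_r2,
    fit_map,
    predict_matrix,
    trait_response_profile,
)
from traitenv.grid_sampler import generate_replicates, split_plot_table
from traitenv.preprocessing import ENVIRONMENTS, TRAITS, build_design
from traitenv.synthetic import Scenario, gen_occurrence, gen_topography, gen_traits

log = logging.getLogger("traitenv")


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001 (strict inequalities)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    scenario: Scenario | None = None
    plots_csv: Path | None = None
    traits_csv: Path | None = None
    occurrence_csv: Path | None = None
    n_replicates: int = 10
    base_seed: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)
    control: dict | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scenario is None and not (
            self.plots_csv and self.traits_csv and self.occurrence_csv
        ):
            raise ValueError("provide either a scenario or plots/traits/occurrence paths")


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        rng = np.random.default_rng(config.scenario.seed)
        plots = gen_topography(config.scenario, rng)
        traits = gen_traits(config.scenario, rng)
        occurrence, truth = gen_occurrence(plots, traits, config.scenario, rng)
        return plots, traits, occurrence, truth
    plots = pd.read_csv(config.plots_csv)
    traits = pd.read_csv(config.traits_csv)
    occurrence = pd.read_csv(config.occurrence_csv, index_col=0)
    return plots, traits, occurrence, None


def fit_replicate(
    plots: pd.DataFrame,
    traits: pd.DataFrame,
    occurrence: pd.DataFrame,
    plot_ids,
    priors: PriorSpec,
    control: dict | None = None,
) -> tuple[ModelFit, dict, "object"]:
    """Standardize one replicate's 150 plots and fit the model.

    Returns the fit and its evaluation dict (metrics + Moran's I on per-plot
    mean Pearson residuals of the population-level predictions).
    """
    sel = plots.set_index("plot_id").loc[list(plot_ids)].reset_index()
    design = build_design(sel, traits)
    data = ModelData.from_design(design, occurrence)
    fit = fit_map(data, priors=priors, control=control)

    P_cond = predict_matrix(fit, include_random=True)
    P_pop = predict_matrix(fit, include_random=False)
    report = metric_report(data.Y, P_cond, species_ids=data.species_ids)
    residuals = plot_residuals(data.Y, P_pop)
    coords = sel[["x", "y"]].to_numpy(dtype=float)
    moran = morans_i(residuals, coords, seed=0)
    evaluation = {
        "metrics": report.to_dict(),
        "morans_i": moran.to_dict(),
        "conditional_r2": conditional_r2(fit),
    }
    return fit, evaluation, design


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Per-replicate failures are recorded (stage and replicate id) and the
    remaining replicates continue.  The run log captures seeds, versions and
    timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    run_log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "base_seed": config.base_seed,
        "n_replicates": config.n_replicates,
        "failures": [],
        "timings": {},
    }

    plots, traits, occurrence, truth = _load_inputs(config)
    plots.to_csv(out / "plots.csv", index=False)
    traits.to_csv(out / "traits.csv", index=False)
    occurrence.to_csv(out / "occurrence.csv")
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)

    sets, scattered = split_plot_table(plots)
    replicates = generate_replicates(
        sets, scattered, n_replicates=config.n_replicates, base_seed=config.base_seed
    )
    with open(out / "samples.json", "w") as fh:
        json.dump(
            [
                {"replicate_id": r.replicate_id, "seed": r.seed, "plot_ids": list(r.plot_ids)}
                for r in replicates
            ],
            fh,
            indent=2,
        )

    fits: list[ModelFit] = []
    for rep in replicates:
        rep_dir = out / f"replicate_{rep.replicate_id:02d}"
        rep_dir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            fit, evaluation, design = fit_replicate(
                plots, traits, occurrence, rep.plot_ids, config.priors, config.control
            )
        except Exception as err:  # keep going; record stage + replicate
            log.exception("replicate %d failed", rep.replicate_id)
            run_log["failures"].append(
                {"stage": "fit", "replicate": rep.replicate_id, "error": str(err)}
            )
            continue
        fit.save(rep_dir / "fit.json")
        design.save(
            rep_dir / "design.csv", rep_dir / "records.json", rep_dir / "design_traits.csv"
        )
        with open(rep_dir / "metrics.json", "w") as fh:
            json.dump(evaluation, fh, indent=2)
        fits.append(fit)
        run_log["timings"][f"replicate_{rep.replicate_id}"] = round(time.time() - t0, 2)
        if rep.replicate_id == 1:
            _write_profiles(fit, rep_dir)

    if fits:
        agg = aggregate_fits(fits)
        agg.to_csv(out / "aggregate.csv")
        moran_rows = []
        for rep in replicates:
            mpath = out / f"replicate_{rep.replicate_id:02d}" / "metrics.json"
            if mpath.exists():
                with open(mpath) as fh:
                    m = json.load(fh)["morans_i"]
                m["replicate"] = rep.replicate_id
                moran_rows.append(m)
        pd.DataFrame(moran_rows).to_csv(out / "morans_i.csv", index=False)

    run_log["n_fitted"] = len(fits)
    run_log["total_seconds"] = round(time.time() - t_start, 2)
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return out


def _write_profiles(fit: ModelFit, rep_dir: Path) -> None:
    """Store the 4 x 3 trait-response panel data for the reporting step."""
    panels = []
    for t in TRAITS:
        for e in ENVIRONMENTS:
            prof = trait_response_profile(fit, t, e)
            panels.append(
                {
                    "trait": prof.trait,
                    "environment": prof.environment,
                    "grid": prof.grid.tolist(),
                    "line": prof.line.tolist(),
                    "lower": prof.lower.tolist(),
                    "upper": prof.upper.tolist(),
                    "species_trait_values": prof.species_trait_values.tolist(),
                    "species_responses": prof.species_responses.tolist(),
                    "coefficient": prof.coefficient,
                    "se": prof.se,
                    "zero_crossing": prof.zero_crossing,
                }
            )
    with open(rep_dir / "profiles.json", "w") as fh:
        json.dump(panels, fh, indent=2)


# ---------------------------------------------------------------------------
# reporting


def write_report(run_dir, *, figures: bool = False) -> Path:
    """Render a run directory into report.md (and optional figures).

    Pure with respect to the run directory: everything is read from the
    stored JSON/CSV outputs, nothing is refitted.  Missing pieces yield a
    partial report with the gaps flagged.
    """
    run_dir = Path(run_dir)
    lines: list[str] = ["# Trait-environment model report", ""]
    missing: list[str] = []

    agg = None
    if (run_dir / "aggregate.csv").exists():
        agg = pd.read_csv(run_dir / "aggregate.csv", index_col=0)
    else:
        missing.append("aggregate.csv")

    rep1 = run_dir / "replicate_01"
    fit1 = None
    if (rep1 / "fit.json").exists():
        with open(rep1 / "fit.json") as fh:
            fit1 = json.load(fh)
    else:
        missing.append("replicate_01/fit.json")

    if fit1 is not None:
        lines.append("## Fixed effects (replicate 1, ranges across replicates)")
        lines.append("")
        lines.append("| Fixed effect | Coefficient | Fit ranges | SE | P value |")
        lines.append("|---|---|---|---|---|")
        for name, row in fit1["fixed"].items():
            rng_str = agg.loc[name, "range"] if agg is not None and name in agg.index else "-"
            stars = significance_stars(row["p"])
            lines.append(
                f"| {name} | {row['coefficient']:.2f} | {rng_str} | "
                f"{row['se']:.2f} | {row['p']:.3g}{stars} |"
            )
        lines.append("")
        lines.append("Stars: \\*P < 0.05, \\*\\*P < 0.01, \\*\\*\\*P < 0.001.")
        lines.append("")
        lines.append("## Random effects (SD)")
        lines.append("")
        lines.append("| Random effect | SD |")
        lines.append("|---|---|")
        for name, sd in fit1["random_sd"].items():
            lines.append(f"| {name} | {sd:.2f} |")
        lines.append("")

        lines.append("## Per-species environmental responses (replicate 1)")
        lines.append("")
        lines.append("| Species | Intercept | " + " | ".join(
            e.capitalize() for e in fit1["species_effects"][1:]) + " |")
        lines.append("|" + "---|" * (1 + len(fit1["species_effects"])))
        alpha = fit1["fixed"]["Intercept"]["coefficient"]
        beta1 = [fit1["fixed"][n]["coefficient"] for n in ("Elevation", "Slope", "Aspect")]
        for sp, modes in zip(fit1["species_ids"], fit1["species_modes"]):
            total = [alpha + modes[0]] + [
                b + m for b, m in zip(beta1, modes[1:])
            ]
            lines.append(f"| {sp} | " + " | ".join(f"{v:.2f}" for v in total) + " |")
        lines.append("")

    metrics_path = rep1 / "metrics.json"
    if metrics_path.exists():
        with open(metrics_path) as fh:
            m = json.load(fh)
        mm = m["metrics"]
        lines.append("## Performance (replicate 1)")
        lines.append("")
        lines.append(f"- Conditional R-squared: {m['conditional_r2']:.2f}")
        lines.append(f"- AUROC across all species (pooled): {mm['pooled_auroc']:.2f}")
        ratio = mm["auprc_prevalence_ratio"]
        lines.append(
            f"- AUPRC/prevalence: mean {ratio['mean']:.2f} "
            f"(ranging from {ratio['min']:.2f} to {ratio['max']:.2f} individually)"
        )
        lines.append("")
    else:
        missing.append("replicate_01/metrics.json")

    if (run_dir / "morans_i.csv").exists():
        moran = pd.read_csv(run_dir / "morans_i.csv")
        lines.append("## Residual spatial autocorrelation (Moran's I)")
        lines.append("")
        lines.append("| Replicate | I | Expected | P |")
        lines.append("|---|---|---|---|")
        for _, row in moran.iterrows():
            lines.append(
                f"| {int(row['replicate'])} | {row['I']:.4f} | "
                f"{row['expected_I']:.4f} | {row['p_value']:.3f} |"
            )
        lines.append("")
    else:
        missing.append("morans_i.csv")

    if (rep1 / "profiles.json").exists():
        with open(rep1 / "profiles.json") as fh:
            panels = json.load(fh)
        lines.append("## Trait-modulated environmental responses (replicate 1)")
        lines.append("")
        lines.append("| Trait | Environment | Coefficient | SE | Mean-response zero crossing (std. trait) |")
        lines.append("|---|---|---|---|---|")
        for p in panels:
            zc = "-" if p["zero_crossing"] is None else f"{p['zero_crossing']:.2f}"
            lines.append(
                f"| {p['trait']} | {p['environment']} | "
                f"{p['coefficient']:.2f} | {p['se']:.2f} | {zc} |"
            )
        lines.append("")
        if figures:
            fig_path = _render_panels(panels, run_dir)
            lines.append(f"![trait-response panels]({fig_path.name})")
            lines.append("")
    else:
        missing.append("replicate_01/profiles.json")

    if missing:
        lines.append("## Missing sections")
        lines.append("")
        for item in missing:
            lines.append(f"- missing input: {item}")
        lines.append("")

    out_path = run_dir / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path


def _render_panels(panels: list[dict], run_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(TRAITS), len(ENVIRONMENTS), figsize=(11, 12), sharey=True)
    by_key = {(p["trait"], p["environment"]): p for p in panels}
    for r, t in enumerate(TRAITS):
        for c, e in enumerate(ENVIRONMENTS):
            p = by_key[(t, e)]
            ax = axes[r, c]
            grid = np.array(p["grid"])
            ax.fill_between(grid, p["lower"], p["upper"], alpha=0.3, color="grey")
            ax.plot(grid, p["line"], color="black")
            ax.scatter(
                p["species_trait_values"], p["species_responses"], s=12, color="tab:blue"
            )
            ax.axhline(0.0, lw=0.5, color="grey")
            ax.set_title(f"{t} x {e}", fontsize=9)
    fig.tight_layout()
    path = run_dir / "trait_response_panels.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
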