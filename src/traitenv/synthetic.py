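"""Synthetic communities with the statistical structure the analysis assumes.

The generator emulates the study layout — three one-hectare sets of one
hundred 10 m x 10 m plots along topographic gradients plus 69 scattered
plots, elevations 200-1000 m, 31 woody species whose four traits span the
observed ranges (SLA 5.60-45.05, seed mass 0.10-9259 mg, wood density
0.35-0.85 g cm^-3, maximum height 5-30 m) — and draws occurrences from the
trait-environment GLMM with known ("true") parameters, whose defaults are
the fitted point estimates of the reference analysis.  Every stage is
deterministic given the scenario seed, so parameter-recovery experiments
and end-to-end pipeline tests need no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from traitenv.glmm import FixedEffects, ModelData, ModelStructure, RandomEffects, eta_matrix
from traitenv.grid_sampler import generate_replicates, split_plot_table
from traitenv.preprocessing import ENVIRONMENTS, TRAITS, build_design

#: Fitted point estimates of the reference topographic model, used as the
#: default simulation truth.  beta1 order: elevation, slope, aspect.
#: beta12 rows: SLA, SM, SD, MH; columns: elevation, slope, aspect.
DEFAULT_ALPHA = -2.23
DEFAULT_BETA1 = (0.27, -0.15, 0.34)
DEFAULT_BETA12 = (
    (0.13, 0.07, -0.02),
    (-0.14, 0.18, 0.29),
    (-0.08, -0.12, 0.04),
    (-0.32, -0.06, -0.18),
)
#: Random-effect SDs: site intercept, species intercept, species slopes for
#: elevation, slope and aspect.
DEFAULT_RANDOM_SD = {
    "site": 1.32,
    "intercept": 1.01,
    "elevation": 0.70,
    "slope": 0.40,
    "aspect": 0.42,
}
DEFAULT_TRAIT_RANGES = {
    "sla": (5.60, 45.05),
    "seed_mass": (0.10, 9259.00),
    "wood_density": (0.35, 0.85),
    "max_height": (5.0, 30.0),
}


@dataclass
class Scenario:
    """Configuration of a synthetic community and its true parameters."""

    n_sets: int = 3
    set_side: int = 10  # plots per side of a set (10 x 10 = 100 plots)
    n_scattered: int = 69
    m_species: int = 31
    true_fixed: FixedEffects = field(
        default_factory=lambda: FixedEffects(
            alpha=DEFAULT_ALPHA,
            beta1=np.array(DEFAULT_BETA1),
            beta12=np.array(DEFAULT_BETA12),
        )
    )
    true_random_sd: dict = field(default_factory=lambda: dict(DEFAULT_RANDOM_SD))
    species_correlations: np.ndarray | None = None  # d x d correlation, default identity
    trait_ranges: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_RANGES))
    elevation_range: tuple = (200.0, 1000.0)
    slope_range: tuple = (1.0, 40.0)
    plot_spacing: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 0 or self.n_scattered < 0:
            raise ValueError("set and scattered plot counts must be nonnegative")
        if self.m_species < 2:
            raise ValueError("need at least 2 species")
        for name, (lo, hi) in {**self.trait_ranges}.items():
            if not (0 < lo < hi):
                raise ValueError(f"trait range for {name!r} must satisfy 0 < min < max")
        for name, rng in {"elevation_range": self.elevation_range, "slope_range": self.slope_range}.items():
            if not rng[0] < rng[1]:
                raise ValueError(f"{name} must be (min, max) with min < max")
        for name, sd in self.true_random_sd.items():
            if sd < 0:
                raise ValueError(f"random-effect SD {name!r} must be nonnegative")

    def species_covariance(self) -> np.ndarray:
        """4 x 4 covariance of (intercept, elevation, slope, aspect) deviations."""
        sds = np.array(
            [self.true_random_sd[k] for k in ("intercept",) + ENVIRONMENTS]
        )
        corr = (
            np.eye(4) if self.species_correlations is None
            else np.asarray(self.species_correlations, dtype=float)
        )
        return corr * np.outer(sds, sds)


def make_scenario(**overrides) -> Scenario:
    """Default scenario (reference study conditions) with validated overrides."""
    valid = set(Scenario.__dataclass_fields__)
    bad = set(overrides) - valid
    if bad:
        raise ValueError(f"unknown scenario fields: {sorted(bad)}")
    if "true_fixed" in overrides and isinstance(overrides["true_fixed"], dict):
        overrides["true_fixed"] = FixedEffects(**overrides["true_fixed"])
    return Scenario(**overrides)


def gen_topography(scenario: Scenario, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Plot table: grid sets with smooth elevation gradients plus scattered plots.

    Each set sits on its own base elevation (bases spread over the elevation
    range so sets contrast environmentally, as a gradient-spanning survey
    intends), with a linear within-set trend plus smooth noise.  Scattered
    plots are uniform over the elevation range.  Aspects are uniform compass
    degrees in [0, 360); slopes uniform within ``slope_range``.
    """
    rng = _as_rng(rng, scenario.seed)
    side, spacing = scenario.set_side, scenario.plot_spacing
    records = []
    bases = np.linspace(
        scenario.elevation_range[0] + 100.0,
        scenario.elevation_range[1] - 100.0,
        max(scenario.n_sets, 1),
    )
    for s in range(scenario.n_sets):
        origin = np.array([2000.0 * s, 0.0])
        grad = rng.uniform(-3.0, 3.0, size=2)  # m elevation per plot step
        smooth = rng.normal(0.0, 2.0, size=(side, side))
        for row in range(side):
            for col in range(side):
                elev = bases[s] + grad[0] * row + grad[1] * col + smooth[row, col]
                elev = float(np.clip(elev, *scenario.elevation_range))
                records.append(
                    {
                        "plot_id": f"S{s + 1}_{row}_{col}",
                        "set_id": f"set{s + 1}",
                        "row": row,
                        "col": col,
                        "x": origin[0] + col * spacing,
                        "y": origin[1] + row * spacing,
                        "elevation": elev,
                        "aspect": float(rng.uniform(0.0, 360.0)),
                        "slope": float(rng.uniform(*scenario.slope_range)),
                    }
                )
    span = 2000.0 * max(scenario.n_sets, 1)
    for i in range(scenario.n_scattered):
        records.append(
            {
                "plot_id": f"X{i + 1}",
                "set_id": None,
                "row": -1,
                "col": -1,
                "x": float(rng.uniform(0.0, span)),
                "y": float(rng.uniform(200.0, 2000.0)),
                "elevation": float(rng.uniform(*scenario.elevation_range)),
                "aspect": float(rng.uniform(0.0, 360.0)),
                "slope": float(rng.uniform(*scenario.slope_range)),
            }
        )
    return pd.DataFrame.from_records(records)


def gen_traits(scenario: Scenario, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Trait table: log-uniform draws within the scenario ranges.

    The first two species are pinned to each trait's minimum and maximum so
    fixture extremes always match the configured ranges (e.g. the tallest
    species is exactly six times the shortest under the defaults).
    """
    rng = _as_rng(rng, scenario.seed + 1)
    m = scenario.m_species
    data = {"species_id": [f"sp{j + 1:02d}" for j in range(m)]}
    for trait in TRAITS:
        lo, hi = scenario.trait_ranges[trait]
        vals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        vals[0], vals[1] = lo, hi
        # pin a different species pair per trait so no species is extreme in all
        shift = TRAITS.index(trait) % m
        data[trait] = np.roll(vals, shift)
    return pd.DataFrame(data)


def gen_occurrence(
    plots: pd.DataFrame,
    traits: pd.DataFrame,
    scenario: Scenario,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw the binary occurrence table from the model with true parameters.

    Covariates are standardized exactly as in preprocessing (over the plots
    passed in), species random effects are drawn from the covariance
    assembled from the true SDs, site effects from normal(0, site SD), and
    y_ij ~ Bernoulli(inverse-logit(eta_ij)).  Returns the wide occurrence
    table (index plot_id, columns species) and a truth dict recording every
    parameter and the realized random effects.
    """
    rng = _as_rng(rng, scenario.seed + 2)
    design = build_design(plots, traits)
    structure = ModelStructure()
    m, n = len(traits), len(plots)
    Sigma = scenario.species_covariance()
    sd_site = scenario.true_random_sd["site"]
    # PSD square root (eigendecomposition) so zero SDs are allowed
    evals, evecs = np.linalg.eigh(Sigma)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    species_effects = rng.standard_normal((m, 4)) @ factor.T
    site_effects = rng.normal(0.0, sd_site, size=n)
    random = RandomEffects(
        species=species_effects,
        site=site_effects,
        Sigma=Sigma + 1e-12 * np.eye(4),
        sigma_site=max(sd_site, 1e-12),
    )
    eta = eta_matrix(
        scenario.true_fixed, random, design.X.to_numpy(), design.Z.to_numpy(), structure
    )
    y = (rng.random((n, m)) < special.expit(eta)).astype(int)
    occurrence = pd.DataFrame(y, index=design.X.index, columns=design.Z.index)
    truth = {
        "alpha": scenario.true_fixed.alpha,
        "beta1": scenario.true_fixed.beta1.tolist(),
        "beta12": scenario.true_fixed.beta12.tolist(),
        "random_sd": dict(scenario.true_random_sd),
        "Sigma": Sigma.tolist(),
        "species_effects": species_effects.tolist(),
        "site_effects": site_effects.tolist(),
        "standardization": {k: r.to_dict() for k, r in design.records.items()},
    }
    return occurrence, truth


def simulate_fit_dataset(
    scenario: Scenario, rng: np.random.Generator | int | None = None
) -> tuple[ModelData, dict]:
    """One recovery-experiment dataset: 150 grid-sampled plots, known truth.

    Generates topography and traits, grid-subsamples one 150-plot modelling
    dataset, standardizes on those plots, and draws occurrences from the
    model on that exact design — so the true coefficients live on the same
    scale the fit estimates.
    """
    rng = _as_rng(rng, scenario.seed)
    plots = gen_topography(scenario, rng)
    traits = gen_traits(scenario, rng)
    sets, scattered = split_plot_table(plots)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    replicate = generate_replicates(
        sets, scattered, n_replicates=1, base_seed=sub_seed
    )[0]
    selected = plots.set_index("plot_id").loc[replicate.plot_ids].reset_index()
    occurrence, truth = gen_occurrence(selected, traits, scenario, rng)
    design = build_design(selected, traits)
    data = ModelData.from_design(design, occurrence)
    truth["sample_seed"] = sub_seed
    return data, truth


def write_dataset(
    out_dir,
    scenario: Scenario,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Write plots.csv, traits.csv, occurrence.csv and truth.json to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _as_rng(rng, scenario.seed)
    plots = gen_topography(scenario, rng)
    traits = gen_traits(scenario, rng)
    occurrence, truth = gen_occurrence(plots, traits, scenario, rng)
    plots.to_csv(out / "plots.csv", index=False)
    traits.to_csv(out / "traits.csv", index=False)
    occurrence.to_csv(out / "occurrence.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"plots": len(plots), "traits": len(traits), "occurrence": occurrence.shape}


def recovery_experiment(
    scenario: Scenario | None = None,
    *,
    n_replicates: int = 200,
    base_seed: int = 0,
    control: dict | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit parameter recovery at known truth.

    Each replicate draws a fresh 150-plot community from ``scenario`` (new
    random effects, new occurrences, new grid subsample) and refits the
    model.  Returns one row per replicate x coefficient with the estimate,
    SE, truth, and whether the 95% Wald interval covered the truth.
    """
    from traitenv.glmm import FixedEffects, fit_map

    scenario = scenario or make_scenario()
    rows = []
    for r in range(n_replicates):
        sc = replace(scenario, seed=base_seed + 1000 * r)
        data, truth = simulate_fit_dataset(sc)
        fit = fit_map(data, control=control)
        true_vec = np.concatenate([[truth["alpha"]], np.ravel(truth["beta1"]),
                                   np.ravel(truth["beta12"])])
        est = fit.fixed.pack()
        for name, e, s, t in zip(FixedEffects.names(), est, fit.se, true_vec):
            rows.append(
                {
                    "replicate": r,
                    "coefficient": name,
                    "estimate": float(e),
                    "se": float(s),
                    "truth": float(t),
                    "covered": bool(abs(e - t) <= 1.96 * s),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def recovery_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-coefficient bias, Monte-Carlo SE of the mean estimate, coverage."""
    grouped = results.groupby("coefficient", sort=False)
    out = grouped.agg(
        mean_estimate=("estimate", "mean"),
        truth=("truth", "first"),
        mc_se=("estimate", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        coverage=("covered", "mean"),
    )
    out["bias"] = out["mean_estimate"] - out["truth"]
    out["bias_in_mc_se"] = out["bias"] / out["mc_se"]
    return out


def _as_rng(rng, default_seed: int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        return np.random.default_rng(default_seed)
    return np.random.default_rng(rng)


def scenario_from_yaml(path) -> Scenario:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "beta12" in cfg or "alpha" in cfg:  # flat layout convenience
        fixed = FixedEffects(
            alpha=cfg.pop("alpha", DEFAULT_ALPHA),
            beta1=np.array(cfg.pop("beta1", DEFAULT_BETA1)),
            beta12=np.array(cfg.pop("beta12", DEFAULT_BETA12)),
        )
        cfg["true_fixed"] = fixed
    for key in ("elevation_range", "slope_range"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    if "trait_ranges" in cfg:
        cfg["trait_ranges"] = {k: tuple(v) for k, v in cfg["trait_ranges"].items()}
    return make_scenario(**cfg)
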