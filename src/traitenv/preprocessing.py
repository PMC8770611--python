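"""Covariate preprocessing: aspect folding, log transforms, 2-SD standardization.

Raw covariates are transformed into the standardized design used by the
trait-environment model:

* aspect (compass degrees) is folded onto a south-north orientation axis,
  0 deg = north-facing to 180 deg = south-facing;
* every other covariate (elevation, slope, and the four traits) is
  natural-log transformed, since the raw distributions are strongly skewed;
* each column is then centred and divided by twice its sample standard
  deviation, so standardized columns have mean 0 and SD 0.5 and a one-unit
  change spans two SDs of the data.  On this scale logistic-regression
  coefficients for continuous inputs are directly comparable with those of
  binary inputs, and the intercept is the overall prevalence at mean traits
  and mean environment.

Every transform is recorded in a :class:`StandardizationRecord` so the exact
design can be rebuilt (or inverted) bit-for-bit from the raw tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

#: Environmental columns of the design, in fixed reporting order.
ENVIRONMENTS = ("elevation", "slope", "aspect")
#: Trait columns of the design, in fixed reporting order.
TRAITS = ("sla", "seed_mass", "wood_density", "max_height")
#: Display labels used in report tables.
DISPLAY = {
    "elevation": "Elevation",
    "slope": "Slope",
    "aspect": "Aspect",
    "sla": "SLA",
    "seed_mass": "SM",
    "wood_density": "SD",
    "max_height": "MH",
}

#: The 12 trait x environment interaction pairs, trait-major, matching the
#: reporting order of the fixed-effect table (SLA:Elevation ... MH:Aspect).
INTERACTION_INDEX: tuple[tuple[str, str], ...] = tuple(
    (t, e) for t in TRAITS for e in ENVIRONMENTS
)


class DegenerateInputError(ValueError):
    """A covariate cannot be standardized (e.g. zero variance)."""


@dataclass
class StandardizationRecord:
    """Invertible record of the transform applied to one covariate column.

    ``apply`` maps raw values to the standardized scale used by the model;
    ``invert`` maps standardized values back to the raw scale.  ``offset`` is
    the additive constant used to keep log arguments positive (0 when no
    zeros were present or no log was taken).
    """

    name: str
    log_applied: bool
    center: float
    scale: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise DegenerateInputError(
                f"standardization scale for {self.name!r} must be > 0, got {self.scale}"
            )

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.log_applied:
            x = np.log(x + self.offset)
        return (x - self.center) / self.scale

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        x = np.asarray(standardized, dtype=float) * self.scale + self.center
        if self.log_applied:
            x = np.exp(x) - self.offset
        return x

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationRecord":
        return cls(**d)


@dataclass
class DesignMatrices:
    """Standardized design: plots x environments and species x traits.

    ``X`` is an ``n_plots x 3`` frame (elevation, slope, aspect) and ``Z`` an
    ``m_species x 4`` frame (sla, seed_mass, wood_density, max_height), both
    indexed by their id columns.  ``interaction_index`` lists the 12
    (trait, environment) pairs in the fixed reporting order, so the full
    fixed-effect design has 1 + 3 + 12 = 16 columns.
    """

    X: pd.DataFrame
    Z: pd.DataFrame
    records: dict[str, StandardizationRecord] = field(default_factory=dict)
    interaction_index: tuple[tuple[str, str], ...] = INTERACTION_INDEX

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(ENVIRONMENTS):
            raise ValueError(f"X must have columns {ENVIRONMENTS}, got {list(self.X.columns)}")
        if list(self.Z.columns) != list(TRAITS):
            raise ValueError(f"Z must have columns {TRAITS}, got {list(self.Z.columns)}")
        if len(self.interaction_index) != len(TRAITS) * len(ENVIRONMENTS):
            raise ValueError("interaction_index must contain every trait x environment pair")

    @property
    def n_fixed_effects(self) -> int:
        """Intercept + environment main effects + trait:environment terms."""
        return 1 + len(ENVIRONMENTS) + len(self.interaction_index)

    def fixed_effect_names(self) -> list[str]:
        names = ["Intercept"] + [DISPLAY[e] for e in ENVIRONMENTS]
        names += [f"{DISPLAY[t]}: {DISPLAY[e]}" for t, e in self.interaction_index]
        return names

    def save(
        self,
        design_csv: Path | str,
        records_json: Path | str,
        traits_csv: Path | str | None = None,
    ) -> None:
        """Write the standardized design and a JSON sidecar of records."""
        xd = self.X.copy()
        xd.index.name = self.X.index.name or "plot_id"
        xd.to_csv(design_csv)
        if traits_csv is not None:
            zd = self.Z.copy()
            zd.index.name = self.Z.index.name or "species_id"
            zd.to_csv(traits_csv)
        with open(records_json, "w") as fh:
            json.dump({k: r.to_dict() for k, r in self.records.items()}, fh, indent=2)


def fold_aspect(degrees):
    """Fold compass aspect onto the 0 (north) .. 180 (south) orientation axis.

    Values at or below 180 pass through; values above are reflected as
    ``(degrees - 360) * -1``.  An input of exactly 360 is treated as 0.
    Accepts scalars or arrays; inputs outside [0, 360] raise ``ValueError``
    naming the offending positions.
    """
    arr = np.asarray(degrees, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr > 360)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"aspect must lie in [0, 360); offending positions {idx.tolist()} "
            f"with values {np.atleast_1d(arr)[idx].tolist()}"
        )
    arr = np.where(arr == 360.0, 0.0, arr)
    folded = np.where(arr <= 180.0, arr, (arr - 360.0) * -1.0)
    if np.isscalar(degrees) or np.ndim(degrees) == 0:
        return float(folded)
    return folded


def log_transform(values, *, offset: str | float = "half-min-positive"):
    """Natural-log transform with an explicit, recorded zero-offset policy.

    If zeros are present and ``offset`` is ``"half-min-positive"``, the
    additive constant is half the smallest positive observed value; a float
    offset is used as given; ``offset=0`` with nonpositive values is an
    error.  Returns ``(logged_values, offset_used)``.
    """
    x = np.asarray(values, dtype=float)
    if offset == "half-min-positive":
        if np.any(x < 0):
            raise ValueError("log transform requires nonnegative values")
        eps = 0.0
        if np.any(x == 0):
            positive = x[x > 0]
            if positive.size == 0:
                raise DegenerateInputError("all values are zero; cannot log-transform")
            eps = 0.5 * float(positive.min())
    else:
        eps = float(offset)
        if np.any(x + eps <= 0):
            raise ValueError(
                f"log transform with offset {eps} hits nonpositive arguments "
                f"(min value {x.min()})"
            )
    return np.log(x + eps), eps


def standardize_2sd(values) -> tuple[np.ndarray, float, float]:
    """Center and scale by twice the sample standard deviation.

    Returns ``(standardized, center, scale)`` where ``scale = 2 * SD`` with
    the n-1 denominator.  The output has mean 0 and sample SD 0.5.  Constant
    input raises :class:`DegenerateInputError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    center = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("constant input: 2-SD scale would be zero")
    scale = 2.0 * sd
    return (x - center) / scale, center, scale


def _standardize_column(
    name: str, raw: np.ndarray, *, log_flag: bool
) -> tuple[np.ndarray, StandardizationRecord]:
    if log_flag:
        logged, eps = log_transform(raw)
    else:
        logged, eps = np.asarray(raw, dtype=float), 0.0
    std, center, scale = standardize_2sd(logged)
    rec = StandardizationRecord(
        name=name, log_applied=log_flag, center=center, scale=scale, offset=eps
    )
    return std, rec


def build_design(plots: pd.DataFrame, traits: pd.DataFrame) -> DesignMatrices:
    """Build the standardized X (plots) and Z (species) design matrices.

    ``plots`` must carry ``plot_id, elevation, aspect, slope`` (aspect in raw
    compass degrees) and ``traits`` must carry ``species_id`` plus the four
    trait columns.  Aspect is folded and not logged; every other column is
    logged then 2-SD standardized.  Standardization statistics are computed
    over exactly the rows passed in, so each fitted dataset defines its own
    "mean environment".
    """
    for col in ("plot_id",) + ENVIRONMENTS:
        if col not in plots.columns:
            raise ValueError(f"plot table missing column {col!r}")
    missing_tr = [c for c in ("species_id",) + TRAITS if c not in traits.columns]
    if missing_tr:
        raise ValueError(f"trait table missing columns {missing_tr}")
    na_species = traits.loc[traits[list(TRAITS)].isna().any(axis=1), "species_id"]
    if len(na_species):
        raise ValueError(f"missing trait values for species: {na_species.tolist()}")
    if plots[list(ENVIRONMENTS)].isna().any().any():
        bad = plots.loc[plots[list(ENVIRONMENTS)].isna().any(axis=1), "plot_id"]
        raise ValueError(f"missing environmental values for plots: {bad.tolist()}")

    records: dict[str, StandardizationRecord] = {}
    xcols = {}
    for env in ENVIRONMENTS:
        raw = plots[env].to_numpy(dtype=float)
        if env == "aspect":
            try:
                raw = fold_aspect(raw)
            except ValueError as err:
                bad = np.flatnonzero((plots[env] < 0) | (plots[env] > 360))
                ids = plots["plot_id"].iloc[bad].tolist()
                raise ValueError(f"invalid aspect for plots {ids}") from err
        xcols[env], records[env] = _standardize_column(env, raw, log_flag=env != "aspect")
    X = pd.DataFrame(xcols, index=pd.Index(plots["plot_id"], name="plot_id"))

    zcols = {}
    for trait in TRAITS:
        raw = traits[trait].to_numpy(dtype=float)
        zcols[trait], records[trait] = _standardize_column(trait, raw, log_flag=True)
    Z = pd.DataFrame(zcols, index=pd.Index(traits["species_id"], name="species_id"))

    return DesignMatrices(X=X, Z=Z, records=records)


def load_records(records_json: Path | str) -> dict[str, StandardizationRecord]:
    with open(records_json) as fh:
        return {k: StandardizationRecord.from_dict(d) for k, d in json.load(fh).items()}
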