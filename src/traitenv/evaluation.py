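"""Model evaluation: discrimination metrics and spatial diagnostics.

Presence-absence data are strongly imbalanced (most species occupy few
plots), so performance is reported both as AUROC and as AUPRC.  A random
classifier's AUPRC equals the species' prevalence, so AUPRC/prevalence says
how many times better than random the model discriminates for that species.

Moran's I on per-plot residuals checks that the grid-subsampling design
removed spatial autocorrelation; its permutation p-value should be
non-significant for a well-thinned dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    """Metric undefined for this label vector (single class / no positives)."""


def auroc(labels, scores) -> float:
    """Rank-based area under the ROC curve with mid-rank tie handling.

    Equivalent to the normalized Mann-Whitney U statistic.  Requires both
    classes present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise UndefinedMetricError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve, average-precision form.

    Uses the interpolation-free summation AP = sum_k (R_k - R_{k-1}) P_k
    (trapezoidal interpolation of PR curves is optimistically biased).
    Requires at least one positive.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positive labels")
    return float(average_precision_score(y, s))


def auprc_prevalence_ratio(labels, scores) -> float:
    """AUPRC divided by prevalence: fold improvement over a random classifier."""
    y = np.asarray(labels)
    prevalence = float(y.mean())
    return auprc(y, scores) / prevalence


@dataclass
class MetricReport:
    """Per-species and pooled discrimination metrics."""

    per_species: pd.DataFrame
    pooled_auroc: float
    pooled_auprc: float
    mean_auroc: float
    ratio_mean: float
    ratio_min: float
    ratio_max: float

    def to_dict(self) -> dict:
        return {
            "per_species": self.per_species.reset_index().to_dict(orient="records"),
            "pooled_auroc": self.pooled_auroc,
            "pooled_auprc": self.pooled_auprc,
            "mean_auroc": self.mean_auroc,
            "auprc_prevalence_ratio": {
                "mean": self.ratio_mean,
                "min": self.ratio_min,
                "max": self.ratio_max,
            },
        }


def metric_report(Y: np.ndarray, P: np.ndarray, species_ids=None) -> MetricReport:
    """Evaluate fitted probabilities against the occurrence matrix.

    ``Y`` and ``P`` are n_plots x m_species.  Species whose column is
    single-class are skipped in the per-species table (their metrics are
    undefined) but still enter the pooled AUROC, which concatenates all
    plot x species cells.
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    ids = list(species_ids) if species_ids is not None else list(range(Y.shape[1]))
    rows = []
    for j, sp in enumerate(ids):
        y, p = Y[:, j], P[:, j]
        if y.min() == y.max():
            continue
        pr = auprc(y, p)
        rows.append(
            {
                "species": sp,
                "prevalence": float(y.mean()),
                "auroc": auroc(y, p),
                "auprc": pr,
                "auprc_prevalence": pr / float(y.mean()),
            }
        )
    per_species = pd.DataFrame(rows).set_index("species")
    ratios = per_species["auprc_prevalence"]
    return MetricReport(
        per_species=per_species,
        pooled_auroc=auroc(Y.ravel(), P.ravel()),
        pooled_auprc=auprc(Y.ravel(), P.ravel()),
        mean_auroc=float(per_species["auroc"].mean()),
        ratio_mean=float(ratios.mean()),
        ratio_min=float(ratios.min()),
        ratio_max=float(ratios.max()),
    )


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class MoransIResult:
    I: float
    expected_I: float
    p_value: float
    weight_spec: str
    n_permutations: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "expected_I": self.expected_I,
            "p_value": self.p_value,
            "weight_spec": self.weight_spec,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def spatial_weights(
    coordinates: np.ndarray, *, kind: str = "inverse_distance", k: int = 8
) -> np.ndarray:
    """Row-standardized spatial weight matrix with zero diagonal.

    ``inverse_distance`` (default): w_uv = 1/d_uv; ``knn``: binary k-nearest
    neighbour weights.  Coincident points are an error for inverse distance.
    """
    xy = np.asarray(coordinates, dtype=float)
    n = xy.shape[0]
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    off = ~np.eye(n, dtype=bool)
    if kind == "inverse_distance":
        if np.any(dist[off] == 0):
            raise ValueError("coincident coordinates: inverse-distance weights undefined")
        W = np.zeros((n, n))
        W[off] = 1.0 / dist[off]
    elif kind == "knn":
        W = np.zeros((n, n))
        order = np.argsort(dist + np.where(off, 0.0, np.inf), axis=1)
        for u in range(n):
            W[u, order[u, :k]] = 1.0
    else:
        raise ValueError(f"unknown weight kind {kind!r}")
    return W / W.sum(axis=1, keepdims=True)


def morans_i(
    residuals,
    coordinates,
    *,
    weights: np.ndarray | None = None,
    weight_kind: str = "inverse_distance",
    n_permutations: int = 999,
    seed: int | None = 0,
    alternative: str = "two-sided",
) -> MoransIResult:
    """Moran's I with a permutation test.

    I = (N/W) * (sum_uv w_uv r_u r_v) / (sum_u r_u^2) on centered residuals,
    null expectation -1/(N-1).  The p-value compares the observed I with its
    permutation distribution (residuals shuffled over locations).
    """
    r = np.asarray(residuals, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    n = r.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 plots")
    if np.ptp(r) == 0:
        raise ValueError("Moran's I undefined for constant residuals")
    if weights is None:
        weights = spatial_weights(xy, kind=weight_kind)
        weight_spec = f"{weight_kind}, row-standardized, zero diagonal"
    else:
        weight_spec = "user-supplied"
    W = float(weights.sum())
    rc = r - r.mean()
    denom = float(rc @ rc)

    def statistic(vec_rows: np.ndarray) -> np.ndarray:
        # vec_rows: (k, n) centered residual rows
        num = np.einsum("ku,uv,kv->k", vec_rows, weights, vec_rows)
        return (n / W) * num / denom

    I_obs = float(statistic(rc[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(rc) for _ in range(n_permutations)])
    I_perm = statistic(perms)
    expected = -1.0 / (n - 1)
    if alternative == "greater":
        extreme = np.sum(I_perm >= I_obs)
    elif alternative == "less":
        extreme = np.sum(I_perm <= I_obs)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(I_perm - expected) >= abs(I_obs - expected))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + float(extreme)) / (1.0 + n_permutations)
    return MoransIResult(
        I=I_obs,
        expected_I=expected,
        p_value=min(p, 1.0),
        weight_spec=weight_spec,
        n_permutations=n_permutations,
        seed=seed,
    )


def plot_residuals(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-plot mean Pearson residual across species (population-level P)."""
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    pearson = (Y - P) / np.sqrt(P * (1.0 - P))
    return pearson.mean(axis=1)


# ---------------------------------------------------------------------------
# cross-replicate aggregation


def aggregate_fits(fits) -> pd.DataFrame:
    """Mean and min-max range of each fixed effect across replicate fits.

    Mirrors the "10 fit ranges" reporting convention: per coefficient, the
    average across fits plus the extremes formatted as "low/high".
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    names = fits[0].fixed_names
    coefs = []
    for fit in fits:
        if fit.fixed_names != names:
            raise ValueError("fits have mismatched coefficient sets")
        coefs.append(fit.fixed.pack())
    arr = np.array(coefs)
    table = pd.DataFrame(
        {
            "mean": arr.mean(axis=0),
            "min": arr.min(axis=0),
            "max": arr.max(axis=0),
        },
        index=pd.Index(names, name="fixed_effect"),
    )
    table["range"] = [f"{lo:.2f}/{hi:.2f}" for lo, hi in zip(table["min"], table["max"])]
    return table
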