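"""Phylogenetic allometry of home range against body mass.

Fits the log10(home range, km²) ~ log10(body mass, kg) power law across
extant macropodids by phylogenetic generalised least squares (PGLS) under a
Brownian-motion covariance model, and predicts home ranges for extinct body
masses from the fitted coefficients.

The GLS estimator is β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y where C is the Brownian-motion
expected covariance of tip values (shared root-to-MRCA branch length).
R² is computed against the GLS-weighted intercept-only model, so that with
C = I the fit reduces exactly to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

__all__ = [
    "TraitRecord",
    "AllometricFit",
    "RangePrediction",
    "weighted_trait_average",
    "read_traits",
    "prune_tree",
    "bm_covariance",
    "pgls_fit",
    "predict_home_range",
]


@dataclass
class TraitRecord:
    """Per-species trait data: body mass (kg) and mean home range (km²)."""

    species: str
    body_mass: float
    home_range: float
    source_estimates: dict | None = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"{self.species}: body_mass must be > 0")
        if self.home_range <= 0:
            raise ValueError(f"{self.species}: home_range must be > 0")


@dataclass
class AllometricFit:
    """Fitted log-log allometry with coefficient covariance."""

    slope: float
    intercept: float
    coef_cov: np.ndarray  # 2x2, order (intercept, slope)
    residual_variance: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n_species: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "coef_cov": np.asarray(self.coef_cov).tolist(),
            "residual_variance": self.residual_variance,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "n_species": self.n_species,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricFit":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            coef_cov=np.asarray(d["coef_cov"], dtype=float),
            residual_variance=d["residual_variance"],
            r_squared=d["r_squared"],
            f_statistic=d["f_statistic"],
            df=tuple(d["df"]),
            p_value=d["p_value"],
            n_species=d["n_species"],
        )


@dataclass
class RangePrediction:
    """Predicted home range (km²) at a given body mass with an interval."""

    mass: float
    point: float
    interval: tuple[float, float]
    coverage_z: float = 2.0


def weighted_trait_average(
    estimates: Sequence[tuple[float, float]], error_power: float = 2.0
) -> float:
    """Error-weighted mean of multiple published estimates of one trait.

    Weights are 1/error**error_power; the default (2) is inverse-variance
    weighting. ``error_power=1`` weights in direct inverse proportion to the
    quoted error.
    """
    if len(estimates) == 0:
        raise ValueError("at least one estimate is required")
    values = np.asarray([v for v, _ in estimates], dtype=float)
    errors = np.asarray([e for _, e in estimates], dtype=float)
    if np.any(errors <= 0):
        raise ValueError("all estimate errors must be > 0")
    w = errors ** (-error_power)
    return float(np.sum(w * values) / np.sum(w))


def read_traits(path, error_power: float = 2.0) -> list[TraitRecord]:
    """Read a trait CSV in wide (`species,body_mass_kg,home_range_km2`) or
    long (`species,trait,value,error,source`) form."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"species", "body_mass_kg", "home_range_km2"} <= cols:
        return [
            TraitRecord(r.species, float(r.body_mass_kg), float(r.home_range_km2))
            for r in df.itertuples()
        ]
    if {"species", "trait", "value", "error"} <= cols:
        records = []
        for sp, grp in df.groupby("species", sort=False):
            vals: dict[str, float] = {}
            ests: dict[str, list] = {}
            for trait, sub in grp.groupby("trait"):
                pairs = list(zip(sub["value"], sub["error"]))
                vals[trait] = weighted_trait_average(pairs, error_power)
                ests[trait] = pairs
            records.append(
                TraitRecord(sp, vals["body_mass_kg"], vals["home_range_km2"], ests)
            )
        return records
    raise ValueError(f"unrecognised trait CSV columns: {sorted(cols)}")


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Prune a tree down to ``keep`` tips, preserving root-to-tip path lengths.

    Degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed.
    """
    keep = set(keep)
    tips = set(_tip_labels(tree))
    unknown = keep - tips
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    pruned = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return pruned


def bm_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion expected covariance matrix of tip values.

    C[i, j] is the branch length shared from the root to the MRCA of tips i
    and j; the diagonal holds root-to-tip distances. Returns (C, tip order).
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # C[i, j] = summed length of edges ancestral to both tips; accumulate
    # each edge over the clade of tips below it. The root's own (stem) edge
    # is not part of the process: the root state is the BM origin.
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        if length is None:
            continue
        if length < 0:
            raise ValueError("negative branch length in tree")
        idx = [index[id(lf)] for lf in node.leaf_iter()]
        C[np.ix_(idx, idx)] += length
    return C, labels


def pgls_fit(records: Sequence[TraitRecord], C: np.ndarray) -> AllometricFit:
    """PGLS fit of log10 home range on log10 body mass.

    ``C`` must be ordered like ``records``. With C = identity this is
    ordinary least squares.
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 species")
    C = np.asarray(C, dtype=float)
    if C.shape != (n, n):
        raise ValueError("covariance matrix does not match number of records")
    x = np.log10([r.body_mass for r in records])
    y = np.log10([r.home_range for r in records])
    X = np.column_stack([np.ones(n), x])
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    # whiten: GLS == OLS on L^-1-transformed data
    Xt = sla.solve_triangular(L, X, lower=True)
    yt = sla.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    # GLS intercept-only null model
    ones_t = sla.solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_t @ yt / (ones_t @ ones_t))
    null_resid = yt - mu * ones_t
    tss = float(null_resid @ null_resid)
    df2 = n - 2
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    sigma2 = rss / df2
    cov = sigma2 * np.linalg.inv(XtX)
    if r2 < 1.0:
        f = df2 * r2 / (1.0 - r2)
        p = float(stats.f.sf(f, 1, df2))
    else:
        f, p = np.inf, 0.0
    return AllometricFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        coef_cov=cov,
        residual_variance=sigma2,
        r_squared=float(r2),
        f_statistic=float(f),
        df=(1, df2),
        p_value=p,
        n_species=n,
    )


def predict_home_range(
    fit: AllometricFit, mass: float, coverage_z: float = 2.0
) -> RangePrediction:
    """Predicted home range (km²) at ``mass`` kg with a ±z·SE interval.

    The point estimate is 10^(slope·log10(mass) + intercept); the standard
    error of the regression line at log10(mass) is propagated from the
    coefficient covariance in log space, then exponentiated, so the interval
    is asymmetric on the km² scale.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    lx = np.log10(mass)
    yhat = fit.intercept + fit.slope * lx
    xvec = np.array([1.0, lx])
    se = float(np.sqrt(xvec @ np.asarray(fit.coef_cov) @ xvec))
    point = 10.0 ** yhat
    lo = 10.0 ** (yhat - coverage_z * se)
    hi = 10.0 ** (yhat + coverage_z * se)
    return RangePrediction(mass=float(mass), point=float(point), interval=(lo, hi), coverage_z=coverage_z)
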