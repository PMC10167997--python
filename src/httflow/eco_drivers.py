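"""Ecological predictors of HTT potential and the driver model.

Five pairwise predictors feed a linear mixed model for the logit of the
Muller index:

1. abiotic niche overlap — Schoener's D between habitat-suitability grids;
2. geographic overlap — asymmetric % intersection of convex-hull ranges;
3. biotic niche overlap — Czechanowski index on flower-use proportions;
4. niche breadth — fraction of available flower species a fly uses;
5. phylogenetic distance — patristic distance on the dated species tree.

The response logit(d_ij) (d clamped away from {0,1}) is modelled with
crossed random intercepts for the acting and the target species; all 2^5
fixed-effect subsets plus the null model are fitted by maximum likelihood
and ranked by the small-sample AICc (with ~20 pairs per dataset the plain
AIC rewards overfitting; AICc is the standard all-subsets ranking at this
n). Models within delta AICc <= 2 of the best are treated as equivalent;
the best model is refitted by REML for the reported coefficients.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint

from ._lmm import LMMResult, fit_lmm_crossed
from .potential_effects import MullerMatrix

logger = logging.getLogger("httflow")

LOGIT_EPS = 1e-6
EARTH_RADIUS_KM = 6371.0

PREDICTORS = ["abiotic", "geographic", "biotic", "breadth", "phylo"]


@dataclass
class SuitabilityGrid:
    """Habitat-suitability raster; masked cells are NODATA."""

    values: np.ndarray
    mask: np.ndarray
    cellsize: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if (~self.mask).sum() == 0:
            raise ValueError("grid has no data cells")
        if np.nanmin(np.where(self.mask, 0.0, self.values)) < 0:
            raise ValueError("suitability values must be non-negative")

    def normalized(self) -> np.ndarray:
        v = np.where(self.mask, 0.0, self.values)
        total = v.sum()
        if total <= 0:
            raise ValueError("grid sums to zero over data cells")
        return v / total


@dataclass
class OverlapSet:
    """Pairwise predictor matrices plus per-species niche breadth.

    Matrices are indexed by species (rows = acting/focal, columns = other);
    Schoener's D and Czechanowski are symmetric, geographic overlap is
    asymmetric (% of the row species' range covered), phylogenetic distance
    is patristic (Mya).
    """

    abiotic: pd.DataFrame
    geographic: pd.DataFrame
    biotic: pd.DataFrame
    breadth: pd.Series
    phylo: pd.DataFrame


@dataclass
class DriverModelResult:
    """AIC ranking over fixed-effect subsets plus the REML-refit best model."""

    ranking: pd.DataFrame  # model label, predictors, aic, delta_aic, converged
    best_models: list[str]  # labels with delta AIC <= 2
    coefficients: pd.DataFrame  # REML estimates of the best model
    random_variances: dict[str, float]
    best_fit: LMMResult = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Overlap indices
# ---------------------------------------------------------------------------


def schoener_d(g1: SuitabilityGrid, g2: SuitabilityGrid) -> float:
    """Schoener's D between two suitability grids: 1 - 0.5 sum|p - q|."""
    if g1.values.shape != g2.values.shape:
        raise ValueError("grids have different shapes")
    if (g1.mask != g2.mask).any():
        raise ValueError("grids have different NODATA masks")
    p, q = g1.normalized(), g2.normalized()
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def czechanowski(u1: np.ndarray, u2: np.ndarray) -> float:
    """Czechanowski overlap of two resource-use vectors (same form as D)."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if u1.shape != u2.shape:
        raise ValueError("resource vectors have different lengths")
    if (u1 < 0).any() or (u2 < 0).any():
        raise ValueError("resource use must be non-negative")
    if u1.sum() == 0 or u2.sum() == 0:
        raise ValueError("zero resource-use vector")
    p, q = u1 / u1.sum(), u2 / u2.sum()
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def _project_equal_area(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Cylindrical equal-area projection (km); preserves areas exactly."""
    x = np.radians(lon) * EARTH_RADIUS_KM
    y = np.sin(np.radians(lat)) * EARTH_RADIUS_KM
    return np.column_stack([x, y])


def range_overlap(
    points_i: np.ndarray,
    points_j: np.ndarray,
    project: bool = True,
) -> tuple[float, float]:
    """Asymmetric % overlap of convex-hull ranges from occurrence points.

    ``points_*`` are (n, 2) lon/lat arrays (WGS84 decimal degrees). Areas
    are computed after a cylindrical equal-area projection unless
    ``project=False`` (raw-degree planar geometry, for parity with GIS
    defaults). Returns (pct of i's range overlapped, pct of j's range).
    """
    hulls = []
    for name, pts in (("i", points_i), ("j", points_j)):
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < 3:
            raise ValueError(f"species {name}: need >= 3 occurrence points")
        xy = _project_equal_area(pts[:, 0], pts[:, 1]) if project else pts
        hull = MultiPoint([tuple(p) for p in xy]).convex_hull
        if hull.geom_type != "Polygon" or hull.area == 0:
            raise ValueError(f"species {name}: degenerate (collinear) hull")
        hulls.append(hull)
    hi, hj = hulls
    inter = hi.intersection(hj).area
    return 100.0 * inter / hi.area, 100.0 * inter / hj.area


def niche_breadth(network: pd.DataFrame, species: str) -> float:
    """Fraction of flower columns the fly species interacts with (> 0)."""
    if species not in network.index:
        raise KeyError(f"species {species!r} not in interaction network")
    row = network.loc[species]
    return float((row > 0).sum() / network.shape[1])


def phylo_distance(tree, i: str, j: str) -> float:
    """Patristic distance (2 x MRCA age) between two leaves; 0 for i = j."""
    if i == j:
        return 0.0
    return tree.patristic(i, j)


# ---------------------------------------------------------------------------
# Predictor assembly and the driver model
# ---------------------------------------------------------------------------


def build_overlaps(
    grids: dict[str, SuitabilityGrid],
    occurrences: pd.DataFrame,
    network: pd.DataFrame,
    tree,
    species: list[str] | None = None,
    project: bool = True,
) -> OverlapSet:
    """Assemble all five predictors for a species set."""
    sp = species or sorted(grids)
    abiotic = pd.DataFrame(1.0, index=sp, columns=sp)
    geographic = pd.DataFrame(100.0, index=sp, columns=sp)
    biotic = pd.DataFrame(1.0, index=sp, columns=sp)
    phylo = pd.DataFrame(0.0, index=sp, columns=sp)
    pts = {
        s: occurrences.loc[occurrences.species == s, ["lon", "lat"]].to_numpy()
        for s in sp
    }
    for i, j in itertools.combinations(sp, 2):
        d = schoener_d(grids[i], grids[j])
        abiotic.loc[i, j] = abiotic.loc[j, i] = d
        pct_i, pct_j = range_overlap(pts[i], pts[j], project=project)
        geographic.loc[i, j] = pct_i
        geographic.loc[j, i] = pct_j
        c = czechanowski(
            network.loc[i].to_numpy(), network.loc[j].to_numpy()
        )
        biotic.loc[i, j] = biotic.loc[j, i] = c
        t = phylo_distance(tree, i, j)
        phylo.loc[i, j] = phylo.loc[j, i] = t
    breadth = pd.Series({s: niche_breadth(network, s) for s in sp})
    return OverlapSet(
        abiotic=abiotic, geographic=geographic, biotic=biotic,
        breadth=breadth, phylo=phylo,
    )


def driver_table(muller: MullerMatrix, overlaps: OverlapSet) -> pd.DataFrame:
    """Long-format table of ordered cross-species pairs with predictors.

    The response is logit(d_ij) with d clamped to [eps, 1-eps]; the self
    term d_ii is excluded. Niche breadth enters for the target species.
    """
    rows = []
    for acting in muller.table.index:
        for target in muller.table.columns:
            if acting == target:
                continue
            d = muller.table.loc[acting, target]
            if not np.isfinite(d):
                continue
            d = min(max(float(d), LOGIT_EPS), 1.0 - LOGIT_EPS)
            rows.append(
                {
                    "acting": acting,
                    "target": target,
                    "dij": d,
                    "logit_dij": math.log(d / (1.0 - d)),
                    "abiotic": overlaps.abiotic.loc[acting, target],
                    "geographic": overlaps.geographic.loc[acting, target],
                    "biotic": overlaps.biotic.loc[acting, target],
                    "breadth": overlaps.breadth[target],
                    "phylo": overlaps.phylo.loc[acting, target],
                }
            )
    return pd.DataFrame(rows)


def fit_driver_model(
    muller: MullerMatrix | pd.DataFrame,
    overlaps: OverlapSet | None = None,
    log_acting_overlap: bool = False,
) -> DriverModelResult:
    """All-subsets mixed-model selection for the drivers of HTT potential.

    Accepts either a Muller matrix plus an :class:`OverlapSet`, or a
    pre-built long table from :func:`driver_table`. With
    ``log_acting_overlap`` the abiotic predictor enters as log1p (one
    reading of overdispersion control for the acting species' overlap; off
    by default).
    """
    if isinstance(muller, pd.DataFrame):
        data = muller.copy()
    else:
        if overlaps is None:
            raise ValueError("overlaps required with a MullerMatrix input")
        data = driver_table(muller, overlaps)
    if data.empty:
        raise ValueError("no finite cross-species dij values")
    if log_acting_overlap:
        data = data.assign(abiotic=np.log1p(data["abiotic"]))

    y = data["logit_dij"].to_numpy()
    acting = data["acting"].to_numpy()
    target = data["target"].to_numpy()

    fits: dict[str, tuple[tuple[str, ...], LMMResult]] = {}
    for r in range(len(PREDICTORS) + 1):
        for subset in itertools.combinations(PREDICTORS, r):
            label = "+".join(subset) if subset else "null"
            x = np.column_stack(
                [np.ones(len(data))] + [data[p].to_numpy() for p in subset]
            )
            try:
                fit = fit_lmm_crossed(y, x, acting, target, reml=False)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("model %s dropped: %s", label, exc)
                continue
            fits[label] = (subset, fit)
    if not fits:
        raise RuntimeError("all candidate models failed to fit")

    n_obs = len(data)

    def aicc(fit: LMMResult) -> float:
        k = fit.n_params
        if n_obs - k - 1 <= 0:
            return float("inf")
        return fit.aic + 2.0 * k * (k + 1) / (n_obs - k - 1)

    ranking = pd.DataFrame(
        [
            {
                "model": label,
                "n_predictors": len(subset),
                "aic": fit.aic,
                "aicc": aicc(fit),
                "llf": fit.llf,
                "converged": fit.converged,
            }
            for label, (subset, fit) in fits.items()
        ]
    ).sort_values(["aicc", "model"], kind="stable").reset_index(drop=True)
    ranking["delta_aicc"] = ranking["aicc"] - ranking["aicc"].min()
    best_models = list(ranking.loc[ranking.delta_aicc <= 2.0, "model"])

    best_label = ranking.iloc[0]["model"]
    best_subset = fits[best_label][0]
    x_best = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy() for p in best_subset]
    )
    refit = fit_lmm_crossed(y, x_best, acting, target, reml=True)
    coefficients = pd.DataFrame(
        {
            "term": ["intercept", *best_subset],
            "beta": refit.params,
            "se": refit.bse,
            "p": refit.pvalues,
        }
    )
    return DriverModelResult(
        ranking=ranking,
        best_models=best_models,
        coefficients=coefficients,
        random_variances={
            "acting": refit.var_acting,
            "target": refit.var_target,
            "residual": refit.sigma2,
        },
        best_fit=refit,
    )


# ---------------------------------------------------------------------------
# Richness / abundance correlations
# ---------------------------------------------------------------------------


def _exact_perm_p(x: np.ndarray, y: np.ndarray, statistic) -> float:
    """Two-sided exact permutation p-value over all orderings of y."""
    obs = abs(statistic(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(statistic(x, np.array(perm))) >= obs - 1e-12:
            count += 1
    return count / total


def richness_correlations(
    richness: np.ndarray,
    abundance: np.ndarray,
    breadth: np.ndarray,
    area: np.ndarray,
) -> pd.DataFrame:
    """Pearson (richness) and Spearman (abundance) correlations vs ecology.

    Pearson r is used for TE superfamily richness against niche breadth and
    range area, Spearman rho for TE abundance; exact permutation p-values
    are reported when n <= 7 (tiny-sample regime), otherwise the asymptotic
    two-sided p.
    """
    vectors = {
        "richness": np.asarray(richness, float),
        "abundance": np.asarray(abundance, float),
        "breadth": np.asarray(breadth, float),
        "area": np.asarray(area, float),
    }
    n = len(vectors["richness"])
    if any(len(v) != n for v in vectors.values()) or n < 3:
        raise ValueError("vectors must share length n >= 3")
    for name, v in vectors.items():
        if np.ptp(v) == 0:
            raise ValueError(f"constant vector {name!r}: correlation undefined")

    def pearson_stat(x, y):
        return stats.pearsonr(x, y)[0]

    def spearman_stat(x, y):
        return stats.spearmanr(x, y)[0]

    rows = []
    for response, predictor, method, stat in (
        ("richness", "breadth", "pearson", pearson_stat),
        ("richness", "area", "pearson", pearson_stat),
        ("abundance", "breadth", "spearman", spearman_stat),
        ("abundance", "area", "spearman", spearman_stat),
    ):
        x, yv = vectors[response], vectors[predictor]
        r = stat(x, yv)
        if n <= 7:
            p = _exact_perm_p(x, yv, stat)
        else:
            p = (
                stats.pearsonr(x, yv)[1]
                if method == "pearson"
                else stats.spearmanr(x, yv)[1]
            )
        rows.append([response, predictor, method, float(r), float(p)])
    return pd.DataFrame(
        rows, columns=["response", "predictor", "method", "estimate", "p"]
    )
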