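"""Local spatial-association analysis of region-level statistics.

Queen-contiguity spatial weights are built from region polygons (two regions
are neighbors iff their boundaries share at least one point — edge or
vertex), the Getis-Ord Gi* statistic locates clusters of high and low
values, and Benjamini-Hochberg false-discovery-rate adjustment controls for
the many dependent local tests before regions are labeled hot or cold.

Gi* for region i, with binary weights and self-inclusion, follows the
standardized Ord-Getis form

    z_i = ( sum_j w_ij x_j - xbar W_i )
          / ( S sqrt( (n sum_j w_ij^2 - W_i^2) / (n - 1) ) )

where W_i = sum_j w_ij, and xbar, S are the global mean and (population)
standard deviation over all n regions. Under spatial randomness z_i is
approximately standard normal; p-values use the two-sided normal tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import shape
from shapely.strtree import STRtree
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "queen_adjacency",
    "getis_ord_gistar",
    "fdr_adjust",
    "classify_clusters",
    "gi_star_clusters",
    "bivariate_classes",
]

HOT, COLD, NOT_SIGNIFICANT, ISOLATED = "hot", "cold", "not_significant", "isolated"


@dataclass
class SpatialWeights:
    """Binary queen-contiguity structure over an ordered set of regions.

    ``neighbors`` never contains a region itself; Gi* adds the self term
    internally (``includes_self`` records that convention).
    """

    ids: list
    neighbors: dict
    includes_self: bool = True

    @property
    def isolated(self) -> set:
        return {i for i in self.ids if not self.neighbors[i]}

    def edge_list(self):
        seen = set()
        for a in self.ids:
            for b in sorted(self.neighbors[a]):
                if (b, a) not in seen:
                    seen.add((a, b))
        return sorted(seen)


def _features_of(polygons) -> list:
    if isinstance(polygons, dict) and polygons.get("type") == "FeatureCollection":
        return polygons["features"]
    return list(polygons)


def queen_adjacency(polygons) -> SpatialWeights:
    """Queen-contiguity weights from a GeoJSON FeatureCollection.

    Each feature needs a unique ``region_id`` property. Contiguity is
    evaluated across the entire layer, so regions of different countries
    that touch are neighbors. Regions touching nothing are kept but
    flagged isolated downstream.
    """
    feats = _features_of(polygons)
    ids, geoms = [], []
    for k, f in enumerate(feats):
        props = f.get("properties") or {}
        rid = props.get("region_id")
        if rid is None:
            raise ValidationError(f"feature {k} lacks a region_id property")
        geom = shape(f["geometry"])
        if geom.is_empty or not geom.is_valid:
            raise ValidationError(f"invalid geometry for feature region_id={rid!r}")
        ids.append(rid)
        geoms.append(geom)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate region_id values: {dupes}")

    neighbors = {i: set() for i in ids}
    tree = STRtree(geoms)
    for a, ga in enumerate(geoms):
        for b in tree.query(ga, predicate="intersects"):
            b = int(b)
            if b != a:
                neighbors[ids[a]].add(ids[b])
    # 'intersects' is symmetric, so the sets are symmetric by construction
    return SpatialWeights(ids=list(ids), neighbors=neighbors, includes_self=True)


def getis_ord_gistar(values, weights: SpatialWeights) -> pd.DataFrame:
    """Standardized Gi* z-scores and two-sided normal p-values per region.

    ``values`` may be a mapping/Series keyed by region_id or an array in
    the order of ``weights.ids``. Isolated regions get NaN z/p and the
    ``isolated`` label; a constant field gets z=0, p=1 everywhere with a
    warning.
    """
    ids = weights.ids
    n = len(ids)
    if n < 2:
        raise ValidationError("Gi* needs at least 2 regions")
    if isinstance(values, (dict, pd.Series)):
        v = pd.Series(values)
        missing = [i for i in ids if i not in v.index]
        if missing:
            raise ValidationError(f"values missing for regions: {missing[:5]}")
        x = v.reindex(ids).to_numpy(float)
    else:
        x = np.asarray(values, dtype=float)
        if x.shape != (n,):
            raise ValidationError(f"values have shape {x.shape}, expected ({n},)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")

    idx = {i: k for k, i in enumerate(ids)}
    xbar = x.mean()
    s = x.std(ddof=0)
    z = np.full(n, np.nan)
    isolated = weights.isolated
    if s == 0.0:
        logger.warning("constant field: all Gi* z-scores set to 0")
        z[:] = 0.0
        p = np.ones(n)
    else:
        for k, i in enumerate(ids):
            if i in isolated:
                continue
            neigh = [idx[j] for j in weights.neighbors[i]]
            wi = len(neigh) + 1  # binary weights, self included
            if wi >= n:
                # neighborhood spans the whole layer: the local sum equals
                # the global sum, numerator and variance are identically
                # zero and no local deviation is measurable
                z[k] = 0.0
                continue
            local_sum = x[neigh].sum() + x[k]
            denom = s * np.sqrt((n * wi - wi**2) / (n - 1.0))
            z[k] = (local_sum - xbar * wi) / denom
        p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"region_id": ids, "value": x, "z": z, "p": p})
    out.loc[out["region_id"].isin(isolated), ["z", "p"]] = np.nan
    return out


def fdr_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, reject flags).

    NaN p-values (isolated regions) pass through as NaN / not rejected and
    do not count toward the number of tests.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if not ok.any():
        return q, reject
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    q[ok] = qv
    reject[ok] = rej
    return q, reject


def classify_clusters(gistar: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label regions hot (z>0), cold (z<0) where BH-adjusted q <= alpha."""
    out = gistar.copy()
    if "q" not in out.columns:
        q, _ = fdr_adjust(out["p"].to_numpy(), alpha)
        out["q"] = q
    z, q = out["z"].to_numpy(float), out["q"].to_numpy(float)
    label = np.where(
        ~np.isfinite(z),
        ISOLATED,
        np.where(
            (q <= alpha) & (z > 0), HOT, np.where((q <= alpha) & (z < 0), COLD, NOT_SIGNIFICANT)
        ),
    )
    out["cluster"] = label
    return out


def gi_star_clusters(
    values, weights: SpatialWeights, alpha: float = 0.05
) -> pd.DataFrame:
    """Gi* + FDR + labels in one call: region_id, value, z, p, q, cluster."""
    res = getis_ord_gistar(values, weights)
    res["q"], _ = fdr_adjust(res["p"].to_numpy(), alpha)
    return classify_clusters(res, alpha)


def _terciles(x: np.ndarray) -> np.ndarray:
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    return 1 + (x > q1).astype(int) + (x > q2).astype(int)


def bivariate_classes(fic, ineq) -> pd.DataFrame:
    """3x3 coverage-by-inequality classes cut at empirical terciles.

    Both inputs are Series/mappings keyed by region_id. Regions with a
    missing (degenerate) inequality value are excluded with a logged
    count. Ties fall to the lower tercile. The class of lowest-tercile
    coverage with highest-tercile inequality is the "double disadvantage"
    corner.
    """
    f = pd.Series(fic, dtype=float)
    w = pd.Series(ineq, dtype=float).reindex(f.index)
    keep = f.notna() & w.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("bivariate classes: excluding %d regions with missing values", dropped)
    f, w = f[keep], w[keep]
    if len(f) < 3:
        raise ValidationError("bivariate classification needs at least 3 regions")
    ft = _terciles(f.to_numpy())
    it = _terciles(w.to_numpy())
    return pd.DataFrame(
        {
            "region_id": f.index,
            "fic": f.to_numpy(),
            "ineq": w.to_numpy(),
            "fic_tercile": ft,
            "ineq_tercile": it,
            "class": [f"F{a}-I{b}" for a, b in zip(ft, it)],
            "double_disadvantage": (ft == 1) & (it == 3),
        }
    ).reset_index(drop=True)
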