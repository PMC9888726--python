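"""Synthetic DHS-like immunization survey generator with known ground truth.

Emulates the structure the analysis assumes: a two-stage cluster sample
(regions -> PSUs -> children) with relative sampling weights, a continuous
household wealth score whose ordering drives vaccine uptake, spatially
autocorrelated region effects on a rectangular lattice of unit-square
polygons, and sequential per-dose uptake so that later doses of a course
require earlier ones.

Model
-----
For each country, region effects ``e`` follow a simultaneous autoregressive
(SAR) field on the region lattice: ``e = (I - rho * A)^-1 eps`` with A the
row-standardized rook adjacency and ``eps ~ N(0, region_effect_sd^2)``.
Planted hot/cold blocks add a fixed logit shift on top.

Child wealth is a PSU-level normal mean plus child-level standard normal
noise; only its within-country weighted fractional rank u in (0, 1) enters
the outcome model. The conditional probability of receiving dose d (given
the previous dose of the same course, if any) is

    sigmoid( intercept_d + e_region + beta * (u - 1/2) )

so ``beta`` is the logit increase per unit of wealth rank and intercepts
describe the median-rank child. Ground-truth region coverage is the exact
expectation of the full-course indicator over u ~ U(0,1), computed by
Gauss-Legendre quadrature.

Weights are a stand-in for DHS design weights: a lognormal per-PSU
selection-probability multiplier, inverted and normalized to mean 1 within
each country (DHS weights are relative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .inequality import weighted_fractional_rank

__all__ = ["SynthConfig", "GroundTruth", "generate_survey", "planted_cluster_layout"]

DOSE_NAMES = ("bcg", "dtp1", "dtp2", "dtp3", "opv1", "opv2", "opv3", "mcv")
# index of the prerequisite dose within DOSE_NAMES (None = unconditional)
_PREREQ = (None, None, 1, 2, None, 4, 5, None)

#: Default per-dose logit intercepts for the median-wealth child, chosen so
#: that the single-dose BCG is rarely missed while the course-ending doses
#: (DTP3/OPV3) and MCV are missed most often, as observed in DHS data.
DEFAULT_DOSE_INTERCEPTS = (2.2, 2.2, 2.4, 2.2, 2.2, 2.4, 2.0, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    n_countries: int = 4
    regions_per_country: int = 25
    psus_per_region: int = 4
    children_per_psu: int = 12
    wealth_sd_between_psu: float = 0.5
    dose_intercepts: tuple = DEFAULT_DOSE_INTERCEPTS
    wealth_slope_beta: float = 1.5
    region_effect_sd: float = 0.5
    spatial_rho: float = 0.6
    age_range_months: tuple = (12, 41)
    card_probability: float = 0.67
    seed: int = 0
    # planted spatial clusters: square blocks of side hot_block / cold_block
    # at the top-left / bottom-right lattice corners, shifting every dose
    # intercept by the given logit amount. 0 disables.
    hot_block: int = 0
    cold_block: int = 0
    hot_effect: float = 2.0
    cold_effect: float = -2.0
    weight_sigma: float = 0.3

    def __post_init__(self):
        for name in ("n_countries", "regions_per_country", "psus_per_region", "children_per_psu"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1 (got {v!r})")
        if len(self.dose_intercepts) != 8:
            raise ConfigError("dose_intercepts must have exactly 8 entries")
        if not 0.0 <= self.card_probability <= 1.0:
            raise ConfigError(f"card_probability must be in [0, 1] (got {self.card_probability!r})")
        if not 0.0 <= self.spatial_rho < 1.0:
            raise ConfigError(f"spatial_rho must be in [0, 1) (got {self.spatial_rho!r})")
        lo, hi = self.age_range_months
        if not (0 <= lo < hi <= 59):
            raise ConfigError(f"age_range_months must satisfy 0 <= min < max <= 59 (got {self.age_range_months!r})")
        for name in ("wealth_sd_between_psu", "region_effect_sd", "weight_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("hot_block", "cold_block"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    region_true_coverage: Mapping[str, float] = field(default_factory=dict)
    true_wealth_slope: float = 0.0
    hot_regions: set = field(default_factory=set)
    cold_regions: set = field(default_factory=set)


def _lattice_shape(n_regions: int) -> tuple[int, int]:
    nrows = max(1, int(np.floor(np.sqrt(n_regions))))
    ncols = int(np.ceil(n_regions / nrows))
    return nrows, ncols


def _region_id(country: int, region: int) -> str:
    return f"C{country:02d}R{region:03d}"


def _country_id(country: int) -> str:
    return f"C{country:02d}"


def planted_cluster_layout(config: SynthConfig) -> GroundTruth:
    """Region sets for the planted hot/cold blocks, per country.

    Hot blocks sit at the top-left lattice corner, cold blocks at the
    bottom-right. Requires a full rectangular lattice of side >= 3 when any
    block is requested, and errors if the two blocks would overlap.
    """
    gt = GroundTruth(true_wealth_slope=config.wealth_slope_beta)
    hb, cb = config.hot_block, config.cold_block
    if hb == 0 and cb == 0:
        return gt
    nr, nc = _lattice_shape(config.regions_per_country)
    if min(nr, nc) < 3:
        raise ConfigError(
            f"planted clusters need a lattice of at least 3x3 per country "
            f"(regions_per_country={config.regions_per_country} gives {nr}x{nc})"
        )
    if nr * nc != config.regions_per_country:
        raise ConfigError(
            "planted clusters require regions_per_country to fill the lattice "
            f"exactly ({nr}x{nc} != {config.regions_per_country})"
        )
    if max(hb, cb) > min(nr, nc):
        raise ConfigError("planted block does not fit on the lattice")
    if hb and cb and (hb > nr - cb) and (hb > nc - cb):
        raise ConfigError("hot and cold blocks overlap on the lattice")
    for c in range(config.n_countries):
        for r in range(config.regions_per_country):
            row, col = divmod(r, nc)
            if hb and row < hb and col < hb:
                gt.hot_regions.add(_region_id(c, r))
            if cb and row >= nr - cb and col >= nc - cb:
                gt.cold_regions.add(_region_id(c, r))
    return gt


def _sar_region_effects(rng, nr, nc, n_regions, rho, sd):
    """Simultaneous-autoregressive Gaussian field on the region lattice."""
    eps = rng.normal(0.0, sd, size=n_regions)
    if rho == 0.0 or sd == 0.0 or n_regions == 1:
        return eps
    A = np.zeros((n_regions, n_regions))
    for r in range(n_regions):
        row, col = divmod(r, nc)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = row + dr, col + dc
            j = rr * nc + cc
            if 0 <= rr < nr and 0 <= cc < nc and j < n_regions:
                A[r, j] = 1.0
    deg = A.sum(axis=1, keepdims=True)
    np.divide(A, deg, out=A, where=deg > 0)
    return np.linalg.solve(np.eye(n_regions) - rho * A, eps)


def _true_region_coverage(intercepts, effect, beta, n_quad=32):
    """E_u[ prod_d sigmoid(intercept_d + effect + beta(u-1/2)) ], u~U(0,1)."""
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    u = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]; weights sum to 2
    lp = np.add.outer(intercepts + effect, beta * (u - 0.5))
    fic = np.prod(1.0 / (1.0 + np.exp(-lp)), axis=0)
    return float(0.5 * wts @ fic)


def _region_polygon(country, region, nc):
    row, col = divmod(region, nc)
    x0 = country * (nc + 1) + col  # one-unit gap between countries
    y0 = row
    return [[[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1], [x0, y0]]]


def generate_survey(config: SynthConfig):
    """Generate (child table, region GeoJSON, GroundTruth).

    The child table has one row per sampled child with the ChildRecord
    schema; identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    layout = planted_cluster_layout(config)
    nr, nc = _lattice_shape(config.regions_per_country)
    intercepts = np.asarray(config.dose_intercepts, dtype=float)
    beta = config.wealth_slope_beta

    frames = []
    features = []
    truth = GroundTruth(
        true_wealth_slope=beta,
        hot_regions=layout.hot_regions,
        cold_regions=layout.cold_regions,
    )
    n_psu_c = config.regions_per_country * config.psus_per_region
    n_child_c = n_psu_c * config.children_per_psu

    for c in range(config.n_countries):
        effects = _sar_region_effects(
            rng, nr, nc, config.regions_per_country,
            config.spatial_rho, config.region_effect_sd,
        )
        region_ids = [_region_id(c, r) for r in range(config.regions_per_country)]
        for r, rid in enumerate(region_ids):
            if rid in truth.hot_regions:
                effects[r] += config.hot_effect
            elif rid in truth.cold_regions:
                effects[r] += config.cold_effect
            features.append(
                {
                    "type": "Feature",
                    "properties": {"region_id": rid, "country": _country_id(c)},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": _region_polygon(c, r, nc),
                    },
                }
            )
            truth.region_true_coverage[rid] = _true_region_coverage(
                intercepts, effects[r], beta
            )

        region_of_child = np.repeat(
            np.arange(config.regions_per_country),
            config.psus_per_region * config.children_per_psu,
        )
        psu_of_child = np.repeat(np.arange(n_psu_c), config.children_per_psu)

        psu_means = rng.normal(0.0, config.wealth_sd_between_psu, size=n_psu_c)
        wealth = psu_means[psu_of_child] + rng.normal(0.0, 1.0, size=n_child_c)

        psu_mult = rng.lognormal(0.0, config.weight_sigma, size=n_psu_c)
        weight = 1.0 / psu_mult[psu_of_child]
        weight *= n_child_c / weight.sum()  # mean 1 within country

        rank = weighted_fractional_rank(wealth, weight)
        lp_base = effects[region_of_child] + beta * (rank - 0.5)
        doses = np.zeros((n_child_c, 8), dtype=np.int8)
        u = rng.random(size=(n_child_c, 8))
        for d in range(8):
            p = 1.0 / (1.0 + np.exp(-(intercepts[d] + lp_base)))
            taken = u[:, d] < p
            if _PREREQ[d] is not None:
                taken &= doses[:, _PREREQ[d]] == 1
            doses[:, d] = taken

        age = rng.integers(
            config.age_range_months[0], config.age_range_months[1] + 1, size=n_child_c
        )
        source = np.where(rng.random(n_child_c) < config.card_probability, "card", "recall")

        df = pd.DataFrame(
            {
                "child_id": [f"C{c:02d}K{k:06d}" for k in range(n_child_c)],
                "country": _country_id(c),
                "region_id": [region_ids[r] for r in region_of_child],
                "psu_id": [f"C{c:02d}P{p:04d}" for p in psu_of_child],
                "weight": weight,
                "age_months": age,
                "wealth_score": wealth,
                **{name: doses[:, d] for d, name in enumerate(DOSE_NAMES)},
                "source": source,
            }
        )
        frames.append(df)

    children = pd.concat(frames, ignore_index=True)
    geojson = {"type": "FeatureCollection", "features": features}
    return children, geojson, truth


def write_children_csv(children: pd.DataFrame, path) -> None:
    children.to_csv(path, index=False)


def write_geojson(geojson: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(geojson, fh)


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    rows = [
        {
            "region_id": rid,
            "true_coverage": cov,
            "cluster": (
                "hot" if rid in truth.hot_regions
                else "cold" if rid in truth.cold_regions
                else "none"
            ),
        }
        for rid, cov in truth.region_true_coverage.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["dose_intercepts"] = list(d["dose_intercepts"])
    d["age_range_months"] = list(d["age_range_months"])
    return d
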