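"""End-to-end orchestration: data -> coverage -> inequality -> spatial -> missed sets.

``run_pipeline`` either simulates a survey (when the run config carries a
:class:`~vaxineq.synth.SynthConfig`) or ingests a child-level CSV plus a
region GeoJSON, then writes the full bundle of result tables and a run
manifest. Identical config + seed give identical outputs; on failure all
partially written outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import inequality as ineq
from . import missed_sets as ms
from . import spatial as sp
from . import synth
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one analysis run needs. Exactly one of
    (``children_csv`` + ``geojson``) or ``synth_config`` must be given."""

    out_dir: str = "results"
    children_csv: str | None = None
    geojson: str | None = None
    population_csv: str | None = None
    synth_config: synth.SynthConfig | None = None
    age_window: tuple = cov.DEFAULT_AGE_WINDOW
    alpha: float = 0.05
    theil_weighted: bool = False
    spatial_mode: str = "pooled"  # or "per_country"
    cluster_se: bool = True
    seed: int = 0

    def validate(self):
        has_files = self.children_csv is not None
        has_synth = self.synth_config is not None
        if has_files == has_synth:
            raise ValidationError(
                "exactly one of (children_csv, synth_config) must be provided"
            )
        if has_files and self.geojson is None:
            raise ValidationError("geojson path required with children_csv")
        if self.spatial_mode not in ("pooled", "per_country"):
            raise ValidationError(f"spatial_mode must be pooled|per_country, got {self.spatial_mode!r}")
        lo, hi = self.age_window
        if lo >= hi:
            raise ValidationError(f"invalid age window {self.age_window!r}")

    def to_dict(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "children_csv": self.children_csv,
            "geojson": self.geojson,
            "population_csv": self.population_csv,
            "synth_config": (
                synth.config_to_dict(self.synth_config) if self.synth_config else None
            ),
            "age_window": list(self.age_window),
            "alpha": self.alpha,
            "theil_weighted": self.theil_weighted,
            "spatial_mode": self.spatial_mode,
            "cluster_se": self.cluster_se,
            "seed": self.seed,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _region_indices(children: pd.DataFrame, keys, cluster: bool) -> pd.DataFrame:
    """Concentration-index inference per group; degenerate groups flagged.

    Wealth ranks are computed within each group, since each group is its
    own reference population for the concentration curve.
    """
    rows = []
    for key, grp in children.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        rec["n_children"] = len(grp)
        h = grp["fully_immunized"].to_numpy(float)
        w = grp["weight"].to_numpy(float)
        mu = float(w @ h / w.sum())
        if mu <= 0.0 or mu >= 1.0 or len(grp) < 2:
            rec.update(
                degenerate=True, mu=mu,
                w=np.nan, w_lo=np.nan, w_hi=np.nan,
                e=np.nan, e_lo=np.nan, e_hi=np.nan,
            )
        else:
            r = ineq.weighted_fractional_rank(grp["wealth_score"].to_numpy(float), w)
            res = ineq.index_inference(h, r, w, grp["psu_id"].to_numpy(), cluster=cluster)
            rec.update(
                degenerate=False, mu=res.mu,
                w=res.wagstaff, w_lo=res.lower_w, w_hi=res.upper_w,
                e=res.erreygers, e_lo=res.lower_e, e_hi=res.upper_e,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def _theil_table(sub: pd.DataFrame, sub_ineq: pd.DataFrame, weighted: bool) -> pd.DataFrame:
    """Theil decomposition across subnational units, grouped by country.

    Rows: per-vaccine coverage, FIC, and the W and E inequality indices.
    GE(1) is defined for nonnegative values only, so for W and E the
    non-positive units are excluded (count reported in ``n_used``).
    """
    rows = []
    measures = [("bcg", sub), ("dtp", sub), ("opv", sub), ("mcv", sub), ("fic", sub),
                ("w", sub_ineq), ("e", sub_ineq)]
    for name, frame in measures:
        vals = frame[name].to_numpy(float)
        groups = frame["country"].to_numpy()
        wts = frame["n_children"].to_numpy(float) if weighted else None
        keep = np.isfinite(vals)
        if name in ("w", "e"):
            keep &= vals > 0
        if keep.sum() < 1 or not np.any(vals[keep] > 0):
            rows.append({"measure": name.upper(), "theil": np.nan, "within": np.nan,
                         "between": np.nan, "n_used": int(keep.sum())})
            continue
        td = ineq.theil_decompose(
            vals[keep], groups[keep], None if wts is None else wts[keep]
        )
        rows.append({"measure": name.upper(), "theil": td.total, "within": td.within,
                     "between": td.between, "n_used": int(keep.sum())})
    return pd.DataFrame(rows)


def _load_geojson(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"GeoJSON file not found: {p}")
    with open(p) as fh:
        return json.load(fh)


def _spatial_tables(sub_stats: pd.DataFrame, geojson: dict, mode: str, alpha: float):
    """Gi* cluster tables for FIC, W and E (NaN-valued regions excluded)."""
    feats = geojson["features"]
    out = {}
    for col in ("fic", "w", "e"):
        series = sub_stats.set_index("region_id")[col].dropna()
        keep = [f for f in feats if f["properties"]["region_id"] in series.index]
        if len(keep) < 2:
            raise ValidationError(f"too few regions with finite {col!r} for Gi*")
        if mode == "pooled":
            weights = sp.queen_adjacency(keep)
            res = sp.gi_star_clusters(series, weights, alpha=alpha)
        else:
            pieces = []
            country_of = sub_stats.set_index("region_id")["country"]
            for ctry in sorted(country_of.unique()):
                sel = [f for f in keep if country_of[f["properties"]["region_id"]] == ctry]
                if len(sel) < 2:
                    continue
                weights = sp.queen_adjacency(sel)
                ids = [f["properties"]["region_id"] for f in sel]
                pieces.append(sp.gi_star_clusters(series[ids], weights, alpha=alpha))
            res = pd.concat(pieces, ignore_index=True)
        out[col] = res
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns {name: path} of everything written."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path

    try:
        if config.synth_config is not None:
            children, geojson, truth = synth.generate_survey(config.synth_config)
            synth.write_children_csv(children, out_dir / "children.csv")
            synth.write_geojson(geojson, out_dir / "regions.geojson")
            synth.write_ground_truth_csv(truth, out_dir / "ground_truth.csv")
            written["children"] = out_dir / "children.csv"
            written["regions"] = out_dir / "regions.geojson"
            written["ground_truth"] = out_dir / "ground_truth.csv"
        else:
            p = Path(config.children_csv)
            if not p.exists():
                raise ValidationError(f"children CSV not found: {p}")
            children = pd.read_csv(p)
            geojson = _load_geojson(config.geojson)

        children = cov.filter_age(children, *config.age_window)
        children = cov.complete_course(children)
        if children.empty:
            raise ValidationError("no children remain after age filtering")

        national = cov.weighted_coverage(children, level="national")
        subnational = cov.weighted_coverage(children, level="subnational")

        nat_ineq = _region_indices(children, ["country"], config.cluster_se)
        sub_ineq = _region_indices(children, ["country", "region_id"], config.cluster_se)

        nat = national.merge(nat_ineq.drop(columns=["n_children"]), on="country")
        nat["rank_fic"] = nat["fic"].rank(method="min").astype(int)
        sub = subnational.merge(
            sub_ineq.drop(columns=["n_children"]), on=["country", "region_id"]
        )
        sub["rank_fic"] = sub["fic"].rank(method="min").astype(int)
        write_csv("national", nat)
        write_csv("subnational", sub)

        write_csv("theil", _theil_table(subnational, sub, config.theil_weighted))

        gi_tables = _spatial_tables(sub, geojson, config.spatial_mode, config.alpha)
        for col, tbl in gi_tables.items():
            write_csv(f"gistar_{col}", tbl)

        fic_s = sub.set_index("region_id")["fic"]
        for col in ("w", "e"):
            biv = sp.bivariate_classes(fic_s, sub.set_index("region_id")[col])
            write_csv(f"bivariate_fic_{col}", biv)

        missed = ms.tabulate_missed_sets(children, group_by="country")
        write_csv("missed_sets", missed)
        write_csv("missed_marginal", ms.marginal_missed(missed))
        write_csv("missed_modal", ms.modal_missed_combination(missed))
        if config.population_csv is not None:
            pop = pd.read_csv(config.population_csv)
            write_csv("missed_scaled", ms.scale_to_population(missed, pop))

        manifest = {
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": config.to_dict(),
            "n_children": int(len(children)),
            "n_regions": int(sub.shape[0]),
            "n_countries": int(nat.shape[0]),
            "row_counts": {k: _row_count(p) for k, p in written.items()},
        }
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written["manifest"] = mpath
    except Exception:
        for path in written.values():
            Path(path).unlink(missing_ok=True)
        raise
    return {k: str(v) for k, v in written.items()}


def _row_count(path: Path) -> int:
    if path.suffix == ".csv":
        with open(path) as fh:
            return sum(1 for _ in fh) - 1
    return 1
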