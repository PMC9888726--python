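"""Set-intersection accounting of missed vaccines.

Among children who are not fully immunized, which *combinations* of the
four EPI vaccines (BCG, DTP, OPV, MCV) are missing? A vaccine counts as
missed when its course is incomplete — a child missing two DTP doses is
counted once for DTP, not twice. The 16 possible combinations (including
the empty one, which is exactly the fully immunized children) partition the
sample, so their weighted shares sum to 1.

Shares can be scaled to absolute child counts with a user-supplied
population table (children of the studied age band per country). Scaled
counts assume coverage is unchanged since the survey year.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

VACCINES = ("BCG", "DTP", "OPV", "MCV")
_STATUS_OF = {
    "BCG": "bcg_complete",
    "DTP": "dtp_complete",
    "OPV": "opv_complete",
    "MCV": "mcv_complete",
}
#: All 16 combinations in canonical order (empty first, then by size).
ALL_COMBINATIONS = tuple(
    "+".join(combo) if combo else "none"
    for size in range(5)
    for combo in itertools.combinations(VACCINES, size)
)


def combination_label(missed) -> str:
    """Canonical label for a set of missed vaccines ('none' if empty)."""
    ordered = [v for v in VACCINES if v in set(missed)]
    unknown = set(missed) - set(VACCINES)
    if unknown:
        raise ValidationError(f"unknown vaccines: {sorted(unknown)}")
    return "+".join(ordered) if ordered else "none"


def missed_combination(status_row) -> frozenset:
    """Set of vaccines with an incomplete course for one child."""
    return frozenset(v for v, col in _STATUS_OF.items() if not status_row[col])


def tabulate_missed_sets(children: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Weighted count and share of each missed-vaccine combination.

    Parameters
    ----------
    children : table with the ``*_complete`` status columns and ``weight``
        (run :func:`vaxineq.coverage.complete_course` first).
    group_by : optional column (e.g., ``'country'``); default is a single
        pooled group labeled ``'all'``.

    Returns a long frame ``group, combination, weighted_count, share``
    covering all 16 combinations per group (zeros included); shares within
    a group sum to 1.
    """
    for col in _STATUS_OF.values():
        if col not in children.columns:
            raise ValidationError(f"missing status column {col!r}; run complete_course first")
    if children.empty:
        raise ValidationError("cannot tabulate an empty table")
    df = children.copy()
    w = pd.to_numeric(df["weight"], errors="coerce")
    if w.isna().any() or (w <= 0).any():
        raise ValidationError("weights must be positive")
    labels = []
    status = df[list(_STATUS_OF.values())].to_numpy()
    for row in status:
        labels.append(
            combination_label([v for v, ok in zip(VACCINES, row) if not ok])
        )
    df["combination"] = labels
    df["_group"] = df[group_by] if group_by else "all"

    rows = []
    for grp, sub in df.groupby("_group", sort=True):
        tot = float(sub["weight"].sum())
        if tot <= 0:
            raise ValidationError(f"group {grp!r} has zero total weight")
        counts = sub.groupby("combination")["weight"].sum()
        for combo in ALL_COMBINATIONS:
            wc = float(counts.get(combo, 0.0))
            rows.append(
                {
                    "group": grp,
                    "combination": combo,
                    "weighted_count": wc,
                    "share": wc / tot,
                }
            )
    return pd.DataFrame(rows)


def marginal_missed(table: pd.DataFrame) -> pd.DataFrame:
    """Per-vaccine marginal missed share: sum over combinations containing it."""
    rows = []
    for grp, sub in table.groupby("group", sort=True):
        for v in VACCINES:
            mask = sub["combination"].str.split("+").apply(lambda parts: v in parts)
            rows.append(
                {
                    "group": grp,
                    "vaccine": v,
                    "weighted_count": float(sub.loc[mask, "weighted_count"].sum()),
                    "share": float(sub.loc[mask, "share"].sum()),
                }
            )
    return pd.DataFrame(rows)


def modal_missed_combination(table: pd.DataFrame) -> pd.DataFrame:
    """Most frequent nonempty missed combination per group."""
    rows = []
    for grp, sub in table.groupby("group", sort=True):
        nonempty = sub[sub["combination"] != "none"]
        best = nonempty.sort_values(
            ["share", "combination"], ascending=[False, True]
        ).iloc[0]
        rows.append(
            {"group": grp, "combination": best["combination"], "share": best["share"]}
        )
    return pd.DataFrame(rows)


def scale_to_population(table: pd.DataFrame, population) -> pd.DataFrame:
    """Scale per-country combination shares to absolute child counts.

    ``population`` maps country -> number of children in the studied age
    band (mapping, Series, or a frame with ``country``/``population``
    columns). Every country present in ``table`` must be covered.
    """
    if isinstance(population, pd.DataFrame):
        population = population.set_index("country")["population"]
    pop = pd.Series(population, dtype=float)
    if (pop < 0).any():
        raise ValidationError("populations must be nonnegative")
    countries = sorted(table["group"].unique())
    missing = [c for c in countries if c not in pop.index]
    if missing:
        raise ValidationError(f"population table missing countries: {missing}")
    out = table.copy()
    out["population"] = out["group"].map(pop)
    out["estimated_children"] = out["share"] * out["population"]
    return out


def upset_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Wide membership matrix (one row per combination) for UpSet-style plots."""
    agg = table.groupby("combination", sort=False)["weighted_count"].sum()
    agg = agg.reindex(ALL_COMBINATIONS).fillna(0.0)
    rows = []
    for combo, wc in agg.items():
        members = set() if combo == "none" else set(combo.split("+"))
        rows.append(
            {"combination": combo, **{v: v in members for v in VACCINES}, "weighted_count": wc}
        )
    return pd.DataFrame(rows)


def plot_missed_sets(table: pd.DataFrame, path=None):
    """Minimal bar chart of nonempty combination counts (debug aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = upset_matrix(table)
    mat = mat[mat["combination"] != "none"]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(mat["combination"], mat["weighted_count"])
    ax.set_ylabel("weighted children")
    ax.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
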