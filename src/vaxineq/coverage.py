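"""Per-vaccine completion status and survey-weighted coverage estimates.

The basic childhood schedule (WHO Expanded Program on Immunization) counted
here is one BCG dose, three DTP doses, three OPV doses, and one
measles-containing vaccine. A child is fully immunized iff all four vaccine
courses are complete; any other combination (including zero doses) counts
as not fully immunized.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DOSE_COLUMNS = ["bcg", "dtp1", "dtp2", "dtp3", "opv1", "opv2", "opv3", "mcv"]
STATUS_COLUMNS = [
    "bcg_complete",
    "dtp_complete",
    "opv_complete",
    "mcv_complete",
    "fully_immunized",
]
VACCINE_COVERAGE_COLUMNS = ["bcg", "dtp", "opv", "mcv"]

DEFAULT_AGE_WINDOW = (15, 35)
SENSITIVITY_AGE_WINDOW = (24, 35)


def complete_course(children: pd.DataFrame, drop_missing: bool = True) -> pd.DataFrame:
    """Append vaccine-course completion indicators to a child table.

    A multi-dose course is complete iff every dose indicator is 1.
    Rows with any missing dose indicator are dropped with a logged count
    (``drop_missing=True``, the default) — coverage is estimated on the
    complete-information subset. Non-binary values raise, identifying the
    offending child.
    """
    missing_cols = [c for c in DOSE_COLUMNS if c not in children.columns]
    if missing_cols:
        raise ValidationError(f"missing dose columns: {missing_cols}")
    out = children.copy()
    doses = out[DOSE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    incomplete = doses.isna().any(axis=1)
    if incomplete.any():
        if not drop_missing:
            raise ValidationError(
                f"{int(incomplete.sum())} children have missing dose indicators"
            )
        logger.info(
            "dropping %d of %d children with missing dose information",
            int(incomplete.sum()),
            len(out),
        )
        out = out.loc[~incomplete].copy()
        doses = doses.loc[~incomplete]
    bad = ~doses.isin([0, 1]).all(axis=1)
    if bad.any():
        ident = (
            out.loc[bad, "child_id"].iloc[0]
            if "child_id" in out.columns
            else out.index[bad][0]
        )
        raise ValidationError(
            f"non-binary dose indicator for child_id={ident!r} "
            f"({int(bad.sum())} children affected)"
        )
    d = doses.astype(np.int8)
    out["bcg_complete"] = d["bcg"]
    out["dtp_complete"] = d["dtp1"] & d["dtp2"] & d["dtp3"]
    out["opv_complete"] = d["opv1"] & d["opv2"] & d["opv3"]
    out["mcv_complete"] = d["mcv"]
    out["fully_immunized"] = (
        out["bcg_complete"]
        & out["dtp_complete"]
        & out["opv_complete"]
        & out["mcv_complete"]
    )
    return out


def filter_age(
    children: pd.DataFrame, min_months: int = 15, max_months: int = 35
) -> pd.DataFrame:
    """Restrict to children aged within [min_months, max_months], inclusive.

    The default window (15, 35) allows catch-up vaccination after the
    scheduled MCV dose at 9-13 months; (24, 35) is the sensitivity window.
    """
    if min_months >= max_months:
        raise ValidationError(
            f"invalid age window: min_months={min_months} >= max_months={max_months}"
        )
    age = pd.to_numeric(children["age_months"], errors="coerce")
    return children.loc[(age >= min_months) & (age <= max_months)].copy()


def weighted_coverage(children: pd.DataFrame, level: str = "subnational") -> pd.DataFrame:
    """Survey-weighted coverage estimates per group.

    ``level='subnational'`` groups by (country, region_id); ``'national'``
    groups by country. Every estimate is the ratio of weighted sums
    sum(w*y)/sum(w), so scaling all weights leaves it unchanged.

    Returns a frame with one row per group: group identifiers,
    ``n_children``, per-vaccine coverage (``bcg``/``dtp``/``opv``/``mcv``,
    full course for the multi-dose vaccines) and ``fic``.
    """
    if level not in ("national", "subnational"):
        raise ValidationError(f"level must be 'national' or 'subnational', got {level!r}")
    for col in STATUS_COLUMNS:
        if col not in children.columns:
            raise ValidationError(
                f"missing status column {col!r}; run complete_course first"
            )
    if children.empty:
        raise ValidationError("cannot estimate coverage from an empty table")
    w = pd.to_numeric(children["weight"], errors="coerce")
    if w.isna().any() or (w <= 0).any():
        raise ValidationError("weights must be positive")

    keys = ["country"] if level == "national" else ["country", "region_id"]
    df = children.copy()
    df["weight"] = w
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        wg = grp["weight"].to_numpy(float)
        tot = wg.sum()
        if tot <= 0:
            raise ValidationError(f"group {key!r} has zero total weight")
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["n_children"] = len(grp)
        for out_name, col in zip(
            VACCINE_COVERAGE_COLUMNS + ["fic"],
            ["bcg_complete", "dtp_complete", "opv_complete", "mcv_complete", "fully_immunized"],
        ):
            rec[out_name] = float(wg @ grp[col].to_numpy(float) / tot)
        rows.append(rec)
    return pd.DataFrame(rows)
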