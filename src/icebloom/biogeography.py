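"""Latitudinal biogeography classification of cASVs.

Reference occurrences are deduplicated by geographic point (dataset id
plus coordinates rounded to a configurable precision, so station
re-occupations and time series count once), binned into latitudinal
zones — polar (|lat| >= 66), temperate (23 <= |lat| < 66), tropical
(|lat| < 23) — and each cASV is assigned a category from its zone
fractions:

==================  ==========================================
category            rule (evaluated in this order, first wins)
==================  ==========================================
unallocated         fewer than ``min_samples`` occurrences
polar               polar >= 90%
temperate           temperate >= 90%
tropical            tropical >= 90%
polar-temperate     polar + temperate >= 90%
temperate-tropical  temperate + tropical >= 90%
cosmopolitan        all three zones > 0
unallocated         anything else (e.g. polar+tropical mixes)
==================  ==========================================

Single-zone rules come before two-zone rules: a two-zone share always
dominates its single-zone shares, so the reverse order could never
assign a pure temperate (or tropical) distribution its own category.

Boundary conventions: 66 is polar, 23 is temperate (half-open bands);
the 90% comparisons are non-strict.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sequence_clustering import CasvAssignment

__all__ = ["CATEGORIES", "assign_zone", "dedup_occurrences", "classify",
           "classify_all"]

logger = logging.getLogger(__name__)

CATEGORIES = ("polar", "polar-temperate", "temperate", "temperate-tropical",
              "tropical", "cosmopolitan", "unallocated")


def assign_zone(latitude: float) -> str:
    """Latitudinal zone of a single latitude (decimal degrees)."""
    if not -90 <= latitude <= 90:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    a = abs(latitude)
    if a >= 66:
        return "polar"
    if a >= 23:
        return "temperate"
    return "tropical"


def _validated(occ: pd.DataFrame) -> pd.DataFrame:
    lat = occ["latitude"].to_numpy(dtype=float)
    lon = occ["longitude"].to_numpy(dtype=float)
    if len(occ) and (np.abs(lat).max() > 90 or np.abs(lon).max() > 180):
        bad = occ[(np.abs(lat) > 90) | (np.abs(lon) > 180)]
        raise ValueError(f"out-of-range coordinates for rows {bad.index.tolist()[:5]}")
    return occ


def dedup_occurrences(occ: pd.DataFrame, precision: float = 0.1) -> pd.DataFrame:
    """Collapse repeated samplings of one geographic point to one occurrence.

    Within each (cASV, dataset) pair, occurrences whose coordinates round
    to the same multiple of ``precision`` degrees are kept once.  Expects
    columns casv_id, dataset_id, latitude, longitude.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    occ = _validated(occ)
    if occ.empty:
        return occ.copy()
    key = occ.assign(
        _rlat=(occ["latitude"] / precision).round() * precision,
        _rlon=(occ["longitude"] / precision).round() * precision,
    )
    out = key.drop_duplicates(["casv_id", "dataset_id", "_rlat", "_rlon"])
    return out.drop(columns=["_rlat", "_rlon"]).reset_index(drop=True)


def classify(n_polar: int, n_temperate: int, n_tropical: int,
             min_samples: int = 5) -> str:
    """Biogeographical category from deduplicated zone occurrence counts."""
    if min(n_polar, n_temperate, n_tropical) < 0:
        raise ValueError("zone counts must be nonnegative")
    total = n_polar + n_temperate + n_tropical
    if total < min_samples:
        return "unallocated"
    # integer arithmetic: x/total >= 0.9  <=>  10*x >= 9*total, exact at the
    # 90% boundary.  Single-zone rules are evaluated before two-zone rules:
    # a two-zone share always dominates its single-zone shares, so the
    # reverse order would make "temperate" unreachable.
    p, t, r = n_polar, n_temperate, n_tropical
    if 10 * p >= 9 * total:
        return "polar"
    if 10 * t >= 9 * total:
        return "temperate"
    if 10 * r >= 9 * total:
        return "tropical"
    if 10 * (p + t) >= 9 * total:
        return "polar-temperate"
    if 10 * (t + r) >= 9 * total:
        return "temperate-tropical"
    if n_polar > 0 and n_temperate > 0 and n_tropical > 0:
        return "cosmopolitan"
    logger.warning(
        "zone counts (%d, %d, %d) fit no category; marked unallocated",
        n_polar, n_temperate, n_tropical)
    return "unallocated"


def classify_all(assign: CasvAssignment, occ: pd.DataFrame,
                 precision: float = 0.1, min_samples: int = 5) -> pd.DataFrame:
    """Classify every study cASV from a reference occurrence table.

    ``occ`` carries one row per (reference ASV, reference sample) with
    columns ref_asv_id (or casv_id), sample_id, dataset_id, latitude,
    longitude.  Reference ASV ids are translated to cASV ids through the
    cluster membership; cASVs with no reference occurrences (unique to
    the study) are unallocated.

    Returns one row per study cASV: zone counts, total, zone fractions
    and category.
    """
    casv_of_member = {m: c for c, mem in assign.members.items() for m in mem}
    study_casvs = sorted(set(assign.study_to_casv.values()))

    if not occ.empty:
        col = "ref_asv_id" if "ref_asv_id" in occ.columns else "casv_id"
        occ = occ.assign(casv_id=occ[col].map(casv_of_member))
        occ = occ.dropna(subset=["casv_id"])
        occ = dedup_occurrences(occ, precision=precision)
        zones = occ["latitude"].map(assign_zone)
        zc = (pd.crosstab(occ["casv_id"], zones)
              .reindex(columns=["polar", "temperate", "tropical"], fill_value=0))
    else:
        zc = pd.DataFrame(columns=["polar", "temperate", "tropical"])

    rows = []
    for casv in study_casvs:
        if casv in zc.index:
            p, t, r = (int(zc.at[casv, "polar"]), int(zc.at[casv, "temperate"]),
                       int(zc.at[casv, "tropical"]))
        else:
            p = t = r = 0
        total = p + t + r
        cat = classify(p, t, r, min_samples=min_samples)
        frac = (np.array([p, t, r]) / total) if total else np.zeros(3)
        rows.append({"casv_id": casv, "n_polar": p, "n_temperate": t,
                     "n_tropical": r, "n_total": total,
                     "frac_polar": frac[0], "frac_temperate": frac[1],
                     "frac_tropical": frac[2], "category": cat})
    return pd.DataFrame(rows).set_index("casv_id")
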