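"""Indicator-value (IndVal) association of ASVs with sample groups.

The group-size-corrected IndVal of an ASV for a target group combines
specificity A — the target group's mean abundance over the sum of all
group mean abundances — and fidelity B — the fraction of target-group
samples in which the ASV is present.  The reported statistic is
sqrt(A · B).  Significance comes from a permutation test: group labels
are shuffled, the best-group statistic is recomputed for each shuffle,
and p = (#{permuted >= observed} + 1) / (n_permutations + 1).

Abundances handed to the screen are per-sample relative counts so that
unequal library sizes do not masquerade as specificity; A itself is
scale-free and B presence-based, so the statistic is invariant to
multiplying all counts by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community_structure import filter_photosynthetic

__all__ = ["IndicatorResult", "indval", "best_group", "permutation_test",
           "run_indicator_screen", "significance_stars"]


@dataclass(frozen=True)
class IndicatorResult:
    asv_id: str
    group: str
    A: float
    B: float
    stat: float
    p: float | None = None
    n_permutations: int = 0
    absent: bool = False  # ASV had zero counts everywhere; stat forced to 0


def _group_indices(groups: pd.Series | dict | np.ndarray,
                   index=None) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(groups)
    if index is not None:
        labels = labels.reindex(index)
        if labels.isna().any():
            raise ValueError("group labels missing for some samples")
    names = sorted(labels.unique())
    codes = labels.map({g: i for i, g in enumerate(names)}).to_numpy()
    return codes, names


def indval(x: np.ndarray | pd.Series, groups, target: str) -> IndicatorResult:
    """Specificity A, fidelity B and IndVal statistic for one ASV.

    ``x`` holds the ASV's abundance in every sample, ``groups`` the sample
    labels, ``target`` the group the association is scored against.
    """
    xs = pd.Series(x)
    codes, names = _group_indices(groups, index=xs.index if hasattr(x, "index") else None)
    if target not in names:
        raise ValueError(f"unknown target group {target!r}")
    v = xs.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    ti = names.index(target)
    group_means = np.array([v[codes == i].mean() for i in range(len(names))])
    tmask = codes == ti
    b = float((v[tmask] > 0).mean())
    asv = xs.name if xs.name is not None else ""
    if group_means.sum() == 0:
        return IndicatorResult(str(asv), target, 0.0, b, 0.0, absent=True)
    a = float(group_means[ti] / group_means.sum())
    return IndicatorResult(str(asv), target, a, b, float(np.sqrt(a * b)))


def best_group(x, groups) -> IndicatorResult:
    """IndVal result for the group maximizing the statistic (ties break by
    group-name order)."""
    _, names = _group_indices(groups, index=x.index if hasattr(x, "index") else None)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    best = None
    for g in names:  # names sorted: ties keep the first group by name
        r = indval(x, groups, g)
        if best is None or r.stat > best.stat:
            best = r
    return best


def _best_stats_permuted(v: np.ndarray, codes: np.ndarray, n_groups: int,
                         n_permutations: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Vectorized best-group IndVal statistic under label permutation."""
    n = v.size
    present = (v > 0).astype(float)
    perm_codes = np.empty((n_permutations, n), dtype=codes.dtype)
    for r in range(n_permutations):
        perm_codes[r] = codes[rng.permutation(n)]
    means = np.empty((n_permutations, n_groups))
    bs = np.empty((n_permutations, n_groups))
    for g in range(n_groups):
        mask = perm_codes == g
        size = (codes == g).sum()  # group sizes are permutation-invariant
        means[:, g] = (mask * v).sum(axis=1) / size
        bs[:, g] = (mask * present).sum(axis=1) / size
    tot = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot > 0, tot, 1), 0.0)
    return np.sqrt(a * bs).max(axis=1)


def permutation_test(x, groups, target: str | None = None,
                     n_permutations: int = 9999,
                     seed: int | None = None) -> IndicatorResult:
    """Permutation significance of an ASV's association with ``target``.

    If ``target`` is None the best group is tested.  For every
    permutation of the sample labels the best-group statistic is
    recomputed; p = (#{permuted >= observed} + 1) / (n_permutations + 1).
    Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    xs = pd.Series(x)
    codes, names = _group_indices(groups, index=xs.index if hasattr(x, "index") else None)
    if len(names) < 2:
        raise ValueError("need >= 2 groups to permute")
    obs = indval(x, groups, target) if target else best_group(x, groups)
    rng = np.random.default_rng(seed)
    perm = _best_stats_permuted(xs.to_numpy(dtype=float), codes, len(names),
                                n_permutations, rng)
    p = float((np.count_nonzero(perm >= obs.stat - 1e-12) + 1)
              / (n_permutations + 1))
    return IndicatorResult(obs.asv_id, obs.group, obs.A, obs.B, obs.stat,
                           p=p, n_permutations=n_permutations,
                           absent=obs.absent)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_indicator_screen(asv_table: pd.DataFrame, meta: pd.DataFrame,
                         trophic: dict[str, str],
                         comparisons: dict[str, str] | None = None,
                         top_n: int = 20, n_permutations: int = 9999,
                         seed: int | None = None) -> pd.DataFrame:
    """Screen the most abundant photosynthetic ASVs for group associations.

    ``comparisons`` maps a comparison name to a metadata column, by
    default substrate (ice vs water) and bloom phase (dark = stage I vs
    light = stages II + III).  The ``top_n`` photosynthetic ASVs by total
    reads are tested per comparison on per-sample relative abundances.
    Emits one row per ASV × comparison with A, B, the statistic, the raw
    permutation p (starred at 0.05 / 0.01 / 0.001) and a Holm-corrected
    p per comparison.
    """
    from .synthetic_data import count_matrix

    if comparisons is None:
        comparisons = {"substrate": "substrate", "phase": "phase"}
    photo = filter_photosynthetic(asv_table, trophic)
    counts = count_matrix(photo)
    totals = counts.sum(axis=1)
    n = min(top_n, len(photo))
    if n < top_n:
        import logging
        logging.getLogger(__name__).info(
            "only %d photosynthetic ASVs available; screening all", n)
    top = totals.sort_index().sort_values(ascending=False, kind="stable").index[:n]
    rel = counts / counts.sum(axis=0).replace(0, 1)

    rows = []
    ss = np.random.SeedSequence(seed)
    for comp_i, (comp, col) in enumerate(sorted(comparisons.items())):
        labels = meta.loc[counts.columns, col]
        for asv_i, asv in enumerate(top):
            sub_seed = int(ss.generate_state(1)[0] >> 1) + comp_i * 100003 + asv_i
            res = permutation_test(rel.loc[asv], labels,
                                   n_permutations=n_permutations,
                                   seed=sub_seed % (2**31 - 1))
            rows.append({"asv_id": asv, "comparison": comp, "group": res.group,
                         "A": res.A, "B": res.B, "stat": res.stat, "p": res.p,
                         "stars": significance_stars(res.p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for comp in out["comparison"].unique():
        m = out["comparison"] == comp
        out.loc[m, "p_holm"] = multipletests(out.loc[m, "p"], method="holm")[1]
    return out
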