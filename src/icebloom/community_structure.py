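"""Community composition and dissimilarity statistics.

Covers bloom-stage assignment from calendar date, trophic-mode filtering
to the photosynthetic fraction, species-level relative abundances,
selection of the top taxa covering a read-share threshold, Bray–Curtis
dissimilarities, and the rank-based ANOSIM permutation test.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = ["AnosimResult", "assign_stage", "phase_of_stage",
           "filter_photosynthetic", "species_of", "relative_abundance",
           "select_top_taxa", "bray_curtis", "anosim"]

logger = logging.getLogger(__name__)

# Under-ice bloom stages of the 2016 ice-camp time series; half-open
# intervals, so a boundary date belongs to the later stage.
STAGE_STARTS = (
    (datetime.date(2016, 5, 1), "I"),    # snow-covered (dark phase)
    (datetime.date(2016, 6, 3), "II"),   # snow-melt
    (datetime.date(2016, 6, 15), "III"),  # ice-melt
)
SEASON_END = datetime.date(2016, 7, 18)

_PHOTO_MODES = frozenset({"phototroph", "mixotroph"})


def assign_stage(date: datetime.date | str) -> str:
    """Bloom stage (I, II or III) of a sampling date."""
    if isinstance(date, str):
        date = datetime.date.fromisoformat(date)
    if not STAGE_STARTS[0][0] <= date <= SEASON_END:
        raise ValueError(f"date {date} outside the sampling season")
    stage = "I"
    for start, name in STAGE_STARTS:
        if date >= start:
            stage = name
    return stage


def phase_of_stage(stage: str) -> str:
    """Light regime of a bloom stage: stage I is the dark phase."""
    return "dark" if stage == "I" else "light"


def filter_photosynthetic(asv_table: pd.DataFrame,
                          trophic: dict[str, str]) -> pd.DataFrame:
    """Retain ASVs whose deepest resolvable taxon is photosynthetic.

    Taxonomy strings are semicolon-separated lineages; ranks are walked
    species-first and the first name found in ``trophic`` decides the
    mode.  Phototrophs and mixotrophs are kept; heterotrophs dropped;
    lineages matching nothing in the lookup are dropped with a logged
    count.
    """
    if not trophic:
        raise ValueError("empty trophic lookup")
    keep, unmatched = [], 0
    for asv, lineage in asv_table["taxonomy"].items():
        mode = None
        for rank in reversed(str(lineage).split(";")):
            if rank in trophic:
                mode = trophic[rank]
                break
        if mode is None:
            unmatched += 1
        elif mode in _PHOTO_MODES:
            keep.append(asv)
    if unmatched:
        logger.info("dropped %d ASVs with no trophic-mode match", unmatched)
    return asv_table.loc[keep]


def species_of(asv_table: pd.DataFrame) -> pd.Series:
    """Species-rank name (last lineage field) per ASV."""
    return asv_table["taxonomy"].map(lambda s: str(s).split(";")[-1])


def relative_abundance(counts: pd.DataFrame,
                       grouping: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample proportions, optionally aggregated to species level.

    ``counts`` is taxa × samples; ``grouping`` maps row ids to species
    names (rows sharing a name are summed first).  Each sample's
    proportions sum to 1; an all-zero sample yields an all-zero column and
    a warning.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if grouping is not None:
        counts = counts.groupby(grouping.reindex(counts.index)).sum()
        counts.index.name = "species"
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) with zero reads emit all-zero "
            "proportions", stacklevel=2)
    safe = totals.replace(0, 1)
    return counts.div(safe, axis=1)


def select_top_taxa(counts: pd.DataFrame, coverage: float = 0.75) -> list[str]:
    """Smallest prefix of taxa, ranked by total reads, covering >= coverage
    of all reads.  Ties in total reads break by lexicographic name."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if counts.empty:
        raise ValueError("empty count table")
    totals = counts.sum(axis=1)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no reads in count table")
    order = totals.sort_index().sort_values(ascending=False, kind="stable")
    cum = order.cumsum() / grand
    n_keep = int(np.searchsorted(cum.to_numpy(), coverage - 1e-12) + 1)
    if coverage == 1.0:
        order = order[order > 0]
        n_keep = len(order)
    return order.index[:n_keep].tolist()


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity matrix between samples (columns).

    d(a, b) = 1 − 2·Σ min(aᵢ, bᵢ) / (Σaᵢ + Σbᵢ).  A pair of all-zero
    samples is undefined; it is reported as 0 with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float).T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = pdist(x, metric="braycurtis")
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s): dissimilarity set to 0",
                      stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(squareform(d), index=counts.columns,
                        columns=counts.columns)


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    n_samples: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = ranks.size
    n = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4))


def anosim(dist: pd.DataFrame, groups: pd.Series | dict,
           n_permutations: int = 9999, seed: int | None = None) -> AnosimResult:
    """ANOSIM: rank-based test of between- vs within-group dissimilarity.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    ranks taken over all off-diagonal pairs with ties averaged; R ∈
    [−1, 1].  The one-sided p-value is (#{permuted R >= observed} + 1) /
    (n_permutations + 1) under random relabelling of samples, reproducible
    for a fixed seed.
    """
    ids = list(dist.index)
    labels = pd.Series(groups).reindex(ids)
    if labels.isna().any():
        raise ValueError("groups missing for some samples")
    sizes = labels.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")

    d = squareform(dist.to_numpy(dtype=float), checks=False)
    ranks = rankdata(d)
    codes = labels.to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pw = codes[perm][iu] == codes[perm][ju]
        if _anosim_r(ranks, pw) >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations, n_samples=n)
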