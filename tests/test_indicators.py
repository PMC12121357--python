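"""IndVal specificity/fidelity, permutation significance, and the screen."""

import numpy as np
import pandas as pd
import pytest

from icebloom.indicator_analysis import (best_group, indval,
                                         permutation_test,
                                         run_indicator_screen,
                                         significance_stars)
from icebloom.synthetic_data import (SimConfig, count_matrix, generate_study,
                                     trophic_lookup)

G2 = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))


def test_perfect_indicator_reaches_one():
    x = pd.Series([2, 2, 0, 0], index=list("abcd"))
    r = indval(x, G2, "g1")
    assert (r.A, r.B, r.stat) == (1.0, 1.0, 1.0)


def test_even_abundance_gives_half_specificity():
    # hand computation: A = 1/2, B = 1, stat = sqrt(0.5)
    x = pd.Series([1, 1, 1, 1], index=list("abcd"))
    r = indval(x, G2, "g1")
    assert r.A == pytest.approx(0.5, abs=1e-12)
    assert r.B == 1.0
    assert r.stat == pytest.approx(np.sqrt(0.5), abs=1e-12)
    assert r.stat ** 2 == pytest.approx(r.A * r.B, abs=1e-12)


def test_absence_from_target_group_zeroes_the_statistic():
    x = pd.Series([0, 0, 3, 1], index=list("abcd"))
    r = indval(x, G2, "g1")
    assert r.B == 0.0 and r.stat == 0.0


def test_everywhere_absent_asv_is_flagged():
    x = pd.Series([0, 0, 0, 0], index=list("abcd"))
    r = indval(x, G2, "g1")
    assert r.absent and r.stat == 0.0


def test_group_size_correction_uses_group_means():
    # unbalanced groups: A is a ratio of group means, not of group sums
    x = pd.Series([4, 0, 2, 2, 2, 2], index=list("abcdef"))
    groups = pd.Series(["g1"] * 2 + ["g2"] * 4, index=list("abcdef"))
    r = indval(x, groups, "g1")
    assert r.A == pytest.approx(2 / (2 + 2))


def test_statistic_is_scale_invariant():
    x = pd.Series([5, 1, 0, 2], index=list("abcd"))
    r1, r2 = indval(x, G2, "g1"), indval(x * 1000, G2, "g1")
    assert r1.stat == pytest.approx(r2.stat, abs=1e-12)


def test_best_group_argmax_and_tie_break(rng):
    x = pd.Series([2, 2, 0, 0], index=list("abcd"))
    assert best_group(x, G2).group == "g1"
    tie = pd.Series([1, 1, 1, 1], index=list("abcd"))
    assert best_group(tie, G2).group == "g1"  # documented name-order tie-break
    # argmax equals per-group brute force on random tables
    for _ in range(25):
        v = pd.Series(rng.integers(0, 6, size=8),
                      index=[f"s{i}" for i in range(8)])
        groups = pd.Series(rng.choice(["p", "q"], size=8), index=v.index)
        if groups.nunique() < 2 or v.sum() == 0:
            continue
        brute = max(sorted(groups.unique()),
                    key=lambda g: round(indval(v, groups, g).stat, 12))
        assert best_group(v, groups).group == brute


def test_constant_taxon_has_permutation_p_of_one():
    x = pd.Series([3, 3, 3, 3], index=list("abcd"))
    r = permutation_test(x, G2, "g1", n_permutations=499, seed=0)
    assert r.p == 1.0


def test_permutation_p_reproducible_and_floored():
    x = pd.Series([9, 8, 0, 1], index=list("abcd"))
    r1 = permutation_test(x, G2, n_permutations=199, seed=42)
    r2 = permutation_test(x, G2, n_permutations=199, seed=42)
    assert r1.p == r2.p >= 1 / 200
    with pytest.raises(ValueError):
        permutation_test(x, pd.Series(["g"] * 4, index=list("abcd")),
                         n_permutations=9)


def test_planted_ice_indicator_detected_with_high_power():
    detected = trials = 0
    for seed in range(15):
        cfg = SimConfig(seed=seed, n_taxa=40, n_ref_samples=50,
                        affinity_effect=8, library_size=4000)
        asv_table, meta, truth = generate_study(cfg)
        counts = count_matrix(asv_table)
        rel = counts / counts.sum(axis=0)
        ice = meta.index[meta["substrate"] == "ice"][:12]
        water = meta.index[meta["substrate"] == "water"][:12]
        cols = list(ice) + list(water)
        groups = meta.loc[cols, "substrate"]
        asv = next(a for a, aff in truth.affinity.items() if aff == "ice")
        r = permutation_test(rel.loc[asv, cols], groups,
                             n_permutations=499, seed=seed)
        trials += 1
        detected += (r.p < 0.05 and r.group == "ice")
    assert detected / trials >= 0.9


def test_null_pvalues_are_roughly_uniform(rng):
    # 200 null taxa: Pr(p <= 0.05) close to 0.05 (never anticonservative)
    n = 24
    groups = pd.Series(["a"] * 12 + ["b"] * 12,
                       index=[f"s{i}" for i in range(n)])
    hits = 0
    m = 200
    for k in range(m):
        x = pd.Series(rng.poisson(5, size=n), index=groups.index)
        r = permutation_test(x, groups, n_permutations=199, seed=k)
        hits += r.p <= 0.05
    assert hits / m < 0.10


def test_stars_follow_the_standard_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.049) == "*"
    assert significance_stars(0.2) == ""


def test_screen_reports_one_row_per_comparison_with_top_n_one(study):
    asv_table, meta, _ = study
    res = run_indicator_screen(asv_table, meta, trophic_lookup(), top_n=1,
                               n_permutations=49, seed=1)
    assert sorted(res["comparison"].unique()) == ["phase", "substrate"]
    assert (res.groupby("comparison").size() == 1).all()
    assert set(res.columns) >= {"asv_id", "group", "A", "B", "stat", "p",
                                "stars", "p_holm"}


def test_screen_recovers_planted_substrate_indicators():
    cfg = SimConfig(seed=21, n_taxa=60, n_ref_samples=50, affinity_effect=8,
                    library_size=8000)
    asv_table, meta, truth = generate_study(cfg)
    res = run_indicator_screen(asv_table, meta, trophic_lookup(), top_n=20,
                               n_permutations=199, seed=3)
    sub = res[res["comparison"] == "substrate"].set_index("asv_id")
    planted = [a for a in sub.index
               if truth.affinity[a] in ("ice", "water")]
    assert len(planted) >= 3
    ok = [a for a in planted
          if sub.loc[a, "p"] < 0.05 and sub.loc[a, "group"] == truth.affinity[a]]
    assert len(ok) / len(planted) >= 0.8
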