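"""Stage assignment, trophic filtering, abundance aggregation, Bray–Curtis
and ANOSIM."""

import datetime

import numpy as np
import pandas as pd
import pytest

from icebloom.community_structure import (anosim, assign_stage, bray_curtis,
                                          filter_photosynthetic,
                                          relative_abundance, select_top_taxa,
                                          species_of)
from icebloom.synthetic_data import count_matrix, trophic_lookup
from oracles import minimal_prefix


@pytest.mark.parametrize("date,stage", [
    ("2016-05-01", "I"), ("2016-05-10", "I"), ("2016-06-02", "I"),
    ("2016-06-03", "II"), ("2016-06-14", "II"),
    ("2016-06-15", "III"), ("2016-07-18", "III"),
])
def test_bloom_stage_intervals_are_half_open(date, stage):
    assert assign_stage(date) == stage
    assert assign_stage(datetime.date.fromisoformat(date)) == stage


@pytest.mark.parametrize("date", ["2016-04-30", "2016-07-19", "2017-06-01"])
def test_dates_outside_the_season_are_rejected(date):
    with pytest.raises(ValueError):
        assign_stage(date)


def _table(tax_modes):
    rows = {f"A{i}": {"sequence": "ACGT", "taxonomy": t}
            for i, t in enumerate(tax_modes)}
    return pd.DataFrame.from_dict(rows, orient="index")


def test_photosynthetic_filter_keeps_photo_and_mixo_drops_hetero():
    table = _table([
        "Eukaryota;Stramenopiles;Bacillariophyceae;X;Y;Nitzschia;N_frigida",
        "Eukaryota;Chlorophyta;Mamiellophyceae;X;Y;Micromonas;M_polaris",
        "Eukaryota;Haptophyta;Prymnesiophyceae;X;Y;Phaeocystis;P_pouchetii",
        "Eukaryota;Alveolata;Dinophyceae;X;Y;Heterocapsa;H_rotundata",
        "Eukaryota;Alveolata;Syndiniales;X;Y;Dino-Group-II;DG_sp",
        "Eukaryota;Picozoa;Picozoa_X;X;Y;Picomonas;P_judraskeda",
    ])
    kept = filter_photosynthetic(table, trophic_lookup())
    assert list(kept.index) == ["A0", "A1", "A2", "A3"]  # mixotroph retained


def test_deepest_taxon_match_wins_over_class_level():
    # Gyrodinium is heterotrophic although its class is mixotrophic
    table = _table([
        "Eukaryota;Alveolata;Dinophyceae;X;Y;Gyrodinium;G_helveticum",
        "Eukaryota;Alveolata;Dinophyceae;X;Y;Heterocapsa;H_rotundata",
    ])
    assert list(filter_photosynthetic(table, trophic_lookup()).index) == ["A1"]


def test_unmatched_lineages_are_dropped_and_empty_lookup_rejected():
    table = _table(["Eukaryota;Stramenopiles;Chrysophyceae;X;Y;Ochromonas;O_sp"])
    assert filter_photosynthetic(table, trophic_lookup()).empty
    assert filter_photosynthetic(table.iloc[:0], trophic_lookup()).empty
    with pytest.raises(ValueError):
        filter_photosynthetic(table, {})


def test_filter_recovers_planted_photosynthetic_set(study):
    asv_table, _, truth = study
    kept = set(filter_photosynthetic(asv_table, trophic_lookup()).index)
    assert kept == {a for a, v in truth.photosynthetic.items() if v}


def test_relative_abundance_proportions_and_species_aggregation():
    counts = pd.DataFrame({"s1": [3, 1, 0], "s2": [0, 0, 0]},
                          index=["a", "b", "c"])
    with pytest.warns(UserWarning, match="zero reads"):
        rel = relative_abundance(counts)
    assert rel["s1"].tolist() == [0.75, 0.25, 0.0]
    assert rel["s2"].tolist() == [0.0, 0.0, 0.0]
    # two ASVs of one species sum their proportions
    grouping = pd.Series({"a": "sp1", "b": "sp1", "c": "sp2"})
    with pytest.warns(UserWarning, match="zero reads"):
        rel2 = relative_abundance(counts, grouping=grouping)
    assert rel2.loc["sp1", "s1"] == 1.0
    with pytest.raises(ValueError):
        relative_abundance(counts - 1)


def test_per_sample_proportions_sum_to_one(study):
    asv_table, _, _ = study
    counts = count_matrix(asv_table)
    rel = relative_abundance(counts, grouping=species_of(asv_table))
    assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-9)


def test_top_taxa_selection_minimal_prefix():
    counts = pd.DataFrame({"s": [50, 30, 20]}, index=["x", "y", "z"])
    assert select_top_taxa(counts, 0.75) == ["x", "y"]
    assert select_top_taxa(counts, 1.0) == ["x", "y", "z"]
    counts.loc["z", "s"] = 0
    assert select_top_taxa(counts, 1.0) == ["x", "y"]
    with pytest.raises(ValueError):
        select_top_taxa(counts.iloc[:0], 0.75)
    with pytest.raises(ValueError):
        select_top_taxa(counts, 0.0)


def test_top_taxa_matches_bruteforce_on_random_tables(rng):
    for _ in range(20):
        n = int(rng.integers(3, 25))
        totals = {f"t{i:02d}": int(rng.integers(0, 500)) for i in range(n)}
        if sum(totals.values()) == 0:
            totals["t00"] = 1
        counts = pd.DataFrame({"s": pd.Series(totals)})
        cov = float(rng.uniform(0.05, 1.0))
        assert select_top_taxa(counts, cov) == minimal_prefix(totals, cov)


def test_bray_curtis_limits_and_hand_value():
    counts = pd.DataFrame({"a": [1, 1], "b": [1, 0], "c": [1, 1],
                           "d": [0, 2]}, index=["t1", "t2"])
    d = bray_curtis(counts)
    assert d.loc["a", "c"] == 0.0                       # identical samples
    assert d.loc["b", "d"] == 1.0                       # disjoint samples
    assert d.loc["a", "b"] == pytest.approx(1 / 3)      # hand computation
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert np.all(np.diag(d.to_numpy()) == 0)


def test_all_zero_sample_pair_yields_zero_with_warning():
    counts = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 2]},
                          index=["t1", "t2"])
    with pytest.warns(UserWarning, match="all-zero"):
        d = bray_curtis(counts)
    assert d.loc["a", "b"] == 0.0
    assert d.loc["a", "c"] == 1.0


def _dist(mat, ids):
    return pd.DataFrame(np.asarray(mat, dtype=float), index=ids, columns=ids)


def test_anosim_is_one_for_perfect_separation_and_zero_for_ties():
    ids = ["a1", "a2", "b1", "b2"]
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=ids)
    sep = _dist([[0, .1, .9, .8], [.1, 0, .85, .95],
                 [.9, .85, 0, .2], [.8, .95, .2, 0]], ids)
    res = anosim(sep, groups, n_permutations=99, seed=0)
    assert res.R == pytest.approx(1.0)
    flat = _dist(0.5 * (1 - np.eye(4)), ids)
    assert anosim(flat, groups, n_permutations=99, seed=0).R == \
        pytest.approx(0.0)


def test_anosim_matches_scikit_bio(rng):
    pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.stats.distance import anosim as skbio_anosim

    n = 12
    ids = [f"s{i}" for i in range(n)]
    x = rng.random((n, 5))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
    ours = anosim(_dist(d, ids), groups, n_permutations=999, seed=1)
    theirs = skbio_anosim(DistanceMatrix(d, ids), groups.to_numpy(),
                          permutations=999)
    assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)


def test_anosim_p_floor_and_seed_reproducibility(study):
    asv_table, meta, _ = study
    counts = count_matrix(asv_table)
    d = bray_curtis(counts)
    groups = meta["substrate"]
    r1 = anosim(d, groups, n_permutations=49, seed=5)
    r2 = anosim(d, groups, n_permutations=49, seed=5)
    assert (r1.R, r1.p) == (r2.R, r2.p)
    assert r1.p >= 1 / 50
    with pytest.raises(ValueError):
        anosim(d.iloc[:3, :3], pd.Series(["a", "a", "b"], index=d.index[:3]),
               n_permutations=9)


def test_anosim_null_distribution_is_centred_on_zero(rng):
    n = 16
    ids = [f"s{i}" for i in range(n)]
    x = rng.random((n, 4))
    d = _dist(np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)), ids)
    rs = []
    for k in range(100):
        labels = rng.permutation(["A"] * 8 + ["B"] * 8)
        rs.append(anosim(d, pd.Series(labels, index=ids),
                         n_permutations=1, seed=k).R)
    assert abs(np.mean(rs)) < 0.06
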