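"""File formats, run configuration and the stage pipeline.

Artifacts are plain text: FASTA for sequences, tab-separated tables for
counts, metadata, occurrences and results, JSON for summaries and planted
truth.  Count matrices are oriented ASVs-in-rows, samples-in-columns;
dates are ISO-8601; coordinates signed decimal degrees (N/E positive).
Every table starts with a provenance comment recording the config hash
and seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import biogeography, community_structure as community, indicator_analysis
from .sequence_clustering import CasvAssignment, cluster_asvs, entries_from_tables
from .synthetic_data import (PlantedTruth, SimConfig, count_matrix,
                             generate_reference, generate_study,
                             sample_columns, trophic_lookup)

__all__ = ["RunConfig", "InputError", "read_inputs", "run_pipeline",
           "stage_simulate", "stage_cluster", "stage_classify",
           "stage_community", "stage_indicators", "stage_report", "FILES"]

logger = logging.getLogger(__name__)

FILES = {
    "study_fasta": "study_asvs.fasta",
    "counts": "counts.tsv",
    "taxonomy": "taxonomy.tsv",
    "metadata": "sample_metadata.tsv",
    "trophic": "trophic_modes.tsv",
    "ref_fasta": "reference_asvs.fasta",
    "occurrences": "reference_occurrences.tsv",
    "truth": "planted_truth.json",
    "casv_map": "casv_map.tsv",
    "casv_members": "casv_members.tsv",
    "biogeo": "biogeography.tsv",
    "biogeo_summary": "biogeography_summary.json",
    "relabund": "relative_abundance.tsv",
    "top_taxa": "top_taxa.tsv",
    "braycurtis": "bray_curtis.tsv",
    "anosim": "anosim.json",
    "indicators": "indicators.tsv",
    "indicator_summary": "indicator_summary.json",
    "report": "report.json",
}


class InputError(ValueError):
    """Malformed or inconsistent input files."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    min_overlap: int = 100          # nt, exact-overlap clustering
    dedup_precision: float = 0.1    # degrees, geographic deduplication
    min_samples: int = 5            # occurrence floor before classification
    coverage: float = 0.75          # read share for top-taxa selection
    n_permutations: int = 9999
    top_n: int = 20                 # ASVs screened per indicator comparison
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in ("min_overlap", "dedup_precision", "min_samples",
                     "n_permutations", "top_n", "coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("sim", {})
        if "seed" in raw and "seed" not in sim:
            sim["seed"] = raw["seed"]
        if isinstance(sim, dict):
            if "zone_mix" in sim:
                sim["zone_mix"] = tuple(sim["zone_mix"])
            sim = SimConfig(**sim)
        return cls(sim=sim, **raw)

    def with_seed(self, seed: int) -> "RunConfig":
        sim = dataclasses.replace(self.sim, seed=seed)
        return dataclasses.replace(self, seed=seed, sim=sim)

    def hash(self) -> str:
        """Digest of the analysis parameters (the output path is location,
        not configuration, and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.md5(json.dumps(d, sort_keys=True, default=str)
                           .encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# readers / writers with provenance

def _provenance_line(cfg: RunConfig) -> str:
    return f"# icebloom config_hash={cfg.hash()} seed={cfg.seed}\n"


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(cfg))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_json(obj, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": {"config_hash": cfg.hash(), "seed": cfg.seed}}
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float)
                    + "\n")


def write_fasta(seqs: dict[str, str], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    """FASTA id → sequence; lowercase input is accepted, uppercased and
    logged."""
    out: dict[str, str] = {}
    lowered = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if s != s.upper():
            lowered += 1
            s = s.upper()
        if rec.id in out:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path.name}")
        if not s or set(s) - set("ACGT"):
            raise InputError(f"non-ACGT sequence for {rec.id!r} in {path.name}")
        out[rec.id] = s
    if lowered:
        logger.info("uppercased %d lowercase sequences in %s", lowered, path.name)
    return out


def read_inputs(cfg: RunConfig) -> dict:
    """Load and cross-validate the study tables of a run directory."""
    out = Path(cfg.outdir)
    seqs = read_fasta(out / FILES["study_fasta"])
    counts = read_table(out / FILES["counts"])
    try:
        counts = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        raise InputError(f"non-numeric read counts: {exc}") from exc
    taxonomy = read_table(out / FILES["taxonomy"])
    meta = read_table(out / FILES["metadata"])

    if set(seqs) != set(counts.index):
        missing = sorted(set(seqs) ^ set(counts.index))
        raise InputError(f"FASTA ids and count rows differ: {missing[:5]}")
    if set(counts.index) != set(taxonomy.index):
        raise InputError("taxonomy table does not cover the count rows")
    extra = sorted(set(counts.columns) - set(meta.index))
    if extra:
        raise InputError(f"count columns missing from metadata: {extra}")
    if (abs(meta["latitude"]) > 90).any() or (abs(meta["longitude"]) > 180).any():
        raise InputError("sample coordinates out of range")
    meta = meta.copy()
    meta["stage"] = [community.assign_stage(d) for d in meta["date"]]
    meta["phase"] = meta["stage"].map(community.phase_of_stage)

    asv_table = pd.DataFrame({"sequence": pd.Series(seqs),
                              "taxonomy": taxonomy["taxonomy"]})
    asv_table.index.name = "asv_id"
    asv_table = asv_table.join(counts)
    trophic = read_table(out / FILES["trophic"])["mode"].to_dict()
    return {"asv_table": asv_table, "meta": meta, "trophic": trophic}


# --------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    asv_table, meta, truth = generate_study(cfg.sim)
    ref_seqs, occ = generate_reference(cfg.sim, asv_table, truth)

    write_fasta(asv_table["sequence"].to_dict(), out / FILES["study_fasta"])
    write_table(count_matrix(asv_table), out / FILES["counts"], cfg)
    write_table(asv_table[["taxonomy"]], out / FILES["taxonomy"], cfg)
    write_table(meta, out / FILES["metadata"], cfg)
    troph = pd.DataFrame(sorted(trophic_lookup().items()),
                         columns=["taxon", "mode"]).set_index("taxon")
    write_table(troph, out / FILES["trophic"], cfg)
    write_fasta(ref_seqs["sequence"].to_dict(), out / FILES["ref_fasta"])
    write_table(occ, out / FILES["occurrences"], cfg, index=False)
    (out / FILES["truth"]).write_text(truth.to_json() + "\n")
    logger.info("simulate: %d ASVs, %d samples, %d reference occurrences",
                len(asv_table), len(meta), len(occ))


def _load_assignment(out: Path) -> CasvAssignment:
    mapping = read_table(out / FILES["casv_map"], index_col=None)
    members = read_table(out / FILES["casv_members"], index_col=None)
    assign = CasvAssignment()
    assign.study_to_casv = dict(zip(mapping["study_asv_id"], mapping["casv_id"]))
    for casv, grp in members.groupby("casv_id"):
        assign.members[str(casv)] = sorted(grp["member_id"])
    return assign


def stage_cluster(cfg: RunConfig) -> CasvAssignment:
    out = Path(cfg.outdir)
    data = read_inputs(cfg)
    ref = pd.DataFrame({"sequence": pd.Series(read_fasta(out / FILES["ref_fasta"]))})
    entries = entries_from_tables(data["asv_table"], ref)
    assign = cluster_asvs(entries, min_overlap=cfg.min_overlap)
    write_table(assign.mapping_frame(), out / FILES["casv_map"], cfg, index=False)
    write_table(assign.members_frame(), out / FILES["casv_members"], cfg,
                index=False)
    logger.info("cluster: %d study ASVs into %d cASVs",
                len(assign.study_to_casv), len(assign.members))
    return assign


def stage_classify(cfg: RunConfig) -> pd.DataFrame:
    out = Path(cfg.outdir)
    assign = _load_assignment(out)
    occ_path = out / FILES["occurrences"]
    if occ_path.exists():
        occ = read_table(occ_path, index_col=None)
    else:
        logger.warning("no reference occurrence table; all cASVs unallocated")
        occ = pd.DataFrame(columns=["ref_asv_id", "sample_id", "dataset_id",
                                    "latitude", "longitude"])
    result = biogeography.classify_all(assign, occ,
                                       precision=cfg.dedup_precision,
                                       min_samples=cfg.min_samples)
    write_table(result, out / FILES["biogeo"], cfg)

    counts = read_table(out / FILES["counts"])
    casv_map = pd.Series({s: c for s, c in _load_assignment(out).study_to_casv.items()})
    cat_of_asv = casv_map.map(result["category"]).reindex(counts.index) \
                         .fillna("unallocated")
    reads = counts.sum(axis=1)
    by_cat_reads = reads.groupby(cat_of_asv).sum()
    by_cat_asvs = cat_of_asv.value_counts()
    summary = {
        "asvs_per_category": {c: int(by_cat_asvs.get(c, 0))
                              for c in biogeography.CATEGORIES},
        "read_fraction_per_category": {
            c: float(by_cat_reads.get(c, 0) / reads.sum())
            for c in biogeography.CATEGORIES},
    }
    write_json(summary, out / FILES["biogeo_summary"], cfg)
    return result


def stage_community(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    data = read_inputs(cfg)
    asv_table, meta, trophic = data["asv_table"], data["meta"], data["trophic"]

    photo = community.filter_photosynthetic(asv_table, trophic)
    counts = count_matrix(photo)
    species = community.species_of(photo)
    rel = community.relative_abundance(counts, grouping=species)

    long = (rel.reset_index().melt(id_vars="species", var_name="sample_id",
                                   value_name="proportion"))
    long = long.merge(meta[["stage", "layer", "size_fraction"]],
                      left_on="sample_id", right_index=True)
    long = long.sort_values(["sample_id", "species"]).reset_index(drop=True)
    write_table(long, out / FILES["relabund"], cfg, index=False)

    sp_counts = counts.groupby(species).sum()
    top = community.select_top_taxa(sp_counts, coverage=cfg.coverage)
    top_df = pd.DataFrame({
        "species": top,
        "total_reads": [int(sp_counts.loc[t].sum()) for t in top],
    })
    top_df["read_share"] = top_df["total_reads"] / sp_counts.to_numpy().sum()
    write_table(top_df, out / FILES["top_taxa"], cfg, index=False)

    dist = community.bray_curtis(counts)
    write_table(dist, out / FILES["braycurtis"], cfg)

    anosim_out = {}
    for k, factor in enumerate(("size_fraction", "substrate", "phase")):
        res = community.anosim(dist, meta.loc[dist.index, factor],
                               n_permutations=cfg.n_permutations,
                               seed=(cfg.seed * 7919 + 101 + k) % (2**31 - 1))
        anosim_out[factor] = {"R": res.R, "p": res.p,
                              "n_permutations": res.n_permutations,
                              "n_samples": res.n_samples}
        logger.info("ANOSIM %s: R=%.3f p=%.4g", factor, res.R, res.p)
    write_json(anosim_out, out / FILES["anosim"], cfg)
    return {"top_taxa": top, "anosim": anosim_out, "dist": dist}


def stage_indicators(cfg: RunConfig) -> pd.DataFrame:
    out = Path(cfg.outdir)
    data = read_inputs(cfg)
    res = indicator_analysis.run_indicator_screen(
        data["asv_table"], data["meta"], data["trophic"],
        top_n=cfg.top_n, n_permutations=cfg.n_permutations,
        seed=(cfg.seed * 7919 + 331) % (2**31 - 1))
    write_table(res, out / FILES["indicators"], cfg, index=False)
    sig = res[res["p"] < 0.05]
    summary = {"n_significant_per_group":
               {g: int((sig["group"] == g).sum())
                for g in sorted(res["group"].unique())}}
    write_json(summary, out / FILES["indicator_summary"], cfg)
    return res


def stage_report(cfg: RunConfig) -> dict:
    """Per-panel (substrate × size fraction × stage) read fractions by
    biogeographical category, over photosynthetic reads; fractions in each
    panel sum to 1 including the unallocated share."""
    out = Path(cfg.outdir)
    data = read_inputs(cfg)
    photo = community.filter_photosynthetic(data["asv_table"], data["trophic"])
    counts = count_matrix(photo)
    meta = data["meta"]
    biogeo = read_table(out / FILES["biogeo"])
    assign = _load_assignment(out)
    cat = (pd.Series(assign.study_to_casv).map(biogeo["category"])
           .reindex(counts.index).fillna("unallocated"))

    panels = {}
    grouped = meta.loc[counts.columns].groupby(
        ["substrate", "size_fraction", "stage"], sort=True)
    for (sub, frac, stage), grp in grouped:
        panel_counts = counts[grp.index].sum(axis=1)
        total = panel_counts.sum()
        by_cat = panel_counts.groupby(cat).sum()
        panels[f"{sub}/{frac}/stage_{stage}"] = {
            c: (float(by_cat.get(c, 0) / total) if total else 0.0)
            for c in biogeography.CATEGORIES}
    report = {"category_read_fractions": panels,
              "n_panels": len(panels)}
    write_json(report, out / FILES["report"], cfg)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """simulate → cluster → classify → community → indicators → report."""
    stages = (("simulate", stage_simulate), ("cluster", stage_cluster),
              ("classify", stage_classify), ("community", stage_community),
              ("indicators", stage_indicators), ("report", stage_report))
    result = None
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            result = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result
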