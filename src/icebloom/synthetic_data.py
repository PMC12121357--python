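"""Synthetic study + global reference data with planted ground truth.

Emulates an Arctic ice-camp time series of 18S rRNA V4 amplicon data:
samples from two sea-ice layers and four water depths, three size
fractions, and calendar dates spanning the three under-ice bloom stages
(snow-covered, snow-melt, ice-melt), together with a global reference
occurrence table whose samples span polar, temperate and tropical
latitudes.  Every taxon carries planted truth — its latitudinal zone, its
substrate/phase affinity, whether it is photosynthetic and whether it
appears in the reference — so downstream stages can be scored against
known answers.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "ConfigurationError",
    "generate_study",
    "generate_reference",
    "sample_columns",
    "count_matrix",
    "trophic_lookup",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


ZONES = ("polar", "temperate", "tropical")
ICE_LAYERS = ("ICE_0", "ICE_1")
WATER_LAYERS = ("WATER_1", "WATER_2", "WATER_3", "WATER_4")
SIZE_FRACTIONS = ("pico", "nano", "micro")
AFFINITIES = ("ice", "water", "dark", "light")

# Three sampling dates per bloom stage, including the stage boundary dates
# so stage assignment edge cases are exercised.
SAMPLING_DATES = (
    "2016-05-01", "2016-05-12", "2016-05-24",   # stage I  (snow-covered)
    "2016-06-03", "2016-06-08", "2016-06-13",   # stage II (snow-melt)
    "2016-06-15", "2016-06-28", "2016-07-18",   # stage III (ice-melt)
)

# Ice-camp coordinates (western Baffin Bay, north of the Arctic circle).
STUDY_LAT = 67.4797
STUDY_LON = -63.7895

# (division, class, genus, species epithets, trophic mode) — a small fixed
# lineage catalogue mixing sympagic/planktonic phototrophs with
# heterotrophs and one mixotroph class.  "None" mode means the taxon is
# absent from the trophic lookup (exercises the unmatched-drop path).
_CATALOG = (
    ("Stramenopiles", "Bacillariophyceae", "Nitzschia", ("frigida", "sp."), "phototroph"),
    ("Stramenopiles", "Bacillariophyceae", "Navicula", ("ramosissima",), "phototroph"),
    ("Stramenopiles", "Bacillariophyceae", "Fragilariopsis", ("cylindrus",), "phototroph"),
    ("Stramenopiles", "Bacillariophyceae", "Pseudo-nitzschia", ("seriata",), "phototroph"),
    ("Stramenopiles", "Mediophyceae", "Thalassiosira", ("nordenskioeldii", "antarctica"), "phototroph"),
    ("Stramenopiles", "Mediophyceae", "Attheya", ("septentrionalis",), "phototroph"),
    ("Stramenopiles", "Mediophyceae", "Porosira", ("glacialis",), "phototroph"),
    ("Stramenopiles", "Pelagophyceae", "Ankylochrysis", ("lutea",), "phototroph"),
    ("Stramenopiles", "Pelagophyceae", "Plocamiomonas", ("psychrophila",), "phototroph"),
    ("Stramenopiles", "Bolidophyceae", "Triparma", ("laevis",), "phototroph"),
    ("Chlorophyta", "Mamiellophyceae", "Micromonas", ("polaris",), "phototroph"),
    ("Chlorophyta", "Mamiellophyceae", "Bathycoccus", ("prasinos",), "phototroph"),
    ("Haptophyta", "Prymnesiophyceae", "Phaeocystis", ("pouchetii", "jahnii"), "phototroph"),
    ("Cryptophyta", "Cryptophyceae", "Baffinella", ("frigidus",), "phototroph"),
    ("Alveolata", "Dinophyceae", "Heterocapsa", ("rotundata",), "mixotroph"),
    ("Alveolata", "Dinophyceae", "Gyrodinium", ("helveticum",), "heterotroph"),
    ("Alveolata", "Syndiniales", "Dino-Group-II", ("sp.",), "heterotroph"),
    ("Picozoa", "Picozoa_X", "Picomonas", ("judraskeda",), "heterotroph"),
    ("Stramenopiles", "MAST-1", "MAST-1C", ("sp.",), "heterotroph"),
    ("Telonemia", "Telonemia_X", "Telonema", ("subtile",), "heterotroph"),
    ("Stramenopiles", "Chrysophyceae", "Ochromonas", ("sp.",), None),
)

_PHOTO_MODES = frozenset({"phototroph", "mixotroph"})


def trophic_lookup() -> dict[str, str]:
    """Taxon name → trophic mode table used by the photosynthetic filter.

    Mostly class-level entries; *Gyrodinium* is a genus-level heterotroph
    override inside the otherwise mixotrophic Dinophyceae, so the filter's
    deepest-match rule matters.  Chrysophyceae are deliberately absent
    (unmatched taxa are dropped with a logged count).
    """
    table: dict[str, str] = {}
    for _, cls, genus, _, mode in _CATALOG:
        if cls == "Chrysophyceae" or mode is None:
            continue
        if genus == "Gyrodinium":
            table[genus] = mode
        else:
            table.setdefault(cls, "phototroph" if mode == "phototroph" else mode)
    table["Dinophyceae"] = "mixotroph"
    return table


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic study and reference generators.

    Parameters
    ----------
    seed : master seed; a fixed seed gives byte-identical outputs.
    n_taxa : number of study ASVs.
    n_ref_samples : number of global reference samples.
    zone_mix : (polar, temperate, tropical) proportions of reference
        samples, summing to 1.
    library_size : reads per study sample (multinomial total).
    affinity_effect : multiplicative abundance fold-change a planted
        indicator enjoys in its preferred substrate/phase (>= 1).
    stray_rate : probability a taxon occurs in a reference sample outside
        its true zone.
    seq_length : ASV sequence length in nucleotides.
    ecotype_pairs : number of planted sequence pairs at Hamming distance 1.
    base_sigma : log-normal sigma of the baseline abundance profile.
    home_rate : probability a taxon occurs in a reference sample of its
        true zone.
    photo_fraction : fraction of taxa drawn from photosynthetic lineages.
    affinity_fraction : fraction of photosynthetic taxa given a planted
        substrate/phase affinity.
    reference_fraction : fraction of taxa present in the reference corpus
        (the rest are unique to the study and stay unallocated).
    """

    seed: int = 0
    n_taxa: int = 300
    n_ref_samples: int = 300
    zone_mix: tuple[float, float, float] = (0.34, 0.33, 0.33)
    library_size: int = 20_000
    affinity_effect: float = 8.0
    stray_rate: float = 0.02
    seq_length: int = 380
    ecotype_pairs: int = 3
    base_sigma: float = 1.5
    home_rate: float = 0.8
    photo_fraction: float = 0.8
    affinity_fraction: float = 0.4
    reference_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.n_taxa <= 0:
            raise ConfigurationError("n_taxa must be positive")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.n_ref_samples <= 0:
            raise ConfigurationError("n_ref_samples must be positive")
        if self.seq_length < 20:
            raise ConfigurationError("seq_length must be at least 20 nt")
        if len(self.zone_mix) != 3 or any(m < 0 for m in self.zone_mix):
            raise ConfigurationError("zone_mix needs three nonnegative entries")
        if abs(sum(self.zone_mix) - 1.0) > 1e-9:
            raise ConfigurationError("zone_mix must sum to 1 within 1e-9")
        if self.affinity_effect < 1:
            raise ConfigurationError("affinity_effect must be >= 1")
        if not 0 <= self.stray_rate <= 1:
            raise ConfigurationError("stray_rate must be in [0, 1]")
        if self.ecotype_pairs < 0 or 2 * self.ecotype_pairs > self.n_taxa:
            raise ConfigurationError("ecotype_pairs exceeds available taxa")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, keyed by study ASV id."""

    zone: dict[str, str] = field(default_factory=dict)
    affinity: dict[str, str | None] = field(default_factory=dict)
    photosynthetic: dict[str, bool] = field(default_factory=dict)
    in_reference: dict[str, bool] = field(default_factory=dict)
    ecotype_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["ecotype_pairs"] = [list(t) for t in self.ecotype_pairs]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["ecotype_pairs"] = [tuple(t) for t in d["ecotype_pairs"]]
        return cls(**d)


def sample_columns(asv_table: pd.DataFrame) -> list[str]:
    """Names of the per-sample count columns of a study ASV table."""
    return [c for c in asv_table.columns if c not in ("sequence", "taxonomy")]


def count_matrix(asv_table: pd.DataFrame) -> pd.DataFrame:
    """ASV × sample read-count matrix view of a study ASV table."""
    return asv_table[sample_columns(asv_table)]


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    return ["".join(alphabet[rng.integers(0, 4, size=length)]) for _ in range(n)]


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _build_sequences(rng: np.random.Generator, cfg: SimConfig,
                     ids: list[str]) -> tuple[dict[str, str], list[tuple[str, str, int]]]:
    """Random ACGT sequences; the first 2*ecotype_pairs ids form planted
    single-mismatch pairs, and all other pairs sit at Hamming distance >= 2
    (regenerated in the astronomically unlikely event of a collision)."""
    n = len(ids)
    for _ in range(20):
        seqs = _random_sequences(rng, n, cfg.seq_length)
        pairs: list[tuple[str, str, int]] = []
        for k in range(cfg.ecotype_pairs):
            i, j = 2 * k, 2 * k + 1
            pos = int(rng.integers(1, cfg.seq_length - 1))
            base = seqs[i][pos]
            alt = rng.choice([b for b in "ACGT" if b != base])
            seqs[j] = seqs[i][:pos] + alt + seqs[i][pos + 1:]
            pairs.append((ids[i], ids[j], pos))
        arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
        arr = arr.reshape(n, cfg.seq_length)
        planted = {(2 * k, 2 * k + 1) for k in range(cfg.ecotype_pairs)}
        ok = True
        for i in range(n):
            d = (arr[i + 1:] != arr[i]).sum(axis=1)
            for off in np.flatnonzero(d < 2):
                if (i, i + 1 + int(off)) not in planted:
                    ok = False
        if ok:
            return dict(zip(ids, seqs)), pairs
    raise RuntimeError("could not build a collision-free sequence set")


def generate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the study ASV table, sample metadata and planted truth.

    Samples enumerate the full design grid: (2 ice layers + 4 water
    layers) × 3 size fractions × 9 dates spanning the three bloom stages.
    Counts per sample are a multinomial draw (total = ``library_size``)
    over a log-normal baseline composition, multiplied by
    ``affinity_effect`` for planted indicators in their preferred
    substrate or bloom phase.

    Returns
    -------
    asv_table : DataFrame indexed by ASV id with columns ``sequence``,
        ``taxonomy`` and one integer count column per sample.
    sample_meta : DataFrame indexed by sample id with substrate, layer,
        size_fraction, date, stage, phase and coordinates.
    truth : PlantedTruth
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"ASV_{i:04d}" for i in range(config.n_taxa)]

    # --- sample metadata over the design grid ---------------------------
    rows = []
    for date_s in SAMPLING_DATES:
        date = datetime.date.fromisoformat(date_s)
        stage = _stage_of(date)
        for layer in ICE_LAYERS + WATER_LAYERS:
            for frac in SIZE_FRACTIONS:
                sid = f"{layer}_{frac}_{date_s.replace('-', '')}"
                rows.append({
                    "sample_id": sid,
                    "substrate": "ice" if layer.startswith("ICE") else "water",
                    "layer": layer,
                    "size_fraction": frac,
                    "date": date_s,
                    "stage": stage,
                    "phase": "dark" if stage == "I" else "light",
                    "latitude": STUDY_LAT,
                    "longitude": STUDY_LON,
                })
    meta = pd.DataFrame(rows).set_index("sample_id")

    # --- planted truth ---------------------------------------------------
    truth = PlantedTruth()
    photo_entries = [e for e in _CATALOG if e[4] in _PHOTO_MODES and e[1] != "Chrysophyceae"]
    other_entries = [e for e in _CATALOG if e not in photo_entries]
    n_photo = max(2 * config.ecotype_pairs, int(round(config.photo_fraction * config.n_taxa)))
    n_photo = min(n_photo, config.n_taxa)

    seqs, pairs = _build_sequences(rng, config, ids)
    truth.ecotype_pairs = pairs

    taxonomies = {}
    for i, asv in enumerate(ids):
        photo = i < n_photo
        pool = photo_entries if photo else other_entries
        division, cls, genus, species_list, mode = pool[int(rng.integers(len(pool)))]
        sp = species_list[int(rng.integers(len(species_list)))]
        species = f"{genus}_{sp}".replace(" ", "_")
        taxonomies[asv] = (
            f"Eukaryota;{division};{cls};{cls}_O;{cls}_F;{genus};{species}"
        )
        truth.photosynthetic[asv] = bool(mode in _PHOTO_MODES and genus != "Gyrodinium")
        truth.zone[asv] = str(rng.choice(ZONES, p=(0.5, 0.3, 0.2)))
        truth.in_reference[asv] = bool(rng.random() < config.reference_fraction)
        truth.affinity[asv] = None

    # ecotype pair members get contrasting substrate affinities (the
    # ice/pelagic ecotype motif); other affinities round-robin over a
    # subset of photosynthetic taxa.
    for a, b, _ in pairs:
        truth.affinity[a] = "ice"
        truth.affinity[b] = "water"
    photo_ids = [a for a in ids if truth.photosynthetic[a] and truth.affinity[a] is None]
    n_aff = int(round(config.affinity_fraction * len(photo_ids)))
    for k, asv in enumerate(photo_ids[:n_aff]):
        truth.affinity[asv] = AFFINITIES[k % 4]

    # --- counts ----------------------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=config.base_sigma, size=config.n_taxa)
    aff = np.array([truth.affinity[a] for a in ids], dtype=object)
    counts = np.zeros((config.n_taxa, len(meta)), dtype=np.int64)
    for j, (sid, m) in enumerate(meta.iterrows()):
        boost = np.ones(config.n_taxa)
        boost[aff == m["substrate"]] = config.affinity_effect
        boost[aff == m["phase"]] = config.affinity_effect
        w = base * boost
        counts[:, j] = rng.multinomial(config.library_size, w / w.sum())

    index = pd.Index(ids, name="asv_id")
    asv_table = pd.concat(
        [pd.DataFrame({"sequence": [seqs[a] for a in ids],
                       "taxonomy": [taxonomies[a] for a in ids]}, index=index),
         pd.DataFrame(counts, index=index, columns=meta.index)],
        axis=1)
    return asv_table, meta, truth


def _stage_of(date: datetime.date) -> str:
    if date < datetime.date(2016, 6, 3):
        return "I"
    if date < datetime.date(2016, 6, 15):
        return "II"
    return "III"


_ZONE_LAT = {"polar": (66.0, 85.0), "temperate": (23.0, 66.0), "tropical": (0.0, 23.0)}
_TS_STATION = {"polar": 71.32, "temperate": 43.12, "tropical": 10.55}


def generate_reference(config: SimConfig, asv_table: pd.DataFrame,
                       truth: PlantedTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the global reference corpus.

    Reference samples draw their latitudes from the zone pools given by
    ``zone_mix`` (|lat| >= 66 polar, 23–66 temperate, < 23 tropical), with
    a repeated-station time series (one rounded coordinate, many samples)
    to exercise geographic deduplication.  Each study taxon present in the
    reference gets one reference ASV whose sequence is an exact copy, a
    truncation, or an extension of the study sequence; planted ecotype
    taxa always get exact copies so the single differing site is never
    trimmed away.  Occurrence is Bernoulli: ``home_rate`` inside the
    taxon's true zone, ``stray_rate`` outside.

    Returns (reference sequence table, occurrence table).
    """
    rng = np.random.default_rng([config.seed, 17])
    zones_present = {truth.zone[a] for a in truth.zone
                     if truth.in_reference.get(a, False)}
    for z, m in zip(ZONES, config.zone_mix):
        if m == 0 and z in zones_present:
            raise ConfigurationError(
                f"zone_mix assigns no reference samples to zone {z!r} "
                f"but the study contains a {z} taxon")

    # --- reference samples ----------------------------------------------
    n_ts = min(30, max(2, config.n_ref_samples // 10))
    ts_zone = next(z for z, m in zip(ZONES, config.zone_mix) if m > 0)
    sample_rows = []
    for i in range(config.n_ref_samples):
        sid = f"REFS_{i:04d}"
        if i < n_ts:
            # repeated station: jitter below the 0.1 degree dedup precision
            lat = _TS_STATION[ts_zone] + float(rng.uniform(-0.02, 0.02))
            lon = -68.50 + float(rng.uniform(-0.02, 0.02))
            zone, ds = ts_zone, "DS_TS"
        else:
            zone = str(rng.choice(ZONES, p=config.zone_mix))
            lo, hi = _ZONE_LAT[zone]
            lat = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            lon = float(rng.uniform(-180, 180))
            ds = f"DS_{int(rng.integers(1, 6)):02d}"
        sample_rows.append({"sample_id": sid, "dataset_id": ds, "zone": zone,
                            "latitude": round(lat, 4), "longitude": round(lon, 4)})
    ref_samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # --- reference sequences ---------------------------------------------
    ecotype_members = {a for pair in truth.ecotype_pairs for a in pair[:2]}
    seq_rows = []
    alphabet = np.array(list("ACGT"))
    for asv in asv_table.index:
        if not truth.in_reference[asv]:
            continue
        seq = asv_table.at[asv, "sequence"]
        if asv in ecotype_members:
            variant = "exact"
        else:
            variant = str(rng.choice(["exact", "trunc", "extend"], p=(0.4, 0.4, 0.2)))
        if variant == "trunc" and len(seq) > 160:
            t1 = int(rng.integers(5, 41))
            t2 = int(rng.integers(5, 41))
            out = seq[t1:len(seq) - t2]
        elif variant == "extend":
            left = "".join(alphabet[rng.integers(0, 4, size=int(rng.integers(5, 26)))])
            right = "".join(alphabet[rng.integers(0, 4, size=int(rng.integers(5, 26)))])
            out = left + seq + right
        else:
            out = seq
        seq_rows.append({"ref_asv_id": asv.replace("ASV", "REF"),
                         "study_asv_id": asv, "sequence": out})
    ref_seqs = pd.DataFrame(seq_rows).set_index("ref_asv_id")

    # --- occurrences ------------------------------------------------------
    occ_rows = []
    zone_arr = ref_samples["zone"].to_numpy()
    for rid, row in ref_seqs.iterrows():
        tz = truth.zone[row["study_asv_id"]]
        p = np.where(zone_arr == tz, config.home_rate, config.stray_rate)
        hits = rng.random(len(ref_samples)) < p
        for sid in ref_samples.index[hits]:
            s = ref_samples.loc[sid]
            occ_rows.append({"ref_asv_id": rid, "sample_id": sid,
                             "dataset_id": s["dataset_id"],
                             "latitude": s["latitude"], "longitude": s["longitude"]})
    occurrences = pd.DataFrame(
        occ_rows, columns=["ref_asv_id", "sample_id", "dataset_id",
                           "latitude", "longitude"])
    return ref_seqs, occurrences
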