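"""Simulate the ice-camp study and the global reference corpus.

Emits the study ASV table (sequences, taxonomy, counts), the sample
metadata over the full design grid (2 ice layers + 4 water layers, three
size fractions, nine dates across the three bloom stages), the reference
sequences/occurrences, and the planted-truth file used by later checks.
"""

import json
import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_config

from icebloom.pipeline_io import FILES, stage_simulate
from icebloom.synthetic_data import PlantedTruth

logging.basicConfig(level=logging.INFO, stream=sys.stderr)

cfg = run_config()
stage_simulate(cfg)
out = Path(cfg.outdir)
truth = PlantedTruth.from_json((out / FILES["truth"]).read_text())
n_photo = sum(truth.photosynthetic.values())
print(f"simulated {len(truth.zone)} ASVs ({n_photo} photosynthetic, "
      f"{len(truth.ecotype_pairs)} single-mismatch ecotype pairs)")
zones = {}
for z in truth.zone.values():
    zones[z] = zones.get(z, 0) + 1
print("planted latitudinal labels:", json.dumps(zones, sort_keys=True))
print(f"artifacts in {cfg.outdir}")
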