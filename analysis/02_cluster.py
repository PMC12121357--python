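"""Cluster study ASVs with the reference by exact overlap identity.

A study ASV merges with reference ASVs only when the sequences agree at
100% identity over an overlap of at least 100 nt; matching clusters of
reference ASVs are merged transitively first.  Study-only ASVs stay
singletons, so single-base-pair ecotypes remain separate cASVs.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_config

from icebloom.pipeline_io import stage_cluster

logging.basicConfig(level=logging.INFO, stream=sys.stderr)

cfg = run_config()
assign = stage_cluster(cfg)
n_study = len(assign.study_to_casv)
matched = sum(1 for s, c in assign.study_to_casv.items() if s != c)
print(f"{n_study} study ASVs -> {len(set(assign.study_to_casv.values()))} "
      f"cASVs; {matched} matched a reference cluster, "
      f"{n_study - matched} are unique to the study")
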