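"""Indicator-species screen of the most abundant photosynthetic ASVs.

For the substrate (ice vs water) and bloom-phase (dark = stage I vs
light = stages II + III) contrasts, computes the group-size-corrected
IndVal statistic sqrt(A*B) on relative abundances for the 20 most
abundant photosynthetic ASVs and its permutation p-value.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_config

from icebloom.pipeline_io import stage_indicators

logging.basicConfig(level=logging.INFO, stream=sys.stderr)

cfg = run_config()
res = stage_indicators(cfg)
sig = res[res["p"] < 0.05]
for comp, grp in sig.groupby("comparison"):
    print(f"{comp}: {len(grp)} significant indicator ASVs")
    for _, row in grp.iterrows():
        print(f"  {row['asv_id']}  -> {row['group']:6s} "
              f"stat={row['stat']:.3f} p={row['p']:.4g} {row['stars']}")
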