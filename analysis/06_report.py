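"""Biogeography composition per substrate, size fraction and bloom stage.

Combines the cASV categories with the photosynthetic read counts into
per-panel read fractions (each panel sums to 1, unallocated included),
the tabular counterpart of a stacked category-composition figure.
"""

import logging
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import run_config

from icebloom.pipeline_io import stage_report

logging.basicConfig(level=logging.INFO, stream=sys.stderr)

cfg = run_config()
report = stage_report(cfg)
for panel, fr in sorted(report["category_read_fractions"].items()):
    top = sorted(fr.items(), key=lambda kv: -kv[1])[:2]
    desc = ", ".join(f"{c} {100 * v:.0f}%" for c, v in top if v > 0)
    print(f"{panel:24s} {desc}")
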