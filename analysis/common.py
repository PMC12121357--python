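"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same run directory (results/analysis by
default) so each step consumes the artifacts of the previous one.
"""

import argparse

from icebloom.pipeline_io import RunConfig
from icebloom.synthetic_data import SimConfig


def run_config() -> RunConfig:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/analysis")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    return RunConfig(outdir=args.outdir, seed=args.seed,
                     sim=SimConfig(seed=args.seed))
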