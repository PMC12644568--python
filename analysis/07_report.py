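#!/usr/bin/env python
"""Collect every stage's outputs into a markdown run report."""

import argparse
from pathlib import Path

from splicespan.io_formats import Config
from splicespan.pipeline import run_pipeline
from splicespan.synthetic_data import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", default="results/pipeline")
    args = parser.parse_args()
    out = run_pipeline(
        args.out_dir,
        SimConfig(seed=args.seed),
        Config(seed=args.seed),
        stages=["report"],
    )
    print((Path(out) / "report.md").read_text())


if __name__ == "__main__":
    main()
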