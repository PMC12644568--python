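#!/usr/bin/env python
"""Map event regions across species by local alignment against the anchor
species and define the conserved event set (accepted in >= 10 species)."""

import argparse

from splicespan.io_formats import Config, read_table
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
        stages=["homology"],
    )
    calls = read_table(out / "homology_calls.tsv", index_col=None)
    conserved = read_table(out / "conserved_events.tsv", index_col=None)
    acc = calls["accepted"].mean()
    print(f"homology calls: {len(calls)} ({acc:.0%} accepted)")
    print(f"conserved events (>= 10 species): {len(conserved)}")


if __name__ == "__main__":
    main()
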