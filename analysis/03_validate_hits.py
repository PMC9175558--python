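#!/usr/bin/env python
"""Validate hits for strain/medium selectivity.

Runs the 4-strain x 2-media validation assay (4 technical replicates,
treated vs untreated) for a planted suppressor and a sulfate-bypass
compound, converts 24 h endpoints to percent growth change with propagated
errors, and classifies each compound's selectivity pattern.
"""

import argparse

from suppscreen.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed, out_dir=args.out)
    state = run_pipeline(config, stages=("validate",))
    print(state["validation"].to_string(index=False))


if __name__ == "__main__":
    main()
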