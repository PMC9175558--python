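#!/usr/bin/env python
"""Score the screen and call hits.

Computes the per-compound, per-timepoint screening Z statistic against each
plate's pooled vehicle controls (mock-s.d. rule for single wells), calls
hits at Z > 0 for >= 6 of 7 reads with growth stimulation, applies the
sulfate-formulation and colored-solution exclusions, and writes the ranked
hit report.
"""

import argparse

from suppscreen.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    config = PipelineConfig(seed=args.seed, out_dir=args.out)
    state = run_pipeline(config, stages=("score", "hits"))
    report = state["hit_report"]
    hits = report[report["is_hit"]]
    excluded = report[report["excluded"] & (report["n_positive"] >= config.min_positive)]
    print(f"{len(hits)} hits of {len(report)} compounds "
          f"({len(excluded)} positives removed by formulation exclusions)")
    print(hits.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
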