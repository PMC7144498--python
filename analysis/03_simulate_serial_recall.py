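#!/usr/bin/env python
"""Simulate the serial-recall experiments with the chunk-atomic primacy model.

Runs the six-word and seven-word triple designs through the full pipeline at
the model's standard operating point: writes corpora, serial-position score
tables, chunk-cohesion-by-starting-position tables (the all-or-none
consequence of treating a triple as one item), and the diagnostic verdict.
"""

import argparse
from pathlib import Path

from chunkrecall import RunConfig, report, run
from chunkrecall.synthdata import compression_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/simulation"))
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--participants", type=int, default=28)
    parser.add_argument("--trials", type=int, default=24, help="trials per condition per participant")
    parser.add_argument("--plots", action="store_true")
    args = parser.parse_args()

    for template in ("exp5-triples-6", "exp6-triples-7"):
        cfg = RunConfig(
            template=template,
            generator=compression_config(
                master_seed=args.seed,
                n_participants=args.participants,
                trials_per_condition=args.trials,
            ),
            schemes=("strict", "item", "LD"),
            make_plots=args.plots,
        )
        bundle = run(cfg, args.out / template)
        print(f"=== {template} ===")
        print(report(bundle))
        coh = bundle["cohesion"][3]
        print(
            "Triple recall is all-or-none by construction: "
            f"P(all three | any) = {coh.pooled:.3f} at every starting position."
        )
        print()
    print(f"Artifacts under {args.out}/")


if __name__ == "__main__":
    main()
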