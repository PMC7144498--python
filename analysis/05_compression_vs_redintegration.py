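#!/usr/bin/env python
"""Can the two accounts of chunking be told apart from the data they generate?

Generates one serial-recall corpus under each generating process
(compression: chunks are single storage units; redintegration: word-by-word
trace plus chunk-completion repair), runs the diagnostic contrast on both,
and checks the 2AFC recognition pattern of the calibrated redintegration
generator (pairs ~.80, singletons ~.73, flat across list compositions).
"""

import argparse
import json
from pathlib import Path

from chunkrecall import (
    diagnostic_contrast,
    generate_2afc_corpus,
    generate_recall_corpus,
    score_corpus,
)
from chunkrecall.design import parse_spec
from chunkrecall.io import write_table
from chunkrecall.pipeline import template_designs
from chunkrecall.synthdata import compression_config, exp1_redintegration_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/diagnostic"))
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--trials", type=int, default=2000, help="trials per condition")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    designs = [(parse_spec(l), None) for l in ("1111111", "11113", "133")]
    configs = {
        "compression": compression_config(
            master_seed=args.seed, n_participants=1, trials_per_condition=args.trials
        ),
        "redintegration": exp1_redintegration_config(
            master_seed=args.seed + 1,
            n_participants=1,
            trials_per_condition=args.trials,
        ).replace(completion_prob=0.8),
    }
    verdicts = {}
    for name, cfg in configs.items():
        corpus = generate_recall_corpus(cfg, designs)
        scores = score_corpus(corpus.pairs(), "item", trial_ids=corpus.trial_ids())
        rep = diagnostic_contrast(scores, seed=args.seed)
        verdicts[name] = {
            "verdict": rep.verdict,
            "singleton_trend": rep.singleton_trend,
            "trend_ci": list(rep.trend_ci),
            "chunk_advantage": rep.chunk_advantage,
        }
        write_table(rep.condition_means, args.out / f"{name}_means.csv", cfg.master_seed)
        print(f"{name}: {rep.verdict}")
        print(
            f"  singleton trend (most vs fewest chunks) {rep.singleton_trend:+.3f}, "
            f"99% CI [{rep.trend_ci[0]:+.3f}, {rep.trend_ci[1]:+.3f}]; "
            f"chunk-member advantage {rep.chunk_advantage:+.3f}"
        )

    cfg = exp1_redintegration_config(master_seed=args.seed + 2)
    probes = generate_2afc_corpus(cfg, template_designs("exp3-pairs-7"))
    acc = (
        probes.groupby(["condition", "word_class"])["correct"].mean().unstack()
    )
    write_table(acc.reset_index(), args.out / "twoafc_accuracy.csv", cfg.master_seed)
    print("\n2AFC recognition accuracy (redintegration generator):")
    print(acc.round(3).to_string())
    print(
        "Pairs stay near .80 and singletons near .73 in every composition: "
        "the benefit of chunking is confined to the chunks themselves."
    )
    (args.out / "verdicts.json").write_text(json.dumps(verdicts, indent=2))
    print(f"Artifacts under {args.out}/")


if __name__ == "__main__":
    main()
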