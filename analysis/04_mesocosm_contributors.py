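#!/usr/bin/env python
"""Estimate the number of contributors per mesocosm under every filtering scheme.

For each of the twelve mesocosms, the masked-allele likelihood is
maximised over x = 1..100 for (a) the tissue-derived allele sets (union
of member genotypes) and (b) the eDNA-derived allele sets filtered at
fixed read-frequency thresholds 0.001 / 0.01 / 0.1 and at the
richness-variable threshold -- each under population frequencies from
the 58 genotyped fish and from combined eDNA reads.  Writes the estimate
and bias tables and prints the bias-by-scheme summary.
"""

import argparse
from pathlib import Path

from ednamix.experiments import (
    RunConfig, run_mesocosm_experiment, run_study, write_manifest,
)
from ednamix.simulate import SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/mesocosm"))
    args = ap.parse_args()

    cfg = RunConfig(sim=SimulationConfig(seed=args.seed), seed=args.seed,
                    outdir=str(args.outdir))
    study = run_study(cfg)
    estimates, bias = run_mesocosm_experiment(study, cfg)

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    estimates.to_csv(out / "estimates.csv", index=False)
    bias.to_csv(out / "bias.csv", index=False)
    write_manifest(out, cfg, {"experiment": "mesocosm",
                              "excluded_loci": study.excluded_loci})

    tissue = estimates[estimates["profile"] == "tissue"]
    print(f"tissue-derived profiles: max |bias| = "
          f"{tissue['bias'].abs().max()} contributors")
    edna = bias[bias["profile"] == "eDNA"]
    for scheme, grp in edna.groupby("scheme"):
        by_x = {int(r.true_x): round(r.mean_bias, 2) for r in grp.itertuples()
                if r.freq_source == "tissue-genotypes"}
        print(f"eDNA profiles, {scheme:12s} mean bias by density: {by_x}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
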