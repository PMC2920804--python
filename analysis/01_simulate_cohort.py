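#!/usr/bin/env python
"""Simulate the synthetic study cohort: 132 subjects, 39 BV-diagnosed women
treated with metronidazole and re-sampled at 2/5/15/25 weeks, plus a
read-level FASTQ batch for the first 10 samples.

Writes results/simulate/{cohort.tsv,truth.tsv,panel.fasta,reads_R*.fastq}.
"""
import argparse

from vagv6 import workflow

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

info = workflow.simulate_stage("results/simulate", seed=args.seed,
                               fastq_samples=10, fastq_depth=20000,
                               error_rate=0.005)
print(f"simulated {info['n_samples']} samples "
      f"(132 baseline + 39 subjects x 4 follow-up visits)")
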