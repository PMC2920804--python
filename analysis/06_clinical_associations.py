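#!/usr/bin/env python
"""Clinical associations: Kendall tau + KL strength of the lactobacilli
fractions against pH, Nugent and the Amsel criteria, and C4.5-style decision
trees predicting pH class and odor from taxon proportions.
"""
import argparse

import pandas as pd

from vagv6 import workflow

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

workflow.associate_stage("results/associate", "results/simulate/cohort.tsv")
rep = pd.read_csv("results/associate/association_table.tsv", sep="\t")
print(rep.to_string(index=False))
trees = workflow.tree_stage("results/tree", "results/simulate/cohort.tsv",
                            seed=args.seed)
for name, r in trees.items():
    print(f"{name} tree: training accuracy {r['training_accuracy']:.3f}, "
          f"10-fold CV {r['cv_accuracy']:.3f}")
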