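#!/usr/bin/env python
"""Per-sample Shannon diversity and richness coverage: how much of each
community's expected OTU richness (rarefaction / ACE / Chao1) the sequencing
depth captured. Writes the coverage census grid.
"""
import pandas as pd

from vagv6 import workflow

workflow.diversity_stage("results/diversity", "results/simulate/cohort.tsv")
census = pd.read_csv("results/diversity/coverage_census.tsv", sep="\t",
                     index_col=0)
print(census.to_string())
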