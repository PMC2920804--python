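#!/usr/bin/env python
"""Filter ISUs at >1% per-sample abundance, cluster at 95% identity into
OTUs, build the ISU neighbor-joining tree, and assign taxonomy against the
panel reference. With PCR errors at <=1% the OTU count equals the number of
source taxa: the 95% cutoff absorbs the error cloud around each seed.
"""
from vagv6 import workflow

info = workflow.otu_stage("results/otu", "results/demux/isu.tsv")
print(f"built {info['n_otus']} OTUs")
cls = workflow.classify_stage("results/classify", "results/otu/seeds.fasta")
print(f"assigned taxonomy to {cls['n_assigned']} seeds")
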