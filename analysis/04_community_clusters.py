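#!/usr/bin/env python
"""Community state typing over the full cohort table: Fisher-Rao angular
distances between sample compositions, the sample neighbor-joining tree,
and major clusters (>10 samples) by average-linkage agglomeration.
"""
from vagv6 import workflow

info = workflow.profile_stage("results/profile",
                              "results/simulate/cohort.tsv")
print(f"{info['n_major_clusters']} major community clusters "
      "(see results/profile/clusters.tsv)")
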