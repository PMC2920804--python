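#!/usr/bin/env python
"""Metronidazole response: per-subject cluster trajectories, the transition
network across visits, BV persistence at week 2, the L. iners abundance
shift, and diversity grouped by visit week and Nugent category.
"""
import json

from vagv6 import workflow

info = workflow.longitudinal_stage("results/longitudinal",
                                   "results/simulate/cohort.tsv",
                                   "results/profile/clusters.tsv")
print(json.dumps(info, indent=2))
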