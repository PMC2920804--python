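"""Stage drivers: each function runs one pipeline stage from/to flat files
so stages can be chained (the `run` umbrella) or executed independently.

Artifacts are plain TSV/FASTA/Newick so every hand-off is inspectable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, demux, diversity, dtree, longitudinal, otu, profiles
from . import synthetic, taxonomy

log = logging.getLogger("vagv6")

LACTO_MAP = {"L. iners": "Lactobacillus iners",
             "L. crispatus": "Lactobacillus crispatus"}


def simulate_stage(outdir: Path, seed: int, n_subjects: int = 132,
                   n_followed: int = 39, fastq_samples: int = 0,
                   fastq_depth: int = 20000, error_rate: float = 0.005
                   ) -> dict:
    """Simulate the cohort ground truth (and optionally a read-level FASTQ
    batch for the first ``fastq_samples`` baseline samples)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = synthetic.SimulationConfig(n_subjects=n_subjects,
                                        n_followed=n_followed, seed=seed)
    panel = synthetic.default_panel()
    cohort, truth = synthetic.simulate_cohort(config, panel=panel)
    synthetic.write_cohort_table(cohort, outdir / "cohort.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "panel.fasta", "w") as fh:
        for t in panel:
            fh.write(f">{t.name.replace(' ', '_')}\n{t.v6_sequence}\n")
    log.info("simulated %d samples (%d subjects, %d followed)",
             len(cohort), n_subjects, n_followed)
    if fastq_samples:
        rng = np.random.default_rng(seed + 1)
        scheme = demux.BarcodeScheme()
        names = [t.name for t in panel]
        sub = cohort.df.head(fastq_samples)
        comps = sub[names].to_numpy(float)
        comps = comps / comps.sum(axis=1, keepdims=True)
        synthetic.simulate_fastq_run(
            comps, panel, [fastq_depth] * len(sub), error_rate, scheme, rng,
            outdir / "reads_R1.fastq", outdir / "reads_R2.fastq",
            outdir / "sample_map.tsv", sample_ids=sub["sample_id"].tolist())
        log.info("wrote FASTQ batch: %d samples x %d reads",
                 len(sub), fastq_depth)
    return {"n_samples": len(cohort)}


def demux_stage(outdir: Path, r1, r2, sample_map_path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = demux.BarcodeScheme()
    mapping = demux.read_sample_map(sample_map_path)
    res = demux.demultiplex(r1, r2, scheme, mapping)
    res.isu.to_tsv(outdir / "isu.tsv")
    with open(outdir / "demux_log.json", "w") as fh:
        json.dump({"assigned": res.assigned,
                   "rejections": dict(res.rejections),
                   "total": res.total}, fh, indent=2)
    log.info("demux: %d/%d pairs assigned", res.assigned, res.total)
    return {"assigned": res.assigned, "total": res.total}


def otu_stage(outdir: Path, isu_path, identity_threshold: float = 0.95,
              abundance_floor: float = 0.01) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    isu = demux.ISUTable.from_tsv(isu_path)
    params = otu.ClusteringParams(identity_threshold, abundance_floor)
    otus = otu.cluster_isus(isu, params)
    table = otu.otu_table(otus)
    table.to_csv(outdir / "otu_table.tsv", sep="\t")
    otu.write_seed_fasta(otus, outdir / "seeds.fasta")
    otu.write_membership(otus, outdir / "membership.tsv")
    seqs = [o.seed_sequence for o in otus]
    if len(seqs) >= 3:
        tree = otu.isu_nj_tree(seqs, [o.id for o in otus])
        (outdir / "isu_tree.nwk").write_text(str(tree))
    log.info("clustered %d ISUs into %d OTUs", len(isu.sequences()), len(otus))
    return {"n_otus": len(otus)}


def classify_stage(outdir: Path, seeds_fasta, ref_fasta=None,
                   ref_lineage=None) -> dict:
    """Assign OTU seeds; defaults to the synthetic panel as reference."""
    from Bio import SeqIO

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ref_fasta is not None:
        reference = taxonomy.read_reference(ref_fasta, ref_lineage)
    else:
        reference = taxonomy.panel_reference(synthetic.default_panel())
    seeds = [(r.id, str(r.seq).upper())
             for r in SeqIO.parse(str(seeds_fasta), "fasta")]
    assignments = {sid: taxonomy.assign(sid, seq, reference)
                   for sid, seq in seeds}
    taxonomy.write_assignments(assignments, outdir / "assignments.tsv")
    return {"n_assigned": len(assignments)}


def profile_stage(outdir: Path, cohort_path,
                  linkage_cutoff: float = profiles.DEFAULT_LINKAGE_CUTOFF
                  ) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_cohort_table(cohort_path)
    props = profiles.to_proportions(cohort.counts)
    dm = profiles.distance_matrix(props)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        outdir / "distance_matrix.tsv", sep="\t")
    tree = profiles.sample_nj_tree(dm)
    (outdir / "sample_tree.nwk").write_text(str(tree))
    clusters = profiles.extract_clusters(dm, props, linkage_cutoff)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t")
    n_major = clusters.loc[clusters["cluster"] != "minor", "cluster"].nunique()
    log.info("%d major clusters; %d samples minor", n_major,
             int((clusters["cluster"] == "minor").sum()))
    return {"n_major_clusters": int(n_major)}


def diversity_stage(outdir: Path, cohort_path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_cohort_table(cohort_path)
    counts = cohort.counts
    per_sample = pd.DataFrame(
        [diversity.richness_summary(row.to_numpy())
         for _, row in counts.iterrows()], index=counts.index)
    per_sample["shannon"] = diversity.diversity_table(counts)
    per_sample.to_csv(outdir / "richness.tsv", sep="\t")
    census = diversity.coverage_census(counts)
    census.to_csv(outdir / "coverage_census.tsv", sep="\t")
    return {"census": census.to_dict()}


def associate_stage(outdir: Path, cohort_path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_cohort_table(cohort_path)
    report = assoc.lactobacilli_association_table(cohort, LACTO_MAP)
    report.to_csv(outdir / "association_table.tsv", sep="\t", index=False)
    return {"n_rows": len(report)}


def tree_stage(outdir: Path, cohort_path, seed: int = 0) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_cohort_table(cohort_path)
    reports = dtree.ph_odor_trees(cohort, seed=seed)
    out = {}
    for name, rep in reports.items():
        (outdir / f"tree_{name}.txt").write_text(rep.rendering)
        out[name] = {"training_accuracy": rep.training_accuracy,
                     "cv_accuracy": rep.cv_accuracy}
    with open(outdir / "tree_report.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def longitudinal_stage(outdir: Path, cohort_path, clusters_path=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.read_cohort_table(cohort_path)
    clusters = (pd.read_csv(clusters_path, sep="\t", index_col=0)
                if clusters_path else None)
    traj = longitudinal.build_trajectories(cohort, clusters)
    traj.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    net = longitudinal.transition_network(traj)
    with open(outdir / "transitions.tsv", "w") as fh:
        fh.write("from\tto\tweight\n")
        for a, b, d in net.edges(data=True):
            fh.write(f"{a}\t{b}\t{d['weight']}\n")
    persistence = longitudinal.bv_persistence(cohort, followup_code=2)
    screen = longitudinal.abundance_shift_screen(cohort)
    screen.to_csv(outdir / "abundance_shifts.tsv", sep="\t", index=False)
    div = longitudinal.diversity_by_timepoint(cohort)
    div.to_csv(outdir / "diversity_by_group.tsv", sep="\t", index=False)
    iners = longitudinal.abundance_shift(cohort, LACTO_MAP["L. iners"])
    out = {"bv_persistence_week2_pct": persistence,
           "liners_median_before": iners["median_before"],
           "liners_median_after": iners["median_after"],
           "liners_p": iners["p_value"]}
    with open(outdir / "longitudinal_summary.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def run_all(outdir: Path, seed: int, n_subjects: int = 132,
            n_followed: int = 39, fastq_samples: int = 6,
            fastq_depth: int = 5000) -> dict:
    """End-to-end: simulate, (read-level demux + OTU + taxonomy on a small
    FASTQ batch), then the table-level analyses on the full cohort."""
    outdir = Path(outdir)
    summary = {}
    summary["simulate"] = simulate_stage(outdir / "simulate", seed,
                                         n_subjects, n_followed,
                                         fastq_samples, fastq_depth)
    if fastq_samples:
        sim = outdir / "simulate"
        summary["demux"] = demux_stage(outdir / "demux", sim / "reads_R1.fastq",
                                       sim / "reads_R2.fastq",
                                       sim / "sample_map.tsv")
        summary["otu"] = otu_stage(outdir / "otu", outdir / "demux" / "isu.tsv")
        summary["classify"] = classify_stage(outdir / "classify",
                                             outdir / "otu" / "seeds.fasta")
    cohort_path = outdir / "simulate" / "cohort.tsv"
    summary["profile"] = profile_stage(outdir / "profile", cohort_path)
    summary["diversity"] = diversity_stage(outdir / "diversity", cohort_path)
    summary["associate"] = associate_stage(outdir / "associate", cohort_path)
    summary["tree"] = tree_stage(outdir / "tree", cohort_path, seed=seed)
    summary["longitudinal"] = longitudinal_stage(
        outdir / "longitudinal", cohort_path,
        outdir / "profile" / "clusters.tsv")
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
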