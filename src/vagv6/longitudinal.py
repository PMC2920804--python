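"""Antibiotic-response analytics over the followed sub-cohort.

Follow-up codes in the cohort table are 0 (baseline, not followed),
1 (baseline, followed) and 2-5 (follow-up visits at 2, 5, 15 and 25 weeks).
The module builds per-subject trajectories through the community clusters,
the cluster-to-cluster transition network across consecutive visits, BV
persistence per visit (Nugent >= 7), per-taxon pre/post abundance shifts
with the paired signed-rank test, and Shannon diversity grouped by visit
week and Nugent category.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .assoc import wilcoxon_signed_rank
from .diversity import diversity_table

FOLLOWUP_WEEKS = {1: 0, 2: 2, 3: 5, 4: 15, 5: 25}
MINOR_LABEL = "U"

NUGENT_CATEGORIES = [(0, 3, "normal"), (4, 6, "intermediate"), (7, 10, "BV")]


def nugent_category(score) -> str | float:
    if pd.isna(score):
        return np.nan
    for lo, hi, name in NUGENT_CATEGORIES:
        if lo <= score <= hi:
            return name
    raise ValueError(f"Nugent score {score} out of range")


def build_trajectories(cohort, clusters: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """One row per (followed subject, visit), ordered by week.

    ``clusters`` is the cluster-assignment frame from
    :func:`vagv6.profiles.extract_clusters`; minor/unassigned samples get
    the label ``"U"``. Adds a ``complete`` flag per subject (all visits
    present).
    """
    df = cohort.df
    followed = set(df.loc[df["followup"] == 1, "subject_id"])
    sub = df[df["subject_id"].isin(followed) & (df["followup"] >= 1)].copy()
    dup = sub.duplicated(subset=["subject_id", "followup"])
    if dup.any():
        raise ValueError("duplicate (subject, visit) rows: "
                         f"{sub.loc[dup, 'sample_id'].tolist()}")
    sub["week"] = sub["followup"].map(FOLLOWUP_WEEKS)
    if clusters is not None:
        lab = clusters["cluster"].reindex(sub["sample_id"]).to_numpy()
        sub["cluster"] = ["U" if (pd.isna(c) or c == "minor") else c
                          for c in lab]
    else:
        sub["cluster"] = "U"
    sub["nugent_category"] = sub["nugent"].map(nugent_category)
    h = diversity_table(cohort.counts)
    sub["shannon"] = h.reindex(sub["sample_id"]).to_numpy()
    n_visits = sub.groupby("subject_id")["week"].count()
    full = 1 + len(set(FOLLOWUP_WEEKS) - {1})
    sub["complete"] = sub["subject_id"].map(n_visits >= full)
    out = sub.sort_values(["subject_id", "week"]).reset_index(drop=True)
    return out[["subject_id", "week", "followup", "sample_id", "cluster",
                "nugent", "nugent_category", "shannon", "complete"]]


def transition_network(trajectories: pd.DataFrame,
                       complete_only: bool = True,
                       major_baseline_only: bool = True) -> nx.DiGraph:
    """Directed weighted graph of cluster transitions across consecutive
    visits; edge weight = number of subjects making that move."""
    t = trajectories
    if complete_only:
        t = t[t["complete"]]
    g = nx.DiGraph()
    for _, traj in t.groupby("subject_id"):
        traj = traj.sort_values("week")
        if major_baseline_only and traj.iloc[0]["cluster"] == MINOR_LABEL:
            continue
        labels = traj["cluster"].tolist()
        for a, b in zip(labels, labels[1:]):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def bv_persistence(cohort, followup_code: int = 2,
                   denominator: str = "visited") -> float:
    """Percentage of treated subjects still at Nugent >= 7 at a follow-up.

    Treated subjects are those with baseline code 1 and baseline
    Nugent >= 7. ``denominator="visited"`` divides by the treated subjects
    who have that visit; ``"all"`` divides by all treated subjects.
    """
    df = cohort.df
    base = df[df["followup"] == 1]
    treated = set(base.loc[base["nugent"] >= 7, "subject_id"])
    visit = df[(df["followup"] == followup_code)
               & df["subject_id"].isin(treated)]
    if visit.empty:
        raise ValueError(f"no visits with follow-up code {followup_code}")
    n_bv = int((visit["nugent"] >= 7).sum())
    denom = len(visit) if denominator == "visited" else len(treated)
    return 100.0 * n_bv / denom


def abundance_shift(cohort, taxon: str, from_code: int = 1,
                    to_code: int = 2) -> dict:
    """Median relative abundance of one taxon before vs after treatment,
    with the paired Wilcoxon signed-rank p-value over subjects present at
    both visits."""
    if taxon not in cohort.otu_columns:
        raise ValueError(f"taxon {taxon!r} not in the OTU table")
    df = cohort.df.set_index("sample_id")
    props = cohort.proportions()
    frames = {}
    for code in (from_code, to_code):
        rows = df[df["followup"] == code]
        frames[code] = pd.Series(props.loc[rows.index, taxon].to_numpy(),
                                 index=rows["subject_id"])
    paired = pd.concat([frames[from_code].rename("before"),
                        frames[to_code].rename("after")],
                       axis=1, join="inner").dropna()
    if len(paired) < 2:
        raise ValueError("fewer than 2 paired subjects")
    w, p = wilcoxon_signed_rank(paired["before"], paired["after"])
    return {
        "taxon": taxon,
        "n_pairs": int(len(paired)),
        "median_before": float(paired["before"].median()),
        "median_after": float(paired["after"].median()),
        "w_plus": w,
        "p_value": p,
    }


def abundance_shift_screen(cohort, from_code: int = 1, to_code: int = 2
                           ) -> pd.DataFrame:
    """Pre/post shift for every taxon (taxa without enough nonzero paired
    differences are reported with NaN p)."""
    rows = []
    for taxon in cohort.otu_columns:
        try:
            rows.append(abundance_shift(cohort, taxon, from_code, to_code))
        except ValueError:
            rows.append({"taxon": taxon, "n_pairs": 0,
                         "median_before": np.nan, "median_after": np.nan,
                         "w_plus": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)


def diversity_by_timepoint(cohort) -> pd.DataFrame:
    """Median/IQR Shannon diversity per follow-up week and per Nugent
    category (empty groups are omitted with a warning)."""
    df = cohort.df.copy()
    h = diversity_table(cohort.counts)
    df["shannon"] = h.reindex(df["sample_id"]).to_numpy()
    rows = []
    followed = set(df.loc[df["followup"] == 1, "subject_id"])
    for code, week in FOLLOWUP_WEEKS.items():
        grp = df[(df["followup"] == code) & df["subject_id"].isin(followed)]
        if grp.empty:
            warnings.warn(f"no samples at follow-up code {code}; omitted",
                          stacklevel=2)
            continue
        rows.append({"grouping": "week", "group": f"week {week}",
                     "n": len(grp),
                     "median_h": float(grp["shannon"].median()),
                     "q1": float(grp["shannon"].quantile(0.25)),
                     "q3": float(grp["shannon"].quantile(0.75))})
    df["nugent_category"] = df["nugent"].map(nugent_category)
    for _, _, name in NUGENT_CATEGORIES:
        grp = df[df["nugent_category"] == name]
        if grp.empty:
            warnings.warn(f"no samples in Nugent category {name}; omitted",
                          stacklevel=2)
            continue
        rows.append({"grouping": "nugent", "group": name, "n": len(grp),
                     "median_h": float(grp["shannon"].median()),
                     "q1": float(grp["shannon"].quantile(0.25)),
                     "q3": float(grp["shannon"].quantile(0.75))})
    return pd.DataFrame(rows)
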