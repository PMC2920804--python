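"""OTU construction: abundance filtering, greedy seed-based clustering of
identical sequence units (ISUs), and the ISU neighbor-joining tree used to
justify the identity cutoff.

Identity between two sequences is edit-distance based:
``1 - Levenshtein(a, b) / max(len(a), len(b))``; at the default 95% cutoff
two 60-nt V6 sequences may differ by up to three substitutions and still
fall in one OTU, which is what absorbs PCR-induced errors into the taxon
cluster of their template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .demux import ISUTable


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = 0.95
    abundance_floor: float = 0.01  # per-sample max relative abundance, strict >

    def __post_init__(self):
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must be in (0.5, 1]")
        if not 0 <= self.abundance_floor < 1:
            raise ValueError("abundance floor must be in [0, 1)")


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def identity(a: str, b: str) -> float:
    """Edit-distance identity with the longer sequence as denominator."""
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def abundance_filter(isu: ISUTable, floor: float = 0.01) -> ISUTable:
    """Retain an ISU iff its relative abundance exceeds ``floor`` (strictly)
    in at least one sample."""
    totals = {s: isu.total(s) for s in isu.counts}
    keep = set()
    for s, counter in isu.counts.items():
        t = totals[s]
        for seq, n in counter.items():
            if n / t > floor:
                keep.add(seq)
    out = ISUTable()
    for s, counter in isu.counts.items():
        for seq, n in counter.items():
            if seq in keep:
                out.add(s, seq, n)
    return out


@dataclass
class OTU:
    id: str
    seed_sequence: str
    member_sequences: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)  # sample -> reads

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def greedy_cluster(isu: ISUTable, params: ClusteringParams | None = None
                   ) -> list[OTU]:
    """Greedy abundance-sorted seed clustering.

    ISUs are visited in decreasing total-count order (ties broken
    lexicographically by sequence); each joins the first already-founded
    seed within the identity threshold, else founds a new OTU with itself as
    seed. Deterministic by construction.
    """
    params = params or ClusteringParams()
    totals = isu.total_by_sequence()
    order = sorted(totals, key=lambda s: (-totals[s], s))
    otus: list[OTU] = []
    assignment: dict[str, OTU] = {}
    for seq in order:
        home = None
        for otu in otus:
            if identity(seq, otu.seed_sequence) >= params.identity_threshold:
                home = otu
                break
        if home is None:
            home = OTU(id=f"OTU_{len(otus) + 1}", seed_sequence=seq)
            otus.append(home)
        home.member_sequences.append(seq)
        assignment[seq] = home
    for sample, counter in isu.counts.items():
        for seq, n in counter.items():
            otu = assignment[seq]
            otu.counts[sample] = otu.counts.get(sample, 0) + n
    return otus


def cluster_isus(isu: ISUTable, params: ClusteringParams | None = None
                 ) -> list[OTU]:
    """Abundance filter followed by greedy clustering (the standard path)."""
    params = params or ClusteringParams()
    return greedy_cluster(abundance_filter(isu, params.abundance_floor),
                          params)


def otu_table(otus: list[OTU], samples: list[str] | None = None
              ) -> pd.DataFrame:
    """Samples x OTUs integer count matrix (column order = founding order)."""
    if samples is None:
        samples = sorted({s for o in otus for s in o.counts})
    data = {o.id: [o.counts.get(s, 0) for s in samples] for o in otus}
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"),
                        dtype=int)


def isu_distance_matrix(sequences: list[str], ids: list[str] | None = None):
    """Pairwise Levenshtein distance matrix as a scikit-bio DistanceMatrix."""
    from skbio import DistanceMatrix

    n = len(sequences)
    ids = ids or [f"ISU_{i}" for i in range(n)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = levenshtein(sequences[i], sequences[j])
    return DistanceMatrix(mat, ids)


def isu_nj_tree(sequences: list[str], ids: list[str] | None = None):
    """Neighbor-joining (Saitou-Nei) tree over ISU Levenshtein distances.

    Returns a ``skbio.TreeNode``; serialize with ``str(tree)`` (Newick).
    """
    if len(sequences) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    from skbio.tree import nj

    return nj(isu_distance_matrix(sequences, ids))


def write_seed_fasta(otus: list[OTU], path) -> None:
    with open(path, "w") as fh:
        for o in otus:
            fh.write(f">{o.id}\n{o.seed_sequence}\n")


def write_membership(otus: list[OTU], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tsequence\tis_seed\n")
        for o in otus:
            for seq in o.member_sequences:
                fh.write(f"{o.id}\t{seq}\t{int(seq == o.seed_sequence)}\n")
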