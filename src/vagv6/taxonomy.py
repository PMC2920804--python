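"""Taxonomic assignment of OTU seed sequences against a local reference.

Each seed is searched against a reference collection (FASTA + lineage
table); the best hit labels the OTU when it is unambiguous at 100% identity
and coverage, ties are resolved to the lowest common lineage rank, and a
fallback pass admits environmental/uncultured records only when no cultured
hit reaches >90% identity. Ties at equal identity/coverage prefer records
from complete genomes, then characterized isolates, then environmental
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

SOURCE_PRECEDENCE = {"complete_genome": 0, "characterized_isolate": 1,
                     "environmental_or_uncultured": 2}


@dataclass(frozen=True)
class ReferenceRecord:
    seq_id: str
    sequence: str
    lineage: tuple[str, ...]       # domain ... species (optional strain)
    source_class: str

    def __post_init__(self):
        if not self.lineage:
            raise ValueError("lineage must be nonempty")
        if self.source_class not in SOURCE_PRECEDENCE:
            raise ValueError(f"unknown source class {self.source_class!r}")

    @property
    def label(self) -> str:
        return self.lineage[-1]


@dataclass(frozen=True)
class Hit:
    record: ReferenceRecord
    identity: float
    coverage: float


@dataclass(frozen=True)
class TaxonAssignment:
    otu_id: str
    label: str
    rank: int | None            # index into the lineage, None if unclassified
    best_identity: float
    best_coverage: float
    basis: str                  # which rule fired


def _align(seed: str, reference: str) -> tuple[float, float]:
    """Identity and query coverage of the seed against the best-matching
    reference subsequence (semi-global / infix alignment)."""
    res = edlib.align(seed, reference, mode="HW", task="distance")
    ident = 1.0 - res["editDistance"] / len(seed)
    coverage = min(1.0, len(reference) / len(seed))
    return max(0.0, ident), coverage


def best_hits(seed: str, reference: list[ReferenceRecord]) -> list[Hit]:
    """All hits ranked by (identity, coverage, source-class precedence)."""
    if not reference:
        raise ValueError("empty reference collection")
    hits = [Hit(rec, *_align(seed, rec.sequence)) for rec in reference]
    hits.sort(key=lambda h: (-h.identity, -h.coverage,
                             SOURCE_PRECEDENCE[h.record.source_class],
                             h.record.seq_id))
    return hits


def lowest_common_rank(lineages: list[tuple[str, ...]]) -> tuple[str, int] | None:
    """Deepest rank at which all lineages agree; None if they share nothing."""
    depth = min(len(l) for l in lineages)
    last = None
    for i in range(depth):
        vals = {l[i] for l in lineages}
        if len(vals) == 1:
            last = (vals.pop(), i)
        else:
            break
    return last


def _genus_label(rec: ReferenceRecord) -> tuple[str, int]:
    # genus = next-to-last rank when present, else the last
    if len(rec.lineage) >= 2:
        return rec.lineage[-2], len(rec.lineage) - 2
    return rec.lineage[-1], len(rec.lineage) - 1


def assign(otu_id: str, seed: str, reference: list[ReferenceRecord],
           fallback_identity: float = 0.90) -> TaxonAssignment:
    """Assign a label to one seed using the precedence rules.

    First pass excludes environmental/uncultured records. A single perfect
    (100% identity and coverage) hit gives its species/strain label;
    multiple perfect hits give their lowest common rank. If the cultured
    search tops out at <= ``fallback_identity``, the search is rerun with
    uncultured records included. Otherwise the best imperfect hit labels the
    OTU at genus rank with the identity recorded.
    """
    cultured = [r for r in reference
                if r.source_class != "environmental_or_uncultured"]
    pool = cultured if cultured else reference
    hits = best_hits(seed, pool)
    perfect = [h for h in hits if h.identity == 1.0 and h.coverage == 1.0]
    if len(perfect) == 1:
        h = perfect[0]
        return TaxonAssignment(otu_id, h.record.label,
                               len(h.record.lineage) - 1, 1.0, 1.0, "unique_perfect")
    if perfect:
        common = lowest_common_rank([h.record.lineage for h in perfect])
        if common is not None:
            label, rank = common
            return TaxonAssignment(otu_id, label, rank, 1.0, 1.0, "lca_of_perfect")
        return TaxonAssignment(otu_id, "unclassified", None, 1.0, 1.0,
                               "no_common_rank")
    best = hits[0]
    if best.identity <= fallback_identity and len(pool) < len(reference):
        all_hits = best_hits(seed, reference)
        top = all_hits[0]
        if top.identity > best.identity:
            if top.identity == 1.0 and top.coverage == 1.0:
                return TaxonAssignment(otu_id, top.record.label,
                                       len(top.record.lineage) - 1,
                                       1.0, 1.0, "fallback")
            label, rank = _genus_label(top.record)
            return TaxonAssignment(otu_id, label, rank, top.identity,
                                   top.coverage, "fallback")
        # uncultured records were no better
        label, rank = _genus_label(best.record)
        return TaxonAssignment(otu_id, label, rank, best.identity,
                               best.coverage, "best_imperfect")
    label, rank = _genus_label(best.record)
    return TaxonAssignment(otu_id, label, rank, best.identity, best.coverage,
                           "best_imperfect")


def strain_resolve(members: list[str], otu_label: str,
                   reference: list[ReferenceRecord]) -> dict[str, str]:
    """Give member ISUs strain-level labels when they exactly match a
    reference sequence (as an exact substring); others inherit the OTU label."""
    labels = {}
    for seq in members:
        exact = [r for r in reference if seq in r.sequence]
        strain_hits = sorted({r.label for r in exact})
        if len(strain_hits) == 1:
            labels[seq] = strain_hits[0]
        else:
            labels[seq] = otu_label
    return labels


# ---------------------------------------------------------------------------
# reference I/O and the synthetic-panel reference


def read_reference(fasta_path, lineage_path) -> list[ReferenceRecord]:
    """Reference = FASTA + 3-column lineage TSV
    (seq_id, semicolon-delimited lineage, source_class)."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    with open(lineage_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header[:3] == ["seq_id", "lineage", "source_class"]
        for line in fh:
            sid, lineage, source = line.rstrip("\n").split("\t")[:3]
            out.append(ReferenceRecord(sid, seqs[sid],
                                       tuple(lineage.split(";")), source))
    return out


def panel_reference(panel) -> list[ReferenceRecord]:
    """Build a species-level reference from a synthetic taxon panel."""
    out = []
    for i, t in enumerate(panel):
        genus = t.name.split()[0]
        lineage = ("Bacteria", genus, t.name)
        out.append(ReferenceRecord(f"ref_{i}", t.v6_sequence, lineage,
                                   "characterized_isolate"))
    return out


def assign_all(otus, reference: list[ReferenceRecord]) -> dict[str, TaxonAssignment]:
    return {o.id: assign(o.id, o.seed_sequence, reference) for o in otus}


def write_assignments(assignments: dict[str, TaxonAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlabel\trank\tidentity\tcoverage\tbasis\n")
        for otu_id, a in assignments.items():
            rank = "" if a.rank is None else a.rank
            fh.write(f"{otu_id}\t{a.label}\t{rank}\t{a.best_identity:.4f}\t"
                     f"{a.best_coverage:.4f}\t{a.basis}\n")
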