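"""Barcode/primer demultiplexing of paired V6 amplicon reads.

Each mate must begin with a registered barcode (3-6 nt) immediately followed
by the amplification primer, matched exactly (IUPAC-aware, zero mismatches).
The V6 payload is the sequence past the primer; the reverse mate is
reverse-complemented and must agree with the forward payload base-for-base,
otherwise the pair is rejected as a sequencing-error disagreement. Accepted
payloads accumulate per sample as identical sequence units (ISUs): exact V6
strings with read counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .seqs import IUPAC, iupac_match, revcomp

LEFT_PRIMER = "CAACGCGARGAACCTTACC"
RIGHT_PRIMER = "ACAACACGAGCTGACGAC"

LEFT_BARCODES = (
    "CATGCG", "GCAGT", "TACGT", "GACTGT", "CGTCGA", "GTCGC", "ACGTA",
    "CACTAC", "TGAC", "AGTA", "ATGA", "TGCA", "ACT", "TCG", "GTA", "CTA",
    "TGA", "GCTA",
)
RIGHT_BARCODES = (
    "CGCATG", "ACTGC", "AGCTA", "ACAGTC", "TCGACG", "GCGAC", "TACGT",
    "GTAGTG", "GTCA", "TACT", "TCAT", "TGCA", "AGT", "CGA", "TAC", "TAG",
)

# reject reason codes
NO_LEFT_MATCH = "no_left_match"
NO_RIGHT_MATCH = "no_right_match"
CROSS_TALK = "cross_talk"
MATE_DISAGREEMENT = "mate_disagreement"
LENGTH_OUT_OF_BAND = "length_out_of_band"


@dataclass(frozen=True)
class BarcodeScheme:
    left_barcodes: tuple[str, ...] = LEFT_BARCODES
    right_barcodes: tuple[str, ...] = RIGHT_BARCODES
    left_primer: str = LEFT_PRIMER
    right_primer: str = RIGHT_PRIMER

    def __post_init__(self):
        for side, bcs, primer in (("left", self.left_barcodes, self.left_primer),
                                  ("right", self.right_barcodes, self.right_primer)):
            for bc in bcs:
                if not 3 <= len(bc) <= 6:
                    raise ValueError(f"{side} barcode {bc!r} outside 3-6 nt")
            _check_prefix_collisions(side, bcs, primer)


def _check_prefix_collisions(side: str, barcodes: tuple[str, ...],
                             primer: str) -> None:
    """Reject schemes where a short barcode + the primer's opening bases
    reproduces a longer barcode *and* the primer re-anchors after it, i.e.
    where primer anchoring cannot disambiguate the two.
    """
    for short in barcodes:
        for long in barcodes:
            if long == short or not long.startswith(short):
                continue
            k = len(long) - len(short)
            ext = long[len(short):]
            # A read from the `long` sample starts long + primer. Parsing it
            # as `short` requires ext + primer to start with the primer,
            # i.e. ext matches primer[:k] and the primer is k-periodic.
            if iupac_match(primer[:k], ext) and _periodic(primer, k):
                raise ValueError(
                    f"{side} barcodes {short!r}/{long!r} are ambiguous "
                    f"given the primer")


def _periodic(primer: str, k: int) -> bool:
    # true iff the primer shifted by k against itself still matches
    return all(set(IUPAC[a]) & set(IUPAC[b])
               for a, b in zip(primer, primer[k:]))


def match_read(read: str, barcodes: Iterable[str], primer: str):
    """Locate barcode + primer at the start of ``read``.

    Barcodes are tried longest-first; the first candidate whose following
    bases match the primer exactly (IUPAC-aware) wins. Returns
    ``(barcode, v6_start)`` or ``(None, reason)``.
    """
    by_len: dict[int, set] = {}
    for bc in barcodes:
        by_len.setdefault(len(bc), set()).add(bc)
    for L in sorted(by_len, reverse=True):
        cand = read[:L]
        if cand in by_len[L] and iupac_match(primer, read[L:L + len(primer)]):
            return cand, L + len(primer)
    return None, "no_match"


class ISUTable:
    """Per-sample counts of identical sequence units (exact V6 strings)."""

    def __init__(self, counts: dict[str, Counter] | None = None):
        self.counts: dict[str, Counter] = counts or {}

    def add(self, sample: str, seq: str, n: int = 1) -> None:
        self.counts.setdefault(sample, Counter())[seq] += n

    def samples(self) -> list[str]:
        return sorted(self.counts)

    def total(self, sample: str) -> int:
        return sum(self.counts[sample].values())

    def sequences(self) -> list[str]:
        out = set()
        for c in self.counts.values():
            out.update(c)
        return sorted(out)

    def total_by_sequence(self) -> Counter:
        tot = Counter()
        for c in self.counts.values():
            tot.update(c)
        return tot

    def __eq__(self, other):
        return isinstance(other, ISUTable) and self.counts == other.counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tsequence\tcount\n")
            for s in self.samples():
                for seq, n in sorted(self.counts[s].items()):
                    fh.write(f"{s}\t{seq}\t{n}\n")

    @classmethod
    def from_tsv(cls, path) -> "ISUTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("sample")
            for line in fh:
                s, seq, n = line.rstrip("\n").split("\t")
                table.add(s, seq, int(n))
        return table


@dataclass
class DemuxResult:
    isu: ISUTable
    assigned: int = 0
    rejections: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.assigned + sum(self.rejections.values())


def demultiplex_pairs(pairs: Iterable[tuple[str, str]], scheme: BarcodeScheme,
                      sample_map: dict[tuple[str, str], str],
                      v6_length_band: tuple[int, int] = (50, 80),
                      reject_disagreements: bool = True) -> DemuxResult:
    """Demultiplex an iterable of (forward, reverse) read sequences.

    A pair is assigned only when both mates carry an intact barcode + primer,
    the (left, right) combination is registered in ``sample_map``, the mates'
    V6 reconstructions agree, and the payload length is inside the band.
    Unregistered combinations are tallied as cross-talk.
    """
    res = DemuxResult(ISUTable())
    lo, hi = v6_length_band
    for fwd, rev in pairs:
        lbc, lpos = match_read(fwd, scheme.left_barcodes, scheme.left_primer)
        if lbc is None:
            res.rejections[NO_LEFT_MATCH] += 1
            continue
        rbc, rpos = match_read(rev, scheme.right_barcodes, scheme.right_primer)
        if rbc is None:
            res.rejections[NO_RIGHT_MATCH] += 1
            continue
        sample = sample_map.get((lbc, rbc))
        if sample is None:
            res.rejections[CROSS_TALK] += 1
            continue
        v6_fwd = fwd[lpos:]
        v6_rev = revcomp(rev[rpos:])
        if v6_fwd != v6_rev and reject_disagreements:
            res.rejections[MATE_DISAGREEMENT] += 1
            continue
        if not lo <= len(v6_fwd) <= hi:
            res.rejections[LENGTH_OUT_OF_BAND] += 1
            continue
        res.isu.add(sample, v6_fwd)
        res.assigned += 1
    return res


def _iter_fastq_pairs(r1_path, r2_path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(r1_path) as f1, open(r2_path) as f2:
        for (t1, s1, _), (t2, s2, _) in zip(
                FastqGeneralIterator(f1), FastqGeneralIterator(f2),
                strict=True):
            yield s1.upper(), s2.upper()


def read_sample_map(path) -> dict[tuple[str, str], str]:
    mapping = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header[:3] == ["left_barcode", "right_barcode", "sample_id"]
        for line in fh:
            lb, rb, sid = line.rstrip("\n").split("\t")[:3]
            mapping[(lb, rb)] = sid
    return mapping


def demultiplex(r1_path, r2_path, scheme: BarcodeScheme,
                sample_map: dict[tuple[str, str], str],
                **kwargs) -> DemuxResult:
    """File-level entry point: paired FASTQ in lockstep order."""
    return demultiplex_pairs(_iter_fastq_pairs(r1_path, r2_path), scheme,
                             sample_map, **kwargs)
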