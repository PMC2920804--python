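"""Synthetic vaginal-microbiota cohort generator.

Emulates the statistical structure the downstream analyses assume: a panel
of V6 taxa with two core members (*Gardnerella vaginalis* and *Lactobacillus
iners*) present in every sample, eight community archetypes with
Dirichlet-distributed compositions, multinomial read sampling at realistic
depths, PCR substitution errors, clinical metadata (pH, Nugent score, Amsel
criteria) statistically coupled to the community state, and a longitudinal
arm in which subjects with bacterial vaginosis (BV) are treated with
metronidazole at baseline and re-sampled at 2, 5, 15 and 25 weeks.

The cohort ground truth is exported in the flat layout of a subject
diagnostic table: one row per sample with follow-up code, subject and sample
ids, Nugent score, the three observed Amsel criteria plus discharge, pH,
composite Amsel score, total reads, and one integer read-count column per
taxon/OTU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqs

# ---------------------------------------------------------------------------
# panel

CORE_TAXA = ("Gardnerella vaginalis", "Lactobacillus iners")

_NAMED_TAXA = [
    "Gardnerella vaginalis",
    "Lactobacillus iners",
    "Lactobacillus crispatus",
    "Prevotella bivia",
    "Atopobium vaginae",
    "Lachnospiraceae sp. 1",
    "Lachnospiraceae sp. 2",
    "Veillonellaceae sp.",
    "Megasphaera sp.",
    "Prevotella amnii",
    "Sneathia sanguinegens",
    "Mobiluncus mulieris",
    "Dialister sp.",
    "Eggerthella sp.",
    "Leptotrichia amnionii",
    "Mycoplasma hominis",
    "Peptostreptococcus anaerobius",
    "Anaerococcus tetradius",
    "Finegoldia magna",
    "Aerococcus christensenii",
]


@dataclass(frozen=True)
class TaxonProfile:
    """One panel member: a taxon label and its (synthetic) V6 sequence."""

    name: str
    v6_sequence: str
    core: bool = False

    def __post_init__(self):
        if not self.v6_sequence or set(self.v6_sequence) - set("ACGT"):
            raise ValueError(f"V6 sequence for {self.name!r} must be over ACGT")
        if not 55 <= len(self.v6_sequence) <= 75:
            raise ValueError(
                f"V6 sequence for {self.name!r} must be 55-75 nt, "
                f"got {len(self.v6_sequence)}"
            )


def default_panel(n_taxa: int = 60, v6_length: int = 60,
                  max_pairwise_identity: float = 0.90) -> list[TaxonProfile]:
    """Panel of ``n_taxa`` synthetic V6 sequences with mutually distinct
    sequences (pairwise identity below ``max_pairwise_identity``).

    Sequences are synthetic stand-ins generated from a fixed internal seed so
    the default panel is a deterministic constant of the package; names for
    the first 20 follow taxa commonly reported in the vaginal niche, the rest
    are numbered placeholders.
    """
    import edlib

    rng = np.random.default_rng(20100812)
    panel_seqs: list[str] = []
    while len(panel_seqs) < n_taxa:
        cand = seqs.random_sequence(v6_length, rng)
        ok = True
        for s in panel_seqs:
            d = edlib.align(cand, s)["editDistance"]
            if 1 - d / max(len(cand), len(s)) >= max_pairwise_identity:
                ok = False
                break
        if ok:
            panel_seqs.append(cand)
    names = list(_NAMED_TAXA[:n_taxa])
    names += [f"Taxon {i + 1}" for i in range(len(names), n_taxa)]
    return [
        TaxonProfile(name=nm, v6_sequence=sq, core=nm in CORE_TAXA)
        for nm, sq in zip(names, panel_seqs)
    ]


# ---------------------------------------------------------------------------
# archetypes


@dataclass(frozen=True)
class ClinicalModel:
    """Per-archetype generative probabilities for the clinical variables."""

    ph_gt_45: float          # P(vaginal pH > 4.5)
    clue: float              # P(clue cells present)
    odor: float              # P(amine odor present)
    discharge: float         # P(milk-like discharge present)
    nugent_probs: tuple[float, float, float]  # P(normal, intermediate, BV)

    def __post_init__(self):
        if abs(sum(self.nugent_probs) - 1) > 1e-9:
            raise ValueError("nugent_probs must sum to 1")


@dataclass(frozen=True)
class CommunityArchetype:
    """A community state: mean composition on the simplex plus a Dirichlet
    concentration controlling sample-to-sample spread, and a clinical model."""

    label: str
    mean_composition: np.ndarray
    concentration: float
    clinical_model: ClinicalModel

    def __post_init__(self):
        m = np.asarray(self.mean_composition, dtype=float)
        if (m < 0).any() or abs(m.sum() - 1) > 1e-9:
            raise ValueError(f"{self.label}: mean composition must be a "
                             "nonnegative vector summing to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(self, "mean_composition", m)

    @property
    def bv_associated(self) -> bool:
        return self.clinical_model.nugent_probs[2] >= 0.5


def _mean_vector(panel: list[TaxonProfile], masses: dict[str, float],
                 tail: float = 0.0001, n_tail: int = 20) -> np.ndarray:
    """Build a sparse mean composition over the panel: the named masses plus
    a thin tail of ``n_tail`` low-abundance taxa (drives singleton counts and
    hence nontrivial richness-coverage behaviour)."""
    names = [t.name for t in panel]
    v = np.zeros(len(panel))
    for nm, m in masses.items():
        v[names.index(nm)] = m
    placed = 0
    for i, t in enumerate(panel):
        if v[i] == 0 and not t.core and placed < n_tail:
            v[i] = tail
            placed += 1
    # core taxa always present in the mean
    for nm in CORE_TAXA:
        i = names.index(nm)
        v[i] = max(v[i], 0.02)
    return v / v.sum()


# Cluster sizes and clinical frequencies follow the published per-cluster
# census (n, pH>4.5, clue cells, odor, Nugent categories); mean compositions
# are illustrative free parameters, not fitted values.
_ARCHETYPE_SPECS: list[tuple[str, int, dict[str, float], ClinicalModel]] = [
    ("L. iners", 39,
     {"Lactobacillus iners": 0.78, "Gardnerella vaginalis": 0.06,
      "Lactobacillus crispatus": 0.03, "Atopobium vaginae": 0.01,
      "Prevotella bivia": 0.01},
     ClinicalModel(10 / 39, 6 / 39, 4 / 39, 0.45, (38 / 39, 1 / 39, 0.0))),
    ("L. iners & G. vaginalis", 21,
     {"Lactobacillus iners": 0.42, "Gardnerella vaginalis": 0.34,
      "Atopobium vaginae": 0.06, "Prevotella bivia": 0.04,
      "Lachnospiraceae sp. 1": 0.03},
     ClinicalModel(12 / 21, 9 / 20, 4 / 20, 0.45, (7 / 21, 8 / 21, 6 / 21))),
    ("L. crispatus", 13,
     {"Lactobacillus crispatus": 0.70, "Lactobacillus iners": 0.12,
      "Gardnerella vaginalis": 0.04, "Aerococcus christensenii": 0.02},
     ClinicalModel(0.0, 2 / 13, 3 / 13, 0.45, (1.0, 0.0, 0.0))),
    ("Lachnospiraceae & Veillonellaceae", 14,
     {"Lachnospiraceae sp. 1": 0.26, "Veillonellaceae sp.": 0.24,
      "Lachnospiraceae sp. 2": 0.08, "Megasphaera sp.": 0.06,
      "Gardnerella vaginalis": 0.08, "Lactobacillus iners": 0.15,
      "Atopobium vaginae": 0.05},
     ClinicalModel(12 / 13, 10 / 14, 13 / 14, 0.45, (0.0, 1 / 14, 13 / 14))),
    ("G. vaginalis", 64,
     {"Gardnerella vaginalis": 0.56, "Lactobacillus iners": 0.18,
      "Atopobium vaginae": 0.07, "Prevotella bivia": 0.04,
      "Megasphaera sp.": 0.03},
     ClinicalModel(50 / 59, 46 / 62, 29 / 64, 0.45,
                   (9 / 64, 19 / 64, 36 / 64))),
    ("P. bivia", 20,
     {"Prevotella bivia": 0.46, "Gardnerella vaginalis": 0.12,
      "Lactobacillus iners": 0.20, "Prevotella amnii": 0.08,
      "Atopobium vaginae": 0.04},
     ClinicalModel(1.0, 14 / 18, 11 / 18, 0.45, (3 / 20, 4 / 20, 13 / 20))),
    ("Multiple species", 15,
     {"Gardnerella vaginalis": 0.13, "Lactobacillus iners": 0.15,
      "Atopobium vaginae": 0.10, "Prevotella bivia": 0.08,
      "Lachnospiraceae sp. 1": 0.08, "Veillonellaceae sp.": 0.08,
      "Megasphaera sp.": 0.08, "Sneathia sanguinegens": 0.07,
      "Mobiluncus mulieris": 0.07, "Dialister sp.": 0.06,
      "Eggerthella sp.": 0.05, "Leptotrichia amnionii": 0.05},
     ClinicalModel(10 / 12, 11 / 13, 10 / 13, 0.45, (0.0, 3 / 15, 12 / 15))),
    ("Lachnospiraceae", 21,
     {"Lachnospiraceae sp. 1": 0.42, "Lachnospiraceae sp. 2": 0.18,
      "Lactobacillus iners": 0.18, "Gardnerella vaginalis": 0.08,
      "Megasphaera sp.": 0.05, "Atopobium vaginae": 0.04},
     ClinicalModel(1.0, 1.0, 16 / 21, 0.45, (0.0, 1 / 21, 20 / 21))),
]

DEFAULT_CONCENTRATION = 80.0

#: Baseline archetype mixture weights (proportional to published cluster sizes).
DEFAULT_WEIGHTS = np.array([n for _, n, _, _ in _ARCHETYPE_SPECS], float)
DEFAULT_WEIGHTS /= DEFAULT_WEIGHTS.sum()

#: Archetype mixture at the first post-metronidazole visit. Chosen so that
#: (a) most subjects move to a different BV-associated state rather than a
#: lactobacilli-dominated one and (b) the induced week-2 BV persistence is in
#: the mid-50% range.
POST_TREATMENT_WEIGHTS = {
    "L. iners": 0.17, "L. iners & G. vaginalis": 0.08, "L. crispatus": 0.02,
    "Lachnospiraceae & Veillonellaceae": 0.06, "G. vaginalis": 0.27,
    "P. bivia": 0.12, "Multiple species": 0.10, "Lachnospiraceae": 0.18,
}


def default_archetypes(panel: list[TaxonProfile] | None = None,
                       concentration: float = DEFAULT_CONCENTRATION
                       ) -> list[CommunityArchetype]:
    """The eight default community archetypes over the default panel."""
    panel = panel if panel is not None else default_panel()
    return [
        CommunityArchetype(label, _mean_vector(panel, masses),
                           concentration, clin)
        for label, _, masses, clin in _ARCHETYPE_SPECS
    ]


# ---------------------------------------------------------------------------
# sampling


CORE_FLOOR = 0.01  # minimum proportion a core taxon keeps in any composition


def sample_community(archetype: CommunityArchetype,
                     rng: np.random.Generator,
                     panel: list[TaxonProfile] | None = None) -> np.ndarray:
    """Draw one composition from the archetype's Dirichlet.

    Taxa absent from the mean stay exactly zero; core taxa are floored at
    ``CORE_FLOOR`` (then renormalised) so that every sample carries the core
    members at detectable abundance. ``concentration=inf`` returns the mean.
    """
    m = archetype.mean_composition
    if np.isinf(archetype.concentration):
        p = m.copy()
    else:
        p = np.zeros_like(m)
        support = m > 0
        p[support] = rng.dirichlet(archetype.concentration * m[support])
    if panel is not None:
        for i, t in enumerate(panel):
            if t.core and p[i] < CORE_FLOOR:
                p[i] = CORE_FLOOR
        p = p / p.sum()
    return p


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class FastqRecord:
    rid: str
    seq: str
    qual: str


def simulate_reads(composition: np.ndarray, panel: list[TaxonProfile],
                   depth: int, error_rate: float,
                   barcode_pair: tuple[str, str],
                   rng: np.random.Generator,
                   left_primer: str = "CAACGCGARGAACCTTACC",
                   right_primer: str = "ACAACACGAGCTGACGAC",
                   read_prefix: str = "read"
                   ) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Simulate ``depth`` paired amplicon reads for one sample.

    The forward read is left barcode + left primer + V6; the reverse read is
    right barcode + right primer + reverse-complement of the V6, so the mates
    fully cover the region. Degenerate primer positions are filled uniformly
    from their IUPAC set (the primer pool is a mixture). Substitution errors
    hit every base of both reads independently at ``error_rate``.
    """
    composition = np.asarray(composition, float)
    if len(composition) != len(panel):
        raise ValueError("composition length does not match panel size")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error rate must be in [0, 0.05]")
    left_bc, right_bc = barcode_pair
    counts = rng.multinomial(depth, composition / composition.sum())
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    k = 0
    for taxon, n in zip(panel, counts):
        for _ in range(n):
            lp = _resolve_iupac(left_primer, rng)
            rp = _resolve_iupac(right_primer, rng)
            v6 = taxon.v6_sequence
            fwd = seqs.mutate(left_bc + lp + v6, error_rate, rng)
            rev = seqs.mutate(right_bc + rp + seqs.revcomp(v6),
                              error_rate, rng)
            rid = f"{read_prefix}:{k}"
            r1.append(FastqRecord(rid + "/1", fwd, "I" * len(fwd)))
            r2.append(FastqRecord(rid + "/2", rev, "I" * len(rev)))
            k += 1
    return r1, r2


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    out = []
    for c in primer:
        opts = seqs.IUPAC[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def write_fastq(records: list[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.rid}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# cohort


CLINICAL_COLUMNS = [
    "followup", "subject_id", "sample_id", "nugent", "amsel_discharge",
    "amsel_odor", "amsel_clue", "ph", "amsel_score", "total_reads",
]

#: Probability that each clinical observation is missing (matches the
#: pairwise-complete sample counts of the published association table).
MISSING_PROBS = {"ph": 0.066, "amsel_odor": 0.026,
                 "amsel_clue": 0.037, "amsel_discharge": 0.048}

_NUGENT_RANGES = [(0, 3), (4, 6), (7, 10)]


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults reproduce the study conditions: 132 subjects at baseline, 39
    BV-diagnosed subjects treated with metronidazole and re-sampled at weeks
    2/5/15/25, per-sample depths log-normal around a median of ~40,931 reads
    clipped to the observed range 7,018-129,054.
    """

    n_subjects: int = 132
    n_followed: int = 39
    visit_weeks: tuple[int, ...] = (2, 5, 15, 25)
    depth_low: int = 7018
    depth_high: int = 129054
    depth_median: int = 40931
    depth_log_sigma: float = 0.45
    error_rate: float = 0.0
    seed: int = 0
    archetype_weights: np.ndarray | None = None
    iners_boost: float = 0.45      # L. iners bloom injected at the week-2 visit
    late_stay_prob: float = 0.6    # P(keep current state at visits 3..)
    clinical_missingness: bool = True

    def __post_init__(self):
        if not (1 <= self.depth_low <= self.depth_high <= 10 ** 6):
            raise ValueError("depth bounds must satisfy 1 <= low <= high <= 1e6")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")


class CohortTable:
    """One row per sample: clinical metadata plus per-OTU read counts.

    Thin wrapper over a :class:`pandas.DataFrame`; ``otu_columns`` names the
    count block. Missing clinical values are :data:`numpy.nan` in memory and
    the token ``NA`` on disk.
    """

    def __init__(self, df: pd.DataFrame, otu_columns: list[str]):
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.otu_columns = list(otu_columns)
        self._validate()

    def _validate(self):
        nug = self.df["nugent"].dropna()
        if ((nug < 0) | (nug > 10)).any() or (nug != nug.astype(int)).any():
            raise ValueError("Nugent scores must be integers in [0, 10]")
        ams = self.df["amsel_score"].dropna()
        if ((ams < 0) | (ams > 4)).any():
            raise ValueError("Amsel scores must be in [0, 4]")
        sums = self.df[self.otu_columns].sum(axis=1)
        bad = self.df.index[sums != self.df["total_reads"]]
        if len(bad):
            rows = ", ".join(str(self.df.loc[i, "sample_id"]) for i in bad[:10])
            warnings.warn(
                f"total_reads differs from the OTU count sum in {len(bad)} "
                f"row(s): {rows}", stacklevel=3)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return (isinstance(other, CohortTable)
                and self.otu_columns == other.otu_columns
                and self.df.equals(other.df))

    @property
    def counts(self) -> pd.DataFrame:
        out = self.df[self.otu_columns].copy()
        out.index = self.df["sample_id"]
        return out

    def proportions(self) -> pd.DataFrame:
        c = self.counts
        return c.div(c.sum(axis=1), axis=0)


def write_cohort_table(table: CohortTable, path) -> None:
    df = table.df.copy()
    for col in ("amsel_discharge", "amsel_odor", "amsel_clue"):
        df[col] = df[col].map({1.0: "y", 0.0: "n", 1: "y", 0: "n"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_table(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    for col in ("amsel_discharge", "amsel_odor", "amsel_clue"):
        bad = set(df[col].dropna()) - {"y", "n"}
        if bad:
            raise ValueError(f"{col}: unexpected values {sorted(bad)}")
        df[col] = df[col].map({"y": 1.0, "n": 0.0})
    otu_columns = [c for c in df.columns if c not in CLINICAL_COLUMNS]
    df[otu_columns] = df[otu_columns].astype(int)
    return CohortTable(df, otu_columns)


def _draw_clinical(model: ClinicalModel, rng: np.random.Generator,
                   missingness: bool) -> dict:
    cat = rng.choice(3, p=model.nugent_probs)
    lo, hi = _NUGENT_RANGES[cat]
    nugent = int(rng.integers(lo, hi + 1))
    ph_high = rng.random() < model.ph_gt_45
    ph = round(float(rng.uniform(4.6, 6.0) if ph_high
                     else rng.uniform(3.8, 4.5)), 1)
    out = {
        "nugent": nugent,
        "ph": ph,
        "amsel_clue": float(rng.random() < model.clue),
        "amsel_odor": float(rng.random() < model.odor),
        "amsel_discharge": float(rng.random() < model.discharge),
    }
    if missingness:
        for key, pmiss in MISSING_PROBS.items():
            if rng.random() < pmiss:
                out[key] = np.nan
    comps = [float(out["ph"] > 4.5) if not np.isnan(out["ph"]) else np.nan,
             out["amsel_clue"], out["amsel_odor"], out["amsel_discharge"]]
    out["amsel_score"] = (np.nan if any(np.isnan(c) for c in comps)
                          else int(sum(comps)))
    return out


def _boost_taxon(p: np.ndarray, idx: int, delta: float) -> np.ndarray:
    q = p.copy()
    q[idx] += delta
    return q / q.sum()


def simulate_cohort(config: SimulationConfig,
                    archetypes: list[CommunityArchetype] | None = None,
                    panel: list[TaxonProfile] | None = None
                    ) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate the full cohort at the count level.

    Returns the ground-truth :class:`CohortTable` (counts drawn
    multinomially from each sample's composition) and a per-sample truth
    frame with the latent archetype label and composition row index.

    Treated subjects are drawn from those with Nugent >= 7 at baseline; at
    the first follow-up their community is redrawn from the post-treatment
    archetype mixture with an *L. iners* boost (the treatment signature), and
    later visits either persist or drift again.
    """
    panel = panel if panel is not None else default_panel()
    archetypes = (archetypes if archetypes is not None
                  else default_archetypes(panel))
    labels = [a.label for a in archetypes]
    weights = (np.asarray(config.archetype_weights, float)
               if config.archetype_weights is not None else DEFAULT_WEIGHTS)
    weights = weights / weights.sum()
    post_w = np.array([POST_TREATMENT_WEIGHTS.get(l, 0.0) for l in labels])
    post_w = post_w / post_w.sum() if post_w.sum() > 0 else weights
    rng = np.random.default_rng(config.seed)
    names = [t.name for t in panel]
    iners_idx = names.index("Lactobacillus iners")

    rows, truth_rows = [], []
    sample_no = 0

    def depth_draw():
        d = rng.lognormal(np.log(config.depth_median), config.depth_log_sigma)
        return int(np.clip(d, config.depth_low, config.depth_high))

    # baseline
    baseline = []
    for s in range(config.n_subjects):
        ai = int(rng.choice(len(archetypes), p=weights))
        clin = _draw_clinical(archetypes[ai].clinical_model, rng,
                              config.clinical_missingness)
        baseline.append((s, ai, clin))
    bv_subjects = [s for s, _, clin in baseline if clin["nugent"] >= 7]
    if len(bv_subjects) < config.n_followed:
        followed = set(bv_subjects)
    else:
        followed = set(rng.choice(bv_subjects, size=config.n_followed,
                                  replace=False).tolist())

    def emit(subject, code, ai, clin, boost=0.0):
        nonlocal sample_no
        sample_no += 1
        sid = f"S{sample_no:04d}"
        p = sample_community(archetypes[ai], rng, panel)
        if boost > 0:
            p = _boost_taxon(p, iners_idx, boost)
        depth = depth_draw()
        counts = rng.multinomial(depth, p)
        row = {"followup": code, "subject_id": f"P{subject + 1:03d}",
               "sample_id": sid, **clin, "total_reads": int(counts.sum())}
        row.update({nm: int(c) for nm, c in zip(names, counts)})
        rows.append(row)
        truth_rows.append({"sample_id": sid, "subject_id": row["subject_id"],
                           "followup": code, "archetype": archetypes[ai].label,
                           "depth": depth})

    for s, ai, clin in baseline:
        emit(s, 1 if s in followed else 0, ai, clin)

    for s, ai0, _ in baseline:
        if s not in followed:
            continue
        ai = ai0
        for v, _week in enumerate(config.visit_weeks):
            code = v + 2
            if v == 0:
                ai = int(rng.choice(len(archetypes), p=post_w))
                boost = config.iners_boost
            else:
                if rng.random() > config.late_stay_prob:
                    ai = int(rng.choice(len(archetypes), p=post_w))
                boost = 0.0
            clin = _draw_clinical(archetypes[ai].clinical_model, rng,
                                  config.clinical_missingness)
            emit(s, code, ai, clin, boost)

    df = pd.DataFrame(rows)[CLINICAL_COLUMNS + names]
    return CohortTable(df, names), pd.DataFrame(truth_rows)


def simulate_fastq_run(compositions: np.ndarray, panel: list[TaxonProfile],
                       depths: list[int], error_rate: float,
                       scheme, rng: np.random.Generator,
                       r1_path, r2_path, sample_map_path,
                       sample_ids: list[str] | None = None) -> dict:
    """Write a paired FASTQ run for a batch of samples plus its sample map.

    Samples are assigned (left, right) barcode combinations in product
    order; raises if the batch exceeds the available combinations.
    """
    from itertools import product

    combos = list(product(scheme.left_barcodes, scheme.right_barcodes))
    n = len(compositions)
    if n > len(combos):
        raise ValueError(
            f"{n} samples exceed the {len(combos)} barcode combinations")
    sample_ids = sample_ids or [f"S{i + 1:04d}" for i in range(n)]
    all_r1, all_r2, mapping = [], [], []
    for i, (comp, depth) in enumerate(zip(compositions, depths)):
        lb, rb = combos[i]
        r1, r2 = simulate_reads(comp, panel, depth, error_rate, (lb, rb),
                                rng, scheme.left_primer, scheme.right_primer,
                                read_prefix=sample_ids[i])
        all_r1 += r1
        all_r2 += r2
        mapping.append((lb, rb, sample_ids[i]))
    write_fastq(all_r1, r1_path)
    write_fastq(all_r2, r2_path)
    with open(sample_map_path, "w") as fh:
        fh.write("left_barcode\tright_barcode\tsample_id\n")
        for lb, rb, sid in mapping:
            fh.write(f"{lb}\t{rb}\t{sid}\n")
    return {sid: (lb, rb) for lb, rb, sid in mapping}
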