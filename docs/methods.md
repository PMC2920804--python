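# Methods

## The synthetic cohort: what it emulates

Raw reads for studies of this design are rarely available, so the package
ships a generative model of the cohort whose statistical structure the
analysis stages assume. Its defaults describe a longitudinal BV-treatment
study: 132 subjects sampled at baseline, of whom those diagnosed with BV
(Nugent ≥ 7) form the treatment pool; 39 treated subjects are re-sampled at
weeks 2, 5, 15 and 25 (follow-up codes 2–5; baseline codes 0 = not followed,
1 = followed). The generator returns a ground-truth cohort table — one row
per sample with Nugent score, the four Amsel criteria, pH, per-taxon read
counts — plus, on request, paired FASTQ for a barcoded sequencing batch.

**Taxon panel.** 60 taxa with synthetic 60-nt V6 sequences drawn once from a
fixed internal seed under a pairwise-identity ceiling of 90% (so OTU
clustering at 95% can never merge two panel taxa). The first 20 carry names
of organisms typical of the vaginal niche; *G. vaginalis* and *L. iners* are
flagged as core members and floored at 1% in every composition.

**Community archetypes.** Eight community states (L. iners; L. iners &
G. vaginalis; L. crispatus; Lachnospiraceae & Veillonellaceae; G. vaginalis;
P. bivia; Multiple species; Lachnospiraceae). Mean compositions are
illustrative free parameters — sparse vectors over ~5–12 named taxa plus a
thin tail of 20 taxa at 10⁻⁴ each (the tail produces the singleton counts
that make the richness-coverage census non-trivial). A sample's composition
is Dirichlet(c·mean) with concentration c = 80, chosen so that within-state
spread (mean angle ≈ 0.15–0.25 rad) stays clearly inside the smallest
between-state separation (≈ 0.43 rad). Concentration is a free knob: the
within-cluster variance of real cohorts is not identified by published
summaries.

**Clinical coupling.** Generative, not mechanistic: each archetype carries
per-state probabilities for pH > 4.5, clue cells, odor, and the Nugent
category, taken from the published per-cluster census of a 272-sample
cohort; the Nugent integer is uniform within its category, pH uniform within
its side of 4.5. Discharge is generated at 0.45 everywhere — deliberately
independent of the community so the association stages have a true negative.
Per-variable missingness (pH 6.6%, odor 2.6%, clue 3.7%, discharge 4.8%)
reproduces realistic pairwise-complete sample counts; the composite Amsel
score (0–4) is computed only when all four components are observed.

**Depths and reads.** Per-sample depth is log-normal with median 40,931
(σ_log = 0.45) clipped to the observed range [7,018, 129,054]. Reads are
multinomial draws from the composition; each simulated read is barcode +
primer + V6 (the mate reverse-complemented) with independent per-base
substitution errors and constant Q40 qualities.

**Treatment dynamics.** At week 2 a treated subject's community is redrawn
from a post-treatment archetype mixture chosen so that (i) most subjects
move to a *different* BV-associated state rather than a lactobacilli one and
(ii) the expected BV persistence is ≈ 56%. A renormalised +0.45 *L. iners*
boost at week 2 emulates the post-antibiotic *L. iners* bloom (median
roughly doubling). Later visits keep the current state with probability 0.6,
else redraw — a slow drift back toward diverse communities.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: Illumina quality-score profiles, chimeras and
indels (substitutions only), missed visits (follow-up is complete, so the
default cohort has 288 samples where a real one with dropouts had fewer),
intra-subject correlation beyond the archetype label, seasonal/behavioural
covariates, and real V6 sequence phylogeny (panel sequences are random, so
taxonomy tests exercise the assignment rules, not marker-gene resolution).

## Numerical and design choices

**Demultiplexing.** Zero mismatches in barcode and primer (the analysis
keeps only reads with intact tags); barcodes matched longest-first with the
full primer as anchor, and schemes are validated at load against genuine
prefix ambiguities (a short barcode extended by the primer's opening bases
reproducing a longer barcode with a periodic primer). Mates that disagree at
any V6 position are rejected (`reject_disagreements=False` keeps the forward
payload instead); disagreement implies at least one sequencing error and the
correct base is not identifiable without quality modelling. Offsets are
0-based half-open.

**Clustering.** Identity uses the Levenshtein distance with the *longer*
sequence as denominator, so length differences are penalised. Candidate
seeds are tried in founding order, first-match-wins — the deterministic
greedy rule; ties in abundance order break lexicographically. The abundance
filter is strict (> 1%), applied at ISU level before clustering, and
filtered reads are excluded from OTU totals.

**Taxonomy.** Hits are ranked by (identity, query coverage, source-class
precedence: complete genome > characterized isolate > environmental).
Identity is semi-global (the seed against its best-matching reference
substring); coverage is the aligned fraction of the seed. The lowest common
ancestor is computed rank-by-rank on lineage strings.

**Angular distance.** Computed on square-root proportions (the Bhattacharyya
angle) because that form is the Fisher–Rao geodesic the "minimum Fisher
information" interpretation requires; the raw-Euclidean-cosine reading is
available via `sqrt_geometry=False`. Cluster extraction uses average-linkage
agglomeration cut at 0.35 rad (calibrated once on synthetic draws, see
above) with the >10-sample majority rule; extraction is invariant to sample
order, and cluster labels are the taxon with the highest within-cluster mean.

**Richness.** Chao1 is bias-corrected by default (classic form behind a
flag) — the corrected form is defined when F2 = 0. ACE falls back to Chao1
with a warning when every rare taxon is a singleton (C_ace = 0).
Rarefaction uses log-gamma binomials for numerical stability. "Rarefaction
coverage" is S_obs divided by the asymptote of a two-parameter
Michaelis–Menten fit S(n) = a·n/(b+n) to the analytic curve — an
interpretation, since "expected diversity" has no canonical rarefaction
definition; Chao1/ACE coverage is simply S_obs/estimate. The census counts
strict exceedances.

**Kendall tau.** Tau-b (tie-corrected). For n ≤ 8 the p-value enumerates all
n! orderings of y (valid under ties); above that, the tie-adjusted normal
approximation.

**KL strength.** The recipe: percentile-rank the fraction, bin each clinical
level's ranks into B = ⌈√(min group size)⌉ equal bins, smooth with a flat
Dirichlet prior (posterior-mean bin probabilities), average the per-level
divergences D_g = Σ_b (1/B) ln[(1/B)/q_gb] with weights n_g/n. A finite
sample shows positive divergence even when nothing is associated (the
plug-in KL's null mean is ≈ (B−1)/(2n_g) per level), so the raw D is
calibrated against its asymptotic null, 2nD ~ χ² with g(B−1) degrees of
freedom: the (1−α) null quantile D₀ is subtracted before the Chernoff–Stein
conversion N = ⌈ln(1/α)/(D−D₀)⌉, and when D ≤ D₀ the 10⁶ cap is reported —
the association is indistinguishable from none at that confidence. This
calibration is what makes "subjects required for ≥95% confidence" exact:
under independence the estimate stays at or above the observed n in ≥95% of
replicates by construction. Binary criteria are used as-is; pH is
dichotomised at 4.5 for the strength statistic but kept continuous for tau.

**Wilcoxon.** Zero differences dropped, midranks for ties. For n ≤ 15 the
exact null is computed by convolution over doubled midranks (exact also
under ties); above, the normal approximation with the tie-corrected
variance.

**Decision trees.** Binary numeric splits only (all features are
proportions). Split choice maximises the gain ratio after subtracting the
numeric-threshold MDL penalty log₂(m)/n (m candidate thresholds) — without
the penalty, chance splits on continuous noise always show positive gain and
trees balloon. Pruning is pessimistic error-based at confidence 0.25 with
the exact binomial bound n(1−CF^{1/n}) for error-free leaves and the
continuity-corrected normal bound otherwise; a subtree collapses when the
leaf bound does not exceed the subtree's summed bound. Thresholds are
midpoints of adjacent distinct values. CV is stratified 10-fold, falling
back to unstratified with a warning when a class has fewer members than
folds.

**Longitudinal.** Nugent categories are 0–3 normal, 4–6 intermediate, 7–10
BV (the 0-inclusive reading, so every score is classifiable). The post-
treatment comparison visit defaults to week 2, the first visit after the
course. BV persistence reports the share of treated subjects with Nugent ≥ 7
among those with the visit present (denominator="all" divides by all treated
subjects instead). Transition networks count subjects with complete
follow-up whose baseline fell in a major cluster; minor-cluster samples are
labelled "U".

## Problem sizes

Defaults keep everything on one CPU in seconds to a couple of minutes: the
cohort table is 288 samples × 60 taxa; read-level demonstrations use 10
samples × 20,000 pairs (the demultiplexer processes ~100k pairs/s); the
acceptance script's full pass runs in ~20 s; the test suite in ~1 min.

## Known limitations

The archetype compositions are plausible but not fitted to any cohort, so
absolute effect sizes (e.g. the exact week-2 persistence percentage or
median abundance shifts) are emulation outputs, not estimates of the
clinical quantities. The strength statistic's binning makes it discretisation
-dependent; only its ordering across variables is meaningful. The taxonomy
module searches a local reference and cannot reproduce assignments that
depended on the contemporaneous contents of public databases. Mate
reconciliation assumes fully overlapping mates; partially overlapping pairs
are out of scope.
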