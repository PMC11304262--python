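# Methods

`nhpnutri` implements the computational workflow of a nonhuman-primate
(cynomolgus macaque, *Macaca fascicularis*) undernutrition study as a
tested, reusable library: construction of a weight-for-age z-score (WAZ)
growth reference and undernutrition screening; in silico gastrointestinal
digestion with peptidome-based protein clustering; peptide
descriptor-based function classification; fatty-acid and triglyceride
metrics; and the omics computations (TPM conversion, variance
partitioning, fuzzy c-means, correlation networks). Every stage is
exercised on synthetic data whose generators are first-class, tested code.

## Weight-for-age screening

For each sex, a reference population of healthy animals (body condition
score, BCS ≥ 2.0) defines the mean µ and sample standard deviation σ
(n − 1 denominator) of the weight-for-age ratio X = weight / age
(kg/year). An animal's z-score is

    WAZ = (X − µ_sex) / σ_sex.

X is interpreted as the animal's weight/age *ratio*: this is the only
reading dimensionally consistent with µ and σ being statistics of the
ratio, and the one the term "weight-for-age z-score" denotes. "Standard
variance" in the defining formula is read as the standard deviation — the
reported ±0.34 dispersions and z-score magnitudes are only consistent with
an SD. The reference is a single ratio distribution per sex (no age
binning); whether the original cohort was age-binned is unknown, so the
simpler single-ratio standard is implemented.

The undernutrition cutoff is defined as the mean WAZ of a clinically
flagged (BCS < 2.0) non-thriving group, with a t-based 95% confidence
interval (`derive_cutoff`); at the defaults this reproduces a cutoff of
−1.83. A quantile-based cutoff is deliberately not the default, because
the −1.83 criterion arises as a group mean. Classification flags
WAZ ≤ cutoff, with ties flagged (conservative screening). Group
comparisons use Welch's unequal-variance t test with Satterthwaite degrees
of freedom; anthropometric summaries use t-based 95% intervals. The
resource-equation sample size is n = ⌈DF/k + 1⌉ per group, inflated by a
casualty provision and rounded up (DF 20, k 4, 20% casualty → 8/group).
`protein_energy` encodes the 4 kcal/g protein-equivalent energy density
(1.5 g/kg/day → 6.0 kcal/kg/day).

## Synthetic cohort generator

Reference animals draw ages uniformly on 2–10 years (the source cohort's
age distribution is not published; this range brackets post-weaning
through adult animals) and weight-for-age ratios from sex-specific
Normals — males N(1.30, 0.34), females N(1.12, 0.34) kg/year, 857 and 530
animals — truncated at zero. At µ/σ ≈ 3.8 the truncation bias on the
reference is ≈ 10⁻⁴ and is documented rather than corrected. Flagged
animals target a mean WAZ of −1.83 (counts 121 male / 128 female); because
their ratio distribution sits only 1.5–2 SD above zero, the truncation
would otherwise lift their expected WAZ by 0.05–0.15, so for flagged
blocks the generator solves for the pre-truncation location whose
*truncated* mean equals µ + WAZ·σ, making the expected WAZ exact by
construction (verified by Monte-Carlo). BCS is drawn uniform [2, 4] for
reference and [1, 2) for flagged animals — a labelling convention, not a
fitted link between condition score and weight.

Serum biochemistry defaults reproduce the normal-versus-undernourished
albumin (47.13 ± 4.68 vs 27.16 ± 6.52 g/L) and total-protein
(72.95 ± 7.31 vs 62.98 ± 6.55 g/L) contrasts at group sizes 20 and 60.

## In silico digestion

Cleavage rules are PeptideCutter-style P1/P1′ predicates: the bond after a
P1 residue is cut unless the next residue blocks it. The shipped registry
(editable via a YAML file) encodes trypsin (K/R, not before P),
high-specificity α-chymotrypsin (F/Y/W, not before P), pepsin at pH > 2
simplified to F/L/W/Y (not before P), pancreatic elastase (A/V/S/G/L/I,
not before P), prolyl oligopeptidase (after P, not before P), and a
simplified thimet oligopeptidase (after F/L/I/V at internal positions,
at least two residues from either terminus). The literature rules for
pepsin and thimet oligopeptidase are considerably more context-dependent;
the registry is data-driven precisely so stricter Keil-style tables can be
substituted.

Digestion is either *sequential* (gastric pepsin first, then the five
pancreatic/oligopeptidase rules acting jointly on the gastric fragments —
the physiological default) or *independent* (each enzyme digests the
intact protein; repertoires concatenated with per-enzyme provenance).
Fragments shorter than 2 residues are dropped from the repertoire (single
residues are amino acids, not peptides) but retained in span bookkeeping,
so span-ordered fragments always reconstruct the parent. Missed cleavages
(default 0 — ideal complete hydrolysis) add unions of adjacent fragments.
The engine is verified against an independent position-scan oracle on
1000 random sequences per enzyme.

Peptide categorization embeds distinct peptides as length-normalized 2-mer
composition vectors (400-dim) and partitions them by count-weighted
k-means into 4 categories per enzyme. This deterministic categorizer
fills the role a Gibbs-sampling motif aligner plays in comparable
workflows; exact variable-length motif alignment is out of scope, and
distinct peptides are processed in sorted order so assignments are
invariant to input order under a fixed seed. The protein × (enzyme,
category) count matrix is the protein's enzymatic fingerprint; rows sum to
the protein's total released peptide count. For clustering, rows are first
divided by their sums — without this, protein length dominates every
column and k-means groups proteins by size rather than composition — then
columns are standardized, PCA retains the fewest components explaining
≥ 80% variance, and k-means (10 restarts) assigns labels.

Repertoire similarity is the weighted Jaccard index Σ min / Σ max over
peptide count vectors. How the original ">80% similarity" between food
protein sources was computed is not stated; weighted Jaccard on pooled
source repertoires is this package's operationalization. Note a
structural fact uncovered during design: pooled repertoires of proteins
with i.i.d. residues cannot reach 0.8 weighted Jaccard at realistic pool
sizes even when the two sources share an *identical* composition (the
heavy tail of distinct peptides keeps two 300-protein pools near 0.7), so
high cross-source similarity requires shared subsequences, i.e. homology.
The family generator therefore offers a homologous mode: families sharing
a `template_seed` are mutated copies of common ancestral sequences, with
substitutions drawn from the family's own residue frequencies at
`mutation_rate` (default 0.03, i.e. ≈ 97% pairwise identity — closely
related orthologs). Homologous dairy-like and legume-like families reach
≈ 0.83 pooled similarity while an unrelated, compositionally divergent
family scores ≈ 0.23.

## Peptide descriptors and function classification

Ten sequence-computable descriptors: length; molecular weight from
average residue masses minus (n − 1) × 18.02 Da of water; net charge at
pH 7 by Henderson–Hasselbalch over side-chain pKa values (D 3.65, E 4.25,
H 6.0, C 8.3, Y 10.07, K 10.53, R 12.48; termini 9.0 / 2.0); mean
Kyte–Doolittle hydropathy; hydrogen-bond donor count (N/O/S atoms bearing
H — the cysteine thiol counts as a donor); acceptor count (all N + O
atoms, the Lipinski NO convention); NHOH (N–H/O–H hydrogen count); NO
atom count; aromatic (F/W/Y) fraction; and branched-chain (I/L/V)
fraction. The per-residue group tables reproduce RDKit's
`Lipinski.NHOHCount`, `NOCount` and `NumHDonors` exactly on test
peptides. The descriptor list is a documented superset of the four
hydrogen-bonding descriptors the source workflow names.

Classification: stratified random split with 30% training / 70%
validation (the stated 3:7 ratio read in sentence order; the training
fraction is a parameter for users who prefer 70/30), standardization fit
on training data with constant features dropped and recorded, PCA to ≥ 80%
variance, and a linear maximum-margin (support-vector) fit with C = 1.
Kernels are deliberately out of scope. A margin score of exactly zero is
assigned to the positive class (documented boundary convention). On the
separable synthetic set (BCAA fraction 0.6 vs 0.1, 250 peptides/class) the
validation accuracy is ≈ 0.95; on label-shuffled data the 50-seed mean
accuracy is within 0.5 ± 0.05.

## Lipid metrics

Fatty-acid species are parsed from `Cxx:y[n z][c|t]` shorthand. Profiles
are normalized to percent moles (sum 100; idempotent and scale-invariant).
Class aggregates partition by double-bond count: SFA (0), MUFA (1), PUFA
(≥ 2), UFA = MUFA + PUFA. The ω6/ω3 ratio sums only n6 and n3 species —
ω9 species enter neither side — and is undefined (error) when the n3 total
is zero. Chain classes follow the printed boundaries exactly: VLCFA at
C ≥ 22 (inclusive), LCFA at 12 < C < 22 (both strict), everything else
short/medium-chain. Triglycerides are normalized to starting tissue
weight and then to the control-group mean within each batch, so the
control mean is exactly 1 and multiplicative batch effects cancel.

## Omics statistics

TPM: per sample, rateᵢ = Nᵢ/Lᵢ and TPMᵢ = rateᵢ × 10⁶ / Σ rates; columns
sum to 10⁶ by construction. The low-expression filter keeps genes with
TPM ≥ 1 in ≥ 20% of samples (thresholds configurable; the source values
are unstated) before log2(TPM + 1).

Variance partitioning uses the two-way crossed random-effects ANOVA
(Henderson) method of moments on a complete tissue × individual design
with one sample per cell: σ̂²_tissue = (MS_T − MS_E)/b, σ̂²_individual =
(MS_I − MS_E)/a, σ̂²_residual = MS_E, truncated at zero per gene and
renormalized to fractions. A closed-form moment estimator was chosen over
an iterative REML fit: it is dependency-free, exactly testable, and on the
balanced designs generated here the two coincide in expectation; on
unbalanced designs REML would differ (unbalanced designs are rejected
rather than approximated). Two aggregation pitfalls are handled
explicitly: averaging per-gene fraction *ratios* is biased toward the
residual when a factor has few levels (0.61 recovered for a true 0.70 with
4 tissues), and pooling per-gene *truncated* components inflates null
components (≈ 0.06 for a true 0). `overall_fractions` therefore pools the
untruncated moment estimates across genes, truncates once, and
normalizes — recovering (0.70, 0.10, 0.20) within ±0.01 at 2000 genes and
≈ 0 under a pure-noise null.

Fuzzy c-means standardizes each feature row to z-scores, then alternates
the classic membership update u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)} and
weighted center update with fuzzifier m = 2 until the maximum center shift
falls below 10⁻⁶. Memberships sum to one per feature, features landing
exactly on a center get full membership there, and the objective is
asserted non-increasing at every iteration. The cluster count c is a user
parameter (6 in the motivating workflow).

Correlation networks rank-transform both matrices (average ranks, so ties
are corrected through the Pearson-on-ranks identity), compute all
gene × metabolite Spearman ρ, derive two-sided p-values from the
t-approximation, and apply Benjamini–Hochberg FDR control across all
pairs (q < 0.05 flags an edge). Constant rows yield NaN ρ and are
reported, never flagged. Fewer than 4 matched samples is an error.

## Synthetic omics generator

Per-gene log2 expression is grand mean (uniform 4–9) + tissue effect +
individual effect + residual, each Gaussian with variances equal to the
requested fractions of a unit total, over a full 4-tissue × 6-individual
crossed design; counts are the rounded antilog and gene lengths uniform
300–5000 bp. Counts are intentionally simple (no negative-binomial
overdispersion, no library-size gradients): they are sufficient for
testing TPM algebra and variance-partition recovery, and passing those
tests says nothing about dispersion modelling on real RNA-seq. Metabolite
rows follow one of c smooth, mutually distinct sample-axis templates
(rising/falling/peaked/dipped sinusoid variants, z-scored) plus Gaussian
noise (SD 0.3); the planted labels are returned for recovery tests.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own scales where those
are meaningful (1387-animal reference cohort; 249 flagged animals; 2000
genes × 24 samples; 1000 coverage replicates; 1000 random sequences per
enzyme for the digestion oracle; 60 proteins per family for pooled
repertoires; 50 null seeds for the classifier), completing in well under a
minute each. Seeds are explicit everywhere; fixed seeds give bit-identical
outputs. Degenerate inputs fail loudly: zero reference spread, empty
repertoires, all-zero samples, missing batch controls, non-crossed
designs, and undefined ω ratios are errors, not warnings.

## Known limitations

- The screening reference ignores growth curvature over age (no LMS/GAMLSS
  modelling); it reproduces the ratio-based standard, not a longitudinal
  reference.
- Digestion is rule-based and all-or-none: no kinetics, efficiencies,
  pH-dependent switching, or post-translational modifications.
- The peptide categorizer is a deterministic stand-in with the same role
  as a Gibbs motif aligner, not a reconstruction of one.
- Descriptors are sequence-level; no 3-D conformer properties.
- The variance model supports exactly one sample per tissue × individual
  cell; replicated or unbalanced designs are rejected.
- Synthetic data certifies the *computations*, not biological claims:
  organ-level findings of the motivating study are outside what desk
  simulation can reproduce.
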