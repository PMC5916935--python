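# Methods

## Study design assumed by the pipeline

Two case groups — 7 benign prostatic hyperplasia (BPH) and 10 prostate
cancer (PCa) serum samples — are each quantified against a common pooled
reference: cases are alkylated on cysteines with ¹³C₃-acrylamide (heavy),
the reference pool with ¹²C₃-acrylamide (light), and each case/reference
mixture is separated by multi-lectin affinity chromatography into three
fractions (UNB flow-through, AAL-bound core-fucosylated glycoforms,
PHA-bound highly branched glycoforms). Every quantified peptide therefore
carries a heavy/light (H/L) ratio relative to the same reference, and a
protein can have up to three fraction-level quantitation values plus a
global level per sample. The 13 reversed-phase fractions collected per
M-LAC fraction (39 slots per sample) affect depth of sampling only and
are recorded as manifest metadata, not modeled.

## Isotope-pair quantitation

The heavy form of a peptide with `n_cys` labeled cysteines at charge `z`
sits `3·n_cys/z` Th above the light form (nominal 3 Da per label; the
exact ¹³C₃−¹²C₃ monoisotopic difference, 3.010 Da, is exposed as
`PER_LABEL_SHIFT_MONOISOTOPIC_DA` but is not the default). The H/L ratio
is the ratio of trapezoidal areas of the heavy and light extracted
elution profiles over the full retention grid; no baseline subtraction or
smoothing is applied (the synthetic profiles are baseline-free). Whether
an instrument pipeline would weight scans by intensity instead is an open
convention; the area ratio was chosen because it is scale-invariant and
exactly label-swap antisymmetric (swapping profiles maps r to 1/r).
Observations are excluded, with counted reasons, when the peptide has no
cysteine (no label site), when the precursor fractional delta mass is
20 ppm or more (strict `< 20 ppm` gate), or when the light area is zero
(undefined ratio).

## Rollup and normalization

Rows with protein-group probability > 0.9 and peptide probability > 0.6
(both strict) are retained. Protein groups sharing any gene name are
merged; the lexicographically smallest name represents the group (the
choice is arbitrary but must be deterministic). Peptide H/L ratios are
averaged on the linear scale per (gene, sample, fraction); the global
level averages all peptides pooled across fractions rather than averaging
the three fraction means — the two differ whenever peptide counts are
unbalanced, and the pooled reading is the default with `mean_of_means`
available as a configuration switch. Averaging before the log transform
is deliberate and documented because the order changes results.

Each sample's values are then log₂-transformed and centered by the median
of that sample's fraction-level (UNB/AAL/PHA) values; the same offset is
subtracted from the sample's global entries. Centering is idempotent and
leaves every sample's fraction-level median at 0 (enforced to 1e-12).
Missing entries stay absent — nothing is imputed — and downstream sample
counts use presence.

## Permutation Welch testing

For each (gene, level) quantified in at least 3 samples per group, the
Welch unequal-variance t statistic (PCa minus BPH direction) is
referenced to its relabeling distribution. Permutations relabel only the
samples actually observed for that feature, so per-feature missingness is
respected. When C(n, n_PCa) ≤ 100,000 every relabeling is enumerated —
C(17,7) = 19,448, so the full design is always exact — and
p = #{|t_perm| ≥ |t_obs|}/C; otherwise `n_perm` seeded Monte Carlo
relabelings are drawn and p = (#{|t_perm| ≥ |t_obs|}+1)/(n_perm+1), which
never returns 0. The test is two-sided via |t|. Tie counting uses a 1e-12
relative tolerance so relabelings that are floating-point re-orderings of
the observed split count as ties. Degenerate features (all values equal)
give t = 0 and p = 1; zero-variance unequal-mean features give a ±inf
sentinel that flows through the comparisons unchanged. A parametric Welch
p-value (scipy) is carried as a debug column only.

## Permutation FDR

For each observed p threshold t, FDR(t) = (mean over permutation rounds
of the number of null p-values ≤ t) / max(1, number of observed p ≤ t),
clipped to [0,1] and made monotone nondecreasing in t by a running
minimum from the largest threshold down; the raw unmonotonized value is
reported alongside. Null p-values are generated per feature by drawing
`n_perm_fdr` (default 200) relabelings from the feature's own null and
converting each drawn statistic to a p-value against that same null, so
the null p-matrix follows exactly the relabeling scheme of the tests.
FDR is computed per level (UNB/AAL/PHA/GLOBAL separately) by default —
the levels have different feature sets and missingness — with pooled
computation behind a flag. Differential quantification uses FDR ≤ 0.01;
pattern classification uses p ≤ 0.05; both columns are reported. The
fold-change gate flags features with |PCa group mean log₂ H/L| ≥ 0.585
(= log₂ 1.5, absolute value — the sidedness of the gate is a documented
choice).

## Pattern classification

Significance (p ≤ 0.05 among eligible levels) across UNB/AAL/PHA/GLOBAL
is mapped to pattern groups with precedence A > B > D > E > F > C > NONE
(most specific first): A = quantitated and significant in all three
fractions; B = significant in every fraction quantitated (fewer than
three); D = ≥ 2 significant fractions not matching A/B; E = exactly one
significant fraction plus global; F = exactly one significant fraction,
global not significant; C = global only. Group A is defined on the
fractions alone; a gene significant in all three fractions whose opposing
trends cancel globally is still A and is flagged `global_discordant`.
Under straight precedence a gene quantitated in a single fraction and
significant there is B, not E/F. The heat-map export sorts genes by the
PCa global group mean (descending), includes genes with n ≥ 3 at the
global level in both groups, and blanks any (gene, level, group) cell
with n < 3 or no detection.

## Synthetic cohort generator

The generator emulates the features the analysis relies on, not the
physics of the measurement. Per (gene, fraction) a baseline log₂ shift
versus the reference is drawn N(0, 1) — genes with injected effects use
their specified `group_baseline_log2` instead; per (sample, gene,
fraction) a latent log₂ H/L is drawn N(baseline + effect·1[PCa],
`noise_sd`), and each peptide observation adds independent
N(0, `noise_sd`) measurement noise before exponentiation. A single
`noise_sd` (default 0.5 log₂ units) serves both tiers for parsimony.
Fraction occupancy is Bernoulli per protein (defaults 0.80/0.65/0.65 for
UNB/AAL/PHA, chosen so per-fraction quantified counts land near the
150–170 out of ~250 proteins typical of this platform), with at least one
fraction forced. Dropout is Bernoulli per (sample, peptide, fraction)
observation (default 0.20). Cysteine counts are uniform on 0–3;
zero-cysteine peptides are generated but never quantifiable, exercising
the label-site constraint. Identification probabilities are drawn above
the confidence gates for 95% of proteins and 90% of peptides, leaving a
low-confidence tail for the filter to remove. Genes named in the effect
list are guaranteed quantifiable (confident group, ≥ 1 cysteine peptide,
occupancy of the scoped fraction): a truth entry that could never be
observed would break the end-to-end identities the truth record exists to
support. All randomness flows from `design.seed`; identical designs give
byte-identical tables.

Raw-data emulation (`generate_elution_pairs`) shares the same latents and
wraps each would-be observation in Gaussian light/heavy elution profiles
on a fixed 41-point retention grid, heavy = true ratio × light shape with
multiplicative point noise of SD `0.1·noise_sd`, and precursor mass
errors drawn N(0, 8 ppm) so a small tail exercises the 20 ppm gate.

**What the generator does not emulate:** retention drift, peak-shape
asymmetry and co-elution interference; intensity-dependent detection
(dropout is independent of abundance); correlated missingness across
peptides of a protein; heteroscedastic noise; shared-peptide protein
inference ambiguity. Passing tests therefore demonstrate the correctness
and calibration of the statistical pipeline under its stated model, not
robustness to these real-data phenomena.

## Numerical and procedural choices

- Exhaustive-enumeration cap 100,000 combinations (~1 MB index matrix at
  the study design; cached per (n, k)).
- Monte Carlo p-values use the +1/+1 correction; FDR draws default to 200
  rounds per feature.
- The clinical-characteristics fixture is a verbatim transcription of the
  cohort table (17 samples; BPH cancer fields N/A) used for
  cohort-arithmetic checks.
- Problem sizes in the test suite (cohorts of 10–250 proteins, 200
  recovery replicates at 40 proteins, 2,000 null replicates) were chosen
  as the smallest sizes at which the binomial tolerances of the
  calibration checks are meaningful.
- Known limitation: with per-protein fraction occupancy shared across
  samples and peptide-level dropout, feature-level n < 3 is rare in
  simulated cohorts; the eligibility and heat-map blank rules are
  additionally exercised on constructed matrices.
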