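# Methods

## Model and procedure

`deltacc` treats a study as a set of expression matrices (probes/genes ×
samples), one per condition, on log2 intensity scale. The analysis has four
stages.

**Differential expression.** For each row, the log2 fold change between two
conditions is the difference of group means (log2 input) or the log2 ratio
of means with a pseudo-value ε = 1e−6 (linear input). Significance comes
from a Poisson likelihood-ratio test of equal per-sample rate applied to
per-condition totals of the intensities rescaled to pseudo-counts
(2^x on log2 input): with totals C_a, C_b over n_a, n_b samples,
T = C_a + C_b and π = n_a/(n_a + n_b), the deviance is
D = 2[C_a ln(C_a/(πT)) + C_b ln(C_b/((1−π)T))], referred to χ²(1). Terms
with zero count contribute zero; a zero total is degenerate and reported as
D = 0, p = 1. A gene is a DEG when |log2FC| ≥ 3.00 and p < 0.05; no
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists). Because the totals are large, the count-model test yields
tiny p-values for even small mean differences; in practice the fold-change
cut does the selecting, which is characteristic of this test family. A
Welch two-sample t-test on intensities is available for users who object to
count models on microarray data.

**Correlation matrices.** Pearson correlation over samples for every gene
pair, per condition. Zero-variance rows give undefined (NaN) correlations
rather than errors; they are excluded from summaries and selection, with a
count carried in the summary. For genome-scale matrices (above a
configurable 5 000-row cap) the full matrix is never materialized; a
blocked routine streams the upper triangle and reports the mean |CC| and
the weak/moderate/strong fractions — the package's quantitative proxy for
global "coordination" of a transcriptome (the motivating study showed this
only as heat maps; the proxy is ours).

**Rewiring and selection.** ΔCC = CC(to) − CC(from) by matrix subtraction.
Pairs are screened on |ΔCC| ≥ 0.70, sign-classified into four transition
categories (zero counts as nonnegative), and trichotomized by |CC| at 0.36
and 0.68. The intervals are half-open (weak < 0.36 ≤ moderate < 0.68 ≤
strong) so every real value classifies uniquely while matching the
published two-decimal bounds (0.35 → weak, 0.36 → moderate, 0.67 →
moderate, 0.68 → strong). A pair enters the panel when its transition is
strong→weak, weak→strong, or strong→strong with a strict sign flip. The
panel is the lexicographically sorted distinct-gene union of selected
pairs.

**Pathways.** Pathway membership is an input (GMT). The packaged reference
fixtures are the DEG membership of the motivating study's top 11 enriched
pathways and its printed per-pathway pre/in-flight correlation values; the
enrichment itself was an external web-tool step and is out of scope.

## Thresholds and numerical choices

| parameter | default | meaning |
|---|---|---|
| `lfc_cut` | 3.00 | |log2FC| cut for DEG calls (dimensionless) |
| `p_cut` | 0.05 | raw p-value cut |
| `delta_cut` | 0.70 | |ΔCC| screen on pair rewiring |
| class bounds | 0.36, 0.68 | weak/moderate/strong |CC| boundaries |
| ε | 1e−6 | pseudo-value on linear means |

The ΔCC screen is applied as **≥** 0.70 although it is usually quoted as
"> 0.70": the published pair table itself contains differentials printed as
exactly ±0.70 that survive into the selected set, so on two-decimal values
the operative rule is ≥; we use ≥ on unrounded values too, for consistency.
The reference table contains one internally inconsistent row (ACSL4–GPT:
printed differential 1.61 versus 0.85 − (−0.66) = 1.51); we treat it as a
typo, exclude it from exact arithmetic checks, and note that its selection
status is unaffected (moderate→strong fails the class rule either way).
Ties, ordering and output sorting are deterministic: pair reports sort by
|ΔCC| descending then pair id; gene pairs are stored unordered with
lexicographically sorted members; DEG reports sort by |log2FC| descending,
then p, then row id.

## Synthetic studies

The generator emulates the motivating study's shape: three conditions ×
(n_subjects × n_replicates) columns, defaults 10 subjects × 2 replicates (20
columns per condition), Gaussian log2 intensities with baseline mean 8.0
and noise SD 0.5 — typical magnitudes for processed two-color array data.
Per-condition target correlation matrices start from a background value
(default 0) with planted pair entries overwritten, are repaired to positive
semidefiniteness by eigenvalue clipping plus diagonal rescaling (simple and
deterministic; an iterative nearest-correlation algorithm would gain little
here), and must preserve planted entries within ±0.02 or generation aborts.
Samples are drawn from a multivariate normal via the symmetric eigenroot;
a single seed drives everything, and planted fold changes shift the In (and
Post) means. Truth labels (which pairs *should* be selected) are computed
from the post-repair target matrices with the same rule the selection stage
applies, so labelling and selection agree by construction on noise-free
input.

What the generator does **not** model: probe-level effects, array
normalization artifacts, subject random effects (available via
`subject_sd`, off by default since replicate profiles are treated as
independent columns), heavy-tailed noise, or any spaceflight biology.
Passing recovery tests therefore show the pipeline's statistical machinery
is correct, not that the thresholds are optimal for real microarray data.

## Validation strategy and problem sizes

The published worked example — ten pathway blocks of printed pre/in-flight
correlations — is packaged as a fixture and reproduced exactly: per-block
selected-pair sets, the 32-gene panel, the 48-gene pathway union, and the
dominance of sign-flip categories. The LRT is validated against
hand-evaluated deviances and calibrated on a simulated equal-rate Poisson
null (2 000 replicates, 10 samples per group, rate 50): the rejection rate
at p < 0.05 must be 0.05 ± 0.02. Transition recovery is scored on seeded
synthetic studies at two sizes: 500 subjects × 2 replicates (1 000 columns
per condition, sensitivity ≥ 0.95 and FPR ≤ 0.01 required) and the real
study shape of 20 columns, where correlation estimates are noisy and only
decisive planted transitions (|ΔCC| ≥ 1.2) are required to be recovered at
sensitivity ≥ 0.5 — the small-sample caveat is documented, not hidden.

The original study's dataset-scale outputs (its 218-DEG list, per-gene fold
changes, and the 30 645-transcript genome-wide matrix) require the
E-GEOD-74708 accession and are deliberately not reproduced; the DEG stage
is validated by null calibration and planted-effect recovery instead.

## Known limitations

- Pearson correlation on 20 columns has a standard error around 0.2 for
  weak true correlations; panel membership at that scale is sensitive to
  sampling noise, which is exactly what the study-shape recovery test
  demonstrates.
- No statistical test is attached to ΔCC (the screen is a fixed cut), and
  no correction is made for the number of pairs screened.
- Replicate profiles from the same subject are treated as independent
  samples unless subject effects are switched on.
- The Poisson LRT inherits the count-model assumption; on intensity data
  its p-values are anti-conservative and meaningful mainly in combination
  with the fold-change cut.
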