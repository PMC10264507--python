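# Methods

## Hit calling on protein-array signals

Each arrayed protein contributes ≥ 2 replicate fluorescence signals; all
negative-control replicates on an array are pooled into one control set.
The Z-factor

Z = 1 − 3(σ_s + σ_c−) / |μ_s − μ_c−|

uses the sample (n−1) standard deviation and the arithmetic mean of the
replicates. Replicates are summarized by their mean for the signal rule;
signals are used raw — no background subtraction or normalization is
applied at the hit-calling stage, because the hit rule is stated directly
on signal units. A hit requires mean signal **strictly greater than**
1000 fluorescence units and Z **strictly greater than** 0.4 (both
thresholds configurable). Z is undefined when the feature mean equals the
control mean; such features are excluded from the repertoire with a
logged warning rather than failing the patient. Z ≤ 1 always, and Z is
invariant under a common positive rescaling of all signals, so the
statistic does not depend on scanner gain.

## Group-differential targets

Array platforms report continuous fluorescence, not counts, so the
differential step uses a Welch two-sample *t*-test on log(signal + 1)
after per-array median normalization (each array's mean-replicate signals
are scaled multiplicatively so its median equals the grand median across
arrays), with Benjamini–Hochberg FDR control across genes. The "enriched"
set is genes with q ≤ α (default 0.05) and a higher mean in the first
group. Genes missing in a patient are treated as missing and tested only
with ≥ 2 values per group; genes constant and identical in both groups
get p = 1. The test is a parameter of the operation, so an alternative
(e.g. a count-model fit) can be plugged in.

Overlap percentages are reported to one decimal place with
round-half-even.

## Expressed somatic SNVs

The cascade is: intersect WES and RNA-seq calls on (chrom, pos, ref,
alt) within a patient; drop variants with population allele frequency
**strictly greater than** 0.005 (suspected germline); keep variants with
VAF **≥ 0.10** (inclusive). The two post-intersection filters commute and
the cascade is idempotent. Intersected records keep the DNA-derived
(WES) VAF, since RNA allele fractions are confounded by allelic
expression imbalance. Variants without a population-AF annotation are
retained with a warning — absence from a population database is not
evidence of commonness. Only single amino-acid substitutions are carried
to tiling; other variants stay in the counts flagged non-tileable.

## Neo-epitope candidates

For a mutation at protein position *p* (1-based) and window length *k*,
window starts run from max(1, p−k+1) to min(p, L−k+1); the number of
windows summed over k ∈ {8, 9, 10} is 27 for any interior mutation with
≥ 9 residues on both flanks. The wildtype pair is the unmutated window,
so the pair differs at exactly one position by construction. Prediction
goes through a behavioral contract (affinity in nM, combined processing
score in [0, 1]); the packaged `ToyPredictor` is a deterministic
fixed-weight matrix per length whose summed window weight x maps to
affinity 50000^(1−x) nM — it has no biological content and exists so the
filter, ranking, and reporting logic are exactly testable. An adapter
(`TablePredictor`) serves scores from an external predictor's tabular
output through the same contract.

Filters (all configurable): mutant affinity < 500 nM, combined score
> 0.6, mutant IC50 lower than wildtype ("greater affinity" is read as
lower IC50, the standard convention). The score threshold defaults to
0.6, the value tied to the per-patient candidate counts; 0.8 can be set
where a stricter processing cut is wanted. Panels rank by mutant
affinity ascending, ties broken by higher combined score then peptide
lexicographic order; one candidate per (gene, mutation, length) is kept;
peptides with Kyte–Doolittle GRAVY above the limit (default 2.0, None to
disable) are excluded before ranking; 2–9 peptides are emitted with a
warning below the minimum.

## MAP matching and panels

Eluted peptides (8–11 residues, standard alphabet) are matched by exact
substring against every protein; I/L equivalence is available but off by
default because mass spectrometry cannot distinguish the isobaric pair
and collapsing them is a caller's decision. Panels take up to 10
known-epitope MAPs then up to 2 autoantibody-target MAPs, deduplicated
by sequence and ordered by (gene, sequence) within category, so the
panel is invariant to input order.

## Synthetic cohort

The generator emulates the study design: 9 patients per group (HGSC-like
and mixed-control), duplicate spots per feature, and a pooled
negative-control set. Signal model: unspiked features draw a latent mean
from a log-normal background (median 300 FU, log-SD 0.25, matching the
right-skewed intensity distributions of fluorescence arrays); replicates
add multiplicative log-normal noise at CV 5 %. Spiked responders sit at
8× the background median; group-enriched features at 3× — elevated
enough to separate the groups on the log scale but below the 1000-FU hit
threshold, which reproduces the observed near-disjointness of the shared
and enriched sets. With these defaults the typical Z for a spiked
feature is ≈ 0.75 (the dominant control variance is between-feature
background, ≈ 0.25·μ), and even accounting for the sampling noise of a
2-replicate SD the probability of a spiked feature falling below Z = 0.4
is well under 1 %, so the ≥ 0.95 sensitivity / ≤ 0.05 FDP recovery
checks have real margin rather than being tuned.

The array carries 500 features — a desk-scale stand-in for the ~9000
features of the real platform — with 30 cohort-shared, 20
group-enriched, and 20 patient-private responders, giving per-patient
hit counts of ~50 (the study's per-patient counts, 200–1301 of ~9000
features, occupy a similar fraction of the array). Variants: 30 true
expressed SNVs per patient plus decoys each violating exactly one rule
(WES-only, RNA-only, population AF in (0.01, 0.1], VAF < 0.10); protein
changes are drawn from the shared random proteome so the annotated
wildtype residue always matches the sequence. MAP lists are exact 8–11mer
substrings of proteome entries plus 10 % decoys rejection-sampled to
match nothing.

What the generator does **not** emulate: spatial array artifacts,
probe-specific affinity differences, batch effects, linkage between
expression and antibody signal, realistic mutational signatures, and
homology structure in the proteome (random sequences make accidental
substring matches vanishingly rare, so MAP-matching precision on
synthetic data overstates what a real proteome with paralogs would
give). Passing tests therefore demonstrate the correctness of the
statistics, filters, and set operations under the stated noise model,
not performance on real cohort data.

## Numerical and design choices

- Percent reporting: one decimal, round-half-even (numpy rounding).
- Degenerate Z (μ_s = μ_c−): excluded and logged at hit calling; raised
  as an error when computed directly.
- Gene identifiers join by exact symbol; a two-column alias map can be
  applied before joining. Missing expression is an explicit `None`,
  never zero.
- Quadrant labels use strict `>` for "high", so a gene exactly at a
  cutoff is "low" on that axis; classification is invariant under any
  strictly monotone transform applied consistently to an axis and its
  cutoff.
- All randomness flows through one `numpy` generator seeded from the
  config; outputs carry no timestamps, so fixed seed + config gives
  byte-identical bundles and run directories.
- Config: YAML with a versioned schema; unknown keys are errors.

## Problem sizes

The default cohort (18 patients × 500 features × 2 replicates, 30 SNVs ×
9 patients, 200-protein proteome, 50 MAPs × 3 patients) runs the full
pipeline in a few seconds; the test suite and the acceptance script each
complete in well under a minute on one CPU.

## Known limitations

- The differential test is a deliberate deviation from count-model
  packages sometimes applied to array data; effect sizes are differences
  of mean log-signals, not log-fold-changes of counts.
- The toy predictor's scores carry no immunological meaning; real
  prioritization requires an external NetMHCpan/NetCTLpan-class
  predictor through the `Predictor` contract.
- VCF ingestion reads a minimal INFO dialect (AF/AD, POP_AF, GENE,
  PCHANGE); richly annotated caller output should be converted to the
  TSV dialect or extended through `read_vcf`'s field parameters.
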