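# seroneo

Multi-omics tumor-antigen prioritization for high-grade serous ovarian
cancer (HGSC)-style cohorts. The package integrates four evidence streams
to nominate antigens for T-cell screening:

1. **Seromics** — plasma IgG autoantibody profiling on high-density
   protein arrays. A feature is a significant "hit" when its mean
   replicate signal exceeds 1000 fluorescence units and its Z-factor

   *Z* = 1 − (3σ_s + 3σ_c−) / |μ_s − μ_c−|

   exceeds 0.4, where (μ_s, σ_s) are the mean and SD of the feature
   replicates and (μ_c−, σ_c−) of the pooled negative-control replicates.
2. **Repertoire set algebra** — targets shared by ≥ *k* patients, targets
   enriched in one clinical group (Welch *t* on median-normalized
   log-signals, Benjamini–Hochberg FDR), their union, and overlap
   percentages between cohort repertoires.
3. **Expressed somatic SNVs** — variants called in both tumor WES and
   tumor RNA-seq, with population allele frequency ≤ 0.005 (suspected
   germline removed) and variant allele frequency ≥ 0.10.
4. **Neo-epitope candidates and MAP panels** — every 8/9/10-mer window
   covering a mutated residue is paired with its wildtype counterpart and
   scored through a pluggable MHC-I predictor; candidates pass with
   predicted affinity < 500 nM, combined processing score > 0.6, and
   mutant affinity stronger than wildtype, then are ranked into a 2–9
   peptide synthesis panel. Eluted MHC-associated peptides (MAPs) are
   assigned to genes by exact substring match against the proteome,
   annotated against antigen gene sets and the autoantibody repertoire,
   and assembled into screening panels (up to 10 known epitopes plus 2
   autoantibody-target MAPs).

A synthetic cohort generator (`seroneo.synthetic`) emulates the whole
study design — array signals with spiked responders, paired WES/RNA
variant calls with filter-violating decoys, expression tables, a
reference proteome, and MAP lists — with a complete ground-truth ledger,
so every stage is testable without any external download.

## Worked example

```python
from seroneo import (CohortConfig, generate_cohort, config_from_bundle,
                     run_pipeline)

bundle = generate_cohort(CohortConfig(seed=1), "scratch/cohort")
summary = run_pipeline(config_from_bundle(bundle, "scratch/run", seed=1))
print(summary["set_sizes"])
print(summary["snv_counts"]["HGSC01"], summary["map_panels"]["HGSC01"])
```

prints

```
{'shared': 30, 'enriched': 20, 'combined': 50}
30 12
```

meaning: 30 genes were hit in ≥ 4 of 9 HGSC-group patients (the
generator spiked 30 shared responders), 20 genes were significantly
enriched in the HGSC group at FDR 0.05 (20 were elevated by design),
their union has 50 genes; patient HGSC01 has 30 expressed somatic SNVs
surviving the WES ∩ RNA / germline / VAF cascade, and its MAP screening
panel holds 12 peptides (10 known HLA-A\*02:01 epitopes + 2
autoantibody-target MAPs).

The same run is available from the shell:

```
seroneo simulate --seed 1 --out scratch/cohort
seroneo run-cohort --cohort scratch/cohort --out scratch/run
```

Set-algebra worked example, using the reported repertoire cardinalities
(199 group-enriched genes, 339 shared genes, 14 in common):

```python
from seroneo import GeneSet, combine_repertoire, overlap_stats
shared = GeneSet("shared", frozenset(f"S{i}" for i in range(339)))
common = frozenset(sorted(shared.genes)[:14])
enriched = GeneSet("enriched", frozenset(f"E{i}" for i in range(185)) | common)
combined = combine_repertoire(enriched, shared)
len(combined)                                   # 524
```

An overlap of 165 of those 524 genes with a second repertoire reports as
31.5 %; 148 of 524 as 28.2 % (one decimal, round-half-even).

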