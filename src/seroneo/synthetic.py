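"""Synthetic multi-patient cohort generator with a ground-truth ledger.

Emulates the study design end to end at desk scale: two groups of nine
patients, protein-array signals with duplicate spots and pooled negative
controls, spiked true autoantibody responders (shared, group-enriched,
and patient-private), tumor and thymic-mTEC expression tables, paired
WES/RNA somatic variant calls with filter-violating decoys, a shared
reference proteome consistent with every variant's protein change,
eluted-peptide (MAP) lists sampled as exact proteome substrings plus
non-matching decoys, annotation gene sets, and a known-epitope list.

Every spiked responder, true variant, and true MAP source is enumerated
in a JSON ledger so downstream results are classifiable as TP/FP/FN with
no ambiguity.  A fixed seed yields byte-identical bundles.

Signal model: negative-control and unspiked features draw a feature-level
latent mean from a log-normal background (median ``background_median``,
log-sd ``background_sigma``); replicates add multiplicative log-normal
noise at coefficient of variation ``replicate_cv``.  Spiked responders
have latent mean ``fold_change x background_median``; group-enriched
features use the milder ``fold_enriched`` so they separate groups without
crossing the hit-calling signal threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design."""

    seed: int = 0
    # cohort layout
    n_patients_per_group: int = 9
    group_labels: tuple[str, str] = ("HGSC", "nonHGSC")
    # array
    n_features: int = 500
    n_controls: int = 50
    n_replicates: int = 2
    n_shared_responders: int = 30  # spiked in every patient of both groups
    n_enriched_responders: int = 20  # elevated in group A only, below hit threshold
    n_private_responders: int = 20  # per patient, patient-specific
    fold_change: float = 8.0
    fold_enriched: float = 3.0
    replicate_cv: float = 0.05
    background_median: float = 300.0
    background_sigma: float = 0.25
    # expression
    high_expr_fraction: float = 0.3
    tpm_high_cutoff: float = 10.0
    # variants (per patient in group A)
    n_true_snv: int = 30
    n_decoy_wes_only: int = 5
    n_decoy_rna_only: int = 5
    n_decoy_high_popaf: int = 5
    n_decoy_low_vaf: int = 5
    # proteome
    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (80, 200)
    # MAPs
    n_map_patients: int = 3
    n_maps_per_patient: int = 50
    map_decoy_fraction: float = 0.1
    n_known_epitopes: int = 10
    # genesets
    n_cta_genes: int = 25
    n_tantigen_genes: int = 25

    def __post_init__(self) -> None:
        counts = [
            self.n_patients_per_group,
            self.n_features,
            self.n_controls,
            self.n_shared_responders,
            self.n_enriched_responders,
            self.n_private_responders,
            self.n_true_snv,
            self.n_proteins,
            self.n_maps_per_patient,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per feature")
        for frac in (self.map_decoy_fraction, self.high_expr_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.fold_change <= 0 or self.replicate_cv < 0 or self.background_median <= 0:
            raise ValueError("signal model parameters must be positive")
        per_patient = (
            self.n_shared_responders + self.n_enriched_responders + self.n_private_responders
        )
        if per_patient > self.n_features:
            raise ValueError("spiked responders exceed number of array features")
        if self.n_proteins > self.n_features:
            raise ValueError("proteome genes are a subset of array genes")


@dataclass
class CohortBundle:
    """Paths to the generated files plus the parsed ground-truth ledger."""

    outdir: Path
    paths: dict[str, object]
    truth: dict
    config: CohortConfig


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # log-sd chosen so the multiplicative noise has the requested CV
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def generate_cohort(config: CohortConfig, outdir) -> CohortBundle:
    """Write the full cohort bundle under ``outdir`` and return its handle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_ids(cfg.n_features)
    group_a, group_b = cfg.group_labels
    patients = [
        (f"{label}{i + 1:02d}", label)
        for label in (group_a, group_b)
        for i in range(cfg.n_patients_per_group)
    ]

    # --- responder assignment -------------------------------------------------
    pool = rng.permutation(genes)
    shared_genes = sorted(pool[: cfg.n_shared_responders])
    enriched_genes = sorted(
        pool[cfg.n_shared_responders : cfg.n_shared_responders + cfg.n_enriched_responders]
    )
    remaining = sorted(pool[cfg.n_shared_responders + cfg.n_enriched_responders :])
    private: dict[str, list[str]] = {}
    for pid, _label in patients:
        private[pid] = sorted(rng.choice(remaining, size=cfg.n_private_responders, replace=False))

    expected_hits = {
        pid: sorted(set(shared_genes) | set(private[pid])) for pid, _ in patients
    }

    # --- array signals --------------------------------------------------------
    sigma_bg = cfg.background_sigma
    array_rows = ["\t".join(
        ["patient_id", "group_label", "gene_id", "replicate_index", "signal", "is_control"]
    )]
    for pid, label in patients:
        spiked = set(expected_hits[pid])
        elevated = set(enriched_genes) if label == group_a else set()
        for gene in genes:
            if gene in spiked:
                latent = cfg.fold_change * cfg.background_median
            elif gene in elevated:
                latent = cfg.fold_enriched * cfg.background_median
            else:
                latent = cfg.background_median * float(rng.lognormal(0.0, sigma_bg))
            reps = latent * _lognormal_noise(rng, cfg.replicate_cv, cfg.n_replicates)
            for j, sig in enumerate(reps):
                array_rows.append(f"{pid}\t{label}\t{gene}\t{j}\t{sig:.4f}\t0")
        for c in range(cfg.n_controls):
            latent = cfg.background_median * float(rng.lognormal(0.0, sigma_bg))
            reps = latent * _lognormal_noise(rng, cfg.replicate_cv, cfg.n_replicates)
            for j, sig in enumerate(reps):
                array_rows.append(f"{pid}\t{label}\tCTRL{c:03d}\t{j}\t{sig:.4f}\t1")
    arrays_path = outdir / "arrays.tsv"
    arrays_path.write_text("\n".join(array_rows) + "\n")

    # --- expression tables ----------------------------------------------------
    n_high = int(round(cfg.high_expr_fraction * cfg.n_features))
    tumor_high = sorted(rng.choice(genes, size=n_high, replace=False))
    mtec_high = sorted(rng.choice(genes, size=n_high, replace=False))

    def expr_table(high: set[str]) -> dict[str, float]:
        vals = {}
        for g in genes:
            if g in high:
                vals[g] = float(np.round(rng.uniform(2.0, 20.0) * cfg.tpm_high_cutoff, 3))
            else:
                vals[g] = float(np.round(rng.uniform(0.0, 0.5) * cfg.tpm_high_cutoff, 3))
        return vals

    tumor_expr = expr_table(set(tumor_high))
    mtec_expr = expr_table(set(mtec_high))
    for name, vals in (("expression_tumor.tsv", tumor_expr), ("expression_mtec.tsv", mtec_expr)):
        lines = ["gene_id\tvalue"] + [f"{g}\t{vals[g]}" for g in genes]
        (outdir / name).write_text("\n".join(lines) + "\n")

    # --- proteome -------------------------------------------------------------
    prot_genes = genes[: cfg.n_proteins]
    lo, hi = cfg.protein_length_range
    proteome = {
        g: "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(lo, hi + 1))))
        for g in prot_genes
    }
    fasta_path = outdir / "proteome.fasta"
    with open(fasta_path, "w") as fh:
        for g in prot_genes:
            fh.write(f">{g} synthetic protein\n{proteome[g]}\n")

    # --- variants (group A patients) ------------------------------------------
    truth_snv: dict[str, list[dict]] = {}
    truth_decoys: dict[str, dict[str, list[dict]]] = {}
    variant_paths: dict[str, dict[str, Path]] = {}
    a_patients = [(pid, label) for pid, label in patients if label == group_a]
    for pid, _label in a_patients:
        pos_counter = 1000
        wes_rows: list[dict] = []
        rna_rows: list[dict] = []

        def make_variant(vaf: float, pop_af: float) -> dict:
            nonlocal pos_counter
            pos_counter += int(rng.integers(10, 500))
            gene = str(rng.choice(prot_genes))
            prot_pos = int(rng.integers(1, len(proteome[gene]) + 1))
            wt = proteome[gene][prot_pos - 1]
            mut = str(rng.choice([a for a in AMINO_ACIDS if a != wt]))
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return {
                "patient_id": pid,
                "chrom": "1",
                "pos": pos_counter,
                "ref_allele": ref,
                "alt_allele": alt,
                "gene_id": gene,
                "protein_change": f"{wt}{prot_pos}{mut}",
                "vaf": round(vaf, 4),
                "population_af": round(pop_af, 6),
            }

        true_list, decoys = [], {"wes_only": [], "rna_only": [], "high_popaf": [], "low_vaf": []}
        for _ in range(cfg.n_true_snv):
            v = make_variant(rng.uniform(0.10, 0.60), rng.uniform(0.0, 0.005))
            true_list.append(v)
            wes_rows.append(v)
            rna_rows.append(v)
        for _ in range(cfg.n_decoy_wes_only):
            v = make_variant(rng.uniform(0.10, 0.60), rng.uniform(0.0, 0.005))
            decoys["wes_only"].append(v)
            wes_rows.append(v)
        for _ in range(cfg.n_decoy_rna_only):
            v = make_variant(rng.uniform(0.10, 0.60), rng.uniform(0.0, 0.005))
            decoys["rna_only"].append(v)
            rna_rows.append(v)
        for _ in range(cfg.n_decoy_high_popaf):
            v = make_variant(rng.uniform(0.10, 0.60), rng.uniform(0.01, 0.10))
            decoys["high_popaf"].append(v)
            wes_rows.append(v)
            rna_rows.append(v)
        for _ in range(cfg.n_decoy_low_vaf):
            v = make_variant(rng.uniform(0.01, 0.095), rng.uniform(0.0, 0.005))
            decoys["low_vaf"].append(v)
            wes_rows.append(v)
            rna_rows.append(v)

        truth_snv[pid] = true_list
        truth_decoys[pid] = decoys
        variant_paths[pid] = {}
        for assay, rows in (("wes", wes_rows), ("rna", rna_rows)):
            rows = sorted(rows, key=lambda v: v["pos"])
            tsv = outdir / f"variants_{assay}_{pid}.tsv"
            _write_variant_tsv(rows, assay.upper() if assay == "wes" else "RNA", tsv)
            vcf = outdir / f"variants_{assay}_{pid}.vcf"
            _write_variant_vcf(rows, vcf)
            variant_paths[pid][assay] = tsv
            variant_paths[pid][f"{assay}_vcf"] = vcf

    # --- MAP lists -------------------------------------------------------------
    truth_maps: dict[str, list[dict]] = {}
    decoy_maps: dict[str, list[str]] = {}
    map_paths: dict[str, Path] = {}
    all_prot_seqs = list(proteome.values())
    map_patients = [pid for pid, _ in a_patients][: cfg.n_map_patients]
    for pid in map_patients:
        n_decoy = int(round(cfg.map_decoy_fraction * cfg.n_maps_per_patient))
        n_true = cfg.n_maps_per_patient - n_decoy
        true_entries = []
        for _ in range(n_true):
            gene = str(rng.choice(prot_genes))
            seq = proteome[gene]
            k = int(rng.integers(8, 12))
            start = int(rng.integers(0, len(seq) - k + 1))
            true_entries.append({"sequence": seq[start : start + k], "gene": gene})
        decoy_entries = []
        while len(decoy_entries) < n_decoy:
            k = int(rng.integers(8, 12))
            pep = "".join(rng.choice(list(AMINO_ACIDS), size=k))
            if not any(pep in s for s in all_prot_seqs):
                decoy_entries.append(pep)
        truth_maps[pid] = true_entries
        decoy_maps[pid] = decoy_entries
        path = outdir / f"maps_{pid}.txt"
        path.write_text(
            "\n".join([e["sequence"] for e in true_entries] + decoy_entries) + "\n"
        )
        map_paths[pid] = path

    # --- genesets and known epitopes -------------------------------------------
    cta = sorted(rng.choice(genes, size=cfg.n_cta_genes, replace=False))
    tantigen = sorted(rng.choice(genes, size=cfg.n_tantigen_genes, replace=False))
    gmt_path = outdir / "genesets.gmt"
    gmt_path.write_text(
        "\t".join(["CTA", "synthetic", *cta])
        + "\n"
        + "\t".join(["TANTIGEN", "synthetic", *tantigen])
        + "\n"
    )
    known: list[list[str]] = []
    if map_patients:
        candidates = truth_maps[map_patients[0]]
        idx = rng.choice(len(candidates), size=min(cfg.n_known_epitopes, len(candidates)), replace=False)
        known = [[candidates[i]["sequence"], candidates[i]["gene"]] for i in sorted(idx)]
    known_path = outdir / "known_epitopes.tsv"
    known_path.write_text("".join(f"{seq}\t{gene}\n" for seq, gene in known))

    # --- ground-truth ledger ----------------------------------------------------
    truth = {
        "config": asdict(cfg),
        "patients": [[pid, label] for pid, label in patients],
        "shared_genes": shared_genes,
        "enriched_genes": enriched_genes,
        "private_responders": {pid: list(private[pid]) for pid, _ in patients},
        "expected_hits": expected_hits,
        "tumor_high_genes": tumor_high,
        "mtec_high_genes": mtec_high,
        "true_snv": truth_snv,
        "decoy_snv": truth_decoys,
        "true_maps": truth_maps,
        "decoy_maps": decoy_maps,
        "known_epitopes": known,
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")

    paths = {
        "arrays": arrays_path,
        "expression_tumor": outdir / "expression_tumor.tsv",
        "expression_mtec": outdir / "expression_mtec.tsv",
        "proteome": fasta_path,
        "genesets": gmt_path,
        "known_epitopes": known_path,
        "variants": variant_paths,
        "maps": map_paths,
        "ground_truth": truth_path,
    }
    return CohortBundle(outdir=outdir, paths=paths, truth=truth, config=cfg)


def _write_variant_tsv(rows: list[dict], evidence: str, path: Path) -> None:
    header = [
        "patient_id", "chrom", "pos", "ref_allele", "alt_allele",
        "gene_id", "protein_change", "vaf", "population_af", "evidence",
    ]
    lines = ["\t".join(header)]
    for v in rows:
        lines.append(
            "\t".join(
                [
                    v["patient_id"], v["chrom"], str(v["pos"]), v["ref_allele"],
                    v["alt_allele"], v["gene_id"], v["protein_change"],
                    str(v["vaf"]), str(v["population_af"]), evidence,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency (gnomAD-style)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_variant_vcf(rows: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in rows:
            info = (
                f"AF={v['vaf']};POP_AF={v['population_af']};"
                f"GENE={v['gene_id']};PCHANGE={v['protein_change']}"
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t.\t{v['ref_allele']}\t{v['alt_allele']}"
                f"\t.\tPASS\t{info}\n"
            )
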