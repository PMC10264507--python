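"""End-to-end orchestration: seromics -> set algebra -> variants ->
neo-epitopes -> expression integration -> MAP panels.

A :class:`RunConfig` (YAML, versioned schema, unknown keys rejected)
names the inputs and every stage threshold; :func:`run_pipeline`
executes the stages in order, writing per-stage TSV/JSON outputs, a run
manifest (config hash, seed, version), and a summary report under the
run directory.  Outputs carry no timestamps, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import expressed_variants as ev
from . import expression_integration as ei
from . import map_panel as mp
from . import neoepitope as ne
from . import repertoire_sets as rs
from . import seromics as sm
from .synthetic import CohortBundle

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class Thresholds:
    signal_threshold: float = sm.DEFAULT_SIGNAL_THRESHOLD
    z_threshold: float = sm.DEFAULT_Z_THRESHOLD
    min_patients: int = 4
    fdr_alpha: float = 0.05
    population_af_threshold: float = ev.DEFAULT_POPULATION_AF_THRESHOLD
    min_vaf: float = ev.DEFAULT_MIN_VAF
    max_affinity_nM: float = ne.DEFAULT_MAX_AFFINITY_NM
    min_combined_score: float = ne.DEFAULT_MIN_COMBINED_SCORE
    panel_min: int = ne.DEFAULT_PANEL_MIN
    panel_max: int = ne.DEFAULT_PANEL_MAX
    hydropathy_limit: float | None = ne.DEFAULT_HYDROPATHY_LIMIT
    allele: str = "HLA-A*02:01"
    tumor_cut: float = 10.0
    mtec_cut: float = 10.0
    max_known: int = mp.DEFAULT_MAX_KNOWN
    max_autoab: int = mp.DEFAULT_MAX_AUTOAB


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration; round-trips losslessly through YAML."""

    outdir: str
    arrays: str
    seed: int = 0
    expression_tumor: str | None = None
    expression_mtec: str | None = None
    proteome: str | None = None
    genesets: str | None = None
    known_epitopes: str | None = None
    variants: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    maps: Mapping[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["variants"] = {k: dict(v) for k, v in self.variants.items()}
        d["maps"] = dict(self.maps)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
        thr = data.pop("thresholds", {}) or {}
        known_thr = {f.name for f in dataclasses.fields(Thresholds)}
        bad = set(thr) - known_thr
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        known_top = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known_top
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(thresholds=Thresholds(**thr), **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def config_from_bundle(bundle: CohortBundle, outdir, seed: int = 0) -> RunConfig:
    """Build a RunConfig pointing at a generated synthetic-cohort bundle."""
    p = bundle.paths
    return RunConfig(
        outdir=str(outdir),
        seed=seed,
        arrays=str(p["arrays"]),
        expression_tumor=str(p["expression_tumor"]),
        expression_mtec=str(p["expression_mtec"]),
        proteome=str(p["proteome"]),
        genesets=str(p["genesets"]),
        known_epitopes=str(p["known_epitopes"]),
        variants={
            pid: {"wes": str(d["wes"]), "rna": str(d["rna"])}
            for pid, d in p["variants"].items()
        },
        maps={pid: str(path) for pid, path in p["maps"].items()},
    )


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the summary report (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    summary: dict[str, Any] = {}

    # ---- seromics ----------------------------------------------------------
    try:
        patients = sm.read_array_table(config.arrays)
        repertoires = [
            sm.call_hits(p, thr.signal_threshold, thr.z_threshold) for p in patients
        ]
        sm.write_hit_table(repertoires, outdir / "hits.tsv")
        cohort = sm.summarize_cohort(repertoires)
        cohort.to_csv(outdir / "hit_counts.tsv", sep="\t", index=False)
        summary["hit_counts"] = dict(zip(cohort["patient_id"], cohort["n_hits"].astype(int)))
        summary["group_mean_hits"] = cohort.attrs["group_means"]
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("seromics", exc) from exc

    # ---- repertoire set algebra -------------------------------------------
    try:
        groups = sorted({p.group_label for p in patients})
        by_group = {g: [p for p in patients if p.group_label == g] for g in groups}
        reps_by_id = {r.patient_id: r for r in repertoires}
        a_label = groups[0] if len(groups) < 2 else ("HGSC" if "HGSC" in groups else groups[0])
        b_label = next((g for g in groups if g != a_label), None)
        a_reps = [reps_by_id[p.patient_id] for p in by_group[a_label]]
        shared = rs.shared_targets(a_reps, thr.min_patients, name="shared")
        if b_label is not None and len(by_group[a_label]) >= 2 and len(by_group[b_label]) >= 2:
            diff = rs.differential_targets(by_group[a_label], by_group[b_label], thr.fdr_alpha)
            rs.write_differential_table(diff, outdir / "differential.tsv")
            enriched = rs.enriched_geneset(diff, thr.fdr_alpha, name="enriched")
        else:
            logger.info("single-group cohort: differential stage skipped")
            enriched = rs.GeneSet("enriched", frozenset())
        combined = rs.combine_repertoire(enriched, shared, name="combined")
        rs.write_gmt([shared, enriched, combined], outdir / "repertoires.gmt")
        summary["set_sizes"] = {
            "shared": len(shared),
            "enriched": len(enriched),
            "combined": len(combined),
        }
        annotation_sets = rs.read_gmt(config.genesets) if config.genesets else []
        overlaps = [rs.overlap_stats(combined, gs) for gs in annotation_sets]
        if overlaps:
            rs.write_overlap_table(overlaps, outdir / "overlaps.tsv")
        summary["overlaps"] = {
            o.set_b_name: {"n_overlap": o.n_overlap, "percent_of_combined": o.percent_of_a_1dp()}
            for o in overlaps
        }
    except Exception as exc:
        raise StageError("repertoire_sets", exc) from exc

    # ---- expressed variants -------------------------------------------------
    expressed: dict[str, list[ev.SomaticVariant]] = {}
    try:
        for pid, assay_paths in sorted(config.variants.items()):
            wes = ev.read_variant_table(assay_paths["wes"])
            rna = ev.read_variant_table(assay_paths["rna"])
            expressed[pid] = ev.expressed_snv_cascade(
                wes, rna, thr.population_af_threshold, thr.min_vaf
            )
        all_expressed = [v for vs in expressed.values() for v in vs]
        if all_expressed:
            ev.write_variant_table(all_expressed, outdir / "expressed_snv.tsv")
            snv_summary = ev.summarize_expressed_snv(all_expressed)
            snv_summary.to_csv(outdir / "snv_counts.tsv", sep="\t", index=False)
            summary["snv_counts"] = dict(
                zip(snv_summary["patient_id"], snv_summary["n_snv"].astype(int))
            )
        else:
            summary["snv_counts"] = {}
    except Exception as exc:
        raise StageError("expressed_variants", exc) from exc

    # ---- neo-epitope selection ----------------------------------------------
    try:
        summary["neoepitope_panels"] = {}
        if config.proteome and expressed:
            proteome = mp.read_proteome_fasta(config.proteome)
            predictor = ne.ToyPredictor()
            panels = []
            for pid, variants in sorted(expressed.items()):
                passing = []
                for v in variants:
                    if not v.is_tileable or v.gene_id not in proteome:
                        continue
                    cands = ne.tile_peptides(
                        proteome[v.gene_id], v.protein_change, v.gene_id, pid
                    )
                    scored = ne.score_candidates(cands, predictor, thr.allele)
                    passing.extend(
                        ne.filter_candidates(
                            scored, thr.max_affinity_nM, thr.min_combined_score
                        )
                    )
                panel = ne.select_panel(
                    passing, thr.panel_min, thr.panel_max, thr.hydropathy_limit
                )
                panels.extend(panel)
                summary["neoepitope_panels"][pid] = len(panel)
            ne.write_panel_table(panels, outdir / "neoepitope_panel.tsv")
            ne.write_panel_fasta(panels, outdir / "neoepitope_panel.fasta")
    except Exception as exc:
        raise StageError("neoepitope_select", exc) from exc

    # ---- expression integration ---------------------------------------------
    try:
        tables = []
        if config.expression_tumor:
            tables.append(ei.ExpressionTable.from_tsv(config.expression_tumor, ei.TUMOR_SOURCE))
        if config.expression_mtec:
            tables.append(ei.ExpressionTable.from_tsv(config.expression_mtec, ei.MTEC_SOURCE))
        # cohort-level Z: per gene, the maximum Z-factor across group-A repertoires
        best: dict[str, tuple[float, float]] = {}
        for r in a_reps:
            for gene, (z, mean) in r.hits.items():
                if gene not in best or z > best[gene][0]:
                    best[gene] = (z, mean)
        pooled = sm.HitRepertoire(patient_id="cohort", hits=best, group_label=a_label)
        annotated = ei.join_expression(combined, tables, pooled, annotation_sets)
        quadrants = ei.classify_quadrants(annotated, thr.tumor_cut, thr.mtec_cut)
        ei.write_annotated_targets(annotated, outdir / "annotated_targets.tsv")
        ei.write_quadrant_summary(quadrants, outdir / "quadrant_summary.json")
        summary["quadrants"] = quadrants
        mutated_overlap = {}
        for pid, variants in sorted(expressed.items()):
            if pid in reps_by_id:
                gset, frac = ei.flag_mutated_targets(reps_by_id[pid], variants)
                mutated_overlap[pid] = {
                    "n_mutated_hits": len(gset),
                    "fraction_of_mutated": frac,
                }
        summary["mutated_target_overlap"] = mutated_overlap
    except Exception as exc:
        raise StageError("expression_integration", exc) from exc

    # ---- MAP panels -----------------------------------------------------------
    try:
        summary["map_panels"] = {}
        if not config.maps or not config.proteome:
            logger.info("MAP inputs missing: MAP stage skipped")
            summary["map_panels"] = {"skipped": "no MAP inputs"}
        else:
            proteome = mp.read_proteome_fasta(config.proteome)
            known = (
                mp.read_known_epitopes(config.known_epitopes)
                if config.known_epitopes
                else []
            )
            for pid, path in sorted(config.maps.items()):
                peptides = mp.read_peptide_list(path)
                matched = mp.match_to_proteome(peptides, proteome, patient_id=pid)
                annotated_maps = mp.annotate_maps(matched, annotation_sets, combined, known)
                panel = mp.select_map_panel(annotated_maps, thr.max_known, thr.max_autoab)
                mp.write_map_panel(
                    panel, outdir / f"map_panel_{pid}.tsv", outdir / f"map_panel_{pid}.fasta"
                )
                summary["map_panels"][pid] = len(panel)
    except Exception as exc:
        raise StageError("map_panel", exc) from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
    }
    _write_json(manifest, outdir / "manifest.json")
    _write_json(summary, outdir / "summary.json")
    return summary
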