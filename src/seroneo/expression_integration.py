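"""Join target gene sets with tumor, thymic, and TCGA-style expression.

Targets from the autoantibody repertoire are annotated with tumor RNA-seq
TPM, medullary thymic epithelial cell (mTEC) expression, and optional
TCGA-style normalized columns; overlaid with cancer/testis-antigen and
T-cell-antigen gene sets; classified into high/low expression quadrants;
and intersected with the patient's mutated genes.  Missing expression is
represented explicitly (None), never as zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expressed_variants import SomaticVariant
from .repertoire_sets import GeneSet
from .seromics import HitRepertoire

TUMOR_SOURCE = "tumor_TPM"
MTEC_SOURCE = "mTEC"
QUADRANT_LABELS = ("high/high", "high/low", "low/high", "low/low", "missing")


@dataclass(frozen=True)
class ExpressionTable:
    """Gene-level expression values from one labeled source."""

    source: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    @classmethod
    def from_tsv(cls, path, source: str, sep: str = "\t") -> "ExpressionTable":
        df = pd.read_csv(path, sep=sep)
        if not {"gene_id", "value"} <= set(df.columns):
            raise ValueError("expression table needs columns gene_id, value")
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene_ids in expression table {path}")
        return cls(source, dict(zip(df["gene_id"].astype(str), df["value"].astype(float))))

    def get(self, gene_id: str) -> float | None:
        return self.values.get(gene_id)


@dataclass
class AnnotatedTarget:
    """One target gene with expression, flags, and quadrant label."""

    gene_id: str
    z_factor: float | None = None
    tumor_expr: float | None = None
    mtec_expr: float | None = None
    other_expr: dict[str, float | None] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    quadrant: str | None = None


def read_alias_map(path, sep: str = "\t") -> dict[str, str]:
    """Two-column alias -> canonical gene symbol map."""
    df = pd.read_csv(path, sep=sep, header=None, names=["alias", "canonical"])
    return dict(zip(df["alias"].astype(str), df["canonical"].astype(str)))


def apply_alias(table: ExpressionTable, alias: Mapping[str, str]) -> ExpressionTable:
    """Rename genes through the alias map before joining (exact match only)."""
    renamed: dict[str, float] = {}
    for gene, value in table.values.items():
        renamed[alias.get(gene, gene)] = value
    return ExpressionTable(table.source, renamed)


def join_expression(
    targets: GeneSet,
    tables: Sequence[ExpressionTable],
    repertoire: HitRepertoire | None = None,
    genesets: Sequence[GeneSet] = (),
) -> list[AnnotatedTarget]:
    """One annotated record per target gene.

    Sources labeled ``tumor_TPM`` and ``mTEC`` populate the dedicated
    columns; any other source lands in ``other_expr`` under its label.
    Genes absent from a table get an explicit missing marker (None), and
    membership in each supplied gene set is recorded as a flag named
    after the set.
    """
    by_source = {t.source: t for t in tables}
    tumor = by_source.get(TUMOR_SOURCE)
    mtec = by_source.get(MTEC_SOURCE)
    others = [t for t in tables if t.source not in (TUMOR_SOURCE, MTEC_SOURCE)]
    out = []
    for gene in sorted(targets.genes):
        rec = AnnotatedTarget(gene_id=gene)
        if repertoire is not None and gene in repertoire.hits:
            rec.z_factor = repertoire.hits[gene][0]
        if tumor is not None:
            rec.tumor_expr = tumor.get(gene)
        if mtec is not None:
            rec.mtec_expr = mtec.get(gene)
        for t in others:
            rec.other_expr[t.source] = t.get(gene)
        rec.flags = {gs.name for gs in genesets if gene in gs}
        out.append(rec)
    return out


def classify_quadrants(
    targets: Iterable[AnnotatedTarget],
    tumor_cut: float,
    mtec_cut: float,
) -> dict[str, int]:
    """Label each target by tumor/mTEC expression quadrant; return counts.

    "High" means strictly above the cutoff; a gene sitting exactly on a
    cutoff is low on that axis.  Targets missing either value are labeled
    "missing".  Mutates the records in place and returns the per-quadrant
    counts.
    """
    counts = {q: 0 for q in QUADRANT_LABELS}
    for rec in targets:
        if rec.tumor_expr is None or rec.mtec_expr is None:
            rec.quadrant = "missing"
        else:
            t = "high" if rec.tumor_expr > tumor_cut else "low"
            m = "high" if rec.mtec_expr > mtec_cut else "low"
            rec.quadrant = f"{t}/{m}"
        counts[rec.quadrant] += 1
    return counts


def flag_mutated_targets(
    repertoire: HitRepertoire, variants: Iterable[SomaticVariant]
) -> tuple[GeneSet, float | None]:
    """Mutated genes that are also autoantibody hits, and their fraction.

    Returns the intersection gene set and the fraction of mutated genes
    found in the hit repertoire; the fraction is None (missing) when the
    patient has no variants.
    """
    mutated = {v.gene_id for v in variants}
    if not mutated:
        return GeneSet(f"{repertoire.patient_id}_mutated_hits", frozenset()), None
    overlap = frozenset(mutated & set(repertoire.hits))
    return (
        GeneSet(f"{repertoire.patient_id}_mutated_hits", overlap),
        len(overlap) / len(mutated),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_annotated_targets(targets: Iterable[AnnotatedTarget], path, sep: str = "\t") -> None:
    rows = []
    for t in targets:
        row = {
            "gene_id": t.gene_id,
            "z_factor": t.z_factor,
            "tumor_expr": t.tumor_expr,
            "mtec_expr": t.mtec_expr,
            "flags": ",".join(sorted(t.flags)),
            "quadrant": t.quadrant or "",
        }
        row.update({f"expr_{k}": v for k, v in sorted(t.other_expr.items())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, na_rep="NA")


def write_quadrant_summary(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(counts), fh, indent=2, sort_keys=True)
        fh.write("\n")
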