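"""Expressed somatic SNV selection from paired WES and RNA-seq calls.

A variant counts as an "expressed somatic SNV" when it is (1) called in
both the tumor exome and the tumor RNA-seq of the same patient, (2) not a
suspected germline polymorphism (population allele frequency <= 0.005;
strictly greater is removed), and (3) well supported (variant allele
frequency >= 0.10, inclusive).  The two post-intersection filters commute
and the whole cascade is idempotent.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_POPULATION_AF_THRESHOLD = 0.005
DEFAULT_MIN_VAF = 0.10

_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z\*])(\d+)([A-Z\*])$")


@dataclass(frozen=True)
class ProteinChange:
    """Single-residue substitution: wildtype residue, 1-based position, mutant."""

    wt_residue: str
    position: int
    mut_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"protein position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, text: str) -> "ProteinChange":
        m = _PROTEIN_CHANGE_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse protein change {text!r} (expected e.g. 'A123T')")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic SNV with its allele frequencies and calling evidence."""

    patient_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene_id: str
    vaf: float
    population_af: float | None = None
    protein_change: ProteinChange | None = None
    evidence: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF must be in [0,1], got {self.vaf}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population AF must be in [0,1], got {self.population_af}")
        object.__setattr__(self, "evidence", frozenset(self.evidence))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_tileable(self) -> bool:
        """True when the variant encodes a single amino-acid substitution."""
        pc = self.protein_change
        return pc is not None and pc.wt_residue != pc.mut_residue and "*" not in (
            pc.wt_residue + pc.mut_residue
        )


def _check_single_patient(variants: Sequence[SomaticVariant]) -> None:
    pids = {v.patient_id for v in variants}
    if len(pids) > 1:
        raise ValueError(f"mixed patient_ids in one call set: {sorted(pids)}")


def intersect_calls(
    wes: Sequence[SomaticVariant], rna: Sequence[SomaticVariant]
) -> list[SomaticVariant]:
    """Variants called in both WES and RNA-seq (keyed by chrom/pos/ref/alt).

    Symmetric in its arguments; retained records carry the WES allele
    frequencies (DNA-derived VAF) with evidence {WES, RNA}.  Both inputs
    must belong to the same patient.
    """
    wes, rna = list(wes), list(rna)
    _check_single_patient(wes + rna)
    rna_keys = {v.key for v in rna}
    rna_by_key = {v.key: v for v in rna}
    out = []
    for v in wes:
        if v.key in rna_keys:
            other = rna_by_key[v.key]
            pop_af = v.population_af if v.population_af is not None else other.population_af
            pc = v.protein_change if v.protein_change is not None else other.protein_change
            out.append(
                replace(
                    v,
                    population_af=pop_af,
                    protein_change=pc,
                    evidence=v.evidence | other.evidence | {"WES", "RNA"},
                )
            )
    return out


def filter_germline(
    variants: Iterable[SomaticVariant],
    af_threshold: float = DEFAULT_POPULATION_AF_THRESHOLD,
) -> list[SomaticVariant]:
    """Remove suspected germline SNPs: population AF strictly above threshold.

    Variants with no population AF annotation are retained with a warning.
    """
    kept = []
    n_missing = 0
    for v in variants:
        if v.population_af is None:
            n_missing += 1
            kept.append(v)
        elif v.population_af <= af_threshold:
            kept.append(v)
    if n_missing:
        warnings.warn(
            f"{n_missing} variant(s) lack population AF annotation; retained",
            stacklevel=2,
        )
    return kept


def filter_vaf(
    variants: Iterable[SomaticVariant], min_vaf: float = DEFAULT_MIN_VAF
) -> list[SomaticVariant]:
    """Retain variants with VAF >= ``min_vaf`` (inclusive)."""
    return [v for v in variants if v.vaf >= min_vaf]


def expressed_snv_cascade(
    wes: Sequence[SomaticVariant],
    rna: Sequence[SomaticVariant],
    af_threshold: float = DEFAULT_POPULATION_AF_THRESHOLD,
    min_vaf: float = DEFAULT_MIN_VAF,
) -> list[SomaticVariant]:
    """Full cascade: WES ∩ RNA, then germline and VAF filters."""
    return filter_vaf(filter_germline(intersect_calls(wes, rna), af_threshold), min_vaf)


def summarize_expressed_snv(variants: Iterable[SomaticVariant]) -> pd.DataFrame:
    """Per-patient expressed-SNV counts and mutated gene lists."""
    by_patient: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_patient.setdefault(v.patient_id, []).append(v)
    rows = [
        {
            "patient_id": pid,
            "n_snv": len(vs),
            "genes": ",".join(sorted({v.gene_id for v in vs})),
        }
        for pid, vs in sorted(by_patient.items())
    ]
    return pd.DataFrame(rows, columns=["patient_id", "n_snv", "genes"])


# ---------------------------------------------------------------------------
# I/O: TSV dialect and VCF ingestion
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "gene_id",
    "protein_change",
    "vaf",
    "population_af",
    "evidence",
]


def read_variant_table(path, sep: str = "\t") -> list[SomaticVariant]:
    """Read the plain delimited variant dialect (see VARIANT_COLUMNS)."""
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    out = []
    for r in df.itertuples():
        pc = None
        if isinstance(r.protein_change, str) and r.protein_change:
            pc = ProteinChange.parse(r.protein_change)
        pop_af = None if pd.isna(r.population_af) else float(r.population_af)
        ev = frozenset(str(r.evidence).split(",")) if isinstance(r.evidence, str) else frozenset()
        out.append(
            SomaticVariant(
                patient_id=str(r.patient_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref_allele=str(r.ref_allele),
                alt_allele=str(r.alt_allele),
                gene_id=str(r.gene_id),
                vaf=float(r.vaf),
                population_af=pop_af,
                protein_change=pc,
                evidence=ev,
            )
        )
    return out


def write_variant_table(variants: Iterable[SomaticVariant], path, sep: str = "\t") -> None:
    rows = [
        {
            "patient_id": v.patient_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
            "gene_id": v.gene_id,
            "protein_change": "" if v.protein_change is None else str(v.protein_change),
            "vaf": v.vaf,
            "population_af": "" if v.population_af is None else v.population_af,
            "evidence": ",".join(sorted(v.evidence)),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep=sep, index=False)


def read_vcf(
    path,
    patient_id: str,
    evidence: str,
    population_af_field: str = "POP_AF",
) -> list[SomaticVariant]:
    """Ingest SNVs from a VCF.

    VAF precedence: INFO/AF first, then alt/total depth from INFO/AD.
    Gene and protein change are read from INFO/GENE and INFO/PCHANGE when
    present.  Population AF comes from ``population_af_field`` (gnomAD-style
    annotation); absent values are stored as missing.
    """
    from cyvcf2 import VCF  # deferred: optional at import time for pure-TSV use

    out = []
    for rec in VCF(str(path)):
        if rec.ALT is None or len(rec.ALT) != 1:
            continue
        info = dict(rec.INFO)
        af = info.get("AF")
        if af is None and "AD" in info:
            ad = info["AD"]
            ref_d, alt_d = (ad if isinstance(ad, tuple) else tuple(ad))[:2]
            total = ref_d + alt_d
            af = alt_d / total if total > 0 else 0.0
        if af is None:
            logger.warning("variant %s:%s has no AF/AD; skipped", rec.CHROM, rec.POS)
            continue
        pop_af = info.get(population_af_field)
        pc_str = info.get("PCHANGE")
        out.append(
            SomaticVariant(
                patient_id=patient_id,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref_allele=str(rec.REF),
                alt_allele=str(rec.ALT[0]),
                gene_id=str(info.get("GENE", "")),
                vaf=float(af),
                population_af=None if pop_af is None else float(pop_af),
                protein_change=ProteinChange.parse(pc_str) if pc_str else None,
                evidence=frozenset({evidence}),
            )
        )
    return out
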