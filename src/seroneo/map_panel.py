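"""Eluted MHC-associated peptide (MAP) matching, annotation, and panels.

Immunopeptidome peptides (8–11-mers eluted from surface MHC and
identified upstream by mass spectrometry) are assigned to genes by exact
substring search against a protein database, annotated against tumor
antigen gene sets, the autoantibody repertoire, and a list of known
HLA-A*02:01 epitopes, and assembled into deterministic screening panels
(known epitopes first, then autoantibody-target MAPs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .repertoire_sets import GeneSet

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
MIN_MAP_LENGTH = 8
MAX_MAP_LENGTH = 11
DEFAULT_MAX_KNOWN = 10
DEFAULT_MAX_AUTOAB = 2


@dataclass(frozen=True)
class MapPeptide:
    """One eluted ligand with its gene assignment(s) and annotations."""

    patient_id: str
    sequence: str
    matched_genes: frozenset[str] = frozenset()
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "matched_genes", frozenset(self.matched_genes))
        object.__setattr__(self, "annotations", frozenset(self.annotations))


def read_proteome_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by gene identifier (first token of header)."""
    proteome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome[rec.id] = str(rec.seq).upper()
    if not proteome:
        raise ValueError(f"no sequences found in {path}")
    return proteome


def read_peptide_list(path) -> list[str]:
    """Plain-text peptide list, one sequence per line."""
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def match_to_proteome(
    peptides: Sequence[str],
    proteome: Mapping[str, str],
    patient_id: str = "",
    il_equivalent: bool = False,
) -> list[MapPeptide]:
    """Assign each peptide to every protein containing it as a substring.

    Peptides outside 8–11 residues or containing non-standard residues
    are skipped with a warning; unmatched peptides are retained with an
    empty match set.  ``il_equivalent`` treats isoleucine and leucine as
    indistinguishable (off by default, reflecting that MS cannot separate
    them).
    """
    if not proteome:
        raise ValueError("proteome is empty")

    def canon(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    canon_proteome = {g: canon(seq) for g, seq in proteome.items()}
    out = []
    for pep in peptides:
        pep = pep.upper()
        if not MIN_MAP_LENGTH <= len(pep) <= MAX_MAP_LENGTH:
            warnings.warn(
                f"peptide {pep!r} length {len(pep)} outside [8, 11]; skipped", stacklevel=2
            )
            continue
        if not set(pep) <= STANDARD_AA:
            warnings.warn(f"peptide {pep!r} has non-standard residues; skipped", stacklevel=2)
            continue
        cp = canon(pep)
        matches = frozenset(g for g, seq in canon_proteome.items() if cp in seq)
        if not matches:
            logger.info("peptide %s matched no protein", pep)
        out.append(MapPeptide(patient_id=patient_id, sequence=pep, matched_genes=matches))
    return out


def annotate_maps(
    map_peptides: Iterable[MapPeptide],
    genesets: Sequence[GeneSet] = (),
    repertoire: GeneSet | None = None,
    known_epitopes: Sequence[tuple[str, str]] = (),
) -> list[MapPeptide]:
    """Set annotation flags from gene membership and known-epitope identity.

    A gene-set flag (named after the set) is set when any matched gene is
    a member; ``autoAb_target`` when any matched gene is in the
    autoantibody repertoire; ``known_A2_epitope`` only on exact sequence
    match to the supplied known-epitope list.
    """
    known_seqs = {seq.upper() for seq, _gene in known_epitopes}
    out = []
    for mp in map_peptides:
        flags = set(mp.annotations)
        for gs in genesets:
            if mp.matched_genes & gs.genes:
                flags.add(gs.name)
        if repertoire is not None and mp.matched_genes & repertoire.genes:
            flags.add("autoAb_target")
        if mp.sequence in known_seqs:
            flags.add("known_A2_epitope")
        out.append(replace(mp, annotations=frozenset(flags)))
    return out


def _category_sort_key(mp: MapPeptide) -> tuple[str, str]:
    gene = min(mp.matched_genes) if mp.matched_genes else ""
    return (gene, mp.sequence)


def select_map_panel(
    annotated: Sequence[MapPeptide],
    max_known: int = DEFAULT_MAX_KNOWN,
    max_autoab: int = DEFAULT_MAX_AUTOAB,
) -> list[MapPeptide]:
    """Assemble a screening panel from annotated MAPs.

    Up to ``max_known`` known-epitope MAPs, then up to ``max_autoab``
    autoantibody-target MAPs, deduplicated by sequence; within each
    category the order is (gene name, sequence), making the panel
    deterministic regardless of input order.
    """
    seen: set[str] = set()
    panel: list[MapPeptide] = []

    known = sorted(
        (mp for mp in annotated if "known_A2_epitope" in mp.annotations),
        key=_category_sort_key,
    )
    for mp in known:
        if len([p for p in panel if "known_A2_epitope" in p.annotations]) >= max_known:
            break
        if mp.sequence not in seen:
            seen.add(mp.sequence)
            panel.append(mp)

    autoab = sorted(
        (
            mp
            for mp in annotated
            if "autoAb_target" in mp.annotations and "known_A2_epitope" not in mp.annotations
        ),
        key=_category_sort_key,
    )
    n_autoab = 0
    for mp in autoab:
        if n_autoab >= max_autoab:
            break
        if mp.sequence not in seen:
            seen.add(mp.sequence)
            panel.append(mp)
            n_autoab += 1

    if not panel:
        warnings.warn("no eligible MAPs; empty panel", stacklevel=2)
    return panel


def read_known_epitopes(path, sep: str = "\t") -> list[tuple[str, str]]:
    """Two-column (sequence, gene) known-epitope list."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"malformed known-epitope line: {line!r}")
            out.append((parts[0].upper(), parts[1]))
    return out


def write_map_panel(panel: Sequence[MapPeptide], tsv_path, fasta_path=None) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "patient_id": mp.patient_id,
                "sequence": mp.sequence,
                "matched_genes": ",".join(sorted(mp.matched_genes)),
                "annotations": ",".join(sorted(mp.annotations)),
            }
            for mp in panel
        ],
        columns=["patient_id", "sequence", "matched_genes", "annotations"],
    ).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for mp in panel:
                gene = min(mp.matched_genes) if mp.matched_genes else "unassigned"
                fh.write(f">{mp.patient_id}|{gene}|{mp.sequence}\n{mp.sequence}\n")
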