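"""Mutation-centered neo-epitope candidate generation and selection.

For each expressed missense SNV, every 8/9/10-mer window of the protein
that covers the mutated residue is paired with its wildtype counterpart,
scored through a pluggable MHC class I predictor (binding affinity in nM
plus a combined processing score in [0,1]), and filtered: predicted
affinity below 500 nM, combined score above 0.6, and mutant affinity
stronger (numerically lower IC50) than wildtype.  Survivors are ranked
and capped into a per-patient synthesis panel, optionally excluding
overly hydrophobic peptides (Kyte–Doolittle GRAVY).

The shipped :class:`ToyPredictor` is a deterministic fixed-weight stand-in
used for testing; adapters for external predictor output tables plug in
through the same :class:`Predictor` contract.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .expressed_variants import ProteinChange

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_LENGTHS = (8, 9, 10)
DEFAULT_MAX_AFFINITY_NM = 500.0
DEFAULT_MIN_COMBINED_SCORE = 0.6
DEFAULT_PANEL_MIN = 2
DEFAULT_PANEL_MAX = 9
DEFAULT_HYDROPATHY_LIMIT = 2.0


class ResidueMismatchError(ValueError):
    """Annotated wildtype residue disagrees with the protein sequence."""


@runtime_checkable
class Predictor(Protocol):
    """Behavioral contract for MHC class I epitope predictors.

    Implementations must be deterministic for fixed inputs and defined
    for peptide lengths 8-10.
    """

    def affinity(self, peptide: str, allele: str) -> float:
        """Predicted binding affinity (IC50) in nM, > 0."""
        ...

    def processing_score(self, peptide: str, allele: str) -> float:
        """Combined processing/presentation score in [0, 1]."""
        ...


class ToyPredictor:
    """Deterministic fixed-weight predictor for testing.

    Holds one per-position residue weight matrix per supported length,
    generated once from a fixed constant; the summed window weight x in
    [0,1] maps to affinity 50000^(1-x) nM (so high-weight peptides are
    strong binders) and to the combined processing score directly.  The
    allele string deterministically offsets the matrix so different
    alleles rank peptides differently.
    """

    _MATRIX_SEED = 874201  # fixed: the matrices are part of the contract

    def __init__(self, lengths: Sequence[int] = DEFAULT_LENGTHS) -> None:
        self.lengths = tuple(lengths)
        rng = np.random.default_rng(self._MATRIX_SEED)
        self._weights = {
            k: rng.uniform(0.0, 1.0, size=(k, len(AMINO_ACIDS))) for k in self.lengths
        }
        self._aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def _window_score(self, peptide: str, allele: str) -> float:
        k = len(peptide)
        if k not in self._weights:
            raise ValueError(f"peptide length {k} unsupported (have {self.lengths})")
        w = self._weights[k]
        try:
            raw = sum(w[i, self._aa_index[aa]] for i, aa in enumerate(peptide))
        except KeyError as exc:
            raise ValueError(f"non-standard residue in peptide {peptide!r}") from exc
        # stable allele-specific phase shift; crc32 is deterministic across runs
        shift = (zlib.crc32(allele.encode()) % 1000) / 1000.0
        return float((raw / k + shift) % 1.0)

    def affinity(self, peptide: str, allele: str) -> float:
        return float(50000.0 ** (1.0 - self._window_score(peptide, allele)))

    def processing_score(self, peptide: str, allele: str) -> float:
        return self._window_score(peptide, allele)


@dataclass(frozen=True)
class EpitopeCandidate:
    """A mutant/wildtype peptide window pair with scores and verdicts."""

    patient_id: str
    gene_id: str
    mutant_peptide: str
    wildtype_peptide: str
    protein_start: int  # 1-based start of the window in the protein
    length: int
    mutation: ProteinChange
    allele: str = ""
    mut_affinity_nM: float | None = None
    wt_affinity_nM: float | None = None
    combined_score: float | None = None
    passes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mutant_peptide) != self.length or len(self.wildtype_peptide) != self.length:
            raise ValueError("peptide lengths disagree with declared window length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.mutant_peptide, self.wildtype_peptide))
            if a != b
        ]
        if len(diffs) != 1:
            raise ValueError(
                "mutant and wildtype peptides must differ at exactly one position"
            )
        covered = self.protein_start + diffs[0]
        if covered != self.mutation.position:
            raise ValueError("window does not place the mutation at its protein position")


def tile_peptides(
    protein_sequence: str,
    mutation: ProteinChange,
    gene_id: str = "",
    patient_id: str = "",
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> list[EpitopeCandidate]:
    """All mutation-covering windows of each requested length.

    For length k and a mutation at 1-based position p in a protein of
    length L, window starts run from max(1, p-k+1) to min(p, L-k+1); the
    wildtype pair is the unmutated window.  Raises
    :class:`ResidueMismatchError` when the annotated wildtype residue
    disagrees with the sequence.
    """
    seq = protein_sequence.upper()
    L = len(seq)
    p = mutation.position
    if not 1 <= p <= L:
        raise ValueError(f"mutation position {p} outside protein of length {L}")
    if seq[p - 1] != mutation.wt_residue:
        raise ResidueMismatchError(
            f"protein has {seq[p - 1]!r} at position {p}, annotation says "
            f"{mutation.wt_residue!r}"
        )
    mut_seq = seq[: p - 1] + mutation.mut_residue + seq[p:]
    out = []
    for k in sorted(lengths):
        for start in range(max(1, p - k + 1), min(p, L - k + 1) + 1):
            out.append(
                EpitopeCandidate(
                    patient_id=patient_id,
                    gene_id=gene_id,
                    mutant_peptide=mut_seq[start - 1 : start - 1 + k],
                    wildtype_peptide=seq[start - 1 : start - 1 + k],
                    protein_start=start,
                    length=k,
                    mutation=mutation,
                )
            )
    return out


def score_candidates(
    candidates: Iterable[EpitopeCandidate],
    predictor: Predictor,
    allele: str,
) -> list[EpitopeCandidate]:
    """Populate affinity and processing scores through the predictor.

    A predictor failure flags the candidate unscored (passes["scored"] =
    False) instead of dropping it silently.
    """
    out = []
    for cand in candidates:
        try:
            mut_aff = predictor.affinity(cand.mutant_peptide, allele)
            wt_aff = predictor.affinity(cand.wildtype_peptide, allele)
            score = predictor.processing_score(cand.mutant_peptide, allele)
        except Exception:
            logger.warning(
                "predictor failed on %s/%s; candidate flagged unscored",
                cand.mutant_peptide,
                allele,
            )
            out.append(replace(cand, allele=allele, passes={"scored": False}))
            continue
        out.append(
            replace(
                cand,
                allele=allele,
                mut_affinity_nM=mut_aff,
                wt_affinity_nM=wt_aff,
                combined_score=score,
                passes={"scored": True},
            )
        )
    return out


def filter_candidates(
    scored: Iterable[EpitopeCandidate],
    max_affinity_nM: float = DEFAULT_MAX_AFFINITY_NM,
    min_combined_score: float = DEFAULT_MIN_COMBINED_SCORE,
    require_mut_stronger: bool = True,
) -> list[EpitopeCandidate]:
    """Apply the neo-epitope filter cascade; return candidates passing all.

    Filters: mutant affinity strictly below ``max_affinity_nM``; combined
    score strictly above ``min_combined_score``; mutant binding stronger
    than wildtype (lower predicted IC50).  Per-filter verdicts are stored
    on every candidate's ``passes`` for reporting.
    """
    out = []
    for cand in scored:
        if not cand.passes.get("scored", False):
            continue
        verdicts = dict(cand.passes)
        verdicts["affinity"] = cand.mut_affinity_nM < max_affinity_nM
        verdicts["combined_score"] = cand.combined_score > min_combined_score
        verdicts["mut_stronger"] = (
            cand.mut_affinity_nM < cand.wt_affinity_nM if require_mut_stronger else True
        )
        cand = replace(cand, passes=verdicts)
        if verdicts["affinity"] and verdicts["combined_score"] and verdicts["mut_stronger"]:
            out.append(cand)
    return out


def gravy(peptide: str) -> float:
    """Kyte–Doolittle grand average of hydropathy."""
    return float(ProteinAnalysis(peptide).gravy())


def panel_sort_key(cand: EpitopeCandidate) -> tuple:
    """Ranking key: affinity ascending, then score descending, then peptide."""
    return (cand.mut_affinity_nM, -cand.combined_score, cand.mutant_peptide)


def select_panel(
    passing: Sequence[EpitopeCandidate],
    n_min: int = DEFAULT_PANEL_MIN,
    n_max: int = DEFAULT_PANEL_MAX,
    hydropathy_limit: float | None = DEFAULT_HYDROPATHY_LIMIT,
) -> list[EpitopeCandidate]:
    """Rank passing candidates into a synthesis panel of at most ``n_max``.

    Peptides with GRAVY above ``hydropathy_limit`` are removed before
    ranking (pass None to disable); at most one candidate per (gene,
    mutation, length) is retained; a warning is issued when fewer than
    ``n_min`` survive.
    """
    if n_min > n_max:
        raise ValueError("n_min must be <= n_max")
    pool = list(passing)
    if hydropathy_limit is not None:
        pool = [c for c in pool if gravy(c.mutant_peptide) <= hydropathy_limit]
    pool.sort(key=panel_sort_key)
    seen: set[tuple] = set()
    panel = []
    for cand in pool:
        dedup_key = (cand.gene_id, str(cand.mutation), cand.length)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        panel.append(cand)
        if len(panel) == n_max:
            break
    if len(panel) < n_min:
        warnings.warn(
            f"panel has {len(panel)} candidate(s), below the requested minimum {n_min}",
            stacklevel=2,
        )
    return panel


# ---------------------------------------------------------------------------
# External predictor adapter and panel I/O
# ---------------------------------------------------------------------------

class TablePredictor:
    """Predictor backed by a precomputed score table.

    Reads a delimited file with columns peptide, allele, affinity_nM,
    combined_score — the tabular output of an external predictor run —
    and serves lookups through the :class:`Predictor` contract.  Unknown
    peptides raise KeyError (surfacing as unscored candidates).
    """

    def __init__(self, path, sep: str = "\t") -> None:
        import pandas as pd

        df = pd.read_csv(path, sep=sep)
        self._aff = {
            (r.peptide, r.allele): float(r.affinity_nM) for r in df.itertuples()
        }
        self._score = {
            (r.peptide, r.allele): float(r.combined_score) for r in df.itertuples()
        }

    def affinity(self, peptide: str, allele: str) -> float:
        return self._aff[(peptide, allele)]

    def processing_score(self, peptide: str, allele: str) -> float:
        return self._score[(peptide, allele)]


PANEL_COLUMNS = [
    "patient_id",
    "gene_id",
    "mutation",
    "mutant_peptide",
    "wildtype_peptide",
    "protein_start",
    "length",
    "allele",
    "mut_affinity_nM",
    "wt_affinity_nM",
    "combined_score",
    "verdicts",
]


def write_panel_table(candidates: Iterable[EpitopeCandidate], path, sep: str = "\t") -> None:
    import pandas as pd

    rows = [
        {
            "patient_id": c.patient_id,
            "gene_id": c.gene_id,
            "mutation": str(c.mutation),
            "mutant_peptide": c.mutant_peptide,
            "wildtype_peptide": c.wildtype_peptide,
            "protein_start": c.protein_start,
            "length": c.length,
            "allele": c.allele,
            "mut_affinity_nM": c.mut_affinity_nM,
            "wt_affinity_nM": c.wt_affinity_nM,
            "combined_score": c.combined_score,
            "verdicts": ";".join(f"{k}={v}" for k, v in sorted(c.passes.items())),
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep=sep, index=False)


def write_panel_fasta(candidates: Iterable[EpitopeCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f">{c.patient_id}|{c.gene_id}|{c.mutation}|len{c.length}|start{c.protein_start}\n"
                f"{c.mutant_peptide}\n"
            )
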