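"""Cross-patient repertoire set algebra and group-differential targets.

Individual hit repertoires are combined into cohort-level gene sets:
targets shared by at least ``min_patients`` patients, targets with
signals significantly enriched in one clinical group over another
(Welch t-test on median-normalized log signals with Benjamini–Hochberg
FDR control), their union ("the total repertoire"), and overlap
statistics between repertoires from different cohorts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seromics import ArrayPatient, HitRepertoire


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class OverlapResult:
    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_overlap: int
    percent_of_a: float  # 100 * |A ∩ B| / |A|

    def percent_of_a_1dp(self) -> float:
        """Percent to one decimal place (round-half-even)."""
        return float(np.round(self.percent_of_a, 1))


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    effect: float  # difference of group mean log-signals (a - b)
    p_value: float
    q_value: float


def shared_targets(
    repertoires: Sequence[HitRepertoire], min_patients: int, name: str = "shared"
) -> GeneSet:
    """Genes hit in at least ``min_patients`` of the given repertoires.

    ``min_patients = 1`` gives the union, ``min_patients = len(repertoires)``
    the intersection.
    """
    reps = list(repertoires)
    if not 1 <= min_patients <= len(reps):
        raise ValueError(
            f"min_patients must be in [1, {len(reps)}], got {min_patients}"
        )
    counts = Counter(g for r in reps for g in r.genes)
    return GeneSet(name, frozenset(g for g, c in counts.items() if c >= min_patients))


def _normalized_log_matrix(patients: Sequence[ArrayPatient]) -> pd.DataFrame:
    """Gene x patient matrix of log(signal+1), per-array median-scaled.

    Each array's mean replicate signals are rescaled multiplicatively so
    its median matches the grand median across arrays, then log(x+1)
    transformed.  Genes absent from a patient are NaN.
    """
    cols = {}
    for p in patients:
        cols[p.patient_id] = pd.Series(
            {f.gene_id: f.mean_signal for f in p.features}, dtype=float
        )
    mat = pd.DataFrame(cols)
    medians = mat.median(axis=0, skipna=True)
    grand = float(np.median(medians))
    scaled = mat * (grand / medians)
    return np.log1p(scaled)


def differential_targets(
    group_a: Sequence[ArrayPatient],
    group_b: Sequence[ArrayPatient],
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-gene two-sided Welch test of group A vs group B array signals.

    Signals are per-array median-normalized and log(x+1) transformed;
    p-values are BH-adjusted across all tested genes.  Genes with fewer
    than 2 non-missing values in either group are skipped.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 patients per group")
    mat = _normalized_log_matrix(list(group_a) + list(group_b))
    a_ids = [p.patient_id for p in group_a]
    b_ids = [p.patient_id for p in group_b]
    genes, effects, pvals = [], [], []
    for gene, row in mat.iterrows():
        a = row[a_ids].dropna().to_numpy()
        b = row[b_ids].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        effect = float(a.mean() - b.mean())
        if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
            p = 1.0 if effect == 0.0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        genes.append(str(gene))
        effects.append(effect)
        pvals.append(p)
    if not genes:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        DifferentialResult(g, e, p, float(q))
        for g, e, p, q in zip(genes, effects, pvals, qvals)
    ]


def enriched_geneset(
    results: Iterable[DifferentialResult], alpha: float = 0.05, name: str = "enriched"
) -> GeneSet:
    """Genes significant at FDR ``alpha`` with higher mean in group A."""
    return GeneSet(
        name,
        frozenset(r.gene_id for r in results if r.q_value <= alpha and r.effect > 0),
    )


def combine_repertoire(enriched: GeneSet, shared: GeneSet, name: str = "combined") -> GeneSet:
    """Union of the enriched and shared target sets (the total repertoire)."""
    return GeneSet(name, enriched.genes | shared.genes)


def overlap_stats(a: GeneSet, b: GeneSet) -> OverlapResult:
    """Intersection count and percent of A shared with B."""
    n_overlap = len(a.genes & b.genes)
    if len(a) == 0:
        warnings.warn(f"gene set {a.name!r} is empty; percent_of_a reported as 0", stacklevel=2)
        pct = 0.0
    else:
        pct = 100.0 * n_overlap / len(a)
    return OverlapResult(a.name, b.name, len(a), len(b), n_overlap, pct)


# ---------------------------------------------------------------------------
# GMT / TSV I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, genes... per tab-separated line)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(genesets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def write_differential_table(results: Iterable[DifferentialResult], path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {"gene_id": r.gene_id, "effect": r.effect, "p_value": r.p_value, "q_value": r.q_value}
            for r in results
        ],
        columns=["gene_id", "effect", "p_value", "q_value"],
    ).to_csv(path, sep=sep, index=False)


def write_overlap_table(results: Iterable[OverlapResult], path, sep: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "set_a": r.set_a_name,
                "set_b": r.set_b_name,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "n_overlap": r.n_overlap,
                "percent_of_a": r.percent_of_a_1dp(),
            }
            for r in results
        ]
    ).to_csv(path, sep=sep, index=False)
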