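"""Autoantibody hit calling on protein-array signals.

A plasma sample probed on a high-density protein array yields, for every
arrayed protein feature, a small number of replicate fluorescence signals,
plus a pool of negative-control features that measure background binding.
A feature is a significant autoantibody "hit" when its mean signal exceeds
a fluorescence threshold (default 1000 units) and its Z-factor — a
signal-to-noise separation statistic between the feature replicates and
the negative controls —

    Z = 1 - 3*(sigma_s + sigma_c) / |mu_s - mu_c|

exceeds a threshold (default 0.4).  ``sigma``/``mu`` are the sample
standard deviation and mean of the feature replicates (``s``) and of the
pooled negative-control replicates (``c``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default hit-calling thresholds: mean signal in fluorescence units and
#: Z-factor (unitless).
DEFAULT_SIGNAL_THRESHOLD = 1000.0
DEFAULT_Z_THRESHOLD = 0.4


class DegenerateZFactorError(ValueError):
    """Feature mean equals control mean: Z-factor is undefined."""


def _validate_signals(signals: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(signals, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{what} needs at least 2 replicate signals, got {arr.size}")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"{what} signals must be finite and non-negative")
    return arr


@dataclass(frozen=True)
class ArrayFeature:
    """One arrayed protein with its replicate fluorescence signals."""

    gene_id: str
    replicate_signals: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = _validate_signals(self.replicate_signals, f"feature {self.gene_id!r}")
        object.__setattr__(self, "replicate_signals", tuple(arr))

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.replicate_signals))

    @property
    def signal_sd(self) -> float:
        return float(np.std(self.replicate_signals, ddof=1))


@dataclass(frozen=True)
class ControlSet:
    """Pooled negative-control replicate signals for one array."""

    replicate_signals: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = _validate_signals(self.replicate_signals, "control set")
        object.__setattr__(self, "replicate_signals", tuple(arr))

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.replicate_signals))

    @property
    def signal_sd(self) -> float:
        return float(np.std(self.replicate_signals, ddof=1))


@dataclass(frozen=True)
class ArrayPatient:
    """One patient's array experiment: features plus negative controls."""

    patient_id: str
    group_label: str
    features: tuple[ArrayFeature, ...]
    controls: ControlSet

    def __post_init__(self) -> None:
        genes = [f.gene_id for f in self.features]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(
                f"duplicate gene_ids on array for patient {self.patient_id!r}: {dupes[:5]}"
            )

    def feature_map(self) -> dict[str, ArrayFeature]:
        return {f.gene_id: f for f in self.features}


@dataclass(frozen=True)
class HitRepertoire:
    """Per-patient autoantibody hits: gene -> (z_factor, mean_signal)."""

    patient_id: str
    hits: Mapping[str, tuple[float, float]]
    group_label: str = ""

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def compute_z_factor(feature: ArrayFeature, controls: ControlSet) -> float:
    """Z-factor separating a feature's replicates from the negative controls.

    Returns ``1 - 3*(sigma_s + sigma_c) / |mu_s - mu_c|`` (unitless, <= 1).
    Raises :class:`DegenerateZFactorError` when the feature mean equals the
    control mean (no separation to measure).
    """
    mu_s, sd_s = feature.mean_signal, feature.signal_sd
    mu_c, sd_c = controls.mean_signal, controls.signal_sd
    denom = abs(mu_s - mu_c)
    if denom == 0.0:
        raise DegenerateZFactorError(
            f"feature {feature.gene_id!r}: mean signal equals control mean ({mu_s})"
        )
    return 1.0 - 3.0 * (sd_s + sd_c) / denom


def call_hits(
    patient: ArrayPatient,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> HitRepertoire:
    """Call the patient's hit repertoire.

    A feature is a hit when mean replicate signal > ``signal_threshold``
    AND Z-factor > ``z_threshold`` (both strict).  Features whose Z-factor
    is degenerate (mean equal to the control mean) are excluded with a
    logged warning rather than failing the patient.
    """
    if not np.isfinite(signal_threshold) or not np.isfinite(z_threshold):
        raise ValueError("thresholds must be finite")
    if not patient.features:
        warnings.warn(
            f"patient {patient.patient_id!r} has no array features; empty repertoire",
            stacklevel=2,
        )
    hits: dict[str, tuple[float, float]] = {}
    for feat in patient.features:
        mean = feat.mean_signal
        if mean <= signal_threshold:
            continue
        try:
            z = compute_z_factor(feat, patient.controls)
        except DegenerateZFactorError:
            logger.warning(
                "patient %s feature %s: degenerate Z-factor (mean equals control mean); excluded",
                patient.patient_id,
                feat.gene_id,
            )
            continue
        if z > z_threshold:
            hits[feat.gene_id] = (z, mean)
    return HitRepertoire(patient_id=patient.patient_id, hits=hits, group_label=patient.group_label)


def summarize_cohort(repertoires: Iterable[HitRepertoire]) -> pd.DataFrame:
    """Per-patient hit counts with group labels.

    Returns one row per patient (``patient_id``, ``group_label``,
    ``n_hits``); per-group mean counts are attached as
    ``df.attrs["group_means"]``.
    """
    reps = list(repertoires)
    if not reps:
        raise ValueError("need at least one repertoire")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in reps],
            "group_label": [r.group_label for r in reps],
            "n_hits": [len(r) for r in reps],
        }
    )
    df.attrs["group_means"] = df.groupby("group_label")["n_hits"].mean().to_dict()
    return df


# ---------------------------------------------------------------------------
# I/O: long-format delimited array tables and hit tables
# ---------------------------------------------------------------------------

ARRAY_COLUMNS = ["patient_id", "gene_id", "replicate_index", "signal", "is_control"]


def read_array_table(path, sep: str = "\t") -> list[ArrayPatient]:
    """Read a long-format array signal table into per-patient objects.

    Required columns: patient_id, gene_id, replicate_index, signal,
    is_control; an optional group_label column is carried through.
    Control rows (is_control truthy) are pooled into one control set per
    patient.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ARRAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"array table missing columns: {missing}")
    has_group = "group_label" in df.columns
    patients: list[ArrayPatient] = []
    for pid, sub in df.groupby("patient_id", sort=True):
        group = str(sub["group_label"].iloc[0]) if has_group else ""
        ctrl_mask = sub["is_control"].astype(bool)
        controls = ControlSet(tuple(sub.loc[ctrl_mask, "signal"].astype(float)))
        feats = []
        for gene, g in sub.loc[~ctrl_mask].groupby("gene_id", sort=True):
            sig = g.sort_values("replicate_index")["signal"].astype(float)
            feats.append(ArrayFeature(str(gene), tuple(sig)))
        patients.append(ArrayPatient(str(pid), group, tuple(feats), controls))
    return patients


def write_hit_table(repertoires: Iterable[HitRepertoire], path, sep: str = "\t") -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "gene_id": gene,
            "mean_signal": mean,
            "z_factor": z,
        }
        for r in repertoires
        for gene, (z, mean) in sorted(r.hits.items())
    ]
    pd.DataFrame(rows, columns=["patient_id", "gene_id", "mean_signal", "z_factor"]).to_csv(
        path, sep=sep, index=False
    )


def read_hit_table(path, sep: str = "\t") -> list[HitRepertoire]:
    df = pd.read_csv(path, sep=sep)
    reps = []
    for pid, sub in df.groupby("patient_id", sort=True):
        hits = {
            str(r.gene_id): (float(r.z_factor), float(r.mean_signal))
            for r in sub.itertuples()
        }
        reps.append(HitRepertoire(patient_id=str(pid), hits=hits))
    return reps
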