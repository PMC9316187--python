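"""Replicate-spectrum preprocessing: SNV normalization, SAM outlier rejection, averaging.

Each replicate is standard-normal-variate transformed (zero mean, unit sample
standard deviation per spectrum), compared to the per-sample mean of all SNV
replicates with the spectral angle mapper (cosine similarity), discarded if
its similarity falls below a threshold (default 0.90), and the survivors are
averaged into one spectrum per sample per band.  The reference mean is
computed once from all input replicates and is not recomputed after discards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic_data import SampleRecord, Spectrum

__all__ = [
    "DEFAULT_SAM_THRESHOLD",
    "FilterReport",
    "AveragedSample",
    "snv",
    "sam_similarity",
    "filter_outliers",
    "average_sample",
    "preprocess_dataset",
    "discarded_fraction",
]

DEFAULT_SAM_THRESHOLD = 0.90


@dataclass
class FilterReport:
    """Outcome of the SAM filter for one sample in one band."""

    sample_id: str
    band: str
    n_input: int
    n_discarded: int
    discarded_indices: tuple[int, ...]
    sam_values: np.ndarray
    threshold: float


@dataclass
class AveragedSample:
    """Mean of the surviving SNV replicates for one sample in one band."""

    sample_id: str
    cultivar: str
    vigor: str
    band: str
    wavelengths: np.ndarray
    intensities: np.ndarray


def _snv_rows(matrix: np.ndarray) -> np.ndarray:
    """SNV-transform each row: (x - mean) / sd with the n-1 denominator."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate spectrum: zero variance, SNV undefined")
    return (matrix - mean) / sd


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate transform of one spectrum."""
    if spectrum.intensities.size < 2:
        raise ValueError("SNV requires at least 2 points")
    out = _snv_rows(spectrum.intensities[None, :])[0]
    return Spectrum(spectrum.band, spectrum.wavelengths, out,
                    spectrum.sample_id, spectrum.replicate_index)


def sam_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle mapper similarity: cosine of the angle between two spectra."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("SAM undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def filter_outliers(
    replicates: Sequence[Spectrum],
    threshold: float = DEFAULT_SAM_THRESHOLD,
) -> tuple[list[Spectrum], FilterReport]:
    """Discard SNV replicates whose SAM similarity to the replicate mean is below threshold.

    The reference is the arithmetic mean of *all* input replicates (single
    pass).  Raises if every replicate falls below the threshold.
    """
    if len(replicates) < 2:
        raise ValueError("outlier filtering requires at least 2 replicates")
    matrix = np.stack([s.intensities for s in replicates])
    reference = matrix.mean(axis=0)
    norm_ref = np.linalg.norm(reference)
    if norm_ref == 0:
        raise ValueError("SAM undefined: zero reference spectrum")
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        raise ValueError("SAM undefined for a zero replicate")
    sams = np.clip(matrix @ reference / (norms * norm_ref), -1.0, 1.0)
    keep = sams >= threshold
    if not np.any(keep):
        raise ValueError("sample unusable: all replicates below the SAM threshold")
    survivors = [s for s, k in zip(replicates, keep) if k]
    discarded = tuple(int(i) for i in np.flatnonzero(~keep))
    report = FilterReport(
        sample_id=replicates[0].sample_id,
        band=replicates[0].band,
        n_input=len(replicates),
        n_discarded=len(discarded),
        discarded_indices=discarded,
        sam_values=sams,
        threshold=threshold,
    )
    return survivors, report


def average_sample(
    replicates: Sequence[Spectrum],
    cultivar: str = "",
    vigor: str = "",
) -> AveragedSample:
    """Pointwise arithmetic mean of the surviving replicates."""
    if len(replicates) == 0:
        raise ValueError("cannot average an empty replicate set")
    matrix = np.stack([s.intensities for s in replicates])
    return AveragedSample(
        sample_id=replicates[0].sample_id,
        cultivar=cultivar,
        vigor=vigor,
        band=replicates[0].band,
        wavelengths=replicates[0].wavelengths,
        intensities=matrix.mean(axis=0),
    )


def preprocess_dataset(
    samples: Sequence[SampleRecord],
    threshold: float = DEFAULT_SAM_THRESHOLD,
) -> tuple[dict[str, list[AveragedSample]], list[FilterReport]]:
    """SNV -> SAM filter -> average, for every sample and band.

    Returns averaged samples keyed by band (input order preserved) and the
    per-sample filter reports.
    """
    averaged: dict[str, list[AveragedSample]] = {}
    reports: list[FilterReport] = []
    for record in samples:
        for band, reps in record.replicates.items():
            matrix = _snv_rows(np.stack([s.intensities for s in reps]))
            snv_reps = [
                Spectrum(band, reps[0].wavelengths, matrix[i], record.sample_id, reps[i].replicate_index)
                for i in range(len(reps))
            ]
            survivors, report = filter_outliers(snv_reps, threshold)
            reports.append(report)
            averaged.setdefault(band, []).append(
                average_sample(survivors, record.cultivar, record.vigor)
            )
    return averaged, reports


def discarded_fraction(reports: Sequence[FilterReport]) -> float:
    """Overall fraction of replicates discarded across all samples and bands."""
    total = sum(r.n_input for r in reports)
    if total == 0:
        return 0.0
    return sum(r.n_discarded for r in reports) / total
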