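"""Acquisition-condition optimization: 2^3 factorial design scored by SBR desirability.

Eleven experiments (eight corner points of a two-level, three-factor design
plus three center replicates) vary laser pulse energy, detector delay time
and signal acquisition (gate) time.  Each experiment's spectra are scored by
the signal-to-background ratio (SBR) of ten monitored emission lines; per
line, SBRs are rescaled across experiments to individual desirabilities
(DI in [0, 1], larger-is-better min-max scaling) and averaged into the
overall desirability (OD).  The experiment with the highest OD wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import EmissionLine, Spectrum

__all__ = [
    "FACTOR_LEVELS",
    "DesignPoint",
    "DesignResult",
    "factorial_design",
    "sbr",
    "desirability",
    "overall_desirability",
    "evaluate_design",
    "select_best",
    "main_effects",
    "design_results_frame",
]

logger = logging.getLogger(__name__)

# Coded level -> real acquisition setting.
FACTOR_LEVELS: Mapping[str, Mapping[int, float]] = {
    "energy_mJ": {-1: 29.73, 0: 42.29, 1: 54.86},
    "delay_us": {-1: 0.50, 0: 1.00, 1: 1.50},
    "gate_us": {-1: 1.00, 0: 11.00, 1: 20.00},
}

# Corner-point ordering of the design matrix (energy, delay, gate).
_CORNER_ORDER: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
)
N_CENTER_REPLICATES = 3


@dataclass(frozen=True)
class DesignPoint:
    """One experiment of the factorial design."""

    experiment_id: int  # 1..11
    coded_levels: tuple[int, int, int]  # (energy, delay, gate), each in {-1, 0, +1}
    is_center: bool

    @property
    def real_levels(self) -> tuple[float, float, float]:
        e, d, g = self.coded_levels
        return (FACTOR_LEVELS["energy_mJ"][e], FACTOR_LEVELS["delay_us"][d],
                FACTOR_LEVELS["gate_us"][g])


@dataclass
class DesignResult:
    """SBR, DI and OD for every experiment of a design."""

    design: tuple[DesignPoint, ...]
    line_labels: tuple[str, ...]
    sbr: np.ndarray  # (n_experiments, n_lines)
    di: np.ndarray  # (n_experiments, n_lines), each column scaled to [0, 1]
    od: np.ndarray  # (n_experiments,)


def factorial_design() -> list[DesignPoint]:
    """The 11-experiment design: 8 corner points plus 3 center replicates."""
    points = [
        DesignPoint(i + 1, coded, is_center=False)
        for i, coded in enumerate(_CORNER_ORDER)
    ]
    points += [
        DesignPoint(len(_CORNER_ORDER) + 1 + j, (0, 0, 0), is_center=True)
        for j in range(N_CENTER_REPLICATES)
    ]
    return points


def sbr(spectrum: Spectrum, line: EmissionLine) -> float:
    """Signal-to-background ratio: (peak - mean background) / mean background.

    The peak is the maximum intensity inside the line's signal window; the
    background is the pooled mean over the two flanking windows.
    """
    w = spectrum.wavelengths
    x = spectrum.intensities
    sig = (w >= line.wavelength - line.signal_halfwidth) & (w <= line.wavelength + line.signal_halfwidth)
    bg = ((w >= line.bg_lo[0]) & (w <= line.bg_lo[1])) | ((w >= line.bg_hi[0]) & (w <= line.bg_hi[1]))
    if not np.any(sig):
        raise ValueError(f"signal window of line {line.label} contains no grid points")
    if not np.any(bg):
        raise ValueError(f"background windows of line {line.label} contain no grid points")
    background = float(x[bg].mean())
    if background <= 0:
        raise ValueError(f"non-positive mean background for line {line.label}: SBR undefined")
    return (float(x[sig].max()) - background) / background


def desirability(sbr_by_experiment: np.ndarray) -> np.ndarray:
    """Larger-is-better min-max scaling of one line's SBR across experiments.

    The experiment with the highest SBR gets DI = 1, the lowest DI = 0.  A
    degenerate all-equal response maps to DI = 0.5 everywhere (with a warning)
    so one flat line cannot abort the whole design evaluation.
    """
    values = np.asarray(sbr_by_experiment, dtype=float)
    if values.size < 2:
        raise ValueError("desirability needs at least 2 experiments")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        logger.warning("degenerate SBR response (all experiments equal); DI set to 0.5")
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def overall_desirability(di: np.ndarray) -> float:
    """Arithmetic mean of the individual desirabilities (well-defined even at DI = 0)."""
    di = np.asarray(di, dtype=float)
    if di.size == 0:
        raise ValueError("empty desirability vector")
    if np.any((di < 0) | (di > 1)):
        raise ValueError("DI values must lie in [0, 1]")
    return float(di.mean())


def evaluate_design(
    spectra_by_experiment: Mapping[int, Mapping[str, Spectrum]],
    lines: Sequence[EmissionLine],
    design: Sequence[DesignPoint] | None = None,
) -> DesignResult:
    """Score every experiment: per-line SBR -> DI across experiments -> OD.

    ``spectra_by_experiment`` maps experiment id to its spectra keyed by band;
    each line is measured in the first band (in key order) whose grid covers
    its signal and background windows.
    """
    design = tuple(design) if design is not None else tuple(factorial_design())
    ids = [p.experiment_id for p in design]
    missing = [i for i in ids if i not in spectra_by_experiment]
    if missing:
        raise ValueError(f"missing spectra for experiments {missing}")

    def pick_spectrum(spectra: Mapping[str, Spectrum], line: EmissionLine) -> Spectrum:
        for spec in spectra.values():
            w = spec.wavelengths
            needed_lo = min(line.bg_lo[0], line.wavelength - line.signal_halfwidth)
            needed_hi = max(line.bg_hi[1], line.wavelength + line.signal_halfwidth)
            if w[0] <= needed_lo and needed_hi <= w[-1]:
                return spec
        raise ValueError(f"no band covers line {line.label}")

    sbr_matrix = np.array(
        [[sbr(pick_spectrum(spectra_by_experiment[i], line), line) for line in lines]
         for i in ids]
    )
    di_matrix = np.column_stack([desirability(sbr_matrix[:, j]) for j in range(len(lines))])
    od = np.array([overall_desirability(di_matrix[i]) for i in range(len(ids))])
    return DesignResult(design, tuple(l.label for l in lines), sbr_matrix, di_matrix, od)


def select_best(results: DesignResult | Sequence[float],
                experiment_ids: Sequence[int] | None = None) -> int:
    """Experiment id with the highest OD; ties broken by the lowest id."""
    if isinstance(results, DesignResult):
        od = results.od
        ids = [p.experiment_id for p in results.design]
    else:
        od = np.asarray(results, dtype=float)
        ids = list(experiment_ids) if experiment_ids is not None else list(range(1, od.size + 1))
    if od.size == 0:
        raise ValueError("no experiments to select from")
    order = np.argsort(ids)  # tie-break on lowest experiment id
    best = min(order, key=lambda i: (-od[i], ids[i]))
    return int(ids[best])


def main_effects(
    design: Sequence[DesignPoint],
    response: Sequence[float],
) -> dict[str, float]:
    """Main-effect and two-factor interaction contrasts over the 8 corner points.

    Effect of a factor = mean(response at +1) - mean(response at -1);
    interaction contrasts use the elementwise product of coded levels.
    """
    response = np.asarray(response, dtype=float)
    if len(design) != response.size:
        raise ValueError("design and response lengths differ")
    corners = [(p, r) for p, r in zip(design, response) if not p.is_center]
    coded = np.array([p.coded_levels for p, _ in corners])
    y = np.array([r for _, r in corners])
    expected = {tuple(c) for c in _CORNER_ORDER}
    if {tuple(c) for c in coded.tolist()} != expected or len(corners) != len(expected):
        raise ValueError("full set of 8 corner points is required")

    names = ("energy", "delay", "gate")
    effects: dict[str, float] = {}
    for k, name in enumerate(names):
        effects[name] = float(y[coded[:, k] == 1].mean() - y[coded[:, k] == -1].mean())
    for a in range(3):
        for b in range(a + 1, 3):
            contrast = coded[:, a] * coded[:, b]
            effects[f"{names[a]}:{names[b]}"] = float(
                y[contrast == 1].mean() - y[contrast == -1].mean()
            )
    return effects


def design_results_frame(result: DesignResult) -> pd.DataFrame:
    """Tabular layout of a design evaluation (one row per experiment)."""
    rows = []
    for i, point in enumerate(result.design):
        row: dict[str, object] = {
            "experiment": point.experiment_id,
            "energy_coded": point.coded_levels[0],
            "delay_coded": point.coded_levels[1],
            "gate_coded": point.coded_levels[2],
            "energy_mJ": point.real_levels[0],
            "delay_us": point.real_levels[1],
            "gate_us": point.real_levels[2],
            "is_center": point.is_center,
        }
        for j, label in enumerate(result.line_labels):
            row[f"SBR {label}"] = result.sbr[i, j]
        for j, label in enumerate(result.line_labels):
            row[f"DI {label}"] = result.di[i, j]
        row["OD"] = result.od[i]
        rows.append(row)
    return pd.DataFrame(rows)
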