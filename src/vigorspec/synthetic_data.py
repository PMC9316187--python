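"""Synthetic LIBS emission spectra with the statistical structure of a seed-vigor study.

The generator emulates a dual-band LIBS campaign on *Brachiaria brizantha*
seed pellets: two detector bands (UV and VIS), a fixed library of atomic (I)
and ionic (II) emission lines, replicate shot-to-shot spectra per sample, a
multiplicative vigor effect on the Mg/Ca/K lines, a cultivar-linked nuisance
effect on the Na/Si lines, log-normal shot jitter, additive detector noise,
and a small fraction of corrupted (outlier) replicates.  Every downstream
stage of the package is testable against data from this module alone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionLine",
    "BandSpec",
    "GeneratorConfig",
    "Spectrum",
    "SampleRecord",
    "DEFAULT_BANDS",
    "DEFAULT_BASE_INTENSITIES",
    "DOE_LINE_KEYS",
    "load_line_library",
    "doe_lines",
    "pseudo_voigt",
    "render_spectrum",
    "generate_dataset",
    "inject_outliers",
    "simulate",
    "save_dataset",
    "load_dataset",
]

CULTIVARS = ("Marandu", "Paiaguás")
VIGOR_CLASSES = ("HV", "LV")


# ---------------------------------------------------------------------------
# Emission lines and bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionLine:
    """One atomic/ionic emission line with its SBR measurement windows.

    ``signal_halfwidth`` defines the peak-search window around the nominal
    wavelength; ``bg_lo``/``bg_hi`` are two flanking intervals assumed free of
    other lines, used to estimate the continuum background.
    """

    element: str
    ionization: str  # "I" (atomic) or "II" (ionic)
    wavelength: float  # nm
    default_width: float = 0.06  # FWHM, nm
    signal_halfwidth: float = 0.30  # nm
    bg_lo: tuple[float, float] = (0.0, 0.0)
    bg_hi: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.ionization not in ("I", "II"):
            raise ValueError(f"ionization must be 'I' or 'II', got {self.ionization!r}")
        if self.default_width <= 0 or self.signal_halfwidth <= 0:
            raise ValueError(f"widths must be > 0 for line {self.label}")
        sig = (self.wavelength - self.signal_halfwidth, self.wavelength + self.signal_halfwidth)
        for win in (self.bg_lo, self.bg_hi):
            if win[0] >= win[1]:
                raise ValueError(f"empty background window {win} for line {self.label}")
            if win[0] < sig[1] and sig[0] < win[1]:
                raise ValueError(f"background window overlaps signal window for line {self.label}")

    @property
    def label(self) -> str:
        return f"{self.element} {self.ionization} {self.wavelength:.3f}"


@dataclass(frozen=True)
class BandSpec:
    """A detector band: wavelength range and grid step, all in nm."""

    name: str
    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.step > 0):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi}] step {self.step}")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)

    def contains(self, wavelength: float) -> bool:
        return self.lo <= wavelength <= self.hi


# The VIS grid extends to 771 nm so the K I doublet at 766.49/769.90 nm and
# its background windows fall on the grid.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("UV", 175.0, 330.0, 0.02),
    BandSpec("VIS", 275.0, 771.0, 0.05),
)

# Mean line amplitudes (a.u. above the continuum) used by the default generator.
DEFAULT_BASE_INTENSITIES: Mapping[str, float] = {
    "C I 247.856": 300.0,
    "Mn II 257.610": 80.0,
    "Fe II 259.940": 120.0,
    "Fe II 274.640": 100.0,
    "Mg II 279.550": 400.0,
    "Mg II 280.270": 300.0,
    "Mg I 285.213": 200.0,
    "Si I 288.150": 250.0,
    "Al I 309.270": 150.0,
    "Cu I 324.750": 60.0,
    "Ca II 393.360": 500.0,
    "Al I 394.400": 180.0,
    "Ca I 422.670": 350.0,
    "Ca I 442.540": 120.0,
    "Ca I 443.590": 110.0,
    "Na I 588.995": 300.0,
    "Na I 589.590": 250.0,
    "Ca I 610.270": 90.0,
    "Ca I 612.220": 85.0,
    "Ca I 643.900": 70.0,
    "K I 766.490": 450.0,
    "K I 769.900": 300.0,
}

# The ten lines monitored during acquisition-condition optimization.
DOE_LINE_KEYS: tuple[str, ...] = (
    "Al I 394.400",
    "C I 247.856",
    "Ca II 393.360",
    "Cu I 324.750",
    "Fe II 274.640",
    "K I 766.490",
    "Mg II 279.550",
    "Mn II 257.610",
    "Na I 589.590",
    "Si I 288.150",
)


def load_line_library(path: str | Path | None = None) -> tuple[EmissionLine, ...]:
    """Load an emission-line library from CSV (the packaged default if ``path`` is None)."""
    if path is None:
        with importlib.resources.as_file(
            importlib.resources.files("vigorspec").joinpath("data/line_library.csv")
        ) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    lines = [
        EmissionLine(
            element=str(row.element),
            ionization=str(row.ionization),
            wavelength=float(row.wavelength_nm),
            default_width=float(row.fwhm_nm),
            signal_halfwidth=float(row.signal_halfwidth_nm),
            bg_lo=(float(row.bg_lo_start), float(row.bg_lo_end)),
            bg_hi=(float(row.bg_hi_start), float(row.bg_hi_end)),
        )
        for row in table.itertuples()
    ]
    return tuple(sorted(lines, key=lambda l: l.wavelength))


def doe_lines(library: Iterable[EmissionLine] | None = None) -> tuple[EmissionLine, ...]:
    """The ten monitored lines used for SBR-based acquisition optimization."""
    lib = tuple(library) if library is not None else load_line_library()
    by_label = {l.label: l for l in lib}
    missing = [k for k in DOE_LINE_KEYS if k not in by_label]
    if missing:
        raise ValueError(f"line library is missing monitored lines: {missing}")
    return tuple(by_label[k] for k in DOE_LINE_KEYS)


# ---------------------------------------------------------------------------
# Spectra and samples
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """One replicate emission spectrum in one band."""

    band: str
    wavelengths: np.ndarray  # strictly increasing, nm
    intensities: np.ndarray  # a.u., same length
    sample_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D vectors of equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class SampleRecord:
    """A seed sample: metadata plus replicate spectra per band."""

    sample_id: str
    cultivar: str
    vigor: str
    replicates: dict[str, list[Spectrum]]  # band name -> replicate spectra

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise ValueError(f"unknown cultivar {self.cultivar!r}")
        if self.vigor not in VIGOR_CLASSES:
            raise ValueError(f"unknown vigor class {self.vigor!r}")


DEFAULT_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("Marandu", "HV", 20),
    ("Paiaguás", "HV", 40),
    ("Marandu", "LV", 40),
    ("Paiaguás", "LV", 20),
)


@dataclass
class GeneratorConfig:
    """Conditions under which a synthetic dataset is generated.

    Defaults reproduce the study structure: 120 samples (20 Marandu-HV,
    40 Paiaguás-HV, 40 Marandu-LV, 20 Paiaguás-LV), 50 replicates per sample
    per band, a 1.3x vigor effect on the Mg/Ca/K lines of HV samples, a 1.2x
    cultivar nuisance effect on the Na/Si lines of Paiaguás samples, 10%
    shot-to-shot jitter, sample-to-sample variability split into a 10% global
    ablation-efficiency factor (removed by SNV) and 2% independent per-line
    variability, and 2% corrupted replicates.
    """

    composition: tuple[tuple[str, str, int], ...] = DEFAULT_COMPOSITION
    replicates_per_sample: int = 50
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    lines: tuple[EmissionLine, ...] | None = None  # None -> packaged library
    base_intensities: Mapping[str, float] | None = None  # None -> defaults
    vigor_effect: float = 1.3
    vigor_elements: tuple[str, ...] = ("Mg", "Ca", "K")
    cultivar_effect: float = 1.2
    cultivar_elements: tuple[str, ...] = ("Na", "Si")
    shot_jitter_cv: float = 0.10
    sample_scale_cv: float = 0.10
    sample_cv: float = 0.02
    noise_sd: float = 1.0
    baseline: float = 20.0
    outlier_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.composition:
            raise ValueError("composition must not be empty")
        for cultivar, vigor, n in self.composition:
            if cultivar not in CULTIVARS or vigor not in VIGOR_CLASSES:
                raise ValueError(f"invalid composition entry ({cultivar}, {vigor}, {n})")
            if n <= 0:
                raise ValueError("composition counts must be > 0")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if not self.bands:
            raise ValueError("at least one band is required")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        for name, value in (
            ("vigor_effect", self.vigor_effect),
            ("cultivar_effect", self.cultivar_effect),
            ("shot_jitter_cv", self.shot_jitter_cv),
            ("sample_scale_cv", self.sample_scale_cv),
            ("sample_cv", self.sample_cv),
            ("noise_sd", self.noise_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved_lines(self) -> tuple[EmissionLine, ...]:
        lines = self.lines if self.lines is not None else load_line_library()
        return tuple(sorted(lines, key=lambda l: l.wavelength))

    def resolved_amplitudes(self, lines: Sequence[EmissionLine]) -> np.ndarray:
        table = dict(DEFAULT_BASE_INTENSITIES)
        if self.base_intensities is not None:
            table.update(self.base_intensities)
        amps = np.array([table.get(l.label, 100.0) for l in lines], dtype=float)
        if np.any(amps < 0):
            raise ValueError("base intensities must be >= 0")
        return amps


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------

def pseudo_voigt(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height pseudo-Voigt profile (equal Gaussian/Lorentzian mix)."""
    delta = np.asarray(x, dtype=float) - center
    gamma = fwhm / 2.0
    gauss = np.exp(-4.0 * np.log(2.0) * (delta / fwhm) ** 2)
    lorentz = gamma**2 / (gamma**2 + delta**2)
    return 0.5 * gauss + 0.5 * lorentz


def render_spectrum(
    lines: Sequence[tuple[EmissionLine, float]],
    grid: np.ndarray,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    band: str = "",
    sample_id: str = "",
    replicate_index: int = 0,
) -> Spectrum:
    """Render one spectrum: baseline + sum of amplitude-scaled line profiles + noise."""
    grid = np.asarray(grid, dtype=float)
    intensity = np.full(grid.shape, float(baseline))
    for line, amplitude in lines:
        if amplitude < 0:
            raise ValueError(f"negative amplitude for line {line.label}")
        if not (grid[0] <= line.wavelength <= grid[-1]):
            raise ValueError(f"line {line.label} lies outside the grid "
                             f"[{grid[0]:.2f}, {grid[-1]:.2f}] nm")
        intensity += amplitude * pseudo_voigt(grid, line.wavelength, line.default_width)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        intensity = intensity + gen.normal(0.0, noise_sd, size=grid.shape)
    return Spectrum(band=band, wavelengths=grid, intensities=intensity,
                    sample_id=sample_id, replicate_index=replicate_index)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal factors with mean 1 and the given CV."""
    if cv == 0:
        # Consume the same number of draws so changing cv to 0 keeps other
        # streams aligned is NOT guaranteed; determinism holds per config.
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_dataset(config: GeneratorConfig) -> list[SampleRecord]:
    """Generate clean replicate spectra for every sample in the composition.

    Deterministic given the config (including its seed).  Outlier corruption
    is a separate step (:func:`inject_outliers`) so ground truth stays explicit.
    """
    config.validate()
    lines = config.resolved_lines()
    base_amps = config.resolved_amplitudes(lines)
    rng = np.random.default_rng(config.seed)

    band_info = []
    for band in config.bands:
        grid = band.grid()
        idx = np.array([i for i, l in enumerate(lines) if band.contains(l.wavelength)], dtype=int)
        profiles = np.stack(
            [pseudo_voigt(grid, lines[i].wavelength, lines[i].default_width) for i in idx]
        ) if idx.size else np.zeros((0, grid.size))
        band_info.append((band, grid, idx, profiles))

    samples: list[SampleRecord] = []
    counter = 0
    for cultivar, vigor, n_samples in config.composition:
        class_scale = np.ones(len(lines))
        for i, line in enumerate(lines):
            if vigor == "HV" and line.element in config.vigor_elements:
                class_scale[i] *= config.vigor_effect
            if cultivar == "Paiaguás" and line.element in config.cultivar_elements:
                class_scale[i] *= config.cultivar_effect
        for _ in range(n_samples):
            counter += 1
            sample_id = f"{cultivar[0]}{vigor}-{counter:03d}"
            # one global ablation-efficiency factor per sample (SNV removes
            # it) plus small independent per-line variability
            sample_amps = (
                base_amps * class_scale
                * _lognormal_factors(rng, config.sample_scale_cv, ())
                * _lognormal_factors(rng, config.sample_cv, len(lines))
            )
            replicates: dict[str, list[Spectrum]] = {}
            for band, grid, idx, profiles in band_info:
                jitter = _lognormal_factors(
                    rng, config.shot_jitter_cv, (config.replicates_per_sample, idx.size)
                )
                amps = sample_amps[idx] * jitter  # (replicates, lines-in-band)
                intensities = config.baseline + amps @ profiles
                intensities += rng.normal(
                    0.0, config.noise_sd, size=intensities.shape
                ) if config.noise_sd > 0 else 0.0
                replicates[band.name] = [
                    Spectrum(band.name, grid, intensities[r], sample_id, r)
                    for r in range(config.replicates_per_sample)
                ]
            samples.append(SampleRecord(sample_id, cultivar, vigor, replicates))
    return samples


# ---------------------------------------------------------------------------
# Outlier injection
# ---------------------------------------------------------------------------

def _corrupt(spectrum: Spectrum, mode: int, rng: np.random.Generator) -> np.ndarray:
    """Distort one intensity vector strongly enough to fail the SAM filter."""
    x = spectrum.intensities
    if mode == 0:  # additive baseline ramp dominating the spectral variance
        span = float(x.max() - x.min()) + 1e-9
        return x + np.linspace(0.0, 6.0 * span, x.size)
    if mode == 1:  # suppressed line set: clip peaks down to near the continuum
        med = float(np.median(x))
        return np.minimum(x, med + 0.01 * (float(x.max()) - med))
    # mode 2: huge spurious emission spike at a random wavelength
    w = spectrum.wavelengths
    center = float(rng.uniform(w[0], w[-1]))
    height = 20.0 * (abs(float(x.max())) + 1.0)
    return x + height * np.exp(-0.5 * ((w - center) / 0.5) ** 2)


def inject_outliers(
    samples: Sequence[SampleRecord],
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SampleRecord], list[tuple[str, int]]]:
    """Corrupt a random fraction of replicates; return the new dataset and ground truth.

    The number corrupted is round-half-away-from-zero of
    ``n_samples * replicates_per_sample * fraction``; a corrupted replicate is
    distorted in every band.  The input dataset is left untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    samples = list(samples)
    if fraction == 0 or not samples:
        return samples, []
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_reps = len(next(iter(samples[0].replicates.values())))
    pairs = [(si, ri) for si in range(len(samples)) for ri in range(n_reps)]
    n_corrupt = int(np.floor(len(pairs) * fraction + 0.5))
    if n_corrupt == 0:
        return samples, []
    chosen = sorted(gen.choice(len(pairs), size=n_corrupt, replace=False).tolist())
    by_sample: dict[int, list[int]] = {}
    for flat in chosen:
        si, ri = pairs[flat]
        by_sample.setdefault(si, []).append(ri)

    out: list[SampleRecord] = []
    truth: list[tuple[str, int]] = []
    for si, record in enumerate(samples):
        if si not in by_sample:
            out.append(record)
            continue
        new_reps = {band: list(reps) for band, reps in record.replicates.items()}
        for ri in by_sample[si]:
            mode = int(gen.integers(0, 3))
            for band, reps in new_reps.items():
                spec = reps[ri]
                reps[ri] = replace(spec, intensities=_corrupt(spec, mode, gen))
            truth.append((record.sample_id, ri))
        out.append(SampleRecord(record.sample_id, record.cultivar, record.vigor, new_reps))
    return out, truth


def simulate(
    config: GeneratorConfig,
    outlier_rng: np.random.Generator | int | None = None,
) -> tuple[list[SampleRecord], list[tuple[str, int]]]:
    """Generate a dataset and apply the configured outlier corruption."""
    samples = generate_dataset(config)
    rng = outlier_rng if outlier_rng is not None else np.random.default_rng(config.seed + 1)
    return inject_outliers(samples, config.outlier_fraction, rng)


# ---------------------------------------------------------------------------
# Dataset on disk
# ---------------------------------------------------------------------------

def save_dataset(samples: Sequence[SampleRecord], outdir: str | Path) -> Path:
    """Write one CSV per sample per band plus a manifest; return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in samples:
        for band, reps in record.replicates.items():
            path = outdir / f"{record.sample_id}_{band}.csv"
            frame = pd.DataFrame({"wavelength_nm": reps[0].wavelengths})
            for spec in reps:
                frame[f"rep_{spec.replicate_index:02d}"] = spec.intensities
            frame.to_csv(path, index=False, float_format="%.6g")
            rows.append(
                {"sample_id": record.sample_id, "cultivar": record.cultivar,
                 "vigor": record.vigor, "band": band, "path": path.name}
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> list[SampleRecord]:
    """Read a dataset written by :func:`save_dataset`."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    records: dict[str, SampleRecord] = {}
    for row in table.itertuples():
        frame = pd.read_csv(manifest.parent / row.path)
        grid = frame["wavelength_nm"].to_numpy()
        reps = [
            Spectrum(str(row.band), grid, frame[col].to_numpy(), str(row.sample_id), i)
            for i, col in enumerate(c for c in frame.columns if c.startswith("rep_"))
        ]
        rec = records.setdefault(
            str(row.sample_id),
            SampleRecord(str(row.sample_id), str(row.cultivar), str(row.vigor), {}),
        )
        rec.replicates[str(row.band)] = reps
    return list(records.values())
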