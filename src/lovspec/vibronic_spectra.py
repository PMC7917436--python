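"""Vibronic absorption lineshapes, ensemble spectra, and Stokes-shift tables.

The homogeneous lineshape is computed with the second-order cumulant expansion
for the displaced harmonic oscillator (DHO), for which the cumulant expansion
is exact.  Each normal mode k contributes a Huang-Rhys factor S_k at frequency
omega_k; the lineshape function is

    g(t) = sum_k S_k [ coth(hbar*omega_k / 2 k_B T) (1 - cos omega_k t)
                       + i sin omega_k t ]

and the absorption profile, relative to the 0-0 origin, is

    sigma(domega) = Re  integral_0^inf  exp(i*domega*t - g(t) - Gamma*t) dt,

area-normalized on its grid.  Gamma is a homogeneous Lorentzian damping.  The
first spectral moment above the origin equals the reorganization energy
lambda = sum_k S_k omega_k, and at T -> 0 a single mode gives the Poisson
Franck-Condon progression exp(-S) S^n / n!.

Ensemble spectra sum the homogeneous lineshape over per-snapshot vertical
excitation energies weighted by |mu_01|^2.  The convention used here places
each snapshot's vertical energy at the lineshape origin; the absolute position
convention is free because reported spectra are rigidly shifted and
max-normalized anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import C_CM_FS, EV_TO_CM, KB_CM
from .errors import (
    ConfigurationError,
    CoverageError,
    NormalizationError,
    UsageError,
)

__all__ = [
    "VibronicMode",
    "SpectralDensity",
    "ElectronicRecord",
    "LineShape",
    "StokesTable",
    "huang_rhys_from_gradient",
    "cumulant_lineshape",
    "ensemble_spectrum",
    "weighted_average_spectra",
    "normalize_and_shift",
    "stokes_table",
    "stokes_from_cluster_rows",
    "cluster_shift",
    "reporting_deviation",
]

logger = logging.getLogger(__name__)

_TWO_PI_C = 2.0 * np.pi * C_CM_FS  # cm^-1 -> rad/fs


@dataclass(frozen=True)
class VibronicMode:
    """One normal mode: frequency (cm^-1) and dimensionless Huang-Rhys factor."""

    frequency_cm1: float
    huang_rhys: float

    def __post_init__(self) -> None:
        if self.frequency_cm1 <= 0:
            raise ConfigurationError("mode frequency must be > 0")
        if self.huang_rhys < 0:
            raise ConfigurationError("Huang-Rhys factor must be >= 0")


@dataclass
class SpectralDensity:
    """A discrete vibronic mode set defining the homogeneous lineshape."""

    modes: list[VibronicMode]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ConfigurationError("spectral density needs at least one mode")

    @property
    def reorganization_energy_cm1(self) -> float:
        """lambda = sum_k S_k * omega_k (cm^-1)."""
        return float(sum(m.huang_rhys * m.frequency_cm1 for m in self.modes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_cm1": [m.frequency_cm1 for m in self.modes],
                "huang_rhys": [m.huang_rhys for m in self.modes],
            }
        )


@dataclass
class ElectronicRecord:
    """Per-snapshot vertical energies (eV) and transition dipole (arb. units)."""

    snapshot: int
    cluster: str
    exc_ev: float
    dipole: np.ndarray
    emi_ev: float | None = None

    def __post_init__(self) -> None:
        self.dipole = np.asarray(self.dipole, dtype=float)
        if self.exc_ev <= 0:
            raise ConfigurationError("excitation energy must be > 0")
        if self.emi_ev is not None:
            if self.emi_ev <= 0:
                raise ConfigurationError("emission energy must be > 0")
            if self.exc_ev < self.emi_ev:
                raise ConfigurationError(
                    f"snapshot {self.snapshot}: excitation ({self.exc_ev} eV) "
                    f"below emission ({self.emi_ev} eV)"
                )

    @property
    def dipole_sq(self) -> float:
        return float(self.dipole @ self.dipole)


@dataclass
class LineShape:
    """A spectrum: strictly increasing wavenumber grid and non-negative intensity."""

    grid_cm1: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_cm1 = np.asarray(self.grid_cm1, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid_cm1.shape != self.intensity.shape:
            raise UsageError("grid and intensity shapes differ")
        if np.any(np.diff(self.grid_cm1) <= 0):
            raise UsageError("wavenumber grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise UsageError("intensities must be non-negative")

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid_cm1))


# ---------------------------------------------------------------------------
# Huang-Rhys factors
# ---------------------------------------------------------------------------

def huang_rhys_from_gradient(
    frequencies_cm1: Sequence[float],
    gradient_projections: Sequence[float],
    hbar: float = 1.0,
) -> list[VibronicMode]:
    """Huang-Rhys factors from excited-state gradients projected on normal modes.

    In the vertical-gradient approximation the excited-state minimum along
    mode k is displaced by Delta_k = g_k / omega_k^2 (mass-weighted), giving

        S_k = omega_k * Delta_k^2 / (2 hbar) = g_k^2 / (2 hbar omega_k^3).

    Frequencies and gradients must be supplied in one consistent unit system
    (``hbar`` expressed in the same units, default 1 for atomic-style units).
    The reported frequency of each mode is passed through unchanged, so
    callers working in cm^-1 obtain cm^-1 modes.
    """
    w = np.asarray(frequencies_cm1, dtype=float)
    g = np.asarray(gradient_projections, dtype=float)
    if w.shape != g.shape:
        raise UsageError("frequencies and gradients must have equal length")
    if np.any(w <= 0):
        raise ConfigurationError("mode frequencies must be > 0")
    s = g**2 / (2.0 * hbar * w**3)
    return [VibronicMode(float(wk), float(sk)) for wk, sk in zip(w, s)]


# ---------------------------------------------------------------------------
# cumulant lineshape
# ---------------------------------------------------------------------------

def _lineshape_function(
    sd: SpectralDensity, t_fs: np.ndarray, temperature_k: float
) -> np.ndarray:
    """g(t) on a femtosecond time grid (frequencies converted from cm^-1)."""
    g = np.zeros_like(t_fs, dtype=complex)
    for m in sd.modes:
        w = _TWO_PI_C * m.frequency_cm1  # rad/fs
        if temperature_k > 0:
            coth = 1.0 / np.tanh(m.frequency_cm1 / (2.0 * KB_CM * temperature_k))
        else:
            coth = 1.0
        g += m.huang_rhys * (coth * (1.0 - np.cos(w * t_fs)) + 1j * np.sin(w * t_fs))
    return g


def default_grid(sd: SpectralDensity, broadening_cm1: float) -> np.ndarray:
    """A grid wide enough for lambda + 5 quanta of the highest mode."""
    wmax = max(m.frequency_cm1 for m in sd.modes)
    lam = sd.reorganization_energy_cm1
    # Lorentzian tails carry ~Gamma/(pi*W) of area beyond +-W, so holding the
    # 1% coverage bound needs ~64 Gamma of padding; the low side additionally
    # holds thermal (hot-band) intensity below the origin.
    pad = 500.0 + 64.0 * broadening_cm1
    lo = -(pad + 2.0 * lam)
    hi = lam + 5.0 * wmax + pad
    return np.arange(lo, hi, 2.0)


def cumulant_lineshape(
    sd: SpectralDensity,
    temperature_k: float = 300.0,
    broadening_cm1: float = 100.0,
    grid_cm1: np.ndarray | None = None,
    dt_fs: float = 0.25,
) -> LineShape:
    """Homogeneous absorption lineshape relative to the 0-0 origin.

    The grid (cm^-1, relative) must span at least lambda + 5 quanta of the
    highest-frequency mode; if >=1% of the spectral area falls outside the
    grid a :class:`CoverageError` is raised.  The result is area-normalized
    to 1 on its grid.
    """
    if broadening_cm1 <= 0:
        raise ConfigurationError("broadening must be > 0")
    if grid_cm1 is None:
        grid_cm1 = default_grid(sd, broadening_cm1)
    grid_cm1 = np.asarray(grid_cm1, dtype=float)
    wmax = max(m.frequency_cm1 for m in sd.modes)
    lam = sd.reorganization_energy_cm1
    if grid_cm1[-1] - grid_cm1[0] < lam + 5.0 * wmax:
        raise CoverageError(
            "grid must span at least lambda + 5 vibrational quanta "
            f"({lam + 5 * wmax:.0f} cm^-1)"
        )

    gamma = _TWO_PI_C * broadening_cm1  # rad/fs
    t_max = min(np.log(1e9) / gamma, 2.0e5)
    t = np.arange(0.0, t_max, dt_fs)
    f = np.exp(-_lineshape_function(sd, t, temperature_k) - gamma * t)

    # sigma(w) = Re int_0^inf f(t) e^{iwt} dt, evaluated by FFT on the uniform
    # time grid and interpolated onto the requested wavenumber grid.  The
    # trapezoid end correction at t=0 is -dt/2 * Re f(0); the t_max end is
    # negligible by construction (|f| < 1e-9 there).
    from scipy.fft import ifft, next_fast_len

    n_fft = next_fast_len(4 * len(t))
    sig_fft = dt_fs * n_fft * np.real(ifft(f, n=n_fft)) - 0.5 * dt_fs * f[0].real
    freq_cm = np.fft.fftfreq(n_fft, d=dt_fs) / C_CM_FS  # cycles/fs -> cm^-1
    order = np.argsort(freq_cm)
    sigma = np.interp(grid_cm1, freq_cm[order], sig_fft[order])

    # full-line area in rad/fs measure is pi * Re f(0) = pi; check coverage
    area_rad = float(np.trapezoid(sigma, _TWO_PI_C * grid_cm1))
    if area_rad < 0.99 * np.pi:
        raise CoverageError(
            f"grid too narrow: captures {100 * area_rad / np.pi:.2f}% of the line area"
        )
    sigma = np.clip(sigma, 0.0, None)  # remove tiny truncation ripples
    sigma /= np.trapezoid(sigma, grid_cm1)
    return LineShape(
        grid_cm1,
        sigma,
        metadata={
            "temperature_K": temperature_k,
            "broadening_cm1": broadening_cm1,
            "reorganization_energy_cm1": lam,
            "origin": "0-0 at 0 cm^-1 (vertical energy placed at origin on assembly)",
        },
    )


# ---------------------------------------------------------------------------
# ensemble assembly
# ---------------------------------------------------------------------------

def ensemble_spectrum(
    records: Sequence[ElectronicRecord],
    lineshape: LineShape,
    grid_cm1: np.ndarray | None = None,
) -> LineShape:
    """Sum of the homogeneous lineshape over snapshots, |mu|^2-weighted.

    I(w) = sum_j |mu_01(j)|^2 sigma(w - w01(j)), with w01 converted from eV
    (1 eV = 8065.544 cm^-1).  The output grid defaults to the lineshape grid
    translated to cover all snapshot energies.
    """
    if not records:
        raise UsageError("ensemble_spectrum needs at least one record")
    centers = np.array([r.exc_ev * EV_TO_CM for r in records])
    weights = np.array([r.dipole_sq for r in records])
    if grid_cm1 is None:
        step = float(np.min(np.diff(lineshape.grid_cm1)))
        lo = centers.min() + lineshape.grid_cm1[0]
        hi = centers.max() + lineshape.grid_cm1[-1]
        grid_cm1 = np.arange(lo, hi + step, step)
    grid_cm1 = np.asarray(grid_cm1, dtype=float)
    intensity = np.zeros_like(grid_cm1)
    for c, w in zip(centers, weights):
        intensity += w * np.interp(
            grid_cm1 - c, lineshape.grid_cm1, lineshape.intensity, left=0.0, right=0.0
        )
    return LineShape(
        grid_cm1,
        intensity,
        metadata={
            "n_records": len(records),
            "lineshape": dict(lineshape.metadata),
        },
    )


def weighted_average_spectra(
    cluster_spectra: Mapping[str, LineShape], populations: Mapping[str, float]
) -> LineShape:
    """Population-weighted pointwise average of per-cluster spectra.

    Populations are renormalized over the supplied clusters; all spectra must
    share one grid.
    """
    names = list(cluster_spectra)
    if not names:
        raise UsageError("no cluster spectra supplied")
    missing = [n for n in names if n not in populations]
    if missing:
        raise UsageError(f"populations missing clusters: {missing}")
    pops = np.array([populations[n] for n in names], dtype=float)
    if np.any(pops < 0) or pops.sum() <= 0:
        raise UsageError("populations must be non-negative with positive sum")
    pops = pops / pops.sum()
    grid = cluster_spectra[names[0]].grid_cm1
    intensity = np.zeros_like(grid)
    for name, w in zip(names, pops):
        spec = cluster_spectra[name]
        if spec.grid_cm1.shape != grid.shape or not np.allclose(spec.grid_cm1, grid):
            raise UsageError(f"cluster {name!r} spectrum is on a different grid")
        intensity += w * spec.intensity
    return LineShape(
        grid,
        intensity,
        metadata={"weights": dict(zip(names, map(float, pops)))},
    )


def normalize_and_shift(spec: LineShape, shift_cm1: float = -3500.0) -> LineShape:
    """Max-normalize to exactly 1 and rigidly shift the wavenumber grid."""
    peak = float(spec.intensity.max())
    if peak <= 0:
        raise NormalizationError("cannot normalize an all-zero spectrum")
    meta = dict(spec.metadata)
    meta.update({"rigid_shift_cm1": float(shift_cm1), "max_normalized": True})
    return LineShape(spec.grid_cm1 + shift_cm1, spec.intensity / peak, metadata=meta)


# ---------------------------------------------------------------------------
# Stokes shifts
# ---------------------------------------------------------------------------

@dataclass
class StokesTable:
    """Per-cluster vertical energies and Stokes shifts plus a weighted row.

    ``rows`` holds unrounded values (cluster, population, exc_ev, emi_ev,
    ss_cm1, n_records); ``weighted`` is the population-weighted average row
    with populations renormalized over the retained clusters.
    """

    rows: pd.DataFrame
    weighted: pd.Series

    def rounded(self) -> pd.DataFrame:
        """Table as reported: energies to 2 decimals (eV), SS to integer cm^-1."""
        full = pd.concat(
            [self.rows, self.weighted.to_frame().T], ignore_index=True
        )
        out = full.copy()
        out["exc_ev"] = out["exc_ev"].astype(float).round(2)
        out["emi_ev"] = out["emi_ev"].astype(float).round(2)
        out["ss_cm1"] = out["ss_cm1"].astype(float).round(0).astype(int)
        return out


def stokes_from_cluster_rows(rows: pd.DataFrame) -> StokesTable:
    """Build a StokesTable (with weighted-average row) from per-cluster rows.

    ``rows`` needs columns cluster, population, exc_ev, emi_ev, ss_cm1; the
    weighted row uses populations renormalized over the given clusters.
    """
    required = {"cluster", "population", "exc_ev", "emi_ev", "ss_cm1"}
    missing = required - set(rows.columns)
    if missing:
        raise UsageError(f"cluster rows missing columns: {sorted(missing)}")
    pops = rows["population"].to_numpy(dtype=float)
    if np.any(pops < 0) or pops.sum() <= 0:
        raise UsageError("populations must be non-negative with positive sum")
    w = pops / pops.sum()
    weighted = pd.Series(
        {
            "cluster": "weighted",
            "population": float(pops.sum()),
            "exc_ev": float(w @ rows["exc_ev"].to_numpy(dtype=float)),
            "emi_ev": float(w @ rows["emi_ev"].to_numpy(dtype=float)),
            "ss_cm1": float(w @ rows["ss_cm1"].to_numpy(dtype=float)),
            "n_records": int(rows.get("n_records", pd.Series(0, index=rows.index)).sum()),
        }
    )
    return StokesTable(rows=rows.reset_index(drop=True), weighted=weighted)


def stokes_table(
    records: Sequence[ElectronicRecord], populations: Mapping[str, float]
) -> StokesTable:
    """Per-cluster mean vertical energies and Stokes shifts from raw records.

    Each record's Stokes shift is (EXC - EMI) * 8065.544 cm^-1; cluster rows
    are per-record means (averaged before any rounding).  Records without an
    emission energy are excluded with a log entry.
    """
    usable = []
    for r in records:
        if r.emi_ev is None:
            logger.warning("snapshot %s (cluster %s) has no emission energy; excluded",
                           r.snapshot, r.cluster)
            continue
        usable.append(r)
    if not usable:
        raise UsageError("no records with both excitation and emission energies")
    df = pd.DataFrame(
        {
            "cluster": [r.cluster for r in usable],
            "exc_ev": [r.exc_ev for r in usable],
            "emi_ev": [r.emi_ev for r in usable],
        }
    )
    df["ss_cm1"] = (df["exc_ev"] - df["emi_ev"]) * EV_TO_CM
    grouped = df.groupby("cluster", sort=True)
    rows = grouped.mean().reset_index()
    rows["n_records"] = grouped.size().to_numpy()
    missing = set(rows["cluster"]) - set(populations)
    if missing:
        raise UsageError(f"populations missing clusters: {sorted(missing)}")
    rows["population"] = [float(populations[c]) for c in rows["cluster"]]
    rows = rows[["cluster", "population", "exc_ev", "emi_ev", "ss_cm1", "n_records"]]
    return stokes_from_cluster_rows(rows)


def cluster_shift(
    records: Sequence[ElectronicRecord], cluster_a: str, cluster_b: str
) -> float:
    """Mean-excitation difference (a - b) in cm^-1 between two clusters."""
    exc_a = [r.exc_ev for r in records if r.cluster == cluster_a]
    exc_b = [r.exc_ev for r in records if r.cluster == cluster_b]
    if not exc_a or not exc_b:
        raise UsageError(
            f"both clusters must have records (got {len(exc_a)} for {cluster_a!r}, "
            f"{len(exc_b)} for {cluster_b!r})"
        )
    return float((np.mean(exc_a) - np.mean(exc_b)) * EV_TO_CM)


def reporting_deviation(exc_ev: float, emi_ev: float, ss_cm1: float) -> float:
    """|SS - (EXC-EMI)*8065.544| for a reported (rounded) table row.

    With energies rounded to 2 decimals the recomputed gap can move by up to
    0.01 eV ~ 81 cm^-1; larger deviations indicate an inconsistent table.
    """
    return float(abs(ss_cm1 - (exc_ev - emi_ev) * EV_TO_CM))
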