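"""Apolar packing ("crowding") via Gaussian pseudo-density overlap.

Each fragment (the flavin isoalloxazine ring, an apolar side chain) is given a
pseudo-electronic density: a sum of unit-normalized isotropic 3-D Gaussians
centered on its heavy atoms, with standard deviation equal to the element's
van der Waals radius.  The packing metric is the overlap integral of two such
densities, which has the closed form

    O(A,B) = sum_{i in A} sum_{j in B}
             (2 pi (s_i^2 + s_j^2))^(-3/2) exp(-d_ij^2 / (2 (s_i^2 + s_j^2)))

The dimensionless Carbo-style index O(A,B)/sqrt(O(A,A) O(B,B)) in [0, 1] is
the default reported quantity; the raw integral (A^-3) is also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import BONDI_RADII
from .errors import ConfigurationError, DefinitionError
from .trajectory_features import FrameSet

__all__ = [
    "PseudoDensity",
    "OverlapResult",
    "build_pseudo_density",
    "overlap",
    "overlap_series",
    "read_radius_table",
]


@dataclass
class PseudoDensity:
    """Sum of atom-centered Gaussians standing in for a fragment's density."""

    label: str
    centers: np.ndarray   # (n, 3) angstrom
    sigmas: np.ndarray    # (n,) angstrom, = van der Waals radii

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if len(self.centers) == 0:
            raise ConfigurationError("pseudo-density needs at least one center")
        if len(self.sigmas) != len(self.centers):
            raise ConfigurationError("one sigma per center required")
        if np.any(self.sigmas <= 0):
            raise ConfigurationError("sigmas must be > 0")


@dataclass(frozen=True)
class OverlapResult:
    """Raw overlap integral (A^-3) and the Carbo-normalized index in [0, 1]."""

    raw: float
    normalized: float


def read_radius_table(path) -> dict[str, float]:
    """Two-column CSV (element, radius in angstrom) -> radius mapping."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ConfigurationError("radius table needs columns (element, radius)")
    el, rad = df.columns[0], df.columns[1]
    return {str(e).upper(): float(r) for e, r in zip(df[el], df[rad])}


def build_pseudo_density(
    frames: FrameSet,
    fragment_selectors: Sequence[tuple[int, str]],
    radius_table: Mapping[str, float] | None = None,
    label: str = "fragment",
) -> list[PseudoDensity]:
    """One pseudo-density per frame from a fragment's heavy atoms.

    Hydrogens are excluded; every remaining element must appear in the radius
    table (default: Bondi van der Waals radii).
    """
    radii = {k.upper(): v for k, v in (radius_table or BONDI_RADII).items()}
    idx = frames.resolve_selection(fragment_selectors)
    heavy = [i for i in idx if str(frames.element[i]).upper() != "H"]
    if not heavy:
        raise DefinitionError(f"fragment {label!r} selects no heavy atoms")
    sigmas = []
    for i in heavy:
        el = str(frames.element[i]).upper()
        if el not in radii:
            raise ConfigurationError(f"element {el!r} missing from radius table")
        sigmas.append(radii[el])
    sigmas = np.asarray(sigmas)
    return [
        PseudoDensity(label, frames.coords[f, heavy, :], sigmas)
        for f in range(frames.n_frames)
    ]


def _pair_overlap(a: PseudoDensity, b: PseudoDensity) -> float:
    s2 = a.sigmas[:, None] ** 2 + b.sigmas[None, :] ** 2
    d2 = cdist(a.centers, b.centers, "sqeuclidean")
    return float(np.sum((2.0 * np.pi * s2) ** -1.5 * np.exp(-d2 / (2.0 * s2))))


def overlap(a: PseudoDensity, b: PseudoDensity) -> OverlapResult:
    """Closed-form Gaussian overlap of two pseudo-densities (symmetric in A, B)."""
    # canonical argument order makes the floating-point sum identical for
    # (A, B) and (B, A), so the symmetry holds exactly, not just to rounding
    key_a = (len(a.centers), a.centers.tobytes(), a.sigmas.tobytes())
    key_b = (len(b.centers), b.centers.tobytes(), b.sigmas.tobytes())
    if key_b < key_a:
        a, b = b, a
    raw = _pair_overlap(a, b)
    norm = raw / np.sqrt(_pair_overlap(a, a) * _pair_overlap(b, b))
    return OverlapResult(raw=raw, normalized=float(norm))


def overlap_series(
    frames: FrameSet,
    frag_a_selectors: Sequence[tuple[int, str]],
    frag_b_selectors: Sequence[tuple[int, str]],
    radius_table: Mapping[str, float] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-frame overlap of two fragments plus a distribution summary.

    Returns a DataFrame (frame, raw, normalized) and a summary dict with the
    mean, standard deviation and quartiles of the normalized index.
    """
    dens_a = build_pseudo_density(frames, frag_a_selectors, radius_table, labels[0])
    dens_b = build_pseudo_density(frames, frag_b_selectors, radius_table, labels[1])
    results = [overlap(da, db) for da, db in zip(dens_a, dens_b)]
    df = pd.DataFrame(
        {
            "raw": [r.raw for r in results],
            "normalized": [r.normalized for r in results],
        },
        index=pd.RangeIndex(frames.n_frames, name="frame"),
    )
    q = df["normalized"].quantile([0.25, 0.5, 0.75])
    summary = {
        "mean_normalized": float(df["normalized"].mean()),
        "sd_normalized": float(df["normalized"].std(ddof=0)),
        "q25": float(q[0.25]),
        "median": float(q[0.5]),
        "q75": float(q[0.75]),
        "mean_raw": float(df["raw"].mean()),
    }
    return df, summary
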