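import numpy as np
import pandas as pd
import pytest

from lovspec.synthetic_data import (
    EnergyModel,
    PocketClass,
    SyntheticConfig,
)


@pytest.fixture
def planted_config() -> SyntheticConfig:
    """Three planted pocket classes at 78/17/5% (minus a 0.5% decoy blob).

    The two OUT classes differ in the Q489 distance (solvent-exposed ~8 A vs
    buried ~5.6 A); the decoy flips N468 instead so it separates along the
    second feature axis.
    """
    classes = [
        PocketClass("C_IN", 0.775, {"Q489": "in", "N468": "in"}),
        PocketClass("C_OUT_solv", 0.17, {"Q489": "out", "N468": "in"}, {"Q489": 8.0}),
        PocketClass("C_OUT_buried", 0.05, {"Q489": "out", "N468": "in"}, {"Q489": 5.6}),
        PocketClass("C_blob", 0.005, {"Q489": "in", "N468": "out"}),
    ]
    energy = {c.name: EnergyModel(3.22, 2.82) for c in classes}
    return SyntheticConfig(
        n_frames=5000, classes=classes, class_dwell_ns=2.0,
        energy_model=energy, seed=42,
    )


@pytest.fixture
def table1_c426a() -> pd.DataFrame:
    """Published-style per-cluster energy table for the single mutant.

    Columns follow the Stokes-table layout: per-cluster vertical excitation
    and emission (eV), Stokes shift (cm^-1), and population fractions.
    """
    return pd.DataFrame(
        {
            "cluster": ["C2_OUT", "C5_OUT", "C7_IN"],
            "population": [0.05, 0.17, 0.78],
            "exc_ev": [3.27, 3.23, 3.22],
            "emi_ev": [2.88, 2.84, 2.82],
            "ss_cm1": [3203.0, 3145.0, 3192.0],
        }
    )


def grid_overlap_quadrature(a, b, spacing=0.05, pad=12.0) -> float:
    """Independent 3-D grid quadrature of the pseudo-density overlap integral.

    The integrand is a sum of pairwise products of isotropic Gaussians, each
    separable in x/y/z, so the 3-D Riemann sum over a regular grid factorises
    exactly into products of 1-D Riemann sums — the value is identical to
    summing over the full 3-D grid, without materialising it.
    """
    total = 0.0
    for ca, sa in zip(a.centers, a.sigmas):
        for cb, sb in zip(b.centers, b.sigmas):
            term = 1.0
            for d in range(3):
                lo = min(ca[d], cb[d]) - pad
                hi = max(ca[d], cb[d]) + pad
                xs = np.arange(lo, hi + spacing, spacing)
                ga = np.exp(-((xs - ca[d]) ** 2) / (2 * sa * sa)) / (sa * np.sqrt(2 * np.pi))
                gb = np.exp(-((xs - cb[d]) ** 2) / (2 * sb * sb)) / (sb * np.sqrt(2 * np.pi))
                term *= float(np.sum(ga * gb)) * spacing
            total += term
    return total
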