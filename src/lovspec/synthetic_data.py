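"""Synthetic trajectories, electronic records, and vibronic mode sets.

The generators emulate the features of the real data this pipeline was built
for — microsecond MD of a flavin-binding pocket and per-snapshot excited-state
calculations — at toy scale, with known ground truth:

* two-state (*in*/*out*) side-chain H-bond dynamics as a discrete-time Markov
  chain on the frame grid, with configurable mean dwell times (an exponential
  residence-time approximation of the ~100-300 ns switching seen in LOV
  pockets);
* optionally, an explicit set of planted pocket *classes* (joint side-chain
  configurations) with prescribed stationary populations, simulated as a
  semi-Markov chain whose transition kernel preserves those populations;
* class-conditional Gaussian excitation/emission energies on the scale of
  flavin QM/MM results (~3.2 eV excitation, ~2.8 eV emission);
* a discrete vibronic mode set (frequency, Huang-Rhys factor) whose envelope
  shows the characteristic two-band flavin absorption.

Every generated distance series is also embedded as pseudo-atom coordinates so
the downstream geometry code can be exercised end-to-end: acceptor atoms sit on
a fixed scaffold and each donor moves along its own axis, which makes the
distance -> coordinate round trip exact to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trajectory_features import FrameSet
from .vibronic_spectra import ElectronicRecord, SpectralDensity, VibronicMode

__all__ = [
    "ResidueStateModel",
    "PocketClass",
    "EnergyModel",
    "SyntheticConfig",
    "GroundTruth",
    "generate_pocket_trajectory",
    "generate_electronic_records",
    "generate_mode_set",
    "generate_ring_trajectory",
    "ring_reference_frame",
    "DEFAULT_MODE_SET",
]

#: Default vibronic mode set: two dominant ring stretches plus a low-frequency
#: mode; chosen so the absorption envelope shows two main vibronic bands
#: separated by ~1300 cm^-1, as observed for flavins.
DEFAULT_MODE_SET: tuple[tuple[float, float], ...] = (
    (1350.0, 0.45),
    (1580.0, 0.30),
    (500.0, 0.15),
)


@dataclass
class ResidueStateModel:
    """Two-state H-bond distance model for one tracked side chain.

    Defaults straddle the 4 A / 5 A in/out thresholds with a clear gap:
    *in* 2.9 +- 0.2 A (a formed heavy-atom H-bond), *out* 6.5 +- 0.8 A.
    """

    in_mean: float = 2.9
    in_sd: float = 0.2
    out_mean: float = 6.5
    out_sd: float = 0.8
    in_dwell_ns: float = 250.0
    out_dwell_ns: float = 250.0

    def validate(self, frame_spacing_ns: float) -> None:
        if self.in_sd <= 0 or self.out_sd <= 0:
            raise ConfigurationError("distance standard deviations must be > 0")
        if self.in_dwell_ns <= frame_spacing_ns or self.out_dwell_ns <= frame_spacing_ns:
            raise ConfigurationError(
                "mean dwell times must exceed the frame spacing "
                f"({frame_spacing_ns} ns)"
            )


@dataclass
class PocketClass:
    """A planted pocket conformation: a joint side-chain state with a population.

    ``states`` maps residue name -> 'in' or 'out'; ``distance_mean`` optionally
    overrides the residue's in/out mean for this class (so several *out*
    classes, e.g. solvent-exposed vs buried, can be told apart geometrically).
    """

    name: str
    population: float
    states: Mapping[str, str]
    distance_mean: Mapping[str, float] = field(default_factory=dict)
    distance_sd: float = 0.2


@dataclass
class EnergyModel:
    """Class-conditional vertical energy distribution (eV).

    Excitation and emission are drawn jointly Gaussian with correlation
    ``correlation`` (default 0.97): snapshots that excite high also emit high,
    so the Stokes gap fluctuates far less than either energy — the pattern
    seen in per-cluster flavin QM/MM tables, where cluster excitation spans
    ~0.05 eV while the gap stays within ~0.01 eV of 0.40 eV.
    """

    exc_mean: float
    emi_mean: float
    exc_sd: float = 0.02
    emi_sd: float = 0.02
    correlation: float = 0.97
    dipole_mean: float = 1.0
    dipole_sd: float = 0.05

    def validate(self) -> None:
        if self.exc_mean <= 0 or self.emi_mean <= 0:
            raise ConfigurationError("energies must be positive")
        if self.exc_sd < 0 or self.emi_sd < 0:
            raise ConfigurationError("energy standard deviations must be >= 0")
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError("energy correlation must lie in [-1, 1]")
        if self.emi_mean >= self.exc_mean:
            raise ConfigurationError(
                "emission mean must be below excitation mean "
                f"(got EXC {self.exc_mean} <= EMI {self.emi_mean})"
            )


@dataclass
class SyntheticConfig:
    """Configuration for the synthetic pocket trajectory generator."""

    n_frames: int = 5000
    frame_spacing_ns: float = 1.0
    residue_states: Mapping[str, ResidueStateModel] = field(
        default_factory=lambda: {"Q489": ResidueStateModel(), "N468": ResidueStateModel()}
    )
    #: Optional planted classes; when given they override per-residue dynamics.
    classes: Sequence[PocketClass] | None = None
    #: Base dwell (ns) for the planted-class chain; class i dwells
    #: class_dwell_ns / (1 - population_i) on average.
    class_dwell_ns: float = 10.0
    #: Circular (mean deg, kappa) of the rotamer dihedral in the unflipped and
    #: flipped states, for generators that emit dihedral-bearing fragments.
    dihedral_modes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"unflipped": (60.0, 50.0), "flipped": (180.0, 50.0)}
    )
    energy_model: Mapping[str, EnergyModel] = field(default_factory=dict)
    mode_set: Sequence[tuple[float, float]] = DEFAULT_MODE_SET
    #: Hard lower bound on any generated heavy-atom distance (angstrom).
    min_distance: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.frame_spacing_ns <= 0:
            raise ConfigurationError("frame_spacing must be > 0")
        if not self.residue_states:
            raise ConfigurationError("at least one tracked residue is required")
        for model in self.residue_states.values():
            model.validate(self.frame_spacing_ns)
        if self.classes is not None:
            pops = np.array([c.population for c in self.classes], dtype=float)
            if np.any(pops <= 0):
                raise ConfigurationError("class populations must be > 0")
            if abs(pops.sum() - 1.0) > 1e-9:
                raise ConfigurationError("class populations must sum to 1")
            if self.class_dwell_ns <= self.frame_spacing_ns:
                raise ConfigurationError("class_dwell_ns must exceed the frame spacing")
            for c in self.classes:
                if set(c.states) != set(self.residue_states):
                    raise ConfigurationError(
                        f"class {c.name!r} must state every tracked residue"
                    )
                if c.distance_sd <= 0:
                    raise ConfigurationError("class distance_sd must be > 0")
        for model in self.energy_model.values():
            model.validate()


@dataclass
class GroundTruth:
    """Known truth emitted alongside a synthetic trajectory."""

    residue_states: pd.DataFrame          # frames x residues, values 'in'/'out'
    class_labels: np.ndarray              # per-frame class name
    frame_class: np.ndarray               # per-frame aggregate 'IN'/'OUT'/'mixed'
    populations: dict[str, float]         # nominal (stationary) class populations
    empirical_populations: dict[str, float]
    energy_means: dict[str, tuple[float, float]]  # class -> (exc, emi) means, eV
    residue_to_distance: dict[str, str]   # residue -> distance column label

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("ground-truth populations must sum to 1")
        if len(self.class_labels) != len(self.residue_states):
            raise ConfigurationError("label sequence length must equal n_frames")


# ---------------------------------------------------------------------------
# state dynamics
# ---------------------------------------------------------------------------

def _two_state_chain(
    n: int, p_leave_in: float, p_leave_out: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a 2-state chain (0=in, 1=out) started from its stationary law."""
    # stationary occupancy of 'in' = dwell_in / (dwell_in + dwell_out)
    pi_in = (1.0 / p_leave_in) / (1.0 / p_leave_in + 1.0 / p_leave_out)
    states = np.empty(n, dtype=np.int8)
    states[0] = 0 if rng.random() < pi_in else 1
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        p_leave = p_leave_in if states[t - 1] == 0 else p_leave_out
        states[t] = states[t - 1] ^ (u[t - 1] < p_leave)
    return states


def _class_chain(
    n: int, populations: np.ndarray, p_base: float, rng: np.random.Generator
) -> np.ndarray:
    """Semi-Markov chain over K classes with stationary law ``populations``.

    From class i the chain leaves with probability p_base*(1-pi_i) per frame and
    jumps to j != i with probability proportional to pi_j.  Balance: the flow
    out of i, pi_i*p_base*(1-pi_i), equals the flow in, so ``populations`` is
    stationary while dominant classes dwell longer — mirroring how the
    majority pocket conformation persists between excursions.
    """
    k = len(populations)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(k, p=populations)
    for t in range(1, n):
        i = states[t - 1]
        if rng.random() < p_base * (1.0 - populations[i]):
            w = populations.copy()
            w[i] = 0.0
            states[t] = rng.choice(k, p=w / w.sum())
        else:
            states[t] = i
    return states


def _truncated_normal(
    mean: np.ndarray, sd: np.ndarray, lower: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian draws redrawn (not clipped) below ``lower``."""
    out = rng.normal(mean, sd)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad],
                              np.broadcast_to(sd, out.shape)[bad])
    return np.maximum(out, lower)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _embed_frames(distances: np.ndarray, residues: Sequence[str]) -> FrameSet:
    """Embed a (n_frames, n_res) distance matrix as donor/acceptor pseudo-atoms.

    Acceptor k (an FMN-like oxygen) is fixed at (0, 8k, 0); donor k (a
    side-chain nitrogen) sits at (d, 8k, 0), so the recomputed distance equals
    the generated one exactly.
    """
    n_frames, n_res = distances.shape
    coords = np.zeros((n_frames, 2 * n_res, 3))
    atom_name, res_name, res_id, element = [], [], [], []
    for k, res in enumerate(residues):
        coords[:, 2 * k, 1] = 8.0 * k          # acceptor, static
        coords[:, 2 * k + 1, 0] = distances[:, k]
        coords[:, 2 * k + 1, 1] = 8.0 * k      # donor on its own axis
        atom_name += [f"O{k + 1}", "ND1"]
        res_name += ["FMN", res[:3].upper().ljust(3)[:3]]
        res_id += [900 + k, k + 1]
        element += ["O", "N"]
    return FrameSet(coords, atom_name, res_name, res_id, element)


def generate_pocket_trajectory(
    config: SyntheticConfig,
) -> tuple[FrameSet, pd.DataFrame, GroundTruth]:
    """Simulate in/out side-chain dynamics and emit frames + distance table + truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    residues = list(config.residue_states)
    n = config.n_frames

    if config.classes is not None:
        pops = np.array([c.population for c in config.classes], dtype=float)
        p_base = config.frame_spacing_ns / config.class_dwell_ns
        idx = _class_chain(n, pops, p_base, rng)
        class_names = np.array([c.name for c in config.classes], dtype=object)
        labels = class_names[idx]
        state_cols = {}
        dist = np.empty((n, len(residues)))
        for k, res in enumerate(residues):
            model = config.residue_states[res]
            res_states = np.array(
                [c.states[res] for c in config.classes], dtype=object
            )[idx]
            state_cols[res] = res_states
            means = np.array(
                [
                    c.distance_mean.get(
                        res, model.in_mean if c.states[res] == "in" else model.out_mean
                    )
                    for c in config.classes
                ]
            )[idx]
            sds = np.array([c.distance_sd for c in config.classes])[idx]
            dist[:, k] = _truncated_normal(means, sds, config.min_distance, rng)
        nominal = {c.name: float(c.population) for c in config.classes}
    else:
        state_cols = {}
        dist = np.empty((n, len(residues)))
        for k, res in enumerate(residues):
            model = config.residue_states[res]
            chain = _two_state_chain(
                n,
                config.frame_spacing_ns / model.in_dwell_ns,
                config.frame_spacing_ns / model.out_dwell_ns,
                rng,
            )
            state_cols[res] = np.where(chain == 0, "in", "out").astype(object)
            means = np.where(chain == 0, model.in_mean, model.out_mean)
            sds = np.where(chain == 0, model.in_sd, model.out_sd)
            dist[:, k] = _truncated_normal(means, sds, config.min_distance, rng)
        states_df_tmp = pd.DataFrame(state_cols)
        all_in = (states_df_tmp == "in").all(axis=1).to_numpy()
        labels = np.where(all_in, "IN", "OUT").astype(object)
        pi_in = {
            res: config.residue_states[res].in_dwell_ns
            / (config.residue_states[res].in_dwell_ns + config.residue_states[res].out_dwell_ns)
            for res in residues
        }
        p_all_in = float(np.prod([pi_in[r] for r in residues]))
        nominal = {"IN": p_all_in, "OUT": 1.0 - p_all_in}

    states_df = pd.DataFrame(state_cols, index=pd.RangeIndex(n, name="frame"))
    all_in = (states_df == "in").all(axis=1).to_numpy()
    any_out = (states_df == "out").any(axis=1).to_numpy()
    frame_class = np.full(n, "mixed", dtype=object)
    frame_class[all_in] = "IN"
    frame_class[any_out] = "OUT"

    labels = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    empirical = {str(u): float(c) / n for u, c in zip(uniq, counts)}

    frames = _embed_frames(dist, residues)
    dist_labels = [f"d{k + 1}" for k in range(len(residues))]
    table = pd.DataFrame(
        dist, columns=dist_labels, index=pd.RangeIndex(n, name="frame")
    )
    truth = GroundTruth(
        residue_states=states_df,
        class_labels=labels,
        frame_class=frame_class,
        populations=nominal,
        empirical_populations=empirical,
        energy_means={
            name: (m.exc_mean, m.emi_mean) for name, m in config.energy_model.items()
        },
        residue_to_distance=dict(zip(residues, dist_labels)),
    )
    return frames, table, truth


def generate_electronic_records(
    truth: GroundTruth, config: SyntheticConfig
) -> list[ElectronicRecord]:
    """One electronic record per frame, with class-conditional vertical energies.

    Every record satisfies excitation > emission (pairs violating it are
    redrawn; with eV-scale gaps and ~0.02 eV spreads this is essentially never
    needed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    missing = sorted(set(map(str, truth.class_labels)) - set(config.energy_model))
    if missing:
        raise ConfigurationError(f"energy_model missing classes: {missing}")
    records = []
    for i, cls in enumerate(truth.class_labels):
        m = config.energy_model[str(cls)]
        rho = m.correlation

        def _draw() -> tuple[float, float]:
            z1, z2 = rng.normal(size=2)
            exc = m.exc_mean + m.exc_sd * z1
            emi = m.emi_mean + m.emi_sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
            return exc, emi

        exc, emi = _draw()
        for _ in range(1000):
            if exc > emi:
                break
            exc, emi = _draw()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mag = max(rng.normal(m.dipole_mean, m.dipole_sd), 1e-6)
        records.append(
            ElectronicRecord(
                snapshot=i,
                cluster=str(cls),
                exc_ev=float(exc),
                emi_ev=float(emi),
                dipole=mag * direction,
            )
        )
    return records


def generate_mode_set(config: SyntheticConfig) -> SpectralDensity:
    """Return the configured vibronic modes as a SpectralDensity."""
    if not config.mode_set:
        raise ConfigurationError("mode_set must not be empty")
    modes = [VibronicMode(float(w), float(s)) for w, s in config.mode_set]
    return SpectralDensity(modes)


# ---------------------------------------------------------------------------
# ring / packing toy system
# ---------------------------------------------------------------------------

_RING_TEMPLATE = np.array(
    [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
) * 1.4  # hexagonal stand-in for the isoalloxazine core, angstrom


def _ring_atoms() -> tuple[list[str], list[str], list[int], list[str]]:
    atom_name = (
        [f"CA{i}" for i in range(8)]
        + [f"C{i + 1}" for i in range(6)]
        + ["CB", "CG", "CD1", "CD2"]
    )
    res_name = ["GLY"] * 8 + ["FMN"] * 6 + ["LEU"] * 4
    res_id = list(range(1, 9)) + [900] * 6 + [472] * 4
    element = ["C"] * 18
    return atom_name, res_name, res_id, element


def _ring_frame(sep: float, chi_deg: float, ring_offset: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    scaffold = np.array(
        [[6.0 * np.cos(a), 6.0 * np.sin(a), (-1.0) ** i]
         for i, a in enumerate(np.linspace(0, 2 * np.pi, 8, endpoint=False))]
    )
    ring = _RING_TEMPLATE + ring_offset
    # side chain above the ring plane; the CD2 arm realises the chi rotamer
    # dihedral about the CG-CD1 bond
    base = np.array([0.0, 0.0, sep])
    cb = base
    cg = base + [1.5, 0.0, 0.0]
    cd1 = base + [2.2, 1.3, 0.0]
    axis = (cd1 - cg) / np.linalg.norm(cd1 - cg)
    arm = np.array([0.0, 0.0, 1.5])
    arm -= axis * (arm @ axis)
    cd2 = cd1 + Rotation.from_rotvec(np.radians(chi_deg) * axis).apply(arm)
    return np.vstack([scaffold, ring, [cb, cg, cd1, cd2]])


def ring_reference_frame(separation: float = 3.5, dihedral_deg: float = 60.0) -> FrameSet:
    """The jitter-free 'crystal' geometry of the toy ring system (one frame)."""
    coords = _ring_frame(separation, dihedral_deg, np.zeros(3))[None]
    return FrameSet(coords, *_ring_atoms())


def generate_ring_trajectory(
    n_frames: int,
    separation: float = 3.5,
    separation_sd: float = 0.15,
    ring_jitter: float = 0.3,
    dihedral_mean: float = 60.0,
    dihedral_kappa: float = 50.0,
    seed: int = 0,
) -> FrameSet:
    """Toy chromophore/side-chain system for packing and mobility analyses.

    Emits per frame: a fixed 8-atom CA scaffold (the alignment reference), a
    6-atom aromatic ring rigidly displaced by isotropic Gaussian jitter of
    scale ``ring_jitter`` (A) about its pocket position, and a 4-carbon
    side-chain fragment whose centroid sits ``separation`` A (+- sd) from the
    ring centroid and whose last atom realises a von Mises-distributed rotamer
    dihedral.  The whole frame is then given a random global rigid motion, so
    downstream RMSD analyses must actually superpose the scaffold.

    Smaller ``separation`` = a more crowded pocket; smaller ``ring_jitter`` = a
    more rigid chromophore.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, 18, 3))
    for f in range(n_frames):
        offset = rng.normal(0.0, ring_jitter, size=3)
        sep = max(float(rng.normal(separation, separation_sd)), 1.8)
        chi = np.degrees(rng.vonmises(np.radians(dihedral_mean), dihedral_kappa))
        frame = _ring_frame(sep, chi, offset)
        g = Rotation.random(rng=rng)
        coords[f] = g.apply(frame) + rng.normal(0.0, 5.0, size=3)
    return FrameSet(coords, *_ring_atoms())
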