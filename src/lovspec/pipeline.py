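"""End-to-end orchestration of the pocket-analysis / spectroscopy pipeline.

A single YAML config drives two variants (e.g. a single-mutant and a
multi-mutant protein) through identical stages:

    simulate -> distances -> states -> PCA + clustering -> representatives
             -> crowding overlap / dihedral / ring RMSD -> spectra -> Stokes

so the cross-variant comparison is an in-silico experiment with all analysis
parameters shared.  Each stage writes its outputs (CSV/JSON/two-column
spectra) into ``output_dir/<variant>/`` and every file carries the config
hash, so stages can be re-run from intermediates — the spectroscopy side can
be recomputed without re-clustering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import (
    EnergyModel,
    PocketClass,
    SyntheticConfig,
    classify_states,
    cluster_density,
    compute_dihedral,
    compute_distances,
    compute_ring_rmsd,
    cumulant_lineshape,
    ensemble_spectrum,
    fit_pca,
    generate_electronic_records,
    generate_mode_set,
    generate_pocket_trajectory,
    generate_ring_trajectory,
    label_clusters,
    normalize_and_shift,
    overlap_series,
    ring_reference_frame,
    sample_representatives,
    stokes_table,
    weighted_average_spectra,
    write_frames,
)
from .errors import ConfigurationError, LovspecError
from .trajectory_features import DistanceDefinition, read_frames
from .vibronic_spectra import ElectronicRecord, SpectralDensity, VibronicMode

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "distances",
    "states",
    "cluster",
    "crowd",
    "spectra",
    "stokes",
    "report",
)


# ---------------------------------------------------------------------------
# config schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClassSpec(_Strict):
    name: str
    population: float = Field(gt=0, le=1)
    states: dict[str, Literal["in", "out"]]
    distance_mean: dict[str, float] = {}
    exc_mean_ev: float = Field(gt=0)
    emi_mean_ev: float = Field(gt=0)
    exc_sd_ev: float = Field(default=0.02, ge=0)
    emi_sd_ev: float = Field(default=0.02, ge=0)


class RingSpec(_Strict):
    separation: float = Field(default=3.5, gt=0)
    ring_jitter: float = Field(default=0.3, gt=0)
    dihedral_mean_deg: float = 60.0
    n_frames: int = Field(default=300, ge=1)


class VariantSpec(_Strict):
    n_frames: int = Field(default=5000, ge=1)
    frame_spacing_ns: float = Field(default=1.0, gt=0)
    class_dwell_ns: float = Field(default=10.0, gt=0)
    residues: list[str] = ["Q489", "N468"]
    classes: list[ClassSpec]
    ring: RingSpec = RingSpec()
    mode_set: list[tuple[float, float]] = [(1350.0, 0.45), (1580.0, 0.30), (500.0, 0.15)]

    @model_validator(mode="after")
    def _check(self) -> "VariantSpec":
        total = sum(c.population for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class populations sum to {total}, expected 1")
        return self


class PipelineConfig(_Strict):
    output_dir: str = "lovspec_out"
    seed: int = 0
    in_max: float = Field(default=4.0, gt=0)
    out_min: float = Field(default=5.0, gt=0)
    pca_variance_target: float = Field(default=0.9, gt=0, le=1)
    min_cluster_size: Optional[int] = None  # default: 1% of frames
    min_samples: Optional[int] = None       # default: max(min_cluster_size, 1% of frames)
    min_population: float = Field(default=0.01, ge=0, le=1)
    n_representatives: int = Field(default=10, ge=1)
    temperature_K: float = Field(default=300.0, ge=0)
    broadening_cm1: float = Field(default=100.0, gt=0)
    shift_cm1: float = -3500.0
    variants: dict[str, VariantSpec]

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.in_max >= self.out_min:
            raise ValueError("in_max must be below out_min")
        if not self.variants:
            raise ValueError("at least one variant is required")
        return self

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a pipeline config, rejecting unknown keys by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("invalid config: " + "; ".join(msgs)) from exc


# ---------------------------------------------------------------------------
# stage I/O helpers
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, index_col=0) -> pd.DataFrame:
    if not path.exists():
        raise LovspecError(f"missing intermediate {path}; run the earlier stages first")
    return pd.read_csv(path, comment="#", index_col=index_col)


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _read_json(path: Path) -> dict:
    if not path.exists():
        raise LovspecError(f"missing intermediate {path}; run the earlier stages first")
    return json.loads(path.read_text())


def _write_spectrum(grid: np.ndarray, intensity: np.ndarray, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n# wavenumber_cm1 intensity\n")
        for g, i in zip(grid, intensity):
            fh.write(f"{g:.4f} {i:.8e}\n")


def _variant_seed(base_seed: int, variant: str, offset: int = 0) -> int:
    h = hashlib.sha256(f"{base_seed}:{variant}:{offset}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _synthetic_config(spec: VariantSpec, seed: int) -> SyntheticConfig:
    classes = [
        PocketClass(c.name, c.population, dict(c.states), dict(c.distance_mean))
        for c in spec.classes
    ]
    energy = {
        c.name: EnergyModel(c.exc_mean_ev, c.emi_mean_ev, c.exc_sd_ev, c.emi_sd_ev)
        for c in spec.classes
    }
    from .synthetic_data import ResidueStateModel

    return SyntheticConfig(
        n_frames=spec.n_frames,
        frame_spacing_ns=spec.frame_spacing_ns,
        residue_states={r: ResidueStateModel() for r in spec.residues},
        classes=classes,
        class_dwell_ns=spec.class_dwell_ns,
        energy_model=energy,
        mode_set=[tuple(m) for m in spec.mode_set],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stages (each reads its predecessors' files and writes its own)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, variant: str, vdir: Path) -> None:
    spec = config.variants[variant]
    h = config.hash()
    syn = _synthetic_config(spec, _variant_seed(config.seed, variant))
    frames, table, truth = generate_pocket_trajectory(syn)
    records = generate_electronic_records(truth, syn)

    write_frames(frames, vdir / "trajectory.pdb")
    _write_csv(table, vdir / "distances_generated.csv", h)
    _write_json(
        {
            "residue_to_distance": truth.residue_to_distance,
            "class_labels": truth.class_labels.tolist(),
            "frame_class": truth.frame_class.tolist(),
            "populations": truth.populations,
            "empirical_populations": truth.empirical_populations,
            "energy_means": {k: list(v) for k, v in truth.energy_means.items()},
        },
        vdir / "truth.json",
        h,
    )
    rec_df = pd.DataFrame(
        {
            "snapshot": [r.snapshot for r in records],
            "cluster": [r.cluster for r in records],
            "exc_eV": [r.exc_ev for r in records],
            "emi_eV": [r.emi_ev for r in records],
            "mux": [r.dipole[0] for r in records],
            "muy": [r.dipole[1] for r in records],
            "muz": [r.dipole[2] for r in records],
        }
    )
    _write_csv(rec_df, vdir / "records.csv", h, index=False)
    # ring / packing toy trajectory for the crowding stage
    ring = generate_ring_trajectory(
        spec.ring.n_frames,
        separation=spec.ring.separation,
        ring_jitter=spec.ring.ring_jitter,
        dihedral_mean=spec.ring.dihedral_mean_deg,
        seed=_variant_seed(config.seed, variant, 1),
    )
    write_frames(ring, vdir / "ring.pdb")
    logger.info("[%s] simulate: %d frames, %d records", variant, spec.n_frames, len(records))


def stage_distances(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    frames = read_frames(vdir / "trajectory.pdb")
    truth = _read_json(vdir / "truth.json")
    res_map = truth["residue_to_distance"]
    defs = [
        DistanceDefinition(lab, k + 1, "ND1", 900 + k, f"O{k + 1}")
        for k, (res, lab) in enumerate(res_map.items())
    ]
    table = compute_distances(frames, defs)
    _write_csv(table, vdir / "distances.csv", h)
    logger.info("[%s] distances: %d frames x %d labels", variant, *table.shape)


def stage_states(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    table = _read_csv(vdir / "distances.csv")
    truth = _read_json(vdir / "truth.json")
    series = classify_states(
        table, truth["residue_to_distance"], config.in_max, config.out_min
    )
    out = series.states.copy()
    out["frame_class"] = series.frame_class
    _write_csv(out, vdir / "states.csv", h)
    logger.info(
        "[%s] states: %s", variant, series.frame_class.value_counts().to_dict()
    )


def stage_cluster(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    table = _read_csv(vdir / "distances.csv")
    states_df = _read_csv(vdir / "states.csv")
    from .pocket_conformations import StateSeries

    series = StateSeries(
        states_df.drop(columns="frame_class"),
        states_df["frame_class"],
        config.in_max,
        config.out_min,
    )
    pca = fit_pca(table, list(table.columns), config.pca_variance_target)
    mcs = config.min_cluster_size or max(2, int(0.01 * len(table)))
    min_samples = config.min_samples or max(mcs, int(0.01 * len(table)))
    logger.info("[%s] clustering: %d PCA components, min_cluster_size=%d, min_samples=%d",
                variant, pca.n_components, mcs, min_samples)
    labels, summaries = cluster_density(
        pca.transform(table), mcs, config.min_population, features=table,
        min_samples=min_samples,
    )
    summaries = label_clusters(summaries, labels, series)
    summaries = sample_representatives(
        summaries, labels, config.n_representatives,
        seed=_variant_seed(config.seed, variant, 2),
    )
    _write_csv(
        pd.DataFrame({"cluster": labels}, index=table.index), vdir / "assignment.csv", h
    )
    _write_json({"pca": pca.to_dict()}, vdir / "pca.json", h)
    _write_json(
        {"clusters": [s.to_dict() for s in summaries],
         "noise_fraction": float(np.mean(labels == -1))},
        vdir / "clusters.json",
        h,
    )


def stage_crowd(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    spec = config.variants[variant]
    ring = read_frames(vdir / "ring.pdb")
    ring_sel = [(900, f"C{i + 1}") for i in range(6)]
    side_sel = [(472, a) for a in ("CB", "CG", "CD1", "CD2")]
    fit_sel = [(i, f"CA{i - 1}") for i in range(1, 9)]
    df, summary = overlap_series(ring, ring_sel, side_sel, labels=("FMN", "L472"))
    reference = ring_reference_frame(
        spec.ring.separation, spec.ring.dihedral_mean_deg
    )
    rmsd = compute_ring_rmsd(ring, fit_sel, ring_sel, reference)
    chi = compute_dihedral(ring, [(472, "CB"), (472, "CG"), (472, "CD1"), (472, "CD2")])
    out = df.copy()
    out["ring_rmsd"] = rmsd
    out["chi_deg"] = chi
    _write_csv(out, vdir / "crowding.csv", h)
    summary["mean_ring_rmsd"] = float(rmsd.mean())
    summary["sd_ring_rmsd"] = float(rmsd.std(ddof=0))
    _write_json({"overlap_summary": summary}, vdir / "crowding_summary.json", h)
    logger.info("[%s] crowding: mean normalized overlap %.4f, mean ring RMSD %.3f A",
                variant, summary["mean_normalized"], summary["mean_ring_rmsd"])


def _load_records(vdir: Path) -> list[ElectronicRecord]:
    df = _read_csv(vdir / "records.csv", index_col=None)
    return [
        ElectronicRecord(
            snapshot=int(r.snapshot),
            cluster=str(r.cluster),
            exc_ev=float(r.exc_eV),
            emi_ev=None if pd.isna(r.emi_eV) else float(r.emi_eV),
            dipole=np.array([r.mux, r.muy, r.muz]),
        )
        for r in df.itertuples()
    ]


def _cluster_populations(vdir: Path) -> dict[str, float]:
    truth = _read_json(vdir / "truth.json")
    return {str(k): float(v) for k, v in truth["empirical_populations"].items()}


def stage_spectra(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    spec = config.variants[variant]
    sd = SpectralDensity([VibronicMode(w, s) for w, s in spec.mode_set])
    line = cumulant_lineshape(sd, config.temperature_K, config.broadening_cm1)
    records = _load_records(vdir)
    pops = _cluster_populations(vdir)
    by_cluster: dict[str, list[ElectronicRecord]] = {}
    for r in records:
        by_cluster.setdefault(r.cluster, []).append(r)
    # one common absolute grid for all clusters of this variant
    centers = [r.exc_ev * 8065.544 for r in records]
    step = float(np.min(np.diff(line.grid_cm1)))
    grid = np.arange(
        min(centers) + line.grid_cm1[0], max(centers) + line.grid_cm1[-1] + step, step
    )
    cluster_spectra = {
        name: ensemble_spectrum(recs, line, grid) for name, recs in by_cluster.items()
    }
    avg = weighted_average_spectra(cluster_spectra, pops)
    for name, s in cluster_spectra.items():
        shifted = normalize_and_shift(s, config.shift_cm1)
        _write_spectrum(shifted.grid_cm1, shifted.intensity, vdir / f"spectrum_{name}.dat", h)
    avg_shifted = normalize_and_shift(avg, config.shift_cm1)
    _write_spectrum(avg_shifted.grid_cm1, avg_shifted.intensity, vdir / "spectrum_AVG.dat", h)
    _write_json(
        {
            "reorganization_energy_cm1": sd.reorganization_energy_cm1,
            "temperature_K": config.temperature_K,
            "broadening_cm1": config.broadening_cm1,
            "rigid_shift_cm1": config.shift_cm1,
            "avg_peak_position_cm1": float(
                avg_shifted.grid_cm1[int(np.argmax(avg_shifted.intensity))]
            ),
        },
        vdir / "spectra_meta.json",
        h,
    )
    logger.info("[%s] spectra: %d cluster spectra + AVG", variant, len(cluster_spectra))


def stage_stokes(config: PipelineConfig, variant: str, vdir: Path) -> None:
    h = config.hash()
    records = _load_records(vdir)
    pops = _cluster_populations(vdir)
    table = stokes_table(records, pops)
    _write_csv(table.rounded(), vdir / "stokes.csv", h, index=False)
    _write_json(
        {
            "rows": table.rows.to_dict(orient="records"),
            "weighted": table.weighted.to_dict(),
        },
        vdir / "stokes.json",
        h,
    )
    logger.info("[%s] stokes: weighted SS %.1f cm^-1", variant, table.weighted["ss_cm1"])


def stage_report(config: PipelineConfig, out_dir: Path) -> dict:
    h = config.hash()
    per_variant: dict[str, dict] = {}
    for variant in config.variants:
        vdir = out_dir / variant
        states = _read_csv(vdir / "states.csv")
        fc = states["frame_class"].value_counts(normalize=True).to_dict()
        clusters = _read_json(vdir / "clusters.json")
        crowd = _read_json(vdir / "crowding_summary.json")["overlap_summary"]
        stokes = _read_json(vdir / "stokes.json")
        spectra = _read_json(vdir / "spectra_meta.json")
        per_variant[variant] = {
            "in_out_populations": {k: float(v) for k, v in fc.items()},
            "clusters": clusters["clusters"],
            "noise_fraction": clusters["noise_fraction"],
            "overlap_summary": crowd,
            "stokes": stokes,
            "spectra": spectra,
        }
    report: dict = {"variants": per_variant}
    names = list(config.variants)
    if len(names) == 2:
        a, b = names
        va, vb = per_variant[a], per_variant[b]
        report["deltas"] = {
            "variant_order": [a, b],
            "mean_overlap_difference": va["overlap_summary"]["mean_normalized"]
            - vb["overlap_summary"]["mean_normalized"],
            "mean_ring_rmsd_difference": va["overlap_summary"]["mean_ring_rmsd"]
            - vb["overlap_summary"]["mean_ring_rmsd"],
            "weighted_ss_difference_cm1": va["stokes"]["weighted"]["ss_cm1"]
            - vb["stokes"]["weighted"]["ss_cm1"],
            "avg_peak_shift_cm1": va["spectra"]["avg_peak_position_cm1"]
            - vb["spectra"]["avg_peak_position_cm1"],
        }
    _write_json(report, out_dir / "report.json", h)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "distances": stage_distances,
    "states": stage_states,
    "cluster": stage_cluster,
    "crowd": stage_crowd,
    "spectra": stage_spectra,
    "stokes": stage_stokes,
}


def run_stage(config: PipelineConfig, stage: str) -> dict | None:
    """Run one named stage for every variant (``report`` runs once)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage == "report":
        return stage_report(config, out_dir)
    if stage not in _STAGE_FUNCS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    for variant in config.variants:
        vdir = out_dir / variant
        vdir.mkdir(parents=True, exist_ok=True)
        try:
            _STAGE_FUNCS[stage](config, variant, vdir)
        except LovspecError as exc:
            raise LovspecError(f"stage {stage!r}, variant {variant!r}: {exc}") from exc
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for all variants and return the comparison report."""
    for stage in STAGES[:-1]:
        run_stage(config, stage)
    return run_stage(config, "report")
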