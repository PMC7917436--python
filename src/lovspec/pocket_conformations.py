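"""Pocket-conformation classification, PCA reduction, and density clustering.

The workflow mirrors the standard H-bond-network analysis of a flavin binding
pocket: each tracked side chain is *in* when its heavy-atom H-bond distance is
below 4 A and *out* above 5 A (the 4-5 A gap is an unclassified intermediate
regime).  A frame is IN when every tracked residue is in, OUT when at least
one is out.  The labeled distance features are reduced by PCA (unstandardized
— all features share angstrom units) and clustered density-wise with HDBSCAN;
clusters below a population floor (default 1%) are discarded as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_IN_MAX, DEFAULT_OUT_MIN
from .errors import DefinitionError, DegenerateInputError, LovspecError, UsageError

__all__ = [
    "StateSeries",
    "PCAModel",
    "ClusterSummary",
    "classify_states",
    "fit_pca",
    "cluster_density",
    "label_clusters",
    "sample_representatives",
]

NOISE = -1


@dataclass
class StateSeries:
    """Per-residue in/out/intermediate states plus the per-frame IN/OUT class."""

    states: pd.DataFrame      # frames x residues, values in {'in','out','intermediate'}
    frame_class: pd.Series    # values in {'IN','OUT','unassigned'}
    in_max: float
    out_min: float


def classify_states(
    table: pd.DataFrame,
    residue_to_distance: Mapping[str, str],
    in_max: float = DEFAULT_IN_MAX,
    out_min: float = DEFAULT_OUT_MIN,
) -> StateSeries:
    """Classify tracked side chains as in/out from their H-bond distances.

    A residue is *in* below ``in_max`` (4 A), *out* above ``out_min`` (5 A),
    *intermediate* in the gap.  Frame class: OUT if any residue is out, IN if
    all are in, otherwise unassigned (an intermediate with no out residue).
    """
    if in_max >= out_min:
        raise UsageError("in_max must be below out_min")
    missing = [c for c in residue_to_distance.values() if c not in table.columns]
    if missing:
        raise DefinitionError(f"unknown distance columns: {missing}")
    states = {}
    for res, col in residue_to_distance.items():
        d = table[col].to_numpy(dtype=float)
        s = np.full(len(d), "intermediate", dtype=object)
        s[d < in_max] = "in"
        s[d > out_min] = "out"
        states[res] = s
    df = pd.DataFrame(states, index=table.index)
    any_out = (df == "out").any(axis=1)
    all_in = (df == "in").all(axis=1)
    frame_class = pd.Series("unassigned", index=table.index, dtype=object)
    frame_class[all_in] = "IN"
    frame_class[any_out] = "OUT"
    return StateSeries(df, frame_class, in_max, out_min)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted principal components of the distance features."""

    feature_labels: list[str]
    mean: np.ndarray
    components: np.ndarray          # (n_retained, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_labels].to_numpy(dtype=float)
        return (x - self.mean) @ self.components.T

    def inverse_transform(self, projected: np.ndarray) -> np.ndarray:
        return projected @ self.components + self.mean

    def to_dict(self) -> dict:
        return {
            "feature_labels": self.feature_labels,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
        }


def fit_pca(
    table: pd.DataFrame,
    feature_labels: Sequence[str],
    variance_target: float = 0.9,
) -> PCAModel:
    """Mean-centered PCA on raw (unstandardized) distance features.

    Retains the smallest number of components whose cumulative explained
    variance reaches ``variance_target``.
    """
    from sklearn.decomposition import PCA

    if not 0 < variance_target <= 1:
        raise UsageError("variance_target must be in (0, 1]")
    missing = [f for f in feature_labels if f not in table.columns]
    if missing:
        raise DefinitionError(f"features not in table: {missing}")
    x = table[list(feature_labels)].to_numpy(dtype=float)
    if len(x) < 2:
        raise UsageError("PCA needs at least 2 frames")
    if np.allclose(x.var(axis=0), 0.0):
        raise DegenerateInputError("all requested features have zero variance")
    pca = PCA(n_components=min(x.shape)).fit(x)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_target - 1e-12) + 1)
    k = min(k, len(evr))
    return PCAModel(
        feature_labels=list(feature_labels),
        mean=pca.mean_,
        components=pca.components_[:k],
        explained_variance_ratio=evr[:k],
        n_components=k,
    )


# ---------------------------------------------------------------------------
# density clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    """One retained pocket-conformation cluster."""

    cluster_id: int
    population: float
    median_features: dict[str, float] = field(default_factory=dict)
    label: str = "unassigned"          # 'IN' / 'OUT' / 'unassigned'
    representatives: list[int] = field(default_factory=list)
    n_frames: int = 0

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "population": self.population,
            "median_features": self.median_features,
            "label": self.label,
            "representatives": list(map(int, self.representatives)),
            "n_frames": self.n_frames,
        }


def cluster_density(
    projected: np.ndarray,
    min_cluster_size: int,
    min_population: float = 0.01,
    features: pd.DataFrame | None = None,
    min_samples: int | None = None,
) -> tuple[np.ndarray, list[ClusterSummary]]:
    """HDBSCAN clustering of the PCA-projected frames, with a population floor.

    Returns per-frame cluster ids (noise = -1) and summaries.  Clusters whose
    population (over all frames) is below ``min_population`` are relabeled
    noise.  Retained clusters are re-indexed by decreasing population, so
    cluster 0 is always the dominant pocket conformation.

    ``min_samples`` controls the density smoothing independently of the
    minimum cluster size (it defaults to ``min_cluster_size``); raising it
    suppresses spurious splits of large dense clusters in low-dimensional
    projections, at the cost of losing clusters smaller than itself.
    """
    projected = np.atleast_2d(np.asarray(projected, dtype=float))
    if projected.ndim == 2 and projected.shape[0] == 1 and projected.shape[1] > 1:
        pass
    if projected.ndim == 1:
        projected = projected[:, None]
    n = projected.shape[0]
    if min_cluster_size < 2:
        raise UsageError("min_cluster_size must be >= 2")
    if n < min_cluster_size:
        raise UsageError(f"need at least min_cluster_size={min_cluster_size} points")

    if np.allclose(projected, projected[0]):
        # degenerate cloud: density clustering is undefined, but all points
        # trivially form one conformation
        labels = np.zeros(n, dtype=int)
    else:
        from sklearn.cluster import HDBSCAN

        labels = HDBSCAN(
            min_cluster_size=int(min_cluster_size),
            min_samples=None if min_samples is None else int(min_samples),
            copy=True,
        ).fit(projected).labels_.astype(int)

    # population floor
    for cid in [c for c in np.unique(labels) if c != NOISE]:
        if np.sum(labels == cid) / n < min_population:
            labels[labels == cid] = NOISE

    # re-index by decreasing population
    kept = [c for c in np.unique(labels) if c != NOISE]
    kept.sort(key=lambda c: (-np.sum(labels == c), c))
    remap = {old: new for new, old in enumerate(kept)}
    new_labels = np.full(n, NOISE, dtype=int)
    for old, new in remap.items():
        new_labels[labels == old] = new

    summaries = []
    for cid in range(len(kept)):
        mask = new_labels == cid
        med = {}
        if features is not None:
            med = {
                col: float(features.loc[features.index[mask], col].median())
                for col in features.columns
            }
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                population=float(mask.sum() / n),
                median_features=med,
                n_frames=int(mask.sum()),
            )
        )
    return new_labels, summaries


def label_clusters(
    summaries: Sequence[ClusterSummary],
    assignment: np.ndarray,
    states: StateSeries,
) -> list[ClusterSummary]:
    """Attach IN/OUT labels to clusters by majority frame class.

    A cluster is IN (OUT) when more than half of its frames carry class IN
    (OUT); anything else — including an exact tie — stays unassigned.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(states.frame_class):
        raise UsageError("cluster assignment and states cover different frames")
    fc = states.frame_class.to_numpy()
    out = []
    for s in summaries:
        mask = assignment == s.cluster_id
        if not mask.any():
            raise LovspecError(f"cluster {s.cluster_id} has no frames")
        n = mask.sum()
        n_in = int(np.sum(fc[mask] == "IN"))
        n_out = int(np.sum(fc[mask] == "OUT"))
        label = "IN" if n_in * 2 > n else ("OUT" if n_out * 2 > n else "unassigned")
        out.append(
            ClusterSummary(
                cluster_id=s.cluster_id,
                population=s.population,
                median_features=dict(s.median_features),
                label=label,
                representatives=list(s.representatives),
                n_frames=s.n_frames,
            )
        )
    return out


def sample_representatives(
    summaries: Sequence[ClusterSummary],
    assignment: np.ndarray,
    n_per_cluster: int = 10,
    seed: int = 0,
) -> list[ClusterSummary]:
    """Uniform random frame sample (without replacement) per retained cluster.

    Clusters smaller than ``n_per_cluster`` contribute all their frames.
    Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    assignment = np.asarray(assignment)
    out = []
    for s in summaries:
        frames = np.flatnonzero(assignment == s.cluster_id)
        k = min(n_per_cluster, len(frames))
        reps = sorted(int(i) for i in rng.choice(frames, size=k, replace=False))
        out.append(
            ClusterSummary(
                cluster_id=s.cluster_id,
                population=s.population,
                median_features=dict(s.median_features),
                label=s.label,
                representatives=reps,
                n_frames=s.n_frames,
            )
        )
    return out
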