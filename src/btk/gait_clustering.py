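"""Gait-cycle partitioning, DTW similarity, embedding and clustering.

A gait cycle is delimited by two consecutive swing onsets of a reference
leg, ending before the second swing starts.  Within each cycle the
anterior-posterior position of every analyzed leg is min-max normalized to
[0, 1] and resampled to 15 timepoints.  Pairwise similarity between cycles
is dependent multivariate dynamic time warping over the chosen legs (all
four pairs, or the three anterior pairs in a reduced analysis); the
distance matrix is embedded into two dimensions with UMAP (precomputed
metric), clustered by agglomerative clustering on the embedding, and
summarized by a silhouette score, per-cluster barycenters (DTW barycenter
averaging plus the pointwise mean), per-cluster kinematics (one-way ANOVA
with Tukey pairwise comparisons over per-animal means), and a seed-to-seed
stability score (optimal-assignment label agreement between embeddings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from ._dtw import dba_barycenter, dtw_distance, dtw_path
from .errors import DegenerateGeometryError, InputError, ModelError, ParameterError

__all__ = [
    "GaitCycleSet",
    "ClusterResult",
    "segment_cycles",
    "dtw_distance_matrix",
    "embed_and_cluster",
    "cluster_stability",
    "label_agreement",
    "cluster_barycenters",
    "cluster_kinematics",
    "N_CYCLE_POINTS",
]

N_CYCLE_POINTS = 15


@dataclass
class GaitCycleSet:
    """Normalized per-cycle leg trajectories.

    ``cycles[i]`` has shape (n_channels, 15) — one row per analyzed leg,
    min-max normalized anterior-posterior position.  ``spans`` holds the
    source ``[start, stop)`` frames.
    """

    cycles: list[np.ndarray]
    channels: tuple[str, ...]
    spans: list[tuple[int, int]]
    reference_leg: str
    animal_id: object = None
    speed: np.ndarray | None = None  # per-cycle mean speed, µm/s
    angle: np.ndarray | None = None  # per-cycle mean heading change, deg
    degenerate: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def as_array(self) -> np.ndarray:
        return np.stack(self.cycles)


@dataclass
class ClusterResult:
    """Embedding, labels and quality metrics of one clustering run."""

    distance_matrix: np.ndarray
    embedding: np.ndarray  # (n_cycles, 2)
    labels: np.ndarray
    n_clusters: int
    silhouette: float
    seed: int


def _resample(series: np.ndarray, n_points: int = N_CYCLE_POINTS) -> np.ndarray:
    x_old = np.linspace(0.0, 1.0, len(series))
    return np.interp(np.linspace(0.0, 1.0, n_points), x_old, series)


def segment_cycles(
    ap_series: dict[str, np.ndarray],
    reference_onsets: list[int],
    channels: list[str],
    reference_leg: str,
    speed: np.ndarray | None = None,
    angle: np.ndarray | None = None,
    animal_id: object = None,
) -> GaitCycleSet:
    """Partition leg series into gait cycles between reference swing onsets.

    Each cycle covers ``[onset_i, onset_{i+1})`` of the reference leg; every
    channel is min-max normalized within the cycle and resampled to 15
    timepoints.  A channel constant within a cycle normalizes to zeros and
    the cycle is flagged degenerate.  Fewer than two onsets give an empty
    set.  Optional per-frame ``speed``/``angle`` series are averaged per
    cycle.
    """
    onsets = sorted(int(o) for o in reference_onsets)
    cycles, spans, degen = [], [], []
    sp_means, an_means = [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a < 2:
            continue
        mat = np.empty((len(channels), N_CYCLE_POINTS))
        is_degen = False
        for k, ch in enumerate(channels):
            seg = np.asarray(ap_series[ch][a:b], dtype=float)
            lo, hi = np.min(seg), np.max(seg)
            if hi - lo <= 0:
                mat[k] = 0.0
                is_degen = True
            else:
                mat[k] = _resample((seg - lo) / (hi - lo))
        cycles.append(mat)
        spans.append((a, b))
        degen.append(is_degen)
        if speed is not None:
            sp_means.append(float(np.nanmean(np.asarray(speed)[a:b])))
        if angle is not None:
            an_means.append(float(np.nanmean(np.asarray(angle)[a:b])))
    return GaitCycleSet(
        cycles=cycles,
        channels=tuple(channels),
        spans=spans,
        reference_leg=reference_leg,
        animal_id=animal_id,
        speed=np.array(sp_means) if speed is not None else None,
        angle=np.array(an_means) if angle is not None else None,
        degenerate=degen,
    )


def dtw_distance_matrix(cycles: GaitCycleSet | list[np.ndarray]) -> np.ndarray:
    """Pairwise dependent multivariate DTW distances between cycles.

    Cycles are (n_channels, n_timepoints) matrices sharing one warping path
    across channels.  The matrix is symmetric with a zero diagonal.
    """
    mats = cycles.cycles if isinstance(cycles, GaitCycleSet) else list(cycles)
    if len(mats) < 2:
        raise InputError("need at least 2 cycles")
    dims = {np.asarray(m).shape[0] for m in mats}
    if len(dims) > 1:
        raise InputError(f"cycles have mismatched channel counts: {sorted(dims)}")
    seqs = [np.asarray(m, dtype=float).T for m in mats]  # (time, dims)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(seqs[i], seqs[j])
    return d


def embed_and_cluster(
    distance_matrix: np.ndarray,
    n_clusters: int = 4,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> ClusterResult:
    """UMAP embedding of precomputed distances + agglomerative clustering.

    The 2-D embedding is built from the DTW distance matrix (precomputed
    metric), clustered with Ward agglomerative clustering on the embedding
    coordinates, and scored by the silhouette on those coordinates.
    Deterministic for a given seed.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise InputError("distance matrix must be square")
    if n_clusters < 2:
        raise ParameterError("n_clusters must be at least 2")
    if n_clusters >= n:
        raise ParameterError(f"n_clusters={n_clusters} must be < n_cycles={n}")
    if np.all(d == 0):
        raise DegenerateGeometryError("all pairwise distances are zero")

    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        emb = reducer.fit_transform(d)
    labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(emb)
    sil = float(silhouette_score(emb, labels)) if len(np.unique(labels)) > 1 else float("nan")
    return ClusterResult(
        distance_matrix=d,
        embedding=np.asarray(emb, dtype=float),
        labels=labels,
        n_clusters=n_clusters,
        silhouette=sil,
        seed=seed,
    )


def label_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Optimal one-to-one label matching agreement (matched fraction).

    Builds the contingency table between the two labelings and finds the
    cluster-to-cluster assignment maximizing overlap (Hungarian algorithm);
    agreement is the fraction of samples whose labels fall on the matched
    pairs.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise InputError("label vectors differ in length")
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((len(ua), len(ub)))
    for i, la in enumerate(ua):
        for j, lb in enumerate(ub):
            cont[i, j] = np.sum((a == la) & (b == lb))
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(a))


def cluster_stability(
    distance_matrix: np.ndarray,
    n_clusters: int,
    seeds: list[int],
    **embed_kw,
) -> float:
    """Mean pairwise label agreement across embedding seeds."""
    if len(seeds) < 2:
        raise ParameterError("need at least 2 seeds")
    labelings = [
        embed_and_cluster(distance_matrix, n_clusters, seed=s, **embed_kw).labels for s in seeds
    ]
    scores = [
        label_agreement(labelings[i], labelings[j])
        for i in range(len(labelings))
        for j in range(i + 1, len(labelings))
    ]
    return float(np.mean(scores))


def cluster_barycenters(
    cycles: GaitCycleSet | list[np.ndarray], labels: np.ndarray
) -> dict[int, dict[str, np.ndarray]]:
    """Representative sequence per cluster: DBA barycenter and pointwise mean.

    The DBA barycenter is initialized at the pointwise mean and the best
    iterate is kept, so its summed DTW distance to the members never
    exceeds the pointwise mean's.
    """
    mats = cycles.cycles if isinstance(cycles, GaitCycleSet) else list(cycles)
    labels = np.asarray(labels)
    out: dict[int, dict[str, np.ndarray]] = {}
    for lab in np.unique(labels):
        members = [np.asarray(mats[i], dtype=float).T for i in np.flatnonzero(labels == lab)]
        if not members:
            raise InputError(f"cluster {lab} is empty")
        mean = np.mean(members, axis=0)
        bary = dba_barycenter(members, init=mean)
        out[int(lab)] = {"barycenter": bary.T, "mean": mean.T}
    return out


def cluster_kinematics(
    labels: np.ndarray,
    speed: np.ndarray,
    angle: np.ndarray,
    animal_id: np.ndarray,
):
    """Per-cluster kinematic distributions with ANOVA + Tukey comparisons.

    Aggregates per-cycle speed and heading-change angle into per-animal
    per-cluster means, then runs a one-way ANOVA over clusters and Tukey's
    multiple-comparison test, separately for speed and angle.  Clusters
    represented by a single (animal, cluster) observation are excluded with
    a warning.  Returns a dict with the per-animal table and, per measure,
    ``(F, p, tukey_summary)``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.asarray(labels)
    speed = np.asarray(speed, dtype=float)
    angle = np.asarray(angle, dtype=float)
    animal_id = np.asarray(animal_id)

    rows = []
    for lab in np.unique(labels):
        for an in np.unique(animal_id):
            sel = (labels == lab) & (animal_id == an)
            if sel.any():
                rows.append((int(lab), an, float(np.nanmean(speed[sel])), float(np.nanmean(angle[sel]))))
    labs = np.array([r[0] for r in rows])
    keep_labels = [l for l in np.unique(labs) if np.sum(labs == l) >= 2]
    dropped = set(np.unique(labs)) - set(keep_labels)
    if dropped:
        warnings.warn(f"excluding single-observation cluster(s) {sorted(dropped)}", stacklevel=2)
    rows = [r for r in rows if r[0] in keep_labels]
    if len(keep_labels) < 2:
        raise ModelError("need at least two clusters with two or more animals each")
    labs = np.array([r[0] for r in rows])
    result: dict[str, object] = {"table": rows}
    for name, col in (("speed", 2), ("angle", 3)):
        vals = np.array([r[col] for r in rows])
        groups = [vals[labs == l] for l in keep_labels]
        f, p = stats.f_oneway(*groups)
        tukey = pairwise_tukeyhsd(vals, labs)
        result[name] = (float(f), float(p), tukey)
    return result
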