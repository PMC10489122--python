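"""Growing hierarchical self-organizing map over regional morphology profiles.

Each cortical region is summarised as a short profile vector (z-scored
area, thickness, curvature, folding index).  A self-organizing map
(SOM) places prototype vectors on a small rectangular grid; the growing
variant starts from a 2x2 grid and

* grows in breadth — inserting a row or column of interpolated nodes
  between the worst-quantising node and its most dissimilar grid
  neighbour — until the map's mean quantization error (MQE) falls below
  ``tau1`` times the parent's quantization error, and
* grows in depth — expanding any node whose quantization error still
  exceeds ``tau2`` times the root error into a child map trained on the
  profiles mapped to that node.

Only the top-layer map defines clusters: its non-empty nodes are the
cluster centroids, regions are assigned to the nearest centroid
(Euclidean distance, ties to the lowest cluster index), and per
participant the intra-cluster distance to a cluster is the mean
Euclidean distance of their z-scored region vectors (for that cluster's
regions) from the centroid.  Deeper maps are retained for inspection
but play no role in the statistics.

Training is batch SOM with a Gaussian neighbourhood shrinking linearly
over the epochs, finished by neighbourhood-free (Lloyd) iterations until
assignments stabilise, which makes every fit deterministic given the
random state used for initialisation.  Because inserted nodes extend the
prototype set without moving existing ones, the converged MQE can only
decrease across accepted growth steps; a growth step that fails to
decrease it is rejected and growth stops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import CORTICAL_METRICS, cortical_region_names


# ---------------------------------------------------------------------------
# profile construction

@dataclass
class RegionProfiles:
    """Z-scored morphology profiles for clustering.

    ``profiles`` holds the cohort-level region profiles (one row per
    region) used to train the map; ``participant_tensor`` holds each
    participant's z-scored region vectors (n_participants x n_regions x
    n_metrics) in the same space, for distance computation; ``constants``
    records the z-scoring mean/sd actually applied.
    """

    profiles: pd.DataFrame
    participant_tensor: np.ndarray
    metrics: tuple[str, ...]
    constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def region_names(self) -> list[str]:
        return list(self.profiles.index)


def zscore_profiles(
    features: pd.DataFrame,
    metrics: tuple[str, ...] = CORTICAL_METRICS,
    axis_policy: str = "pooled_per_metric",
) -> RegionProfiles:
    """Build z-scored region profiles from a feature matrix.

    ``axis_policy`` controls the normalisation constants:

    * ``pooled_per_metric`` (default): one mean/sd per metric, pooled
      over all participants and all 68 regions.  Regional differences
      survive, so the cohort-mean profiles carry the morphological
      archetype structure the map is meant to find.
    * ``per_feature``: mean/sd per (region, metric) across participants.
      Every cohort-mean profile is then exactly zero, so the profiles
      express each participant's *deviation* from the cohort; useful for
      distance analyses, not for training the map.

    Zero-variance input raises, naming the offending metric or feature.
    """
    regions = cortical_region_names()
    n = len(features)
    tensor = np.empty((n, len(regions), len(metrics)))
    constants: dict[str, tuple[float, float]] = {}

    for mi, metric in enumerate(metrics):
        cols = [f"{r}_{metric}" for r in regions]
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix lacks column(s) {missing[:3]} for metric {metric!r}")
        vals = features[cols].to_numpy(dtype=float)
        if axis_policy == "pooled_per_metric":
            mu = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if sd == 0:
                raise ValueError(f"metric {metric!r} has zero variance; cannot z-score")
            tensor[:, :, mi] = (vals - mu) / sd
            constants[metric] = (mu, sd)
        elif axis_policy == "per_feature":
            mu = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1) if n > 1 else np.zeros(vals.shape[1])
            bad = np.flatnonzero(sd == 0)
            if len(bad):
                raise ValueError(f"zero-variance feature {cols[bad[0]]!r}; cannot z-score")
            tensor[:, :, mi] = (vals - mu) / sd
        else:
            raise ValueError(f"unknown axis_policy {axis_policy!r}")

    profiles = pd.DataFrame(tensor.mean(axis=0), index=regions, columns=list(metrics))
    return RegionProfiles(
        profiles=profiles, participant_tensor=tensor, metrics=tuple(metrics), constants=constants
    )


# ---------------------------------------------------------------------------
# SOM machinery

def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _bmu(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _node_qe(X: np.ndarray, W: np.ndarray, bmu: np.ndarray) -> np.ndarray:
    """Mean Euclidean distance of each node's mapped points; NaN if empty."""
    qe = np.full(W.shape[0], np.nan)
    dist = np.linalg.norm(X - W[bmu], axis=1)
    for node in range(W.shape[0]):
        mask = bmu == node
        if mask.any():
            qe[node] = dist[mask].mean()
    return qe


def _mqe(X: np.ndarray, W: np.ndarray) -> float:
    """Map MQE: mean quantization error over non-empty nodes."""
    bmu = _bmu(X, W)
    qe = _node_qe(X, W, bmu)
    return float(np.nanmean(qe))


def _train_batch(
    X: np.ndarray,
    W: np.ndarray,
    shape: tuple[int, int],
    epochs: int,
    sigma0: float | None = None,
) -> np.ndarray:
    """Batch SOM epochs with shrinking Gaussian neighbourhood, then Lloyd."""
    coords = _grid_coords(*shape)
    if sigma0 is None:
        sigma0 = max(shape) / 2.0
    W = W.copy()
    for epoch in range(epochs):
        sigma = max(sigma0 * (1.0 - epoch / max(epochs, 1)), 0.3)
        bmu = _bmu(X, W)
        g2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        H = np.exp(-g2 / (2.0 * sigma**2))  # node x node neighbourhood
        influence = H[bmu]  # sample x node
        denom = influence.sum(axis=0)
        numer = influence.T @ X
        nonzero = denom > 1e-12
        W[nonzero] = numer[nonzero] / denom[nonzero, None]
    # neighbourhood-free refinement until the partition stabilises;
    # empty nodes are reseeded at the worst-quantised point so prototypes
    # collapsed during the neighbourhood phase can recover
    prev = None
    for _ in range(100):
        bmu = _bmu(X, W)
        empty = np.setdiff1d(np.arange(W.shape[0]), np.unique(bmu))
        for node in empty:
            dist = np.linalg.norm(X - W[bmu], axis=1)
            far = int(dist.argmax())
            if dist[far] == 0.0:
                break
            W[node] = X[far]
            bmu = _bmu(X, W)
        if prev is not None and np.array_equal(bmu, prev):
            break
        prev = bmu
        for node in range(W.shape[0]):
            mask = bmu == node
            if mask.any():
                W[node] = X[mask].mean(axis=0)
    return W


def _insert(W: np.ndarray, shape: tuple[int, int], err: int, diss: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Insert an interpolated row/column between the error node and neighbour."""
    rows, cols = shape
    grid = W.reshape(rows, cols, -1)
    er, ec = divmod(err, cols)
    dr, dc = divmod(diss, cols)
    if er != dr:  # vertical neighbours -> insert a row between them
        lo = min(er, dr)
        new_row = (grid[lo] + grid[lo + 1]) / 2.0
        grid = np.insert(grid, lo + 1, new_row, axis=0)
        return grid.reshape(-1, W.shape[1]), (rows + 1, cols)
    lo = min(ec, dc)
    new_col = (grid[:, lo] + grid[:, lo + 1]) / 2.0
    grid = np.insert(grid, lo + 1, new_col, axis=1)
    return grid.reshape(-1, W.shape[1]), (rows, cols + 1)


def _grow_map(
    X: np.ndarray,
    parent_qe: float,
    tau1: float,
    epochs: int,
    rng: np.random.Generator,
    max_nodes: int,
) -> tuple[np.ndarray, tuple[int, int], list[float]]:
    """Train a single map, growing in breadth until MQE < tau1 * parent_qe."""
    d = X.shape[1]
    shape = (2, 2)
    if X.shape[0] >= 4:
        W = X[rng.choice(X.shape[0], size=4, replace=False)].astype(float).copy()
        W = W + rng.normal(0.0, 1e-6, size=W.shape)  # break exact duplicates
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)
        W = rng.uniform(0.0, 1.0, size=(4, d)) * (hi - lo) + lo
    W = _train_batch(X, W, shape, epochs)
    history = [_mqe(X, W)]

    while history[-1] >= tau1 * parent_qe and W.shape[0] < max_nodes:
        bmu = _bmu(X, W)
        qe = _node_qe(X, W, bmu)
        if np.isnan(qe).all():
            break
        err = int(np.nanargmax(qe))
        neighbours = _grid_neighbours(err, shape)
        if not neighbours:
            break
        diss = max(neighbours, key=lambda nb: float(np.linalg.norm(W[err] - W[nb])))
        W_new, shape_new = _insert(W, shape, err, diss)
        W_new = _train_batch(X, W_new, shape_new, epochs)
        mqe_new = _mqe(X, W_new)
        if mqe_new >= history[-1]:
            break  # growth no longer reduces error; reject and stop
        W, shape = W_new, shape_new
        history.append(mqe_new)
    return W, shape, history


def _grid_neighbours(node: int, shape: tuple[int, int]) -> list[int]:
    rows, cols = shape
    r, c = divmod(node, cols)
    out = []
    if r > 0:
        out.append(node - cols)
    if r < rows - 1:
        out.append(node + cols)
    if c > 0:
        out.append(node - 1)
    if c < cols - 1:
        out.append(node + 1)
    return out


# ---------------------------------------------------------------------------
# the estimator

@dataclass
class _ChildMap:
    parent_node: int
    weights: np.ndarray
    shape: tuple[int, int]
    children: list["_ChildMap"]


class GHSOM:
    """Growing hierarchical SOM clusterer (scikit-learn style).

    Parameters
    ----------
    tau1 : float in (0, 1)
        Breadth threshold: a map grows until its mean quantization error
        drops below ``tau1`` times its parent node's error.
    tau2 : float in (0, 1)
        Depth threshold: nodes whose error exceeds ``tau2`` times the
        root error are expanded into child maps.
    epochs : int
        Batch-SOM epochs per growth stage (before Lloyd refinement).
    max_nodes : int
        Budget on one map's node count; growth past it stops with the
        current map.
    max_depth : int
        Hierarchy depth (1 = top layer only).
    random_state : int or None
        Seed for prototype initialisation; fits are deterministic given it.

    Attributes (after ``fit``)
    --------------------------
    centroids_ : (k, d) array — non-empty top-layer node weights
    labels_ : cluster index of each training profile (compacted, 0..k-1)
    mqe_history_ : converged MQE after each accepted growth step (non-increasing)
    root_qe_ : quantization error of the single layer-0 node
    """

    def __init__(
        self,
        tau1: float = 0.6,
        tau2: float = 0.1,
        epochs: int = 200,
        max_nodes: int = 64,
        max_depth: int = 2,
        random_state: int | None = None,
    ):
        self.tau1 = tau1
        self.tau2 = tau2
        self.epochs = epochs
        self.max_nodes = max_nodes
        self.max_depth = max_depth
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "tau1": self.tau1, "tau2": self.tau2, "epochs": self.epochs,
            "max_nodes": self.max_nodes, "max_depth": self.max_depth,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "GHSOM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None) -> "GHSOM":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            self.index_in_ = list(X.index)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = None
            self.index_in_ = None
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("need a 2-D array with at least one profile")
        if not (0 < self.tau1 <= 1 and 0 < self.tau2 < 1):
            raise ValueError("growth thresholds must lie in (0, 1]")
        if not np.isfinite(X).all():
            raise ValueError("profiles must be finite")

        rng = np.random.default_rng(self.random_state)
        root = X.mean(axis=0)
        self.root_qe_ = float(np.linalg.norm(X - root, axis=1).mean())

        if self.root_qe_ == 0.0:
            # all profiles identical: a single node quantises perfectly
            self.top_weights_ = root.reshape(1, -1)
            self.top_shape_ = (1, 1)
            self.mqe_history_ = [0.0]
        else:
            W, shape, history = _grow_map(
                X, self.root_qe_, self.tau1, self.epochs, rng, self.max_nodes
            )
            self.top_weights_ = W
            self.top_shape_ = shape
            self.mqe_history_ = history

        # prune empty nodes; compact cluster indices in node order
        bmu = _bmu(X, self.top_weights_)
        occupied = np.unique(bmu)
        self.centroids_ = self.top_weights_[occupied]
        relabel = {node: i for i, node in enumerate(occupied)}
        self.labels_ = np.array([relabel[b] for b in bmu])
        self.n_clusters_ = len(occupied)

        # depth expansion (inspection only; clusters come from the top layer)
        self.children_ = self._expand(X, bmu, self.top_weights_, self.top_shape_, rng, depth=1)
        return self

    def _expand(self, X, bmu, W, shape, rng, depth) -> list[_ChildMap]:
        if depth >= self.max_depth or self.root_qe_ == 0.0:
            return []
        children = []
        qe = _node_qe(X, W, bmu)
        for node in range(W.shape[0]):
            mask = bmu == node
            if mask.sum() < 4 or np.isnan(qe[node]) or qe[node] <= self.tau2 * self.root_qe_:
                continue
            sub = X[mask]
            Wc, shc, _ = _grow_map(sub, qe[node], self.tau1, self.epochs, rng, self.max_nodes)
            sub_bmu = _bmu(sub, Wc)
            grand = self._expand(sub, sub_bmu, Wc, shc, rng, depth + 1)
            children.append(_ChildMap(parent_node=node, weights=Wc, shape=shc, children=grand))
        return children

    # -- assignment -------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Nearest-centroid cluster index; ties go to the lowest index."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    """Region-to-cluster mapping with the centroids that induced it."""

    labels: pd.Series  # region -> cluster index
    centroids: pd.DataFrame  # cluster x metric
    distance_to_centroid: pd.Series  # region -> distance to own centroid

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.labels.index, "cluster": self.labels.to_numpy(),
             "distance_to_centroid": self.distance_to_centroid.to_numpy()}
        )


def assign_regions(model: GHSOM, profiles: RegionProfiles | pd.DataFrame) -> ClusterAssignment:
    """Assign every region to its nearest top-layer centroid."""
    frame = profiles.profiles if isinstance(profiles, RegionProfiles) else profiles
    labels = model.predict(frame)
    X = frame.to_numpy(dtype=float)
    dist = np.linalg.norm(X - model.centroids_[labels], axis=1)
    # drop clusters that received no region, compacting indices
    used = np.unique(labels)
    relabel = {c: i for i, c in enumerate(used)}
    labels = np.array([relabel[c] for c in labels])
    centroids = pd.DataFrame(model.centroids_[used], columns=frame.columns)
    centroids.index.name = "cluster"
    return ClusterAssignment(
        labels=pd.Series(labels, index=frame.index, name="cluster"),
        centroids=centroids,
        distance_to_centroid=pd.Series(dist, index=frame.index, name="distance"),
    )


def intra_cluster_distances(
    assignment: ClusterAssignment,
    profiles: RegionProfiles,
    participant_ids=None,
) -> pd.DataFrame:
    """Per-participant mean distance to each cluster's centroid.

    Entry (i, c) is the mean over regions r assigned to cluster c of the
    Euclidean distance between participant i's z-scored vector for r and
    the centroid of c.  Non-negative; zero only when every one of the
    participant's vectors in that cluster sits exactly on the centroid.
    """
    tensor = profiles.participant_tensor  # n x regions x metrics
    region_names = profiles.region_names
    unassigned = [r for r in region_names if r not in assignment.labels.index]
    if unassigned:
        raise ValueError(f"region(s) without cluster assignment: {unassigned[:3]}")
    n = tensor.shape[0]
    k = assignment.n_clusters
    out = np.empty((n, k))
    labels = assignment.labels.reindex(region_names).to_numpy()
    cents = assignment.centroids.to_numpy(dtype=float)
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        diffs = tensor[:, idx, :] - cents[c][None, None, :]
        out[:, c] = np.linalg.norm(diffs, axis=2).mean(axis=1)
    index = participant_ids if participant_ids is not None else pd.RangeIndex(n)
    return pd.DataFrame(out, index=index, columns=[f"cluster_{c}" for c in range(k)])
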