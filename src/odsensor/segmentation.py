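"""K-means pixel clustering in CIELAB and region-of-interest tracking.

The clustering minimises the within-cluster sum of squared Euclidean
distances

    J = sum_n sum_k  r_nk * || x_n - mu_k ||^2

over hard assignments ``r_nk`` and centres ``mu_k`` via Lloyd iterations
from k-means++ seeding.  The tracker segments every frame of every
timepoint independently, matches each frame's clustering to a running
reference centre by nearest Euclidean distance, and updates the reference
with the mean of the four matched centres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .colourspace import LabTriple

__all__ = [
    "ClusterModel",
    "ElbowCurve",
    "TrackState",
    "kmeans_cluster",
    "select_k_elbow",
    "segment_image",
    "match_cluster",
    "track_roi",
]

log = logging.getLogger(__name__)

MAX_ITER = 300


@dataclass
class ClusterModel:
    """Result of one k-means fit.

    ``inertia`` is the objective J; ``inertia_history`` records J after each
    Lloyd iteration of the winning restart and is non-increasing.
    """

    centres: np.ndarray          # (K, 3)
    labels: np.ndarray           # (N,) int
    inertia: float
    n_iter: int
    inertia_history: list[float]
    requested_k: int

    @property
    def k(self) -> int:
        return self.centres.shape[0]

    def centre(self, idx: int) -> LabTriple:
        c = self.centres[idx]
        return LabTriple(float(c[0]), float(c[1]), float(c[2]))

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ElbowCurve:
    """Per-K clustering criterion used by the elbow heuristic."""

    ks: list[int]
    inertia: list[float]            # J at each K (best of restarts)
    separation_ratio: list[float]   # mean between-centre / mean within-cluster distance
    chosen_k: int


@dataclass
class TrackState:
    """Bookkeeping of the region-of-interest tracker.

    ``c_tilde`` is the user-chosen initial centre, ``c_bar`` the running
    reference, ``stored`` the per-measurement centres in timepoint order.
    """

    c_tilde: LabTriple
    c_bar: LabTriple
    stored: list[LabTriple] = field(default_factory=list)
    matched_indices: list[list[int]] = field(default_factory=list)
    frame_models: list[list[ClusterModel]] | None = None


def _pairwise_sq(points: np.ndarray, centres: np.ndarray) -> np.ndarray:
    # (N, K) squared Euclidean distances without forming N*K*3 temporaries twice
    p2 = np.einsum("ij,ij->i", points, points)[:, None]
    c2 = np.einsum("ij,ij->i", centres, centres)[None, :]
    return np.maximum(p2 + c2 - 2.0 * points @ centres.T, 0.0)


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centres = np.empty((k, points.shape[1]))
    centres[0] = points[rng.integers(n)]
    d2 = np.einsum("ij,ij->i", points - centres[0], points - centres[0])
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass on already-chosen colours; pick uniformly
            centres[j] = points[rng.integers(n)]
            continue
        idx = rng.choice(n, p=d2 / total)
        centres[j] = points[idx]
        d2 = np.minimum(d2, np.einsum("ij,ij->i", points - centres[j], points - centres[j]))
    return centres


def _lloyd(
    points: np.ndarray, init_centres: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centres = init_centres.copy()
    k = centres.shape[0]
    labels = np.full(points.shape[0], -1, dtype=np.intp)
    history: list[float] = []
    for it in range(1, MAX_ITER + 1):
        d2 = _pairwise_sq(points, centres)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: re-seed at the point farthest from its centre
        counts = np.bincount(new_labels, minlength=k)
        for empty in np.flatnonzero(counts == 0):
            far = d2[np.arange(points.shape[0]), new_labels].argmax()
            log.debug("re-seeding empty cluster %d at point %d", empty, far)
            centres[empty] = points[far]
            d2[:, empty] = np.einsum(
                "ij,ij->i", points - centres[empty], points - centres[empty]
            )
            new_labels = d2.argmin(axis=1)
            counts = np.bincount(new_labels, minlength=k)
        j_val = float(d2[np.arange(points.shape[0]), new_labels].sum())
        if history and j_val > history[-1] + 1e-7 * max(1.0, history[-1]):
            raise AssertionError("k-means objective increased between iterations")
        history.append(j_val)
        if np.array_equal(new_labels, labels):
            return centres, labels, history[-1], it, history
        labels = new_labels
        for c in range(k):
            members = points[labels == c]
            if members.shape[0]:
                centres[c] = members.mean(axis=0)
    # iteration cap hit: recompute J for the last centre update
    d2 = _pairwise_sq(points, centres)
    labels = d2.argmin(axis=1)
    j_val = float(d2[np.arange(points.shape[0]), labels].sum())
    history.append(min(j_val, history[-1]))
    return centres, labels, history[-1], MAX_ITER, history


def kmeans_cluster(
    pixels: np.ndarray | Sequence[Sequence[float]],
    k: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
) -> ClusterModel:
    """Cluster Lab pixels into ``k`` groups, best objective over restarts.

    Deterministic for a given ``seed``.  If fewer distinct colours than
    ``k`` exist, the cluster count is reduced with a warning.
    """
    points = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    if points.shape[0] == 0:
        raise ValueError("cannot cluster an empty pixel list")
    if k < 1:
        raise ValueError(f"cluster count must be >= 1, got {k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    n_unique = np.unique(points, axis=0).shape[0]
    k_eff = min(k, n_unique)
    if k_eff < k:
        log.warning("only %d distinct colours; reducing K from %d", n_unique, k)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_restarts):
        init = _kmeanspp_init(points, k_eff, rng)
        centres, labels, inertia, n_iter, history = _lloyd(points, init, rng)
        if best is None or inertia < best[2]:
            best = (centres, labels, inertia, n_iter, history)
        if inertia == 0.0:
            break
    centres, labels, inertia, n_iter, history = best
    return ClusterModel(
        centres=centres,
        labels=labels,
        inertia=inertia,
        n_iter=n_iter,
        inertia_history=history,
        requested_k=k,
    )


def select_k_elbow(
    pixels: np.ndarray,
    k_max: int,
    threshold: float = 0.1,
    seed: int = 0,
    n_restarts: int = 3,
) -> tuple[int, ElbowCurve]:
    """Choose a cluster count by the elbow heuristic.

    Fits k-means for K = 1 .. ``k_max`` and returns the smallest K after
    which the relative improvement of the objective J stays below
    ``threshold``.  The full curve (J and the between/within separation
    ratio) is returned for inspection.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    points = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    n_unique = np.unique(points, axis=0).shape[0]
    if n_unique < k_max:
        log.warning("only %d distinct colours; lowering k_max from %d", n_unique, k_max)
        k_max = max(1, n_unique)

    rng = np.random.default_rng(seed)
    ks, inertias, ratios = [], [], []
    for k in range(1, k_max + 1):
        model = kmeans_cluster(points, k, seed=rng, n_restarts=n_restarts)
        ks.append(k)
        inertias.append(model.inertia)
        if k == 1:
            ratios.append(0.0)
        else:
            between = _pairwise_sq(model.centres, model.centres)
            mean_between = float(np.sqrt(between[np.triu_indices(k, 1)]).mean())
            within = np.sqrt(
                _pairwise_sq(points, model.centres)[np.arange(points.shape[0]), model.labels]
            ).mean()
            ratios.append(mean_between / max(float(within), 1e-12))

    chosen = ks[-1]
    for i in range(1, len(ks)):
        prev, cur = inertias[i - 1], inertias[i]
        rel = (prev - cur) / prev if prev > 0 else 0.0
        if rel < threshold:
            chosen = ks[i - 1]
            break
    curve = ElbowCurve(ks=ks, inertia=inertias, separation_ratio=ratios, chosen_k=chosen)
    return chosen, curve


def segment_image(
    img: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 5,
    subsample: int | None = None,
) -> ClusterModel:
    """Cluster all pixels of a Lab image.

    With ``subsample`` set, the centres are fitted on a seeded random
    subset for speed and every pixel is then assigned to its nearest
    fitted centre (labels always cover the full image).
    """
    lab = np.asarray(img, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 Lab image, got shape {lab.shape}")
    points = lab.reshape(-1, 3)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subsample is not None and subsample < points.shape[0]:
        idx = rng.choice(points.shape[0], size=subsample, replace=False)
        model = kmeans_cluster(points[idx], k, seed=rng, n_restarts=n_restarts)
        d2 = _pairwise_sq(points, model.centres)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(points.shape[0]), labels].sum())
        return ClusterModel(
            centres=model.centres,
            labels=labels,
            inertia=inertia,
            n_iter=model.n_iter,
            inertia_history=model.inertia_history,
            requested_k=k,
        )
    return kmeans_cluster(points, k, seed=rng, n_restarts=n_restarts)


def match_cluster(model: ClusterModel, reference: LabTriple | Sequence[float]) -> tuple[int, LabTriple]:
    """Index and centre of the cluster nearest (Euclidean) to ``reference``.

    Ties are broken in favour of the lowest cluster index.
    """
    ref = np.asarray(reference, dtype=np.float64)
    d2 = np.einsum("ij,ij->i", model.centres - ref, model.centres - ref)
    idx = int(d2.argmin())  # argmin returns the first minimum: lowest index wins
    return idx, model.centre(idx)


def track_roi(
    frames: Sequence[Sequence[np.ndarray]],
    k: int,
    initial_choice: int | LabTriple | Sequence[float],
    seed: int = 0,
    n_restarts: int = 5,
    subsample: int | None = None,
    keep_models: bool = False,
) -> TrackState:
    """Track the region of interest across a timepoint series of frames.

    ``frames`` is a per-timepoint sequence of (nominally four) Lab images.
    The first frame of the first timepoint is segmented and the cluster of
    interest chosen there — either by index or by a reference Lab colour
    (nearest centre) — giving the initial centre.  Then, for every
    timepoint including the first, each frame is segmented independently,
    its nearest cluster to the running reference is matched, and the
    reference is replaced by the mean of the matched centres, which is
    stored as that measurement's region colour.
    """
    if len(frames) == 0:
        raise ValueError("no timepoints supplied")
    for t, fl in enumerate(frames):
        if len(fl) == 0:
            raise ValueError(f"timepoint index {t} has an empty frame list")
        if len(fl) != 4:
            log.warning("timepoint index %d has %d frames (expected 4)", t, len(fl))

    def frame_seed(t: int, j: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((seed, t, j)))

    first_model = segment_image(
        frames[0][0], k, seed=frame_seed(0, 0), n_restarts=n_restarts, subsample=subsample
    )
    if isinstance(initial_choice, (int, np.integer)):
        if not 0 <= int(initial_choice) < first_model.k:
            raise ValueError(
                f"initial cluster index {initial_choice} out of range 0..{first_model.k - 1}"
            )
        c_tilde = first_model.centre(int(initial_choice))
    else:
        _, c_tilde = match_cluster(first_model, initial_choice)

    state = TrackState(c_tilde=c_tilde, c_bar=c_tilde)
    if keep_models:
        state.frame_models = []

    c_bar = np.asarray(c_tilde, dtype=np.float64)
    for t, frame_list in enumerate(frames):
        matched_centres = []
        matched_idx = []
        models = []
        for j, lab in enumerate(frame_list):
            if t == 0 and j == 0:
                model = first_model  # identical seed; avoids a redundant refit
            else:
                model = segment_image(
                    lab, k, seed=frame_seed(t, j), n_restarts=n_restarts, subsample=subsample
                )
            idx, centre = match_cluster(model, c_bar)
            matched_centres.append(centre.as_array())
            matched_idx.append(idx)
            if keep_models:
                models.append(model)
        c_bar = np.mean(matched_centres, axis=0)
        state.c_bar = LabTriple(*map(float, c_bar))
        state.stored.append(state.c_bar)
        state.matched_indices.append(matched_idx)
        if keep_models:
            state.frame_models.append(models)
    return state
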