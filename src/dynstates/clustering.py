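"""Recurring connectivity-state estimation by k-means with correlation distance.

All subjects' windowed connectivity vectors are pooled and clustered with
k-means under the correlation distance d(a, b) = 1 - Pearson(a, b), which is
sensitive to the connectivity *pattern* irrespective of magnitude. The
procedure is two-stage: many randomly initialized replicates keep the
partition with the lowest total within-cluster distance, then every window
is re-assigned to its nearest centroid and final centroids are reported as
the element-wise median of the assigned windows. The number of states is
chosen by an elbow criterion on a within/between cluster validity index.

States are relabeled in descending order of pooled occupancy so that
"state 1" is always the most visited state; ties break on the first window
index at which each state occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class StateModel:
    """Fitted connectivity-state model."""

    k: int
    centroids: np.ndarray  # k x P, element-wise median of assigned windows
    labels: np.ndarray  # pooled window labels in 1..k
    best_objective: float  # stage-1 total within-cluster correlation distance
    seed: int | None = None
    distance: str = "correlation"
    replicate_objectives: np.ndarray = field(default=None)

    def split_by_subject(self, window_counts) -> list[np.ndarray]:
        """Split the pooled label vector into per-subject state vectors."""
        bounds = np.cumsum([0] + list(window_counts))
        if bounds[-1] != self.labels.size:
            raise ValueError("window counts do not sum to the pooled size")
        return [self.labels[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class ElbowCurve:
    """Cluster validity index across candidate k, with the selected elbow."""

    k_values: np.ndarray
    cvi: np.ndarray
    selected_k: int


def correlation_distance(a, b) -> float:
    """d = 1 - Pearson(a, b); range [0, 2]. Constant vectors are rejected."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation distance undefined for constant vectors")
    ac = a - a.mean()
    bc = b - b.mean()
    r = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
    return float(1.0 - r)


def _row_normalize(X: np.ndarray) -> np.ndarray:
    """Center and scale rows so that 1 - U @ v gives correlation distance."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("constant window vectors cannot be clustered")
    return Xc / norms


def _distances_to_centroids(U: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # degenerate (constant) centroids can arise transiently; give them unit
    # distance to everything rather than an undefined correlation
    Cc = centroids - centroids.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cc, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    Cn = np.where(norms == 0, 0.0, Cc / safe)
    return 1.0 - U @ Cn.T


def _kmeans_once(X, U, k, rng, max_iter=100, tol=1e-7):
    """One Lloyd run under correlation distance from a random initialization.

    The working centroid during iterations is the arithmetic mean of member
    vectors (the standard dFNC practice); medians are only used for final
    reporting. Empty clusters are re-seeded at the farthest point.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    prev_obj = np.inf
    for _ in range(max_iter):
        D = _distances_to_centroids(U, centroids)
        labels = D.argmin(axis=1)
        mind = D[np.arange(n), labels]
        for j in range(k):
            if not (labels == j).any():
                far = mind.argmax()
                labels[far] = j
                mind[far] = 0.0
        obj = float(mind.sum())
        for j in range(k):
            member = X[labels == j]
            if member.size:
                centroids[j] = member.mean(axis=0)
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    D = _distances_to_centroids(U, centroids)
    labels = D.argmin(axis=1)
    obj = float(D[np.arange(n), labels].sum())
    return labels, centroids, obj


def _relabel_by_occupancy(labels: np.ndarray, k: int) -> np.ndarray:
    """Map raw cluster ids to 1..k in descending occupancy order."""
    counts = np.bincount(labels, minlength=k)
    first = np.full(k, labels.size)
    for j in range(k):
        idx = np.flatnonzero(labels == j)
        if idx.size:
            first[j] = idx[0]
    order = sorted(range(k), key=lambda j: (-counts[j], first[j]))
    mapping = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new + 1
    return mapping[labels]


def cluster_states(
    windows: np.ndarray,
    k: int,
    n_replicates: int = 500,
    seed: int | None = None,
    max_iter: int = 100,
) -> StateModel:
    """Cluster pooled window vectors into k recurring states.

    Stage 1 runs ``n_replicates`` randomly initialized k-means replicates
    under correlation distance and keeps the lowest-objective solution.
    Stage 2 re-assigns every window to the nearest stage-1 centroid and
    reports final centroids as the element-wise median of each state's
    windows. Deterministic given the seed: replicate r uses a child seed
    derived from (seed, r), so the best objective is non-increasing in
    ``n_replicates``.
    """
    X = np.asarray(windows, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError("need at least k window vectors")
    U = _row_normalize(X)
    ss = np.random.SeedSequence(seed)
    best = None
    objectives = np.empty(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(r,)))
        labels, centroids, obj = _kmeans_once(X, U, k, rng, max_iter=max_iter)
        objectives[r] = obj
        if best is None or obj < best[2]:
            best = (labels, centroids, obj)
    _, centroids, obj = best
    # stage 2: final assignment of every window to the nearest centroid
    D = _distances_to_centroids(U, centroids)
    labels = D.argmin(axis=1)
    for j in range(k):
        if not (labels == j).any():
            warnings.warn(f"state {j} empty after final assignment")
    labels = _relabel_by_occupancy(labels, k)
    final_centroids = np.empty((k, X.shape[1]))
    for s in range(1, k + 1):
        member = X[labels == s]
        final_centroids[s - 1] = (
            np.median(member, axis=0) if member.size else np.full(X.shape[1], np.nan)
        )
    return StateModel(
        k=k,
        centroids=final_centroids,
        labels=labels,
        best_objective=obj,
        seed=seed,
        replicate_objectives=objectives,
    )


def cluster_validity_index(X: np.ndarray, model: StateModel) -> float:
    """Within/between distance ratio for the elbow criterion.

    Numerator: total correlation distance of windows to their assigned
    centroid. Denominator: size-weighted correlation distance of each
    centroid to the element-wise grand median of all windows.
    """
    U = _row_normalize(X)
    grand = np.median(X, axis=0)
    within = 0.0
    between = 0.0
    for s in range(1, model.k + 1):
        member = X[model.labels == s]
        if member.size == 0:
            continue
        c = model.centroids[s - 1]
        within += float(
            (1.0 - _row_normalize(member) @ _row_normalize(c[None, :])[0]).sum()
        )
        between += member.shape[0] * correlation_distance(c, grand)
    if between == 0:
        return np.inf
    return within / between


def elbow_select_k(
    windows: np.ndarray,
    k_range=range(2, 11),
    n_replicates: int = 500,
    seed: int | None = None,
) -> ElbowCurve:
    """Scan k, compute the validity index, and pick the elbow.

    The elbow is the k at which the index curve bends most: the point of
    maximum deviation below the chord joining the curve's endpoints (the
    standard knee-point construction). On the convex, monotonically
    decreasing curves this index produces, the raw discrete second
    difference degenerates to the smallest interior k — the initial drop
    always dominates — whereas the chord deviation locates the k where
    further clusters stop paying for themselves. If no point falls below
    the chord the curve has no elbow; the smallest k whose relative drop
    from the previous k is below 10% is selected, with a warning.
    """
    ks = np.asarray(sorted(k_range))
    cvi = np.empty(ks.size)
    for i, k in enumerate(ks):
        model = cluster_states(windows, int(k), n_replicates=n_replicates, seed=seed)
        cvi[i] = cluster_validity_index(np.asarray(windows, dtype=float), model)
    if ks.size < 3:
        return ElbowCurve(ks, cvi, int(ks[np.argmin(cvi)]))
    chord = cvi[0] + (cvi[-1] - cvi[0]) * (ks - ks[0]) / (ks[-1] - ks[0])
    gap = chord - cvi  # positive where the curve dips below the chord
    if gap.max() > 1e-12:
        selected = int(ks[gap.argmax()])
    else:
        warnings.warn("validity curve has no elbow; using relative-drop rule")
        selected = int(ks[0])
        for i in range(1, ks.size):
            if cvi[i - 1] > 0 and (cvi[i - 1] - cvi[i]) / cvi[i - 1] < 0.10:
                selected = int(ks[i])
                break
    return ElbowCurve(ks, cvi, selected)


def subject_state_centroids(
    z_stack: np.ndarray, labels_by_subject: list[np.ndarray], k: int
) -> np.ndarray:
    """Per-subject, per-state element-wise median connectivity.

    Returns an n_subjects x k x P array with NaN where a subject has no
    windows assigned to a state (not every subject visits every state).
    """
    n = len(labels_by_subject)
    P = z_stack.shape[-1]
    out = np.full((n, k, P), np.nan)
    for i, labels in enumerate(labels_by_subject):
        for s in range(1, k + 1):
            member = z_stack[i][labels == s]
            if member.size:
                out[i, s - 1] = np.median(member, axis=0)
    return out


def group_state_centroids(subject_centroids: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Average subject centroids over one group, ignoring absent states.

    Warns when no subject in the group visited a state; that state's group
    centroid is NaN.
    """
    sel = subject_centroids[group_mask]
    present = ~np.isnan(sel[:, :, 0])
    k = sel.shape[1]
    out = np.full(sel.shape[1:], np.nan)
    for s in range(k):
        if not present[:, s].any():
            warnings.warn(f"state {s + 1} visited by no subject in the group")
            continue
        out[s] = np.nanmean(sel[:, s, :], axis=0)
    return out


def match_states(estimated: np.ndarray, planted: np.ndarray):
    """Optimal one-to-one matching of estimated to planted state patterns.

    Hungarian assignment on the pairwise correlation-distance matrix.
    Returns (row indices, column indices, matched correlation values).
    """
    ke, kp = estimated.shape[0], planted.shape[0]
    D = np.empty((ke, kp))
    for i in range(ke):
        for j in range(kp):
            D[i, j] = correlation_distance(estimated[i], planted[j])
    ri, ci = linear_sum_assignment(D)
    return ri, ci, 1.0 - D[ri, ci]
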