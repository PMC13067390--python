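"""Two-state brain-state model and per-subject state dynamics.

All subjects' sliding-window FC matrices are pooled (upper-triangle
vectorized) and clustered with k-means (k = 2, cosine distance).  The two
centroids are labeled by their graph character: the centroid whose matrix
has the higher global efficiency is the **integrated** state I, the other
the **segregated** state S (a consistency check verifies I also has the
lower modularity and warns otherwise).  Each window is then assigned to the
cosine-nearest centroid, and the per-subject label sequences are summarized
as:

* ``Prev_S`` / ``Prev_I`` — percent of windows in each state (they sum to
  100 exactly);
* ``MDT_S`` / ``MDT_I`` — mean dwell time: mean duration of maximal
  constant runs of a state, in seconds (step = 1 TR, boundary runs
  included); absent when a state is never visited;
* ``ITI`` — mean inter-transition interval in seconds; absent with fewer
  than two transitions;
* ``Var_S`` / ``Var_I`` — 100 x mean cosine distance of a subject's
  state-assigned window vectors from the subject's own mean vector for that
  state (the "extent of the within-subject state cloud").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .connectivity import FCMatrix, WindowedFC
from .graph import metrics_for_fc

STATE_S, STATE_I = "S", "I"

# k-means defaults: fixed k = 2, cosine distance
DEFAULT_N_INIT = 100
DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6


def vectorize_fc(fc: FCMatrix) -> np.ndarray:
    """Upper-triangle (excluding diagonal) of an FC matrix as a flat vector."""
    return squareform(fc.values, checks=False)


def matrix_from_vector(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_fc` (zero diagonal)."""
    return squareform(np.asarray(vec, dtype=float))


@dataclass
class StatePool:
    """All subjects' window vectors stacked, with provenance indices."""

    vectors: np.ndarray  # (n_rows, n_pairs)
    subject_ids: np.ndarray  # (n_rows,) str
    window_index: np.ndarray  # (n_rows,) int

    @classmethod
    def from_windowed(cls, windowed: list[WindowedFC]) -> "StatePool":
        rows, subs, wins = [], [], []
        for wfc in windowed:
            for w, m in enumerate(wfc.matrices):
                rows.append(vectorize_fc(m))
                subs.append(wfc.subject_id)
                wins.append(w)
        return cls(
            vectors=np.asarray(rows), subject_ids=np.asarray(subs), window_index=np.asarray(wins)
        )

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class StateModel:
    """Two labeled centroids (raw-mean vectors) plus their graph metrics."""

    centroid_i: np.ndarray
    centroid_s: np.ndarray
    inertia: float
    label_metrics: dict = field(default_factory=dict)  # {"I": {...}, "S": {...}}

    @property
    def centroids(self) -> np.ndarray:
        """Stacked (2, n_pairs): row 0 = S, row 1 = I."""
        return np.vstack([self.centroid_s, self.centroid_i])


@dataclass
class StateSequence:
    """One subject's per-window state labels; step = 1 TR."""

    subject_id: str
    labels: np.ndarray  # array of "S"/"I"
    step_seconds: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.step_seconds <= 0:
            raise ValueError("step_seconds must be positive")

    @property
    def n_windows(self) -> int:
        return self.labels.size


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-norm vector in pool: cosine distance undefined")
    return x / norms


def _kmeans_pp_init(xn: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under cosine distance (1 - dot on unit vectors)."""
    n = xn.shape[0]
    centers = np.empty((k, xn.shape[1]))
    centers[0] = xn[rng.integers(n)]
    d = 1.0 - xn @ centers[0]
    for j in range(1, k):
        d = np.maximum(d, 0.0)
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = xn[rng.choice(n, p=probs)]
        d = np.minimum(d, 1.0 - xn @ centers[j])
    return centers


def _spherical_kmeans_once(
    xn: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
):
    centers = _kmeans_pp_init(xn, k, rng)
    centers = _normalize_rows(centers)
    prev_inertia = np.inf
    assign = None
    for _ in range(max_iter):
        sims = xn @ centers.T  # cosine similarity to each centroid
        assign = np.argmax(sims, axis=1)
        inertia = float(np.sum(1.0 - sims[np.arange(xn.shape[0]), assign]))
        new_centers = np.empty_like(centers)
        for j in range(k):
            members = xn[assign == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster at the worst-fit point
                worst = np.argmin(sims[np.arange(xn.shape[0]), assign])
                new_centers[j] = xn[worst]
            else:
                m = members.mean(axis=0)
                norm = np.linalg.norm(m)
                new_centers[j] = m / norm if norm > 0 else xn[rng.integers(xn.shape[0])]
        centers = new_centers
        if prev_inertia - inertia <= tol:
            break
        prev_inertia = inertia
    sims = xn @ centers.T
    assign = np.argmax(sims, axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(xn.shape[0]), assign]))
    return centers, assign, inertia


def fit_states(
    pool: StatePool,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> StateModel:
    """k-means with k = 2 and cosine distance over the pooled window vectors.

    Implemented as spherical k-means: vectors are L2-normalized, assignment
    maximizes cosine similarity, and centroid updates are
    mean-then-renormalize.  The best of ``n_init`` k-means++ seeded runs (by
    cosine inertia) wins.  Centroids are returned *un-normalized* as the
    mean of the assigned raw vectors, which keeps them on the Fisher-z scale
    for interpretation and graph labeling.
    """
    x = np.asarray(pool.vectors, dtype=float)
    if x.shape[0] < 2 or np.allclose(x, x[0]):
        raise ValueError("pool must contain at least two distinct vectors")
    xn = _normalize_rows(x)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, assign, inertia = _spherical_kmeans_once(xn, 2, rng, max_iter, tol)
        if best is None or inertia < best[2] - 1e-15:
            best = (centers, assign, inertia)
    _, assign, inertia = best
    raw_centroids = np.vstack([x[assign == j].mean(axis=0) for j in range(2)])
    model = StateModel(
        centroid_i=raw_centroids[0], centroid_s=raw_centroids[1], inertia=inertia
    )
    return label_states(model)


def label_states(model: StateModel) -> StateModel:
    """Assign I/S identities to the two centroids by graph character.

    The centroid whose matrix has the higher global efficiency becomes the
    integrated state I.  A consistency check warns if that centroid does not
    also have the lower modularity; efficiency decides.  An efficiency tie
    (to 1e-12) is unlabelable.
    """
    cands = [np.asarray(model.centroid_i, float), np.asarray(model.centroid_s, float)]
    mats = [FCMatrix(matrix_from_vector(c)) for c in cands]
    mets = [metrics_for_fc(m) for m in mats]
    e = [m["global_efficiency"] for m in mets]
    if abs(e[0] - e[1]) <= 1e-12:
        raise ValueError("centroids tie in global efficiency; states unlabelable")
    i_idx = int(np.argmax(e))
    s_idx = 1 - i_idx
    q = [m["modularity"] for m in mets]
    if np.isfinite(q[i_idx]) and np.isfinite(q[s_idx]) and q[i_idx] > q[s_idx]:
        warnings.warn(
            "integrated-labeled centroid has higher modularity than the "
            "segregated one; labeling by efficiency anyway"
        )
    return StateModel(
        centroid_i=cands[i_idx],
        centroid_s=cands[s_idx],
        inertia=model.inertia,
        label_metrics={STATE_I: mets[i_idx], STATE_S: mets[s_idx]},
    )


def assign_windows(model: StateModel, subject_windows: WindowedFC) -> StateSequence:
    """Label each window by the cosine-nearest centroid; ties go to S."""
    x = np.asarray([vectorize_fc(m) for m in subject_windows.matrices], dtype=float)
    xn = _normalize_rows(x)
    cs = model.centroid_s / np.linalg.norm(model.centroid_s)
    ci = model.centroid_i / np.linalg.norm(model.centroid_i)
    sim_s = xn @ cs
    sim_i = xn @ ci
    labels = np.where(sim_i > sim_s, STATE_I, STATE_S)  # tie -> S
    return StateSequence(
        subject_id=subject_windows.subject_id,
        labels=labels,
        step_seconds=subject_windows.tr_seconds,
    )


# ---------------------------------------------------------------------------
# per-subject dynamics
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray):
    """Maximal constant runs as (state, length) pairs, in order."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(labels[a], b - a) for a, b in zip(bounds[:-1], bounds[1:])]


def prevalence(seq: StateSequence) -> tuple[float, float]:
    """(Prev_S, Prev_I) in percent; they sum to 100 exactly."""
    if seq.n_windows == 0:
        raise ValueError("empty state sequence")
    prev_s = 100.0 * float(np.count_nonzero(seq.labels == STATE_S)) / seq.n_windows
    return prev_s, 100.0 - prev_s


def mean_dwell_time(seq: StateSequence, state: str) -> float | None:
    """Mean duration of the state's maximal runs, in seconds.

    Boundary (censored) runs at the start and end of the scan are included.
    ``None`` when the state is never visited — the subject is then excluded
    from that parameter's group statistics.
    """
    runs = [length for s, length in _runs(seq.labels) if s == state]
    if not runs:
        return None
    return float(np.mean(runs)) * seq.step_seconds


def inter_transition_interval(seq: StateSequence) -> float | None:
    """Mean time between consecutive state switches, in seconds.

    Transition times are the window indices where the label changes; the ITI
    is the mean gap between consecutive transitions.  ``None`` with fewer
    than two transitions.
    """
    trans = np.flatnonzero(seq.labels[1:] != seq.labels[:-1]) + 1
    if trans.size < 2:
        return None
    return float(np.mean(np.diff(trans))) * seq.step_seconds


def state_variability(
    seq: StateSequence, subject_windows: WindowedFC, state: str
) -> float | None:
    """100 x mean cosine distance of the subject's state windows from the
    subject's own mean vector for that state; 0 for a single window,
    ``None`` when the state is unvisited."""
    mask = seq.labels == state
    if not mask.any():
        return None
    x = np.asarray(
        [vectorize_fc(m) for m, keep in zip(subject_windows.matrices, mask) if keep],
        dtype=float,
    )
    center = x.mean(axis=0)
    cn = np.linalg.norm(center)
    if cn == 0:
        return 100.0  # degenerate: mean vector vanished, distances are maximal
    xn = _normalize_rows(x)
    cos = xn @ (center / cn)
    return float(100.0 * np.mean(1.0 - cos))


@dataclass
class DynamicsSummary:
    subject_id: str
    prev_s: float
    prev_i: float
    mdt_s: float | None
    mdt_i: float | None
    iti: float | None
    var_s: float | None
    var_i: float | None


def summarize_dynamics(seq: StateSequence, subject_windows: WindowedFC) -> DynamicsSummary:
    prev_s, prev_i = prevalence(seq)
    return DynamicsSummary(
        subject_id=seq.subject_id,
        prev_s=prev_s,
        prev_i=prev_i,
        mdt_s=mean_dwell_time(seq, STATE_S),
        mdt_i=mean_dwell_time(seq, STATE_I),
        iti=inter_transition_interval(seq),
        var_s=state_variability(seq, subject_windows, STATE_S),
        var_i=state_variability(seq, subject_windows, STATE_I),
    )


def dynamics_table(summaries: list[DynamicsSummary]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "prev_s": s.prev_s,
            "prev_i": s.prev_i,
            "mdt_s": s.mdt_s,
            "mdt_i": s.mdt_i,
            "iti": s.iti,
            "var_s": s.var_s,
            "var_i": s.var_i,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def group_centroids(
    sequences: list[StateSequence],
    windows: list[WindowedFC],
    group_labels: dict,
) -> dict:
    """Group-level state centroids: per subject and state the elementwise
    *median* window matrix, then per group and state the elementwise *mean*
    of the subject medians.

    ``group_labels`` maps subject_id -> group key.  Returns
    {(group, state): matrix}.
    """
    per_subject: dict = {}
    for seq, wfc in zip(sequences, windows):
        stack = np.asarray([m.values for m in wfc.matrices])
        for state in (STATE_S, STATE_I):
            mask = seq.labels == state
            if mask.any():
                per_subject.setdefault((group_labels[seq.subject_id], state), []).append(
                    np.median(stack[mask], axis=0)
                )
    return {key: np.mean(mats, axis=0) for key, mats in per_subject.items()}
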