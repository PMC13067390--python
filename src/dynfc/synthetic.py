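"""Synthetic resting-state cohorts with two-state switching connectivity.

Real parcellated rs-fMRI with sex labels is restricted, so every downstream
stage of the pipeline is exercised on simulated cohorts instead.  Each
subject's ROI signal is a zero-mean multivariate Gaussian whose correlation
structure switches between two regimes under a first-order Markov chain:

* a **segregated** regime — strong within-module correlation, weak coupling
  across modules (high modularity, low global efficiency), and
* an **integrated** regime — the same modules but with much stronger
  cross-module coupling (high global efficiency, low modularity).

The per-sex switch probabilities control state occupancy: the defaults plant
a ~13-percentage-point sex difference in the prevalence of the segregated
state (stationary occupancy ~35.5% in males vs ~48% in females), with mean
dwell times of roughly half a minute at TR = 0.720 s — the regime the group
statistics downstream are meant to detect.

Behavioral variables follow a linear mediation model on sex and a brain
integration mediator, so the mediation stage has planted ground truth, and a
framewise-displacement series per subject exercises the motion QC rule.

This generator is a stand-in: it makes no claim to hemodynamics, temporal
autocorrelation, or spatial realism (see the methods note for what that
implies for the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries

SEGREGATED, INTEGRATED = 0, 1  # frame-state codes
MALE, FEMALE = 1, 2  # sex coding used throughout (1 = male, 2 = female)

#: default per-sex (p_S->I, p_I->S) switch probabilities; stationary
#: pi_S = p_IS / (p_SI + p_IS) gives ~0.355 (male) vs ~0.480 (female)
DEFAULT_SWITCH_PROBS = {MALE: (0.020, 0.011), FEMALE: (0.018, 0.0166)}


@dataclass
class CohortSpec:
    """Generative settings for one synthetic cohort."""

    n_subjects: int = 80
    sex_labels: np.ndarray = None  # per-subject 1/2; default: near-balanced split
    n_rois: int = 10
    n_modules: int = 2
    n_frames: int = 300
    tr_seconds: float = 0.720
    within_r: float = 0.6
    between_r_segregated: float = 0.05
    between_r_integrated: float = 0.45
    switch_prob_by_sex: dict = field(default_factory=lambda: dict(DEFAULT_SWITCH_PROBS))
    fd_outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_rois % self.n_modules:
            raise ValueError("n_modules must divide n_rois")
        if not (0 < self.within_r < 1):
            raise ValueError("within_r must lie in (0, 1)")
        if not (0 <= self.between_r_segregated < self.within_r):
            raise ValueError("between_r_segregated must lie in [0, within_r)")
        if not (self.between_r_segregated < self.between_r_integrated <= self.within_r):
            raise ValueError(
                "between_r_integrated must exceed between_r_segregated and not exceed within_r"
            )
        if self.sex_labels is None:
            # near-balanced split, males first (mirrors the roughly balanced cohorts)
            n_male = self.n_subjects // 2 + self.n_subjects % 2
            self.sex_labels = np.array([MALE] * n_male + [FEMALE] * (self.n_subjects - n_male))
        else:
            self.sex_labels = np.asarray(self.sex_labels, dtype=int)
            if self.sex_labels.shape != (self.n_subjects,):
                raise ValueError("sex_labels must have one entry per subject")
            if not np.isin(self.sex_labels, [MALE, FEMALE]).all():
                raise ValueError("sex labels must be coded 1 (male) / 2 (female)")

    def state_covariance(self, state: int) -> np.ndarray:
        between = self.between_r_segregated if state == SEGREGATED else self.between_r_integrated
        return make_state_covariances(self.n_rois, self.n_modules, self.within_r, between)


@dataclass
class MediationSpec:
    """Planted linear mediation model: sex -> mediator -> outcome."""

    a_effect: float = 0.4
    b_effect: float = 0.3
    c_prime: float = 0.2
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_m <= 0 or self.noise_sd_y <= 0:
            raise ValueError("noise standard deviations must be positive")


def make_state_covariances(
    n_rois: int, n_modules: int, within_r: float, between_r: float
) -> np.ndarray:
    """Block-uniform correlation matrix: 1 on the diagonal, ``within_r`` inside
    module blocks, ``between_r`` across blocks.

    The eigenvalues of this structure are known in closed form; the
    positive-semidefiniteness bounds are checked and violated combinations are
    rejected with the offending bound named.
    """
    if n_rois < 1 or n_modules < 1 or n_rois % n_modules:
        raise ValueError("n_modules must be a positive divisor of n_rois")
    block = n_rois // n_modules
    # eigenvalues: (1 - w) on within-module contrasts, (1 - w) + (w - b)*block on
    # module contrasts, and (1 - w) + (w - b)*block + b*n on the constant vector
    lam_within = 1.0 - within_r
    lam_module = lam_within + (within_r - between_r) * block
    lam_const = lam_module + between_r * n_rois
    tol = -1e-12
    if lam_within < tol:
        raise ValueError(f"within_r={within_r} > 1 makes the matrix indefinite")
    if lam_module < tol:
        raise ValueError(
            f"between_r={between_r} exceeds within_r + (1-within_r)/{block}; "
            "module-contrast eigenvalue would be negative"
        )
    if lam_const < tol:
        raise ValueError(
            f"between_r={between_r} is too negative; the constant-vector "
            "eigenvalue would be negative"
        )
    cov = np.full((n_rois, n_rois), between_r, dtype=float)
    for m in range(n_modules):
        cov[m * block : (m + 1) * block, m * block : (m + 1) * block] = within_r
    np.fill_diagonal(cov, 1.0)
    return cov


def simulate_state_sequence(
    p_si: float, p_is: float, n_frames: int, seed: int | np.random.Generator
) -> np.ndarray:
    """First-order Markov chain over {segregated, integrated}.

    ``p_si`` is P(S -> I) and ``p_is`` is P(I -> S); the initial state is
    drawn from the stationary distribution pi_S = p_is / (p_si + p_is).
    Degenerate zero probabilities are allowed (the chain then never leaves
    its initial state; with both zero the initial state is segregated).
    """
    if not (0 <= p_si <= 1 and 0 <= p_is <= 1):
        raise ValueError("switch probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=np.int8)
    pi_s = p_is / (p_si + p_is) if (p_si + p_is) > 0 else 1.0
    states[0] = SEGREGATED if rng.random() < pi_s else INTEGRATED
    u = rng.random(n_frames - 1) if n_frames > 1 else np.empty(0)
    for t in range(1, n_frames):
        if states[t - 1] == SEGREGATED:
            states[t] = INTEGRATED if u[t - 1] < p_si else SEGREGATED
        else:
            states[t] = SEGREGATED if u[t - 1] < p_is else INTEGRATED
    return states


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # per-subject streams from one global seed so any subject reproduces alone
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(subject_index + 1)[-1])


def simulate_subject(spec: CohortSpec, subject_index: int):
    """One subject's frames x ROIs signal plus the true frame-state labels.

    Each frame is drawn i.i.d. (no temporal autocorrelation within state)
    from a zero-mean Gaussian with the covariance of the frame's true state.
    Deterministic given (spec.seed, subject_index).
    """
    if not (0 <= subject_index < spec.n_subjects):
        raise ValueError("subject_index out of range")
    rng = _subject_rng(spec.seed, subject_index)
    sex = int(spec.sex_labels[subject_index])
    p_si, p_is = spec.switch_prob_by_sex[sex]
    states = simulate_state_sequence(p_si, p_is, spec.n_frames, rng)
    chol = {
        s: np.linalg.cholesky(spec.state_covariance(s)) for s in (SEGREGATED, INTEGRATED)
    }
    white = rng.standard_normal((spec.n_frames, spec.n_rois))
    data = np.where(
        (states == SEGREGATED)[:, None], white @ chol[SEGREGATED].T, white @ chol[INTEGRATED].T
    )
    ts = RoiTimeSeries(
        subject_id=f"sub{subject_index:04d}", tr_seconds=spec.tr_seconds, data=data
    )
    return ts, states


def simulate_fd_series(
    n_frames: int, outlier_frac: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Nonnegative framewise-displacement series with a controlled fraction of
    high-motion frames (FD >= 0.5 mm).

    Baseline motion is folded-normal around ~0.14 mm (the median FD scale of
    typical low-motion adults); ``round(outlier_frac * n_frames)`` frames are
    replaced by spikes above the 0.5 mm threshold.
    """
    if not (0 <= outlier_frac <= 1):
        raise ValueError("outlier_frac must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fd = np.abs(rng.normal(0.12, 0.05, size=n_frames))
    fd = np.minimum(fd, 0.49)  # baseline never crosses the threshold
    n_out = int(round(outlier_frac * n_frames))
    if n_out:
        idx = rng.choice(n_frames, size=n_out, replace=False)
        fd[idx] = 0.5 + rng.exponential(0.2, size=n_out)
    return fd


def simulate_behavior(
    mediation_spec: MediationSpec,
    sex_labels: np.ndarray,
    mediator_values: np.ndarray | None = None,
    n_noise_vars: int = 3,
) -> pd.DataFrame:
    """Behavioral table with one planted mediated outcome plus pure-noise columns.

    ``Y = c' * sex + b * M + eps_y``.  When ``mediator_values`` is None a
    fresh mediator ``M = a * sex + eps_m`` is generated; otherwise the passed
    mediator (e.g. the recovered Prev_I) is used and ``a`` is whatever the
    data imply.
    """
    rng = np.random.default_rng(mediation_spec.seed)
    sex = np.asarray(sex_labels, dtype=float)
    n = sex.size
    if mediator_values is None:
        m = mediation_spec.a_effect * sex + rng.normal(0, mediation_spec.noise_sd_m, n)
    else:
        m = np.asarray(mediator_values, dtype=float)
        if m.shape != sex.shape:
            raise ValueError("mediator_values must align with sex_labels")
    y = (
        mediation_spec.c_prime * sex
        + mediation_spec.b_effect * m
        + rng.normal(0, mediation_spec.noise_sd_y, n)
    )
    table = {"mediated_outcome": y}
    for k in range(n_noise_vars):
        table[f"noise_{k}"] = rng.normal(0, 1, n)
    out = pd.DataFrame(table)
    out.insert(0, "mediator", m)
    return out


def simulate_cohort(spec: CohortSpec):
    """All subjects of a cohort: list of (RoiTimeSeries, true states), FD
    series per subject, and the manifest DataFrame."""
    subjects = [simulate_subject(spec, i) for i in range(spec.n_subjects)]
    fd_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    fd = [
        simulate_fd_series(spec.n_frames, spec.fd_outlier_frac, fd_rng)
        for _ in range(spec.n_subjects)
    ]
    manifest = pd.DataFrame(
        {
            "subject_id": [ts.subject_id for ts, _ in subjects],
            "sex": spec.sex_labels,
            "tr_seconds": spec.tr_seconds,
            "n_frames": spec.n_frames,
        }
    )
    return subjects, fd, manifest


def write_cohort(spec: CohortSpec, out_dir: str | Path, mediation: MediationSpec | None = None):
    """Materialize a cohort as the delimited-text layout the pipeline reads.

    Layout: ``manifest.tsv``, ``timeseries/<subject>.tsv`` (frames x ROIs with
    a header of ROI names), ``fd/<subject>.txt`` (one FD value per line),
    ``behavior.tsv`` and ``true_states/<subject>.txt``.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "fd").mkdir(exist_ok=True)
    (out / "true_states").mkdir(exist_ok=True)
    subjects, fd, manifest = simulate_cohort(spec)
    for (ts, states), fd_series in zip(subjects, fd):
        pd.DataFrame(ts.data, columns=ts.roi_names).to_csv(
            out / "timeseries" / f"{ts.subject_id}.tsv", sep="\t", index=False,
            float_format="%.8g",
        )
        np.savetxt(out / "fd" / f"{ts.subject_id}.txt", fd_series, fmt="%.6g")
        np.savetxt(out / "true_states" / f"{ts.subject_id}.txt", states, fmt="%d")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    if mediation is not None:
        # mediator = each subject's realized integrated-state occupancy
        # (standardized), so the outcome really is mediated by the brain
        # quantity the pipeline later recovers as Prev_I
        occ_i = np.array([np.mean(states == INTEGRATED) for _, states in subjects])
        occ_std = (occ_i - occ_i.mean()) / occ_i.std(ddof=0)
        behavior = simulate_behavior(mediation, spec.sex_labels, mediator_values=occ_std)
        behavior = behavior.drop(columns=["mediator"])
        behavior.insert(0, "subject_id", manifest["subject_id"])
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False, float_format="%.8g")
    return manifest


def _stationary_pi_s(p_si: float, p_is: float) -> float:
    return p_is / (p_si + p_is) if (p_si + p_is) > 0 else 1.0
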