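"""Synthetic multi-subject cohort with hidden-Markov connectivity states.

The generator emulates the study design the analysis pipeline expects:
two groups of subjects (patients and controls), each subject carrying five
network component time courses (aDMN, pDMN, LCEN, RCEN, SN) sampled at
TR = 2 s for 180 volumes. Connectivity states are planted as a small set of
well-separated covariance matrices; each subject follows a hidden Markov
state sequence with a group-specific transition kernel and emits
multivariate-normal samples from the covariance of the current state.
Group effects enter only through the transition kernels: by default
patients have a stickier chain biased toward state 1, producing higher
state-1 occupancy and dwell time and fewer transitions — the direction of
the clinical findings the pipeline is designed to detect.

Clinical scores (SDMT, TMT-A) are linear in the planted temporal metrics
plus Gaussian noise, so score-metric correlations have known sign.
Nuisance contamination (polynomial trends, motion leakage, spikes) is
injected on top so the post-processing stage has real work to do.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import temporal_properties

COMPONENT_NAMES = ("aDMN", "pDMN", "LCEN", "RCEN", "SN")


@dataclass
class CovariateModel:
    """Demographic covariate distributions (truncated normals, Bernoulli sex)."""

    age_mean: float = 33.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (19.0, 46.0)
    sex_p_male: float = 0.5
    edu_mean: float = 11.5
    edu_sd: float = 3.1
    edu_range: tuple[float, float] = (5.0, 22.0)


@dataclass
class ScoreModel:
    """Linear link from planted temporal metrics to clinical scores.

    SDMT (a psychomotor-speed score) increases with the number of state
    transitions; TMT-A completion time (seconds) increases with state-1
    dwell time. Both carry additive Gaussian noise.
    """

    sdmt_intercept: float = 20.0
    sdmt_per_transition: float = 2.2
    sdmt_noise_sd: float = 8.0
    tmt_intercept: float = 40.0
    tmt_per_dwell1: float = 1.0
    tmt_noise_sd: float = 14.0


@dataclass
class NuisanceConfig:
    """Artifact injection settings (amplitudes in signal-SD units)."""

    trend_amplitudes: tuple[float, ...] = (0.5, 0.3, 0.2)  # orders 1..3
    motion_gain: float = 0.3
    spike_rate: float = 0.01  # probability a volume carries a spike
    spike_amplitude: tuple[float, float] = (5.0, 9.0)  # in robust SDs


def default_transition_matrices(
    n_states: int = 4,
    control_stay: float = 0.965,
    patient_stay_state1: float = 0.994,
    patient_stay_other: float = 0.988,
    patient_state1_bias: float = 0.7,
) -> dict:
    """Group transition kernels with the default planted effects.

    Controls: symmetric chain with stay probability 0.965 (mean regime
    duration ~29 TRs, about six regime switches per 180-volume scan).
    Patients: much stickier chain (stay 0.994 in state 1, 0.988 elsewhere)
    with 70% of switches out of other states landing in state 1, yielding higher
    state-1 occupancy and dwell time and fewer transitions — the planted
    analogue of the group differences this pipeline is designed to detect.
    Regime durations are long relative to the 30-TR window so that the
    windowed estimator operates in its intended quasi-stationary regime.
    """
    off = (1 - control_stay) / (n_states - 1)
    control = np.full((n_states, n_states), off)
    np.fill_diagonal(control, control_stay)

    patient = np.zeros((n_states, n_states))
    patient[0] = (1 - patient_stay_state1) / (n_states - 1)
    patient[0, 0] = patient_stay_state1
    leave = 1 - patient_stay_other
    bias = 1.0 if n_states == 2 else patient_state1_bias
    for i in range(1, n_states):
        patient[i, i] = patient_stay_other
        patient[i, 0] = bias * leave
        rest = (1 - bias) * leave / max(n_states - 2, 1)
        for j in range(1, n_states):
            if j != i:
                patient[i, j] = rest
    return {"patient": patient, "control": control}


@dataclass
class CohortConfig:
    n_patients: int = 66
    n_controls: int = 66
    n_components: int = 5
    n_timepoints: int = 180
    n_discard: int = 10
    tr_seconds: float = 2.0
    n_states: int = 4
    state_separation: float = 0.4
    window_width: int = 30
    group_transition_matrices: dict | None = None
    covariates: CovariateModel = field(default_factory=CovariateModel)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    seed: int = 0

    def __post_init__(self):
        if self.group_transition_matrices is None and self.n_states >= 2:
            self.group_transition_matrices = default_transition_matrices(self.n_states)

    def validate(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be at least 2")
        if self.group_transition_matrices is None:
            raise ValueError("group transition matrices are required")
        if self.state_separation <= 0:
            raise ValueError("state_separation must be positive")
        if self.n_timepoints <= self.window_width + self.n_discard:
            raise ValueError("n_timepoints must exceed window width + n_discard")
        for name, M in self.group_transition_matrices.items():
            M = np.asarray(M)
            if M.shape != (self.n_states, self.n_states):
                raise ValueError(f"{name} transition matrix has wrong shape")
            if np.abs(M.sum(axis=1) - 1).max() > 1e-12:
                raise ValueError(f"{name} transition rows must sum to 1")
            if (M < 0).any():
                raise ValueError(f"{name} transition matrix has negative entries")


@dataclass
class SubjectTimeCourses:
    subject_id: str
    group: str  # "patient" or "control"
    data: np.ndarray  # T x C
    tr_seconds: float
    motion: np.ndarray | None  # T x 6
    age: float
    sex: int  # 1 = male, 0 = female
    education: float
    sdmt: float
    tmt_a: float


@dataclass
class SyntheticTruth:
    state_covariances: list
    sequences: list  # per-subject hidden state sequence, length n_timepoints
    fractional_windows: np.ndarray  # n_subjects x k, percent
    mean_dwell_time: np.ndarray  # n_subjects x k, timepoints
    n_transitions: np.ndarray  # n_subjects
    groups: list
    transition_matrices: dict
    seed: int


def _off_diag_corr_distance(A: np.ndarray, B: np.ndarray) -> float:
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    ac, bc = a - a.mean(), b - b.mean()
    return 1.0 - float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def make_state_covariances(
    n_states: int, n_components: int, separation: float, seed: int, max_attempts: int = 2000
) -> list[np.ndarray]:
    """Rejection-sample SPD state covariances with separated patterns.

    Candidate covariances are Wishart draws standardized to correlation
    form (unit variances), accepted only if the correlation distance
    between their off-diagonal vectors and those of every previously
    accepted state is at least ``separation``. A small diagonal ridge
    keeps candidates comfortably positive-definite while preserving the
    strong off-diagonal structure characteristic of recurring
    connectivity states; candidates with a near-unit correlation entry
    are discarded for numerical sanity.
    """
    if n_states < 1:
        raise ValueError("n_states must be at least 1")
    if not 0 < separation < 2:
        raise ValueError("separation must lie in (0, 2)")
    rng = np.random.default_rng(seed)
    states: list[np.ndarray] = []
    attempts = 0
    iu = np.triu_indices(n_components, k=1)
    while len(states) < n_states:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_states} states at separation {separation} "
                f"within {max_attempts} attempts; lower the separation"
            )
        A = rng.standard_normal((n_components, n_components))
        S = A @ A.T + 0.02 * n_components * np.eye(n_components)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        if np.abs(R[iu]).max() > 0.95:
            continue
        if all(_off_diag_corr_distance(R, prev) >= separation for prev in states):
            states.append(R)
    return states


def sample_state_sequence(transition, initial, T: int, seed: int) -> np.ndarray:
    """Length-T Markov state sequence with labels 1..n_states."""
    P = np.asarray(transition, dtype=float)
    pi = np.asarray(initial, dtype=float)
    if np.abs(P.sum(axis=1) - 1).max() > 1e-12 or (P < 0).any():
        raise ValueError("transition matrix must be row-stochastic")
    if abs(pi.sum() - 1) > 1e-12 or (pi < 0).any():
        raise ValueError("initial distribution must sum to 1")
    if T < 1:
        raise ValueError("T must be at least 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(T)
    seq = np.empty(T, dtype=int)
    s = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    seq[0] = s
    for t in range(1, T):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        seq[t] = s
    return seq + 1


def stationary_distribution(transition) -> np.ndarray:
    """Left stationary distribution of a row-stochastic matrix."""
    P = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def emit_subject_timecourses(sequence, covariances, seed: int) -> np.ndarray:
    """Draw row t from a zero-mean MVN with the covariance of state(t)."""
    seq = np.asarray(sequence, dtype=int)
    k = len(covariances)
    if seq.min() < 1 or seq.max() > k:
        raise ValueError("state index out of range for the covariance list")
    C = covariances[0].shape[0]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((seq.size, C))
    out = np.empty_like(z)
    for s in range(1, k + 1):
        idx = seq == s
        if idx.any():
            L = np.linalg.cholesky(covariances[s - 1])
            out[idx] = z[idx] @ L.T
    return out


def simulate_motion(T: int, rng: np.random.Generator) -> np.ndarray:
    """Slow random-walk realignment parameters (3 translations mm, 3 rotations deg)."""
    steps = rng.standard_normal((T, 6)) * np.array([0.02] * 3 + [0.01] * 3)
    return np.cumsum(steps, axis=0)


def inject_nuisance(data: np.ndarray, config: NuisanceConfig, seed: int):
    """Add polynomial trends, motion leakage, and spikes to clean signal.

    Returns ``(contaminated, motion, spikes)`` where ``spikes`` is a list
    of (timepoint, channel) locations. An all-zero configuration returns
    the input unchanged (motion is still generated for the record).
    """
    if config.spike_rate < 0:
        raise ValueError("spike rate must be nonnegative")
    X = np.asarray(data, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("data must be finite")
    T, C = X.shape
    rng = np.random.default_rng(seed)
    out = X.copy()
    t = np.linspace(-1.0, 1.0, T)
    for order, amp in enumerate(config.trend_amplitudes, start=1):
        if amp != 0:
            coeffs = rng.standard_normal(C) * amp
            out += np.outer(t**order, coeffs)
    motion = simulate_motion(T, rng)
    if config.motion_gain != 0:
        mixing = rng.standard_normal((6, C))
        leak = motion @ mixing
        leak_sd = leak.std(axis=0)
        leak_sd[leak_sd == 0] = 1.0
        out += config.motion_gain * leak / leak_sd
    spikes: list[tuple[int, int]] = []
    if config.spike_rate > 0:
        spike_vols = np.flatnonzero(rng.random(T) < config.spike_rate)
        scale = np.median(np.abs(X - np.median(X, axis=0)), axis=0) * 1.4826
        scale[scale == 0] = 1.0
        lo, hi = config.spike_amplitude
        for v in spike_vols:
            c = int(rng.integers(C))
            amp = rng.uniform(lo, hi) * scale[c] * rng.choice([-1.0, 1.0])
            out[v, c] += amp
            spikes.append((int(v), c))
    return out, motion, spikes


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_cohort(config: CohortConfig):
    """Generate the full cohort and its ground-truth record.

    Returns ``(subjects, truth)``. Per-subject truth metrics are exactly
    the temporal-properties computation applied to the hidden sequence,
    so every downstream estimate has an exact reference.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_states, seed_subjects = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]
    covs = make_state_covariances(
        config.n_states, config.n_components, config.state_separation, seed_states
    )
    n_total = config.n_patients + config.n_controls
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    sub_ss = np.random.SeedSequence(seed_subjects).spawn(n_total)
    subjects: list[SubjectTimeCourses] = []
    sequences, fracs, dwells, trans = [], [], [], []
    for i, (group, child) in enumerate(zip(groups, sub_ss)):
        s_seq, s_emit, s_nuis, s_cov, s_score = [
            int(c.generate_state(1)[0] % 2**31) for c in child.spawn(5)
        ]
        P = np.asarray(config.group_transition_matrices[group], dtype=float)
        pi = stationary_distribution(P)
        seq = sample_state_sequence(P, pi, config.n_timepoints, s_seq)
        clean = emit_subject_timecourses(seq, covs, s_emit)
        data, motion, _ = inject_nuisance(clean, config.nuisance, s_nuis)
        props = temporal_properties(seq, config.n_states)
        rng_cov = np.random.default_rng(s_cov)
        cm = config.covariates
        age = float(_truncated_normal(rng_cov, cm.age_mean, cm.age_sd, *cm.age_range))
        sex = int(rng_cov.random() < cm.sex_p_male)
        edu = float(_truncated_normal(rng_cov, cm.edu_mean, cm.edu_sd, *cm.edu_range))
        rng_score = np.random.default_rng(s_score)
        sm = config.score_model
        sdmt = (
            sm.sdmt_intercept
            + sm.sdmt_per_transition * props.n_transitions
            + rng_score.normal(0, sm.sdmt_noise_sd)
        )
        tmt = (
            sm.tmt_intercept
            + sm.tmt_per_dwell1 * props.mean_dwell_time[0]
            + rng_score.normal(0, sm.tmt_noise_sd)
        )
        subjects.append(
            SubjectTimeCourses(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                data=data,
                tr_seconds=config.tr_seconds,
                motion=motion,
                age=age,
                sex=sex,
                education=edu,
                sdmt=float(sdmt),
                tmt_a=float(tmt),
            )
        )
        sequences.append(seq)
        fracs.append(props.fractional_windows)
        dwells.append(props.mean_dwell_time)
        trans.append(props.n_transitions)
    truth = SyntheticTruth(
        state_covariances=covs,
        sequences=sequences,
        fractional_windows=np.array(fracs),
        mean_dwell_time=np.array(dwells),
        n_transitions=np.array(trans),
        groups=groups,
        transition_matrices={
            g: np.asarray(M) for g, M in config.group_transition_matrices.items()
        },
        seed=config.seed,
    )
    return subjects, truth
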