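"""Synthetic cohort generator with known representational ground truth.

Condition-by-voxel response patterns are drawn as an additive mixture of

* a model-structured, group-shared component whose expected pattern
  cross-covariance equals a weighted sum of hypothesis RSMs,
* an unstructured group-shared component (common to all subjects of a
  group),
* an individual component (common to a subject's runs),
* a session component (common within a run, across repetition halves), and
* i.i.d. measurement noise per repetition half.

This additive decomposition mirrors the measurement model assumed by
cross-subject RSM averaging and by the covariance-trace variance
partitioning, so every downstream estimator can be validated by parameter
recovery. Per-run head motion is emulated with lognormal framewise
displacement (FWD) traces whose group means reproduce the empirical motion
gradient (infants move far more than adults), which is what the
motion-matched importance-reweighted bootstrap has to correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from devgeo.stimuli import EventTable, StimulusSet

# Empirical group mean FWD (mm): 2-month infants, 9-month infants, adults.
GROUP_MEAN_FWD = {"2mo": 0.912, "9mo": 0.532, "adult": 0.177}


@dataclass
class MotionTrace:
    """Per-frame framewise displacement in mm for one run."""

    fwd: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        if self.fwd.ndim != 1 or self.fwd.size == 0:
            raise ValueError("FWD trace must be a non-empty 1-D array")
        if np.any(self.fwd < 0):
            raise ValueError("FWD must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.fwd.size

    @property
    def mean(self) -> float:
        return float(self.fwd.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.fwd))


@dataclass
class GroundTruthMixture:
    """Generative parameters for synthetic condition patterns.

    ``weights`` maps component names to (weight, RSM matrix) pairs; the
    expected cross-subject pattern covariance of the structured component
    is sum_k w_k * M_k (floored to positive semidefinite). The sigma_*
    terms are standard deviations of the unstructured additive components,
    in the same (arbitrary BOLD) units as the patterns.
    """

    weights: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)
    sigma_group: float = 0.0
    sigma_individual: float = 0.0
    sigma_session: float = 0.0
    sigma_noise: float = 1.0

    def __post_init__(self) -> None:
        for s in (
            self.sigma_group,
            self.sigma_individual,
            self.sigma_session,
            self.sigma_noise,
        ):
            if s < 0:
                raise ValueError("component standard deviations must be >= 0")
        for name, (w, m) in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"weight for {name!r} is not finite")
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"model matrix for {name!r} is not square")

    def target_covariance(self, n_conditions: int) -> np.ndarray:
        """Sum_k w_k * M_k, symmetrized and floored to PSD.

        Hypothesis RSMs are usually indefinite; flooring by a diagonal
        shift (adding |lambda_min| of isotropic, stimulus-specific signal
        variance) keeps every off-diagonal entry of the mixture exact,
        whereas eigenvalue clipping would distort the very similarity
        structure the generator is supposed to plant.
        """
        c = np.zeros((n_conditions, n_conditions))
        for _, (w, m) in self.weights.items():
            m = np.asarray(m, dtype=float)
            if m.shape != c.shape:
                raise ValueError("model RSM shape mismatch with stimulus set")
            c = c + w * m
        c = (c + c.T) / 2.0
        lam_min = float(np.linalg.eigvalsh(c)[0]) if self.weights else 0.0
        if lam_min < 0:
            c = c + (-lam_min) * np.eye(n_conditions)
        return c

    def structured_root(self, n_conditions: int) -> np.ndarray:
        """Matrix square root L with L @ L.T = floored target covariance."""
        c = self.target_covariance(n_conditions)
        vals, vecs = np.linalg.eigh(c)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


@dataclass
class Run:
    run_id: int
    motion: MotionTrace | None
    # repetition-half patterns, shape (2, n_conditions, n_voxels)
    halves: np.ndarray | None = None
    timeseries: np.ndarray | None = None

    @property
    def patterns(self) -> np.ndarray:
        """Run-level condition patterns (mean of the repetition halves)."""
        if self.halves is None:
            raise ValueError("run has no simulated patterns")
        return self.halves.mean(axis=0)


@dataclass
class Subject:
    subject_id: str
    group: str
    nicu: bool
    runs: list[Run]

    @property
    def patterns(self) -> np.ndarray:
        """Subject-level patterns: mean over the subject's runs."""
        return np.mean([r.patterns for r in self.runs], axis=0)

    @property
    def mean_fwd(self) -> float:
        vals = [r.motion.mean for r in self.runs if r.motion is not None]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class SyntheticCohort:
    """Subjects with per-run motion traces and condition patterns.

    ``links`` maps subject ids in this cohort to subject ids of a linked
    (longitudinal) cohort; links must be one-to-one.
    """

    stimulus_set: StimulusSet
    subjects: list[Subject]
    group: str
    mixture: GroundTruthMixture | None = None
    links: dict[str, str] = field(default_factory=dict)
    # realized group-shared signal (structured + unstructured), conditions x
    # voxels; the cohort-conditional estimand of any cross-subject statistic
    # is a function of this realization, not of the mixture expectation
    shared_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if len(set(self.links.values())) != len(self.links):
            raise ValueError("longitudinal links must be one-to-one")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def units(self, level: str = "run") -> list[tuple[tuple[str, int], np.ndarray]]:
        """Sampling units as ((subject_id, run_id), patterns) at run level,
        or ((subject_id, -1), run-averaged patterns) at subject level."""
        if level == "run":
            return [
                ((s.subject_id, r.run_id), r.patterns)
                for s in self.subjects
                for r in s.runs
            ]
        if level == "subject":
            return [((s.subject_id, -1), s.patterns) for s in self.subjects]
        raise ValueError("level must be 'run' or 'subject'")


def sample_fwd_trace(
    n_frames: int,
    mean_fwd: float,
    rng: np.random.Generator,
    sigma_within: float = 0.5,
    sigma_between: float = 0.8,
) -> MotionTrace:
    """Hierarchical lognormal FWD trace.

    Motion varies far more between runs than between the frames of one
    run (a calm infant stays calm), so the run's own mean FWD is first
    drawn from a lognormal centered on the group mean (``sigma_between``
    on the log scale), and frames are then lognormal around that run mean
    (``sigma_within``). The group expectation of a run's mean FWD equals
    ``mean_fwd``; the broad between-run spread is what motion binning and
    importance reweighting operate on.
    """
    if mean_fwd <= 0:
        raise ValueError("mean_fwd must be positive")
    run_mean = rng.lognormal(
        np.log(mean_fwd) - sigma_between**2 / 2.0, sigma_between
    )
    mu = np.log(run_mean) - sigma_within**2 / 2.0
    return MotionTrace(rng.lognormal(mu, sigma_within, size=n_frames))


def _simulate_subject_patterns(
    shared: np.ndarray,
    mixture: GroundTruthMixture,
    runs_per_subject: int,
    n_voxels: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    n = shared.shape[0]
    indiv = mixture.sigma_individual * rng.standard_normal((n, n_voxels))
    out = []
    for _ in range(runs_per_subject):
        sess = mixture.sigma_session * rng.standard_normal((n, n_voxels))
        halves = np.stack(
            [
                shared
                + indiv
                + sess
                + mixture.sigma_noise * rng.standard_normal((n, n_voxels))
                for _ in range(2)
            ]
        )
        out.append(halves)
    return out


def simulate_patterns(
    stimulus_set: StimulusSet,
    mixture: GroundTruthMixture,
    n_subjects: int,
    runs_per_subject: int | list[int] = 1,
    n_voxels: int = 500,
    seed: int | None = None,
    group: str = "2mo",
    mean_fwd: float | None = None,
    n_frames_per_run: int = 450,
    nicu_fraction: float = 0.0,
    structured_basis: np.ndarray | None = None,
) -> SyntheticCohort:
    """Simulate a cohort of condition-by-voxel patterns.

    The model-structured, group-shared signal is L @ Z with Z i.i.d.
    standard normal and L the matrix square root of the target mixture
    covariance, so that E[X X^T / n_voxels] equals sum_k w_k M_k. The
    unstructured group, individual, session and measurement components are
    added per the mixture's standard deviations. Each run carries two
    repetition halves differing only in measurement noise, plus a
    lognormal FWD trace.

    ``structured_basis`` (conditions x voxels, standard normal) fixes the
    latent basis Z of the structured component: cohorts built on the same
    basis realize the *same* representational geometry (up to their
    mixture scaling), which is how linked age groups or longitudinal
    timepoints of one population are generated.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n = stimulus_set.n_conditions
    if isinstance(runs_per_subject, int):
        runs_per_subject = [runs_per_subject] * n_subjects
    if len(runs_per_subject) != n_subjects:
        raise ValueError("runs_per_subject list length must equal n_subjects")
    if mean_fwd is None:
        mean_fwd = GROUP_MEAN_FWD.get(group, 0.5)

    root = mixture.structured_root(n)
    if structured_basis is None:
        structured_basis = rng.standard_normal((n, n_voxels))
    elif structured_basis.shape != (n, n_voxels):
        raise ValueError("structured_basis must be n_conditions x n_voxels")
    structured = root @ structured_basis
    group_comp = mixture.sigma_group * rng.standard_normal((n, n_voxels))
    shared = structured + group_comp

    subjects = []
    for i in range(n_subjects):
        halves_list = _simulate_subject_patterns(
            shared, mixture, runs_per_subject[i], n_voxels, rng
        )
        runs = [
            Run(
                run_id=j,
                motion=sample_fwd_trace(n_frames_per_run, mean_fwd, rng),
                halves=halves,
            )
            for j, halves in enumerate(halves_list)
        ]
        subjects.append(
            Subject(
                subject_id=f"{group}-sub{i:03d}",
                group=group,
                nicu=bool(rng.random() < nicu_fraction),
                runs=runs,
            )
        )
    return SyntheticCohort(
        stimulus_set=stimulus_set,
        subjects=subjects,
        group=group,
        mixture=mixture,
        shared_signal=shared,
    )


def expected_pair_rsm(cohort: SyntheticCohort, level: str = "subject") -> np.ndarray:
    """Cohort-conditional expectation of the cross-subject pair RSM.

    Conditional on the realized group-shared signal S, a unit's pattern is
    S plus independent noise (individual + session + half-averaged
    measurement), so the expected cross-measurement Pearson entry (p, q)
    is cov(S_p, S_q) / sqrt((var(S_p) + s2)(var(S_q) + s2)) with the
    empirical across-voxel moments of S and the per-voxel noise variance
    s2 implied by the mixture. This is the estimand that resampling
    subjects targets — the shared realization itself cannot be resampled.
    """
    if cohort.shared_signal is None or cohort.mixture is None:
        raise ValueError("cohort lacks generator internals")
    s = cohort.shared_signal
    mix = cohort.mixture
    r = int(np.median([len(sub.runs) for sub in cohort.subjects]))
    per_run = mix.sigma_session**2 + mix.sigma_noise**2 / 2.0
    s2 = mix.sigma_individual**2 + (per_run / r if level == "subject" else per_run)
    sc = s - s.mean(axis=1, keepdims=True)
    v = s.shape[1]
    cov = (sc @ sc.T) / v
    d = np.sqrt(np.diag(cov) + s2)
    return cov / np.outer(d, d)


def simulate_bold_run(
    events: EventTable,
    mixture: GroundTruthMixture,
    stimulus_set: StimulusSet,
    n_voxels: int = 200,
    tr: float | None = None,
    n_frames: int | None = None,
    seed: int | None = None,
    run: int = 0,
    motion_trace: MotionTrace | None = None,
    mean_fwd: float = 0.2,
    fwd_spike_threshold: float = 1.5,
    spike_amplitude: float = 20.0,
    drift_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    hrf_params: dict | None = None,
    patterns: np.ndarray | None = None,
) -> tuple[np.ndarray, MotionTrace, np.ndarray]:
    """Forward-model a BOLD run from an event schedule.

    timeseries = (event boxcars convolved with the double-gamma HRF,
    sampled at TR) @ condition patterns + linear drift + Gaussian noise.
    Frames whose FWD exceeds ``fwd_spike_threshold`` receive additive
    spike artifacts. Returns (timeseries [frames x voxels], motion trace,
    true patterns [conditions x voxels]).
    """
    from devgeo.glm import hrf_convolved_regressors  # deferred: avoid cycle

    tr = events.tr if tr is None else tr
    if tr <= 0:
        raise ValueError("tr must be positive")
    n_frames = events.n_frames if n_frames is None else n_frames
    run_events = events.for_run(run)
    if (run_events["onset"] + run_events["duration"]).max() > n_frames * tr:
        raise ValueError("events extend beyond the run duration")

    rng = np.random.default_rng(seed)
    n = stimulus_set.n_conditions
    if patterns is None:
        root = mixture.structured_root(n)
        patterns = root @ rng.standard_normal((n, n_voxels))
        patterns = patterns + mixture.sigma_noise * rng.standard_normal(
            (n, n_voxels)
        )
    else:
        patterns = np.asarray(patterns, dtype=float)
        n_voxels = patterns.shape[1]

    design = hrf_convolved_regressors(
        run_events, n, tr, n_frames, hrf_params=hrf_params
    )
    ts = design @ patterns
    if drift_amplitude:
        t = np.linspace(-1, 1, n_frames)[:, None]
        ts = ts + drift_amplitude * t
    if noise_sd:
        ts = ts + noise_sd * rng.standard_normal(ts.shape)

    if motion_trace is None:
        motion_trace = sample_fwd_trace(n_frames, mean_fwd, rng)
    if motion_trace.n_frames != n_frames:
        raise ValueError("motion trace length must equal n_frames")
    spikes = motion_trace.fwd > fwd_spike_threshold
    if spikes.any():
        ts[spikes] += spike_amplitude * rng.standard_normal(
            (int(spikes.sum()), n_voxels)
        )
    return ts, motion_trace, patterns
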