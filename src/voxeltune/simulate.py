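"""Synthetic voxels, BOLD timeseries and behaviour for the tuning pipeline.

The generator emulates the measurement model the downstream analysis assumes:
each voxel carries a 4-vector of mean response amplitudes (one per condition
CG/CC/EG/EC); a *tuned* voxel has its preferred condition's amplitude elevated
by a tuning gain over a common base level, an *untuned* voxel responds equally
to all four.  Trial responses are the condition mean plus i.i.d. Gaussian
trial noise; the BOLD series is the trial impulse train (at cue onsets)
convolved with the canonical double-gamma HRF, sampled on the TR = 2 s grid,
with additive Gaussian (optionally AR(1)) scanner noise.  Behaviour is
Bernoulli errors and truncated-Gaussian reaction times with per-condition
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter
from scipy.stats import truncnorm

from .design import CONDITIONS, Schedule
from .hrf import canonical_hrf

__all__ = [
    "VoxelPopulation",
    "BehaviorParams",
    "make_voxel_population",
    "simulate_trial_amplitudes",
    "simulate_bold",
    "simulate_betas",
    "simulate_behavior",
]

#: microtime resolution (ms) for impulse placement before TR sampling;
#: divides every possible cue onset (jitters are multiples of 500 ms).
DT_MS = 500


@dataclass
class VoxelPopulation:
    """A synthetic ROI: per-voxel condition tuning plus noise levels.

    Attributes
    ----------
    mu : ndarray, shape (n_voxels, 4)
        Mean response per condition, ordered as :data:`CONDITIONS`.
    noise_sd : ndarray, shape (n_voxels,)
        Trial-level Gaussian noise sd per voxel.
    baseline : float
        Common additive offset.
    designated_preference : ndarray, shape (n_voxels,), int
        Index into :data:`CONDITIONS` for tuned voxels, -1 for untuned.
    """

    mu: np.ndarray
    noise_sd: np.ndarray
    baseline: float = 0.0
    designated_preference: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.mu.size == 0:
            self.mu = self.mu.reshape(0, len(CONDITIONS))
        if self.mu.shape[1] != len(CONDITIONS):
            raise ValueError("mu must have one column per condition (4)")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_voxels,)
        ).copy()
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.designated_preference is None:
            pref = self.mu.argmax(axis=1)
            untuned = np.ptp(self.mu, axis=1) == 0
            pref[untuned] = -1
            self.designated_preference = pref
        else:
            self.designated_preference = np.asarray(
                self.designated_preference, dtype=int
            )
            tuned = self.designated_preference >= 0
            if tuned.any() and not np.array_equal(
                self.designated_preference[tuned], self.mu[tuned].argmax(axis=1)
            ):
                raise ValueError(
                    "designated_preference must equal argmax(mu) for tuned voxels"
                )

    @property
    def n_voxels(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class BehaviorParams:
    """Per-condition behaviour model.

    Defaults follow the additive (no-interaction) decomposition of the
    reported marginal means: error rates grammar 5.5% vs count 3.0% and
    episodic 5.6% vs contextual 2.9%; RT means grammar 798 ms vs count
    812 ms with no cue effect.  These are generator defaults for producing
    realistic sessions, not fitted values.  Trial-level RT sd defaults to
    150 ms; RTs are truncated to the (0, 2000] ms response window.
    """

    error_prob: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.0415, "CC": 0.0165, "EG": 0.0685, "EC": 0.0435}
    )
    rt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {"CG": 798.0, "CC": 812.0, "EG": 798.0, "EC": 812.0}
    )
    rt_sd_ms: dict[str, float] = field(
        default_factory=lambda: {c: 150.0 for c in CONDITIONS}
    )
    response_window_ms: float = 2000.0

    def validate(self) -> None:
        for c in CONDITIONS:
            if not 0.0 <= self.error_prob[c] <= 1.0:
                raise ValueError(f"error_prob[{c}] outside [0, 1]")
            if self.rt_sd_ms[c] < 0:
                raise ValueError(f"rt_sd_ms[{c}] must be >= 0")


def make_voxel_population(
    n_voxels: int,
    proportions: dict[str, float] | None = None,
    tuning_gain: float = 1.0,
    noise_sd: float = 1.0,
    baseline: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> VoxelPopulation:
    """Build a synthetic voxel population with the requested tuning mix.

    Parameters
    ----------
    proportions : dict
        Fractions per condition plus an optional ``"untuned"`` entry; must
        sum to 1.  Default: a quarter per condition, no untuned voxels.
    tuning_gain : float
        Elevation of the preferred condition's mean over the others.
    noise_sd : float
        Trial-level noise sd shared by all voxels.

    Voxel counts follow the proportions under largest-remainder rounding,
    and the preference order within the population is shuffled.
    """
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    if tuning_gain < 0:
        raise ValueError("tuning_gain must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    proportions = proportions or {c: 0.25 for c in CONDITIONS}
    keys = list(CONDITIONS) + ["untuned"]
    p = np.array([proportions.get(k, 0.0) for k in keys], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")

    ideal = p * n_voxels
    counts = np.floor(ideal).astype(int)
    remainder = int(n_voxels - counts.sum())
    if remainder:
        order = np.argsort(-(ideal - counts))
        counts[order[:remainder]] += 1

    pref = np.repeat(np.array([0, 1, 2, 3, -1]), counts)
    rng.shuffle(pref)
    mu = np.zeros((n_voxels, len(CONDITIONS)))
    tuned = pref >= 0
    mu[np.nonzero(tuned)[0], pref[tuned]] = tuning_gain
    return VoxelPopulation(
        mu=mu,
        noise_sd=np.full(n_voxels, noise_sd),
        baseline=baseline,
        designated_preference=pref,
    )


def _condition_indices(schedule: Schedule) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(CONDITIONS)}
    return np.array([lookup[t.condition] for t in schedule.trials], dtype=int)


def simulate_trial_amplitudes(
    pop: VoxelPopulation,
    schedule: Schedule,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-trial response amplitudes, shape (n_trials, n_voxels).

    amplitude[t, v] = baseline + mu[v, condition(t)] + N(0, noise_sd[v]).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cond = _condition_indices(schedule)
    amps = pop.baseline + pop.mu[:, cond].T  # (trials, voxels)
    noise = rng.standard_normal(amps.shape) * pop.noise_sd[None, :]
    return amps + noise


def n_volumes_for(schedule: Schedule, tr_s: float | None = None, pad_s: float = 32.0) -> int:
    """Number of TR-grid volumes covering the session plus HRF tail padding."""
    tr_s = tr_s if tr_s is not None else schedule.params.tr_s
    return int(np.ceil((schedule.duration_ms / 1000.0 + pad_s) / tr_s))


def convolved_timeseries(
    onsets_ms: np.ndarray,
    amplitudes: np.ndarray,
    n_volumes: int,
    tr_s: float,
    dt_ms: int = DT_MS,
) -> np.ndarray:
    """HRF-convolve an impulse train and sample it on the TR grid.

    ``amplitudes`` is (n_events,) or (n_events, n_voxels); impulses are placed
    on a ``dt_ms`` microtime grid (onsets must lie on it), convolved with the
    unit-peak canonical HRF sampled at ``dt_ms``, and read out at volume
    acquisition times 0, TR, 2·TR, …  This same routine builds both the
    simulated signal and the GLM regressors, so the two share one
    discretisation.
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    squeeze = amplitudes.ndim == 1
    amps = amplitudes[:, None] if squeeze else amplitudes
    frames = onsets_ms / dt_ms
    idx = np.round(frames).astype(int)
    if not np.allclose(frames, idx, atol=1e-9):
        raise ValueError(f"event onsets must lie on the {dt_ms} ms microtime grid")
    n_fine = int(np.ceil(n_volumes * tr_s * 1000.0 / dt_ms)) + 1
    kernel = canonical_hrf(dt_ms / 1000.0)
    if len(kernel) > n_fine:
        raise ValueError("HRF kernel longer than the session")
    impulses = np.zeros((n_fine, amps.shape[1]))
    np.add.at(impulses, idx, amps)
    conv = fftconvolve(impulses, kernel[:, None], axes=0)[:n_fine]
    step = tr_s * 1000.0 / dt_ms
    if abs(step - round(step)) > 1e-9:
        raise ValueError("TR must be a multiple of the microtime resolution")
    sampled = conv[:: int(round(step))][:n_volumes]
    return sampled[:, 0] if squeeze else sampled


def simulate_bold(
    amplitudes: np.ndarray,
    schedule: Schedule,
    noise_sd: float = 0.0,
    ar_coef: float = 0.0,
    tr_s: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synthesize a (n_volumes, n_voxels) BOLD timeseries for one session.

    Each trial contributes ``amplitude × HRF`` at its cue onset; scanner
    noise is additive Gaussian with sd ``noise_sd``, passed through an AR(1)
    filter with coefficient ``ar_coef`` when non-zero (the innovation sd is
    scaled so the marginal sd stays ``noise_sd``).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tr_s = tr_s if tr_s is not None else schedule.params.tr_s
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    if amplitudes.shape[0] != schedule.n_trials:
        raise ValueError("amplitudes must have one row per trial")
    onsets = np.array([t.cue_onset_ms for t in schedule.trials], dtype=float)
    n_vol = n_volumes_for(schedule, tr_s)
    signal = convolved_timeseries(onsets, amplitudes, n_vol, tr_s)
    if noise_sd > 0:
        noise = rng.standard_normal(signal.shape) * noise_sd
        if ar_coef:
            if not -1 < ar_coef < 1:
                raise ValueError("ar_coef must lie in (-1, 1)")
            noise *= np.sqrt(1 - ar_coef**2)
            noise = lfilter([1.0], [1.0, -ar_coef], noise, axis=0)
        signal = signal + noise
    return signal


def simulate_betas(
    pop: VoxelPopulation,
    n_runs: int = 6,
    trials_per_cell: int = 8,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Direct run×condition×voxel beta draws, bypassing the BOLD/GLM stage.

    Each cell's beta is the mean of ``trials_per_cell`` trial amplitudes, so
    betas[r, c, v] = baseline + mu[v, c] + N(0, noise_sd[v] / sqrt(trials)).
    Useful for fast tuning-procedure studies at the beta level.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    se = pop.noise_sd / np.sqrt(trials_per_cell)
    noise = rng.standard_normal((n_runs, len(CONDITIONS), pop.n_voxels)) * se
    return pop.baseline + pop.mu.T[None, :, :] + noise


def simulate_behavior(
    schedule: Schedule,
    params: BehaviorParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-trial accuracy and reaction time.

    Errors are Bernoulli with the condition's error probability; RTs are
    Gaussian truncated to (0, response window].  Returns a DataFrame with
    columns trial, condition, correct, rt_ms.
    """
    params = params or BehaviorParams()
    params.validate()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for t in schedule.trials:
        c = t.condition
        err = rng.random() < params.error_prob[c]
        m, s, w = params.rt_mean_ms[c], params.rt_sd_ms[c], params.response_window_ms
        if s == 0:
            rt = float(np.clip(m, 0.0, w))
        else:
            a, b = (0.0 - m) / s, (w - m) / s
            rt = float(truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng))
        rows.append(
            {"trial": t.index, "condition": c, "correct": not err, "rt_ms": rt}
        )
    return pd.DataFrame(rows, columns=["trial", "condition", "correct", "rt_ms"])
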