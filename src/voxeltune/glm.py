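"""Run-wise condition betas from event-related timeseries.

For the tuning analysis a single continuous session is split into six
pseudo-runs: per condition, the correct trials are randomly partitioned into
six equal groups (8 of 48 at study scale).  One GLM is fitted per run
partition: four condition regressors built from that run's assigned trials
(zero-duration impulses at cue onset convolved with the canonical HRF), one
nuisance regressor collecting every other event (other runs' trials,
erroneous and dropped trials, null events), discrete-cosine drift columns
implementing a 128 s high-pass, and an intercept.  The per-run condition
betas are stacked into a runs × conditions × voxels array and z-scored per
voxel across the 24 run×condition cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, Schedule
from .hrf import canonical_hrf  # noqa: F401  (re-exported: part of this surface)
from .simulate import convolved_timeseries, n_volumes_for

__all__ = [
    "RunAssignment",
    "BetaArray",
    "RankDeficientDesignError",
    "assign_trials_to_runs",
    "canonical_hrf",
    "cosine_drift",
    "build_run_design",
    "fit_glm",
    "extract_beta_array",
    "znormalize",
    "RunwiseGLM",
]

HIGHPASS_CUTOFF_S = 128.0


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when a design matrix loses full column rank."""


@dataclass
class RunAssignment:
    """Partition of correct trials into analysis runs.

    ``run_of_trial[i]`` is the 0-based run of trial ``i``, or -1 when the
    trial never enters a condition regressor (erroneous, or dropped to keep
    runs equally sized when correct counts are not divisible by ``n_runs``).
    """

    run_of_trial: np.ndarray
    n_runs: int
    erroneous: np.ndarray  # bool, per trial
    dropped: np.ndarray  # bool, per trial (correct but unassigned remainder)

    def trials_in_run(self, run: int, condition_idx: np.ndarray) -> dict[int, np.ndarray]:
        out = {}
        for ci in range(len(CONDITIONS)):
            out[ci] = np.nonzero(
                (self.run_of_trial == run) & (condition_idx == ci)
            )[0]
        return out


@dataclass
class BetaArray:
    """Per-subject beta estimates, shape (n_runs, 4, n_voxels)."""

    values: np.ndarray
    normalized: bool = False
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != len(CONDITIONS):
            raise ValueError("BetaArray values must be (n_runs, 4, n_voxels)")
        if self.excluded is None:
            self.excluded = np.zeros(self.values.shape[2], dtype=bool)

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def to_long_frame(self, subject: int | str = 0) -> pd.DataFrame:
        r, c, v = np.meshgrid(
            np.arange(self.n_runs),
            np.arange(len(CONDITIONS)),
            np.arange(self.n_voxels),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "subject": subject,
                "run": r.ravel(),
                "condition": np.array(CONDITIONS)[c.ravel()],
                "voxel": v.ravel(),
                "beta": self.values.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, normalized: bool = False) -> "BetaArray":
        n_runs = int(df["run"].max()) + 1
        n_vox = int(df["voxel"].max()) + 1
        vals = np.full((n_runs, len(CONDITIONS), n_vox), np.nan)
        cidx = {c: i for i, c in enumerate(CONDITIONS)}
        vals[
            df["run"].to_numpy(),
            df["condition"].map(cidx).to_numpy(),
            df["voxel"].to_numpy(),
        ] = df["beta"].to_numpy()
        return cls(values=vals, normalized=normalized)


def _condition_index(schedule: Schedule) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(CONDITIONS)}
    return np.array([lookup[t.condition] for t in schedule.trials], dtype=int)


def assign_trials_to_runs(
    schedule: Schedule,
    behavior: pd.DataFrame | np.ndarray | None = None,
    n_runs: int = 6,
    rng: np.random.Generator | int | None = None,
) -> RunAssignment:
    """Randomly partition each condition's correct trials into runs.

    Parameters
    ----------
    behavior : DataFrame with a boolean ``correct`` column (trial order), a
        boolean array, or None for all-correct.
    n_runs : int
        Number of pseudo-runs (6 in the study design).

    Correct-trial counts that are not divisible by ``n_runs`` are handled by
    dropping the excess at random so every run holds the same number of
    trials per condition; dropped and erroneous trials are flagged and end
    up in the nuisance regressor.

    Raises
    ------
    ValueError
        If any condition has fewer than ``n_runs`` correct trials.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = schedule.n_trials
    if behavior is None:
        correct = np.ones(n, dtype=bool)
    elif isinstance(behavior, pd.DataFrame):
        correct = behavior.sort_values("trial")["correct"].to_numpy(dtype=bool)
    else:
        correct = np.asarray(behavior, dtype=bool)
    if correct.shape != (n,):
        raise ValueError("behavior must provide one correct flag per trial")

    cond = _condition_index(schedule)
    run_of_trial = np.full(n, -1, dtype=int)
    dropped = np.zeros(n, dtype=bool)
    deficits = {}
    for ci, cname in enumerate(CONDITIONS):
        idx = np.nonzero((cond == ci) & correct)[0]
        per_run = len(idx) // n_runs
        if per_run == 0:
            deficits[cname] = len(idx)
            continue
        perm = rng.permutation(idx)
        keep = per_run * n_runs
        dropped[perm[keep:]] = True
        run_of_trial[perm[:keep]] = np.repeat(np.arange(n_runs), per_run)
    if deficits:
        raise ValueError(
            "too few correct trials to fill every run: "
            + ", ".join(f"{k}={v} correct (< {n_runs})" for k, v in deficits.items())
        )
    return RunAssignment(
        run_of_trial=run_of_trial,
        n_runs=n_runs,
        erroneous=~correct,
        dropped=dropped,
    )


def cosine_drift(n_volumes: int, tr_s: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (periods longer than ``cutoff_s``).

    Returns an (n_volumes, k) matrix of unit-norm cosines with k chosen so
    the shortest included period exceeds the cutoff; the constant term is
    excluded (the design carries an explicit intercept).
    """
    total_s = n_volumes * tr_s
    order = int(np.floor(2.0 * total_s / cutoff_s))
    t = np.arange(n_volumes)
    basis = np.array(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, order + 1)]
    ).T
    if basis.size == 0:
        return np.empty((n_volumes, 0))
    return basis * np.sqrt(2.0 / n_volumes)


def build_run_design(
    schedule: Schedule,
    assignment: RunAssignment,
    run: int,
    tr_s: float | None = None,
    n_volumes: int | None = None,
    highpass_s: float = HIGHPASS_CUTOFF_S,
    extra_regressors: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one run partition.

    Columns: one HRF-convolved regressor per condition built from the run's
    assigned trials (impulses at cue onset), one nuisance regressor from all
    other events (other runs' trials, erroneous/dropped trials and null
    events), optional user-supplied columns (e.g. motion), cosine drift
    columns for the high-pass, and an intercept.

    Returns the (n_volumes, n_cols) matrix and the column names.

    Raises
    ------
    ValueError
        If any condition regressor for this run would be empty.
    """
    tr_s = tr_s if tr_s is not None else schedule.params.tr_s
    if n_volumes is None:
        n_volumes = n_volumes_for(schedule, tr_s)
    cond = _condition_index(schedule)
    onsets = np.array([t.cue_onset_ms for t in schedule.trials], dtype=float)

    cols, names = [], []
    in_run = assignment.run_of_trial == run
    if schedule.n_trials:  # a trial-less (all-null) session has no task columns
        for ci, cname in enumerate(CONDITIONS):
            sel = in_run & (cond == ci)
            if not sel.any():
                raise ValueError(
                    f"run {run}: condition {cname} has no assigned trials"
                )
            amps = sel.astype(float)
            cols.append(convolved_timeseries(onsets, amps, n_volumes, tr_s))
            names.append(cname)

    nuis_events = list(onsets[~in_run])
    # null events enter the nuisance regressor at their (virtual) cue onset
    jit_span = schedule.params.trial_span_ms
    for on, dur in schedule.null_events:
        nuis_events.append(on + (dur - jit_span))  # onset + its jitter
    if nuis_events:
        nuis = convolved_timeseries(
            np.array(nuis_events), np.ones(len(nuis_events)), n_volumes, tr_s
        )
    else:
        nuis = np.zeros(n_volumes)
    cols.append(nuis)
    names.append("nuisance")

    if extra_regressors is not None:
        extra = np.atleast_2d(np.asarray(extra_regressors, dtype=float))
        if extra.shape[0] != n_volumes:
            extra = extra.T
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"extra_{j}")

    drift = cosine_drift(n_volumes, tr_s, highpass_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift_{j+1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return np.column_stack(cols), names


def fit_glm(
    timeseries: np.ndarray,
    design: np.ndarray,
    names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares fit of a design to (n_volumes, n_voxels) data.

    Returns (betas, residual_variance): betas is (n_cols, n_voxels) and the
    residual variance uses n - rank degrees of freedom.

    Raises
    ------
    RankDeficientDesignError
        Naming the collinear columns, when the design is rank deficient.
    ValueError
        When there are no more volumes than columns.
    """
    Y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if Y.shape[0] == design.shape[0]:
        pass
    elif Y.shape[1] == design.shape[0]:
        Y = Y.T
    else:
        raise ValueError("timeseries and design have incompatible shapes")
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need more volumes ({n}) than design columns ({p})")
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    bad = np.nonzero(diag < tol)[0]
    if bad.size:
        labels = (
            [names[i] for i in bad] if names is not None else [f"col {i}" for i in bad]
        )
        raise RankDeficientDesignError(
            f"design is rank deficient; collinear columns: {', '.join(labels)}"
        )
    betas = np.linalg.solve(r, q.T @ Y)
    resid = Y - design @ betas
    dof = n - p
    resid_var = (resid**2).sum(axis=0) / dof
    return betas, resid_var


def build_single_design(
    schedule: Schedule,
    assignment: RunAssignment,
    tr_s: float | None = None,
    n_volumes: int | None = None,
    highpass_s: float = HIGHPASS_CUTOFF_S,
    extra_regressors: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the single-GLM variant: one regressor per
    run×condition cell (n_runs × 4 of them) plus one nuisance regressor for
    erroneous/dropped trials and null events, drift columns and intercept.

    Unlike the per-run variant, every assigned trial is modelled by its own
    cell regressor, so a noiseless condition-amplitude signal lies exactly in
    the column space and the betas recover the generating amplitudes exactly.
    """
    tr_s = tr_s if tr_s is not None else schedule.params.tr_s
    if n_volumes is None:
        n_volumes = n_volumes_for(schedule, tr_s)
    cond = _condition_index(schedule)
    onsets = np.array([t.cue_onset_ms for t in schedule.trials], dtype=float)

    cols, names = [], []
    for run in range(assignment.n_runs):
        in_run = assignment.run_of_trial == run
        for ci, cname in enumerate(CONDITIONS):
            sel = in_run & (cond == ci)
            if not sel.any():
                raise ValueError(
                    f"run {run}: condition {cname} has no assigned trials"
                )
            cols.append(
                convolved_timeseries(onsets, sel.astype(float), n_volumes, tr_s)
            )
            names.append(f"run{run}_{cname}")

    unassigned = assignment.run_of_trial < 0
    nuis_events = list(onsets[unassigned])
    jit_span = schedule.params.trial_span_ms
    for on, dur in schedule.null_events:
        nuis_events.append(on + (dur - jit_span))
    if nuis_events:
        cols.append(
            convolved_timeseries(
                np.array(nuis_events), np.ones(len(nuis_events)), n_volumes, tr_s
            )
        )
        names.append("nuisance")

    if extra_regressors is not None:
        extra = np.atleast_2d(np.asarray(extra_regressors, dtype=float))
        if extra.shape[0] != n_volumes:
            extra = extra.T
        for j in range(extra.shape[1]):
            cols.append(extra[:, j])
            names.append(f"extra_{j}")

    drift = cosine_drift(n_volumes, tr_s, highpass_s)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift_{j+1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return np.column_stack(cols), names


def extract_beta_array(
    schedule: Schedule,
    assignment: RunAssignment,
    timeseries: np.ndarray,
    tr_s: float | None = None,
    highpass_s: float = HIGHPASS_CUTOFF_S,
    extra_regressors: np.ndarray | None = None,
    variant: str = "per-run",
) -> BetaArray:
    """Estimate the (n_runs, 4, n_voxels) condition betas.

    ``variant="per-run"`` (default) fits one GLM per run partition, each with
    four condition regressors and a single combined nuisance regressor for
    every other event.  ``variant="single"`` fits one GLM with a regressor
    per run×condition cell; the two differ slightly under noise, and only
    the single variant recovers noiseless amplitudes exactly.

    Returns an unnormalised :class:`BetaArray`.
    """
    Y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    n_vol = Y.shape[0]
    nc = len(CONDITIONS)
    if variant == "per-run":
        out = np.empty((assignment.n_runs, nc, Y.shape[1]))
        for run in range(assignment.n_runs):
            X, names = build_run_design(
                schedule,
                assignment,
                run,
                tr_s=tr_s,
                n_volumes=n_vol,
                highpass_s=highpass_s,
                extra_regressors=extra_regressors,
            )
            betas, _ = fit_glm(Y, X, names)
            out[run] = betas[:nc]
    elif variant == "single":
        X, names = build_single_design(
            schedule,
            assignment,
            tr_s=tr_s,
            n_volumes=n_vol,
            highpass_s=highpass_s,
            extra_regressors=extra_regressors,
        )
        betas, _ = fit_glm(Y, X, names)
        out = betas[: assignment.n_runs * nc].reshape(assignment.n_runs, nc, -1)
    else:
        raise ValueError("variant must be 'per-run' or 'single'")
    return BetaArray(values=out, normalized=False)


def znormalize(betas: BetaArray, axis: str = "voxel", ddof: int = 0) -> BetaArray:
    """z-score a BetaArray to remove mean-intensity differences.

    With ``axis="voxel"`` (default) each voxel is standardised across its
    n_runs × 4 run×condition cells to mean 0, sd 1.  ``axis="run"`` instead
    standardises each run×condition map across voxels.  Constant voxels
    (zero spread) cannot be standardised; they are set to NaN and flagged in
    ``excluded`` so downstream stages skip them.  The transform is
    idempotent and invariant to per-voxel positive affine rescaling.
    """
    v = betas.values
    if axis == "voxel":
        flat = v.reshape(-1, v.shape[2])  # cells × voxels
        mean = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=ddof)
        constant = sd == 0
        sd = np.where(constant, 1.0, sd)
        out = (v - mean[None, None, :]) / sd[None, None, :]
        out[:, :, constant] = np.nan
        excluded = betas.excluded | constant | np.isnan(flat).any(axis=0)
    elif axis == "run":
        mean = v.mean(axis=2, keepdims=True)
        sd = v.std(axis=2, ddof=ddof, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant run×condition map; cannot z-score across voxels")
        out = (v - mean) / sd
        excluded = betas.excluded.copy()
    else:
        raise ValueError("axis must be 'voxel' or 'run'")
    return BetaArray(values=out, normalized=True, excluded=excluded)


class RunwiseGLM:
    """Model object bundling the run-partition GLM for one subject's session.

    Parameters
    ----------
    schedule : Schedule
    timeseries : ndarray (n_volumes, n_voxels)
    behavior : DataFrame/array of correct flags, optional
    n_runs : int

    ``fit(rng)`` draws the trial-to-run assignment, fits the per-run GLMs
    and returns the z-normalised :class:`BetaArray`.
    """

    def __init__(
        self,
        schedule: Schedule,
        timeseries: np.ndarray,
        behavior: pd.DataFrame | np.ndarray | None = None,
        n_runs: int = 6,
        highpass_s: float = HIGHPASS_CUTOFF_S,
        normalization_axis: str = "voxel",
        variant: str = "per-run",
    ) -> None:
        self.schedule = schedule
        self.timeseries = np.atleast_2d(np.asarray(timeseries, dtype=float))
        self.behavior = behavior
        self.n_runs = n_runs
        self.highpass_s = highpass_s
        self.normalization_axis = normalization_axis
        self.variant = variant

    def fit(
        self,
        rng: np.random.Generator | int | None = None,
        normalize: bool = True,
    ) -> BetaArray:
        assignment = assign_trials_to_runs(
            self.schedule, self.behavior, self.n_runs, rng
        )
        self.assignment_ = assignment
        betas = extract_beta_array(
            self.schedule,
            assignment,
            self.timeseries,
            highpass_s=self.highpass_s,
            variant=self.variant,
        )
        self.raw_betas_ = betas
        return znormalize(betas, axis=self.normalization_axis) if normalize else betas
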