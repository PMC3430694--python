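"""Voxel tuning functions via leave-one-run-out preference classification.

The central analysis: for each of the six runs in turn, the other five
("classification") runs determine every voxel's preferred condition as the
argmax of its across-run mean beta.  A voxel's preference counts as *reliable*
only if the same condition is also its within-run argmax in at least half of
the classification runs (>= 3 of 5).  The held-out ("analysis") run — never
consulted for classification — supplies the voxel's 4-point tuning curve, so
selection and measurement stay independent.  Repeating this over all six
hold-outs yields per-fold tuned-voxel counts per condition and mean tuning
curves, summarised per subject and compared across subjects with a 2×2
repeated-measures ANOVA on the counts and paired t-tests on tuning success.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .design import CONDITIONS
from .glm import BetaArray
from .stats import PairedTResult, paired_t

__all__ = [
    "FoldResult",
    "TuningSummary",
    "classify_preference",
    "reliability_filter",
    "loocv_tuning",
    "summarize_tuning",
    "tuning_success",
    "null_reliability_enumeration",
    "null_reliability_mc",
    "VoxelTuning",
    "VoxelTuningResults",
]


@dataclass
class FoldResult:
    """Outcome of one leave-one-run-out fold.

    Attributes
    ----------
    analysis_run : int
        The held-out run supplying the tuning curves.
    preference : ndarray (n_voxels,) int
        Index into :data:`CONDITIONS`; -1 for untuned (exact tie) voxels.
    per_run_preferences : ndarray (k, n_voxels) int
        Within-run argmax per classification run; -1 marks within-run ties.
    reliable : ndarray (n_voxels,) bool
    tuning_curves : ndarray (4, n_voxels)
        Analysis-run betas, all voxels (mask with ``reliable`` downstream).
    excluded : ndarray (n_voxels,) bool
        Voxels with NaN betas, never counted as tuned or untuned.
    """

    analysis_run: int
    preference: np.ndarray
    per_run_preferences: np.ndarray
    reliable: np.ndarray
    tuning_curves: np.ndarray
    excluded: np.ndarray

    def tuned_counts(self) -> np.ndarray:
        """Number of reliable voxels preferring each condition (length 4)."""
        out = np.zeros(len(CONDITIONS))
        for ci in range(len(CONDITIONS)):
            out[ci] = np.sum(self.reliable & (self.preference == ci))
        return out


@dataclass
class TuningSummary:
    """Per-subject (per-ROI) summary over folds."""

    tuned_counts: np.ndarray  # (4,) mean count of reliable voxels per condition
    mean_curves: np.ndarray  # (4, 4): preferred condition × condition mean beta
    untuned_fraction: float
    n_voxels: int
    n_excluded: int
    aggregation: str = "mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": CONDITIONS,
                "tuned_count": self.tuned_counts,
                "untuned_fraction": self.untuned_fraction,
            }
        )


def _argmax_with_ties(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """argmax along ``axis`` with exact ties (or any NaN) mapped to -1."""
    vmax = np.max(values, axis=axis)
    is_max = values == np.expand_dims(vmax, axis)
    pref = np.argmax(is_max, axis=axis)
    pref = np.where(is_max.sum(axis=axis) != 1, -1, pref)
    return np.where(np.isnan(vmax), -1, pref)


def classify_preference(classification_betas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Preferred condition from (k_runs, 4[, n_voxels]) classification betas.

    Returns ``(preference, excluded)``: the argmax of the across-run mean per
    voxel (-1 for an exact tie) and a flag for voxels with any NaN beta.
    """
    b = np.asarray(classification_betas, dtype=float)
    single = b.ndim == 2
    if single:
        b = b[:, :, None]
    if b.shape[1] != len(CONDITIONS):
        raise ValueError("classification betas must have 4 conditions on axis 1")
    excluded = np.isnan(b).any(axis=(0, 1))
    means = b.mean(axis=0)  # (4, n_voxels)
    pref = _argmax_with_ties(means, axis=0)
    pref = np.where(excluded, -1, pref)
    if single:
        return int(pref[0]), bool(excluded[0])
    return pref, excluded


def reliability_filter(preference, per_run_preferences) -> np.ndarray | bool:
    """True where the overall preference recurs as the within-run argmax in at
    least half (= ceil(k/2)) of the k classification runs.

    Accepts scalars-plus-list for one voxel or arrays (pref (V,), per-run
    (k, V)) for many; condition names or indices both work.
    """
    name_to_idx = {c: i for i, c in enumerate(CONDITIONS)}

    def coerce(x):
        a = np.asarray(x)
        if a.dtype.kind in "US":
            a = np.vectorize(lambda s: name_to_idx[s])(a)
        return a.astype(int)

    pref = coerce(preference)
    per_run = coerce(per_run_preferences)
    scalar = pref.ndim == 0
    if scalar:
        pref = pref[None]
        per_run = per_run[:, None]
    k = per_run.shape[0]
    need = -(-k // 2)  # ceil(k/2)
    matches = (per_run == pref[None, :]) & (pref[None, :] >= 0)
    out = matches.sum(axis=0) >= need
    return bool(out[0]) if scalar else out


def loocv_tuning(betas: BetaArray | np.ndarray) -> list[FoldResult]:
    """Run the full leave-one-run-out tuning procedure.

    Expects a z-normalised (n_runs, 4, n_voxels) :class:`BetaArray` (a bare
    array is accepted and wrapped).  Each fold classifies on the other
    n_runs−1 runs and reads tuning curves from the held-out run only; the
    number of voxels per condition is left free ("winner take all" per
    voxel).  Returns one :class:`FoldResult` per analysis run.
    """
    if not isinstance(betas, BetaArray):
        betas = BetaArray(values=np.asarray(betas, dtype=float))
    v = betas.values
    n_runs = betas.n_runs
    if n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    folds = []
    base_excluded = betas.excluded | np.isnan(v).any(axis=(0, 1))
    for analysis_run in range(n_runs):
        cls = np.delete(v, analysis_run, axis=0)  # (k, 4, V)
        pref, _ = classify_preference(cls)
        pref = np.where(base_excluded, -1, pref)
        per_run = _argmax_with_ties(cls, axis=1)  # (k, V)
        reliable = reliability_filter(pref, per_run) & (pref >= 0) & ~base_excluded
        folds.append(
            FoldResult(
                analysis_run=analysis_run,
                preference=pref,
                per_run_preferences=per_run,
                reliable=reliable,
                tuning_curves=v[analysis_run].copy(),
                excluded=base_excluded.copy(),
            )
        )
    return folds


def summarize_tuning(
    folds: list[FoldResult], aggregation: str = "mean"
) -> TuningSummary:
    """Aggregate fold results into per-subject tuned counts and mean curves.

    Counts are averaged over folds by default (``aggregation="sum"`` adds
    them instead).  Mean tuning curves are averaged over each fold's
    reliable voxels of the given preference, then over the folds that have
    any; the per-fold accounting identity (tuned counts + untuned + excluded
    = n_voxels) is asserted.
    """
    if not folds:
        raise ValueError("need at least one fold")
    if aggregation not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    nc = len(CONDITIONS)
    n_vox = folds[0].preference.shape[0]
    counts = np.zeros((len(folds), nc))
    curves = np.full((len(folds), nc, nc), np.nan)
    untuned = np.zeros(len(folds))
    for fi, fold in enumerate(folds):
        counts[fi] = fold.tuned_counts()
        n_excl = int(fold.excluded.sum())
        n_untuned = int(np.sum(~fold.reliable & ~fold.excluded))
        assert counts[fi].sum() + n_untuned + n_excl == n_vox
        untuned[fi] = n_untuned
        for ci in range(nc):
            sel = fold.reliable & (fold.preference == ci)
            if sel.any():
                curves[fi, ci] = fold.tuning_curves[:, sel].mean(axis=1)
    agg = np.mean if aggregation == "mean" else np.sum
    import warnings

    with warnings.catch_warnings():
        # a preference with no reliable voxels in any fold stays NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_curves = np.nanmean(curves, axis=0)
    n_excluded = int(folds[0].excluded.sum())
    return TuningSummary(
        tuned_counts=agg(counts, axis=0),
        mean_curves=mean_curves,
        untuned_fraction=float(np.mean(untuned) / max(n_vox - n_excluded, 1)),
        n_voxels=n_vox,
        n_excluded=n_excluded,
        aggregation=aggregation,
    )


def tuning_success(
    summaries: list[TuningSummary], condition: str | int
) -> PairedTResult:
    """Group-level tuning success for one condition.

    For each subject, takes the mean analysis-run beta of the voxels tuned to
    ``condition`` at that condition, and the mean of the same voxels' betas
    over the other three conditions; returns the paired t-test across
    subjects.  Subjects without any reliably tuned voxel for the condition
    are excluded (with a warning) and the degrees of freedom shrink
    accordingly.
    """
    ci = CONDITIONS.index(condition) if isinstance(condition, str) else int(condition)
    own, other = [], []
    n_dropped = 0
    for s in summaries:
        curve = s.mean_curves[ci]
        if np.isnan(curve).any():
            n_dropped += 1
            continue
        own.append(curve[ci])
        rest = np.delete(curve, ci)
        other.append(rest.mean())
    if n_dropped:
        import warnings

        warnings.warn(
            f"{n_dropped} subject(s) lack voxels tuned to "
            f"{CONDITIONS[ci]}; excluded from the paired t-test",
            stacklevel=2,
        )
    if len(own) < 2:
        raise ValueError(
            f"need >=2 subjects with voxels tuned to {CONDITIONS[ci]}"
        )
    return paired_t(np.array(own), np.array(other))


def null_reliability_enumeration(n_classification_runs: int = 5, n_conditions: int = 4) -> float:
    """Exact P(some condition is the within-run argmax in >= ceil(k/2) runs)
    under i.i.d. uniform per-run winners, by enumerating all n_cond^k
    patterns.

    This is the probability that a majority preference *exists*; it upper-
    bounds the procedure's null reliability rate, which additionally requires
    the across-run-mean argmax to coincide with that majority.
    """
    k, nc = n_classification_runs, n_conditions
    need = -(-k // 2)
    hits = 0
    for pat in product(range(nc), repeat=k):
        if np.bincount(pat, minlength=nc).max() >= need:
            hits += 1
    return hits / nc**k


def null_reliability_mc(
    n_classification_runs: int = 5,
    n_conditions: int = 4,
    n_samples: int = 1_000_000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Monte-Carlo null reliability rate of the actual procedure.

    Draws i.i.d. standard-normal betas (k runs × conditions), classifies the
    across-run-mean argmax and checks the >= ceil(k/2) per-run recurrence —
    a direct, pipeline-independent implementation of the null model.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = n_classification_runs
    need = -(-k // 2)
    hits = 0
    chunk = 200_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        b = rng.standard_normal((m, k, n_conditions))
        pref = b.mean(axis=1).argmax(axis=1)
        per_run = b.argmax(axis=2)
        hits += int(((per_run == pref[:, None]).sum(axis=1) >= need).sum())
        done += m
    return hits / n_samples


class VoxelTuning:
    """Model object for the leave-one-run-out voxel tuning analysis.

    Parameters
    ----------
    betas : BetaArray or (n_runs, 4, n_voxels) array
        Run-wise condition betas for one subject's ROI.  Normalised betas are
        expected; pass ``normalize=True`` (default) to z-score per voxel
        across the run×condition cells first.
    aggregation : {"mean", "sum"}
        How per-fold tuned counts combine into the per-subject count.
    """

    def __init__(
        self,
        betas: BetaArray | np.ndarray,
        normalize: bool = True,
        aggregation: str = "mean",
    ) -> None:
        from .glm import znormalize

        if not isinstance(betas, BetaArray):
            betas = BetaArray(values=np.asarray(betas, dtype=float))
        if normalize and not betas.normalized:
            betas = znormalize(betas)
        self.betas = betas
        self.aggregation = aggregation

    def fit(self) -> "VoxelTuningResults":
        folds = loocv_tuning(self.betas)
        summary = summarize_tuning(folds, self.aggregation)
        return VoxelTuningResults(model=self, folds=folds, summary=summary)


@dataclass
class VoxelTuningResults:
    """Fitted tuning analysis for one subject: folds plus their summary."""

    model: VoxelTuning
    folds: list[FoldResult]
    summary: TuningSummary

    @property
    def tuned_counts(self) -> np.ndarray:
        return self.summary.tuned_counts

    @property
    def mean_curves(self) -> np.ndarray:
        return self.summary.mean_curves

    def summary_frame(self) -> pd.DataFrame:
        df = self.summary.to_frame()
        df["n_voxels"] = self.summary.n_voxels
        df["n_excluded"] = self.summary.n_excluded
        return df

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for pi, pref in enumerate(CONDITIONS):
            for ci, cond in enumerate(CONDITIONS):
                rows.append(
                    {
                        "preferred_condition": pref,
                        "condition": cond,
                        "mean_beta": self.summary.mean_curves[pi, ci],
                    }
                )
        return pd.DataFrame(rows)

    def plot_tuning_curves(self, ax=None):
        """Plot the mean tuning curve for each preferred condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(CONDITIONS))
        for pi, pref in enumerate(CONDITIONS):
            curve = self.summary.mean_curves[pi]
            if np.isnan(curve).all():
                continue
            ax.plot(x, curve, marker="o", label=f"tuned to {pref}")
        ax.set_xticks(x, CONDITIONS)
        ax.set_xlabel("condition")
        ax.set_ylabel("mean normalised beta (analysis run)")
        ax.legend()
        return ax
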