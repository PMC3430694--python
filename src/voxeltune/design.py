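"""Counterbalanced 2×2 (CUE × TASK) event-related session schedules.

One session crosses two cue sets with two sequencing tasks.  A *contextual*
cue maps directly to a task (square → grammar judgement, diamond → count
judgement); an *episodic* cue is relative to the previous trial (triangle up →
repeat the previous task, triangle down → switch to the other one).  The four
conditions are CG, CC, EG and EC (Contextual/Episodic × Grammar/Count).

At the default scale a session holds 192 trials — 48 per condition, with 48
squares, 48 diamonds, 48 up- and 48 down-triangles — plus 48 null events
(fixation only) interspersed at random.  Within the grammar task the
grammatical/ungrammatical stimuli split 50/50, within the count task the
match/mismatch stimuli likewise.  The four task-to-task transitions are
counterbalanced to within one occurrence.

Trial timing: an onset jitter of 0/500/1000/1500 ms, a 1000 ms cue, six
syllables at 1000 ms each, a 2000 ms response window, 500 ms feedback and a
3000 ms fixation, i.e. 12 500 ms plus jitter per trial.  Null events occupy
the same span.  All onsets are in ms from session start; the scanner grid is
derived at TR = 2 s.

The schedule sampler is constructive rather than rejection-based: the task
sequence is drawn uniformly among sequences realising a balanced transition
profile (via random compositions of the task blocks), episodic cues are then
allotted across the four (task, repeat/switch) position classes with weights
proportional to the number of concrete assignments, which makes every count
constraint — including the 48/48 episodic resolution into EG/EC — hold by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .agstim import SequenceSpec, generate_sequence

__all__ = [
    "CONDITIONS",
    "DesignParams",
    "Trial",
    "Schedule",
    "resolve_episodic",
    "generate_schedule",
    "schedule_onsets",
]

#: Canonical condition order used throughout the package.
CONDITIONS = ("CG", "CC", "EG", "EC")

_CONTEXTUAL_SYMBOL = {"grammar": "square", "count": "diamond"}
_TASKS = ("grammar", "count")


@dataclass(frozen=True)
class DesignParams:
    """Session-design parameters; defaults reproduce the study-scale session."""

    trials_per_condition: int = 48
    n_null: int = 48
    jitters_ms: tuple[int, ...] = (0, 500, 1000, 1500)
    cue_ms: int = 1000
    syllable_ms: int = 1000
    n_syllables: int = 6
    response_ms: int = 2000
    feedback_ms: int = 500
    fixation_ms: int = 3000
    tr_s: float = 2.0

    @property
    def trial_span_ms(self) -> int:
        """Fixed trial duration excluding the leading jitter (12 500 ms)."""
        return (
            self.cue_ms
            + self.n_syllables * self.syllable_ms
            + self.response_ms
            + self.feedback_ms
            + self.fixation_ms
        )

    def validate(self) -> None:
        if self.trials_per_condition < 2 or self.trials_per_condition % 2:
            raise ValueError(
                "trials_per_condition must be an even number >= 2 "
                "(50/50 stimulus label splits within each task)"
            )
        if self.n_null < 0:
            raise ValueError("n_null must be >= 0")


@dataclass
class Trial:
    """One cued sequence-judgement trial."""

    index: int
    cue_kind: str  # "contextual" | "episodic"
    cue_symbol: str  # square | diamond | triangle_up | triangle_down
    resolved_task: str  # "grammar" | "count"
    condition: str  # CG | CC | EG | EC
    sequence: SequenceSpec
    correct_response: str  # "yes" | "no"
    jitter_ms: int
    onset_ms: int = -1  # block start; cue appears at onset_ms + jitter_ms

    @property
    def cue_onset_ms(self) -> int:
        return self.onset_ms + self.jitter_ms


@dataclass
class Schedule:
    """An ordered session: trials plus interleaved null events."""

    trials: list[Trial]
    null_events: list[tuple[int, int]]  # (onset_ms, duration_ms) incl. jitter
    params: DesignParams
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_ms(self) -> int:
        ends = [t.onset_ms + t.jitter_ms + self.params.trial_span_ms for t in self.trials]
        ends += [on + dur for on, dur in self.null_events]
        return max(ends) if ends else 0

    def condition_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            out[t.condition] += 1
        return out

    def to_events_table(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration in seconds)."""
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.onset_ms / 1000.0,
                    "duration": (t.jitter_ms + self.params.trial_span_ms) / 1000.0,
                    "trial_type": t.condition,
                    "cue_symbol": t.cue_symbol,
                    "cue_onset": t.cue_onset_ms / 1000.0,
                    "sequence": str(t.sequence),
                    "correct_response": t.correct_response,
                    "jitter_ms": t.jitter_ms,
                }
            )
        for on, dur in self.null_events:
            rows.append(
                {
                    "onset": on / 1000.0,
                    "duration": dur / 1000.0,
                    "trial_type": "null",
                    "cue_symbol": "",
                    "cue_onset": np.nan,
                    "sequence": "",
                    "correct_response": "",
                    "jitter_ms": dur - self.params.trial_span_ms,
                }
            )
        df = pd.DataFrame(rows).sort_values("onset", kind="stable")
        return df.reset_index(drop=True)


def resolve_episodic(previous_task: str, symbol: str) -> str:
    """Resolve an episodic cue given the previously performed task.

    Triangle up repeats the previous task; triangle down switches to the
    other one.  A session-initial episodic cue is undefined and raises.
    """
    if previous_task not in _TASKS:
        raise ValueError(
            "episodic cue has no defined task: previous_task must be "
            f"'grammar' or 'count', got {previous_task!r}"
        )
    if symbol == "triangle_up":
        return previous_task
    if symbol == "triangle_down":
        return "grammar" if previous_task == "count" else "count"
    raise ValueError(f"unknown episodic cue symbol {symbol!r}")


def _random_composition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random composition of `total` into `parts` positive integers."""
    if parts == 0:
        return np.empty(0, dtype=int)
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    bounds = np.concatenate(([0], cuts, [total]))
    return np.diff(bounds)


def _task_sequence(m: int, rng: np.random.Generator) -> list[str]:
    """Uniform task sequence of length 4m with 2m of each task, a balanced
    transition profile (counts {m, m, m, m-1}) and a contextual-compatible
    (well-defined) start.

    The short transition type is assigned to one of the two within-task
    transitions at random; the sequence then starts and ends on that task,
    and decomposes into alternating blocks whose sizes are drawn as uniform
    random compositions.
    """
    first = _TASKS[rng.integers(2)]  # task with the m-1 self-transition count
    other = "grammar" if first == "count" else "count"
    # first-task blocks: m+1 of them summing to 2m; other-task blocks: m of 2m
    sizes_first = _random_composition(2 * m, m + 1, rng)
    sizes_other = _random_composition(2 * m, m, rng)
    seq: list[str] = []
    for i in range(m + 1):
        seq.extend([first] * int(sizes_first[i]))
        if i < m:
            seq.extend([other] * int(sizes_other[i]))
    return seq


def _assign_cue_kinds(
    tasks: list[str], m: int, rng: np.random.Generator
) -> list[str]:
    """Choose contextual/episodic per trial so that every cue-count constraint
    holds: m episodic trials per task, m repeat (up) and m switch (down)
    episodic trials, session-initial trial contextual.

    Positions split into classes by (task, repeat-of-previous?).  With the
    transition profile {m, m, m, m-1} the class sizes are (G,rep)=m,
    (G,sw)=m, (first-task,rep)=m-1, (first-task,sw)=m plus the initial
    trial.  Writing ``a`` for the episodic count in the non-initial task's
    repeat class forces the remaining class counts (a + b = m etc.); ``a`` is
    drawn with probability proportional to the number of concrete position
    assignments it admits, making the overall assignment uniform.
    """
    n = len(tasks)
    first = tasks[0]
    classes: dict[tuple[str, bool], list[int]] = {}
    for i in range(1, n):
        key = (tasks[i], tasks[i] == tasks[i - 1])
        classes.setdefault(key, []).append(i)
    other = "grammar" if first == "count" else "count"
    rep_o = classes.get((other, True), [])
    sw_o = classes.get((other, False), [])
    rep_f = classes.get((first, True), [])
    sw_f = classes.get((first, False), [])
    assert (len(rep_o), len(sw_o), len(rep_f), len(sw_f)) == (m, m, m - 1, m)

    # episodic counts: a in rep_o, m-a in sw_o, m-(m-a)=a in sw_f, m-a in rep_f
    a_vals = np.arange(max(1, 0), m + 1)  # a >= 1 since rep_f holds only m-1
    logw = (
        _log_comb(m, a_vals)
        + _log_comb(m, m - a_vals)
        + _log_comb(m - 1, m - a_vals)
        + _log_comb(m, a_vals)
    )
    w = np.exp(logw - logw.max())
    a = int(rng.choice(a_vals, p=w / w.sum()))

    episodic = set()
    for positions, k in (
        (rep_o, a),
        (sw_o, m - a),
        (rep_f, m - a),
        (sw_f, a),
    ):
        episodic.update(rng.choice(positions, size=k, replace=False).tolist())
    return ["episodic" if i in episodic else "contextual" for i in range(n)]


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _balanced_labels(count: int, rng: np.random.Generator) -> np.ndarray:
    """A shuffled half-True/half-False boolean vector (`count` even)."""
    labels = np.zeros(count, dtype=bool)
    labels[: count // 2] = True
    rng.shuffle(labels)
    return labels


def generate_schedule(
    params: DesignParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Schedule:
    """Generate one counterbalanced session schedule.

    Parameters
    ----------
    params : DesignParams, optional
        Counts and timing; defaults to the study-scale session (192 trials,
        48 per condition, 48 null events).
    rng : numpy Generator or int seed
        Source of randomness; an int is used to seed a fresh Generator.

    Returns
    -------
    Schedule
        With onsets already computed (see :func:`schedule_onsets`).
    """
    params = params or DesignParams()
    params.validate()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = params.trials_per_condition

    tasks = _task_sequence(m, rng)
    cue_kinds = _assign_cue_kinds(tasks, m, rng)

    # Stimulus labels: primary label balanced within task, secondary balanced too.
    n_task = 2 * m
    gram_primary = _balanced_labels(n_task, rng)  # is_grammatical for grammar trials
    gram_secondary = _balanced_labels(n_task, rng)  # count_match for grammar trials
    count_primary = _balanced_labels(n_task, rng)  # count_match for count trials
    count_secondary = _balanced_labels(n_task, rng)

    # Jitters balanced within each condition.
    jitter_pool: dict[str, list[int]] = {}
    for cond in CONDITIONS:
        reps = -(-m // len(params.jitters_ms))  # ceil
        pool = np.tile(params.jitters_ms, reps)[:m]
        rng.shuffle(pool)
        jitter_pool[cond] = pool.tolist()

    trials: list[Trial] = []
    ig = ic = 0
    prev_task: str | None = None
    for i, (task, kind) in enumerate(zip(tasks, cue_kinds)):
        if kind == "contextual":
            symbol = _CONTEXTUAL_SYMBOL[task]
        else:
            assert prev_task is not None
            symbol = "triangle_up" if task == prev_task else "triangle_down"
            assert resolve_episodic(prev_task, symbol) == task
        condition = ("C" if kind == "contextual" else "E") + (
            "G" if task == "grammar" else "C"
        )
        if task == "grammar":
            grammatical = bool(gram_primary[ig])
            cm = bool(gram_secondary[ig])
            ig += 1
        else:
            cm = bool(count_primary[ic])
            grammatical = bool(count_secondary[ic])
            ic += 1
        seq = generate_sequence(3, grammatical, cm, rng)
        answer = seq.is_grammatical if task == "grammar" else seq.count_match
        trials.append(
            Trial(
                index=i,
                cue_kind=kind,
                cue_symbol=symbol,
                resolved_task=task,
                condition=condition,
                sequence=seq,
                correct_response="yes" if answer else "no",
                jitter_ms=jitter_pool[condition].pop(),
            )
        )
        prev_task = task

    schedule = Schedule(trials=trials, null_events=[], params=params, seed=seed)
    _interleave_nulls_and_set_onsets(schedule, rng)
    return schedule


def _interleave_nulls_and_set_onsets(
    schedule: Schedule, rng: np.random.Generator
) -> None:
    """Place null events uniformly among trial positions and lay out onsets."""
    p = schedule.params
    n_events = schedule.n_trials + p.n_null
    null_slots = set(
        rng.choice(n_events, size=p.n_null, replace=False).tolist()
    ) if p.n_null else set()
    reps = -(-p.n_null // len(p.jitters_ms)) if p.n_null else 0
    null_jitters = np.tile(p.jitters_ms, max(reps, 1))[: p.n_null]
    rng.shuffle(null_jitters)

    t = 0
    trial_iter = iter(schedule.trials)
    null_jit = iter(null_jitters.tolist())
    nulls: list[tuple[int, int]] = []
    for slot in range(n_events):
        if slot in null_slots:
            jit = next(null_jit)
            dur = jit + p.trial_span_ms
            nulls.append((t, dur))
            t += dur
        else:
            trial = next(trial_iter)
            trial.onset_ms = t
            t += trial.jitter_ms + p.trial_span_ms
    schedule.null_events = nulls


def schedule_onsets(schedule: Schedule) -> pd.DataFrame:
    """Expand a schedule into a stage-level event table.

    One row per presentation stage (jitter, cue, each syllable, response
    window, feedback, fixation) per trial, plus one row per null event;
    onsets in ms, strictly increasing within a trial.
    """
    p = schedule.params
    rows = []
    for trial in schedule.trials:
        t = trial.onset_ms
        stages = [("jitter", trial.jitter_ms), ("cue", p.cue_ms)]
        stages += [(f"syllable_{k+1}", p.syllable_ms) for k in range(p.n_syllables)]
        stages += [
            ("response", p.response_ms),
            ("feedback", p.feedback_ms),
            ("fixation", p.fixation_ms),
        ]
        for name, dur in stages:
            if dur == 0:
                continue
            rows.append(
                {"trial": trial.index, "stage": name, "onset_ms": t, "duration_ms": dur}
            )
            t += dur
        expected = trial.onset_ms + trial.jitter_ms + p.trial_span_ms
        if t != expected:  # pragma: no cover - construction invariant
            raise RuntimeError("internal error: stage durations do not tile the trial")
    for onset, dur in schedule.null_events:
        rows.append({"trial": -1, "stage": "null", "onset_ms": onset, "duration_ms": dur})
    df = pd.DataFrame(
        rows, columns=["trial", "stage", "onset_ms", "duration_ms"]
    ).sort_values(["onset_ms", "trial"], kind="stable")
    return df.reset_index(drop=True)
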