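"""Group-level statistics: 2×2 repeated-measures ANOVA, paired t, Pearson r.

Everything here operates on per-subject quantities (error rates, reaction
times, tuned-voxel counts).  In a 2×2 within-subject design every effect has
a single degree of freedom, so each F statistic is exactly the square of the
paired t on the corresponding within-subject contrast, with df = (1, n−1) and
identical two-tailed p; the ANOVA is computed through that identity (which
also makes sphericity a non-issue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Cell22Data",
    "PairedTResult",
    "AnovaResult",
    "paired_t",
    "rm_anova_2x2",
    "pearson_r",
]

#: t magnitude reported when the difference scores have zero variance but a
#: non-zero mean (the statistic is formally infinite); flagged as degenerate.
T_CAP = 1e6


@dataclass
class Cell22Data:
    """Per-subject 2×2 tables, shape (n_subjects, 2, 2).

    Axis 1 is the CUE factor (contextual, episodic), axis 2 the TASK factor
    (count, grammar) — but any consistent 2×2 labelling works; effects are
    reported under the supplied factor names.
    """

    values: np.ndarray
    factor_names: tuple[str, str] = ("CUE", "TASK")
    level_names: tuple[tuple[str, str], tuple[str, str]] = (
        ("contextual", "episodic"),
        ("count", "grammar"),
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (2, 2):
            raise ValueError("values must be (n_subjects, 2, 2)")
        if np.isnan(self.values).any():
            raise ValueError("missing cells: every subject needs all 4 cells")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")

    @classmethod
    def from_condition_dict(cls, per_condition: dict[str, np.ndarray]) -> "Cell22Data":
        """Build from per-condition vectors keyed CG/CC/EG/EC."""
        n = len(next(iter(per_condition.values())))
        vals = np.empty((n, 2, 2))
        vals[:, 0, 0] = per_condition["CC"]
        vals[:, 0, 1] = per_condition["CG"]
        vals[:, 1, 0] = per_condition["EC"]
        vals[:, 1, 1] = per_condition["EG"]
        return cls(values=vals)


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero-variance differences with non-zero mean

    def __iter__(self):
        return iter((self.t, self.df, self.p))


@dataclass
class AnovaResult:
    """F, df and p per within-subject effect of a 2×2 design."""

    effects: dict[str, tuple[float, tuple[int, int], float]] = field(
        default_factory=dict
    )

    def summary(self) -> pd.DataFrame:
        rows = [
            {"effect": name, "F": F, "df1": df[0], "df2": df[1], "p": p}
            for name, (F, df, p) in self.effects.items()
        ]
        return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n−1.

    All-zero differences give t = 0, p = 1.  Constant non-zero differences
    make the statistic formally infinite; it is reported capped at ±1e6 with
    ``degenerate=True`` so near-ceiling data never silently produce NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    df = n - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTResult(t=0.0, df=df, p=1.0)
        return PairedTResult(
            t=float(np.sign(d.mean()) * T_CAP), df=df, p=0.0, degenerate=True
        )
    res = sps.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def rm_anova_2x2(data: Cell22Data | np.ndarray) -> AnovaResult:
    """2×2 repeated-measures ANOVA via within-subject contrasts.

    For each effect the per-subject contrast is the difference of level
    means (factor A: row means; factor B: column means; interaction: the
    double difference); F(1, n−1) = t² of the one-sample t on that contrast
    and the two-tailed p values coincide.  Effects are invariant to adding a
    per-subject constant.
    """
    if not isinstance(data, Cell22Data):
        data = Cell22Data(values=np.asarray(data, dtype=float))
    v = data.values
    a, b = data.factor_names
    contrasts = {
        a: v[:, 1, :].mean(axis=1) - v[:, 0, :].mean(axis=1),
        b: v[:, :, 1].mean(axis=1) - v[:, :, 0].mean(axis=1),
        f"{a}x{b}": (v[:, 1, 1] - v[:, 1, 0]) - (v[:, 0, 1] - v[:, 0, 0]),
    }
    n = v.shape[0]
    out = AnovaResult()
    for name, d in contrasts.items():
        res = paired_t(d, np.zeros(n))
        F = min(res.t**2, T_CAP)
        out.effects[name] = (float(F), (1, n - 1), res.p)
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product–moment correlation; requires length >= 3 and non-zero spread."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)
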