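"""Group × muscle comparison: summary tables and the random-block ANOVA.

The design is a classic split-plot: worker group (dairy location) is a
between-subject factor, muscle a within-subject factor, and each subject
is a block contributing one value per muscle.  For complete
within-subject data the F-tests follow from the expected-mean-squares
decomposition:

* group is tested against the subject-within-group mean square,
* muscle and group × muscle against the residual (subject × muscle)
  mean square.

Simple main effects of group within each muscle use the whole-plot plus
split-plot variance combination ``(MS_subj + (m-1)·MS_err) / m`` with
Satterthwaite degrees of freedom, and a Tukey–Kramer adjustment over the
family of group × muscle cell means (studentized range with
k = n_groups × n_muscles), mirroring standard post-hoc practice for a
significant interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ModelFitError, ValidationError
from .io import METRICS

logger = logging.getLogger(__name__)


@dataclass
class MetricDataset:
    """Long-format per-subject metric values with a remembered factor order.

    One row per subject × muscle × metric; group and muscle order follow
    first appearance (the reporting convention puts the large-herd group
    first).
    """

    frame: pd.DataFrame
    group_order: tuple[str, ...] = ()
    muscle_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"group", "subject", "muscle", "metric", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"metric table missing columns {sorted(missing)}")
        if self.frame.empty:
            raise ValidationError("metric table is empty")
        dup = self.frame.duplicated(subset=["subject", "muscle", "metric"])
        if dup.any():
            raise ValidationError("duplicate subject×muscle×metric rows in metric table")
        unknown = set(self.frame["metric"]) - set(METRICS)
        if unknown:
            raise ValidationError(f"unknown metric names {sorted(unknown)}")
        if not self.group_order:
            self.group_order = tuple(dict.fromkeys(self.frame["group"]))
        if not self.muscle_order:
            self.muscle_order = tuple(dict.fromkeys(self.frame["muscle"]))

    @property
    def is_balanced(self) -> bool:
        """True when every subject has every muscle for every metric."""
        counts = self.frame.groupby(["metric", "subject"], sort=False)["muscle"].nunique()
        return bool((counts == len(self.muscle_order)).all())

    def for_metric(self, metric: str) -> pd.DataFrame:
        if metric not in METRICS:
            raise ValidationError(f"unknown metric {metric!r}")
        sub = self.frame[self.frame["metric"] == metric]
        if sub.empty:
            raise ValidationError(f"no rows for metric {metric!r}")
        return sub


@dataclass(frozen=True)
class TermTest:
    """One fixed-effect F-test."""

    name: str
    f_value: float
    df_num: float
    df_den: float
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """Random-block ANOVA fit for one metric.

    ``terms`` holds the group, muscle and interaction tests;
    ``sigma2_subject``/``sigma2_error`` are the method-of-moments variance
    components; cell means and design counts are retained so simple main
    effects can be derived from the same fit.
    """

    metric: str
    terms: dict[str, TermTest]
    sigma2_subject: float
    sigma2_error: float
    alpha: float
    cell_means: pd.DataFrame        # groups × muscles
    group_sizes: dict[str, int]
    ms_subject: float
    df_subject: float
    ms_error: float
    df_error: float
    group_order: tuple[str, ...]
    muscle_order: tuple[str, ...]
    n_dropped_subjects: int = 0


@dataclass(frozen=True)
class SimpleMainEffectRow:
    """Group contrast within one muscle (large-herd estimate first)."""

    muscle: str
    estimate_group_a: float
    estimate_group_b: float
    delta: float
    p_adjusted: float
    p_unadjusted: float = float("nan")
    se: float = float("nan")
    df: float = float("nan")

    @classmethod
    def from_estimates(
        cls,
        muscle: str,
        estimate_group_a: float,
        estimate_group_b: float,
        p_adjusted: float = float("nan"),
    ) -> "SimpleMainEffectRow":
        """Worked-example constructor: delta is the difference A − B."""
        return cls(
            muscle=muscle,
            estimate_group_a=estimate_group_a,
            estimate_group_b=estimate_group_b,
            delta=estimate_group_a - estimate_group_b,
            p_adjusted=p_adjusted,
        )


def aggregate_profiles(dataset: MetricDataset) -> pd.DataFrame:
    """Mean and sample SD (n−1) per group × muscle × metric cell.

    Cells with a single subject report the mean with SD set to NaN
    (undefined, flagged via the ``n`` column).
    """
    grouped = dataset.frame.groupby(["group", "muscle", "metric"], sort=False)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
    return out.reset_index()


def _complete_wide(sub: pd.DataFrame, muscle_order: tuple[str, ...]) -> tuple[pd.DataFrame, pd.Series, int]:
    """Pivot to subjects × muscles, dropping subjects with missing muscles."""
    wide = sub.pivot(index="subject", columns="muscle", values="value")
    missing_muscles = [m for m in muscle_order if m not in wide.columns]
    if missing_muscles:
        raise ModelFitError(
            f"muscle level(s) {missing_muscles} absent from every subject; "
            f"present: {sorted(wide.columns)}"
        )
    wide = wide[list(muscle_order)]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("dropping %d subject(s) with incomplete muscle data", n_dropped)
    groups = sub.drop_duplicates("subject").set_index("subject")["group"]
    return complete, groups.loc[complete.index], n_dropped


def fit_random_block_anova(
    dataset: MetricDataset,
    metric: str,
    alpha: float = 0.05,
) -> AnovaResult:
    """Fit the split-plot (random-block) ANOVA for one metric.

    Fixed effects: group, muscle, group × muscle; random block: subject
    nested within group.  Subjects lacking any muscle are dropped
    listwise for the metric.
    """
    sub = dataset.for_metric(metric)
    wide, subj_groups, n_dropped = _complete_wide(sub, dataset.muscle_order)
    groups = [g for g in dataset.group_order if g in set(subj_groups)]
    if len(groups) < 2:
        raise ModelFitError(f"need at least 2 groups with complete subjects, found {groups}")
    sizes = {g: int((subj_groups == g).sum()) for g in groups}
    deficient = [g for g, n in sizes.items() if n < 2]
    if deficient:
        raise ModelFitError(f"group(s) {deficient} have fewer than 2 complete subjects")

    y = wide.to_numpy(dtype=float)           # subjects × muscles
    glabels = subj_groups.to_numpy()
    n_subj, m = y.shape
    n_groups = len(groups)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[glabels == g].mean() for g in groups])
    ng = np.array([sizes[g] for g in groups], dtype=float)

    # whole-plot stratum (between subjects)
    ss_group = m * float(np.sum(ng * (group_means - grand) ** 2))
    ss_subj = m * float(
        sum(np.sum((subj_means[glabels == g] - group_means[i]) ** 2) for i, g in enumerate(groups))
    )
    df_group = n_groups - 1
    df_subj = n_subj - n_groups

    # split-plot stratum (within subjects)
    cell = np.vstack([y[glabels == g].mean(axis=0) for g in groups])  # groups × muscles
    muscle_means = y.mean(axis=0)
    ss_muscle = n_subj * float(np.sum((muscle_means - grand) ** 2))
    ss_cells = float(np.sum(ng[:, None] * (cell - cell.mean(axis=1, keepdims=True)) ** 2))
    ss_inter = ss_cells - ss_muscle
    df_muscle = m - 1
    df_inter = (n_groups - 1) * (m - 1)

    fitted = cell[[groups.index(g) for g in glabels], :]
    resid = y - subj_means[:, None] - fitted + fitted.mean(axis=1, keepdims=True)
    ss_err = float(np.sum(resid**2))
    df_err = (n_subj - n_groups) * (m - 1)
    if df_err <= 0 or df_subj <= 0:
        raise ModelFitError("not enough subjects/muscles for residual degrees of freedom")

    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err
    if ms_err <= 0 or ms_subj <= 0:
        raise ModelFitError(
            f"zero-variance stratum for metric {metric!r} (MS_subject={ms_subj:.3g}, "
            f"MS_error={ms_err:.3g}); the design is degenerate"
        )

    def term(name: str, ss: float, df_num: float, ms_den: float, df_den: float) -> TermTest:
        f = (ss / df_num) / ms_den
        p = float(sps.f.sf(f, df_num, df_den))
        return TermTest(name=name, f_value=float(f), df_num=df_num, df_den=df_den, p_value=p)

    terms = {
        "group": term("group", ss_group, df_group, ms_subj, df_subj),
        "muscle": term("muscle", ss_muscle, df_muscle, ms_err, df_err),
        "group:muscle": term("group:muscle", max(ss_inter, 0.0), df_inter, ms_err, df_err),
    }
    sigma2_subject = max((ms_subj - ms_err) / m, 0.0)

    return AnovaResult(
        metric=metric,
        terms=terms,
        sigma2_subject=sigma2_subject,
        sigma2_error=ms_err,
        alpha=alpha,
        cell_means=pd.DataFrame(cell, index=groups, columns=list(dataset.muscle_order)),
        group_sizes=sizes,
        ms_subject=ms_subj,
        df_subject=float(df_subj),
        ms_error=ms_err,
        df_error=float(df_err),
        group_order=tuple(groups),
        muscle_order=tuple(dataset.muscle_order),
        n_dropped_subjects=n_dropped,
    )


def simple_main_effects(fit: AnovaResult) -> list[SimpleMainEffectRow]:
    """Group contrast within each muscle, Tukey-adjusted.

    Estimates are the model cell means (equal to observed cell means for
    complete data).  The contrast variance pools whole-plot and
    split-plot mean squares; p-values use the studentized range over the
    full family of group × muscle cell means (Tukey–Kramer), so the
    adjusted p is never below the unadjusted one.
    """
    if len(fit.group_order) != 2:
        raise ModelFitError("simple main effects are defined for exactly 2 groups")
    ga, gb = fit.group_order
    na, nb = fit.group_sizes[ga], fit.group_sizes[gb]
    m = len(fit.muscle_order)
    # Var(cell mean difference) = (sigma2_subj + sigma2_err)(1/na + 1/nb);
    # estimated by S2 = (MS_subj + (m-1) MS_err)/m, a Satterthwaite combination.
    a, b = 1.0 / m, (m - 1.0) / m
    s2 = a * fit.ms_subject + b * fit.ms_error
    df = s2**2 / (
        (a * fit.ms_subject) ** 2 / fit.df_subject + (b * fit.ms_error) ** 2 / fit.df_error
    )
    se = float(np.sqrt(s2 * (1.0 / na + 1.0 / nb)))
    k = len(fit.group_order) * m  # family: all group × muscle cell means

    rows = []
    for muscle in fit.muscle_order:
        est_a = float(fit.cell_means.loc[ga, muscle])
        est_b = float(fit.cell_means.loc[gb, muscle])
        delta = est_a - est_b
        t = delta / se
        p_un = float(2.0 * sps.t.sf(abs(t), df))
        p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        rows.append(
            SimpleMainEffectRow(
                muscle=muscle,
                estimate_group_a=est_a,
                estimate_group_b=est_b,
                delta=delta,
                p_adjusted=min(p_adj, 1.0),
                p_unadjusted=min(p_un, 1.0),
                se=se,
                df=float(df),
            )
        )
    return rows


def simple_main_effects_frame(rows: list[SimpleMainEffectRow], fit: AnovaResult) -> pd.DataFrame:
    """Tabular (report-shaped) view of simple main effect rows."""
    ga, gb = fit.group_order
    return pd.DataFrame(
        {
            "muscle": [r.muscle for r in rows],
            f"estimate_{ga}": [r.estimate_group_a for r in rows],
            f"estimate_{gb}": [r.estimate_group_b for r in rows],
            "delta": [r.delta for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "p_unadjusted": [r.p_unadjusted for r in rows],
        }
    )
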