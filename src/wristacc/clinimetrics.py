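"""Clinimetric validation statistics: convergent validity, reliability,
sensitivity to change.

Convergent validity correlates baseline instrument scores pairwise, choosing
Pearson when both variables pass a Shapiro-Wilk normality gate and Spearman
otherwise, with a Bonferroni-corrected significance threshold for the family
of tests.  Test-retest reliability is an intraclass correlation coefficient,
by default ICC(2,1) — two-way random effects, absolute agreement, single
measure — computed from the ANOVA mean squares; daily measures are split
into the means of days 1-3 and days 4-6 to form the two sessions.  Ordinal
agreement (spinal-level internal rotation) uses a weighted kappa.
Sensitivity to change dichotomizes subjects on the Global Rating of Change
Scale (GRCS >= +4 improved; -4 < GRCS < +4 stable; GRCS <= -4 worsened,
reported but excluded) and computes standardized response means
SRM = |mean change| / SD(change), labelled minimal (<0.2), small (0.2-0.49),
moderate (0.5-0.79) or large (>= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal import InputError

__all__ = [
    "CohortTable",
    "ChangeGroups",
    "ValidationReport",
    "SrmResult",
    "normality_gate",
    "convergent_validity",
    "bonferroni_threshold",
    "test_retest_icc",
    "split_half_daily_icc",
    "weighted_kappa",
    "dichotomize_grcs",
    "srm",
    "srm_label",
    "build_validation_report",
    "TIMEPOINTS",
]

#: canonical visit/week labels, in study order: two preinjection assessments
#: (a week before and immediately before the injection) and two follow-ups
TIMEPOINTS = ("visit0", "visit1", "week2", "week4")

GRCS_IMPROVED_CUT = 4
GRCS_WORSENED_CUT = -4


# ---------------------------------------------------------------------------
# distribution gate and correlation


def normality_gate(x: Sequence[float], alpha: float = 0.05) -> bool:
    """True iff a Shapiro-Wilk test does not reject normality (p >= alpha)."""
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise InputError("normality gate needs at least 3 observations")
    if np.ptp(arr) == 0:
        raise InputError("normality gate undefined for constant input")
    return bool(stats.shapiro(arr).pvalue >= alpha)


def convergent_validity(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    exact_p: bool = False,
) -> tuple[float, float, str, int]:
    """Correlate two paired scores; Pearson if both pass the normality gate,
    Spearman otherwise.

    Missing pairs are deleted pairwise.  Returns ``(r, p, method, n)``.
    With ``exact_p`` and n <= 10 the p-value comes from the exact
    permutation distribution instead of the asymptotic approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InputError(f"need >= 3 complete pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant variable")
    use_pearson = normality_gate(x, alpha) and normality_gate(y, alpha)
    method_kw = {}
    if exact_p and n <= 10:
        method_kw["method"] = stats.PermutationMethod(
            n_resamples=np.inf, rng=np.random.default_rng(0)
        )
    if use_pearson:
        res = stats.pearsonr(x, y, **method_kw)
        method = "pearson"
    else:
        res = stats.spearmanr(x, y)
        method = "spearman"
    return float(res.statistic), float(res.pvalue), method, n


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m for a family of m tests."""
    if m < 1:
        raise InputError("family size m must be >= 1")
    if not (0 < alpha < 1):
        raise InputError("alpha must lie in (0, 1)")
    return alpha / m


# ---------------------------------------------------------------------------
# reliability


def _icc_from_anova(data: np.ndarray, model: str) -> float:
    """Single-measure ICC from the two-way ANOVA mean squares.

    ``data`` is subjects x sessions.  Model '2,1' is two-way random effects,
    absolute agreement; '3,1' is two-way mixed, consistency.
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "2,1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif model == "3,1":
        denom = msr + (k - 1) * mse
    else:
        raise InputError(f"unknown ICC model {model!r}; use '2,1' or '3,1'")
    if denom == 0:
        raise InputError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def test_retest_icc(
    session1: Sequence[float],
    session2: Sequence[float],
    model: str = "2,1",
) -> tuple[float, int]:
    """ICC between two assessment sessions; pairwise deletion of missing.

    Returns the raw coefficient (it may be negative for discordant
    sessions; clip only when reporting) and the number of complete pairs.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise InputError("sessions must be paired")
    keep = np.isfinite(s1) & np.isfinite(s2)
    s1, s2 = s1[keep], s2[keep]
    n = int(s1.size)
    if n < 5:
        raise InputError(f"need >= 5 complete pairs for ICC, have {n}")
    data = np.column_stack([s1, s2])
    if np.ptp(data) == 0:
        raise InputError("zero total variance; ICC undefined")
    return _icc_from_anova(data, model), n


def split_half_daily_icc(
    daily_series: Mapping[object, Sequence[float]],
    model: str = "2,1",
) -> tuple[float, int, int]:
    """Reliability of daily measures from consecutive-day split halves.

    For each subject with >= 6 consecutive daily values, session 1 is the
    mean of days 1-3 and session 2 the mean of days 4-6; the two sessions
    then enter ``test_retest_icc``.  Returns ``(icc, n_included,
    n_excluded)``.
    """
    first, second, excluded = [], [], 0
    for _, series in daily_series.items():
        vals = np.asarray(series, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 6:
            excluded += 1
            continue
        first.append(vals[:3].mean())
        second.append(vals[3:6].mean())
    if len(first) < 5:
        raise InputError(
            f"only {len(first)} subjects have >= 6 daily values "
            f"({excluded} excluded); ICC needs >= 5"
        )
    icc, n = test_retest_icc(first, second, model=model)
    return icc, n, excluded


def weighted_kappa(
    rater1: Sequence[object],
    rater2: Sequence[object],
    categories: Sequence[object] | None = None,
    weights: str = "linear",
) -> float:
    """Weighted kappa for paired ordinal ratings on a shared ladder.

    kappa = 1 - sum(w * observed) / sum(w * expected), with expected cell
    proportions from the marginal products.  Linear disagreement weights by
    default (ordinal vertebral levels are roughly equidistant); quadratic
    via ``weights='quadratic'``.
    """
    r1 = list(rater1)
    r2 = list(rater2)
    if len(r1) != len(r2) or not r1:
        raise InputError("raters must supply paired, nonempty ratings")
    if categories is None:
        categories = sorted(set(r1) | set(r2))
    cats = list(categories)
    if len(set(r1)) == 1 and len(set(r2)) == 1 and r1[0] == r2[0]:
        raise InputError(
            "both raters used a single identical category; "
            "agreement beyond chance is undefined"
        )
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    obs = np.zeros((k, k))
    for a, b in zip(r1, r2):
        obs[index[a], index[b]] += 1
    obs /= obs.sum()
    marg1 = obs.sum(axis=1)
    marg2 = obs.sum(axis=0)
    exp = np.outer(marg1, marg2)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weights == "linear":
        w = np.abs(i - j) / (k - 1)
    elif weights == "quadratic":
        w = ((i - j) / (k - 1)) ** 2
    else:
        raise InputError(f"unknown weights {weights!r}")
    denom = float((w * exp).sum())
    if denom == 0:
        raise InputError("degenerate marginals; kappa undefined")
    return float(1.0 - (w * obs).sum() / denom)


# ---------------------------------------------------------------------------
# sensitivity to change


@dataclass(frozen=True)
class ChangeGroups:
    """GRCS-anchored partition of subjects into change strata."""

    improved: frozenset
    stable: frozenset
    worsened: frozenset


def dichotomize_grcs(grcs: Mapping[object, int]) -> ChangeGroups:
    """Partition subjects on the Global Rating of Change Scale.

    GRCS >= +4 ("moderately better" or more) is improved; -4 < GRCS < +4 is
    stable; GRCS <= -4 is worsened, reported separately and excluded from
    both SRM groups.
    """
    improved, stable, worsened = set(), set(), set()
    for subject, score in grcs.items():
        if not (isinstance(score, (int, np.integer)) and -7 <= score <= 7):
            raise InputError(
                f"GRCS for subject {subject!r} must be an integer in "
                f"[-7, 7], got {score!r}"
            )
        if score >= GRCS_IMPROVED_CUT:
            improved.add(subject)
        elif score <= GRCS_WORSENED_CUT:
            worsened.add(subject)
        else:
            stable.add(subject)
    return ChangeGroups(
        improved=frozenset(improved),
        stable=frozenset(stable),
        worsened=frozenset(worsened),
    )


def srm_label(value: float) -> str:
    """Effect-size band for an SRM magnitude."""
    v = abs(value)
    if v < 0.2:
        return "minimal"
    if v < 0.5:
        return "small"
    if v < 0.8:
        return "moderate"
    return "large"


@dataclass(frozen=True)
class SrmResult:
    srm: float          # magnitude |mean change| / SD(change)
    signed_mean_change: float
    n: int
    label: str


def srm(pre: Sequence[float], post: Sequence[float]) -> SrmResult:
    """Standardized response mean of paired pre/post scores.

    SRM = |mean(post - pre)| / SD(post - pre) with the sample (n-1) SD.
    The magnitude is reported (improvement directions differ across
    instruments); the signed mean change is retained alongside.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise InputError("pre and post must be paired")
    keep = np.isfinite(pre) & np.isfinite(post)
    change = (post - pre)[keep]
    n = int(change.size)
    if n < 2:
        raise InputError(f"SRM needs >= 2 complete pairs, have {n}")
    sd = float(np.std(change, ddof=1))
    if sd == 0:
        if np.mean(change) == 0:
            return SrmResult(0.0, 0.0, n, "minimal")
        raise InputError("zero change-SD with nonzero mean; SRM undefined")
    mean_change = float(np.mean(change))
    value = abs(mean_change) / sd
    return SrmResult(value, mean_change, n, srm_label(value))


# ---------------------------------------------------------------------------
# cohort container and full report


@dataclass
class CohortTable:
    """Subjects x timepoints of instrument scores with GRCS anchors.

    ``scores`` is a wide DataFrame indexed by ``(subject_id, timepoint)``
    with one column per variable; ``grcs`` is indexed by subject with
    integer columns ``grcs_week2`` and ``grcs_week4`` (NaN when missing).
    """

    scores: pd.DataFrame
    grcs: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.scores.index.names) != ["subject_id", "timepoint"]:
            raise InputError(
                "scores must be indexed by (subject_id, timepoint)"
            )
        for col in ("grcs_week2", "grcs_week4"):
            if col not in self.grcs.columns:
                raise InputError(f"grcs table missing column {col!r}")
            vals = self.grcs[col].dropna()
            if ((vals < -7) | (vals > 7)).any():
                raise InputError(f"{col} values outside [-7, 7]")

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.scores.index.get_level_values("timepoint").unique())

    @property
    def variables(self) -> list[str]:
        return list(self.scores.columns)

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        """Wide subject x variable frame at one timepoint."""
        if timepoint not in set(
            self.scores.index.get_level_values("timepoint")
        ):
            raise InputError(f"cohort is missing timepoint {timepoint!r}")
        return self.scores.xs(timepoint, level="timepoint")

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, grcs: pd.DataFrame
    ) -> "CohortTable":
        """Build from a tidy frame with columns
        subject_id, timepoint, variable, value."""
        required = {"subject_id", "timepoint", "variable", "value"}
        if not required.issubset(long.columns):
            raise InputError(
                f"long cohort table needs columns {sorted(required)}"
            )
        wide = long.pivot_table(
            index=["subject_id", "timepoint"],
            columns="variable",
            values="value",
            aggfunc="first",
        )
        wide.columns.name = None
        return cls(scores=wide, grcs=grcs.set_index("subject_id")
                   if "subject_id" in grcs.columns else grcs)


@dataclass
class ValidationReport:
    """The three validation analyses in tabular form."""

    correlations: pd.DataFrame
    icc: pd.DataFrame
    srm: pd.DataFrame
    kappa: pd.DataFrame | None = None
    bonferroni_alpha: float = float("nan")
    n_worsened_excluded: int = 0

    def to_dict(self) -> dict:
        out = {
            "bonferroni_alpha": self.bonferroni_alpha,
            "n_worsened_excluded": self.n_worsened_excluded,
            "correlations": self.correlations.to_dict(orient="records"),
            "icc": self.icc.to_dict(orient="records"),
            "srm": self.srm.to_dict(orient="records"),
        }
        if self.kappa is not None:
            out["kappa"] = self.kappa.to_dict(orient="records")
        return out


def build_validation_report(
    cohort: CohortTable,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    icc_model: str = "2,1",
    baseline_timepoint: str = "visit1",
) -> ValidationReport:
    """Run the full validation battery over a cohort table.

    Convergent validity: all unordered variable pairs at visit0, Pearson or
    Spearman per the normality gate, flagged at the Bonferroni-corrected
    threshold (family size defaults to the number of pairs).  Test-retest:
    ICC per variable between visit0 and visit1.  Sensitivity to change:
    SRMs from the preinjection baseline to week2 and week4 within the
    GRCS-improved and GRCS-stable groups.
    """
    for tp in TIMEPOINTS:
        if tp not in set(
            cohort.scores.index.get_level_values("timepoint")
        ):
            raise InputError(f"cohort is missing timepoint {tp!r}")

    base = cohort.at_timepoint("visit0")
    variables = [v for v in cohort.variables if base[v].notna().sum() >= 3]

    pairs = [
        (variables[i], variables[j])
        for i in range(len(variables))
        for j in range(i + 1, len(variables))
    ]
    m = bonferroni_m if bonferroni_m is not None else max(len(pairs), 1)
    corr_alpha = bonferroni_threshold(alpha, m)
    corr_rows = []
    for vx, vy in pairs:
        try:
            r, p, method, n = convergent_validity(base[vx], base[vy], alpha)
        except InputError:
            continue
        corr_rows.append(
            {
                "var_x": vx, "var_y": vy, "r": r, "p": p,
                "method": method, "n": n,
                "significant": p < corr_alpha,
            }
        )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["var_x", "var_y", "r", "p", "method", "n", "significant"],
    )

    retest = cohort.at_timepoint("visit1")
    icc_rows = []
    for v in variables:
        merged = pd.concat(
            [base[v].rename("s1"), retest[v].rename("s2")], axis=1
        ).dropna()
        try:
            icc_val, n = test_retest_icc(
                merged["s1"], merged["s2"], model=icc_model
            )
        except InputError:
            continue
        icc_rows.append(
            {"variable": v, "icc": icc_val, "model": f"ICC({icc_model})",
             "n": n}
        )
    icc_table = pd.DataFrame(
        icc_rows, columns=["variable", "icc", "model", "n"]
    )

    baseline = cohort.at_timepoint(baseline_timepoint)
    srm_rows = []
    n_worsened = 0
    for week, grcs_col in (("week2", "grcs_week2"), ("week4", "grcs_week4")):
        follow = cohort.at_timepoint(week)
        anchors = cohort.grcs[grcs_col].dropna()
        groups = dichotomize_grcs(
            {s: int(v) for s, v in anchors.items()}
        )
        n_worsened = max(n_worsened, len(groups.worsened))
        for group_name, members in (
            ("improved", groups.improved), ("stable", groups.stable),
        ):
            subjects = [
                s for s in members
                if s in baseline.index and s in follow.index
            ]
            for v in variables:
                pre = baseline.loc[subjects, v]
                post = follow.loc[subjects, v]
                try:
                    res = srm(pre, post)
                except InputError:
                    continue
                srm_rows.append(
                    {
                        "variable": v, "week": week, "group": group_name,
                        "n": res.n, "srm": res.srm,
                        "signed_mean_change": res.signed_mean_change,
                        "label": res.label,
                    }
                )
    srm_table = pd.DataFrame(
        srm_rows,
        columns=[
            "variable", "week", "group", "n", "srm",
            "signed_mean_change", "label",
        ],
    )

    return ValidationReport(
        correlations=correlations,
        icc=icc_table,
        srm=srm_table,
        bonferroni_alpha=corr_alpha,
        n_worsened_excluded=n_worsened,
    )
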