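"""Evaluation harness for the recommender.

For each user the chronologically first ``k`` records train the recommender
and every remaining record tests it.  Efficacy of the algorithmically
selected (AS) sessions — test records whose session is among the top-3
recommendations — is compared against the efficacy of *all* test records
(the user-selected, US, baseline: the user's own choices, deliberately
including any sessions the algorithm would also have chosen).  The harness
provides:

* per-k AS−US efficacy differentials and their linear trend in k,
* a within-subject two-condition ANOVA at a fixed training size
  (for two conditions, F is identically the squared paired t statistic),
* 10-fold cross-validation by re-running the ANOVA on random 80% subsamples
  of users,
* Pearson correlations between the three measure deltas, and
* observed-vs-chance overlap between AS sessions and the sessions the user
  actually completed in the test window, under an exact hypergeometric null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measures import (
    Cohort,
    MeasureSpec,
    SessionLibrary,
    SessionRecord,
    UserHistory,
    deltas_frame,
    get_measure,
    oriented_benefit,
    zscore_within_user,
)
from .recommend import DEFAULT_CONFIG, Recommendation, RecommenderConfig, recommend

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation parameters.

    ``k_range_efficacy`` defaults to 1..18 and ``k_range_overlap`` to 1..25,
    giving the regression degrees of freedom (1, 16) and (2, 22) used in the
    headline analyses.  ``anova_k`` fixes the training size for the paired
    AS-vs-US comparison.  Benefits are z-scored within user x measure by
    default so the differential is comparable across measures.
    """

    k_range_efficacy: tuple[int, ...] = tuple(range(1, 19))
    k_range_overlap: tuple[int, ...] = tuple(range(1, 26))
    anova_k: int = 15
    bootstrap_folds: int = 10
    bootstrap_fraction: float = 0.8
    bootstrap_with_replacement: bool = False
    z_normalize: bool = True
    rng_seed: int = 0


DEFAULT_EVAL_CONFIG = EvalConfig()


@dataclass(frozen=True)
class StatResult:
    """A single inferential result (F/t/r statistic with df and p)."""

    kind: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)


def split_history(
    history: UserHistory, k: int
) -> tuple[list[SessionRecord], list[SessionRecord]]:
    """Chronological train/test split: records 1..k train, k+1..n test."""
    n = len(history)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < {n}, got k={k}")
    records = list(history)
    return records[:k], records[k:]


def user_benefit_series(
    history: UserHistory, measure: MeasureSpec | str, z_normalize: bool = True
) -> np.ndarray:
    """Oriented benefits of all records, optionally z-scored within user."""
    spec = get_measure(measure)
    values = np.array([oriented_benefit(r, spec) for r in history], dtype=float)
    return zscore_within_user(values) if z_normalize else values


@dataclass(frozen=True)
class EfficacyPoint:
    """AS-vs-US efficacy for one user at one training size."""

    user_id: str
    measure: str
    k: int
    as_mean: float
    us_mean: float
    n_as_test: int
    n_test: int

    @property
    def differential(self) -> float:
        return self.as_mean - self.us_mean


def efficacy_point(
    history: UserHistory,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    k: int,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    config: EvalConfig = DEFAULT_EVAL_CONFIG,
    benefits: np.ndarray | None = None,
) -> EfficacyPoint | None:
    """One user's AS-vs-US differential at training size ``k``.

    Returns None when the user cannot contribute: the history is too short
    for the split, or no test record matches an AS session.  Only the train
    split reaches the recommender; test data enter means only.
    """
    spec = get_measure(measure)
    if not 1 <= k < len(history):
        return None
    if benefits is None:
        benefits = user_benefit_series(history, spec, config.z_normalize)
    rec = recommend(history, library, spec, rec_config, k)
    as_set = set(rec.as_sessions)
    test_records = list(history)[k:]
    test_benefits = benefits[k:]
    as_mask = np.array([r.session_id in as_set for r in test_records])
    n_as = int(as_mask.sum())
    if n_as == 0:
        return None
    return EfficacyPoint(
        user_id=history.user_id,
        measure=spec.name,
        k=k,
        as_mean=float(test_benefits[as_mask].mean()),
        us_mean=float(test_benefits.mean()),
        n_as_test=n_as,
        n_test=len(test_records),
    )


@dataclass(frozen=True)
class EfficacyCurve:
    """Cohort efficacy differentials per training size plus linear trend."""

    measure: str
    points: tuple[EfficacyPoint, ...]
    per_k: pd.DataFrame  # columns: k, mean_differential, n_users
    regression: StatResult

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "user_id": p.user_id, "k": p.k, "as_mean": p.as_mean,
                    "us_mean": p.us_mean, "differential": p.differential,
                    "n_as_test": p.n_as_test, "n_test": p.n_test,
                }
                for p in self.points
            ]
        )


def _linear_regression(x: np.ndarray, y: np.ndarray) -> StatResult:
    """OLS slope test: F = t^2 on (1, n-2) df."""
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.allclose(y, y[0]):
        if n >= 3 and np.allclose(y, y[0]):
            # flat response: slope exactly 0, F = 0
            return StatResult("linear_regression", 0.0, (1, n - 2), 1.0)
        return StatResult("linear_regression", float("nan"), (1, max(n - 2, 0)), float("nan"))
    fit = sps.linregress(x, y)
    f = math.inf if fit.stderr == 0 else float((fit.slope / fit.stderr) ** 2)
    return StatResult(
        "linear_regression", f, (1, n - 2), float(fit.pvalue),
        effect_size=float(fit.slope),
    )


def efficacy_curve(
    cohort: Cohort,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    config: EvalConfig = DEFAULT_EVAL_CONFIG,
) -> EfficacyCurve:
    """Per-k cohort mean AS−US differentials and their linear trend in k."""
    spec = get_measure(measure)
    points: list[EfficacyPoint] = []
    for history in cohort.values():
        if len(history) < 2:
            logger.info("user %s skipped: fewer than 2 records", history.user_id)
            continue
        benefits = user_benefit_series(history, spec, config.z_normalize)
        for k in config.k_range_efficacy:
            point = efficacy_point(
                history, library, spec, k, rec_config, config, benefits=benefits
            )
            if point is not None:
                points.append(point)
    frame = pd.DataFrame(
        [{"k": p.k, "differential": p.differential} for p in points]
    )
    if frame.empty:
        per_k = pd.DataFrame(columns=["k", "mean_differential", "n_users"])
    else:
        per_k = (
            frame.groupby("k")["differential"]
            .agg(mean_differential="mean", n_users="count")
            .reset_index()
        )
        per_k = per_k[per_k["n_users"] >= 2].reset_index(drop=True)
    if len(per_k) >= 3:
        regression = _linear_regression(
            per_k["k"].to_numpy(float), per_k["mean_differential"].to_numpy(float)
        )
    else:
        regression = StatResult("linear_regression", float("nan"), (1, 0), float("nan"))
    return EfficacyCurve(
        measure=spec.name, points=tuple(points), per_k=per_k, regression=regression
    )


def paired_comparison(points: Sequence[EfficacyPoint]) -> StatResult:
    """Within-subject two-condition ANOVA of AS vs US efficacy.

    With two conditions the repeated-measures F equals the squared paired t
    statistic on (1, n−1) df.  Effect size is the paired Cohen d,
    mean(diff) / sd(diff).
    """
    diffs = np.array([p.differential for p in points], dtype=float)
    n = len(diffs)
    if n < 2:
        return StatResult("paired_anova", float("nan"), (1, max(n - 1, 0)), float("nan"))
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        d = 0.0 if diffs.mean() == 0 else math.inf
        f = 0.0 if diffs.mean() == 0 else math.inf
        p = 1.0 if diffs.mean() == 0 else 0.0
        return StatResult("paired_anova", f, (1, n - 1), p, effect_size=d)
    t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(
        "paired_anova", float(t * t), (1, n - 1), float(p),
        effect_size=float(diffs.mean() / sd),
    )


def anova_points(
    cohort: Cohort,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    config: EvalConfig = DEFAULT_EVAL_CONFIG,
    user_ids: Sequence[str] | None = None,
) -> list[EfficacyPoint]:
    """Per-user efficacy points at the fixed ANOVA training size."""
    spec = get_measure(measure)
    ids = list(cohort) if user_ids is None else list(user_ids)
    points = []
    for uid in ids:
        history = cohort[uid]
        if len(history) < 2:
            continue
        point = efficacy_point(history, library, spec, config.anova_k, rec_config, config)
        if point is not None:
            points.append(point)
    return points


@dataclass(frozen=True)
class FoldResult:
    stat: StatResult
    mean_differential: float
    n_users: int


@dataclass(frozen=True)
class BootstrapResult:
    """Full-cohort paired comparison plus its 10-fold 80% cross-validation."""

    full: StatResult
    full_mean_differential: float
    folds: tuple[FoldResult, ...]
    agreement: float  # fraction of folds matching the full result's direction


def bootstrap_cv(
    cohort: Cohort,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    config: EvalConfig = DEFAULT_EVAL_CONFIG,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Cross-validate the paired comparison on random 80% user subsamples.

    Each of the ``bootstrap_folds`` folds draws round(fraction * n_users)
    users — without replacement by default — and repeats the identical
    training/testing on the reduced sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    spec = get_measure(measure)
    all_points = anova_points(cohort, library, spec, rec_config, config)
    by_user = {p.user_id: p for p in all_points}
    full = paired_comparison(all_points)
    full_mean = float(np.mean([p.differential for p in all_points])) if all_points else float("nan")
    user_ids = sorted(cohort)
    fold_size = round(config.bootstrap_fraction * len(user_ids))
    folds = []
    n_agree = 0
    for _ in range(config.bootstrap_folds):
        sample = rng.choice(
            user_ids, size=fold_size, replace=config.bootstrap_with_replacement
        )
        points = [by_user[uid] for uid in sample if uid in by_user]
        stat = paired_comparison(points)
        mean_diff = float(np.mean([p.differential for p in points])) if points else float("nan")
        folds.append(FoldResult(stat=stat, mean_differential=mean_diff, n_users=len(points)))
        if math.isfinite(mean_diff) and math.isfinite(full_mean):
            n_agree += int(np.sign(mean_diff) == np.sign(full_mean))
    return BootstrapResult(
        full=full,
        full_mean_differential=full_mean,
        folds=tuple(folds),
        agreement=n_agree / len(folds) if folds else float("nan"),
    )


def delta_correlations(cohort: Cohort) -> pd.DataFrame:
    """3x3 Pearson matrix of the native deltas across all records."""
    frame = deltas_frame(cohort)
    if len(frame) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    deltas = frame[["delta_osl", "delta_srs", "delta_srm"]]
    deltas.columns = ["osl", "srs", "srm"]
    corr = deltas.corr(method="pearson")
    if corr.isna().any().any():
        logger.warning("delta_correlations: zero-variance measure, entries undefined")
    return corr


@dataclass(frozen=True)
class OverlapProbs:
    """Exact hypergeometric chance probabilities of AS/US overlap."""

    pmf: tuple[float, ...]  # P(overlap = 0..a)
    p_ge1: float
    p_ge2: float
    p_eq3: float


def expected_overlap(library_size: int, n_test_distinct: int, n_as: int = 3) -> OverlapProbs:
    """Chance overlap distribution between ``n_as`` AS sessions and a random
    ``n_test_distinct``-subset of an ``library_size``-session library.

    P(overlap = j) = C(a, j) C(L−a, u−j) / C(L, u), computed exactly with
    integer arithmetic.
    """
    L, u, a = library_size, n_test_distinct, n_as
    if not 0 <= u <= L:
        raise ValueError(f"need 0 <= u <= L, got u={u}, L={L}")
    if not 0 <= a <= L:
        raise ValueError(f"need 0 <= a <= L, got a={a}, L={L}")
    denom = math.comb(L, u)
    pmf = []
    for j in range(a + 1):
        if j > u or u - j > L - a:
            pmf.append(0.0)
        else:
            pmf.append(math.comb(a, j) * math.comb(L - a, u - j) / denom)
    tail = [float(sum(pmf[j:])) for j in range(a + 1)]
    return OverlapProbs(
        pmf=tuple(pmf),
        p_ge1=tail[1] if a >= 1 else 0.0,
        p_ge2=tail[2] if a >= 2 else 0.0,
        p_eq3=pmf[3] if a >= 3 else 0.0,
    )


@dataclass(frozen=True)
class OverlapAnalysis:
    """Observed vs chance AS/US overlap across training sizes."""

    measure: str
    points: pd.DataFrame  # per (user, k): observed, u, L, chance probabilities
    per_k: pd.DataFrame   # per k: observed and expected proportions per level
    anova: StatResult     # observed vs expected, paired across users
    quadratic: StatResult  # quadratic trend of observed P(>=1) in k


def _quadratic_regression(x: np.ndarray, y: np.ndarray) -> StatResult:
    import statsmodels.api as sm

    n = len(x)
    if n < 4:
        return StatResult("quadratic_regression", float("nan"), (2, max(n - 3, 0)), float("nan"))
    X = sm.add_constant(np.column_stack([x, x ** 2]))
    fit = sm.OLS(y, X).fit()
    return StatResult(
        "quadratic_regression", float(fit.fvalue), (2, n - 3), float(fit.f_pvalue)
    )


def overlap_analysis(
    cohort: Cohort,
    library: SessionLibrary,
    measure: MeasureSpec | str,
    rec_config: RecommenderConfig = DEFAULT_CONFIG,
    config: EvalConfig = DEFAULT_EVAL_CONFIG,
) -> OverlapAnalysis:
    """Compare observed AS/US overlap against the hypergeometric null.

    Observed overlap for one user at one k = how many of the 3 AS sessions
    (trained on records 1..k) appear among the user's *distinct* test-window
    sessions.  The chance level conditions on the number of distinct test
    sessions u: AS behaving like a random 3-subset of the library.

    The observed-vs-expected ANOVA uses users as the independent unit: each
    user contributes the mean (over k and the three overlap levels) of the
    observed indicator minus its chance probability; a paired comparison of
    those means against zero yields F on (1, n_users − 1) df.  The quadratic
    trend regresses the per-k observed proportion of users with any overlap
    on k and k^2.
    """
    spec = get_measure(measure)
    L = len(library)
    rows = []
    for history in cohort.values():
        records = list(history)
        for k in config.k_range_overlap:
            if not 1 <= k < len(records):
                continue
            rec = recommend(history, library, spec, rec_config, k)
            test_sessions = {r.session_id for r in records[k:]}
            observed = len(set(rec.as_sessions) & test_sessions)
            probs = expected_overlap(L, len(test_sessions), len(rec.as_sessions))
            rows.append(
                {
                    "user_id": history.user_id, "k": k, "observed": observed,
                    "u": len(test_sessions), "L": L,
                    "p_ge1": probs.p_ge1, "p_ge2": probs.p_ge2, "p_eq3": probs.p_eq3,
                }
            )
    points = pd.DataFrame(rows)
    if points.empty:
        empty = StatResult("paired_anova", float("nan"), (1, 0), float("nan"))
        return OverlapAnalysis(spec.name, points, pd.DataFrame(), empty,
                               StatResult("quadratic_regression", float("nan"), (2, 0), float("nan")))
    points["obs_ge1"] = (points["observed"] >= 1).astype(float)
    points["obs_ge2"] = (points["observed"] >= 2).astype(float)
    points["obs_eq3"] = (points["observed"] == 3).astype(float)
    per_k = (
        points.groupby("k")
        .agg(
            observed_ge1=("obs_ge1", "mean"),
            observed_ge2=("obs_ge2", "mean"),
            observed_eq3=("obs_eq3", "mean"),
            expected_ge1=("p_ge1", "mean"),
            expected_ge2=("p_ge2", "mean"),
            expected_eq3=("p_eq3", "mean"),
            n_users=("user_id", "count"),
        )
        .reset_index()
    )
    per_user = points.groupby("user_id").apply(
        lambda g: float(
            (g["obs_ge1"] - g["p_ge1"] + g["obs_ge2"] - g["p_ge2"]
             + g["obs_eq3"] - g["p_eq3"]).mean()
        ),
        include_groups=False,
    )
    anova = _paired_against_zero(per_user.to_numpy(float))
    quad_frame = per_k[per_k["n_users"] >= 2]
    quadratic = _quadratic_regression(
        quad_frame["k"].to_numpy(float), quad_frame["observed_ge1"].to_numpy(float)
    )
    return OverlapAnalysis(spec.name, points, per_k, anova, quadratic)


def _paired_against_zero(diffs: np.ndarray) -> StatResult:
    """Paired ANOVA (F = t^2) of per-unit differences against zero."""
    n = len(diffs)
    if n < 2:
        return StatResult("paired_anova", float("nan"), (1, max(n - 1, 0)), float("nan"))
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        zero = diffs.mean() == 0
        return StatResult(
            "paired_anova", 0.0 if zero else math.inf, (1, n - 1),
            1.0 if zero else 0.0, effect_size=0.0 if zero else math.inf,
        )
    t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(
        "paired_anova", float(t * t), (1, n - 1), float(p),
        effect_size=float(diffs.mean() / sd),
    )
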