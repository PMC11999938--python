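"""Deviation-score assessment of abnormal EMG-force relationships.

A gesture-specific force estimator trained on healthy data is applied to a
new subject's repetitions; the per-repetition force-estimation RMSE (%) is
a deviation score of that subject's EMG-force relationship, and the mean
over repetitions is the subject score.  Group structure (healthy controls
vs cerebral palsy, MACS grade, symptom type, longitudinal tracking) is then
tested with rank-based statistics:

* Mann-Whitney U for two independent groups (exact enumeration for small
  tie-free samples, normal approximation with tie correction otherwise);
* Kruskal-Wallis for three or more independent groups;
* Dunn's post-hoc pairwise z-tests with Bonferroni-adjusted significance
  level 0.05 / C(k, 2) (0.0167 for 3 comparisons, 0.0083 for 6);
* Friedman's test for repeated measures (tie-corrected; a fully tied table
  yields statistic 0, p = 1);
* a Welch t-test utility for interval covariates such as age.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError
from .model import ForceEstimator, predict, rmse
from .preprocess import PreprocessConfig, preprocess_recording
from .sim import Recording


# ---------------------------------------------------------------------------
# deviation scores
# ---------------------------------------------------------------------------

@dataclass
class DeviationScore:
    subject_id: str
    gesture: str
    repetition_rmse: list[float]
    group: str = ""
    macs: int | None = None
    symptom_type: str | None = None

    @property
    def subject_rmse(self) -> float:
        return float(np.mean(self.repetition_rmse))


def subject_deviation(
    model: ForceEstimator,
    recordings: list[Recording],
    cfg: PreprocessConfig | None = None,
) -> DeviationScore:
    """Score one subject's repetitions of one gesture under a trained model.

    Each repetition runs through the full preprocessing chain; its RMSE
    between predicted and measured normalized force is recorded, and the
    subject score is the mean over repetitions.
    """
    if not recordings:
        raise ValidationError("no recordings to score")
    gestures = {r.gesture for r in recordings}
    subjects = {r.subject_id for r in recordings}
    if len(gestures) != 1 or len(subjects) != 1:
        raise ValidationError("recordings must share one subject and one gesture")
    rep_rmse = []
    for rec in recordings:
        samples, _ = preprocess_recording(rec, cfg)
        if len(samples) == 0:
            continue
        y_pred = predict(model, samples)
        rep_rmse.append(rmse(samples.targets, y_pred))
    if not rep_rmse:
        raise ValidationError("no repetition produced any valid window")
    first = recordings[0]
    return DeviationScore(
        subject_id=first.subject_id, gesture=first.gesture,
        repetition_rmse=rep_rmse, group=first.group,
        macs=first.meta.get("macs"), symptom_type=first.meta.get("symptom_type"),
    )


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    adjusted_alpha: float | None = None
    labels: tuple = ()
    extra: dict = field(default_factory=dict)


def mann_whitney_u(scores_a, scores_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two independent groups.

    The reported U counts pairs won by group a.  Exact enumeration is used
    for combined n <= 12 without ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs at least 3 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        test="mann_whitney_u", statistic=float(res.statistic),
        p_value=float(res.pvalue), extra={"method": method},
    )


def kruskal_wallis(groups) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    if len(np.unique(np.concatenate(groups))) == 1:
        raise ValidationError("all observations identical: ranks degenerate")
    res = sstats.kruskal(*groups)
    return GroupComparison(test="kruskal_wallis", statistic=float(res.statistic),
                           p_value=float(res.pvalue))


def dunn_bonferroni(groups, labels=None) -> list[GroupComparison]:
    """Dunn's post-hoc pairwise z-tests on mean ranks after Kruskal-Wallis.

    Uses mid-ranks with the tie-corrected variance; the adjusted
    significance level is 0.05 / C(k, 2) (0.0083 for k = 4 groups).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValidationError("Dunn's test needs at least 3 groups")
    labels = list(labels) if labels is not None else list(range(k))
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sstats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_comparisons = k * (k - 1) // 2
    alpha = 0.05 / n_comparisons
    out = []
    for (i, j) in itertools.combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sstats.norm.sf(abs(z))
        out.append(GroupComparison(
            test="dunn_bonferroni", statistic=float(z), p_value=float(p),
            adjusted_alpha=alpha, labels=(labels[i], labels[j]),
        ))
    return out


def friedman(matrix) -> GroupComparison:
    """Friedman repeated-measures test on a subjects x conditions matrix.

    Mid-ranks within each subject; the tie-corrected statistic follows the
    general form chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 /
    (sum_ij r_ij^2 - n k (k+1)^2 / 4).  A fully tied table gives 0 with
    p = 1 rather than a division by zero.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("friedman expects a 2-D subjects x conditions matrix")
    n, k = x.shape
    if k < 3 or n < 2:
        raise ValidationError("friedman needs >= 3 conditions and >= 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValidationError("friedman does not accept missing cells")
    ranks = np.apply_along_axis(sstats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    numerator = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    denominator = float(np.sum(ranks ** 2)) - n * k * (k + 1) ** 2 / 4.0
    if denominator <= 0:
        return GroupComparison(test="friedman", statistic=0.0, p_value=1.0)
    statistic = numerator / denominator
    p = float(sstats.chi2.sf(statistic, k - 1))
    return GroupComparison(test="friedman", statistic=float(statistic), p_value=p)


def welch_t(a, b) -> GroupComparison:
    """Welch two-sample t-test (covariate checks such as group age)."""
    res = sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return GroupComparison(test="welch_t", statistic=float(res.statistic),
                           p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

GROUPINGS = ("HCvsCP", "MACS", "symptom_type", "tracking")


def _group_key(rec: Recording, grouping: str):
    if grouping == "HCvsCP":
        return rec.group
    if grouping == "MACS":
        return rec.meta.get("macs")
    if grouping == "symptom_type":
        return rec.meta.get("symptom_type")
    if grouping == "tracking":
        return rec.meta.get("timepoint")
    raise ValidationError(f"unknown grouping {grouping!r}")


def cohort_report(
    models: dict[str, ForceEstimator] | ForceEstimator,
    cohort: list[Recording],
    grouping: str = "HCvsCP",
    cfg: PreprocessConfig | None = None,
) -> dict:
    """Score a labeled cohort and run the grouping's statistical scheme.

    ``models`` maps gesture labels to gesture-specific estimators (a single
    estimator is applied to every gesture).  Returns per-subject scores, per
    group summaries (mean, sd, min-max range of subject means) and the
    applicable tests: Mann-Whitney U for two groups, Kruskal-Wallis plus
    Dunn-Bonferroni for three or more.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}")
    by_cell: dict[tuple, list[Recording]] = {}
    for rec in cohort:
        key = _group_key(rec, grouping)
        if key is None:
            raise ValidationError(
                f"recording {rec.subject_id}/{rec.gesture} lacks the "
                f"{grouping} grouping label")
        by_cell.setdefault((rec.subject_id, rec.gesture, key), []).append(rec)

    score_rows = []
    for (subject, gesture, key), recs in sorted(by_cell.items()):
        model = models[gesture] if isinstance(models, dict) else models
        score = subject_deviation(model, recs, cfg)
        score_rows.append({
            "subject": subject, "gesture": gesture, "group": key,
            "rmse": score.subject_rmse, "n_reps": len(score.repetition_rmse),
        })
    scores = pd.DataFrame(score_rows)
    levels = sorted(scores["group"].unique())
    if grouping == "HCvsCP" and len(levels) < 2:
        raise ValidationError("HCvsCP grouping needs both an HC and a CP group")

    summaries = scores.groupby(["group", "gesture"], as_index=False).agg(
        rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"),
        rmse_min=("rmse", "min"), rmse_max=("rmse", "max"),
        n_subjects=("subject", "nunique"),
    )

    tests = []
    for gesture in sorted(scores["gesture"].unique()):
        gs = scores[scores["gesture"] == gesture]
        samples = [gs.loc[gs["group"] == lv, "rmse"].to_numpy() for lv in levels]
        samples = [s for s in samples if len(s)]
        if len(samples) == 2 and all(len(s) >= 3 for s in samples):
            cmp_ = mann_whitney_u(samples[0], samples[1])
            tests.append({"gesture": gesture, **_cmp_dict(cmp_, tuple(levels))})
        elif len(samples) >= 3 and all(len(s) >= 2 for s in samples):
            kw = kruskal_wallis(samples)
            tests.append({"gesture": gesture, **_cmp_dict(kw, tuple(levels))})
            for cmp_ in dunn_bonferroni(samples, labels=levels):
                tests.append({"gesture": gesture, **_cmp_dict(cmp_, cmp_.labels)})
    return {
        "grouping": grouping,
        "scores": scores,
        "summaries": summaries,
        "tests": tests,
    }


def _cmp_dict(cmp_: GroupComparison, labels) -> dict:
    return {
        "test": cmp_.test, "statistic": cmp_.statistic, "p_value": cmp_.p_value,
        "adjusted_alpha": cmp_.adjusted_alpha, "labels": tuple(labels),
    }
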