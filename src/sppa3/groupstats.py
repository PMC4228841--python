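"""Group screening and classification over per-subject cubelet probabilities.

Each subject contributes one probability box per coupling/variant; every
cubelet becomes a candidate index.  Screening compares the per-subject
probabilities of one cubelet between two subject groups with a two-sided
Mann–Whitney U-test and assigns one of three significance tiers:
significant (0.01 ≤ p < 0.05), highly significant (p < 0.01), and the
Bonferroni criterion p < 0.00003 (0.05 over the 1728 cubelets, one
significant figure).  Surviving indices feed a leave-one-out
cross-validated linear (Fisher) discriminant; the held-out scores define a
ROC curve, AUC, and the sensitivity/specificity at the operating point
nearest the ideal (FPR 0, TPR 1) corner.  Index sets of two (one
univariate plus one multivariate candidate) are searched exhaustively.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "GROUP_LABELS",
    "GROUP_TESTS",
    "TIER_NS",
    "TIER_SIGNIFICANT",
    "TIER_HIGHLY",
    "TIER_BONFERRONI",
    "BONFERRONI_P",
    "bonferroni_threshold",
    "GroupTestSpec",
    "group_test",
    "CohortFeatures",
    "ScreeningResult",
    "DiscriminantEvaluation",
    "mann_whitney_u",
    "tier_of",
    "screen_cubelets",
    "count_significant",
    "roc_summary",
    "loocv_discriminant",
    "best_index_search",
]

log = logging.getLogger(__name__)

GROUP_LABELS = ("CON", "PREG", "CH", "PIH", "PE")

TIER_NS = "ns"
TIER_SIGNIFICANT = "significant"
TIER_HIGHLY = "highly"
TIER_BONFERRONI = "bonferroni"
_TIER_ORDER = {TIER_NS: 0, TIER_SIGNIFICANT: 1, TIER_HIGHLY: 2, TIER_BONFERRONI: 3}

#: Bonferroni criterion for 1728 simultaneous cubelet tests, stored as the
#: one-significant-figure constant.
BONFERRONI_P = 0.00003


def bonferroni_threshold(n_tests: int = 1728, alpha: float = 0.05) -> float:
    """alpha/n_tests rounded to one significant figure."""
    x = alpha / n_tests
    return float(round(x, -int(np.floor(np.log10(abs(x))))))


@dataclass(frozen=True)
class GroupTestSpec:
    """One two-group contrast, e.g. test VIII: {CH, PIH} vs {PE}."""

    id: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        for g in self.group_a | self.group_b:
            if g not in GROUP_LABELS:
                raise ValueError(f"unknown group label {g!r}")
        if self.group_a & self.group_b:
            raise ValueError("groups overlap")


#: The ten fixed group contrasts of the screening protocol.
GROUP_TESTS: dict[str, GroupTestSpec] = {
    "I": GroupTestSpec("I", frozenset({"CON"}), frozenset({"PREG"})),
    "II": GroupTestSpec("II", frozenset({"PREG"}), frozenset({"CH"})),
    "III": GroupTestSpec("III", frozenset({"PREG"}), frozenset({"PIH"})),
    "IV": GroupTestSpec("IV", frozenset({"PREG"}), frozenset({"PE"})),
    "V": GroupTestSpec("V", frozenset({"CH"}), frozenset({"PIH"})),
    "VI": GroupTestSpec("VI", frozenset({"CH"}), frozenset({"PE"})),
    "VII": GroupTestSpec("VII", frozenset({"PIH"}), frozenset({"PE"})),
    "VIII": GroupTestSpec("VIII", frozenset({"CH", "PIH"}), frozenset({"PE"})),
    "IX": GroupTestSpec("IX", frozenset({"PREG", "CH", "PIH"}), frozenset({"PE"})),
    "X": GroupTestSpec("X", frozenset({"PREG"}), frozenset({"CH", "PIH", "PE"})),
}


def group_test(test_id: str) -> GroupTestSpec:
    try:
        return GROUP_TESTS[test_id]
    except KeyError:
        raise ValueError(f"unknown group test {test_id!r}") from None


@dataclass
class CohortFeatures:
    """Per-subject cubelet-probability tables for one or more feature sets.

    ``tables[name]`` is a subjects × cubelet-labels DataFrame; ``variants``
    tags each feature set as multivariate (a coupling) or univariate (a lag
    embedding), which the two-index search uses to mix one of each.
    """

    subjects: list[str]
    labels: list[str]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    variants: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.labels):
            raise ValueError("one group label per subject required")
        for lab in self.labels:
            if lab not in GROUP_LABELS:
                raise ValueError(f"unknown group label {lab!r}")

    def add_table(
        self, name: str, frame: pd.DataFrame, variant: str = "multivariate"
    ) -> None:
        if variant not in ("multivariate", "univariate"):
            raise ValueError(f"unknown variant {variant!r}")
        if list(frame.index) != list(self.subjects):
            raise ValueError(f"feature table {name!r} subject index mismatch")
        self.tables[name] = frame
        self.variants[name] = variant

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels)

    def group_mask(self, groups: frozenset[str] | set[str]) -> np.ndarray:
        return np.isin(self.label_array(), sorted(groups))


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact null distribution when min(n) ≤ 8 and there are no ties; normal
    approximation with tie correction and continuity otherwise.  Completely
    tied data (common for empty cubelets) returns p = 1 so empty cubelets
    never look significant.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def tier_of(p: float) -> str:
    if p < BONFERRONI_P:
        return TIER_BONFERRONI
    if p < 0.01:
        return TIER_HIGHLY
    if p < 0.05:
        return TIER_SIGNIFICANT
    return TIER_NS


@dataclass(frozen=True)
class ScreeningResult:
    """Per-cubelet p-values of one group test on one feature set."""

    test: GroupTestSpec
    feature_set: str
    pvalues: pd.Series  # index: cubelet labels

    @property
    def tiers(self) -> pd.Series:
        return self.pvalues.map(tier_of)

    def candidates(self, min_tier: str = TIER_HIGHLY) -> list[str]:
        """Cubelet labels at or beyond ``min_tier``, most significant first."""
        thr = {TIER_SIGNIFICANT: 0.05, TIER_HIGHLY: 0.01, TIER_BONFERRONI: BONFERRONI_P}[
            min_tier
        ]
        sel = self.pvalues[self.pvalues < thr].sort_values(kind="stable")
        return list(sel.index)


def screen_cubelets(
    cohort: CohortFeatures, test: GroupTestSpec, feature_set: str
) -> ScreeningResult:
    """One Mann–Whitney p per cubelet over the per-subject probabilities."""
    frame = cohort.tables[feature_set]
    mask_a = cohort.group_mask(test.group_a)
    mask_b = cohort.group_mask(test.group_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError(f"group test {test.id}: a group has no subjects")
    a = frame.to_numpy(float)[mask_a]
    b = frame.to_numpy(float)[mask_b]

    tied = (a.max(axis=0) == a.min(axis=0)) & (b.max(axis=0) == b.min(axis=0))
    tied &= a[0] == b[0]
    if min(len(a), len(b)) > 8:
        # vectorised asymptotic path; all-tied columns patched to p = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", axis=0
            )
        p = np.where(tied | ~np.isfinite(res.pvalue), 1.0, res.pvalue)
    else:
        p = np.array(
            [mann_whitney_u(a[:, j], b[:, j]) for j in range(a.shape[1])]
        )
    return ScreeningResult(
        test=test,
        feature_set=feature_set,
        pvalues=pd.Series(p, index=frame.columns, name="p"),
    )


def count_significant(result: ScreeningResult, tier: str = TIER_HIGHLY) -> int:
    """Number of cubelets at or beyond the tier (e.g. 'highly' counts p < 0.01)."""
    thr = {
        TIER_SIGNIFICANT: 0.05,
        TIER_HIGHLY: 0.01,
        TIER_BONFERRONI: BONFERRONI_P,
    }.get(tier)
    if thr is None:
        raise ValueError(f"unknown tier {tier!r}")
    return int((result.pvalues < thr).sum())


@dataclass(frozen=True)
class DiscriminantEvaluation:
    """LOOCV discriminant scores and ROC summary for one index (or pair)."""

    indices: tuple[tuple[str, str], ...]  # (feature_set, cubelet label)
    loocv_scores: np.ndarray
    y_true: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float  # percent
    sens: float  # percent
    spec: float  # percent

    @property
    def index_labels(self) -> tuple[str, ...]:
        return tuple(lab for _fs, lab in self.indices)


def roc_summary(
    scores: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """ROC curve over score thresholds; AUC by trapezoid; SENS/SPEC at the
    operating point minimising the Euclidean distance to (FPR 0, TPR 1)."""
    fpr, tpr, _ = roc_curve(y, scores)
    auc_pct = 100.0 * float(_trapezoid_auc(fpr, tpr))
    k = int(np.argmin(np.hypot(fpr, 1.0 - tpr)))
    return fpr, tpr, auc_pct, 100.0 * float(tpr[k]), 100.0 * float(1.0 - fpr[k])


def _fisher_direction(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm Fisher discriminant direction, diagonal fallback if singular."""
    x0, x1 = x[~y], x[y]
    diff = x1.mean(axis=0) - x0.mean(axis=0)
    c0 = x0 - x0.mean(axis=0)
    c1 = x1 - x1.mean(axis=0)
    sw = (c0.T @ c0 + c1.T @ c1) / max(len(x) - 2, 1)
    sw = np.atleast_2d(sw)
    try:
        if np.linalg.cond(sw) > 1e10:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        log.warning("singular within-class covariance; diagonal discriminant used")
        d = np.clip(np.diag(sw), 1e-12, None)
        w = diff / d
    norm = np.linalg.norm(w)
    if norm == 0.0:  # identical class means: direction is arbitrary
        w = np.ones_like(w)
        norm = np.linalg.norm(w)
    return w / norm


def loocv_discriminant(
    features: np.ndarray,
    labels: np.ndarray,
    indices: tuple[tuple[str, str], ...] = (),
) -> DiscriminantEvaluation:
    """Leave-one-out linear discriminant with ROC over the held-out scores.

    For each subject a Fisher discriminant is refit on the remaining
    subjects and the held-out subject's projection onto the (unit-norm)
    discriminant direction is its score.
    """
    x = np.asarray(features, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(bool)
    if x.shape[1] not in (1, 2):
        raise ValueError("1 or 2 features required")
    if min((~y).sum(), y.sum()) < 3:
        raise ValueError("at least 3 subjects per class required")

    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        w = _fisher_direction(x[mask], y[mask])
        scores[i] = float(x[i] @ w)
    fpr, tpr, auc_pct, sens, spec = roc_summary(scores, y)
    return DiscriminantEvaluation(
        indices=tuple(indices),
        loocv_scores=scores,
        y_true=y,
        fpr=fpr,
        tpr=tpr,
        auc=auc_pct,
        sens=sens,
        spec=spec,
    )


def best_index_search(
    cohort: CohortFeatures,
    test: GroupTestSpec,
    screenings: dict[str, ScreeningResult],
    max_pair: bool = False,
    min_tier: str = TIER_HIGHLY,
    all_pairs: bool = False,
) -> list[DiscriminantEvaluation]:
    """Rank screened candidate indices by LOOCV/ROC performance.

    Candidates are the cubelets at or beyond ``min_tier`` in the supplied
    screenings.  With ``max_pair`` every pair mixing one univariate and one
    multivariate candidate is evaluated too (``all_pairs`` lifts the mixing
    restriction).  Ranking: AUC descending, ties broken by SENS+SPEC, then
    lexicographically by label.
    """
    candidates: list[tuple[str, str]] = []
    for fs, sr in screenings.items():
        if sr.test.id != test.id:
            raise ValueError("screening/test mismatch")
        candidates.extend((fs, lab) for lab in sr.candidates(min_tier))
    if not candidates:
        log.warning("no candidate cubelet survives screening for test %s", test.id)
        return []

    mask = cohort.group_mask(test.group_a) | cohort.group_mask(test.group_b)
    y = cohort.group_mask(test.group_b)[mask]

    def column(fs: str, lab: str) -> np.ndarray:
        return cohort.tables[fs][lab].to_numpy(float)[mask]

    evals: list[DiscriminantEvaluation] = []
    for fs, lab in candidates:
        evals.append(
            loocv_discriminant(column(fs, lab), y, indices=((fs, lab),))
        )
    if max_pair:
        uni = [c for c in candidates if cohort.variants.get(c[0]) == "univariate"]
        multi = [c for c in candidates if cohort.variants.get(c[0]) == "multivariate"]
        pairs = (
            itertools.combinations(candidates, 2)
            if all_pairs
            else itertools.product(uni, multi)
        )
        for c1, c2 in pairs:
            feat = np.column_stack([column(*c1), column(*c2)])
            evals.append(loocv_discriminant(feat, y, indices=(c1, c2)))

    evals.sort(
        key=lambda e: (-e.auc, -(e.sens + e.spec), tuple(e.index_labels))
    )
    return evals
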