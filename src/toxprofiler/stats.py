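"""The association battery: two-group tests, binned trends, enrichment scan.

Every comparison in the analysis reduces to one of three primitive tests —
a Wilcoxon rank-sum on a continuous feature between toxic and non-toxic
proteins, a Welch t-test on means, or a Fisher exact test on a 2x2 table —
plus two descriptive devices: equal-frequency binning of a feature with a
linear or quadratic trend fit on the per-bin toxic percentage, and a scan
of functional classes for enrichment/depletion of toxic proteins.

p-values are reported raw (no correction), matching the screen-analysis
convention for a handful of pre-registered comparisons; the enrichment scan
additionally emits Benjamini-Hochberg q-values, clearly separated, for
readers who want them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_io import LabeledCohort

logger = logging.getLogger(__name__)

#: pooled-sample-size threshold below which the rank-sum test is exact
RANK_SUM_EXACT_MAX_N = 12


@dataclass
class TestResult:
    """Outcome of one two-group or 2x2 comparison."""

    test_name: str
    statistic: float
    p_value: float
    group_summaries: tuple[tuple[int, float], ...]
    effect_direction: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class BinProfile:
    """Equal-frequency bin profile of a feature with a fitted trend."""

    feature_name: str
    bin_edges: np.ndarray
    bin_mean_feature: np.ndarray
    bin_n: np.ndarray
    bin_percent_toxic: np.ndarray
    fit_kind: str
    fit_coefficients: np.ndarray  # highest degree first (numpy polyfit order)


@dataclass
class EnrichmentResult:
    """One functional class's toxic-protein enrichment within a cohort."""

    class_id: str
    class_name: str
    n_in_class: int
    n_toxic_in_class: int
    percent_toxic_in_class: float
    background_percent: float
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def _clamp_p(p: float) -> float:
    """Keep p inside (0, 1] when the underlying routine under/overflows."""
    return min(max(float(p), 5e-324), 1.0)


def _direction(a: float, b: float) -> int:
    if math.isnan(a) or math.isnan(b) or a == b:
        return 0
    return 1 if a > b else -1


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for pooled n <= 12, otherwise the normal
    approximation with tie correction.  Group medians are reported;
    effect_direction is the sign of median(a) - median(b).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    # the exact null distribution assumes no ties; with ties fall back to
    # the tie-corrected normal approximation even at small n
    small = a.size + b.size <= RANK_SUM_EXACT_MAX_N
    method = "exact" if small and np.unique(pooled).size == pooled.size else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return TestResult(
        test_name="rank_sum",
        statistic=float(res.statistic),
        p_value=_clamp_p(res.pvalue),
        group_summaries=((a.size, med_a), (b.size, med_b)),
        effect_direction=_direction(med_a, med_b),
    )


def fisher_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's.  The odds ratio is the sample (a*d)/(b*c); division
    by zero yields inf (or nan for 0/0), logged rather than raised.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    (a, b), (c, d) = t
    res = sps.fisher_exact(t, alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
        logger.info("fisher_2x2: zero denominator, odds ratio = %s", odds)
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        test_name="fisher_exact",
        statistic=odds,
        p_value=_clamp_p(res.pvalue),
        group_summaries=((int(a + b), a / (a + b) if a + b else float("nan")),
                         (int(c + d), c / (c + d) if c + d else float("nan"))),
        effect_direction=0 if (math.isnan(odds) or odds == 1) else (1 if odds > 1 else -1),
    )


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Welch two-sided t-test; group means reported.

    Degenerate input (zero variance in both groups with equal means) gives
    t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.std() == 0 and b.std() == 0 and mean_a == mean_b:
        stat, p = 0.0, 1.0
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):
            stat, p = 0.0, 1.0
    return TestResult(
        test_name="welch_t",
        statistic=stat,
        p_value=_clamp_p(p),
        group_summaries=((a.size, mean_a), (b.size, mean_b)),
        effect_direction=_direction(mean_a, mean_b),
    )


def equal_freq_bins(values: Sequence[float], k: int, seed: int = 0) -> np.ndarray:
    """Assign each value to one of ``k`` equal-frequency bins (0..k-1).

    Values are ranked ascending with ties broken by a seeded shuffle
    (stable sort after permutation), then cut into k contiguous groups
    whose sizes differ by at most one.  Deterministic given the seed.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    order = perm[np.argsort(vals[perm], kind="stable")]
    # bin sizes differing by <=1, larger bins first
    base, extra = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:extra] += 1
    assignment = np.empty(n, dtype=int)
    start = 0
    for i, size in enumerate(sizes):
        assignment[order[start : start + size]] = i
        start += size
    return assignment


def bin_toxicity_trend(
    values: Sequence[float],
    toxic_flags: Sequence[bool],
    k: int = 20,
    fit_kind: str = "LINEAR",
    feature_name: str = "feature",
    seed: int = 0,
) -> BinProfile:
    """Per-bin toxic percentage across ``k`` equal-frequency bins of a feature,
    with a least-squares polynomial trend (degree 1 for LINEAR, 2 for
    QUADRATIC) of percent-toxic on the bin-mean feature value.

    The fits are descriptive (plot aids), no inference is attached.
    """
    vals = np.asarray(values, dtype=float)
    flags = np.asarray(toxic_flags, dtype=bool)
    if vals.size != flags.size:
        raise ValueError("toxic_flags must align with values")
    degree = {"LINEAR": 1, "QUADRATIC": 2}.get(fit_kind.upper())
    if degree is None:
        raise ValueError(f"fit_kind must be LINEAR or QUADRATIC, got {fit_kind!r}")
    assignment = equal_freq_bins(vals, k, seed=seed)
    bin_n = np.bincount(assignment, minlength=k)
    bin_mean = np.array([vals[assignment == i].mean() for i in range(k)])
    bin_pct = np.array(
        [100.0 * flags[assignment == i].mean() for i in range(k)]
    )
    sorted_vals = np.sort(vals)
    cuts = np.cumsum(bin_n)[:-1]
    edges = np.concatenate(([sorted_vals[0]], sorted_vals[cuts - 1], [sorted_vals[-1]]))
    coeffs = np.polyfit(bin_mean, bin_pct, degree)
    return BinProfile(
        feature_name=feature_name,
        bin_edges=edges,
        bin_mean_feature=bin_mean,
        bin_n=bin_n,
        bin_percent_toxic=bin_pct,
        fit_kind=fit_kind.upper(),
        fit_coefficients=coeffs,
    )


def class_minus_class(members_a: set[str], members_b: set[str]) -> set[str]:
    """Set difference a \\ b, e.g. regulatory proteins minus transcription
    factors for the TF-excluded enrichment re-run."""
    return set(members_a) - set(members_b)


def enrichment_scan(
    cohort: LabeledCohort,
    class_memberships: Mapping[str, set[str]],
    min_size: int = 200,
    class_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Scan functional classes for enrichment of toxic proteins.

    For every class whose within-cohort membership reaches ``min_size``, a
    Fisher exact test on (in-class vs out-of-class) x (toxic vs non-toxic)
    is computed; results are sorted by p ascending.  The background percent
    is the cohort-wide toxic fraction.  A class identical to the cohort has
    an undefined odds ratio (zero out-of-class margin) and p = 1, logged.
    Benjamini-Hochberg q-values over the scanned classes are attached.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    ids = cohort.ids
    toxic = dict(zip(ids, cohort.toxic_flags))
    n = len(cohort)
    n_toxic = cohort.n_toxic
    background = cohort.percent_toxic
    results: list[EnrichmentResult] = []
    for class_id, members in class_memberships.items():
        in_class = [i for i in ids if i in members]
        k = len(in_class)
        if k < min_size:
            continue
        k_toxic = sum(bool(toxic[i]) for i in in_class)
        table = [
            [k_toxic, k - k_toxic],
            [n_toxic - k_toxic, (n - n_toxic) - (k - k_toxic)],
        ]
        if k == n:
            logger.info("class %s covers the whole cohort; odds ratio undefined", class_id)
            odds, p = float("nan"), 1.0
        else:
            tr = fisher_2x2(table)
            odds, p = tr.statistic, tr.p_value
        results.append(
            EnrichmentResult(
                class_id=class_id,
                class_name=(class_names or {}).get(class_id, class_id),
                n_in_class=k,
                n_toxic_in_class=k_toxic,
                percent_toxic_in_class=100.0 * k_toxic / k,
                background_percent=background,
                odds_ratio=odds,
                p_value=p,
            )
        )
    results.sort(key=lambda r: r.p_value)
    if results:
        _, qvals, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a DataFrame (one row per class)."""
    return pd.DataFrame(
        [
            {
                "class_id": r.class_id,
                "class_name": r.class_name,
                "n_in_class": r.n_in_class,
                "n_toxic_in_class": r.n_toxic_in_class,
                "percent_toxic_in_class": r.percent_toxic_in_class,
                "background_percent": r.background_percent,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
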