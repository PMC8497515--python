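"""Class-discriminative feature screening for pathway and KO tables.

Two screens are provided:

* :func:`lefse_screen` — the multi-class biomarker screen: per-million
  normalization, a tie-corrected Kruskal–Wallis test per feature, and a
  deterministic effect score on the log10 scale.  The effect score is the
  log10 of the largest pairwise difference of class means on the per-million
  scale.  This is a deliberate, documented surrogate for the bootstrapped
  LDA score of the LEfSe tool: it tracks the same quantity (the magnitude of
  the between-class abundance difference) while being deterministic, so the
  conventional thresholds (p < 0.05, score >= 2.0) keep their meaning.
* :func:`welch_two_group` — pairwise comparison of mean percentage
  proportions between two classes with Welch's unequal-variance t-test,
  Welch–Satterthwaite degrees of freedom and a 95% confidence interval for
  the difference, the statistic behind extended-error-bar plots.  No
  multiplicity correction is applied by default; Benjamini–Hochberg is
  available.

For small designs (N <= 12 samples, e.g. 3 classes x 3 replicates) the
Kruskal–Wallis p-value is computed by full enumeration of the exact
permutation distribution, because the chi-square approximation is poor
there; larger designs use the chi-square tail.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .prediction import to_relative_proportions
from .tables import FeatureTable

__all__ = [
    "DifferentialResult",
    "TwoGroupResult",
    "normalize_per_million",
    "kruskal_wallis",
    "kruskal_wallis_permutation",
    "lda_effect_size",
    "lefse_screen",
    "welch_two_group",
]

#: Samples up to which the exact permutation distribution is fully enumerated.
EXACT_ENUMERATION_LIMIT = 12
#: Guard on the number of distinct assignments enumerated.
MAX_ASSIGNMENTS = 500_000

_EFFECT_FLOOR = 1.0  # per-million units below which the effect score is 0


def normalize_per_million(table: FeatureTable) -> FeatureTable:
    """Scale each sample to a total of 1,000,000 (idempotent)."""
    return to_relative_proportions(table, scale=1e6)


def _multinomial_count(sizes: tuple[int, ...]) -> int:
    total = math.factorial(sum(sizes))
    for n in sizes:
        total //= math.factorial(n)
    return total


@lru_cache(maxsize=32)
def _assignment_labels(sizes: tuple[int, ...]) -> np.ndarray:
    """All distinct assignments of N positions into groups of the given sizes,
    as an (n_assignments, N) integer label matrix."""
    n = sum(sizes)
    out: list[list[int]] = []
    labels = [0] * n

    def rec(available: frozenset[int], gi: int) -> None:
        if gi == len(sizes):
            out.append(labels.copy())
            return
        # groups are ordered (one per class label), so plain combinations
        # enumerate each distinct labelled assignment exactly once
        for comb in itertools.combinations(sorted(available), sizes[gi]):
            for i in comb:
                labels[i] = gi
            rec(available - frozenset(comb), gi + 1)

    rec(frozenset(range(n)), 0)
    return np.asarray(out, dtype=np.int64)


def _group_arrays(
    values: Sequence[float], classes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str], tuple[int, ...]]:
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    if values.shape != classes.shape:
        raise ValidationError("values and class labels differ in length")
    labels = sorted(pd.unique(classes).tolist())
    if len(labels) < 2:
        raise ValidationError("at least two classes are required")
    sizes = tuple(int((classes == lab).sum()) for lab in labels)
    if any(s < 2 for s in sizes):
        small = [lab for lab, s in zip(labels, sizes) if s < 2]
        raise ValidationError(f"class(es) with fewer than 2 samples: {small}")
    code = np.searchsorted(np.asarray(labels), classes)
    return values, code, labels, sizes


def _h_statistic(
    ranks: np.ndarray, label_matrix: np.ndarray, sizes: tuple[int, ...], tie_term: float
) -> np.ndarray:
    """Tie-corrected Kruskal–Wallis H for every row of a label matrix."""
    n = ranks.size
    h = np.zeros(label_matrix.shape[0])
    for g, size in enumerate(sizes):
        rg = (label_matrix == g) @ ranks
        h += rg * rg / size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term


def _tie_term(ranks_source: np.ndarray) -> float:
    n = ranks_source.size
    _, counts = np.unique(ranks_source, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))


def kruskal_wallis(
    values: Sequence[float],
    classes: Sequence[str],
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis test.

    Midranks handle ties; the statistic is divided by the usual tie
    correction 1 - sum(t^3 - t)/(N^3 - N).  When all values tie across all
    samples the result is (H=0, p=1).  For N <= ``exact_limit`` the p-value
    is the exact permutation tail P(H >= H_obs) over all distinct
    assignments of the observed values to groups; otherwise the chi-square
    approximation with g - 1 degrees of freedom is used.
    """
    vals, code, _, sizes = _group_arrays(values, classes)
    n = vals.size
    tie = _tie_term(vals)
    if tie <= 0:  # every observation identical
        return 0.0, 1.0
    ranks = stats.rankdata(vals)
    identity = code[np.newaxis, :]
    h_obs = float(_h_statistic(ranks, identity, sizes, tie)[0])
    if n <= exact_limit and _multinomial_count(sizes) <= MAX_ASSIGNMENTS:
        label_matrix = _assignment_labels(sizes)
        h_all = _h_statistic(ranks, label_matrix, sizes, tie)
        p = float((h_all >= h_obs - 1e-12).mean())
    else:
        p = float(stats.chi2.sf(h_obs, df=len(sizes) - 1))
    return h_obs, min(p, 1.0)


def kruskal_wallis_permutation(
    values: Sequence[float],
    classes: Sequence[str],
    n_resamples: int = 9999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo permutation p-value for the Kruskal–Wallis statistic.

    Used as an independent check of the chi-square tail on designs too large
    for full enumeration.  Returns (H, p) with the add-one permutation
    estimator.
    """
    rng = rng or np.random.default_rng()
    vals, code, _, sizes = _group_arrays(values, classes)
    tie = _tie_term(vals)
    if tie <= 0:
        return 0.0, 1.0
    ranks = stats.rankdata(vals)
    h_obs = float(_h_statistic(ranks, code[np.newaxis, :], sizes, tie)[0])
    perms = rng.permuted(np.tile(code, (n_resamples, 1)), axis=1)
    h_perm = _h_statistic(ranks, perms, sizes, tie)
    p = (1.0 + float((h_perm >= h_obs - 1e-12).sum())) / (n_resamples + 1.0)
    return h_obs, min(p, 1.0)


def lda_effect_size(
    table_pm: FeatureTable, classes: pd.Series | None = None
) -> pd.DataFrame:
    """Deterministic effect score per feature on a per-million table.

    Returns a frame indexed by feature id with columns ``effect`` (log10 of
    the largest pairwise class-mean difference, 0 when that difference is
    below one per-million unit), ``assigned_class`` (class attaining the
    maximum mean; lexicographically first on ties) and one ``mean_<class>``
    column per class.
    """
    labels = classes if classes is not None else table_pm.class_labels()
    labels = pd.Series(labels).loc[table_pm.data.index]
    if labels.nunique() < 2:
        raise ValidationError("effect size requires at least two classes")
    class_means = table_pm.data.groupby(labels).mean().sort_index()
    max_diff = class_means.max(axis=0) - class_means.min(axis=0)
    effect = pd.Series(0.0, index=class_means.columns)
    big = max_diff >= _EFFECT_FLOOR
    effect[big] = np.log10(max_diff[big])
    assigned = class_means.idxmax(axis=0)
    out = pd.DataFrame({"effect": effect, "assigned_class": assigned})
    for cls in class_means.index:
        out[f"mean_{cls}"] = class_means.loc[cls]
    return out


@dataclass(frozen=True)
class DifferentialResult:
    """Outcome of the multi-class screen for one feature (per-million scale)."""

    feature_id: str
    class_means: dict[str, float]
    kw_h: float
    p_value: float
    effect_size: float
    assigned_class: str
    significant: bool


def lefse_screen(
    table: FeatureTable,
    classes: pd.Series | None = None,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
) -> list[DifferentialResult]:
    """Multi-class differential screen on a count or abundance table.

    Normalizes samples to per-million, runs the exact/asymptotic
    Kruskal–Wallis test and the deterministic effect score per feature, and
    flags features with p < ``alpha`` and effect >= ``lda_threshold`` as
    significant.  Results are sorted by effect descending, ties broken
    lexicographically by feature id.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if lda_threshold <= 0:
        raise ValidationError(f"lda_threshold must be positive, got {lda_threshold}")
    labels = classes if classes is not None else table.class_labels()
    labels = pd.Series(labels).loc[table.data.index]
    table_pm = normalize_per_million(table)
    effects = lda_effect_size(table_pm, labels)
    results: list[DifferentialResult] = []
    label_values = labels.to_numpy()
    for feature in table_pm.feature_ids:
        values = table_pm.data[feature].to_numpy()
        h, p = kruskal_wallis(values, label_values)
        eff = float(effects.loc[feature, "effect"])
        assigned = str(effects.loc[feature, "assigned_class"])
        means = {
            str(cls): float(effects.loc[feature, f"mean_{cls}"])
            for cls in sorted(labels.unique())
        }
        results.append(
            DifferentialResult(
                feature_id=str(feature),
                class_means=means,
                kw_h=h,
                p_value=p,
                effect_size=eff,
                assigned_class=assigned,
                significant=(p < alpha) and (eff >= lda_threshold),
            )
        )
    results.sort(key=lambda r: (-r.effect_size, r.feature_id))
    return results


@dataclass(frozen=True)
class TwoGroupResult:
    """Welch comparison of one feature's mean percentage proportions."""

    feature_id: str
    mean_a: float
    mean_b: float
    difference: float
    ci_low: float
    ci_high: float
    welch_t: float
    welch_df: float
    p_value: float
    significant: bool
    degenerate: bool = False


def welch_two_group(
    table: FeatureTable,
    class_a: str,
    class_b: str,
    classes: pd.Series | None = None,
    alpha: float = 0.05,
    correction: str = "none",
) -> list[TwoGroupResult]:
    """Welch's t-test per feature between two classes, on percent proportions.

    Each sample is first scaled to a total of 100 so means are percentage
    proportions.  Zero-variance degeneracies: equal means give p = 1;
    unequal means give p = 0 with the ``degenerate`` flag set.  With
    ``correction="bh"`` significance is decided on Benjamini–Hochberg
    adjusted p-values (the reported ``p_value`` stays raw).
    """
    if correction not in ("none", "bh"):
        raise ValidationError(f"correction must be 'none' or 'bh', got {correction!r}")
    labels = classes if classes is not None else table.class_labels()
    labels = pd.Series(labels).loc[table.data.index]
    for cls in (class_a, class_b):
        if (labels == cls).sum() < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 samples")
    table_pct = to_relative_proportions(table, scale=100.0)
    a = table_pct.data.loc[labels[labels == class_a].index]
    b = table_pct.data.loc[labels[labels == class_b].index]
    n_a, n_b = len(a), len(b)
    rows: list[dict] = []
    for feature in table_pct.feature_ids:
        xa = a[feature].to_numpy()
        xb = b[feature].to_numpy()
        m_a, m_b = float(xa.mean()), float(xb.mean())
        v_a, v_b = float(xa.var(ddof=1)), float(xb.var(ddof=1))
        diff = m_a - m_b
        if v_a == 0.0 and v_b == 0.0:
            if diff == 0.0:
                rows.append(
                    dict(feature_id=str(feature), mean_a=m_a, mean_b=m_b,
                         difference=0.0, ci_low=0.0, ci_high=0.0, welch_t=0.0,
                         welch_df=float(n_a + n_b - 2), p_value=1.0, degenerate=False)
                )
            else:
                rows.append(
                    dict(feature_id=str(feature), mean_a=m_a, mean_b=m_b,
                         difference=diff, ci_low=diff, ci_high=diff,
                         welch_t=math.copysign(math.inf, diff),
                         welch_df=float(n_a + n_b - 2), p_value=0.0, degenerate=True)
                )
            continue
        se = math.sqrt(v_a / n_a + v_b / n_b)
        t_stat = diff / se
        df = (v_a / n_a + v_b / n_b) ** 2 / (
            (v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1)
        )
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
        half = float(stats.t.ppf(0.975, df)) * se
        rows.append(
            dict(feature_id=str(feature), mean_a=m_a, mean_b=m_b, difference=diff,
                 ci_low=diff - half, ci_high=diff + half, welch_t=t_stat,
                 welch_df=df, p_value=p, degenerate=False)
        )
    p_raw = np.array([r["p_value"] for r in rows])
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        p_decide = multipletests(p_raw, method="fdr_bh")[1]
    else:
        p_decide = p_raw
    return [
        TwoGroupResult(significant=bool(p_adj < alpha), **row)
        for row, p_adj in zip(rows, p_decide)
    ]
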