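"""Cohort-level biomarker statistics.

The unit of analysis is the per-subject marker count table (long form:
subject, group, marker, value).  This module provides the rank-based AUC,
the exact permutation test on group means, the binomial group-size test,
group-maximum normalization, fold changes, correlations, the enumerative
composite-biomarker search over the grammar {m, m1+m2, m1/m2, (m1+m2)/m3},
two-sample t-test power via the noncentral t distribution, and assay
precision coefficients of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompositeExpression",
    "PowerSpec",
    "auc",
    "permutation_exact_test",
    "binomial_group_size_test",
    "group_max_normalize",
    "evaluate_composite",
    "enumerate_expressions",
    "composite_search",
    "fold_change",
    "correlate",
    "power_two_sample_t",
    "cv_precision",
    "cohort_to_wide",
]


def cohort_to_wide(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-form cohort table to subjects x markers (keeps 'group')."""
    wide = cohort.pivot_table(index=["subject", "group"], columns="marker",
                              values="value", aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC of ``scores`` for the positive class.

    ``labels`` are truthy for disease.  Equals the probability that a random
    disease subject scores above a random control, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # mid-ranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points (threshold, fpr, tpr) over the sorted unique thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & labels).sum() / max(labels.sum(), 1)
        fpr = (pred & ~labels).sum() / max((~labels).sum(), 1)
        rows.append((t, fpr, tpr))
    return pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])


def permutation_exact_test(
    x,
    y,
    two_sided: bool = True,
    max_exact: int = 184756,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> float:
    """Permutation test on the difference of group means.

    All C(n+m, n) relabelings are enumerated when that count does not
    exceed ``max_exact`` (184756 = C(20,10), i.e. exact up to 10 vs 10);
    otherwise a seeded Monte-Carlo estimate over ``n_resamples`` random
    relabelings is used, with the observed statistic included in the
    reference set so p is never zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    obs = x.mean() - y.mean()
    stat = np.abs if two_sided else (lambda v: v)
    obs_stat = stat(obs)
    total = pooled.sum()
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))

    if comb(n + m, n) <= max_exact:
        hits = 0
        count = 0
        idx = np.arange(n + m)
        for chosen in combinations(idx, n):
            sx = pooled[list(chosen)].sum()
            delta = sx / n - (total - sx) / m
            if stat(delta) >= obs_stat - tol:
                hits += 1
            count += 1
        return hits / count

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        delta = perm[:n].mean() - perm[n:].mean()
        if stat(delta) >= obs_stat - tol:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def binomial_group_size_test(n1: int, n2: int) -> float:
    """Two-sided exact binomial test that two group sizes are balanced.

    Tests n1 successes in n1+n2 trials against p0 = 0.5 (e.g. 30 vs 20
    subjects gives p = 0.20).
    """
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("sizes must be non-negative and not both zero")
    return float(stats.binomtest(n1, n1 + n2, 0.5).pvalue)


def group_max_normalize(values, groups) -> np.ndarray:
    """Divide each value by the maximum within its own diagnostic group.

    This is the normalization applied to the denominator marker in ratio
    biomarkers; afterwards each group's maximum equals 1.

    .. warning::
       The scheme uses the subject's own diagnostic label, which leaks
       group membership into the normalized score; downstream AUCs on such
       scores are optimistic.  A warning is emitted on every call.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    warnings.warn(
        "group-max normalization uses diagnostic labels and leaks them "
        "into the normalized scores", stacklevel=2)
    out = np.empty_like(values)
    for g in np.unique(groups):
        sel = groups == g
        gmax = values[sel].max()
        if gmax <= 0:
            raise ValueError(f"group {g!r} has non-positive maximum")
        out[sel] = values[sel] / gmax
    return out


@dataclass(frozen=True)
class CompositeExpression:
    """A composite biomarker formula over marker names.

    ``form`` is one of "m", "m1+m2", "m1/m2", "(m1+m2)/m3"; ``markers``
    supplies the operands in order.  ``normalize_denominator`` applies
    group-max normalization to the denominator marker before division.
    """

    form: str
    markers: tuple[str, ...]
    normalize_denominator: bool = False

    _ARITY = {"m": 1, "m1+m2": 2, "m1/m2": 2, "(m1+m2)/m3": 3}

    def __post_init__(self) -> None:
        if self.form not in self._ARITY:
            raise ValueError(f"unknown form {self.form!r}")
        if len(self.markers) != self._ARITY[self.form]:
            raise ValueError(f"form {self.form!r} takes "
                             f"{self._ARITY[self.form]} markers")
        if self.normalize_denominator and "/" not in self.form:
            raise ValueError("normalize_denominator requires a ratio form")

    def __str__(self) -> str:
        m = self.markers
        base = {"m": lambda: m[0],
                "m1+m2": lambda: f"{m[0]}+{m[1]}",
                "m1/m2": lambda: f"{m[0]}/{m[1]}",
                "(m1+m2)/m3": lambda: f"({m[0]}+{m[1]})/{m[2]}"}[self.form]()
        return base + ("*" if self.normalize_denominator else "")


def evaluate_composite(
    expr: CompositeExpression,
    wide: pd.DataFrame,
) -> np.ndarray:
    """Per-subject scores of a composite expression on a wide cohort table.

    ``wide`` must have one row per subject with marker columns and a
    ``group`` column (needed when the denominator is group-max normalized).
    """
    for mk in expr.markers:
        if mk not in wide.columns:
            raise KeyError(f"marker {mk!r} missing from the cohort")
        bad = wide[wide[mk].isna()]
        if len(bad):
            raise ValueError(
                f"marker {mk!r} missing for subject {bad['subject'].iloc[0]!r}")

    def denom(name: str) -> np.ndarray:
        v = wide[name].to_numpy(dtype=float)
        if expr.normalize_denominator:
            v = group_max_normalize(v, wide["group"].to_numpy())
        if np.any(v == 0):
            raise ZeroDivisionError(f"zero denominator in marker {name!r}")
        return v

    m = expr.markers
    if expr.form == "m":
        return wide[m[0]].to_numpy(dtype=float)
    if expr.form == "m1+m2":
        return wide[m[0]].to_numpy(float) + wide[m[1]].to_numpy(float)
    if expr.form == "m1/m2":
        return wide[m[0]].to_numpy(float) / denom(m[1])
    return (wide[m[0]].to_numpy(float) + wide[m[1]].to_numpy(float)) / denom(m[2])


def enumerate_expressions(
    markers: list[str],
    normalize_denominator: bool = False,
) -> list[CompositeExpression]:
    """Every expression in the composite grammar over the given markers.

    For k markers the count is k singles + C(k,2) sums + k(k-1) ordered
    ratios + 3*C(k,3) sum-ratios (unordered numerator pair, any distinct
    denominator): k + C(k,2) + k(k-1) + C(k,2)*(k-2).
    """
    exprs = [CompositeExpression("m", (mk,)) for mk in markers]
    exprs += [CompositeExpression("m1+m2", pair)
              for pair in combinations(markers, 2)]
    exprs += [CompositeExpression("m1/m2", pair, normalize_denominator)
              for pair in permutations(markers, 2)]
    for pair in combinations(markers, 2):
        for d in markers:
            if d not in pair:
                exprs.append(CompositeExpression(
                    "(m1+m2)/m3", (*pair, d), normalize_denominator))
    return exprs


def composite_search(
    cohort: pd.DataFrame,
    markers: list[str] | None = None,
    *,
    normalize_denominator: bool = False,
    extra_metrics: pd.DataFrame | None = None,
    positive_group: str = "disease",
) -> pd.DataFrame:
    """Enumerate and rank composite biomarkers by AUC.

    Every expression in the grammar over ``markers`` (plus any per-subject
    ``extra_metrics`` columns, e.g. a morphologically distinct fraction) is
    scored per subject and ranked by descending AUC for the positive group,
    with a deterministic lexicographic tie-break on the expression string.
    Expressions whose denominator hits zero are skipped.
    """
    wide = cohort_to_wide(cohort)
    if extra_metrics is not None:
        wide = wide.merge(extra_metrics, on="subject", how="left")
    if markers is None:
        markers = [c for c in wide.columns if c not in ("subject", "group")]
    if len(markers) < 1:
        raise ValueError("need at least one marker")
    labels = wide["group"].to_numpy() == positive_group
    rows = []
    for expr in enumerate_expressions(markers, normalize_denominator):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = evaluate_composite(expr, wide)
        except ZeroDivisionError:
            continue
        rows.append((str(expr), auc(scores, labels)))
    out = pd.DataFrame(rows, columns=["expression", "auc"])
    out = out.sort_values(["auc", "expression"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def fold_change(disease, control) -> dict[str, float]:
    """Disease/control fold change of group means (medians also reported)."""
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if control.mean() <= 0:
        raise ValueError("control mean must be positive")
    result = {"mean_fold": float(disease.mean() / control.mean())}
    med = np.median(control)
    result["median_fold"] = float(np.median(disease) / med) if med > 0 else float("nan")
    return result


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    Pearson for linear dependence; Spearman when the dependence is
    monotone but nonlinear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r.statistic), float(r.pvalue)


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power design point."""

    d_cohen: float = 2.0
    n_per_group: int = 10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.d_cohen < 0:
            raise ValueError("d_cohen must be >= 0")


def power_two_sample_t(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test.

    Uses the noncentral t distribution with noncentrality d*sqrt(n/2) and
    2n-2 degrees of freedom; at d = 2, n = 10/group, alpha = 0.05 the power
    is 0.988 (99% to the nearest percent).
    """
    df = 2 * spec.n_per_group - 2
    nc = spec.d_cohen * np.sqrt(spec.n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = (1.0 - stats.nct.cdf(tcrit, df, nc)
             + stats.nct.cdf(-tcrit, df, nc))
    return float(power)


def cv_precision(measurements: pd.DataFrame) -> dict:
    """Intra- and inter-assay precision as mean coefficients of variation.

    ``measurements`` has columns ``sample, plate, value``.  Intra-assay CV
    averages per-sample CVs of replicates within a plate; inter-assay CV
    averages per-sample CVs of plate means across plates.  Both carry an
    acceptability flag at the 20% bound.
    """
    required = {"sample", "plate", "value"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")

    def cv(v: np.ndarray) -> float:
        if v.mean() == 0:
            raise ValueError("CV undefined for zero mean")
        return 100.0 * v.std(ddof=1) / v.mean() if v.size > 1 else np.nan

    intra = []
    for (_, _), grp in measurements.groupby(["sample", "plate"]):
        v = grp["value"].to_numpy(dtype=float)
        if v.size >= 2:
            intra.append(cv(v))
    inter = []
    for _, grp in measurements.groupby("sample"):
        plate_means = grp.groupby("plate")["value"].mean().to_numpy()
        if plate_means.size >= 2:
            inter.append(cv(plate_means))
    if not intra and not inter:
        raise ValueError("need at least 2 replicates per sample somewhere")
    out = {
        "intra_cv_pct": float(np.mean(intra)) if intra else float("nan"),
        "inter_cv_pct": float(np.mean(inter)) if inter else float("nan"),
    }
    out["acceptable"] = all(np.isnan(v) or v < 20.0
                            for v in (out["intra_cv_pct"], out["inter_cv_pct"]))
    return out
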