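"""Cohort-level nonparametric statistics.

Group comparisons use the two-sided Mann–Whitney U test (95% confidence
level) and associations use Spearman's rank correlation (99% confidence
level), matching common practice for small caries cohorts.  With nine
specimens per group, normal approximations are questionable, so the U test
enumerates all C(n₁+n₂, n₁) group labelings exactly whenever both samples
have at most 10 observations (midranks for ties; the exact p-value is then
invariant under any common monotone transform of the pooled data).  Larger
samples fall back to the tie- and continuity-corrected normal approximation.

Spearman's rho is the Pearson correlation of midranks; its p-value uses the
standard t approximation, with an exact permutation option for n ≤ 9.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedCorrelationError

METRIC_COLUMNS = (
    "ca_loss",
    "mineral_loss",
    "f_uptake_before",
    "f_uptake_after",
    "f_penetration_before",
    "f_penetration_after",
)

#: (x, y, subset) correlation pairs reported by :func:`cohort_report`.
CORRELATION_PAIRS = (
    ("ca_loss", "mineral_loss", "pooled"),
    ("f_uptake_before", "ca_loss", "pooled"),
    ("f_penetration_before", "ca_loss", "pooled"),
    ("f_penetration_before", "ca_loss", "FCM"),
)


@dataclass
class GroupComparison:
    metric: str
    n1: int
    n2: int
    u: float | None
    p_value: float | None
    method: str            # "exact", "normal_approx" or "underpowered"
    alpha: float = 0.05
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and self.significant is None:
            self.significant = bool(self.p_value < self.alpha)


@dataclass
class CorrelationResult:
    x: str
    y: str
    subset: str
    n: int
    rho: float | None
    p_value: float | None
    alpha: float = 0.01
    significant: bool | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.p_value is not None and self.significant is None:
            self.significant = bool(self.p_value < self.alpha)


@lru_cache(maxsize=8)
def _labeling_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index sets of size k from range(n), as an int array."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def exact_mannwhitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of labelings.

    Midranks handle ties; the observed U (of sample ``a``) is compared with
    the permutation distribution of U over every C(n₁+n₂, n₁) assignment of
    the pooled values to group a.  Returns (U, p)."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    combos = _labeling_matrix(n1 + n2, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-12))
    return u_obs, p


def mann_whitney_u(
    a, b, alpha: float = 0.05, method: str = "auto", metric: str = ""
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two independent samples.

    ``method``: "auto" (exact when both n ≤ 10), "exact", or
    "normal_approx" (tie-corrected, continuity-corrected).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("Mann-Whitney requires two non-empty samples")
    use_exact = method == "exact" or (
        method == "auto" and a.size <= 10 and b.size <= 10
    )
    if method not in ("auto", "exact", "normal_approx"):
        raise InputError(f"unknown method {method!r}")
    if use_exact:
        u, p = exact_mannwhitney_p(a, b)
        how = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(min(1.0, res.pvalue))
        how = "normal_approx"
    return GroupComparison(
        metric=metric, n1=int(a.size), n2=int(b.size), u=u, p_value=p,
        method=how, alpha=alpha,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    return float(np.sum(rx * ry) / denom)


def spearman_rho(
    x, y, alpha: float = 0.01, method: str = "t_approx",
    labels: tuple[str, str] = ("x", "y"), subset: str = "pooled",
) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    p-value via the t approximation (default) or exact permutation of the
    rank vector (``method="exact"``, n ≤ 9).  Constant input raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("samples must have equal length")
    n = x.size
    if n < 3:
        raise InputError("Spearman correlation needs n >= 3")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_pearson(rx, ry)
    if method == "exact":
        if n > 9:
            raise InputError("exact permutation p limited to n <= 9")
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = np.sqrt(np.sum(rxc**2) * np.sum(ryc**2))
        rho_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    elif method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    else:
        raise InputError(f"unknown method {method!r}")
    return CorrelationResult(
        x=labels[0], y=labels[1], subset=subset, n=n, rho=rho,
        p_value=min(1.0, p), alpha=alpha,
    )


@dataclass
class CohortReport:
    """Machine-readable cohort summary: per-group medians and min~max
    ranges, FCM-vs-control U tests per metric, and the standard correlation
    panel.  ``underpowered`` is set when a group has fewer than two
    specimens, in which case tests are flagged rather than computed."""

    n_fcm: int
    n_control: int
    group_summaries: dict
    comparisons: list[GroupComparison]
    correlations: list[CorrelationResult]
    underpowered: bool = False
    alpha_comparison: float = 0.05
    alpha_correlation: float = 0.01

    def to_dict(self) -> dict:
        return {
            "n_fcm": self.n_fcm,
            "n_control": self.n_control,
            "underpowered": self.underpowered,
            "alpha_comparison": self.alpha_comparison,
            "alpha_correlation": self.alpha_correlation,
            "group_summaries": self.group_summaries,
            "comparisons": [vars(c).copy() for c in self.comparisons],
            "correlations": [vars(c).copy() for c in self.correlations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortReport":
        return cls(
            n_fcm=d["n_fcm"],
            n_control=d["n_control"],
            underpowered=d["underpowered"],
            alpha_comparison=d["alpha_comparison"],
            alpha_correlation=d["alpha_correlation"],
            group_summaries=d["group_summaries"],
            comparisons=[GroupComparison(**c) for c in d["comparisons"]],
            correlations=[CorrelationResult(**c) for c in d["correlations"]],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def comparison(self, metric: str) -> GroupComparison:
        for c in self.comparisons:
            if c.metric == metric:
                return c
        raise KeyError(metric)

    def correlation(self, x: str, y: str, subset: str = "pooled") -> CorrelationResult:
        for c in self.correlations:
            if (c.x, c.y, c.subset) == (x, y, subset):
                return c
        raise KeyError((x, y, subset))


def cohort_report(
    metrics: pd.DataFrame,
    alpha_comparison: float = 0.05,
    alpha_correlation: float = 0.01,
) -> CohortReport:
    """Summarise a cohort metrics table (one row per specimen).

    Required columns: ``group`` plus the metric columns (``mineral_loss``
    optional).  Medians and ranges are reported per group; each metric is
    compared FCM vs control by Mann–Whitney U; the correlation panel covers
    (ca_loss, mineral_loss), (f_uptake_before, ca_loss),
    (f_penetration_before, ca_loss) pooled, and the FCM-only
    (f_penetration_before, ca_loss).
    """
    required = {"group", *(c for c in METRIC_COLUMNS if c != "mineral_loss")}
    missing = sorted(required - set(metrics.columns))
    if missing:
        raise InputError(f"metrics table missing columns: {', '.join(missing)}")
    available = [c for c in METRIC_COLUMNS if c in metrics.columns
                 and metrics[c].notna().any()]
    groups = {g: metrics[metrics["group"] == g] for g in ("FCM", "control")}
    n_fcm, n_control = len(groups["FCM"]), len(groups["control"])
    underpowered = min(n_fcm, n_control) < 2

    summaries: dict[str, dict] = {}
    for col in available:
        summaries[col] = {}
        for g, df in groups.items():
            vals = df[col].dropna().to_numpy(dtype=float)
            summaries[col][g] = {
                "n": int(vals.size),
                "median": float(np.median(vals)) if vals.size else None,
                "min": float(vals.min()) if vals.size else None,
                "max": float(vals.max()) if vals.size else None,
            }

    comparisons: list[GroupComparison] = []
    for col in available:
        a = groups["FCM"][col].dropna().to_numpy(dtype=float)
        b = groups["control"][col].dropna().to_numpy(dtype=float)
        if underpowered or a.size < 2 or b.size < 2:
            comparisons.append(GroupComparison(
                metric=col, n1=int(a.size), n2=int(b.size), u=None,
                p_value=None, method="underpowered", alpha=alpha_comparison,
            ))
        else:
            comparisons.append(
                mann_whitney_u(a, b, alpha=alpha_comparison, metric=col)
            )

    correlations: list[CorrelationResult] = []
    for xcol, ycol, subset in CORRELATION_PAIRS:
        if xcol not in available or ycol not in available:
            continue
        df = metrics if subset == "pooled" else groups[subset]
        sub = df[[xcol, ycol]].dropna()
        x = sub[xcol].to_numpy(dtype=float)
        y = sub[ycol].to_numpy(dtype=float)
        if x.size < 3:
            correlations.append(CorrelationResult(
                x=xcol, y=ycol, subset=subset, n=int(x.size), rho=None,
                p_value=None, alpha=alpha_correlation, note="underpowered",
            ))
            continue
        try:
            correlations.append(spearman_rho(
                x, y, alpha=alpha_correlation, labels=(xcol, ycol),
                subset=subset,
            ))
        except UndefinedCorrelationError:
            correlations.append(CorrelationResult(
                x=xcol, y=ycol, subset=subset, n=int(x.size), rho=None,
                p_value=None, alpha=alpha_correlation,
                note="undefined (constant input)",
            ))

    return CohortReport(
        n_fcm=n_fcm,
        n_control=n_control,
        group_summaries=summaries,
        comparisons=comparisons,
        correlations=correlations,
        underpowered=underpowered,
        alpha_comparison=alpha_comparison,
        alpha_correlation=alpha_correlation,
    )
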