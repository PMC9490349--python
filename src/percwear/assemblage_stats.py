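"""Descriptive and nonparametric inferential statistics for assemblages.

The comparisons mirror standard practice for small archaeological samples:
min/max/mean/sample-s.d. blocks, Mann–Whitney U (exact for small untied
samples, tie-corrected normal approximation otherwise), Kruskal–Wallis with
tie correction, Dunn's post hoc z tests under Bonferroni, and PCA on the
correlation matrix of the mixed-unit damage variables.  Significance is
assessed at alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SchemaError

ALPHA = 0.05

#: the damage-pattern variable set used for assemblage comparison and PCA
COMPARISON_VARIABLES = [
    "n_use_wear", "pa_percent", "density_per_cm2",
    "dac_min_mm", "dac_mean_mm", "dac_max_mm",
    "dae_min_mm", "dae_mean_mm", "dae_max_mm",
]


@dataclass
class GroupComparisonResult:
    """One statistical comparison between groups."""

    test: str                        # mann_whitney_u | kruskal_wallis | dunn
    statistic: float                 # U, H or z
    p: float
    groups: dict[str, int]           # label -> n
    df: int | None = None            # KW only
    correction: str = "none"
    alpha: float = ALPHA
    variable: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


@dataclass
class PCAResult:
    scores: np.ndarray               # observations × components
    loadings: np.ndarray             # variables × components, orthonormal
    percent_variance: np.ndarray
    variables: list[str]
    labels: list | None = None


def describe_distribution(values) -> tuple[float, float, float, float]:
    """(min, max, mean, sample s.d.).  The s.d. uses the n−1 denominator and
    is NaN for a single observation."""
    v = np.asarray([x for x in np.asarray(values, dtype=float)
                    if np.isfinite(x)])
    if v.size == 0:
        raise ParameterError("describe_distribution needs at least one value")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else np.nan
    return float(v.min()), float(v.max()), float(v.mean()), sd


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(a, b, method: str = "auto") -> GroupComparisonResult:
    """Two-sided Mann–Whitney U test.

    U is reported as min(U1, U2); both are kept in ``extras``.  The p-value
    is exact (full null distribution) when the pooled sample has at most 12
    untied observations, otherwise it comes from the normal approximation
    with tie-corrected variance and continuity correction.  ``method`` can
    force "exact" or "asymptotic".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if method == "auto":
        method = ("exact" if (n1 + n2 <= 12 and not _has_ties(pooled))
                  else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    return GroupComparisonResult(
        test="mann_whitney_u", statistic=min(u1, u2), p=float(res.pvalue),
        groups={"a": n1, "b": n2},
        extras={"U1": u1, "U2": u2, "method": method})


def kruskal_wallis(groups: list) -> GroupComparisonResult:
    """Kruskal–Wallis rank test over two or more groups.

    H is the rank-sum statistic divided by the tie-correction factor
    1 − Σ(t³−t)/(N³−N); p from the chi-square upper tail on k−1 df.
    """
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ParameterError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ParameterError("all values identical: H undefined under ties")
    H, p = stats.kruskal(*arrays)
    return GroupComparisonResult(
        test="kruskal_wallis", statistic=float(H), p=float(p),
        df=len(groups) - 1,
        groups={f"g{i+1}": len(g) for i, g in enumerate(arrays)})


def dunn_posthoc(groups: list, labels: list[str] | None = None,
                 correction: str = "bonferroni") -> list[GroupComparisonResult]:
    """Dunn's pairwise post hoc z tests after Kruskal–Wallis.

    For groups i, j:  z = (mean rank_i − mean rank_j) /
    sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) · (1/n_i + 1/n_j)].
    Two-sided p, Bonferroni-adjusted by m = k(k−1)/2 (capped at 1).
    """
    k = len(groups)
    if k < 3:
        raise ParameterError("Dunn's test needs ≥3 groups; "
                             "use mann_whitney_u for two")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i+1}" for i in range(k)]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_un = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, m * p_un) if correction == "bonferroni" else p_un
            out.append(GroupComparisonResult(
                test="dunn", statistic=float(z), p=float(p_adj),
                groups={labels[i]: sizes[i], labels[j]: sizes[j]},
                correction=correction,
                extras={"p_unadjusted": float(p_un), "m": m,
                        "pair": (labels[i], labels[j])}))
    return out


def run_pca(table: pd.DataFrame, standardize: bool = True,
            labels: list | None = None) -> PCAResult:
    """PCA of an observations × variables table.

    By default on the correlation matrix (each variable scaled to unit
    sample variance — the damage variables mix counts, percentages and mm);
    ``standardize=False`` gives covariance PCA.  Rows with missing values
    are dropped.  Component signs are fixed so the largest-magnitude loading
    of each component is positive.
    """
    table = pd.DataFrame(table)
    if table.shape[1] < 2:
        raise ParameterError("PCA needs at least 2 variables")
    keep = table.notna().all(axis=1)
    if labels is not None:
        labels = [l for l, k in zip(labels, keep) if k]
    dropped = int((~keep).sum())
    X = table.loc[keep].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ParameterError("PCA needs at least 3 complete observations")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if len(zero):
            raise ParameterError(
                "zero-variance variable(s) under standardization: "
                + ", ".join(str(table.columns[z]) for z in zero))
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (X.shape[0] - 1)
    loadings = vt.T
    # sign convention: largest-magnitude loading of each component positive
    for c in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, c])), c] < 0:
            loadings[:, c] *= -1
    scores = Xc @ loadings
    pct = 100.0 * eigvals / eigvals.sum()
    res = PCAResult(scores=scores, loadings=loadings, percent_variance=pct,
                    variables=list(table.columns), labels=labels)
    res.n_dropped = dropped
    return res


def compare_assemblages(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        variables: list[str] | None = None,
                        label_a: str = "A", label_b: str = "B",
                        ) -> tuple[list[GroupComparisonResult], PCAResult]:
    """Variable-by-variable Mann–Whitney comparison of two per-tool summary
    tables plus a pooled PCA with group labels carried into the scores."""
    if variables is None:
        variables = COMPARISON_VARIABLES
    for tbl, name in ((table_a, "table_a"), (table_b, "table_b")):
        if len(tbl) == 0:
            raise ParameterError(f"{name} is empty")
        missing = [v for v in variables if v not in tbl.columns]
        if missing:
            raise SchemaError(f"{name} lacks column(s): {', '.join(missing)}")
    results = []
    for v in variables:
        a = table_a[v].dropna().to_numpy(dtype=float)
        b = table_b[v].dropna().to_numpy(dtype=float)
        r = mann_whitney_u(a, b)
        r.variable = v
        r.groups = {label_a: len(a), label_b: len(b)}
        results.append(r)
    pooled = pd.concat([table_a[variables], table_b[variables]],
                       ignore_index=True)
    labels = [label_a] * len(table_a) + [label_b] * len(table_b)
    pca = run_pca(pooled, standardize=True, labels=labels)
    return results, pca


def comparison_report(results: list[GroupComparisonResult]) -> pd.DataFrame:
    """Tabular report of a list of comparisons (one row per test)."""
    rows = []
    for r in results:
        rows.append({
            "measure": r.variable or "", "test": r.test,
            "statistic": r.statistic, "df": r.df, "p_value": r.p,
            "significant": r.significant, "correction": r.correction,
            "groups": ";".join(f"{k}={v}" for k, v in r.groups.items()),
        })
    return pd.DataFrame(rows)
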