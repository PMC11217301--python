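"""Group comparison protocol: normality-gated tests with covariate control.

The comparison of a scalar measure between two groups follows a fixed
protocol: both samples are screened for normality with the Jarque-Bera
test and the D'Agostino-Pearson omnibus test; if every screen passes
(at alpha = 0.05 by default) the groups are compared with an unpaired
pooled-variance t-test, otherwise with the Wilcoxon rank-sum test
(normal approximation with tie correction).  For region-wise scores,
age and sex are first regressed out of the pooled sample by ordinary
least squares and Benjamini-Hochberg q-values are appended across
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CovariateTable

__all__ = [
    "GroupComparisonResult",
    "RegionwiseReport",
    "normality_gate",
    "compare_groups",
    "residualize",
    "regionwise_compare",
]

_MIN_N_NORMALITY = 8


@dataclass
class GroupComparisonResult:
    measure: str
    test_used: str  # "t-test" or "rank-sum"
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_medians: tuple[float, float]
    n_per_group: tuple[int, int]
    parametric_gate: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.test_used not in ("t-test", "rank-sum"):
            raise ValueError(f"unknown test: {self.test_used}")

    def to_summary_dict(self) -> dict:
        return {
            "measure": self.measure,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_means": list(self.group_means),
            "group_medians": list(self.group_medians),
            "n_per_group": list(self.n_per_group),
            "parametric_gate": self.parametric_gate,
        }


@dataclass
class RegionwiseReport:
    """Per-region statistics with BH-FDR q-values appended."""

    table: pd.DataFrame  # columns: region, statistic, p_value, fdr_q
    covariates_removed: list[str]


def _passes_normality(x: np.ndarray, alpha: float, rule: str) -> bool:
    jb_p = stats.jarque_bera(x).pvalue
    dp_p = stats.normaltest(x).pvalue
    if rule == "both":
        return bool(jb_p > alpha and dp_p > alpha)
    return bool(jb_p > alpha or dp_p > alpha)


def normality_gate(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05, rule: str = "both"
) -> bool:
    """True (parametric path) iff both samples look normal on both screens.

    ``rule="either"`` relaxes the combination so one passing screen per
    sample suffices.  Samples smaller than 8 cannot be screened; the
    gate then returns False (nonparametric path) with a warning.
    """
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < _MIN_N_NORMALITY:
        warnings.warn(
            "sample too small for normality screening; using nonparametric path",
            stacklevel=2,
        )
        return False
    return _passes_normality(x, alpha, rule) and _passes_normality(y, alpha, rule)


def compare_groups(
    x: np.ndarray, y: np.ndarray, gate: bool, measure: str = "measure"
) -> GroupComparisonResult:
    """Two-sided two-sample comparison on the path selected by the gate.

    Parametric path: unpaired pooled-variance t-test.  Nonparametric
    path: Wilcoxon rank-sum via the Mann-Whitney U statistic with
    tie-corrected normal approximation.  Zero pooled variance under the
    t-test falls back to the nonparametric path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([x, y])
    if pooled.std() == 0:
        # no variation at all: no evidence against the null on either path
        return GroupComparisonResult(
            measure=measure,
            test_used="rank-sum",
            statistic=float(x.size * y.size / 2),
            p_value=1.0,
            group_means=(float(x.mean()), float(y.mean())),
            group_medians=(float(np.median(x)), float(np.median(y))),
            n_per_group=(x.size, y.size),
            parametric_gate=gate,
        )
    use_t = gate
    if use_t:
        res = stats.ttest_ind(x, y, equal_var=True)
        test_used, stat, p = "t-test", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        test_used, stat, p = "rank-sum", float(res.statistic), float(res.pvalue)
    return GroupComparisonResult(
        measure=measure,
        test_used=test_used,
        statistic=stat,
        p_value=min(p, 1.0),
        group_means=(float(x.mean()), float(y.mean())),
        group_medians=(float(np.median(x)), float(np.median(y))),
        n_per_group=(x.size, y.size),
        parametric_gate=gate,
    )


def _design_matrix(covariates: CovariateTable) -> tuple[np.ndarray, list[str]]:
    tab = covariates.table
    cols: list[np.ndarray] = [np.ones(len(tab))]
    names = ["intercept"]
    cols.append(tab["age"].to_numpy(dtype=float))
    names.append("age")
    sex_levels = sorted(tab["sex"].astype(str).unique())
    if len(sex_levels) == 1:
        warnings.warn(
            "dropping collinear covariate column 'sex' (single level)",
            stacklevel=3,
        )
    for level in sex_levels[1:]:  # first level is the reference
        cols.append((tab["sex"].astype(str) == level).to_numpy(dtype=float))
        names.append(f"sex[{level}]")
    X = np.column_stack(cols)
    # drop collinear / constant columns beyond the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear covariate column {names[j]!r}", stacklevel=3
            )
    return X[:, keep], [names[j] for j in keep]


def residualize(
    values: np.ndarray, covariates: CovariateTable
) -> tuple[np.ndarray, list[str]]:
    """OLS residuals of ``values`` on intercept + age + sex indicators.

    Values must be ordered like the covariate table rows (the pooled
    two-group sample).  Returns the residuals and the covariate columns
    actually used (collinear columns are dropped with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(covariates):
        raise ValueError(
            f"{values.size} values for {len(covariates)} covariate rows"
        )
    X, names = _design_matrix(covariates)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta, names[1:]


def regionwise_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    covariates: CovariateTable,
    region_names: list[str] | None = None,
    alpha: float = 0.05,
) -> RegionwiseReport:
    """Per-region group comparison of residualized scores with BH-FDR.

    ``scores_a`` / ``scores_b`` are regions x subjects matrices for the
    two groups, rows aligned on the same region set; the covariate table
    holds group A's subjects first, then group B's.  Each region's
    pooled scores are residualized on age and sex, then compared with an
    unpaired t-test; q-values are Benjamini-Hochberg across regions.
    """
    scores_a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    scores_b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if scores_a.shape[0] != scores_b.shape[0]:
        raise ValueError(
            f"region mismatch: {scores_a.shape[0]} vs {scores_b.shape[0]} rows"
        )
    n_regions = scores_a.shape[0]
    n_a, n_b = scores_a.shape[1], scores_b.shape[1]
    if n_a + n_b != len(covariates):
        raise ValueError("covariate table does not cover all subjects")
    if region_names is None:
        region_names = [f"region_{i}" for i in range(n_regions)]

    stats_out = np.empty(n_regions)
    pvals = np.empty(n_regions)
    removed: list[str] = []
    for i in range(n_regions):
        pooled = np.concatenate([scores_a[i], scores_b[i]])
        resid, removed = residualize(pooled, covariates)
        res = compare_groups(
            resid[:n_a], resid[n_a:], gate=True, measure=region_names[i]
        )
        stats_out[i] = res.statistic
        pvals[i] = res.p_value
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame(
        {
            "region": region_names,
            "statistic": stats_out,
            "p_value": pvals,
            "fdr_q": qvals,
        }
    )
    return RegionwiseReport(table=table, covariates_removed=removed)
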