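"""Group statistics: two-sample t-tests, pooled SEM, Pearson correlations.

Conventions follow the study's reporting style: two-tailed pooled-variance
Student's t-tests per variable (Welch selectable), no multiple-testing
correction, and a single "pooled SEM" column per comparison.  Two pooled-SEM
conventions circulate in animal-science tables; both are reported:

``pooled_sem``
    sqrt(sp^2 * (1/n_a + 1/n_b)) — the pooled standard error of the group
    DIFFERENCE.  This is the headline value: it reproduces the printed
    p-values of the reference tables from their means and pooled SEMs.
``pooled_sem_group``
    sqrt(sp^2 * (1/n_a + 1/n_b) / 2) — a per-group-mean standard error on
    the pooled variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, UndefinedCorrelationError


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    pooled_sem: float          # SE of the difference on the pooled variance
    pooled_sem_group: float    # per-group-mean SE on the pooled variance
    t_stat: float
    df: int
    p_value: float
    variant: str = "pooled"
    flags: tuple = field(default=())


def students_t(values_a, values_b, variant: str = "pooled",
               variable: str = "") -> GroupComparison:
    """Two-sample two-tailed t-test on raw per-animal values.

    ``variant="pooled"`` (default) assumes equal variances; ``"welch"`` does
    not.  Degenerate inputs: two zero-variance samples with equal means give
    t = 0, p = 1; zero variance with unequal means is flagged
    ``degenerate-sample`` with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ConfigError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ConfigError(f"unknown t-test variant {variant!r}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
    se_diff = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    flags = []
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf, 0.0
            flags.append("degenerate-sample")
    else:
        res = sps.ttest_ind(b, a, equal_var=(variant == "pooled"))
        t, p = float(res.statistic), float(res.pvalue)
        df = int(round(res.df)) if variant == "welch" else df
    return GroupComparison(
        variable=variable, mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=n_a, n_b=n_b, pooled_sem=float(se_diff),
        pooled_sem_group=float(se_diff / np.sqrt(2)), t_stat=t, df=df,
        p_value=p, variant=variant, flags=tuple(flags))


def t_from_summary(mean_a: float, sem_a: float, n_a: int,
                   mean_b: float, sem_b: float, n_b: int,
                   variable: str = "") -> GroupComparison:
    """t-test from published summary statistics (group means and SEMs).

    t = (mean_b - mean_a) / sqrt(sem_a^2 + sem_b^2), df = n_a + n_b - 2,
    two-tailed p.  Used to audit printed tables where only summaries exist.
    """
    if sem_a <= 0 or sem_b <= 0:
        raise ConfigError("SEMs must be > 0")
    if n_a < 2 or n_b < 2:
        raise ConfigError("each group needs at least 2 animals")
    se = np.sqrt(sem_a ** 2 + sem_b ** 2)
    t = (mean_b - mean_a) / se
    df = n_a + n_b - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        variable=variable, mean_a=mean_a, mean_b=mean_b, n_a=n_a, n_b=n_b,
        pooled_sem=float(se), pooled_sem_group=float(se / np.sqrt(2)),
        t_stat=float(t), df=df, p_value=float(p), variant="summary")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-tailed p-values."""

    variables: tuple
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def annotated(self) -> pd.DataFrame:
        """r values with significance stars (* p<0.05, ** p<0.01)."""
        out = self.r.round(2).astype(str)
        for i in self.variables:
            for j in self.variables:
                if i == j:
                    continue
                stars = ("**" if self.p.loc[i, j] < 0.01
                         else "*" if self.p.loc[i, j] < 0.05 else "")
                out.loc[i, j] = f"{self.r.loc[i, j]:.2f}{stars}"
        return out


def pearson_matrix(table: pd.DataFrame, variables=None) -> CorrelationMatrix:
    """Pearson correlation matrix over per-animal variables.

    ``table`` has one row per animal; ``variables`` defaults to all numeric
    columns.  A constant column makes the correlation undefined and raises
    :class:`UndefinedCorrelationError` naming it.
    """
    if variables is None:
        variables = [c for c in table.columns
                     if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[list(variables)].astype(float)
    if len(sub) < 3:
        raise ConfigError("need at least 3 animals for correlations")
    for col in variables:
        if sub[col].nunique() <= 1:
            raise UndefinedCorrelationError(col)
    n = len(sub)
    r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((len(variables),) * 2), index=variables,
                     columns=variables)
    for i, vi in enumerate(variables):
        p.loc[vi, vi] = 0.0
        for vj in variables[i + 1:]:
            res = sps.pearsonr(sub[vi], sub[vj])
            r.loc[vi, vj] = r.loc[vj, vi] = float(res.statistic)
            p.loc[vi, vj] = p.loc[vj, vi] = float(res.pvalue)
    return CorrelationMatrix(variables=tuple(variables), r=r, p=p, n=n)


def group_table(table: pd.DataFrame, variables, group_col: str = "group",
                groups=("control", "treatment"),
                variant: str = "pooled") -> pd.DataFrame:
    """Study-style summary table: group means, pooled SEM and p per variable."""
    a = table.loc[table[group_col] == groups[0]]
    b = table.loc[table[group_col] == groups[1]]
    rows = []
    for var in variables:
        cmp_ = students_t(a[var], b[var], variant=variant, variable=var)
        rows.append({
            "variable": var, groups[0]: cmp_.mean_a, groups[1]: cmp_.mean_b,
            "pooled_sem": cmp_.pooled_sem,
            "pooled_sem_group": cmp_.pooled_sem_group,
            "t": cmp_.t_stat, "df": cmp_.df, "p_value": cmp_.p_value,
            "flags": ";".join(cmp_.flags),
        })
    return pd.DataFrame(rows)
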