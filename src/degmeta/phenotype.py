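"""Two-factor interaction statistics for phenotype tables.

A phenotype table holds replicate measurements (e.g. hypocotyl length in
mm) indexed by two crossed factors — typically genotype and environment
(growth temperature), or drug treatment crossed with either. The question
behind a genotype-by-environment (GxE) claim is whether the reaction norms
are parallel: a non-zero interaction term means the genotypes respond
differently to the environment.

The interaction test is a model comparison: the residual sum of squares of
the additive model (A + B) minus that of the full cell-means model (A + B +
A:B) is the interaction sum of squares (Type II decomposition, which
coincides with the classical balanced-design partition when cell counts are
equal). Main-effect sums of squares are likewise Type II.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPE_COLUMNS = ("factor_a", "factor_b", "replicate", "value")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns factor_a, factor_b, replicate, value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df["value"] = df["value"].astype(float)
    return df


def validate_phenotype_table(df: pd.DataFrame) -> None:
    for col in PHENOTYPE_COLUMNS[:2] + ("value",):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    for col in ("factor_a", "factor_b"):
        if df[col].nunique() < 2:
            raise ValueError(f"{col} needs at least 2 levels, found {df[col].nunique()}")
    cells = df.groupby(["factor_a", "factor_b"], observed=True).size()
    expected = df["factor_a"].nunique() * df["factor_b"].nunique()
    if len(cells) < expected:
        observed = set(cells.index)
        for a in df["factor_a"].unique():
            for b in df["factor_b"].unique():
                if (a, b) not in observed:
                    raise ValueError(f"empty cell: factor_a={a!r}, factor_b={b!r}")


@dataclass(frozen=True)
class AnovaResult:
    """Type II sums of squares and the interaction F-test."""

    ss_a: float
    ss_b: float
    ss_interaction: float
    ss_residual: float
    df_a: int
    df_b: int
    df_interaction: int
    df_residual: int
    F_interaction: float
    p_interaction: float

    def to_dict(self) -> dict[str, float]:
        return {
            "ss_a": self.ss_a,
            "ss_b": self.ss_b,
            "ss_interaction": self.ss_interaction,
            "ss_residual": self.ss_residual,
            "df_a": self.df_a,
            "df_b": self.df_b,
            "df_interaction": self.df_interaction,
            "df_residual": self.df_residual,
            "F_interaction": self.F_interaction,
            "p_interaction": self.p_interaction,
        }


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def two_way_anova_interaction(table: pd.DataFrame) -> AnovaResult:
    """Fit the two-factor model with interaction and test the interaction term.

    Sums of squares are Type II (model comparison): each term's SS is the
    drop in residual SS when it is added last among terms of its order.
    F = (SS_int / df_int) / (SS_res / df_res); p from the F distribution.
    """
    validate_phenotype_table(table)
    y = table["value"].to_numpy(dtype=float)
    a = pd.get_dummies(table["factor_a"].astype(str), drop_first=True, dtype=float).to_numpy()
    b = pd.get_dummies(table["factor_b"].astype(str), drop_first=True, dtype=float).to_numpy()
    n = len(y)
    n_a_lv = a.shape[1] + 1
    n_b_lv = b.shape[1] + 1
    df_int = (n_a_lv - 1) * (n_b_lv - 1)
    df_res = n - n_a_lv * n_b_lv
    if df_res < 1:
        raise ValueError("zero residual degrees of freedom; need replication in some cell")
    ones = np.ones((n, 1))
    ab = np.einsum("ni,nj->nij", a, b).reshape(n, -1)
    X_full = np.hstack([ones, a, b, ab])
    X_add = np.hstack([ones, a, b])
    sse_full = _sse(y, X_full)
    sse_add = _sse(y, X_add)
    sse_no_a = _sse(y, np.hstack([ones, b]))
    sse_no_b = _sse(y, np.hstack([ones, a]))
    ss_int = max(0.0, sse_add - sse_full)
    ss_a = max(0.0, sse_no_a - sse_add)
    ss_b = max(0.0, sse_no_b - sse_add)
    ms_res = sse_full / df_res
    if ms_res == 0.0:
        F = np.inf if ss_int > 0 else 0.0
    else:
        F = (ss_int / df_int) / ms_res
    p = float(stats.f.sf(F, df_int, df_res)) if np.isfinite(F) else 0.0
    return AnovaResult(
        ss_a=ss_a,
        ss_b=ss_b,
        ss_interaction=ss_int,
        ss_residual=sse_full,
        df_a=n_a_lv - 1,
        df_b=n_b_lv - 1,
        df_interaction=df_int,
        df_residual=df_res,
        F_interaction=float(F),
        p_interaction=p,
    )


def students_t(
    group1: np.ndarray | list[float],
    group2: np.ndarray | list[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default, Welch optional.

    When both groups have zero variance and equal means the statistic is
    0/0; by convention this returns (0.0, 1.0).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0 and g1.mean() == g2.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
    return float(t), float(p)


def reaction_norm_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Cell means and standard errors per factor combination, for reaction-norm plots.

    A cell with a single observation has an undefined standard error,
    reported as missing.
    """
    grouped = table.groupby(["factor_a", "factor_b"], observed=True)["value"]
    out = grouped.agg(mean="mean", n="size", sd=lambda v: v.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, ["sd", "se"]] = np.nan
    return out[["factor_a", "factor_b", "n", "mean", "sd", "se"]]
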