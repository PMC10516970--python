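"""Compositional and inferential statistics for qSIP community tables.

CLR transform of absolute abundances, PCA on the Euclidean geometry of the
CLR space, a two-way permutation PERMANOVA with sequential (Type-I) sums of
squares, two-way fixed-effects ANOVA, Welch t-tests, Benjamini–Hochberg FDR,
and the normality/homoscedasticity gate that routes between ANOVA and
pairwise rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import DesignError

__all__ = [
    "StatResult",
    "GateResult",
    "clr_transform",
    "pca",
    "permanova_two_way",
    "anova_two_way",
    "welch_t_test",
    "rank_sum_test",
    "bh_adjust",
    "normality_homoscedasticity_gate",
]


@dataclass
class StatResult:
    """One test or model term: statistic, degrees of freedom, p-values."""

    term: str
    statistic: float
    stat_name: str  # "F", "t", "U", ...
    df: float | tuple
    p: float
    p_adj: float | None = None
    r2: float | None = None

    def as_dict(self) -> dict:
        d = {
            "term": self.term,
            "statistic": self.statistic,
            "stat_name": self.stat_name,
            "df": self.df,
            "p": self.p,
        }
        if self.p_adj is not None:
            d["p_adj"] = self.p_adj
        if self.r2 is not None:
            d["r2"] = self.r2
        return d


def clr_transform(abundances: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform, samples as rows.

    ``x → log(x + pseudocount) − mean(log(x + pseudocount))`` per sample;
    every output row sums to zero.  The pseudocount (default 1 gene copy on
    the absolute-abundance scale) keeps zero counts finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = abundances.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size:
        raise DesignError(
            f"all-zero sample(s) at rows {list(abundances.index[zero_rows])}"
        )
    logx = np.log(x + pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=abundances.index, columns=abundances.columns)


def pca(matrix: pd.DataFrame):
    """Centered PCA via SVD.

    Returns ``(scores, loadings, variance_explained)``; the explained-variance
    ratios over all retained components sum to 1, and pairwise Euclidean
    distances between full score vectors equal those of the centered data.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    model = _SkPCA(n_components=min(x.shape))
    scores = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores = pd.DataFrame(scores, index=matrix.index, columns=cols)
    loadings = pd.DataFrame(model.components_.T, index=matrix.columns, columns=cols)
    return scores, loadings, model.explained_variance_ratio_


def _factor_dummies(levels: pd.Series) -> np.ndarray:
    """Full-rank treatment-coded dummy block for one factor."""
    cats = pd.Categorical(levels)
    if len(cats.categories) < 2:
        raise DesignError(f"factor has a single level: {cats.categories.tolist()}")
    return pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of x."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10
    q = q[:, keep]
    return q @ q.T


def permanova_two_way(
    distances,
    factor_a,
    factor_b=None,
    n_perm: int = 9999,
    seed: int = 0,
    names: tuple = ("A", "B", "A:B"),
) -> list[StatResult]:
    """Permutation PERMANOVA with sequential (Type-I) sums of squares.

    Partitions the Gower-centered inner-product matrix of the distance matrix
    over factor A, then B, then the A×B interaction (term order matters for
    unbalanced designs and is the caller's choice).  Pseudo-F per term uses
    the residual mean square; p-values count permuted pseudo-F values at or
    above the observed one, ``p = (1 + #{F* ≥ F}) / (1 + n_perm)``, permuting
    sample labels with a seeded generator.  With ``factor_b=None`` this is a
    one-way PERMANOVA.

    Returns one :class:`StatResult` per term plus a ``Residual`` entry; the
    term and residual R² sum to 1.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    a = pd.Series(list(factor_a))
    if len(a) != n:
        raise ValueError("factor length must match the distance matrix")

    # Gower centering: G = -1/2 J D^2 J
    a2 = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a2 @ j

    xa = _factor_dummies(a)
    blocks = [xa]
    if factor_b is not None:
        b = pd.Series(list(factor_b))
        if len(b) != n:
            raise ValueError("factor length must match the distance matrix")
        xb = _factor_dummies(b)
        xab = np.einsum("ij,ik->ijk", xa, xb).reshape(n, -1)
        blocks += [xb, xab]
    term_names = list(names[: len(blocks)])

    intercept = np.ones((n, 1))
    hats = []
    dfs = []
    prev = _hat(intercept)
    prev_rank = 1
    design = intercept
    for block in blocks:
        design = np.hstack([design, block])
        h = _hat(design)
        rank = int(round(np.trace(h)))
        hats.append(h - prev)
        dfs.append(rank - prev_rank)
        prev, prev_rank = h, rank
    df_resid = n - prev_rank
    if df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    h_resid = np.eye(n) - prev

    def term_stats(gmat):
        ss = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_resid = float(np.sum(h_resid * gmat))
        ms_resid = ss_resid / df_resid
        ms_term = ss / np.array(dfs)
        if ms_resid <= 0:
            # degenerate geometry (all points identical, or a perfect fit):
            # define F as 0 where the term explains nothing, inf otherwise
            f = np.where(ms_term > 0, np.inf, 0.0)
        else:
            f = ms_term / ms_resid
        return ss, ss_resid, f

    ss, ss_resid, f_obs = term_stats(g)
    ss_total = float(np.trace(g))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, _, f_perm = term_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    results = [
        StatResult(
            term=term_names[i], statistic=float(f_obs[i]), stat_name="pseudo-F",
            df=(dfs[i], df_resid), p=float(pvals[i]),
            r2=float(ss[i] / ss_total) if ss_total > 0 else 0.0,
        )
        for i in range(len(hats))
    ]
    results.append(
        StatResult(
            term="Residual", statistic=float("nan"), stat_name="pseudo-F",
            df=(df_resid, df_resid), p=float("nan"),
            r2=float(ss_resid / ss_total) if ss_total > 0 else 0.0,
        )
    )
    return results


def anova_two_way(
    values, factor_a, factor_b, names: tuple = ("A", "B", "A:B")
) -> list[StatResult]:
    """Fixed-effects two-way ANOVA with interaction (sequential SS).

    On a balanced design this is identical to every standard formulation.
    Requires at least two replicates per cell for the interaction term.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "a": list(factor_a), "b": list(factor_b)})
    cells = df.groupby(["a", "b"]).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if n_a < 2 or n_b < 2:
        raise DesignError("each factor needs at least two levels")
    if len(cells) < n_a * n_b:
        raise DesignError("empty cell in the two-way design")
    if (cells < 2).any():
        raise DesignError("interaction needs at least two replicates per cell")
    model = ols("y ~ C(a) * C(b)", data=df).fit()
    table = anova_lm(model, typ=1)
    mapping = {"C(a)": names[0], "C(b)": names[1], "C(a):C(b)": names[2]}
    out = []
    for row_name, row in table.iterrows():
        if row_name == "Residual":
            continue
        out.append(
            StatResult(
                term=mapping.get(row_name, row_name),
                statistic=float(row["F"]),
                stat_name="F",
                df=(float(row["df"]), float(table.loc["Residual", "df"])),
                p=float(row["PR(>F)"]),
            )
        )
    return out


def welch_t_test(x, y, label: str = "x vs y") -> StatResult:
    """Two-sided Welch t-test with Welch–Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return StatResult(label, 0.0, "t", float(x.size + y.size - 2), 1.0)
        return StatResult(label, np.inf if np.mean(x) > np.mean(y) else -np.inf,
                          "t", float(x.size + y.size - 2), 0.0)
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatResult(label, float(res.statistic), "t", float(res.df), float(res.pvalue))


def rank_sum_test(x, y, label: str = "x vs y") -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null distribution for small samples (n ≤ 8 per group, no ties),
    normal approximation otherwise — the fallback when the ANOVA gate fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return StatResult(label, float(res.statistic), "U", float(x.size * y.size),
                      float(res.pvalue))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GateResult:
    """Outcome of the normality/homoscedasticity gate."""

    decision: str  # "anova" | "pairwise-rank"
    shapiro_p: float | None
    levene_p: float | None
    abstained: bool = False


def normality_homoscedasticity_gate(values, groups, alpha: float = 0.05) -> GateResult:
    """Choose between two-way ANOVA and pairwise rank tests.

    Shapiro–Wilk on the group-mean residuals and median-centered Levene across
    groups, both at ``alpha``.  Groups smaller than 3 values, or constant
    data, make the gate abstain and route to the rank-based family.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    group_values = [sub["y"].to_numpy() for _, sub in df.groupby("g")]
    if any(v.size < 3 for v in group_values):
        return GateResult("pairwise-rank", None, None, abstained=True)
    resid = df["y"] - df.groupby("g")["y"].transform("mean")
    if np.allclose(resid, resid.iloc[0]) or np.allclose(df["y"], df["y"].iloc[0]):
        return GateResult("pairwise-rank", None, None, abstained=True)
    sh_p = float(sps.shapiro(resid).pvalue)
    lev_p = float(sps.levene(*group_values, center="median").pvalue)
    decision = "anova" if (sh_p > alpha and lev_p > alpha) else "pairwise-rank"
    return GateResult(decision, sh_p, lev_p)
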