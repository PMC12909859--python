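"""Inferential chain on per-dyad global synchrony values.

The five conditions of the Still-Face Paradigm are compared within dyads:
outlier screening per condition column, exploratory covariate checks (Welch
t between infant sexes, Pearson correlation with infant age), a Friedman
omnibus test per frequency band, pairwise Wilcoxon signed-rank post hocs
with Benjamini-Hochberg FDR correction, and a parametric repeated-measures
ANCOVA as a sensitivity check.  Rank tests admit no covariates, so the
covariates enter only through the exploratory screens and the parametric
sensitivity path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import SynchronyTable

DEFAULT_CONDITIONS: tuple[str, ...] = ("FP1", "SF1", "FP2", "SF2", "RU")


@dataclass
class ContrastResult:
    """One test: statistic, degrees of freedom, raw and FDR-adjusted p."""

    test_name: str
    comparison: str
    statistic: float
    df: str
    p_raw: float
    p_fdr: float
    n: int
    note: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def results_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CohortTable:
    """Per-dyad global synchrony in long form plus dyad metadata.

    ``values``: DataFrame (dyad, band, condition, global_wpli) with one row
    per cell; missing cells (outliers removed, dropped conditions) are
    simply absent or NaN.  ``meta``: one row per dyad with infant age in
    months and infant sex.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS

    @classmethod
    def from_synchrony(cls, table: SynchronyTable, meta: pd.DataFrame,
                       conditions: tuple[str, ...] = DEFAULT_CONDITIONS
                       ) -> "CohortTable":
        vals = table.global_df[["dyad", "band", "condition", "global_wpli"]]
        return cls(values=vals.copy(), meta=meta.copy(),
                   conditions=conditions)

    @classmethod
    def from_wide(cls, df: pd.DataFrame,
                  bands: tuple[str, ...] = ("theta", "alpha"),
                  conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
                  dyad_col: str = "dyad", age_col: str = "infant_age_months",
                  sex_col: str = "infant_sex") -> "CohortTable":
        """Convert a one-row-per-dyad table with ``<band>_<condition>``
        columns (the layout of deposited per-dyad synchrony tables)."""
        rows = []
        for r in df.itertuples(index=False):
            rd = r._asdict()
            for b in bands:
                for c in conditions:
                    col = f"{b}_{c}"
                    if col in rd:
                        rows.append({"dyad": rd[dyad_col], "band": b,
                                     "condition": c,
                                     "global_wpli": rd[col]})
        meta_cols = [c for c in (dyad_col, age_col, sex_col) if c in df]
        meta = df[meta_cols].rename(columns={
            dyad_col: "dyad", age_col: "infant_age_months",
            sex_col: "infant_sex"})
        return cls(values=pd.DataFrame(rows), meta=meta,
                   conditions=conditions)

    def bands(self) -> list[str]:
        return list(dict.fromkeys(self.values["band"]))

    def wide(self, band: str) -> pd.DataFrame:
        """Dyads x conditions matrix for one band (NaN where missing)."""
        sub = self.values[self.values.band == band]
        w = sub.pivot_table(index="dyad", columns="condition",
                            values="global_wpli", aggfunc="mean")
        return w.reindex(columns=list(self.conditions))

    def drop_cells(self, flags: pd.DataFrame, band: str) -> "CohortTable":
        """Remove flagged (dyad, condition) cells for one band."""
        vals = self.values.copy()
        for dyad in flags.index:
            for cond in flags.columns:
                if bool(flags.loc[dyad, cond]):
                    sel = ((vals.dyad == dyad) & (vals.band == band)
                           & (vals.condition == cond))
                    vals = vals[~sel]
        return CohortTable(vals, self.meta, self.conditions)


# ---------------------------------------------------------------------------

def detect_outliers(table: CohortTable, band: str, rule: str = "3sd",
                    threshold: float = 3.0) -> pd.DataFrame:
    """Flag per-cell outliers, by default |value - mean| > 3 SD per
    condition column.  ``rule="none"`` flags nothing."""
    wide = table.wide(band)
    if len(wide) < 5:
        raise ValueError("outlier screening needs at least 5 dyads")
    if rule == "none":
        return wide.isna() & False
    if rule != "3sd":
        raise ValueError(f"unknown outlier rule {rule!r}")
    mu = wide.mean(axis=0)
    sd = wide.std(axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        flags = (wide - mu).abs() > threshold * sd
    return flags.fillna(False)


def friedman_conditions(table: CohortTable, band: str,
                        missing: str = "listwise") -> ContrastResult:
    """Friedman omnibus test over the five conditions for one band.

    Complete blocks are required by the rank structure; dyads with a
    missing condition value are dropped listwise by default, or their
    missing cells are filled with the condition-column mean
    (``missing="impute"``) so the dyad's remaining values still contribute.
    The dropped count is noted on the result.
    """
    wide = table.wide(band)
    if missing == "impute":
        wide = wide.fillna(wide.mean(axis=0))
    elif missing != "listwise":
        raise ValueError(f"unknown missing-data policy {missing!r}")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"Friedman needs >= 3 complete dyads, got {len(complete)}")
    X = complete.to_numpy()
    k = X.shape[1]
    if np.all(X == X[:, [0]]):
        stat, p = 0.0, 1.0       # every block fully tied
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = sps.friedmanchisquare(*(X[:, j] for j in range(k)))
        if np.isnan(stat):
            stat, p = 0.0, 1.0
    return ContrastResult(
        test_name="friedman", comparison=f"{band}: conditions",
        statistic=float(stat), df=str(k - 1), p_raw=float(p),
        p_fdr=float(p), n=len(complete),
        note=f"{n_dropped} dyads dropped listwise" if n_dropped else "")


def _exact_signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank test by enumerating all sign patterns.

    Handles tied |differences| via average ranks (zeros must be removed
    already).  Returns (W = smaller rank sum, p).
    """
    ranks = sps.rankdata(np.abs(d))
    n = d.size
    total = ranks.sum()
    w_pos = ranks[d > 0].sum()
    w_obs = min(w_pos, total - w_pos)
    signs = np.array(
        [[(i >> j) & 1 for j in range(n)] for i in range(2 ** n)])
    w_all = signs @ ranks            # W+ under every sign assignment
    lo = np.mean(w_all <= w_pos + 1e-9)
    hi = np.mean(w_all >= w_pos - 1e-9)
    p = min(1.0, 2.0 * min(lo, hi))
    return float(w_obs), float(p)


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank; W = smaller signed-rank sum.

    Zero differences are dropped.  Small samples (n <= 14) use full
    enumeration of the signed-rank distribution (exact even with tied
    ranks); up to n = 25 without ties the standard exact distribution is
    used; otherwise the normal approximation with continuity correction.
    All-zero differences degenerate to W = 0, p = 1.
    """
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0, "degenerate: all differences zero"
    if nz.size <= 14:
        w, p = _exact_signed_rank(nz)
        return w, p, "exact (enumeration)"
    if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size \
            and nz.size == d.size:
        res = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.wilcoxon(x, y, alternative="two-sided", method="approx",
                       correction=True)
    return float(res.statistic), float(res.pvalue), \
        "normal approx, continuity corrected"


def pairwise_wilcoxon_fdr(table: CohortTable, band: str
                          ) -> list[ContrastResult]:
    """All 10 pairwise condition contrasts, BH-FDR corrected as one family.

    Dyads missing either member of a pair are dropped for that pair only
    (pairwise deletion), so an outlier removal in one condition does not
    cost the dyad everywhere.
    """
    wide = table.wide(band)
    results = []
    for c1, c2 in itertools.combinations(table.conditions, 2):
        sub = wide[[c1, c2]].dropna()
        w, p, how = _wilcoxon(sub[c1].to_numpy(), sub[c2].to_numpy())
        results.append(ContrastResult(
            test_name="wilcoxon", comparison=f"{band}: {c1} vs {c2}",
            statistic=w, df="", p_raw=p, p_fdr=np.nan, n=len(sub),
            note=how))
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def covariate_checks(table: CohortTable) -> list[ContrastResult]:
    """Exploratory covariate screens per (band, condition).

    Welch two-sample t between mother-daughter and mother-son dyads
    (unequal variances, Welch-Satterthwaite df) and Pearson correlation of
    synchrony with infant age in months.
    """
    meta = table.meta.set_index("dyad")
    sexes = sorted(meta["infant_sex"].unique())
    if len(sexes) != 2:
        raise ValueError(f"expected two sex levels, got {sexes}")
    results = []
    for band in table.bands():
        wide = table.wide(band)
        for cond in table.conditions:
            col = wide[cond].dropna()
            sex = meta.loc[col.index, "infant_sex"]
            g1 = col[sex == sexes[0]].to_numpy()
            g2 = col[sex == sexes[1]].to_numpy()
            if min(g1.size, g2.size) < 2:
                raise ValueError(
                    f"sex group with < 2 dyads in {band}/{cond}")
            if np.var(g1) == 0 and np.var(g2) == 0 and g1.mean() == g2.mean():
                t, p, dfw = 0.0, 1.0, float(g1.size + g2.size - 2)
            else:
                res = sps.ttest_ind(g1, g2, equal_var=False)
                t, p, dfw = float(res.statistic), float(res.pvalue), \
                    float(res.df)
            results.append(ContrastResult(
                test_name="welch_t_sex",
                comparison=f"{band}/{cond}: {sexes[0]} vs {sexes[1]}",
                statistic=t, df=f"{dfw:.2f}", p_raw=p, p_fdr=p,
                n=int(g1.size + g2.size)))
            age = meta.loc[col.index, "infant_age_months"].to_numpy()
            vals = col.to_numpy()
            if np.std(age) == 0 or np.std(vals) == 0:
                r_, pr = 0.0, 1.0
            else:
                r_, pr = sps.pearsonr(age, vals)
            results.append(ContrastResult(
                test_name="pearson_age", comparison=f"{band}/{cond}: age",
                statistic=float(r_), df=str(col.size - 2), p_raw=float(pr),
                p_fdr=float(pr), n=int(col.size)))
    return results


def rm_anova_sensitivity(table: CohortTable, band: str) -> ContrastResult:
    """Parametric sensitivity check: repeated-measures ANCOVA condition F.

    Thin wrapper fitting, on the long table (complete dyads only), an OLS
    model with dyad fixed effects, the condition factor, and
    condition x age / condition x sex interactions -- the within-subject
    error structure of the classic RM-ANCOVA.  The reported F is for the
    condition main effect.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    wide = table.wide(band).dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 complete dyads")
    meta = table.meta.set_index("dyad")
    long = wide.reset_index().melt(
        id_vars="dyad", var_name="condition", value_name="y")
    long["age"] = meta.loc[long.dyad, "infant_age_months"].to_numpy()
    long["age"] -= long["age"].mean()
    long["sex"] = meta.loc[long.dyad, "infant_sex"].to_numpy()
    k = len(table.conditions)
    cond_means = wide.mean(axis=0)
    if np.allclose(cond_means.to_numpy(), cond_means.iloc[0]) and \
            np.allclose(wide.sub(wide.mean(axis=1), axis=0).to_numpy(), 0):
        return ContrastResult(
            test_name="rm_ancova", comparison=f"{band}: conditions",
            statistic=0.0, df=f"{k - 1}, {(len(wide) - 1) * (k - 1)}",
            p_raw=1.0, p_fdr=1.0, n=len(wide),
            note="degenerate: identical condition profiles")
    model = smf.ols(
        "y ~ C(dyad) + C(condition) + C(condition):age + C(condition):sex",
        data=long).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    row = tab.loc["C(condition)"]
    df2 = float(tab.loc["Residual", "df"])
    return ContrastResult(
        test_name="rm_ancova", comparison=f"{band}: conditions",
        statistic=float(row["F"]), df=f"{int(row['df'])}, {df2:.0f}",
        p_raw=float(row["PR(>F)"]), p_fdr=float(row["PR(>F)"]),
        n=len(wide))


def run_stats(table: CohortTable, outlier_rule: str = "3sd",
              with_sensitivity: bool = True) -> pd.DataFrame:
    """The full inferential chain for every band in the table."""
    results: list[ContrastResult] = []
    for band in table.bands():
        flags = detect_outliers(table, band, rule=outlier_rule)
        n_out = int(flags.to_numpy().sum())
        screened = table.drop_cells(flags, band) if n_out else table
        fr = friedman_conditions(screened, band)
        if n_out:
            fr.note = (fr.note + f"; {n_out} outlier cells removed").strip("; ")
        results.append(fr)
        results.extend(pairwise_wilcoxon_fdr(screened, band))
        if with_sensitivity:
            results.append(rm_anova_sensitivity(screened, band))
    try:
        results.extend(covariate_checks(table))
    except ValueError as err:
        warnings.warn(f"covariate checks skipped: {err}")
    return results_frame(results)
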