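"""Group-level statistics for gaze metrics and presaccadic amplitudes.

Four pieces:

* a mixed (between x within) repeated-measures ANOVA on the eye-tracking
  metrics, with least-square means +/- SEM for significant interactions and
  Holm-Sidak adjusted pairwise comparisons;
* a gated MANOVA on (frontal, parietal) amplitudes — Wilks' lambda first,
  univariate two-way ANOVAs only when the multivariate test is significant,
  with a Lilliefors normality check and an aligned-rank-transform fallback;
* Kruskal-Wallis with Dunn's post-hoc z-tests (tie-corrected) for the
  neuropsychological comparisons;
* the design-stage sample-size computation for a one-way k-group ANOVA via
  noncentral-F power, with a Monte-Carlo cross-check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ManovaResult",
    "rm_anova",
    "manova_then_univariate",
    "kruskal_dunn",
    "power_sample_size",
    "anova_power",
    "monte_carlo_anova_power",
    "holm_sidak",
]


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (monotone, >= raw)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm-sidak")[1]


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # Source, F, df1, df2, p
    lsm: pd.DataFrame | None = None  # cell means +/- SEM, for significant interaction
    posthoc: pd.DataFrame | None = None  # Holm-Sidak adjusted pairwise comparisons

    def effect(self, source: str) -> pd.Series:
        m = self.effects[self.effects["Source"].str.lower() == source.lower()]
        if m.empty:
            raise KeyError(source)
        return m.iloc[0]


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "variable",
    subject: str = "subject_id",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-factor mixed ANOVA: between-subjects group, within-subjects variable.

    Expects one row per subject x within-level (long format; average
    replicates first). When the interaction is significant at ``alpha``,
    least-square means +/- SEM per Group x Variable cell and Holm-Sidak
    adjusted pairwise group comparisons within each variable level are
    attached.
    """
    import pingouin as pg

    groups = data[between].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = data.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("within-factor levels must be balanced across subjects")

    aov = pg.mixed_anova(data=data, dv=dv, between=between, within=within, subject=subject)
    effects = pd.DataFrame(
        {
            "Source": aov["Source"].replace({"Interaction": "interaction"}),
            "F": aov["F"],
            "df1": aov["DF1"],
            "df2": aov["DF2"],
            "p": aov["p_unc"],
        }
    )
    res = AnovaResult(effects=effects)

    inter_p = float(effects.loc[effects["Source"] == "interaction", "p"].iloc[0])
    if inter_p < alpha:
        res.lsm = least_square_means(data, dv, between, within, subject)
        res.posthoc = _pairwise_groups(data, dv, between, within, subject)
    return res


def least_square_means(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str,
    subject: str,
) -> pd.DataFrame:
    """Cell means with model-based SEM per (between x within) cell.

    With the balanced within-factor design the least-square mean equals the
    unweighted cell mean; its SEM uses the pooled within-cell error MS.
    """
    cell = data.groupby([between, within])[dv]
    means = cell.mean()
    n = cell.count()
    resid = data[dv] - data.set_index([between, within]).index.map(means).to_numpy()
    df_err = len(data) - means.size
    mse = float((resid**2).sum() / df_err) if df_err > 0 else float("nan")
    out = means.reset_index().rename(columns={dv: "lsm"})
    out["sem"] = np.sqrt(mse / n.to_numpy())
    return out


def _pairwise_groups(data, dv, between, within, subject) -> pd.DataFrame:
    """Welch t-tests between groups within each within-level, Holm-Sidak adjusted."""
    rows = []
    for lev, sub in data.groupby(within):
        for g1, g2 in itertools.combinations(sorted(sub[between].unique()), 2):
            a = sub.loc[sub[between] == g1, dv].to_numpy()
            b = sub.loc[sub[between] == g2, dv].to_numpy()
            t, p = sps.ttest_ind(a, b, equal_var=False)
            rows.append({within: lev, "A": g1, "B": g2, "t": float(t), "p_unc": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = holm_sidak(df["p_unc"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# MANOVA -> univariate gating


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    correlation_r: float
    correlation_ok: bool
    n_outliers_removed: int
    univariate: dict = field(default_factory=dict)  # dv -> effects DataFrame
    normality: dict = field(default_factory=dict)  # dv -> (stat, p, normal?)
    nonparametric: dict = field(default_factory=dict)  # dv -> ART effects, when used


def _mahalanobis_outliers(X: np.ndarray, chi2_q: float = 0.975) -> np.ndarray:
    mu = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False))
    inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", X - mu, inv, X - mu)
    return d2 > sps.chi2.ppf(chi2_q, df=X.shape[1])


def manova_then_univariate(
    data: pd.DataFrame,
    dvs: tuple[str, str] = ("frontal", "parietal"),
    factors: tuple[str, str] = ("size_class", "group"),
    alpha: float = 0.05,
    corr_limits: tuple[float, float] = (0.3, 0.6),
    remove_outliers: bool = True,
    nonparametric: str = "art",
) -> ManovaResult:
    """Wilks' lambda MANOVA on the dependent-variable pair, gated follow-ups.

    The assumption screen checks that the DVs correlate moderately
    (``corr_limits``); violations are reported as a warning, not an abort.
    Multivariate outliers are removed by Mahalanobis distance (chi-square
    97.5% cut). Univariate two-way ANOVAs per DV run only when the
    multivariate group effect is significant; DVs whose residuals fail a
    Lilliefors-corrected Kolmogorov-Smirnov test are re-tested with an
    aligned-rank-transform ANOVA.
    """
    if len(dvs) < 2:
        raise ValueError("need at least two dependent variables")
    fsize, fgroup = factors
    df = data.dropna(subset=list(dvs)).copy()

    n_out = 0
    if remove_outliers and len(df) > len(dvs) + 2:
        mask = _mahalanobis_outliers(df[list(dvs)].to_numpy(dtype=float))
        n_out = int(mask.sum())
        df = df.loc[~mask]

    r = float(np.corrcoef(df[dvs[0]], df[dvs[1]])[0, 1])
    corr_ok = corr_limits[0] <= abs(r) <= corr_limits[1]
    if not corr_ok:
        warnings.warn(
            f"DV correlation r={r:.2f} outside the moderate band "
            f"{corr_limits}; MANOVA assumption screen failed",
            stacklevel=2,
        )

    dv_cov = np.cov(df[list(dvs)].to_numpy(dtype=float), rowvar=False)
    if np.linalg.matrix_rank(np.atleast_2d(dv_cov)) < len(dvs):
        raise ValueError("dependent variables are collinear; MANOVA is undefined")

    formula = f"{dvs[0]} + {dvs[1]} ~ C({fgroup})"
    if df[fsize].nunique() > 1:
        formula += f" + C({fsize})"
    mv = MANOVA.from_formula(formula, data=df)
    tab = mv.mv_test().results[f"C({fgroup})"]["stat"]
    wl = tab.loc["Wilks' lambda"]
    res = ManovaResult(
        wilks_lambda=float(wl["Value"]),
        F=float(wl["F Value"]),
        df1=float(wl["Num DF"]),
        df2=float(wl["Den DF"]),
        p=float(wl["Pr > F"]),
        correlation_r=r,
        correlation_ok=corr_ok,
        n_outliers_removed=n_out,
    )

    if res.p >= alpha:
        return res

    for dv in dvs:
        uni_formula = f"{dv} ~ C({fsize}) * C({fgroup})" if df[fsize].nunique() > 1 \
            else f"{dv} ~ C({fgroup})"
        fit = ols(uni_formula, data=df).fit()
        res.univariate[dv] = _tidy_anova(anova_lm(fit, typ=2))
        resid = fit.resid.to_numpy()
        stat, p_norm = lilliefors(resid, dist="norm")
        normal = p_norm >= alpha
        res.normality[dv] = {"stat": float(stat), "p": float(p_norm), "normal": normal}
        if not normal:
            res.nonparametric[dv] = art_anova(df, dv, fsize, fgroup, method=nonparametric)
    return res


def _tidy_anova(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab.reset_index().rename(columns={"index": "Source", "PR(>F)": "p"})
    return tab[["Source", "df", "F", "p"]]


def art_anova(
    data: pd.DataFrame,
    dv: str,
    factor_a: str,
    factor_b: str,
    method: str = "art",
) -> pd.DataFrame:
    """Nonparametric factorial ANOVA by aligned rank transform.

    For each effect, responses are aligned (all other estimated effects
    subtracted), ranked, and submitted to the parametric factorial ANOVA;
    only the aligned effect's row is retained. ``method='rank'`` skips the
    alignment (plain rank-transform ANOVA).
    """
    df = data.copy()
    two_way = df[factor_a].nunique() > 1 and df[factor_b].nunique() > 1
    formula_full = (f"y_r ~ C({factor_a}) * C({factor_b})" if two_way
                    else f"y_r ~ C({factor_b})")
    effects = ([f"C({factor_a})", f"C({factor_b})", f"C({factor_a}):C({factor_b})"]
               if two_way else [f"C({factor_b})"])

    y = df[dv].to_numpy(dtype=float)
    gm = y.mean()
    a_eff = df.groupby(factor_a)[dv].transform("mean").to_numpy() - gm
    b_eff = df.groupby(factor_b)[dv].transform("mean").to_numpy() - gm
    cell = df.groupby([factor_a, factor_b])[dv].transform("mean").to_numpy()
    ab_eff = cell - gm - a_eff - b_eff
    resid = y - cell

    rows = []
    for eff in effects:
        if method == "rank":
            aligned = y
        elif eff == f"C({factor_a})":
            aligned = resid + a_eff
        elif eff == f"C({factor_b})":
            aligned = resid + b_eff
        else:
            aligned = resid + ab_eff
        df["y_r"] = sps.rankdata(aligned)
        fit = ols(formula_full, data=df).fit()
        tab = _tidy_anova(anova_lm(fit, typ=2))
        rows.append(tab[tab["Source"] == eff])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn


def kruskal_dunn(
    values,
    groups,
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis omnibus with Dunn's post-hoc z-tests (unequal n).

    Dunn's comparisons use tie-corrected rank variance; pairwise p-values
    are reported raw and Holm-Sidak adjusted. Post-hocs attach only when
    the omnibus is significant.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 3:
        raise ValueError("need at least 3 groups for the omnibus test")
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    H, p = sps.kruskal(*samples)
    out = {"H": float(H), "p": float(p), "df": len(labels) - 1, "posthoc": None}
    if p >= alpha:
        return out

    N = len(values)
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        n1, n2 = (groups == g1).sum(), (groups == g2).sum()
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        rows.append({"A": g1, "B": g2, "z": float(z),
                     "p_unc": float(2 * sps.norm.sf(abs(z)))})
    ph = pd.DataFrame(rows)
    ph["p_adj"] = holm_sidak(ph["p_unc"].to_numpy())
    out["posthoc"] = ph
    return out


# ---------------------------------------------------------------------------
# ANOVA power / sample size


def _means_for_convention(detectable_mean: float, n_groups: int, convention: str) -> np.ndarray:
    if convention == "extremes-midpoint":
        # detectable_mean = difference between extreme group means; the
        # remaining groups sit at the midpoint (least favourable spread for
        # a given range; the convention of standard sample-size software).
        m = np.full(n_groups, detectable_mean / 2.0)
        m[0], m[-1] = 0.0, detectable_mean
    elif convention == "equally-spaced":
        m = np.linspace(0.0, detectable_mean, n_groups)
    elif convention == "sd-of-means":
        # detectable_mean = population SD of the group means
        m = np.linspace(0.0, 1.0, n_groups)
        m = (m - m.mean()) / m.std() * detectable_mean
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return m


def anova_power(
    means,
    residual_sd: float,
    n_per_group: int,
    alpha: float = 0.05,
) -> float:
    """Exact noncentral-F power of the one-way ANOVA at the given cell means."""
    means = np.asarray(means, dtype=float)
    k = len(means)
    df1, df2 = k - 1, k * (n_per_group - 1)
    if df2 <= 0:
        return 0.0
    lam = n_per_group * float(np.sum((means - means.mean()) ** 2)) / residual_sd**2
    fcrit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def power_sample_size(
    detectable_mean: float = 0.3,
    residual_sd: float = 0.15,
    alpha: float = 0.05,
    power: float = 0.95,
    n_groups: int = 3,
    convention: str = "extremes-midpoint",
    max_n: int = 10_000,
) -> int:
    """Smallest per-group n whose one-way ANOVA power reaches the target.

    ``detectable_mean`` is interpreted per ``convention`` (default: the
    difference between the extreme group means, remaining groups at the
    midpoint). Power is computed from the noncentral-F distribution.
    """
    if min(detectable_mean, residual_sd, alpha) <= 0 or not 0 < power < 1:
        raise ValueError("parameters must be positive and power in (0, 1)")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    means = _means_for_convention(detectable_mean, n_groups, convention)
    for n in range(2, max_n + 1):
        if anova_power(means, residual_sd, n, alpha) >= power:
            return n
    raise ValueError("no feasible sample size below max_n")


def monte_carlo_anova_power(
    means,
    residual_sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Simulation estimate of one-way ANOVA power (independent of anova_power)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    k = len(means)
    rejections = 0
    for _ in range(n_sims):
        samples = rng.normal(means[:, None], residual_sd, size=(k, n_per_group))
        _, p = sps.f_oneway(*samples)
        rejections += p < alpha
    return rejections / n_sims
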