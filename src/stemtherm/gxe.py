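"""Cross-year genotype x year analysis: BLUEs, BLUPs, variance components,
broad-sense heritability, trait correlations and final-height models.

The two-way model for spatially corrected plot values y_pij of genotype i
in year j is

    y_pij = mu + G_i + Y_j + GY_ij + e_pij

with year effects fixed, the genotype-by-year interaction GY random, and
the genotype either fixed (adjusted means, BLUEs) or random (BLUPs and the
genotypic variance). Variance components are estimated by REML; the
restricted likelihood factorizes into within-cell replicate contrasts
(informing the residual variance) and genotype-year cell means (informing
the interaction and genotypic variances), which keeps the computation exact
and fast for trials with hundreds of genotypes.

Broad-sense heritability on a genotype-mean basis:

    H^2 = s2_G / (s2_G + s2_GY / n_years + s2_e / (n_years * n_reps))

For traits scored on a single replicate per year the GY term is not
identifiable and H^2 = s2_G / (s2_G + s2_e / n_env).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponents",
    "GxEFit",
    "fit_gxe",
    "heritability",
    "heritability_single_rep",
    "percent_variance",
    "trait_correlations",
    "HeightModelFit",
    "fit_height_model",
    "cross_year_r2",
    "bonferroni_neglog_threshold",
    "anova_variance_components",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gy: float
    sigma2_e: float
    n_years: int
    n_reps: float

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gy", "sigma2_e"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass
class GxEFit:
    trait: str
    genotype_role: str            # "fixed" or "random"
    mu: float
    year_effects: pd.Series       # per year, first year = 0
    genotype_values: pd.Series    # BLUEs (fixed) or BLUPs (random), on the trait scale
    vc: VarianceComponents
    reml_loglik: float
    n_genotypes: int
    dropped_genotypes: list


def _cell_stats(data: pd.DataFrame):
    """Cell means / replicate counts and within-cell sums of squares."""
    g = data.groupby(["genotype", "year"])["value"]
    cells = g.agg(mean="mean", n="size").reset_index()
    ss_within = float(((data["value"] - g.transform("mean")) ** 2).sum())
    df_within = int(len(data) - len(cells))
    return cells, ss_within, df_within


def anova_variance_components(data: pd.DataFrame) -> tuple[float, float, float]:
    """Expected-mean-squares estimators for the balanced crossed design.

    Returns raw (possibly negative) moment estimates (s2_g, s2_gy, s2_e);
    exact REML on balanced data when all three are positive. Serves as the
    optimizer start and as the classical oracle.
    """
    cells, ss_w, df_w = _cell_stats(data)
    wide = cells.pivot(index="genotype", columns="year", values="mean")
    I, J = wide.shape
    r = float(cells["n"].mean())
    mse = ss_w / df_w if df_w > 0 else 0.0
    m = wide.to_numpy()
    gi = m.mean(axis=1, keepdims=True)
    yj = m.mean(axis=0, keepdims=True)
    gm = m.mean()
    ms_gy = r * float(((m - gi - yj + gm) ** 2).sum()) / ((I - 1) * (J - 1))
    ms_g = r * J * float(((gi - gm) ** 2).sum()) / (I - 1)
    s2_e = mse
    s2_gy = (ms_gy - mse) / r
    s2_g = (ms_g - ms_gy) / (r * J)
    return s2_g, s2_gy, s2_e


def _reml_pieces(cells: pd.DataFrame, years: np.ndarray):
    geno = cells["genotype"].to_numpy()
    glev, gidx = np.unique(geno, return_inverse=True)
    yidx = pd.Categorical(cells["year"], categories=years).codes
    I, J = len(glev), len(years)
    ybar = np.full((I, J), np.nan)
    reps = np.zeros((I, J))
    ybar[gidx, yidx] = cells["mean"].to_numpy()
    reps[gidx, yidx] = cells["n"].to_numpy()
    return glev, ybar, reps


def _reml_fixed_g(ybar, reps, ss_w, df_w, s2_gy, s2_e):
    """Restricted log-likelihood, genotype fixed: cell-mean WLS via
    Frisch-Waugh absorption of the genotype dummies. Returns (ll, alpha,
    gamma) with alpha the year effects (first year 0) and gamma the
    genotype effects."""
    I, J = ybar.shape
    w = s2_gy + s2_e / reps  # cell-mean variances; reps==0 -> inf -> weight 0
    with np.errstate(divide="ignore"):
        winv = np.where(reps > 0, 1.0 / w, 0.0)
    sw = winv.sum(axis=1)  # per genotype
    # absorb genotype: weighted demeaning
    ytil = np.where(reps > 0, ybar - (np.nansum(winv * ybar, axis=1) / sw)[:, None], 0.0)
    ytil = np.nan_to_num(ytil)
    # year dummies for years 2..J
    S = np.zeros((J - 1, J - 1))
    rhs = np.zeros(J - 1)
    A = np.zeros((J - 1, J - 1))
    for j in range(1, J):
        A[j - 1, j - 1] = winv[:, j].sum()
    B = winv[:, 1:]  # (I, J-1): per-genotype weighted year indicator sums
    S = A - (B.T / sw) @ B
    yw = np.nan_to_num(winv * np.nan_to_num(ybar))
    rhs = yw[:, 1:].sum(axis=0) - (B.T / sw) @ yw.sum(axis=1)
    alpha = np.linalg.solve(S, rhs)
    alpha_full = np.concatenate([[0.0], alpha])
    resid = np.nan_to_num(ybar) - alpha_full[None, :]
    gamma = (winv * resid).sum(axis=1) / sw
    r2 = resid - gamma[:, None]
    rss_w = float((winv * r2**2).sum())
    logdet_w = float(np.where(reps > 0, np.log(np.where(reps > 0, w, 1.0)), 0.0).sum())
    sign, logdet_S = np.linalg.slogdet(S)
    logdet_x = float(np.log(sw).sum() + logdet_S)
    ll_cells = -0.5 * (logdet_w + logdet_x + rss_w)
    ll_within = -0.5 * (df_w * np.log(s2_e) + ss_w / s2_e) if df_w > 0 else 0.0
    return ll_cells + ll_within, alpha_full, gamma


def _reml_random_g(ybar, reps, ss_w, df_w, s2_g, s2_gy, s2_e):
    """Restricted log-likelihood with genotype random; uniform-pattern fast
    path, per-genotype loop otherwise. Returns (ll, beta, blups)."""
    I, J = ybar.shape
    w = s2_gy + s2_e / np.where(reps > 0, reps, np.inf)
    X = np.hstack([np.ones((J, 1)), np.eye(J)[:, 1:]])  # intercept + years 2..J
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdet = 0.0
    uniform = np.all(reps == reps[0]) and np.all(reps[0] > 0)
    if uniform:
        V = s2_g * np.ones((J, J)) + np.diag(w[0])
        Vi = np.linalg.inv(V)
        sign, ld = np.linalg.slogdet(V)
        logdet = I * ld
        XtVX = I * (X.T @ Vi @ X)
        XtVy = X.T @ Vi @ ybar.sum(axis=0)
        beta = np.linalg.solve(XtVX, XtVy)
        R = ybar - (X @ beta)[None, :]
        quad = float(np.einsum("ij,jk,ik->", R, Vi, R))
        blups = s2_g * (R @ Vi.sum(axis=1))
    else:
        Vis = []
        for i in range(I):
            obs = reps[i] > 0
            Vi_full = np.zeros((J, J))
            V = s2_g * np.ones((obs.sum(), obs.sum())) + np.diag(w[i, obs])
            Vinv = np.linalg.inv(V)
            sign, ld = np.linalg.slogdet(V)
            logdet += ld
            Xi = X[obs]
            yi = ybar[i, obs]
            XtVX += Xi.T @ Vinv @ Xi
            XtVy += Xi.T @ Vinv @ yi
            Vi_full[np.ix_(obs, obs)] = Vinv
            Vis.append((obs, Vi_full))
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        blups = np.zeros(I)
        for i, (obs, Vinv) in enumerate(Vis):
            ri = np.nan_to_num(ybar[i] - X @ beta) * obs
            quad += float(ri @ Vinv @ ri)
            blups[i] = s2_g * float(Vinv.sum(axis=1) @ ri)
    sign, logdet_x = np.linalg.slogdet(XtVX)
    ll_cells = -0.5 * (logdet + logdet_x + quad)
    ll_within = -0.5 * (df_w * np.log(s2_e) + ss_w / s2_e) if df_w > 0 else 0.0
    return ll_cells + ll_within, beta, blups


def fit_gxe(
    data: pd.DataFrame,
    genotype_role: str = "fixed",
    trait: str = "trait",
    value_col: str = "value",
) -> GxEFit:
    """REML fit of the genotype x year model on plot-level trait values.

    ``data`` needs columns genotype, year and ``value_col``. Only genotypes
    present in all years enter (the complete-across-years rule); the dropped
    ones are reported on the fit. Genotype fixed yields BLUEs plus
    (s2_GY, s2_e); genotype random yields BLUPs plus all three components.
    Components that hit the lower boundary are truncated to zero.
    """
    if genotype_role not in ("fixed", "random"):
        raise ValueError("genotype_role must be 'fixed' or 'random'")
    df = data.rename(columns={value_col: "value"})[["genotype", "year", "value"]].dropna()
    years = np.sort(df["year"].unique())
    if len(years) < 2:
        raise ValueError("GY not identifiable: need at least 2 years")
    per_geno = df.groupby("genotype")["year"].nunique()
    complete = per_geno[per_geno == len(years)].index
    dropped = sorted(set(per_geno.index) - set(complete))
    df = df[df["genotype"].isin(complete)]
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes present in all years")

    cells, ss_w, df_w = _cell_stats(df)
    glev, ybar, reps = _reml_pieces(cells, years)
    vary = float(df["value"].var())
    if vary <= 0:
        vary = 1.0
    floor = 1e-10 * vary

    s2_g0, s2_gy0, s2_e0 = anova_variance_components(df)
    start = np.log(np.maximum([s2_g0, s2_gy0, s2_e0], floor))

    lo, hi = np.log(floor), np.log(1e8 * vary)

    if genotype_role == "fixed":
        def negll(theta):
            s2_gy, s2_e = np.exp(np.clip(theta, lo, hi))
            try:
                return -_reml_fixed_g(ybar, reps, ss_w, df_w, s2_gy, s2_e)[0]
            except np.linalg.LinAlgError:
                return np.inf

        x0 = start[1:]
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        cand = [x0, res.x]
        vals = [negll(c) for c in cand]
        xbest = cand[int(np.argmin(vals))]
        # tie toward the moment start (exact on balanced interior data)
        if vals[0] <= vals[1] + 1e-9 * (1.0 + abs(vals[1])):
            xbest = x0
        s2_gy, s2_e = np.exp(np.clip(xbest, lo, hi))
        ll, alpha, gamma = _reml_fixed_g(ybar, reps, ss_w, df_w, s2_gy, s2_e)
        s2_gy = 0.0 if s2_gy <= 10 * floor else float(s2_gy)
        s2_e = 0.0 if s2_e <= 10 * floor else float(s2_e)
        values = pd.Series(gamma + alpha.mean(), index=glev, name=trait)
        vc = VarianceComponents(
            sigma2_g=float("nan"), sigma2_gy=s2_gy, sigma2_e=s2_e,
            n_years=len(years), n_reps=float(cells["n"].mean()),
        )
    else:
        def negll(theta):
            s2_g, s2_gy, s2_e = np.exp(np.clip(theta, lo, hi))
            try:
                return -_reml_random_g(ybar, reps, ss_w, df_w, s2_g, s2_gy, s2_e)[0]
            except np.linalg.LinAlgError:
                return np.inf

        res = optimize.minimize(
            negll, start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        cand = [start, res.x]
        vals = [negll(c) for c in cand]
        xbest = cand[int(np.argmin(vals))]
        if vals[0] <= vals[1] + 1e-9 * (1.0 + abs(vals[1])):
            xbest = start
        s2_g, s2_gy, s2_e = np.exp(np.clip(xbest, lo, hi))
        ll, beta, blups = _reml_random_g(ybar, reps, ss_w, df_w, s2_g, s2_gy, s2_e)
        alpha = np.concatenate([[0.0], beta[1:]])
        s2_g = 0.0 if s2_g <= 10 * floor else float(s2_g)
        s2_gy = 0.0 if s2_gy <= 10 * floor else float(s2_gy)
        s2_e = 0.0 if s2_e <= 10 * floor else float(s2_e)
        values = pd.Series(beta[0] + alpha.mean() + blups, index=glev, name=trait)
        vc = VarianceComponents(
            sigma2_g=s2_g, sigma2_gy=s2_gy, sigma2_e=s2_e,
            n_years=len(years), n_reps=float(cells["n"].mean()),
        )
    mu = float(values.mean())
    return GxEFit(
        trait=trait,
        genotype_role=genotype_role,
        mu=mu,
        year_effects=pd.Series(alpha, index=years),
        genotype_values=values,
        vc=vc,
        reml_loglik=float(ll),
        n_genotypes=len(glev),
        dropped_genotypes=list(dropped),
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on a genotype-mean basis.

    H^2 = s2_G / (s2_G + s2_GY/n_years + s2_e/(n_years*n_reps)); with three
    years and two replicates the divisors are 3 and 6.
    """
    denom = vc.sigma2_g + vc.sigma2_gy / vc.n_years + vc.sigma2_e / (
        vc.n_years * vc.n_reps
    )
    if not denom > 0:
        raise ValueError("heritability undefined: all variance components zero")
    return vc.sigma2_g / denom


def heritability_single_rep(sigma2_g: float, sigma2_e: float, n_env: int) -> float:
    """Heritability without a GY term: one replicate per environment.

    The residual variance is divided by the number of year-site
    replications: H^2 = s2_G / (s2_G + s2_e / n_env).
    """
    if n_env < 1:
        raise ValueError("need at least 1 environment")
    denom = sigma2_g + sigma2_e / n_env
    if not denom > 0:
        raise ValueError("heritability undefined: zero denominator")
    return sigma2_g / denom


def percent_variance(vc: VarianceComponents) -> pd.Series:
    """Shares of total variance (%), summing to 100."""
    total = vc.sigma2_g + vc.sigma2_gy + vc.sigma2_e
    if not total > 0:
        raise ValueError("zero total variance")
    return pd.Series(
        {
            "genotype": 100.0 * vc.sigma2_g / total,
            "genotype_x_year": 100.0 * vc.sigma2_gy / total,
            "residual": 100.0 * vc.sigma2_e / total,
        }
    )


def trait_correlations(blues: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values across genotypes.

    ``blues`` is genotypes x traits; pairs use pairwise-complete
    observations. Constant traits yield NaN entries (flagged by the NaN
    itself); the diagonal is exactly 1 with p = 0.
    """
    cols = list(blues.columns)
    if len(blues) < 3:
        raise ValueError("need at least 3 genotypes for correlations")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = blues[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rv, pv = float("nan"), float("nan")
            else:
                rv, pv = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


@dataclass
class HeightModelFit:
    formula: str
    coefficients: pd.Series
    anova: pd.DataFrame          # type II: term, sum_sq, df, F, PR(>F)
    r_squared: float
    dropped_terms: list
    model: object                # fitted statsmodels results


def fit_height_model(
    table: pd.DataFrame,
    response: str = "fh",
    predictors: tuple[str, ...] = ("slope", "vigour", "gdd_se", "rht_b1", "rht_d1", "ppd_d1"),
    interactions: bool = True,
    drop_singular: bool = True,
) -> HeightModelFit:
    """Least-squares model of final height with all two-way interactions.

    Predictors are numeric (allele contrasts coded 0 = wild type,
    1 = mutant). Singular columns (e.g. an allele-by-allele interaction no
    genotype carries) are detected by pivoted QR and the offending terms
    dropped by name before the type II ANOVA, where each term's sum of
    squares is adjusted for all other terms except interactions containing
    it.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy.linalg import qr
    from statsmodels.stats.anova import anova_lm

    data = table.dropna(subset=[response, *predictors]).copy()
    terms = list(predictors)
    if interactions:
        terms += [
            f"{a}:{b}"
            for k, a in enumerate(predictors)
            for b in predictors[k + 1 :]
        ]
    if len(data) <= len(terms) + 1:
        raise ValueError("fewer observations than model parameters")

    def build(ts):
        return f"{response} ~ " + " + ".join(ts)

    dropped: list[str] = []
    if drop_singular:
        def col(t):
            if ":" in t:
                a, b = t.split(":")
                return data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
            return data[t].to_numpy(dtype=float)

        # greedy forward pass: main effects enter first, so only the later
        # (interaction) term of a collinear pair is dropped
        kept: list[str] = []
        X = np.ones((len(data), 1))
        for t in terms:
            cand = np.column_stack([X, col(t)])
            norms = np.linalg.norm(cand, axis=0)
            if norms[-1] == 0:
                dropped.append(t)
                continue
            s = np.linalg.svd(cand / norms, compute_uv=False)
            if s[-1] > s[0] * max(cand.shape) * np.finfo(float).eps * 1e4:
                kept.append(t)
                X = cand
            else:
                dropped.append(t)
        terms = kept

    formula = build(terms)
    fit = smf.ols(formula, data=data).fit()
    anova = anova_lm(fit, typ=2)
    return HeightModelFit(
        formula=formula,
        coefficients=fit.params,
        anova=anova,
        r_squared=float(fit.rsquared),
        dropped_terms=dropped,
        model=fit,
    )


def cross_year_r2(
    blues_train: pd.DataFrame,
    blues_test: pd.DataFrame,
    formula: str = "fh ~ slope + vigour + gdd_se",
    response: str = "fh",
) -> float:
    """Train a linear model on one year's BLUEs, predict another year's.

    Rows are genotypes (index); only shared genotypes are used (>= 10
    required). Returns the squared Pearson correlation between predicted and
    observed test-year values.
    """
    import statsmodels.formula.api as smf

    shared = blues_train.index.intersection(blues_test.index)
    if len(shared) == 0:
        raise ValueError("train and test years share no genotypes")
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genotypes, need >= 10")
    train = blues_train.loc[shared].dropna()
    test = blues_test.loc[shared].dropna()
    fit = smf.ols(formula, data=train).fit()
    pred = fit.predict(test)
    obs = test[response]
    ok = pred.notna() & obs.notna()
    r, _ = stats.pearsonr(pred[ok], obs[ok])
    return float(r**2)


def bonferroni_neglog_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold on the -log10(p) scale: -log10(alpha/n_tests)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-np.log10(alpha / n_tests))
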