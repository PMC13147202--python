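"""Group-comparison and association statistics.

Covers the downstream inferential layer: two-factor ANCOVA (Type-III sums
of squares, sum-to-zero coding) with estimated-marginal-means contrasts, a
Wilks-lambda MANCOVA omnibus, chi-square / Fisher's exact dispatch with the
20%-expected-cell rule, Benjamini-Hochberg FDR adjustment, partial Pearson
correlations, multiple regression, ICC(2,1) inter-rater reliability and
percent agreement.

Conventions: unbalanced cells make Type-I sums order-dependent, so factor
effects are tested by comparing residual sums of squares of nested models
under sum-to-zero coding (Type-III style). Fisher's two-sided p uses the
point-probability rule (sum of the probabilities of all tables, under fixed
margins, no more probable than the observed one), the dominant convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "AncovaFit",
    "factorial_ancova",
    "mancova_wilks",
    "emm_pairwise",
    "chi_or_fisher",
    "fisher_exact_rc",
    "bh_adjust",
    "partial_correlation",
    "multiple_regression",
    "icc",
    "percent_agreement",
]


@dataclass
class StatResult:
    effect: str
    statistic: float
    df: tuple[float, float] | float
    p: float
    p_adj: float | None = None
    effect_size: float | None = None
    test: str = ""
    extra: dict = field(default_factory=dict)


def _sum_code(values: Sequence) -> tuple[np.ndarray, list]:
    """Two-level factor -> +1/-1 column (levels sorted; first level +1)."""
    levels = sorted(set(values))
    if len(levels) != 2:
        raise ValueError(f"expected a two-level factor, got levels {levels}")
    x = np.where(np.asarray(values) == levels[0], 1.0, -1.0)
    return x, levels


@dataclass
class AncovaFit:
    """Fitted two-factor ANCOVA (sum-to-zero coding), enough state for EMMs."""

    coef: np.ndarray  # [intercept, fA, fB, fA:fB, covariate]
    sigma2: float  # residual variance (RSS / df_resid)
    df_resid: float
    xtx_inv: np.ndarray
    levels_a: list
    levels_b: list
    covariate_mean: float
    rss: float


def _ancova_design(diagnosis, sex, covariate):
    a, levels_a = _sum_code(diagnosis)
    b, levels_b = _sum_code(sex)
    z = np.asarray(covariate, dtype=float)
    X = np.column_stack([np.ones_like(a), a, b, a * b, z])
    return X, levels_a, levels_b


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def factorial_ancova(
    y,
    diagnosis,
    sex,
    covariate,
) -> tuple[list[StatResult], AncovaFit]:
    """Type-III tests of factor A (diagnosis), factor B (sex) and their
    interaction, adjusting for a continuous covariate.

    Returns the effect list and the fitted model (for EMM contrasts).
    Effect size is partial eta squared, SS_effect / (SS_effect + SS_resid).
    """
    y = np.asarray(y, dtype=float)
    X, levels_a, levels_b = _ancova_design(diagnosis, sex, covariate)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (aliased term)")
    cells = pd.Series(zip(diagnosis, sex)).value_counts()
    if len(cells) < 4:
        raise ValueError("empty cell in the diagnosis x sex design")
    if cells.min() <= 5:
        import warnings

        warnings.warn(f"smallest cell has n={cells.min()} (<= 5)", stacklevel=2)
    rss_full = _rss(y, X)
    df_resid = n - p
    sigma2 = rss_full / df_resid
    results = []
    term_cols = {"diagnosis": 1, "sex": 2, "interaction": 3, "covariate": 4}
    for name, col in term_cols.items():
        X_red = np.delete(X, col, axis=1)
        ss_effect = max(_rss(y, X_red) - rss_full, 0.0)
        f = (ss_effect / 1.0) / sigma2 if sigma2 > 0 else 0.0
        pval = float(sps.f.sf(f, 1, df_resid))
        denom = ss_effect + rss_full
        results.append(
            StatResult(
                effect=name,
                statistic=float(f),
                df=(1.0, float(df_resid)),
                p=pval,
                effect_size=float(ss_effect / denom) if denom > 0 else 0.0,
                test="F",
            )
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = AncovaFit(
        coef=beta,
        sigma2=sigma2,
        df_resid=df_resid,
        xtx_inv=np.linalg.inv(X.T @ X),
        levels_a=levels_a,
        levels_b=levels_b,
        covariate_mean=float(np.mean(np.asarray(covariate, dtype=float))),
        rss=rss_full,
    )
    return results, fit


def emm_pairwise(fit: AncovaFit, factor: str) -> pd.DataFrame:
    """Estimated marginal means at the covariate mean, equally weighted over
    the other factor, with the pairwise t contrast."""
    if factor == "diagnosis":
        levels, sign_col = fit.levels_a, 1
    elif factor == "sex":
        levels, sign_col = fit.levels_b, 2
    else:
        raise ValueError(f"unknown factor {factor!r}")
    rows = []
    vecs = {}
    for level, sign in zip(levels, (1.0, -1.0)):
        # equally weighted over the other factor: its code and the
        # interaction average to zero
        v = np.array([1.0, 0.0, 0.0, 0.0, fit.covariate_mean])
        v[sign_col] = sign
        emm = float(v @ fit.coef)
        se = math.sqrt(fit.sigma2 * float(v @ fit.xtx_inv @ v))
        vecs[level] = v
        rows.append({"level": level, "emmean": emm, "se": se})
    out = pd.DataFrame(rows)
    c = vecs[levels[0]] - vecs[levels[1]]
    est = float(c @ fit.coef)
    se = math.sqrt(fit.sigma2 * float(c @ fit.xtx_inv @ c))
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
    contrast = pd.DataFrame(
        [
            {
                "contrast": f"{levels[0]} - {levels[1]}",
                "estimate": est,
                "se": se,
                "t": t,
                "df": fit.df_resid,
                "p": p,
            }
        ]
    )
    return out, contrast


def mancova_wilks(Y, diagnosis, sex, covariate) -> list[StatResult]:
    """Wilks-lambda omnibus per effect via hypothesis/error SSCP matrices,
    with Rao's F approximation."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = Y.shape
    X, *_ = _ancova_design(diagnosis, sex, covariate)
    p_full = X.shape[1]
    if n <= d + p_full:
        raise ValueError("too few observations for the multivariate model")

    def sscp(Xd):
        beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        R = Y - Xd @ beta
        return R.T @ R

    E = sscp(X)
    if np.linalg.det(E) <= 0:
        raise ValueError("singular error SSCP")
    df_err = n - p_full
    results = []
    for name, col in {"diagnosis": 1, "sex": 2, "interaction": 3, "covariate": 4}.items():
        H = sscp(np.delete(X, col, axis=1)) - E
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        q = 1.0  # hypothesis df per effect
        # Rao's approximation
        t_ = math.sqrt((d**2 * q**2 - 4) / (d**2 + q**2 - 5)) if d**2 + q**2 - 5 > 0 else 1.0
        w = df_err + q - (d + q + 1) / 2.0
        df1 = d * q
        df2 = w * t_ - (d * q - 2) / 2.0
        lam_t = lam ** (1.0 / t_)
        f = (1.0 - lam_t) / lam_t * df2 / df1
        pval = float(sps.f.sf(f, df1, df2))
        results.append(
            StatResult(
                effect=name,
                statistic=float(f),
                df=(df1, float(df2)),
                p=pval,
                effect_size=1.0 - lam,
                test="Wilks",
                extra={"wilks_lambda": lam},
            )
        )
    return results


# ---------------------------------------------------------------------------
# contingency tables


def _expected(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total


def fisher_exact_rc(counts: np.ndarray, rel_tol: float = 1e-9) -> float:
    """Two-sided Fisher exact p for an r x c table by full enumeration over
    tables with the observed margins (point-probability rule)."""
    counts = np.asarray(counts, dtype=int)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    lgam = math.lgamma
    log_const = (
        sum(lgam(r + 1) for r in row_sums)
        + sum(lgam(c + 1) for c in col_sums)
        - lgam(n + 1)
    )

    def log_prob(cells: np.ndarray) -> float:
        return log_const - sum(lgam(v + 1) for v in cells)

    obs_lp = log_prob(counts.ravel())
    cutoff = obs_lp + rel_tol
    r, c = counts.shape
    total_p = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, lp_acc: float):
        nonlocal total_p
        if row == r - 1:
            lp = lp_acc - sum(lgam(v + 1) for v in remaining_cols)
            if lp <= cutoff:
                total_p += math.exp(lp)
            return
        target = row_sums[row]

        def fill(col: int, left: int, cells_lp: float, rem: np.ndarray):
            if col == c - 1:
                if left <= rem[col]:
                    rem2 = rem.copy()
                    rem2[col] -= left
                    recurse(row + 1, rem2, cells_lp - lgam(left + 1))
                return
            for v in range(min(left, rem[col]) + 1):
                rem2 = rem.copy()
                rem2[col] -= v
                fill(col + 1, left - v, cells_lp - lgam(v + 1), rem2)

        fill(0, int(target), lp_acc, remaining_cols)

    recurse(0, col_sums.copy(), log_const)
    return min(total_p, 1.0)


def chi_or_fisher(counts, expected_threshold: float = 5.0) -> StatResult:
    """Pearson chi-square, or Fisher's exact when >= 20% of cells have an
    expected count below ``expected_threshold``."""
    counts = np.asarray(counts)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    expected = _expected(counts)
    frac_small = float(np.mean(expected < expected_threshold))
    if frac_small >= 0.2:
        p = fisher_exact_rc(counts)
        return StatResult(
            effect="association",
            statistic=float("nan"),
            df=float("nan"),
            p=float(p),
            test="fisher",
            extra={"expected": expected, "frac_expected_lt_5": frac_small},
        )
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return StatResult(
        effect="association",
        statistic=float(chi2),
        df=float(dof),
        p=float(p),
        test="chi2",
        extra={"expected": expected, "frac_expected_lt_5": frac_small},
    )


def bh_adjust(pvalues, q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values (cumulative-min
    monotone, capped at 1) and rejection flags at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    reject = adj <= q
    return adj, reject


def partial_correlation(x, y, z) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on z.

    z may be a vector or a matrix of covariates; p is t-based with
    n - 2 - n_covariates degrees of freedom. Returns (nan, nan) when a
    residual vector is (numerically) constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = x.size
    if n < Z.shape[1] + 3:
        raise ValueError("too few observations for a partial correlation")
    D = np.column_stack([np.ones(n), Z])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - Z.shape[1]
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def multiple_regression(y, predictors: pd.DataFrame) -> dict:
    """OLS of y on the given predictors (an intercept is added).

    Returns the coefficient table, R^2, the overall F against the
    intercept-only model, and ``gate_passed`` — whether the omnibus is
    significant at .05, the gate for interpreting individual predictors.
    """
    import statsmodels.api as sm

    X = sm.add_constant(pd.DataFrame(predictors).astype(float))
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e10:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    model = sm.OLS(np.asarray(y, dtype=float), X).fit()
    coefs = pd.DataFrame(
        {
            "coef": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )
    return {
        "coefficients": coefs,
        "r_squared": float(model.rsquared),
        "f_statistic": float(model.fvalue),
        "f_p": float(model.f_pvalue),
        "df": (float(model.df_model), float(model.df_resid)),
        "gate_passed": bool(model.f_pvalue < 0.05),
    }


_ICC_LABELS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def icc(ratings) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is items x raters. Agreement bands: .5-.75 moderate,
    .75-.9 good, > .9 excellent. Returns (nan, 'undefined') when there is
    no between-item variance.
    """
    R = np.asarray(ratings, dtype=float)
    n, k = R.shape
    if n < 2:
        raise ValueError("need at least 2 items")
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 1e-12:
        return float("nan"), "undefined"
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = float((msr - mse) / denom)
    label = "poor"
    for cut, name in _ICC_LABELS:
        if value > cut:
            label = name
            break
    return value, label


def percent_agreement(labels_a, labels_b) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0:
        raise ValueError("empty label sequences")
    if a.shape != b.shape:
        raise ValueError("label sequences differ in length")
    return float(100.0 * np.mean(a == b))
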