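"""Latent profile analysis: diagonal-covariance Gaussian mixtures fit by EM.

Profiles (latent classes over continuous indicators) are modeled as a
k-component Gaussian mixture with class-specific diagonal covariances —
the common LPA default when the covariance structure is unrestricted
within the "variances free, covariances zero" family. Indicators are
z-scored before fitting so scales are comparable.

Model selection over k = 1..6 follows the usual LPA workflow: AIC, BIC,
normalized classification entropy, smallest/largest profile proportions,
and the parametric bootstrap likelihood-ratio test (BLRT) comparing k
against k-1. The free-parameter count is p = (k-1) + 2kd (mixing weights
plus per-class means and variances), so AIC = -2 ll + 2p and
BIC = -2 ll + p ln n. Classification entropy is the 0-1 normalized

    E = 1 - [ sum_i sum_c -p_ic ln p_ic ] / (n ln k)

(1 = perfectly separated classes; undefined for k = 1).

The EM implementation is intentionally self-contained: k-means++-style
seeding, best of ``restarts`` runs by log-likelihood, variance floor to
avoid degenerate spikes, and a restart when any class collapses below one
observation of weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "LPAModel",
    "BLRTResult",
    "zscore_matrix",
    "fit_lpa",
    "information_criteria",
    "classification_entropy",
    "blrt",
    "select_model",
    "profile_membership_test",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class FeatureMatrix:
    """z-scored indicator matrix with row ids and optional group labels."""

    X: np.ndarray  # n x d, standardized
    columns: list[str]
    ids: list[str]
    groups: list[str] | None = None
    center: np.ndarray | None = None  # original column means
    scale: np.ndarray | None = None  # original column SDs

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def inverse_transform(self) -> np.ndarray:
        if self.center is None or self.scale is None:
            raise ValueError("no transformation parameters retained")
        return self.X * self.scale + self.center


@dataclass
class LPAModel:
    k: int
    weights: np.ndarray
    means: np.ndarray  # k x d
    variances: np.ndarray  # k x d
    loglik: float
    posteriors: np.ndarray  # n x k
    aic: float
    bic: float
    entropy: float  # NaN for k = 1
    assignments: np.ndarray  # modal classes, length n
    seed: int
    restarts: int
    n_iter: int
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.posteriors.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_parameters(self) -> int:
        return (self.k - 1) + 2 * self.k * self.d

    def profile_proportions(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k) / self.n


@dataclass
class BLRTResult:
    k: int
    observed_lrt: float
    boot_lrts: np.ndarray
    p_value: float
    n_boot: int
    seed: int


def zscore_matrix(
    raw: pd.DataFrame,
    columns: Sequence[str] | None = None,
    id_column: str = "id",
    group_column: str | None = None,
) -> FeatureMatrix:
    """Column-standardize indicators; rows with missing values are dropped
    (listwise deletion). Raises for zero-variance columns, naming them."""
    df = raw.copy()
    if columns is None:
        columns = [
            c
            for c in df.columns
            if c not in (id_column, group_column) and pd.api.types.is_numeric_dtype(df[c])
        ]
    columns = list(columns)
    before = len(df)
    df = df.dropna(subset=columns)
    dropped = before - len(df)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "listwise deletion removed %d of %d rows", dropped, before
        )
    if len(df) < 2:
        raise ValueError("need at least 2 complete rows")
    X = df[columns].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = [c for c, s in zip(columns, scale) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {', '.join(zero)}")
    ids = (
        df[id_column].astype(str).tolist()
        if id_column in df.columns
        else [str(i) for i in range(len(df))]
    )
    groups = df[group_column].astype(str).tolist() if group_column else None
    return FeatureMatrix(
        X=(X - center) / scale,
        columns=columns,
        ids=ids,
        groups=groups,
        center=center,
        scale=scale,
    )


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def _log_density(X, weights, means, variances):
    """n x k matrix of log( w_c N(x | mu_c, diag sigma2_c) )."""
    n, d = X.shape
    out = np.empty((n, len(weights)))
    for c in range(len(weights)):
        diff2 = (X - means[c]) ** 2 / variances[c]
        out[:, c] = (
            math.log(weights[c])
            - 0.5 * (d * _LOG_2PI + np.log(variances[c]).sum())
            - 0.5 * diff2.sum(axis=1)
        )
    return out


def _em_once(X, k, rng, tol, max_iter, var_floor):
    n, d = X.shape
    # k-means++-style mean seeding
    means = np.empty((k, d))
    means[0] = X[rng.integers(n)]
    closest = np.full(n, np.inf)
    for c in range(1, k):
        dist = ((X - means[c - 1]) ** 2).sum(axis=1)
        closest = np.minimum(closest, dist)
        probs = closest / closest.sum() if closest.sum() > 0 else None
        means[c] = X[rng.choice(n, p=probs)]
    weights = np.full(k, 1.0 / k)
    variances = np.tile(np.maximum(X.var(axis=0), var_floor), (k, 1))
    loglik_path = []
    prev = -np.inf
    for it in range(1, max_iter + 1):
        logdens = _log_density(X, weights, means, variances)
        m = logdens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logdens - m).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logdens - lse[:, None])
        loglik_path.append(loglik)
        if loglik - prev < tol and it > 1:
            prev = loglik
            break
        prev = loglik
        nk = resp.sum(axis=0)
        if np.any(nk < 1.0):  # degenerate class: fewer than one observation
            return None
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for c in range(k):
            diff2 = (X - means[c]) ** 2
            variances[c] = np.maximum((resp[:, c] @ diff2) / nk[c], var_floor)
    return weights, means, variances, prev, resp, np.array(loglik_path)


def fit_lpa(
    X,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    var_floor: float = 1e-4,
    max_iter: int = 1000,
) -> LPAModel:
    """Best-of-restarts EM fit of a k-profile diagonal Gaussian mixture."""
    A = _as_array(X)
    n, d = A.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if k == 1:
        mu = A.mean(axis=0, keepdims=True)
        var = np.maximum(A.var(axis=0, keepdims=True), var_floor)
        ll = float(
            _log_density(A, np.array([1.0]), mu, var).sum()
        )
        post = np.ones((n, 1))
        model = LPAModel(
            k=1,
            weights=np.array([1.0]),
            means=mu,
            variances=var,
            loglik=ll,
            posteriors=post,
            aic=0.0,
            bic=0.0,
            entropy=float("nan"),
            assignments=np.zeros(n, dtype=int),
            seed=seed,
            restarts=restarts,
            n_iter=1,
            loglik_path=np.array([ll]),
        )
        model.aic, model.bic = information_criteria(model)
        return model
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        fit = _em_once(A, k, rng, tol, max_iter, var_floor)
        if fit is None:
            continue
        if best is None or fit[3] > best[3]:
            best = fit
    if best is None:
        raise RuntimeError(f"all {restarts} EM restarts degenerated for k={k}")
    weights, means, variances, ll, resp, path = best
    model = LPAModel(
        k=k,
        weights=weights,
        means=means,
        variances=variances,
        loglik=ll,
        posteriors=resp,
        aic=0.0,
        bic=0.0,
        entropy=0.0,
        assignments=resp.argmax(axis=1),
        seed=seed,
        restarts=restarts,
        n_iter=len(path),
        loglik_path=path,
    )
    model.aic, model.bic = information_criteria(model)
    model.entropy = classification_entropy(model)
    return model


def information_criteria(m: LPAModel) -> tuple[float, float]:
    p = m.n_parameters
    return (-2.0 * m.loglik + 2.0 * p, -2.0 * m.loglik + p * math.log(m.n))


def classification_entropy(m: LPAModel) -> float:
    """Normalized entropy in [0, 1]; 1 means crisp assignment. NaN for k=1."""
    if m.k < 2:
        return float("nan")
    p = np.clip(m.posteriors, 1e-300, 1.0)
    ent = float(-(p * np.log(p)).sum())
    return 1.0 - ent / (m.n * math.log(m.k))


def _sample_mixture(model: LPAModel, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(model.k, size=n, p=model.weights)
    Z = rng.standard_normal((n, model.d))
    return model.means[comp] + Z * np.sqrt(model.variances[comp])


def blrt(
    X,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-5,
    var_floor: float = 1e-4,
    max_iter: int = 500,
) -> BLRTResult:
    """Bootstrap likelihood-ratio test of k profiles against k-1.

    Parametric bootstrap: datasets of size n are simulated from the fitted
    (k-1)-profile model; both models are refit to each and the LRT
    2 (ll_k - ll_{k-1}) forms the null distribution. Add-one p-value.
    """
    if k < 2:
        raise ValueError("BLRT requires k >= 2")
    A = _as_array(X)
    n = A.shape[0]
    em = dict(restarts=restarts, tol=tol, var_floor=var_floor, max_iter=max_iter)
    null_model = fit_lpa(A, k - 1, seed=seed, **em)
    alt_model = fit_lpa(A, k, seed=seed + 1, **em)
    observed = 2.0 * (alt_model.loglik - null_model.loglik)
    rng = np.random.default_rng(seed)
    boot = []
    attempts = 0
    while len(boot) < n_boot:
        attempts += 1
        if attempts > 3 * n_boot:
            raise RuntimeError("too many failed bootstrap fits")
        Xb = _sample_mixture(null_model, n, rng)
        bseed = int(rng.integers(2**31 - 1))
        try:
            ll0 = fit_lpa(Xb, k - 1, seed=bseed, **em).loglik
            ll1 = fit_lpa(Xb, k, seed=bseed + 1, **em).loglik
        except RuntimeError:
            continue
        boot.append(2.0 * (ll1 - ll0))
    boot = np.array(boot)
    p = (1.0 + np.sum(boot >= observed)) / (1.0 + n_boot)
    return BLRTResult(
        k=k,
        observed_lrt=float(observed),
        boot_lrts=boot,
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def select_model(
    X,
    k_range: Sequence[int] = range(1, 7),
    restarts: int = 20,
    seed: int = 0,
    n_boot: int = 0,
    min_proportion: float = 0.05,
    **em_kwargs,
) -> pd.DataFrame:
    """Fit-index table over a range of profile counts.

    Columns: k, aic, bic, entropy, smallest/largest profile proportion, and
    (when ``n_boot`` > 0) the BLRT p-value for k vs k-1. The BIC-minimal
    model and any model containing a profile below ``min_proportion`` are
    flagged; the final choice is left to the analyst.
    """
    A = _as_array(X)
    rows = []
    for k in k_range:
        m = fit_lpa(A, k, restarts=restarts, seed=seed + k, **em_kwargs)
        props = m.profile_proportions()
        row = {
            "k": k,
            "loglik": m.loglik,
            "aic": m.aic,
            "bic": m.bic,
            "entropy": m.entropy,
            "smallest_proportion": float(props.min()) if k > 1 else float("nan"),
            "largest_proportion": float(props.max()) if k > 1 else float("nan"),
            "small_profile_flag": bool(k > 1 and props.min() < min_proportion),
        }
        if n_boot > 0 and k > 1:
            row["blrt_p"] = blrt(A, k, n_boot=n_boot, seed=seed + 100 * k).p_value
        elif n_boot > 0:
            row["blrt_p"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    table["bic_minimal"] = table["bic"] == table["bic"].min()
    return table


def profile_membership_test(
    assignments: Sequence[int],
    labels: Sequence[str],
    q: float = 0.10,
) -> pd.DataFrame:
    """Per (profile, group) over/under-representation vs the rest of the sample.

    Each cell is tested with a 2x2 table (in profile vs not, in group vs
    not) through the chi-square/Fisher dispatch with its 20%-expected-cell
    rule; p-values are Benjamini-Hochberg adjusted as one family.
    """
    from .stats import bh_adjust, chi_or_fisher

    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    rows = []
    for prof in np.unique(assignments):
        in_prof = assignments == prof
        for grp in np.unique(labels):
            in_grp = labels == grp
            tbl = np.array(
                [
                    [np.sum(in_prof & in_grp), np.sum(in_prof & ~in_grp)],
                    [np.sum(~in_prof & in_grp), np.sum(~in_prof & ~in_grp)],
                ]
            )
            res = chi_or_fisher(tbl)
            expected = in_prof.mean() * in_grp.sum()
            rows.append(
                {
                    "profile": int(prof),
                    "group": str(grp),
                    "observed": int(tbl[0, 0]),
                    "expected": float(expected),
                    "direction": "over" if tbl[0, 0] > expected else "under",
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    adj, reject = bh_adjust(out["p"].to_numpy(), q=q)
    out["p_adj"] = adj
    out["flagged"] = reject
    return out
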