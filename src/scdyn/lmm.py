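"""Linear mixed model machinery.

Two flavours are needed:

- a single-kernel (kinship) model ``y = W c + x b + u + e`` with
  ``u ~ N(0, sg^2 K)``, fitted per gene by maximum likelihood over the
  heritability ratio on the eigenbasis of ``K``; the variance ratio is
  estimated once under the null (covariates only) and reused for every
  cis variant of the gene, so per-variant tests reduce to weighted
  least squares in the whitened space (the score/EMMAX-style speedup);
- a crossed-random-effects model ``y = X b + sum_i u_i + e`` with
  grouped random intercepts (experiment, day, line, donor, ...),
  fitted by ML or REML through the Woodbury identity so the cost is
  linear in the number of observations.

Likelihood-ratio p-values for fixed effects always compare two ML fits
of nested mean models at the same variance structure (chi-square
reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_EPS = 1e-12


# ---------------------------------------------------------------------------
# single-kernel (kinship) model


@dataclass
class KinshipEigen:
    """Eigendecomposition of a kinship matrix, shared across genes."""

    values: np.ndarray  # (n,)
    vectors: np.ndarray  # (n, n)

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipEigen":
        K = np.asarray(K, dtype=float)
        s, u = np.linalg.eigh(K)
        return cls(values=np.maximum(s, 0.0), vectors=u)


@dataclass
class NullModelFit:
    """Per-gene null model (covariates only) at the ML variance ratio."""

    h2: float
    loglik: float
    rss0: float
    d: np.ndarray  # (n,) whitening weights h2 * s + (1 - h2)
    eigen: KinshipEigen
    Wt: np.ndarray  # whitened covariates
    y_resid: np.ndarray  # whitened phenotype with covariates projected out
    n: int


def _whiten(eigen: KinshipEigen, d: np.ndarray, M: np.ndarray) -> np.ndarray:
    return (eigen.vectors.T @ M) / np.sqrt(d)[:, None]


def _profile_ml(yt: np.ndarray, Wt: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Profile log-likelihood and RSS at fixed whitening weights."""
    n = yt.shape[0]
    beta, *_ = np.linalg.lstsq(Wt, yt, rcond=None)
    resid = yt - Wt @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, _EPS)
    ll = -0.5 * (
        n * np.log(2 * np.pi * sigma2) + n + np.log(d).sum()
    )
    return ll, rss


def fit_null_lmm(
    y: np.ndarray,
    W: np.ndarray,
    eigen: KinshipEigen,
    n_grid: int = 21,
) -> NullModelFit:
    """ML fit of the covariates-only model over the variance ratio h2.

    ``h2`` parameterises ``V = h2 * K + (1 - h2) * I``; a coarse grid
    plus bounded refinement locates the maximum (the likelihood is
    unimodal in practice; the boundary h2 = 0 recovers OLS exactly).
    """
    y = np.asarray(y, dtype=float).ravel()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = y.shape[0]
    yt_raw = eigen.vectors.T @ y
    Wt_raw = eigen.vectors.T @ W
    s = eigen.values

    def nll(h2: float) -> float:
        d = h2 * s + (1.0 - h2)
        d = np.maximum(d, _EPS)
        sq = np.sqrt(d)
        ll, _ = _profile_ml(yt_raw / sq, Wt_raw / sq[:, None], d)
        return -ll

    grid = np.linspace(0.0, 1.0 - 1e-4, n_grid)
    vals = np.array([nll(h) for h in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        h2 = float(res.x) if res.fun <= vals[j] else float(grid[j])
    else:
        h2 = float(grid[j])

    d = np.maximum(h2 * s + (1.0 - h2), _EPS)
    sq = np.sqrt(d)
    yt = yt_raw / sq
    Wt = Wt_raw / sq[:, None]
    ll, rss0 = _profile_ml(yt, Wt, d)
    # project covariates out once; reused for every variant
    q, _ = np.linalg.qr(Wt)
    y_resid = yt - q @ (q.T @ yt)
    return NullModelFit(
        h2=h2, loglik=ll, rss0=rss0, d=d, eigen=eigen, Wt=Wt,
        y_resid=y_resid, n=n,
    )


def lrt_variants(null: NullModelFit, X: np.ndarray) -> dict[str, np.ndarray]:
    """Per-variant LRT against the null, reusing the null variance ratio.

    ``X`` is observations x variants (already on the analysis rows).
    Returns arrays ``beta``, ``se``, ``stat``, ``p``; the effect size is
    in phenotype units per unit of the supplied genotype coding.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != null.n:
        raise ValueError("variant matrix row count does not match the model")
    Xt = (null.eigen.vectors.T @ X) / np.sqrt(null.d)[:, None]
    q, _ = np.linalg.qr(null.Wt)
    Xr = Xt - q @ (q.T @ Xt)

    xtx = (Xr**2).sum(axis=0)
    xty = Xr.T @ null.y_resid
    ok = xtx > _EPS
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    stat = np.zeros(X.shape[1])
    beta[ok] = xty[ok] / xtx[ok]
    rss1 = np.maximum(null.rss0 - np.where(ok, xty**2 / np.where(ok, xtx, 1.0), 0.0), _EPS)
    stat = null.n * (np.log(null.rss0) - np.log(rss1))
    stat = np.where(ok, np.maximum(stat, 0.0), 0.0)
    se[ok] = np.sqrt(rss1[ok] / null.n / xtx[ok])
    p = stats.chi2.sf(stat, df=1)
    p = np.where(ok, p, np.nan)
    return {"beta": beta, "se": se, "stat": stat, "p": p}


# ---------------------------------------------------------------------------
# crossed grouped random effects (Woodbury)


@dataclass
class CrossedLmmFit:
    loglik: float
    variances: dict[str, float]  # per random effect plus "residual"
    beta: np.ndarray
    converged: bool
    reml: bool


def _indicator(groups) -> np.ndarray:
    """Dense n x q indicator matrix of group membership."""
    import pandas as pd

    codes, _ = pd.factorize(np.asarray(groups))
    q = codes.max() + 1
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _crossed_nll(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    reml: bool,
) -> float:
    sigma2 = np.exp(theta)
    se2 = sigma2[-1]
    n = y.shape[0]
    if Zs:
        W = np.concatenate(
            [np.sqrt(sigma2[i]) * Z for i, Z in enumerate(Zs)], axis=1
        )
        q = W.shape[1]
        G = W.T @ W
        A = se2 * np.eye(q) + G
        cho = np.linalg.cholesky(A)

        def vinv(M: np.ndarray) -> np.ndarray:
            WtM = W.T @ M
            sol = np.linalg.solve(cho.T, np.linalg.solve(cho, WtM))
            return (M - W @ sol) / se2

        logdet = n * np.log(se2) + 2 * np.log(np.diag(cho)).sum() - q * np.log(se2)
    else:
        def vinv(M: np.ndarray) -> np.ndarray:
            return M / se2

        logdet = n * np.log(se2)

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
    resid = y - X @ beta
    quad = float(resid @ vinv(resid[:, None])[:, 0])
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    if reml:
        sign, ld2 = np.linalg.slogdet(XtViX)
        ll -= 0.5 * ld2
    return -ll


def fit_crossed_lmm(
    y: np.ndarray,
    X: np.ndarray,
    random_effects: dict[str, np.ndarray],
    reml: bool = False,
) -> CrossedLmmFit:
    """Fit grouped crossed random intercepts by (RE)ML.

    ``random_effects`` maps an effect name to its group labels (length
    n). Variances are optimised on the log scale by L-BFGS-B; the cost
    per evaluation is O(n q^2) with q the total number of groups.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response dimensions differ")
    names = list(random_effects)
    Zs = [_indicator(random_effects[k]) for k in names]
    for name, Z in zip(names, Zs):
        if Z.shape[1] < 2:
            raise ValueError(f"random effect {name!r} needs >= 2 levels")

    vy = max(float(np.var(y)), _EPS)
    k = len(Zs) + 1
    theta0 = np.log(np.full(k, vy / k))
    res = optimize.minimize(
        _crossed_nll,
        theta0,
        args=(y, X, Zs, reml),
        method="L-BFGS-B",
        bounds=[(np.log(vy) - 23.0, np.log(vy) + 6.0)] * k,
    )
    sigma2 = np.exp(res.x)
    nll = _crossed_nll(res.x, y, X, Zs, reml)
    # recover beta at the optimum
    se2 = sigma2[-1]
    if Zs:
        W = np.concatenate(
            [np.sqrt(sigma2[i]) * Z for i, Z in enumerate(Zs)], axis=1
        )
        A = se2 * np.eye(W.shape[1]) + W.T @ W
        ViX = (X - W @ np.linalg.solve(A, W.T @ X)) / se2
        Viy = (y - W @ np.linalg.solve(A, W.T @ y)) / se2
    else:
        ViX, Viy = X / se2, y / se2
    beta = np.linalg.lstsq(X.T @ ViX, X.T @ Viy, rcond=None)[0]
    variances = {name: float(sigma2[i]) for i, name in enumerate(names)}
    variances["residual"] = float(se2)
    return CrossedLmmFit(
        loglik=-float(nll),
        variances=variances,
        beta=beta,
        converged=bool(res.success),
        reml=reml,
    )


def lrt_fixed_effect(
    y: np.ndarray,
    X_full: np.ndarray,
    X_null: np.ndarray,
    random_effects: dict[str, np.ndarray],
    df: int = 1,
) -> dict[str, float]:
    """ML likelihood-ratio test of nested fixed-effect designs."""
    full = fit_crossed_lmm(y, X_full, random_effects, reml=False)
    null = fit_crossed_lmm(y, X_null, random_effects, reml=False)
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return {
        "stat": stat,
        "p": float(stats.chi2.sf(stat, df=df)),
        "loglik_full": full.loglik,
        "loglik_null": null.loglik,
        "beta": float(full.beta[-1]) if full.beta.size else np.nan,
        "converged": float(full.converged and null.converged),
    }
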