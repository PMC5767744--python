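"""Mixed linear model machinery for marker association.

The trait model is y = X b + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I); X holds the intercept and the Q-matrix covariates.
The null model is fitted once by profiled REML over the variance ratio
delta = sigma_e^2 / sigma_g^2 on the eigenbasis of K, and the fitted
variance structure is then reused for every marker test (the
population-parameters-previously-determined, P3D/EMMAX strategy). Exact
per-marker REML refits are available behind a flag. Pseudo-heritability is
h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) = 1 / (1 + delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class NullMLM:
    """Fitted null mixed model plus the eigen-rotation cache for P3D scans."""

    varcomp: VarianceComponents
    delta: float
    reml_loglik: float
    eigenvalues: np.ndarray   # of K
    eigenvectors: np.ndarray
    y: np.ndarray             # original scale
    X: np.ndarray             # covariates incl. intercept
    K: np.ndarray

    @property
    def h2(self) -> float:
        return self.varcomp.h2


def _check_psd(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    w, v = np.linalg.eigh(K)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    return np.clip(w, 0.0, None), v


def _reml_loglik(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                 S: np.ndarray, logdet_xx: float) -> float:
    delta = 10.0 ** log_delta
    n, p = Xt.shape
    w = 1.0 / (S + delta)
    Xw = Xt * w[:, None]
    xtwx = Xt.T @ Xw
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    r = yt - Xt @ beta
    rwr = float(r @ (w * r))
    nf = n - p
    ll = 0.5 * (
        nf * np.log(nf / (2 * np.pi)) - nf - nf * np.log(rwr)
        + np.sum(np.log(w)) - logdet_xtwx + logdet_xx
    )
    return ll


def fit_null_mlm(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                 grid: int = 81) -> NullMLM:
    """Profile-REML fit of the null model.

    delta is optimized on a log10 grid over [1e-5, 1e5] and refined by
    bounded golden-section search around the grid optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    S, U = _check_psd(K)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    log_grid = np.linspace(-5, 5, grid)
    lls = np.array([_reml_loglik(ld, yt, Xt, S, logdet_xx) for ld in log_grid])
    i = int(np.argmax(lls))
    lo = log_grid[max(i - 1, 0)]
    hi = log_grid[min(i + 1, grid - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik(ld, yt, Xt, S, logdet_xx),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    log_delta = float(res.x)
    if i in (0, grid - 1):
        warnings.warn("REML optimum at the delta grid boundary")
    delta = 10.0 ** log_delta

    n, p = Xt.shape
    w = 1.0 / (S + delta)
    Xw = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma_g2 = float(r @ (w * r)) / (n - p)
    sigma_e2 = delta * sigma_g2
    return NullMLM(
        varcomp=VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2),
        delta=delta,
        reml_loglik=float(-res.fun),
        eigenvalues=S, eigenvectors=U, y=y, X=X, K=np.asarray(K, dtype=float),
    )


def _partial_regression(yw: np.ndarray, Xw: np.ndarray, Mw: np.ndarray):
    """Per-column effect/SE/t/p of Mw in OLS of yw on [Xw, Mw[:, j]].

    Frisch-Waugh: project Xw out of yw and each marker column, then simple
    regression of residuals. Exact, vectorized over markers.
    """
    n, p = Xw.shape
    Q, _ = np.linalg.qr(Xw)
    y_res = yw - Q @ (Q.T @ yw)
    M_res = Mw - Q @ (Q.T @ Mw)
    mm = np.einsum("ij,ij->j", M_res, M_res)
    my = M_res.T @ y_res
    yy = float(y_res @ y_res)
    ok = mm > 1e-12 * max(1.0, float(np.max(mm, initial=0.0)))
    beta = np.full(Mw.shape[1], np.nan)
    se = np.full(Mw.shape[1], np.nan)
    beta[ok] = my[ok] / mm[ok]
    rss = yy - beta[ok] ** 2 * mm[ok]
    df = n - p - 1
    rss = np.clip(rss, 0.0, None)
    se[ok] = np.sqrt(rss / df / mm[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p_val = np.full(Mw.shape[1], np.nan)
    p_val[ok] = 2 * stats.t.sf(np.abs(t[ok]), df)
    p_val[ok] = np.clip(p_val[ok], np.finfo(float).tiny, 1.0)
    return beta, se, t, p_val, df


def gls_scan(null: NullMLM, markers: np.ndarray):
    """P3D marker scan under the fitted null variance structure.

    ``markers`` is an accession x marker dosage matrix; NaN entries drop the
    corresponding accessions for that marker only. Returns arrays
    (effect, se, t, p) aligned with marker columns. Markers that are missing
    or monomorphic on the retained accessions yield NaN effect and p = 1.
    """
    markers = np.asarray(markers, dtype=float)
    n, m = markers.shape
    if n != len(null.y):
        raise ValueError("marker matrix and trait length differ")
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.ones(m)

    S, U = null.eigenvalues, null.eigenvectors
    w = 1.0 / (S + null.delta)
    sqw = np.sqrt(w)

    complete = ~np.isnan(markers).any(axis=0)
    if complete.any():
        yw = sqw * (U.T @ null.y)
        Xw = sqw[:, None] * (U.T @ null.X)
        Mw = sqw[:, None] * (U.T @ markers[:, complete])
        b, s, t, p, _ = _partial_regression(yw, Xw, Mw)
        effect[complete], se[complete] = b, s
        tval[complete], pval[complete] = t, p

    # group incomplete markers by missingness pattern; whiten on the subset
    incomplete = np.where(~complete)[0]
    if incomplete.size:
        sigma = null.varcomp.sigma_g2 * null.K + null.varcomp.sigma_e2 * np.eye(n)
        patterns: dict[bytes, list[int]] = {}
        for j in incomplete:
            mask = ~np.isnan(markers[:, j])
            patterns.setdefault(mask.tobytes(), []).append(j)
        for key, cols in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            if mask.sum() <= null.X.shape[1] + 1:
                continue
            sub = np.ix_(mask, mask)
            L = np.linalg.cholesky(
                sigma[sub] + 1e-10 * np.eye(int(mask.sum()))
            )
            from scipy.linalg import solve_triangular

            yw = solve_triangular(L, null.y[mask], lower=True)
            Xw = solve_triangular(L, null.X[mask], lower=True)
            Mw = solve_triangular(L, markers[np.ix_(mask, cols)], lower=True)
            b, s, t, p, _ = _partial_regression(yw, Xw, Mw)
            effect[cols], se[cols] = b, s
            tval[cols], pval[cols] = t, p
    return effect, se, tval, pval


def exact_scan(y: np.ndarray, X: np.ndarray, K: np.ndarray,
               markers: np.ndarray):
    """Per-marker REML refit (slow; the exact alternative to P3D)."""
    markers = np.asarray(markers, dtype=float)
    m = markers.shape[1]
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.ones(m)
    for j in range(m):
        col = markers[:, j]
        mask = ~np.isnan(col)
        if mask.sum() <= X.shape[1] + 1 or np.ptp(col[mask]) == 0:
            continue
        sub_null = fit_null_mlm(
            y[mask], np.column_stack([X[mask], col[mask]]),
            K[np.ix_(mask, mask)],
        )
        # Wald test of the marker coefficient under the refitted structure
        S, U = sub_null.eigenvalues, sub_null.eigenvectors
        w = 1.0 / (S + sub_null.delta)
        sqw = np.sqrt(w)
        yw = sqw * (U.T @ y[mask])
        Xw = sqw[:, None] * (U.T @ X[mask])
        Mw = sqw[:, None] * (U.T @ col[mask, None])
        b, s, t, p, _ = _partial_regression(yw, Xw, Mw)
        effect[j], se[j], tval[j], pval[j] = b[0], s[0], t[0], p[0]
    return effect, se, tval, pval
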