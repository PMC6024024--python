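"""Multi-component REML estimation of genomic variance components.

The model is ``y ~ N(X beta, sum_G A_G sigma2_G + I sigma2_e)`` and the
estimator maximizes the restricted likelihood by average-information (AI)
Newton steps with EM-REML fallback: the first iterations use EM updates, and
any AI proposal that would decrease the restricted log-likelihood or leave
the admissible region is replaced by step-halving and finally an EM step, so
the likelihood never decreases across accepted iterations. Components
driven to zero are constrained at a small floor (1e-8 x var(y)) and read as
"~0"; standard errors come from the inverse AI matrix at convergence, with
heritability-proportion SEs by the delta method.

The single-GRM case is solved through one eigendecomposition of the GRM
(every iteration is then O(n)); the general multi-GRM case uses direct dense
solves, which is comfortable at cohort scale (n up to a few thousand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .datatypes import GRM, GenotypeMatrix
from .grm import compute_grm


@dataclass
class VarianceComponentFit:
    """REML result: per-component variances, proportions and diagnostics."""

    labels: list
    sigma2: np.ndarray  # per genetic component
    sigma2_e: float
    h2: np.ndarray
    h2_se: np.ndarray
    sigma2_se: np.ndarray
    beta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    identifiable: bool = True

    @property
    def sigma2_total(self) -> float:
        return float(self.sigma2.sum() + self.sigma2_e)


@dataclass
class _State:
    loglik: float
    score: np.ndarray
    ai: np.ndarray
    beta: np.ndarray


class _DenseEngine:
    """Direct-solve likelihood/score/AI evaluation for k >= 1 GRMs."""

    def __init__(self, K_list, y, X):
        self.K = K_list
        self.y = y
        self.X = X
        self.n, self.p = X.shape

    def evaluate(self, theta) -> _State:
        n, p = self.n, self.p
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.K):
            V += t * K
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        W = Vinv @ self.X
        XtVX = self.X.T @ W
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        XtVX_inv = np.linalg.inv(XtVX)
        P = Vinv - W @ XtVX_inv @ W.T
        Py = P @ self.y
        ypy = float(self.y @ Py)
        loglik = -0.5 * (logdet_v + logdet_x + ypy)
        k = len(self.K) + 1
        APy = np.empty((n, k))
        tr_pa = np.empty(k)
        for i, K in enumerate(self.K):
            APy[:, i] = K @ Py
            tr_pa[i] = float(np.sum(P * K))
        APy[:, -1] = Py
        tr_pa[-1] = float(np.trace(P))
        quad = APy.T @ Py  # y'P A_i P y
        score = -0.5 * (tr_pa - quad)
        PAPy = P @ APy
        ai = 0.5 * (APy.T @ PAPy)
        beta = XtVX_inv @ (W.T @ self.y)
        return _State(loglik, score, ai, beta)


class _EigenEngine:
    """O(n)-per-iteration evaluation for a single GRM via eigenrotation."""

    def __init__(self, K, y, X):
        self.d, U = np.linalg.eigh(K)
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = X.shape

    def evaluate(self, theta) -> _State:
        sg, se = theta
        v = sg * self.d + se
        if (v <= 0).any():
            raise np.linalg.LinAlgError("V not positive definite")
        vin = 1.0 / v
        Xw = self.X * vin[:, None]
        XtVX = self.X.T @ Xw
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ (Xw.T @ self.y)

        def P_dot(u):
            return u * vin - Xw @ (XtVX_inv @ (Xw.T @ u))

        Py = P_dot(self.y)
        ypy = float(self.y @ Py)
        loglik = -0.5 * (np.log(v).sum() + logdet_x + ypy)
        # tr(P A) = tr(V^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X), A diag here
        tr_pa = np.empty(2)
        quad = np.empty(2)
        cols = (self.d, np.ones(self.n))
        for i, a in enumerate(cols):
            tr_pa[i] = float(a @ vin) - float(
                np.trace(XtVX_inv @ (self.X.T @ (self.X * (a * vin * vin)[:, None])))
            )
            quad[i] = float((a * Py) @ Py)
        score = -0.5 * (tr_pa - quad)
        ai = np.empty((2, 2))
        u = [self.d * Py, Py]
        pu = [P_dot(x) for x in u]
        for i in range(2):
            for j in range(i, 2):
                ai[i, j] = ai[j, i] = 0.5 * float(u[i] @ pu[j])
        return _State(loglik, score, ai, beta)


class GREML(BaseEstimator):
    """Genomic REML (GREML) variance-component estimator.

    Parameters
    ----------
    max_iter : int
        Iteration cap; non-convergence flags the result instead of raising.
    tol_loglik, tol_param : float
        Convergence requires |delta logL| < ``tol_loglik`` and a maximum
        relative parameter change < ``tol_param``.
    n_em_steps : int
        Leading EM-REML iterations before AI steps begin.
    floor_frac : float
        Zero-floor for variance components, as a fraction of var(y).

    Attributes (after :meth:`fit`)
    ------------------------------
    sigma2_ : per-component genetic variances; sigma2_e_ : residual variance;
    h2_ : per-component proportions of phenotypic variance with h2_se_;
    beta_ : fixed-effect estimates; loglik_; n_iter_; converged_;
    identifiable_ : False when the AI matrix is numerically singular (e.g. a
    GRM proportional to the identity).
    """

    def __init__(self, max_iter: int = 100, tol_loglik: float = 1e-6,
                 tol_param: float = 1e-5, n_em_steps: int = 2,
                 floor_frac: float = 1e-8):
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param
        self.n_em_steps = n_em_steps
        self.floor_frac = floor_frac

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_matrices(K):
        if isinstance(K, (GRM, np.ndarray)):
            K = [K]
        mats, labels = [], []
        for i, k in enumerate(K):
            if isinstance(k, GRM):
                mats.append(k.matrix)
                labels.append(k.label)
            else:
                mats.append(np.asarray(k, dtype=np.float64))
                labels.append(f"K{i + 1}")
        return mats, labels

    def fit(self, K, y, X=None, labels=None):
        """Fit variance components for phenotype ``y``.

        ``K`` is a GRM / square array or a list of them (one per genetic
        component); ``X`` the fixed-effect design (default: intercept).
        """
        mats, default_labels = self._as_matrices(K)
        self.labels_ = list(labels) if labels is not None else default_labels
        y = np.asarray(y, dtype=np.float64).ravel()
        n = y.size
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        for m in mats:
            if m.shape != (n, n):
                raise ValueError("GRM dimensions do not match phenotype length")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")

        k = len(mats)
        vy = float(np.var(y))
        floor = self.floor_frac * vy
        theta = np.full(k + 1, vy / (k + 1))
        engine = _EigenEngine(mats[0], y, X) if k == 1 else _DenseEngine(mats, y, X)

        state = engine.evaluate(theta)
        loglik_path = [float(state.loglik)]
        converged = False
        identifiable = True
        it = 0
        for it in range(1, self.max_iter + 1):
            use_em = it <= self.n_em_steps
            cand, st_new = None, None
            if not use_em:
                cond = np.linalg.cond(state.ai)
                if not np.isfinite(cond) or cond > 1e10:
                    identifiable = False
                    use_em = True
                else:
                    delta = np.linalg.solve(state.ai, state.score)
                    step = 1.0
                    while step >= 1.0 / 64:
                        cand = np.maximum(theta + step * delta, floor)
                        try:
                            st_new = engine.evaluate(cand)
                        except np.linalg.LinAlgError:
                            st_new = None
                        if st_new is not None and st_new.loglik >= state.loglik - 1e-10:
                            break
                        st_new = None
                        step /= 2.0
                    if st_new is None:
                        use_em = True
            if use_em:
                quad = state.score * 2.0  # recover y'PAPy - tr(PA)
                cand = np.maximum(theta + theta**2 * quad / n, floor)
                st_new = engine.evaluate(cand)

            dll = st_new.loglik - state.loglik
            dpar = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
            theta, state = cand, st_new
            loglik_path.append(float(state.loglik))
            if abs(dll) < self.tol_loglik and dpar < self.tol_param:
                converged = True
                break

        if not identifiable:
            warnings.warn(
                "variance components are not identifiable (singular AI matrix); "
                "estimates are arbitrary along the confounded direction",
                stacklevel=2,
            )

        # covariance of variance components from the AI matrix
        try:
            cov = np.linalg.inv(state.ai)
        except np.linalg.LinAlgError:
            cov = np.full((k + 1, k + 1), np.nan)
        sig_tot = float(theta.sum())
        h2 = theta[:-1] / sig_tot
        h2_se = np.empty(k)
        for i in range(k):
            grad = np.full(k + 1, -theta[i] / sig_tot**2)
            grad[i] += 1.0 / sig_tot
            h2_se[i] = np.sqrt(max(float(grad @ cov @ grad), 0.0))

        self.sigma2_ = theta[:-1].copy()
        self.sigma2_e_ = float(theta[-1])
        self.h2_ = h2
        self.h2_se_ = h2_se
        self.sigma2_se_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.beta_ = state.beta
        self.loglik_ = float(state.loglik)
        self.loglik_path_ = loglik_path
        self.n_iter_ = it
        self.converged_ = converged
        self.identifiable_ = identifiable
        self.floor_ = floor
        return self

    def result_(self) -> VarianceComponentFit:
        return VarianceComponentFit(
            labels=self.labels_, sigma2=self.sigma2_, sigma2_e=self.sigma2_e_,
            h2=self.h2_, h2_se=self.h2_se_, sigma2_se=self.sigma2_se_[:-1],
            beta=self.beta_, loglik=self.loglik_, n_iter=self.n_iter_,
            converged=self.converged_, identifiable=self.identifiable_,
        )


def fit_reml(y, X, grms, **kwargs) -> VarianceComponentFit:
    """Functional wrapper over :class:`GREML` (one fit, many GRMs)."""
    est = GREML(**kwargs)
    est.fit(grms, y, X=X)
    return est.result_()


def partition_analysis(
    y,
    X,
    g: GenotypeMatrix,
    partitions: dict,
    mode: str = "joint",
) -> pd.DataFrame:
    """Separate or joint variance partitioning over labelled SNP subsets.

    ``separate`` fits one single-GRM model per label; ``joint`` fits all
    partition GRMs simultaneously (subsets must then be disjoint). Returns a
    table with one row per label: n_snps, h2, SE, sigma2, loglik, converged.
    """
    if mode not in ("separate", "joint"):
        raise ValueError("mode must be 'separate' or 'joint'")
    if mode == "joint":
        seen: set = set()
        for label, ids in partitions.items():
            dup = seen.intersection(ids)
            if dup:
                raise ValueError(
                    f"joint mode needs disjoint subsets; '{label}' overlaps "
                    f"{len(dup)} SNPs with another subset"
                )
            seen.update(ids)
    grms = {
        label: compute_grm(g, subset=ids, label=label)
        for label, ids in partitions.items()
    }
    rows = []
    if mode == "separate":
        for label, grm in grms.items():
            fit = fit_reml(y, X, [grm])
            rows.append({
                "label": label, "n_snps": grm.n_snps, "mode": mode,
                "h2": float(fit.h2[0]), "se": float(fit.h2_se[0]),
                "sigma2": float(fit.sigma2[0]), "loglik": fit.loglik,
                "converged": fit.converged,
            })
    else:
        fit = fit_reml(y, X, list(grms.values()))
        for i, (label, grm) in enumerate(grms.items()):
            rows.append({
                "label": label, "n_snps": grm.n_snps, "mode": mode,
                "h2": float(fit.h2[i]), "se": float(fit.h2_se[i]),
                "sigma2": float(fit.sigma2[i]), "loglik": fit.loglik,
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def chromosome_length_regression(h2_per_chrom, lengths):
    """OLS of per-chromosome h2 on physical length (bp).

    Returns ``(slope, intercept, r_squared)``. Accepts mappings with shared
    keys or aligned sequences.
    """
    from scipy.stats import linregress

    if isinstance(h2_per_chrom, dict) and isinstance(lengths, dict):
        keys = sorted(h2_per_chrom)
        h2 = np.array([h2_per_chrom[k] for k in keys], dtype=float)
        ln = np.array([lengths[k] for k in keys], dtype=float)
    else:
        h2 = np.asarray(h2_per_chrom, dtype=float)
        ln = np.asarray(lengths, dtype=float)
    if np.allclose(h2, h2[0]):
        return 0.0, float(h2[0]), 0.0  # constant response: no relationship
    res = linregress(ln, h2)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
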