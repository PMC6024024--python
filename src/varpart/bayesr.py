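"""Four-component Bayesian mixture regression over SNP effects (BayesR).

Each SNP effect is drawn from a mixture of normals with variances
``(0, 1e-4, 1e-3, 1e-2) x sigma2_A``, where ``sigma2_A`` is the trait's
additive genetic variance. A single-site Gibbs sampler sweeps the markers:
the component indicator is drawn from its conditional posterior (current
mixture proportions times the marginal likelihood of the SNP's residual
score), the effect from its conditional normal, residuals are updated
incrementally, mixture proportions from the Dirichlet posterior of the
indicator counts, and the residual variance from its scaled inverse
chi-square conditional. ``sigma2_A`` is fixed from a prior single-GRM REML
fit by default (it can also be given explicitly or sampled).

Genotypes are centered but not variance-standardized inside the sampler, so
``2 p (1-p) beta^2`` is a SNP's contribution to the genetic variance —
matching the %Vg formula ``100 x 2 p q beta^2 / sigma2_A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix


@dataclass
class MixtureConfig:
    """Sampler settings. ``sigma2_additive`` is 'reml' (fix from a prior
    single-GRM REML fit), 'sample' (scaled inverse-chi-square update), or an
    explicit variance."""

    multipliers: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    chain_length: int = 50_000
    burn_in: int = 20_000
    thin: int = 10
    dirichlet_alpha: float = 1.0
    sigma2_additive: object = "reml"
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.multipliers, dtype=float)
        if m[0] != 0.0 or (np.diff(m) <= 0).any():
            raise ValueError("multipliers must start at 0 and strictly increase")
        if not 0 <= self.burn_in < self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BayesRResult:
    """Posterior summaries of the mixture fit."""

    snp_ids: np.ndarray
    pi: np.ndarray  # posterior mean mixture proportions
    beta: np.ndarray  # per-SNP posterior mean effects
    comp_prob: np.ndarray  # (m, k) membership probabilities
    expected_counts: np.ndarray  # posterior mean SNP count per component
    var_by_component: np.ndarray  # genetic variance attributed per component
    sigma2_G: float
    sigma2_e: float
    sigma2_additive: float
    multipliers: tuple = (0.0, 1e-4, 1e-3, 1e-2)
    n_draws: int = 0

    @property
    def nsnp_nonzero(self) -> float:
        """Expected number of SNPs in the nonzero-variance components."""
        return float(self.expected_counts[1:].sum())


@njit(cache=True, fastmath=True)
def _gibbs(Xt, y, xtx, het, mults, sigma2A, alpha, n_iter, burn_in, thin,
           sigma2e_init, fix_sigma2e, sample_sigma2A, seed):
    # Xt is (m, n) float32: each SNP's centered dosages are a contiguous row.
    # Residuals are kept in float32 for SIMD speed and refreshed from the
    # exact float64 state every 100 sweeps to stop round-off drift.
    m, n = Xt.shape
    k = mults.shape[0]
    np.random.seed(seed)
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    r = y.astype(np.float32)
    pi = np.full(k, 1.0 / k)
    sigma2e = sigma2e_init
    s2a = sigma2A

    pi_sum = np.zeros(k)
    beta_sum = np.zeros(m)
    comp_hits = np.zeros((m, k))
    count_sum = np.zeros(k)
    varcomp_sum = np.zeros(k)
    sigma2e_sum = 0.0
    s2a_sum = 0.0
    n_draws = 0

    logw = np.empty(k)
    w = np.empty(k)
    counts = np.empty(k)

    for it in range(n_iter):
        if it % 100 == 0 and it > 0:  # exact residual refresh
            r64 = y.copy()
            for j in range(m):
                if beta[j] != 0.0:
                    for i in range(n):
                        r64[i] -= Xt[j, i] * beta[j]
            for i in range(n):
                r[i] = np.float32(r64[i])
        counts[:] = 0.0
        for j in range(m):
            bj = beta[j]
            row = Xt[j]
            s = np.float32(0.0)
            for i in range(n):
                s += row[i] * r[i]
            rhs = np.float64(s) + xtx[j] * bj
            mx = -1e300
            for c in range(k):
                v = xtx[j] * sigma2e + xtx[j] * xtx[j] * mults[c] * s2a
                lw = np.log(pi[c]) - 0.5 * np.log(v) - 0.5 * rhs * rhs / v
                logw[c] = lw
                if lw > mx:
                    mx = lw
            tot = 0.0
            for c in range(k):
                w[c] = np.exp(logw[c] - mx)
                tot += w[c]
            u = np.random.random() * tot
            cj = k - 1
            acc = 0.0
            for c in range(k):
                acc += w[c]
                if u <= acc:
                    cj = c
                    break
            comp[j] = cj
            counts[cj] += 1.0
            if mults[cj] == 0.0:
                bnew = 0.0
            else:
                vc = mults[cj] * s2a
                prec = xtx[j] / sigma2e + 1.0 / vc
                mean = (rhs / sigma2e) / prec
                bnew = mean + np.random.normal() / np.sqrt(prec)
            if bnew != bj:
                diff = np.float32(bnew - bj)
                for i in range(n):
                    r[i] -= row[i] * diff
            beta[j] = bnew
        if not np.isfinite(r[0]):
            raise RuntimeError("non-finite residuals in Gibbs sweep")

        # mixture proportions | indicator counts
        tot = 0.0
        for c in range(k):
            pi[c] = np.random.gamma(alpha + counts[c], 1.0)
            tot += pi[c]
        for c in range(k):
            pi[c] /= tot

        # residual variance | residuals (flat scaled-inverse-chi-square)
        if not fix_sigma2e:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            sigma2e = sse / np.random.chisquare(n)

        if sample_sigma2A:
            q = 0
            ssb = 0.0
            for j in range(m):
                if comp[j] > 0:
                    q += 1
                    ssb += beta[j] * beta[j] / mults[comp[j]]
            if q > 2:
                s2a = ssb / np.random.chisquare(q)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_draws += 1
            sigma2e_sum += sigma2e
            s2a_sum += s2a
            for c in range(k):
                pi_sum[c] += pi[c]
                count_sum[c] += counts[c]
            for j in range(m):
                beta_sum[j] += beta[j]
                comp_hits[j, comp[j]] += 1.0
                if comp[j] > 0:
                    varcomp_sum[comp[j]] += het[j] * beta[j] * beta[j]

    return (pi_sum, beta_sum, comp_hits, count_sum, varcomp_sum,
            sigma2e_sum, s2a_sum, n_draws)


class BayesRMixture(BaseEstimator):
    """sklearn-style wrapper around the Gibbs kernel.

    Attributes after :meth:`fit`: ``result_`` (:class:`BayesRResult`) plus
    the flat views ``pi_``, ``beta_``, ``sigma2_G_``, ``sigma2_e_``.
    """

    def __init__(self, multipliers=(0.0, 1e-4, 1e-3, 1e-2), chain_length=50_000,
                 burn_in=20_000, thin=10, dirichlet_alpha=1.0,
                 sigma2_additive="reml", fix_sigma2_e=None, seed=0):
        self.multipliers = multipliers
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.thin = thin
        self.dirichlet_alpha = dirichlet_alpha
        self.sigma2_additive = sigma2_additive
        self.fix_sigma2_e = fix_sigma2_e
        self.seed = seed

    def fit(self, G, y):
        """Run the chain on genotypes ``G`` (GenotypeMatrix or dosage array)
        and a centered adjusted phenotype ``y``."""
        cfg = MixtureConfig(
            multipliers=tuple(self.multipliers), chain_length=self.chain_length,
            burn_in=self.burn_in, thin=self.thin,
            dirichlet_alpha=self.dirichlet_alpha,
            sigma2_additive=self.sigma2_additive, seed=self.seed,
        )
        if isinstance(G, GenotypeMatrix):
            X = G.imputed_dosages()
            snp_ids = G.snp_ids
        else:
            X = np.asarray(G, dtype=np.float64)
            snp_ids = np.array([f"snp{i + 1}" for i in range(X.shape[1])])
        y = np.asarray(y, dtype=np.float64).ravel()
        y = y - y.mean()
        p = X.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        if not poly.all():
            raise ValueError("subset contains monomorphic SNPs; QC them away first")
        het = 2.0 * p * (1.0 - p)
        Xc = (X - X.mean(axis=0)).astype(np.float32)
        Xt = np.ascontiguousarray(Xc.T)  # (m, n): SNP-major for the kernel
        xtx = (Xt.astype(np.float64) ** 2).sum(axis=1)

        sample_s2a = cfg.sigma2_additive == "sample"
        if cfg.sigma2_additive == "reml":
            from .grm import compute_grm
            from .reml import GREML

            K = (Xc.astype(np.float64) / np.sqrt(het)) @ \
                (Xc.astype(np.float64) / np.sqrt(het)).T / Xc.shape[1]
            null = GREML().fit(K, y)
            s2a = max(float(null.sigma2_[0]), 1e-6 * float(np.var(y)))
        elif sample_s2a:
            s2a = 0.5 * float(np.var(y))  # starting value, then sampled
        else:
            s2a = float(cfg.sigma2_additive)
            if s2a <= 0:
                raise ValueError("sigma2_additive must be positive")

        fix_e = self.fix_sigma2_e is not None
        s2e0 = float(self.fix_sigma2_e) if fix_e else 0.5 * float(np.var(y)) + 1e-12

        (pi_sum, beta_sum, comp_hits, count_sum, varcomp_sum,
         s2e_sum, s2a_sum, n_draws) = _gibbs(
            Xt, y, xtx, het, np.asarray(cfg.multipliers, dtype=np.float64),
            s2a, float(cfg.dirichlet_alpha), int(cfg.chain_length),
            int(cfg.burn_in), int(cfg.thin), s2e0, fix_e, sample_s2a,
            int(cfg.seed) % (2**31 - 1),
        )
        self.result_ = BayesRResult(
            snp_ids=snp_ids,
            pi=pi_sum / n_draws,
            beta=beta_sum / n_draws,
            comp_prob=comp_hits / n_draws,
            expected_counts=count_sum / n_draws,
            var_by_component=varcomp_sum / n_draws,
            sigma2_G=float(varcomp_sum.sum() / n_draws),
            sigma2_e=float(s2e_sum / n_draws),
            sigma2_additive=float(s2a_sum / n_draws),
            multipliers=tuple(cfg.multipliers),
            n_draws=int(n_draws),
        )
        self.pi_ = self.result_.pi
        self.beta_ = self.result_.beta
        self.sigma2_G_ = self.result_.sigma2_G
        self.sigma2_e_ = self.result_.sigma2_e
        return self


def fit_bayesr(y_adj, g: GenotypeMatrix, subset=None,
               cfg: MixtureConfig | None = None) -> BayesRResult:
    """Functional wrapper: restrict to ``subset`` SNP ids and run the chain."""
    cfg = cfg or MixtureConfig()
    sub = g if subset is None else g.subset_snps(subset)
    est = BayesRMixture(
        multipliers=cfg.multipliers, chain_length=cfg.chain_length,
        burn_in=cfg.burn_in, thin=cfg.thin,
        dirichlet_alpha=cfg.dirichlet_alpha,
        sigma2_additive=cfg.sigma2_additive, seed=cfg.seed,
    )
    if isinstance(y_adj, pd.Series):
        y_adj = y_adj.reindex(sub.samples).to_numpy(dtype=float)
    est.fit(sub, y_adj)
    return est.result_


# ---------------------------------------------------------------------------
# reporting arithmetic
# ---------------------------------------------------------------------------

def snp_contribution(p: float, beta: float, sigma2_A: float, q: float | None = None) -> float:
    """Percent of additive genetic variance from one SNP:
    ``100 x 2 p q beta^2 / sigma2_A``."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    if sigma2_A <= 0:
        raise ValueError("sigma2_A must be positive")
    q = 1.0 - p if q is None else q
    return 100.0 * 2.0 * p * q * beta**2 / sigma2_A


def var_per_snp(h2: float, n_snps_in_class: int) -> float:
    """Per-SNP share of variance for a class, scaled for display:
    ``(h2 / n) x 100 / 1e-4``."""
    if n_snps_in_class < 1:
        raise ValueError("class must contain at least one SNP")
    return (h2 / n_snps_in_class) * 100.0 / 1e-4


def component_summary(result: BayesRResult, total_snps: int | None = None) -> pd.DataFrame:
    """Mixture-component report: expected SNP count, percentage of the
    subset, and attributed genetic variance per component; the table carries
    ``nsnp_nonzero`` and ``top_two_variance_share_pct`` (share of the total
    genetic variance from the two largest-variance components) as attrs."""
    counts = result.expected_counts
    total = int(total_snps) if total_snps is not None else float(counts.sum())
    rows = []
    for c, mult in enumerate(result.multipliers):
        rows.append({
            "component": c,
            "multiplier": mult,
            "expected_count": int(round(counts[c])),
            "expected_count_exact": float(counts[c]),
            "pct_of_snps": 100.0 * counts[c] / total,
            "genetic_variance": float(result.var_by_component[c]),
        })
    df = pd.DataFrame(rows)
    df.attrs["nsnp_nonzero"] = result.nsnp_nonzero
    sg = result.sigma2_G
    top2 = float(result.var_by_component[-2:].sum())
    df.attrs["top_two_variance_share_pct"] = 100.0 * top2 / sg if sg > 0 else 0.0
    df.attrs["sigma2_G"] = sg
    return df
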