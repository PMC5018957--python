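"""Bayesian admixture clustering of haploid genotypes, with Evanno delta-K.

The model is the classic admixture model for K ancestral populations,
specialised to inbred (haploid-equivalent) genotypes: accession a draws,
independently at each site s, a population of origin
z[a,s] ~ Categorical(q[a]) and then its allele x[a,s] ~
Bernoulli(p[z[a,s], s]). Priors: p[k,s] ~ Beta(lambda, lambda) with
lambda = 1 (uncorrelated frequencies), q[a] ~ Dirichlet(alpha, ..., alpha),
and alpha uniform on (0, alpha_max] updated by a Metropolis step.

Gibbs sweeps alternate z | q, p -> p | z, x -> q | z -> alpha | q.
Reported Q and P are posterior means over post-burn-in sweeps, and L is
the mean data log-likelihood sum_{a,s} log sum_k q[a,k] P(x | p[k,s])
over the same sweeps — the quantity whose second differences across K
feed the Evanno delta-K model-choice statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BiallelicMatrix

log = logging.getLogger(__name__)


@dataclass
class AdmixtureFit:
    """Posterior summaries of one run at a fixed K."""

    K: int
    accessions: list[str]
    Q: np.ndarray  # accessions x K posterior-mean ancestry
    P: np.ndarray  # K x sites posterior-mean alt-allele frequencies
    log_likelihood: float  # mean data log-likelihood over kept sweeps
    alpha: float  # posterior-mean Dirichlet concentration
    seed: int
    burnin: int
    reps: int

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster_{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.accessions, columns=cols)


def fit_admixture(
    matrix: BiallelicMatrix,
    K: int,
    burnin: int = 30_000,
    reps: int = 60_000,
    seed: int = 0,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_proposal_sd: float = 0.05,
    freq_lambda: float = 1.0,
) -> AdmixtureFit:
    """Run the Gibbs sampler for one K on the bi-allelic matrix.

    ``reps`` counts post-burn-in sweeps (a run performs burnin + reps
    sweeps in total). Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if matrix.n_accessions < K:
        raise ValueError(f"K={K} exceeds the number of accessions ({matrix.n_accessions})")
    if matrix.n_sites == 0:
        raise ValueError("cannot fit admixture on an empty matrix")
    rng = np.random.default_rng(seed)
    X = matrix.genotypes.astype(np.int8)
    A, S = X.shape

    q = np.full((A, K), 1.0 / K)
    p = rng.uniform(0.2, 0.8, size=(K, S))
    alpha = float(alpha_init)

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    alpha_sum = 0.0
    ll_sum = 0.0
    kept = 0
    X1 = (X == 1)

    for sweep in range(burnin + reps):
        # P(x | k): K is small, sites/accessions vectorised
        like = np.where(X1[:, None, :], p[None, :, :], 1.0 - p[None, :, :])  # A x K x S
        w = q[:, :, None] * like
        denom = w.sum(axis=1)
        # z | q, p  (inverse-CDF sampling along the K axis)
        u = rng.random((A, S)) * denom
        cdf = np.cumsum(w, axis=1)
        z = (u[:, None, :] > cdf).sum(axis=1)  # A x S in 0..K-1

        # p | z, x : Beta(lambda + alt, lambda + ref) per cluster and site
        onehot = z[:, None, :] == np.arange(K)[None, :, None]  # A x K x S
        alt = (onehot & X1[:, None, :]).sum(axis=0)
        tot = onehot.sum(axis=0)
        p = rng.beta(freq_lambda + alt, freq_lambda + (tot - alt))
        np.clip(p, 1e-9, 1.0 - 1e-9, out=p)

        # q | z : Dirichlet(alpha + counts), sampled via Gammas
        counts = onehot.sum(axis=2)  # A x K
        g = rng.gamma(alpha + counts)
        q = g / g.sum(axis=1, keepdims=True)
        np.clip(q, 1e-12, None, out=q)
        q /= q.sum(axis=1, keepdims=True)

        # alpha | q : Metropolis with uniform prior on (0, alpha_max]
        if K > 1:
            alpha = _update_alpha(rng, alpha, q, alpha_max, alpha_proposal_sd)

        if sweep >= burnin:
            like = np.where(X1[:, None, :], p[None, :, :], 1.0 - p[None, :, :])
            ll = float(np.log((q[:, :, None] * like).sum(axis=1)).sum())
            q_sum += q
            p_sum += p
            alpha_sum += alpha
            ll_sum += ll
            kept += 1

    return AdmixtureFit(
        K=K,
        accessions=list(matrix.accessions),
        Q=q_sum / kept,
        P=p_sum / kept,
        log_likelihood=ll_sum / kept,
        alpha=alpha_sum / kept,
        seed=seed,
        burnin=burnin,
        reps=reps,
    )


def _update_alpha(rng, alpha: float, q: np.ndarray, alpha_max: float, sd: float) -> float:
    prop = alpha + rng.normal(0.0, sd)
    if not (0.0 < prop <= alpha_max):
        return alpha
    A, K = q.shape
    logq = np.log(q).sum()

    def log_dens(a: float) -> float:
        return A * (math.lgamma(K * a) - K * math.lgamma(a)) + (a - 1.0) * logq

    if math.log(rng.random()) < log_dens(prop) - log_dens(alpha):
        return prop
    return alpha


def fit_k_range(
    matrix: BiallelicMatrix,
    k_values: range | list[int],
    n_runs: int = 3,
    burnin: int = 30_000,
    reps: int = 60_000,
    seed: int = 0,
) -> dict[int, list[AdmixtureFit]]:
    """Replicate runs across a K range; run seeds derive from ``seed``."""
    fits: dict[int, list[AdmixtureFit]] = {}
    for K in k_values:
        fits[K] = [
            fit_admixture(matrix, K, burnin=burnin, reps=reps, seed=(seed * 10_007 + 101 * K + r) % (2**31 - 1))
            for r in range(n_runs)
        ]
    return fits


def evanno_delta_k(L_runs: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno et al. delta-K from replicate log-likelihoods per K.

    delta K(K) = mean_r |L_r(K-1) - 2 L_r(K) + L_r(K+1)| / sd_r(L(K)),
    using replicate-wise second differences and the across-replicate
    standard deviation (ddof=1), defined for interior K only. sd = 0
    yields inf when the mean second difference is non-zero, else 0 (with
    a warning). Requires >= 3 consecutive K values with >= 2 replicates.
    """
    ks = sorted(L_runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need at least three consecutive K values")
    for k in ks:
        if len(L_runs[k]) < 2:
            raise ValueError(f"K={k}: at least two replicate runs are required")
    n_reps = min(len(L_runs[k]) for k in ks)
    L = np.array([L_runs[k][:n_reps] for k in ks], dtype=float)  # K x reps
    mean_l = L.mean(axis=1)
    sd_l = L.std(axis=1, ddof=1)
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        second = np.abs(L[i - 1] - 2.0 * L[i] + L[i + 1]).mean()
        if sd_l[i] == 0.0:
            if second == 0.0:
                log.warning("K=%d: zero replicate sd and zero second difference; delta K set to 0", ks[i])
                delta[i] = 0.0
            else:
                delta[i] = np.inf
        else:
            delta[i] = second / sd_l[i]
    return pd.DataFrame({"K": ks, "mean_L": mean_l, "sd_L": sd_l, "delta_K": delta})


def best_k(delta_table: pd.DataFrame) -> int:
    """argmax of delta K over interior K values."""
    interior = delta_table.dropna(subset=["delta_K"])
    if interior.empty:
        raise ValueError("delta K is undefined for every K")
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


def match_clusters(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match Q_true (label switching).

    Greedy assignment on column correlations-of-means; exact enumeration
    for K <= 6.
    """
    K = Q.shape[1]
    if Q_true.shape != Q.shape:
        raise ValueError("Q and Q_true must have identical shapes")
    from itertools import permutations

    best_perm, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q[:, list(perm)] - Q_true).mean()
        if err < best_err:
            best_perm, best_err = perm, err
    return Q[:, list(best_perm)]
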