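"""Model-based ancestry inference (admixture proportions) with EM.

The model is the classic unsupervised admixture likelihood: individual
i's genotype at SNP j is Binomial(2, sum_k q_ik f_kj), where Q holds
per-individual ancestry proportions over K clusters and F the clusters'
allele frequencies. The log-likelihood

    l = sum_ij [ g_ij ln(sum_k q_ik f_kj) + (2 - g_ij) ln(sum_k q_ik (1 - f_kj)) ]

is maximised by expectation-maximisation; missing genotypes are simply
skipped. K is chosen by masking a fraction of genotype entries, fitting
on the rest, and scoring the mean squared error of the reconstructed
dosages 2 * (Q F) on the held-out entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hapmap_io import BreedkitError, GenotypeMatrix

__all__ = ["AdmixtureFit", "KSelection", "fit_admixture", "cv_error", "align_q"]

_F_EPS = 1e-6


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray              # (n, K), rows sum to 1
    F: np.ndarray              # (K, m), entries in [eps, 1-eps]
    loglik: float
    iterations: int
    converged: bool
    individual_ids: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class KSelection:
    k_values: list[int]
    cv_errors: list[float]
    chosen_k: int


def _loglik(G: np.ndarray, mask: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(mask, np.nan_to_num(G) * np.log(P)
                      + (2 - np.nan_to_num(G)) * np.log1p(-P), 0.0)
    return float(ll.sum())


def _em_once(
    G: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> AdmixtureFit:
    n, m = G.shape
    mask = ~np.isnan(G)
    Gz = np.nan_to_num(G)
    m_i = mask.sum(axis=1).astype(float)
    if (m_i == 0).any():
        raise BreedkitError("an individual has no non-missing genotypes")

    Q = rng.dirichlet(np.ones(K), size=n)
    base = np.clip(Gz.sum(0) / np.maximum(2.0 * mask.sum(0), 1.0), 0.05, 0.95)
    F = np.clip(base[None, :] + rng.normal(0, 0.1, size=(K, m)), _F_EPS, 1 - _F_EPS)

    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
        Ra = np.where(mask, Gz / P, 0.0)
        Rb = np.where(mask, (2.0 - Gz) / (1.0 - P), 0.0)
        Q_new = np.empty_like(Q)
        F_new = np.empty_like(F)
        for k in range(K):
            wa = (Q[:, k][:, None] * F[k][None, :]) * Ra        # E[alt copies from k]
            wb = (Q[:, k][:, None] * (1 - F[k])[None, :]) * Rb  # E[ref copies from k]
            Q_new[:, k] = (wa + wb).sum(axis=1)
            num = wa.sum(axis=0)
            den = num + wb.sum(axis=0)
            F_new[k] = np.where(den > 0, num / np.maximum(den, 1e-300), base)
        Q = Q_new / (2.0 * m_i)[:, None]
        Q = np.clip(Q, 0.0, None)
        Q = Q / Q.sum(axis=1, keepdims=True)
        F = np.clip(F_new, _F_EPS, 1 - _F_EPS)
        ll = _loglik(G, mask, Q, F)
        trace.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

    return AdmixtureFit(
        K=K,
        Q=Q,
        F=F,
        loglik=trace[-1],
        iterations=it,
        converged=converged,
        loglik_trace=np.array(trace),
    )


def fit_admixture(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit; best of ``restarts`` EM runs.

    K=1 has a closed form (Q all ones, F = mean dosage / 2) and skips
    iteration. The per-run log-likelihood trace is stored and is
    non-decreasing — the EM guarantee.
    """
    ids = list(G.individual_ids) if isinstance(G, GenotypeMatrix) else []
    X = np.asarray(G.dosages if isinstance(G, GenotypeMatrix) else G, dtype=float)
    n, m = X.shape
    if K < 1:
        raise BreedkitError("K must be >= 1")
    if K > n:
        raise BreedkitError(f"K={K} exceeds the number of individuals ({n})")
    mask = ~np.isnan(X)
    if K == 1:
        cnt = np.maximum(mask.sum(axis=0), 1)
        F = np.clip((np.nan_to_num(X).sum(axis=0) / (2.0 * cnt))[None, :],
                    _F_EPS, 1 - _F_EPS)
        Q = np.ones((n, 1))
        ll = _loglik(X, mask, Q, F)
        return AdmixtureFit(1, Q, F, ll, 0, True, ids, np.array([ll]))

    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, restarts)):
        fit = _em_once(X, K, rng, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    best.individual_ids = ids
    return best


def cv_error(
    G: GenotypeMatrix | np.ndarray,
    k_values,
    mask_fraction: float = 0.1,
    reps: int = 3,
    seed: int = 0,
    restarts: int = 2,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> KSelection:
    """Choose K by masked-entry cross-validation.

    Per replicate, a random ``mask_fraction`` of non-missing genotype
    entries is hidden; the model is fitted on the rest and the hidden
    dosages are predicted as 2 * (Q F). The CV error for K is the mean
    squared prediction error averaged over replicates; the chosen K is
    the argmin (lowest K on ties).
    """
    if not 0.0 < mask_fraction < 0.5:
        raise BreedkitError("mask_fraction must be in (0, 0.5)")
    X = np.asarray(G.dosages if isinstance(G, GenotypeMatrix) else G, dtype=float)
    k_values = [int(k) for k in k_values]
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(X))
    errors = {k: [] for k in k_values}
    for _ in range(reps):
        n_mask = max(1, int(round(mask_fraction * len(obs))))
        pick = rng.choice(len(obs), size=n_mask, replace=False)
        rows, cols = obs[pick, 0], obs[pick, 1]
        X_train = X.copy()
        truth = X[rows, cols]
        X_train[rows, cols] = np.nan
        for k in k_values:
            fit = fit_admixture(
                X_train if not isinstance(G, GenotypeMatrix) else _wrap(G, X_train),
                k,
                seed=int(rng.integers(0, 2**31 - 1)),
                restarts=restarts,
                tol=tol,
                max_iter=max_iter,
            )
            pred = 2.0 * (fit.Q @ fit.F)[rows, cols]
            errors[k].append(float(np.mean((pred - truth) ** 2)))
    cv = [float(np.mean(errors[k])) for k in k_values]
    chosen = k_values[int(np.argmin(cv))]
    return KSelection(k_values=k_values, cv_errors=cv, chosen_k=chosen)


def _wrap(G: GenotypeMatrix, dosages: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(list(G.individual_ids), G.snps, dosages)


def align_q(fit: AdmixtureFit, reference) -> AdmixtureFit:
    """Resolve label switching against a reference fit or label vector.

    Columns of Q (and rows of F) are permuted by the Hungarian
    assignment maximising column-wise correlation with the reference
    ancestry matrix (labels are one-hot encoded first).
    """
    if isinstance(reference, AdmixtureFit):
        ref_Q = reference.Q
    elif isinstance(reference, np.ndarray) and reference.ndim == 2:
        ref_Q = reference
    else:
        labels = list(reference)
        cats = list(dict.fromkeys(labels))
        ref_Q = np.zeros((len(labels), len(cats)))
        for i, lab in enumerate(labels):
            ref_Q[i, cats.index(lab)] = 1.0
    if ref_Q.shape[1] != fit.K:
        raise BreedkitError(
            f"reference has {ref_Q.shape[1]} components, fit has {fit.K}"
        )
    K = fit.K
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            x, y = fit.Q[:, a], ref_Q[:, b]
            sx, sy = x.std(), y.std()
            corr[a, b] = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(x, y)[0, 1])
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[col] = row  # column b of the output takes input column matched to it
    return AdmixtureFit(
        K=K,
        Q=fit.Q[:, perm],
        F=fit.F[perm, :],
        loglik=fit.loglik,
        iterations=fit.iterations,
        converged=fit.converged,
        individual_ids=list(fit.individual_ids),
        loglik_trace=fit.loglik_trace.copy(),
    )
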