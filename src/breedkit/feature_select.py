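"""Ranking SNPs by breed association and cutting a minimal panel.

Association is measured on the 2 x C allele-count table (alleles by
breed, missing calls omitted) for the chi-square and Fisher tests, and
on the genotype-class (0/1/2) distribution for the information-theoretic
scores. Mutual information and information gain are plug-in estimates
in bits. Redundant SNPs are pruned greedily in rank order by squared
Pearson correlation of dosages.

Fisher's exact test enumerates all tables with the observed margins
when the problem is small (<= 3 breeds and <= 60 alleles) and otherwise
falls back to seeded Monte-Carlo sampling of the permutation null; the
two-sided p-value sums the probabilities of tables no more probable
than the observed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapmap_io import BreedkitError, BreedTable, GenotypeMatrix

__all__ = [
    "SnpScoreTable",
    "SnpPanel",
    "snp_association_scores",
    "redundancy_prune",
    "select_top",
    "allele_count_table",
    "fisher_exact_2xc",
]

_EXACT_MAX_BREEDS = 3
_EXACT_MAX_ALLELES = 60
_MC_TABLES = 100_000


@dataclass
class SnpScoreTable:
    """Per-SNP association scores, ranked (rank 1 = most informative)."""

    table: pd.DataFrame  # columns: snp_id, statistic, p_value, rank
    method: str

    def ranked_ids(self) -> list[str]:
        return self.table.sort_values("rank")["snp_id"].tolist()


@dataclass
class SnpPanel:
    """Ordered discriminative SNP subset with selection provenance."""

    snp_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise BreedkitError("panel SNP ids must be unique")
        if not self.snp_ids:
            raise BreedkitError("panel must be non-empty")

    def __len__(self) -> int:
        return len(self.snp_ids)


def allele_count_table(dosages: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2 x C table of (ref, alt) allele counts per breed, missing omitted."""
    cats = list(dict.fromkeys(labels))
    out = np.zeros((2, len(cats)))
    for c, cat in enumerate(cats):
        d = dosages[labels == cat]
        d = d[~np.isnan(d)]
        alt = d.sum()
        out[0, c] = 2 * len(d) - alt
        out[1, c] = alt
    return out


def _chi2_stat(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) with df = C - 1."""
    from scipy import stats

    table = table[:, table.sum(axis=0) > 0]
    table = table[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def _log_table_prob(cells: np.ndarray, col_sums: np.ndarray, row1: int) -> float:
    # multivariate hypergeometric: prod_c C(n_c, x_c) / C(N, R1)
    lp = -math.lgamma(col_sums.sum() + 1) + math.lgamma(row1 + 1) + math.lgamma(
        col_sums.sum() - row1 + 1
    )
    for x, n in zip(cells, col_sums):
        lp += math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
    return lp


def fisher_exact_2xc(table: np.ndarray, seed: int = 0) -> float:
    """Two-sided Fisher exact p for a 2 x C count table.

    Exact enumeration of the conditional (fixed-margin) distribution
    when C <= 3 and the total allele count is <= 60; otherwise a seeded
    Monte-Carlo estimate from 1e5 random fixed-margin tables. The
    p-value is the total conditional probability of tables at most as
    probable as the observed one.
    """
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    C = table.shape[1]
    if C < 2 or table.sum(axis=1).min() == 0:
        return 1.0
    col_sums = table.sum(axis=0).astype(int)
    row1 = int(table[0].sum())
    N = int(col_sums.sum())
    obs = table[0].astype(int)
    lp_obs = _log_table_prob(obs, col_sums, row1)

    if C <= _EXACT_MAX_BREEDS and N <= _EXACT_MAX_ALLELES:
        total = 0.0
        p = 0.0

        def rec(c: int, remaining: int, cells: list[int]) -> None:
            nonlocal total, p
            if c == C - 1:
                if remaining <= col_sums[c]:
                    full = np.array(cells + [remaining])
                    lp = _log_table_prob(full, col_sums, row1)
                    prob = math.exp(lp)
                    total += prob
                    if lp <= lp_obs + 1e-9:
                        p += prob
                return
            for x in range(0, min(col_sums[c], remaining) + 1):
                rec(c + 1, remaining - x, cells + [x])

        rec(0, row1, [])
        return min(1.0, p / total)  # total ~ 1; normalise away rounding

    # Monte-Carlo: sample fixed-margin tables via random allele labelling
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(C), col_sums)
    hits = 0
    for _ in range(_MC_TABLES):
        pick = rng.permutation(pool)[:row1]
        cells = np.bincount(pick, minlength=C)
        if _log_table_prob(cells, col_sums, row1) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (_MC_TABLES + 1)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_info(dosages: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in MI in bits between genotype class (0/1/2) and breed."""
    ok = ~np.isnan(dosages)
    d = dosages[ok].astype(int)
    lab = labels[ok]
    cats = list(dict.fromkeys(lab))
    joint = np.zeros((3, len(cats)))
    for c, cat in enumerate(cats):
        joint[:, c] = np.bincount(d[lab == cat], minlength=3)
    n = joint.sum()
    if n == 0:
        return 0.0
    h_g = _entropy(joint.sum(axis=1))
    h_b = _entropy(joint.sum(axis=0))
    h_joint = _entropy(joint.ravel())
    return max(0.0, h_g + h_b - h_joint)


def _entropy_gain(dosages: np.ndarray, labels: np.ndarray) -> float:
    """H(breed) - H(breed | genotype class), bits."""
    ok = ~np.isnan(dosages)
    d = dosages[ok].astype(int)
    lab = labels[ok]
    cats = list(dict.fromkeys(lab))
    lab_idx = np.array([cats.index(x) for x in lab])
    n = len(d)
    if n == 0:
        return 0.0
    h_b = _entropy(np.bincount(lab_idx, minlength=len(cats)).astype(float))
    h_cond = 0.0
    for g in (0, 1, 2):
        sel = d == g
        if sel.any():
            h_cond += sel.mean() * _entropy(
                np.bincount(lab_idx[sel], minlength=len(cats)).astype(float)
            )
    return max(0.0, h_b - h_cond)


def snp_association_scores(
    G: GenotypeMatrix,
    breeds: BreedTable,
    method: str = "chi2",
    seed: int = 0,
) -> SnpScoreTable:
    """Score every informative SNP for breed association.

    ``chi2`` and ``fisher`` work on the 2 x C allele-count table;
    ``mutual_info`` and ``entropy_gain`` on genotype classes.
    Monomorphic and all-missing SNPs are excluded with a warning.
    Ranking is by ascending p for the test methods, descending
    statistic otherwise; ties break by snp_id.
    """
    if method not in ("chi2", "fisher", "mutual_info", "entropy_gain"):
        raise BreedkitError(f"unknown method {method!r}")
    labels = breeds.labels_for(G.individual_ids)
    if len(set(labels)) < 2:
        raise BreedkitError("association scoring needs at least 2 breeds")

    X = G.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(X, axis=0) / 2.0
    informative = ~np.isnan(freq) & (freq > 0) & (freq < 1)
    n_dropped = int((~informative).sum())
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} monomorphic or all-missing SNP(s) from scoring",
            stacklevel=2,
        )

    rows = []
    for j in np.nonzero(informative)[0]:
        d = X[:, j]
        if method in ("chi2", "fisher"):
            tab = allele_count_table(d, labels)
            if method == "chi2":
                stat, p = _chi2_stat(tab)
            else:
                p = fisher_exact_2xc(tab, seed=seed + int(j))
                stat = -math.log10(max(p, 1e-300))
        elif method == "mutual_info":
            stat, p = _mutual_info(d, labels), np.nan
        else:
            stat, p = _entropy_gain(d, labels), np.nan
        rows.append((G.snp_ids[j], stat, p))

    df = pd.DataFrame(rows, columns=["snp_id", "statistic", "p_value"])
    if method in ("chi2", "fisher"):
        df = df.sort_values(["p_value", "snp_id"], kind="mergesort")
    else:
        df = df.sort_values(["statistic", "snp_id"],
                            ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return SnpScoreTable(df.reset_index(drop=True), method=method)


def redundancy_prune(
    G: GenotypeMatrix, scores: SnpScoreTable, r2_threshold: float = 0.9
) -> SnpScoreTable:
    """Greedy correlation filter in rank order.

    A SNP is dropped when its squared Pearson correlation of dosages
    (pairwise-complete observations) with any already-kept SNP exceeds
    the threshold.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise BreedkitError("r2_threshold must be in (0, 1]")
    col = {s: i for i, s in enumerate(G.snp_ids)}
    kept: list[str] = []
    kept_cols: list[int] = []
    X = G.dosages
    for snp in scores.ranked_ids():
        j = col[snp]
        xj = X[:, j]
        redundant = False
        for i in kept_cols:
            r2 = _pairwise_r2(X[:, i], xj)
            if r2 > r2_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(snp)
            kept_cols.append(j)
    df = scores.table[scores.table["snp_id"].isin(kept)].copy()
    df = df.sort_values("rank", kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return SnpScoreTable(df, method=scores.method)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def select_top(
    scores: SnpScoreTable,
    fraction: float | None = None,
    count: int | None = None,
) -> SnpPanel:
    """Cut the top of the ranking into a panel.

    Give either ``fraction`` in (0, 1] (size = round(fraction * m)) or
    an explicit ``count``.
    """
    ranked = scores.ranked_ids()
    m = len(ranked)
    if (fraction is None) == (count is None):
        raise BreedkitError("give exactly one of fraction or count")
    if fraction is not None:
        if not 0.0 < fraction <= 1.0:
            raise BreedkitError("fraction must be in (0, 1]")
        count = max(1, int(round(fraction * m)))
    if not 1 <= count <= m:
        raise BreedkitError(f"count {count} outside [1, {m}]")
    return SnpPanel(
        ranked[:count],
        metadata={"method": scores.method, "fraction": fraction, "count": count},
    )
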