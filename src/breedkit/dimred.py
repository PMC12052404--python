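"""Low-dimensional embeddings of individuals from genotype dosages.

Three views of population structure: PCA on the (centred, optionally
standardised) dosage matrix, classical metric MDS (Torgerson double
centring) on a precomputed distance matrix, and UMAP delegated to
umap-learn. Missing dosages are mean-imputed per SNP by default.

Each principal component / MDS axis is sign-fixed so that its
largest-magnitude loading (respectively coordinate) is positive, making
outputs deterministic across BLAS backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapmap_io import BreedkitError, BreedTable, GenotypeMatrix

__all__ = ["Embedding", "impute_dosages", "pca", "classical_mds", "umap_embed",
           "drop_individuals"]


@dataclass
class Embedding:
    """Coordinates of individuals in a reduced space."""

    individual_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    method: str
    explained_variance_pct: np.ndarray | None = None  # PCA only
    params: dict = field(default_factory=dict)

    def to_frame(self, breeds: BreedTable | None = None) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        df = pd.DataFrame({"ID": self.individual_ids, **cols})
        if breeds is not None:
            mapping = breeds.breed_of()
            df["breed"] = [mapping.get(i, "") for i in self.individual_ids]
        return df


def impute_dosages(
    G: GenotypeMatrix, missing_policy: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Dense dosage matrix with missing entries resolved.

    Returns ``(X, kept)`` where ``kept`` is the boolean mask of retained
    SNP columns: under ``mean`` policy an all-missing SNP cannot be
    imputed and is dropped with a warning; under ``drop`` any SNP with a
    missing call is dropped.
    """
    X = np.array(G.dosages, dtype=float)
    miss = np.isnan(X)
    if missing_policy == "drop":
        kept = ~miss.any(axis=0)
        return X[:, kept], kept
    if missing_policy != "mean":
        raise BreedkitError(f"unknown missing_policy {missing_policy!r}")
    kept = ~miss.all(axis=0)
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} all-missing SNP(s) before imputation",
            stacklevel=2,
        )
        X = X[:, kept]
        miss = miss[:, kept]
    if miss.any():
        col_mean = np.nanmean(X, axis=0)
        X[miss] = np.take(col_mean, np.nonzero(miss)[1])
    return X, kept


def _fix_signs(coords: np.ndarray, loadings: np.ndarray | None = None) -> np.ndarray:
    """Flip each column so its reference vector's extreme entry is positive."""
    ref = loadings if loadings is not None else coords
    for i in range(coords.shape[1]):
        v = ref[:, i] if ref.ndim == 2 else ref
        if v.size and v[np.argmax(np.abs(v))] < 0:
            coords[:, i] = -coords[:, i]
            if loadings is not None:
                loadings[:, i] = -loadings[:, i]
    return coords


def pca(
    G: GenotypeMatrix,
    k: int = 2,
    missing_policy: str = "mean",
    standardize: bool = False,
) -> Embedding:
    """Principal components of the centred dosage matrix.

    ``explained_variance_pct`` reports 100 * lambda_i / sum(lambda) over
    *all* components, so the full spectrum sums to 100.
    """
    n = G.n_individuals
    X, _ = impute_dosages(G, missing_policy)
    m = X.shape[1]
    if k > min(n - 1, m) or k < 1:
        raise BreedkitError(f"k={k} outside [1, min(n-1, m)={min(n - 1, m)}]")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        nz = sd > 0
        Xc[:, nz] = Xc[:, nz] / sd[nz]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    coords = U[:, :k] * s[:k]
    coords = _fix_signs(coords, Vt[:k].T.copy())
    if total > 0:
        pct = 100.0 * eigvals[:k] / total
    else:
        pct = np.zeros(k)
    return Embedding(
        list(G.individual_ids),
        coords,
        method="pca",
        explained_variance_pct=pct,
        params={"k": k, "missing_policy": missing_policy, "standardize": standardize},
    )


def classical_mds(D, k: int = 2) -> Embedding:
    """Torgerson classical scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and keeps the
    top-k axes; negative eigenvalues (non-Euclidean input) are truncated
    to zero.
    """
    ids = list(D.individual_ids)
    M = np.asarray(D.values, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise BreedkitError("distance matrix is not symmetric")
    n = M.shape[0]
    if not 1 <= k <= n:
        raise BreedkitError(f"k={k} outside [1, {n}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order][:k], 0.0, None)
    eigvecs = eigvecs[:, order][:, :k]
    coords = eigvecs * np.sqrt(eigvals)
    coords = _fix_signs(coords)
    return Embedding(ids, coords, method="mds", params={"k": k})


def umap_embed(
    G: GenotypeMatrix,
    params: dict | None = None,
    seed: int = 0,
    missing_policy: str = "mean",
) -> Embedding:
    """Two-dimensional UMAP embedding (delegated to umap-learn), seeded."""
    params = dict(params or {})
    n_neighbors = int(params.pop("n_neighbors", 15))
    if G.n_individuals < n_neighbors + 1:
        raise BreedkitError(
            f"UMAP needs n >= n_neighbors+1 ({n_neighbors + 1}), got {G.n_individuals}"
        )
    import umap  # deferred: numba compilation is slow to import

    X, _ = impute_dosages(G, missing_policy)
    reducer = umap.UMAP(
        n_components=int(params.pop("n_components", 2)),
        n_neighbors=n_neighbors,
        random_state=seed,
        **params,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(X)
    return Embedding(
        list(G.individual_ids),
        np.asarray(coords, dtype=float),
        method="umap",
        params={"n_neighbors": n_neighbors, "seed": seed},
    )


def drop_individuals(
    G: GenotypeMatrix, breeds: BreedTable, ids
) -> tuple[GenotypeMatrix, BreedTable]:
    """Remove named individuals (outlier curation); inputs untouched."""
    ids = list(ids)
    known = set(G.individual_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise BreedkitError(f"unknown individual ids: {unknown}")
    keep = [i for i in G.individual_ids if i not in set(ids)]
    new_G = G.subset_individuals(keep)
    new_table = breeds.table[~breeds.table["ID"].isin(ids)].reset_index(drop=True)
    return new_G, BreedTable(new_table)
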