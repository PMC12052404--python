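"""Synthetic multi-breed SNP datasets in the pipeline's input formats.

Breeds are simulated under the Balding–Nichols island model: each SNP j
draws an ancestral allele frequency p_j, and each breed k draws its own
frequency f_kj from Beta(p_j(1-F)/F, (1-p_j)(1-F)/F), so that
E[f_kj] = p_j and Var[f_kj] = p_j(1-p_j)F with F the fixation index
(FST) controlling between-breed differentiation. Individual dosages are
Binomial(2, f_kj) draws; admixed individuals use the mixture frequency
sum_k q_k f_kj. The generator emits the same three files the pipeline
reads (HapMap genotypes, ID/breed table, per-breed geography) and keeps
a truth record for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hapmap_io import (
    BreedkitError,
    BreedTable,
    GenotypeMatrix,
    GeoTable,
    write_hapmap,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_breeds",
    "random_genotypes",
    "write_fixture_suite",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated multi-breed dataset.

    ``admixed_spec`` is an optional list of ``(q_vector, count)`` pairs
    appending individuals whose ancestry mixes the breeds with weights
    ``q_vector`` (length ``n_breeds``, summing to 1).
    """

    n_breeds: int = 10
    n_per_breed: int | Sequence[int] = 20
    n_snps: int = 2000
    fst: float = 0.15
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    admixed_spec: list[tuple[Sequence[float], int]] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def per_breed_counts(self) -> list[int]:
        if np.isscalar(self.n_per_breed):
            return [int(self.n_per_breed)] * self.n_breeds
        counts = [int(c) for c in self.n_per_breed]
        if len(counts) != self.n_breeds:
            raise BreedkitError(
                f"n_per_breed: expected {self.n_breeds} entries, got {len(counts)}"
            )
        return counts

    def validate(self) -> None:
        if self.n_breeds < 1:
            raise BreedkitError("n_breeds: must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise BreedkitError("fst: must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise BreedkitError("missing_rate: must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise BreedkitError("ancestral_freq_range: need 0 < lo < hi < 1")
        if any(c < 0 for c in self.per_breed_counts()):
            raise BreedkitError("n_per_breed: counts must be >= 0")
        if self.n_snps < 1:
            raise BreedkitError("n_snps: must be >= 1")
        for q, count in self.admixed_spec or []:
            q = np.asarray(q, dtype=float)
            if q.shape != (self.n_breeds,) or not np.isclose(q.sum(), 1.0):
                raise BreedkitError("admixed_spec: each Q vector must have one weight "
                                    "per breed and sum to 1")
            if count < 0:
                raise BreedkitError("admixed_spec: counts must be >= 0")


@dataclass
class SimulationTruth:
    """Generative parameters behind a simulated dataset."""

    ancestral_freq: np.ndarray      # (m,)
    breed_freq: np.ndarray          # (n_breeds, m)
    breed_names: list[str]
    q_matrix: np.ndarray            # (n_individuals, n_breeds) ancestry
    config: SimulationConfig = field(repr=False, default=None)


def _snp_metadata(m: int) -> pd.DataFrame:
    # positions are synthetic and unused downstream; alleles fixed A(ref)/G(alt)
    return pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": [1000 * (j + 1) for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )


def simulate_breeds(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, BreedTable, GeoTable, SimulationTruth]:
    """Simulate a multi-breed genotype dataset under Balding–Nichols."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    K = config.n_breeds
    counts = config.per_breed_counts()
    breed_names = [f"Breed{chr(ord('A') + k)}" if K <= 26 else f"Breed{k + 1}"
                   for k in range(K)]

    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=m)
    F = config.fst
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    breed_freq = rng.beta(a[None, :], b[None, :], size=(K, m))

    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[str] = []
    q_rows: list[np.ndarray] = []
    for k, (name, n_k) in enumerate(zip(breed_names, counts)):
        if n_k == 0:
            continue
        dos = rng.binomial(2, breed_freq[k][None, :], size=(n_k, m)).astype(float)
        rows.append(dos)
        ids.extend(f"{name}_{i + 1}" for i in range(n_k))
        labels.extend([name] * n_k)
        q = np.zeros(K)
        q[k] = 1.0
        q_rows.extend([q] * n_k)
    for mix_idx, (q, count) in enumerate(config.admixed_spec or []):
        q = np.asarray(q, dtype=float)
        mix_freq = q @ breed_freq
        if count == 0:
            continue
        dos = rng.binomial(2, mix_freq[None, :], size=(count, m)).astype(float)
        rows.append(dos)
        ids.extend(f"Admix{mix_idx + 1}_{i + 1}" for i in range(count))
        labels.extend([f"Admix{mix_idx + 1}"] * count)
        q_rows.extend([q] * count)

    dosages = np.vstack(rows) if rows else np.empty((0, m))
    if config.missing_rate > 0 and dosages.size:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    G = GenotypeMatrix(ids, _snp_metadata(m), dosages)
    breeds = BreedTable(pd.DataFrame({"ID": ids, "breed": labels}))
    geo = GeoTable(_grid_geo(breed_names))
    truth = SimulationTruth(
        ancestral_freq=p,
        breed_freq=breed_freq,
        breed_names=breed_names,
        q_matrix=np.array(q_rows) if q_rows else np.empty((0, K)),
        config=config,
    )
    return G, breeds, geo, truth


def _grid_geo(breed_names: list[str]) -> pd.DataFrame:
    # decorative coordinates on a grid inside valid lat/lon ranges
    K = len(breed_names)
    lats = np.linspace(-60, 60, max(K, 2))[:K]
    lons = np.linspace(-150, 150, max(K, 2))[:K]
    return pd.DataFrame(
        {
            "breed": breed_names,
            "Latitude": np.round(lats, 4),
            "Longitude": np.round(lons, 4),
            "Location": [f"Site {i + 1}" for i in range(K)],
        }
    )


def random_genotypes(
    n: int, snp_metadata: pd.DataFrame, seed: int = 0
) -> GenotypeMatrix:
    """Individuals with i.i.d. uniform dosages over {0,1,2}.

    These carry no population signal at all; they exercise the one-class
    screen that should reject genotypes unlike any training breed.
    """
    rng = np.random.default_rng(seed)
    m = len(snp_metadata)
    dosages = rng.integers(0, 3, size=(n, m)).astype(float)
    ids = [f"rand_{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, snp_metadata.reset_index(drop=True).copy(), dosages)


def write_fixture_suite(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Simulate a dataset and write the three standard input files.

    Produces ``genotype.hmp.txt`` (HapMap), ``classification.txt``
    (ID/breed) and ``location.txt`` (per-breed geography) under
    ``outdir``; deterministic for a fixed config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G, breeds, geo, _ = simulate_breeds(config)
    paths = {
        "genotypes": outdir / "genotype.hmp.txt",
        "breeds": outdir / "classification.txt",
        "geo": outdir / "location.txt",
    }
    write_hapmap(G, paths["genotypes"])
    breeds.table.to_csv(paths["breeds"], sep="\t", index=False)
    geo.table.to_csv(paths["geo"], sep="\t", index=False)
    return paths
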