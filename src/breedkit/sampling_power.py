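"""Per-breed sample-size recommendation and class balancing.

The sample-size rule treats breed discrimination at a single SNP as a
two-proportion test on allele counts: with n individuals (2n alleles)
per breed, how large must n be to detect an allele-frequency difference
``delta`` at size ``alpha`` with the target power? The normal
approximation n_alleles = (z_{1-a/2} + z_{1-b})^2 (p1 q1 + p2 q2) / delta^2
gives a starting point which is then checked (and raised if needed)
against the exact binomial power of the z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hapmap_io import BreedkitError, BreedTable, GenotypeMatrix

__all__ = ["PowerSpec", "recommend_min_n", "exact_power", "balance_breeds"]


@dataclass
class PowerSpec:
    """Target effect size and error rates for the per-SNP power rule."""

    delta: float = 0.2
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise BreedkitError("delta must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise BreedkitError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise BreedkitError("power must be in (0, 1)")


def exact_power(n_individuals: int, p1: float, p2: float, alpha: float) -> float:
    """Exact power of the unpooled two-proportion z-test on allele counts.

    Enumerates the joint Binomial(2n, p1) x Binomial(2n, p2) outcome grid
    and sums the probability of rejection at two-sided size ``alpha``.
    """
    n = 2 * n_individuals
    z_crit = stats.norm.ppf(1 - alpha / 2)
    k = np.arange(n + 1)
    pmf1 = stats.binom.pmf(k, n, p1)
    pmf2 = stats.binom.pmf(k, n, p2)
    ph = k / n
    P1, P2 = np.meshgrid(ph, ph, indexing="ij")
    var = P1 * (1 - P1) / n + P2 * (1 - P2) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (P1 - P2) / np.sqrt(var), 0.0)
    # degenerate cells (both proportions 0 or both 1 give var=0): reject
    # only when the two proportions differ, which var=0 rules out except
    # for the (0,1)/(1,0) corners
    reject = np.abs(z) > z_crit
    reject |= (var == 0) & (P1 != P2)
    return float(pmf1 @ reject @ pmf2)


def recommend_min_n(spec: PowerSpec, p_base: float = 0.5) -> int:
    """Smallest individuals-per-breed count meeting the power target.

    The comparison frequency is ``p_base - delta`` when that lies in
    (0, 1), otherwise ``p_base + delta``; if neither does the spec is
    infeasible. The normal-approximation count is verified by exact
    binomial power evaluation and raised if the approximation was
    optimistic.
    """
    if not 0.0 < p_base < 1.0:
        raise BreedkitError(f"p_base {p_base} outside (0, 1)")
    p1 = p_base
    if 0.0 < p_base - spec.delta < 1.0:
        p2 = p_base - spec.delta
    elif 0.0 < p_base + spec.delta < 1.0:
        p2 = p_base + spec.delta
    else:
        raise BreedkitError(
            f"infeasible spec: p_base {p_base} +/- delta {spec.delta} leaves (0, 1)"
        )
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    # for power below the test size z_a + z_b can go negative; the required
    # count then collapses to the floor of one individual
    z_sum = max(z_a + z_b, 0.0)
    n_alleles = z_sum**2 * (p1 * (1 - p1) + p2 * (1 - p2)) / spec.delta**2
    n = max(1, math.ceil(math.ceil(n_alleles) / 2))
    # the normal formula can undershoot at small counts; step up until the
    # exact rejection probability clears the target (cap keeps this finite)
    for _ in range(10_000):
        if exact_power(n, p1, p2, spec.alpha) >= spec.power:
            break
        n += 1
    return n


def balance_breeds(
    G: GenotypeMatrix,
    breeds: BreedTable,
    strategy: str = "down",
    seed: int = 0,
) -> tuple[GenotypeMatrix, BreedTable]:
    """Equalise per-breed counts by resampling individuals.

    ``up`` keeps every original individual and adds with-replacement
    duplicates (IDs suffixed ``__dupK``) until each breed reaches the
    largest class size; ``down`` subsamples without replacement to the
    smallest class size. Reproducible for a fixed seed.
    """
    if strategy not in ("up", "down"):
        raise BreedkitError(f"unknown strategy {strategy!r}")
    mapping = breeds.breed_of()
    groups: dict[str, list[str]] = {}
    for ind in G.individual_ids:
        if ind not in mapping:
            raise BreedkitError(f"individual {ind!r} has no breed label")
        groups.setdefault(mapping[ind], []).append(ind)
    if len(groups) < 2:
        raise BreedkitError("balancing needs at least 2 breeds")
    if any(len(v) == 0 for v in groups.values()):
        raise BreedkitError("a breed has zero individuals")
    rng = np.random.default_rng(seed)
    sizes = {b: len(v) for b, v in groups.items()}

    chosen: list[tuple[str, str]] = []  # (source individual, output id)
    if strategy == "down":
        target = min(sizes.values())
        for b in sorted(groups):
            members = groups[b]
            keep = rng.choice(len(members), size=target, replace=False)
            chosen.extend((members[i], members[i]) for i in sorted(keep))
    else:
        target = max(sizes.values())
        for b in sorted(groups):
            members = groups[b]
            chosen.extend((m, m) for m in members)
            extra = target - len(members)
            if extra > 0:
                picks = rng.choice(len(members), size=extra, replace=True)
                dup_count: dict[str, int] = {}
                for i in picks:
                    src = members[i]
                    dup_count[src] = dup_count.get(src, 0) + 1
                    chosen.append((src, f"{src}__dup{dup_count[src]}"))

    src_ids = [s for s, _ in chosen]
    out_ids = [o for _, o in chosen]
    sub = G.subset_individuals(list(dict.fromkeys(src_ids)))
    row_of = {v: i for i, v in enumerate(sub.individual_ids)}
    dosages = sub.dosages[[row_of[s] for s in src_ids]]
    new_G = GenotypeMatrix(out_ids, G.snps.copy(), dosages)
    new_breeds = BreedTable(
        pd.DataFrame({"ID": out_ids, "breed": [mapping[s] for s in src_ids]})
    )
    return new_G, new_breeds
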