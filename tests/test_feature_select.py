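"""SNP association scoring, redundancy pruning and panel cutting."""

import itertools
import math

import numpy as np
import pytest

from breedkit import (
    BreedkitError,
    redundancy_prune,
    select_top,
    snp_association_scores,
)
from breedkit.feature_select import (
    SnpScoreTable,
    allele_count_table,
    fisher_exact_2xc,
)

from .conftest import breed_table, genotype_matrix

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def chi2_oracle(table: np.ndarray) -> float:
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def fisher_oracle(table: np.ndarray) -> float:
    """Two-sided exact p by direct enumeration over all margin-preserving
    tables, summing probabilities <= that of the observed table."""
    col_sums = table.sum(axis=0).astype(int)
    row1 = int(table[0].sum())

    def prob(cells) -> float:
        num = 1.0
        for x, n in zip(cells, col_sums):
            num *= math.comb(int(n), int(x))
        return num / math.comb(int(col_sums.sum()), row1)

    obs_p = prob(table[0])
    p = 0.0
    ranges = [range(c + 1) for c in col_sums]
    for cells in itertools.product(*ranges):
        if sum(cells) == row1:
            q = prob(cells)
            if q <= obs_p * (1 + 1e-9):
                p += q
    return p


def mi_oracle(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return mi


# ---------------------------------------------------------------------------


class TestAssociationScores:
    def _fixed_snp_dataset(self):
        # SNP 1: fixed difference; SNP 2: identical distribution
        dosages = np.array(
            [[2, 1], [2, 1], [2, 1], [2, 1], [2, 1],
             [0, 1], [0, 1], [0, 1], [0, 1], [0, 1]],
            dtype=float,
        )
        ids = [f"S{i}" for i in range(10)]
        return genotype_matrix(dosages, ids), breed_table(
            ids, ["A"] * 5 + ["B"] * 5
        )

    def test_fixed_difference_chi2_is_twenty(self):
        G, bt = self._fixed_snp_dataset()
        scores = snp_association_scores(G, bt, "chi2")
        row = scores.table.set_index("snp_id").loc["snp1"]
        assert row["statistic"] == pytest.approx(20.0)
        assert row["rank"] == 1

    def test_fixed_difference_fisher_p(self):
        G, bt = self._fixed_snp_dataset()
        tab = allele_count_table(G.dosages[:, 0], bt.labels_for(G.individual_ids))
        p = fisher_exact_2xc(tab)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_perfectly_determining_genotype_has_one_bit_mi(self):
        G, bt = self._fixed_snp_dataset()
        scores = snp_association_scores(G, bt, "mutual_info")
        row = scores.table.set_index("snp_id").loc["snp1"]
        assert row["statistic"] == pytest.approx(1.0)

    def test_entropy_gain_equals_mutual_information(self):
        rng = np.random.default_rng(5)
        G = genotype_matrix(rng.integers(0, 3, size=(30, 10)))
        bt = breed_table(G.individual_ids, ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        mi = snp_association_scores(G, bt, "mutual_info").table.set_index("snp_id")
        eg = snp_association_scores(G, bt, "entropy_gain").table.set_index("snp_id")
        for snp in mi.index:
            assert mi.loc[snp, "statistic"] == pytest.approx(
                eg.loc[snp, "statistic"], abs=1e-12
            )

    def test_mutual_info_nonnegative_and_zero_for_proportional(self):
        G = genotype_matrix(
            [[0, 0], [1, 1], [0, 0], [1, 1]], ids=["S1", "S2", "S3", "S4"]
        )
        bt = breed_table(G.individual_ids, ["A", "A", "B", "B"])
        scores = snp_association_scores(G, bt, "mutual_info")
        assert (scores.table["statistic"] >= 0).all()
        assert scores.table["statistic"].max() == pytest.approx(0.0, abs=1e-12)

    def test_statistics_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(20):
            C = int(rng.integers(2, 4))
            table = rng.integers(0, 8, size=(2, C)).astype(float)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            from breedkit.feature_select import _chi2_stat

            stat, _ = _chi2_stat(table)
            assert stat == pytest.approx(chi2_oracle(table), abs=1e-9)
            assert fisher_exact_2xc(table) == pytest.approx(
                fisher_oracle(table), abs=1e-9
            )
            checked += 1
        assert checked >= 10

    def test_monomorphic_snps_excluded_with_warning(self):
        G = genotype_matrix([[0, 1], [0, 2], [0, 1], [0, 0]])
        bt = breed_table(G.individual_ids, ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="monomorphic"):
            scores = snp_association_scores(G, bt, "chi2")
        assert scores.table["snp_id"].tolist() == ["snp2"]

    def test_single_breed_errors(self):
        G = genotype_matrix([[0, 1], [1, 2]])
        bt = breed_table(G.individual_ids, ["A", "A"])
        with pytest.raises(BreedkitError):
            snp_association_scores(G, bt, "chi2")


class TestRedundancyPrune:
    def _scores(self, snp_ids):
        import pandas as pd

        df = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "statistic": np.arange(len(snp_ids), 0, -1, dtype=float),
                "p_value": np.nan,
                "rank": np.arange(1, len(snp_ids) + 1),
            }
        )
        return SnpScoreTable(df, method="mutual_info")

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=30).astype(float)
        G = genotype_matrix(np.column_stack([col, col]))
        pruned = redundancy_prune(G, self._scores(["snp1", "snp2"]), 0.9)
        assert pruned.table["snp_id"].tolist() == ["snp1"]

    def test_orthogonal_columns_kept(self):
        rng = np.random.default_rng(2)
        G = genotype_matrix(rng.integers(0, 3, size=(50, 4)))
        pruned = redundancy_prune(G, self._scores([f"snp{i}" for i in range(1, 5)]), 0.5)
        assert len(pruned.table) == 4

    def test_greedy_chain_keeps_first_and_third(self):
        A = np.array([0.0] * 20 + [2.0] * 20)
        B = A.copy()
        B[:2] = 1.0
        C = A.copy()
        C[:6] = 1.0

        def r2(x, y):
            return np.corrcoef(x, y)[0, 1] ** 2

        assert r2(A, B) > 0.9 and r2(B, C) > 0.9 and r2(A, C) <= 0.9
        G = genotype_matrix(np.column_stack([A, B, C]))
        pruned = redundancy_prune(G, self._scores(["snp1", "snp2", "snp3"]), 0.9)
        assert pruned.table["snp_id"].tolist() == ["snp1", "snp3"]

    def test_no_kept_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, size=(40, 6)).astype(float)
        # add near-duplicates to force pruning
        dosages = np.column_stack([base, base[:, 0], base[:, 2]])
        G = genotype_matrix(dosages)
        pruned = redundancy_prune(
            G, self._scores([f"snp{i}" for i in range(1, 9)]), 0.8
        )
        kept = pruned.table["snp_id"].tolist()
        cols = {s: i for i, s in enumerate(G.snp_ids)}
        for a, b in itertools.combinations(kept, 2):
            r = np.corrcoef(G.dosages[:, cols[a]], G.dosages[:, cols[b]])[0, 1]
            assert r * r <= 0.8 + 1e-12


class TestSelectTop:
    def _ranked(self, m):
        return self._scores_for(m)

    def _scores_for(self, m):
        import pandas as pd

        df = pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(1, m + 1)],
                "statistic": np.arange(m, 0, -1, dtype=float),
                "p_value": np.nan,
                "rank": np.arange(1, m + 1),
            }
        )
        return SnpScoreTable(df, method="mutual_info")

    def test_seventeen_percent_of_thousand(self):
        panel = select_top(self._ranked(1000), fraction=0.17)
        assert len(panel) == 170
        assert panel.snp_ids[0] == "snp1"

    def test_fraction_one_keeps_all_in_order(self):
        panel = select_top(self._ranked(10), fraction=1.0)
        assert panel.snp_ids == [f"snp{i}" for i in range(1, 11)]

    def test_explicit_count_panel(self):
        panel = select_top(self._ranked(1000), count=860)
        assert len(panel) == 860

    def test_count_exceeding_m_errors(self):
        with pytest.raises(BreedkitError):
            select_top(self._ranked(10), count=11)

    def test_exactly_one_of_fraction_or_count(self):
        with pytest.raises(BreedkitError):
            select_top(self._ranked(10))
        with pytest.raises(BreedkitError):
            select_top(self._ranked(10), fraction=0.5, count=3)
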