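"""Over-representation, immune scoring, Kendall screen, single-cell summaries."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrpipe.annotation import (
    immune_score,
    kendall_screen,
    ora_enrich,
    single_cell_summary,
)
from mrpipe.data_io import GeneSetCollection, SingleCellMatrix


def make_sets(**sets) -> GeneSetCollection:
    return GeneSetCollection(sets={k: ("", list(v)) for k, v in sets.items()})


class TestOraEnrich:
    def test_exact_hypergeometric_example(self):
        universe = [f"g{i}" for i in range(100)]
        gene_sets = make_sets(S=universe[:10])
        query = universe[:3] + universe[50:52]  # overlap 3 of query 5
        table = ora_enrich(query, universe, gene_sets)
        expected = sum(
            comb(10, i) * comb(90, 5 - i) / comb(100, 5) for i in range(3, 6)
        )
        assert table.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert table.loc[0, "p_value"] == pytest.approx(6.64e-3, rel=0.01)
        assert bool(table.loc[0, "passes_filter"])

    def test_single_gene_overlap_fails_filter(self):
        universe = [f"g{i}" for i in range(50)]
        gene_sets = make_sets(S=universe[:1])
        table = ora_enrich(universe[:1], universe, gene_sets)
        assert table.loc[0, "n_overlap"] == 1
        assert not bool(table.loc[0, "passes_filter"])

    def test_query_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        gene_sets = make_sets(S=universe[:7])
        table = ora_enrich(universe, universe, gene_sets)
        assert table.loc[0, "n_overlap"] == 7
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrich(["g1"], [], make_sets(S=["g1"]))

    def test_matches_enumeration_oracle_on_small_universes(self):
        """Exhaustive enumeration of query draws for universes <= 20."""
        rng = np.random.default_rng(14)
        for _ in range(25):
            n_universe = int(rng.integers(5, 21))
            universe = [f"g{i}" for i in range(n_universe)]
            set_size = int(rng.integers(1, n_universe + 1))
            members = list(rng.choice(universe, size=set_size, replace=False))
            q_size = int(rng.integers(1, n_universe + 1))
            query = list(rng.choice(universe, size=q_size, replace=False))
            k = len(set(query) & set(members))
            total = 0
            hits = 0
            member_set = set(members)
            for draw in combinations(universe, q_size):
                total += 1
                hits += len(set(draw) & member_set) >= k
            table = ora_enrich(query, universe, make_sets(S=members))
            assert table.loc[0, "p_value"] == pytest.approx(hits / total, rel=1e-9)


class TestImmuneScore:
    def make_expression(self, n_genes=200, n_samples=3, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.lognormal(3, 1, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_top_ranked_signature_scores_positive(self):
        expr = self.make_expression()
        sample = expr["s0"].sort_values(ascending=False)
        top = list(sample.index[:15])
        bottom = list(sample.index[-15:])
        scores = immune_score(expr[["s0"]], top)
        assert scores["s0"] > 0
        assert immune_score(expr[["s0"]], bottom)["s0"] < 0

    def test_invariant_under_monotone_transform(self):
        expr = self.make_expression(seed=2)
        sig = list(expr.index[:20])
        a = immune_score(expr, sig)
        b = immune_score(np.log1p(expr) * 7 + 1, sig)
        pd.testing.assert_series_equal(a, b)

    def test_signature_too_small_rejected(self):
        expr = self.make_expression()
        with pytest.raises(ValueError, match="signature"):
            immune_score(expr, list(expr.index[:3]))

    def test_scores_increase_with_planted_immune_fraction(self):
        """Mixtures with a larger immune component score higher."""
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        signature = genes[:30]
        base = rng.lognormal(2, 0.5, size=300)
        immune_profile = base.copy()
        immune_profile[:30] *= 5  # signature genes elevated in immune cells
        columns = {}
        for fraction in (0.0, 0.25, 0.5):
            columns[f"f{fraction}"] = (1 - fraction) * base + fraction * immune_profile
        expr = pd.DataFrame(columns, index=genes)
        scores = immune_score(expr, signature)
        assert scores["f0.0"] < scores["f0.25"] < scores["f0.5"]


class TestKendallScreen:
    def test_perfect_concordance(self):
        s = pd.Series([1, 2, 3], index=list("abc"))
        rec = kendall_screen(s, s, s)
        assert rec.tau_discrete == pytest.approx(1.0)

    def test_hand_counted_tau(self):
        x = pd.Series([1, 2, 3], index=list("abc"))
        y = pd.Series([3, 1, 2], index=list("abc"))
        rec = kendall_screen(x, x, y)
        assert rec.tau_discrete == pytest.approx(-1 / 3)

    def test_dual_level_rule(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(40)]
        scores = pd.Series(np.arange(40.0), index=idx)
        states = pd.Series((np.arange(40) > 20).astype(int), index=idx)
        anti = pd.Series(-np.arange(40.0) + rng.normal(0, 0.1, 40), index=idx)
        rec = kendall_screen(states, anti, scores)
        assert rec.tau_discrete > 0 and rec.p_discrete < 0.05
        assert rec.tau_expression < 0
        assert not rec.correlated

    def test_constant_vector_logged_not_correlated(self, caplog):
        idx = list("abcd")
        with caplog.at_level("INFO"):
            rec = kendall_screen(
                pd.Series([1, 1, 1, 1], index=idx),
                pd.Series([1.0, 2.0, 3.0, 4.0], index=idx),
                pd.Series([1.0, 3.0, 2.0, 4.0], index=idx),
            )
        assert np.isnan(rec.tau_discrete)
        assert not rec.correlated

    def test_tau_matches_brute_force_tau_b(self):
        """Concordant/discordant pair counting with tie correction."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            x = rng.integers(-1, 2, size=n).astype(float)
            y = rng.normal(size=n)
            if np.unique(x).size < 2:
                continue
            concordant = discordant = 0
            tx = ty = 0
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = x[i] - x[j], y[i] - y[j]
                    if a == 0 and b == 0:
                        tx += 1
                        ty += 1
                    elif a == 0:
                        tx += 1
                    elif b == 0:
                        ty += 1
                    elif a * b > 0:
                        concordant += 1
                    else:
                        discordant += 1
            n0 = n * (n - 1) / 2
            expected = (concordant - discordant) / np.sqrt((n0 - tx) * (n0 - ty))
            idx = [f"s{i}" for i in range(n)]
            rec = kendall_screen(
                pd.Series(x, index=idx), pd.Series(x, index=idx), pd.Series(y, index=idx)
            )
            assert rec.tau_discrete == pytest.approx(expected)


class TestSingleCellSummary:
    def make_sc(self):
        tpm = pd.DataFrame(
            {
                "c1": [0.0, 1.0],
                "c2": [5.0, 0.0],
                "c3": [10.0, 0.0],
                "d1": [2.0, 0.0],
            },
            index=["g1", "g2"],
        )
        types = pd.Series({"c1": "X", "c2": "X", "c3": "X", "d1": "Y"})
        return SingleCellMatrix(tpm=tpm, cell_types=types)

    def test_mean_and_pct_nonzero(self):
        summary, bins = single_cell_summary(self.make_sc())
        assert summary.loc["g1", ("X", "mean_tpm")] == pytest.approx(5.0)
        assert summary.loc["g1", ("X", "pct_nonzero")] == pytest.approx(100 * 2 / 3)
        assert summary.loc["g2", ("Y", "mean_tpm")] == 0.0
        assert summary.loc["g2", ("Y", "pct_nonzero")] == 0.0

    def test_invariant_under_cell_permutation(self):
        sc = self.make_sc()
        perm = ["d1", "c3", "c1", "c2"]
        sc_perm = SingleCellMatrix(tpm=sc.tpm[perm], cell_types=sc.cell_types[perm])
        a, _ = single_cell_summary(sc)
        b, _ = single_cell_summary(sc_perm)
        pd.testing.assert_frame_equal(a, b)

    def test_decile_bins_sum_to_gene_count(self):
        summary, bins = single_cell_summary(self.make_sc())
        assert (bins.sum(axis=0) == 2).all()
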