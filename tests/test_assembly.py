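"""Null-model statistics: βMNTD, βNTI, RC_Bray and process classification."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pandas as pd
import pytest

from salinet import assembly, io, simulate
from salinet.datatypes import OtuTable, Phylogeny, SalinetError
from tests.conftest import make_table


def tree_from_newick(newick: str) -> Phylogeny:
    return Phylogeny(
        dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    )


class TestBetaMntd:
    def test_identical_communities_zero(self):
        tree = tree_from_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        table = make_table([[3, 1, 0, 2], [3, 1, 0, 2]], otu_ids=list("ABCD"))
        out = assembly.beta_mntd(table, tree)
        assert out.iloc[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_two_singleton_communities_closed_form(self):
        # patristic distance A-C = 0.1 + 0.3 + 0.2 + 0.4 = 1.0; scale to 0.8
        tree = tree_from_newick("((A:0.08,B:0.2):0.24,(C:0.32,D:0.1):0.16);")
        table = make_table([[5, 0, 0, 0], [0, 0, 7, 0]], otu_ids=list("ABCD"))
        out = assembly.beta_mntd(table, tree)
        assert out.iloc[0, 1] == pytest.approx(0.8)

    def test_four_taxon_brute_force(self):
        """Exhaustive nearest-taxon computation on a printed instance."""
        tree = tree_from_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        counts = np.array([[4, 1, 0, 0], [0, 2, 3, 5]])
        table = make_table(counts, otu_ids=list("ABCD"))
        dist = tree.patristic_distances().loc[list("ABCD"), list("ABCD")].to_numpy()

        def brute(k, m):
            fk = counts[k] / counts[k].sum()
            fm = counts[m] / counts[m].sum()
            sk = np.flatnonzero(counts[k])
            sm = np.flatnonzero(counts[m])
            term_k = sum(fk[i] * min(dist[i, j] for j in sm) for i in sk)
            term_m = sum(fm[j] * min(dist[i, j] for i in sk) for j in sm)
            return 0.5 * (term_k + term_m)

        out = assembly.beta_mntd(table, tree)
        assert out.iloc[0, 1] == pytest.approx(brute(0, 1), abs=1e-12)

    def test_symmetry_and_tip_order_invariance(self, small_dataset):
        table, _, _, tree = small_dataset
        sub = OtuTable(table.counts.iloc[:4])
        out = assembly.beta_mntd(sub, tree)
        assert np.allclose(out.to_numpy(), out.to_numpy().T)
        assert (out.to_numpy() >= 0).all()
        shuffled = OtuTable(sub.counts[list(reversed(sub.otu_ids))])
        out2 = assembly.beta_mntd(shuffled, tree)
        assert np.allclose(out.to_numpy(), out2.to_numpy())

    def test_matches_picante(self, tmp_path):
        """Independent R oracle: picante's abundance-weighted comdistnt."""
        table, _, _, tree = simulate.fixture_dataset(
            seed=55, n_samples=5, n_otus=15, depth=400
        )
        io.write_tree(tree, tmp_path / "tree.nwk")
        table.counts.to_csv(tmp_path / "comm.csv")
        mine = assembly.beta_mntd(table, tree)
        script = textwrap.dedent(
            """
            suppressMessages({library(picante); library(ape)})
            args <- commandArgs(trailingOnly=TRUE)
            tree <- read.tree(file.path(args[1], "tree.nwk"))
            comm <- as.matrix(read.csv(file.path(args[1], "comm.csv"), row.names=1))
            d <- as.matrix(comdistnt(comm, cophenetic(tree), abundance.weighted=TRUE))
            write.csv(d, file.path(args[1], "ref.csv"))
            """
        )
        subprocess.run(
            ["Rscript", "-e", script, str(tmp_path)], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        np.testing.assert_allclose(
            mine.loc[ref.index, ref.columns].to_numpy(), ref.to_numpy(), atol=1e-9
        )

    def test_missing_tip_listed(self):
        tree = tree_from_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.1):0.2);")
        table = make_table([[1, 1], [1, 1]], otu_ids=["A", "Zmissing"])
        with pytest.raises(SalinetError, match="Zmissing"):
            assembly.beta_mntd(table, tree)


class TestBetaNti:
    def test_star_phylogeny_flagged_undefined(self):
        """All tips equidistant: shuffling changes nothing, null SD = 0."""
        tree = tree_from_newick("(A:1,B:1,C:1,D:1);")
        table = make_table([[5, 3, 0, 0], [0, 0, 4, 6]], otu_ids=list("ABCD"))
        out = assembly.beta_nti(table, tree, n_null=99, seed=0)
        assert np.isnan(out.bnti.iloc[0, 1])

    def test_reproducible_under_seed(self, small_dataset):
        table, _, _, tree = small_dataset
        sub = OtuTable(table.counts.iloc[:5])
        a = assembly.beta_nti(sub, tree, n_null=99, seed=4).bnti
        b = assembly.beta_nti(sub, tree, n_null=99, seed=4).bnti
        assert a.equals(b)

    def test_null_draw_calibration(self):
        """A pair that is itself a null draw has βNTI roughly standard:
        across many synthetic neutral pairs, mean ≈ 0 and SD ≈ 1."""
        table, _, _, tree = simulate.fixture_dataset(
            seed=21, n_samples=14, n_otus=80, regime="neutral", depth=1500
        )
        out = assembly.beta_nti(table, tree, n_null=199, seed=1)
        vals = out.bnti.to_numpy()[np.triu_indices(14, 1)]
        vals = vals[~np.isnan(vals)]
        assert abs(np.mean(vals)) < 0.5
        assert 0.5 < np.std(vals) < 2.0


class TestRcBray:
    def test_identical_samples_more_similar_than_null(self):
        """Duplicated diverse samples: observed BC = 0, below nearly every
        null draw, so RC is at/near -1."""
        rng = np.random.default_rng(6)
        base = rng.integers(1, 50, size=30)
        counts = np.vstack([base, base, rng.integers(1, 50, size=30)])
        table = make_table(counts)
        rc = assembly.rc_bray(table, n_null=99, seed=0)
        assert rc.iloc[0, 1] < -0.95

    def test_disjoint_samples_less_similar_than_null(self):
        rng = np.random.default_rng(7)
        a = np.concatenate([rng.integers(5, 50, 15), np.zeros(15, dtype=int)])
        b = np.concatenate([np.zeros(15, dtype=int), rng.integers(5, 50, 15)])
        pool = rng.integers(1, 30, size=(4, 30))
        table = make_table(np.vstack([a, b, pool]))
        rc = assembly.rc_bray(table, n_null=99, seed=1)
        assert rc.iloc[0, 1] > 0.95

    def test_bounded_and_reproducible(self, small_dataset):
        table, _, _, _ = small_dataset
        sub = OtuTable(table.counts.iloc[:5])
        rc1 = assembly.rc_bray(sub, n_null=99, seed=9)
        rc2 = assembly.rc_bray(sub, n_null=99, seed=9)
        assert rc1.equals(rc2)
        vals = rc1.to_numpy()
        assert (vals >= -1).all() and (vals <= 1).all()

    def test_zero_total_sample_rejected(self):
        table = make_table([[0, 0], [1, 2]])
        with pytest.raises(SalinetError):
            assembly.rc_bray(table, n_null=99)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.0, "variable_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (-1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.99, "dispersal_limitation"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.99, "dispersal_limitation"),  # boundary |βNTI|=2 stochastic
            (0.0, 0.95, "undominated"),  # boundary RC=0.95
            (0.0, -0.95, "undominated"),
            (float("nan"), 0.0, "undefined"),
        ],
    )
    def test_thresholds(self, bnti, rc, expected):
        assert assembly.classify_assembly(bnti, rc) == expected

    def test_exhaustive_grid_partition(self):
        """Every defined (βNTI, RC) pair receives exactly one of the five
        labels, consistent with the printed thresholds."""
        for b in np.linspace(-4, 4, 41):
            for r in np.linspace(-1, 1, 41):
                label = assembly.classify_assembly(b, r)
                assert label in assembly.PROCESS_LABELS
                if b > 2:
                    assert label == "variable_selection"
                elif b < -2:
                    assert label == "homogeneous_selection"
                elif r < -0.95:
                    assert label == "homogenizing_dispersal"
                elif r > 0.95:
                    assert label == "dispersal_limitation"
                else:
                    assert label == "undominated"


class TestProcessFractions:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_i", "sample_j", "bmntd", "bnti", "bc", "rcbray", "process"]
        )

    def test_all_undominated(self):
        pairs = self._pairs(
            [["a", "b", 0.1, 0.0, 0.5, 0.0, "undominated"],
             ["a", "c", 0.1, 0.5, 0.5, 0.1, "undominated"],
             ["b", "c", 0.1, -0.5, 0.5, -0.1, "undominated"]]
        )
        groups = pd.Series({"a": "salt", "b": "salt", "c": "salt"})
        out = assembly.process_fractions(pairs, groups)
        assert out.fractions.loc["salt", "undominated"] == 1.0
        assert out.fractions.loc["salt"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_mixture_recovered(self):
        """30% of pairs planted deterministic: recovered within binomial error."""
        rng = np.random.default_rng(12)
        rows = []
        n = 400
        n_det = 0
        for k in range(n):
            det = rng.random() < 0.3
            n_det += det
            b = 3.0 if det else 0.0
            rows.append([f"x{k}", f"y{k}", 0.1, b, 0.5, 0.0,
                         assembly.classify_assembly(b, 0.0)])
        pairs = self._pairs(rows)
        groups = pd.Series(
            {s: "salt" for k in range(n) for s in (f"x{k}", f"y{k}")}
        )
        out = assembly.process_fractions(pairs, groups)
        assert out.fractions.loc["salt", "variable_selection"] == pytest.approx(n_det / n)

    def test_kruskal_type_one_error(self):
        """Identical βNTI distributions in all groups: rejection ≈ alpha."""
        rng = np.random.default_rng(13)
        rejections = 0
        runs = 400
        for _ in range(runs):
            groups = np.repeat(["a", "b", "c"], 10)
            vals = rng.normal(size=30)
            from scipy import stats

            _, p = stats.kruskal(vals[:10], vals[10:20], vals[20:])
            rejections += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / runs)
        assert abs(rejections / runs - 0.05) < 3 * se

    def test_undefined_pairs_counted_not_fractioned(self):
        pairs = self._pairs(
            [["a", "b", 0.1, np.nan, 0.5, 0.0, "undefined"],
             ["a", "c", 0.1, 0.0, 0.5, 0.0, "undominated"],
             ["b", "c", 0.1, 0.0, 0.5, 0.0, "undominated"]]
        )
        groups = pd.Series({"a": "salt", "b": "salt", "c": "salt"})
        out = assembly.process_fractions(pairs, groups)
        assert out.n_undefined == 1
        assert out.fractions.loc["salt"].sum() == pytest.approx(1.0)
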