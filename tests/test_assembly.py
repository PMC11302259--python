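import itertools

import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.assembly import (
    AssemblyModel,
    NullModelConfig,
    _null_sample,
    _stream,
    classify_pair,
)
from ecoassembly.containers import CommunityTable, SampleMetadata

from conftest import random_table, tree_from_newick


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_beta_mntd(counts, dist, weighted):
    """Double-loop betaMNTD, coded independently of the vectorized version."""
    n_taxa, n_samples = counts.shape
    out = np.zeros((n_samples, n_samples))
    for j in range(n_samples):
        for k in range(n_samples):
            if j == k:
                continue
            pres_j = [i for i in range(n_taxa) if counts[i, j] > 0]
            pres_k = [i for i in range(n_taxa) if counts[i, k] > 0]
            tot_j = sum(counts[i, j] for i in pres_j)
            tot_k = sum(counts[i, k] for i in pres_k)
            term_j = 0.0
            for i in pres_j:
                w = counts[i, j] / tot_j if weighted else 1.0 / len(pres_j)
                term_j += w * min(dist[i, i2] for i2 in pres_k)
            term_k = 0.0
            for i in pres_k:
                w = counts[i, k] / tot_k if weighted else 1.0 / len(pres_k)
                term_k += w * min(dist[i, i2] for i2 in pres_j)
            out[j, k] = 0.5 * (term_j + term_k)
    return out


def brute_raup_crick(table, n_null, seed, rescale=True):
    """Per-pair null loop sharing the implementation's RNG stream but with
    independently coded selection ordering, Bray-Curtis, tie handling and
    rescaling."""
    counts = table.counts.astype(float)
    pool = counts.sum(axis=1) > 0
    sub = counts[pool]
    occ = (sub > 0).sum(axis=1).astype(float)
    meta_p = sub.sum(axis=1) / sub.sum()
    log_occ = np.log(occ)
    n = table.n_samples
    out = np.zeros((n, n))
    for pair_index, (j, k) in enumerate(itertools.combinations(range(n), 2)):
        a, b = sub[:, j], sub[:, k]
        obs = sum(abs(x - y) for x, y in zip(a, b)) / sum(x + y for x, y in zip(a, b))
        rng = _stream(seed, 1, pair_index)
        less = ties = 0
        for _ in range(n_null):
            nulls = []
            for col in (a, b):
                s = int((col > 0).sum())
                total = int(col.sum())
                keys = log_occ + rng.gumbel(size=log_occ.size)
                drawn = sorted(np.argsort(keys)[-s:])
                p = np.array([meta_p[i] for i in drawn])
                reads = rng.multinomial(total - s, p / p.sum())
                vec = np.zeros(log_occ.size)
                for pos, i in enumerate(drawn):
                    vec[i] = 1 + reads[pos]
                nulls.append(vec)
            nb = sum(abs(x - y) for x, y in zip(*nulls)) / sum(x + y for x, y in zip(*nulls))
            if abs(nb - obs) <= 1e-12:
                ties += 1
            elif nb < obs:
                less += 1
        raw = (less + 0.5 * ties) / n_null
        val = 2 * (raw - 0.5) if rescale else raw
        out[j, k] = out[k, j] = val
    return out


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

class TestPatristic:
    def test_hand_path_sums(self, small_tree):
        d = ea.patristic_distances(small_tree).filter(["A", "B", "C"])
        assert d["A", "B"] == pytest.approx(2.0)
        assert d["A", "C"] == pytest.approx(4.0)
        assert d["B", "C"] == pytest.approx(4.0)

    def test_ultrametric_bound(self):
        tree = ea.simulate_tree(12, seed=5)
        depth = max(tip.accumulate_to_ancestor(tree) for tip in tree.tips())
        d = ea.patristic_distances(tree)
        assert d.data.max() <= 2 * depth + 1e-9

    def test_star_tree_equal_lengths(self):
        star = tree_from_newick("(A:1.5,B:1.5,C:1.5,D:1.5);")
        d = ea.patristic_distances(star)
        off = d.data[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 3.0)


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------

class TestBetaMntd:
    def test_identical_samples_zero(self):
        table = CommunityTable(np.array([[3, 3], [2, 2]]), ["A", "B"], ["s1", "s2"])
        tree = tree_from_newick("(A:1,B:1);")
        assert ea.beta_mntd(table, tree)["s1", "s2"] == 0.0

    def test_two_singleton_samples(self):
        table = CommunityTable(np.array([[4, 0], [0, 9]]), ["A", "B"], ["s1", "s2"])
        tree = tree_from_newick("(A:1,B:1);")
        assert ea.beta_mntd(table, tree)["s1", "s2"] == pytest.approx(2.0)

    def test_matches_picante_weighted(self, reference_fixture):
        # frozen oracle: picante::comdistnt(abundance.weighted=TRUE,
        # exclude.conspecifics=FALSE) on the reference fixture
        table, tree = reference_fixture
        expected = np.array(
            [
                [0.0, 0.2129302, 0.5685925, 0.1109303, 1.1126361],
                [0.2129302, 0.0, 0.4030204, 0.2739264, 0.4393079],
                [0.5685925, 0.4030204, 0.0, 0.4340181, 0.4282246],
                [0.1109303, 0.2739264, 0.4340181, 0.0, 0.9704523],
                [1.1126361, 0.4393079, 0.4282246, 0.9704523, 0.0],
            ]
        )
        got = ea.beta_mntd(table, tree).filter([f"s{i}" for i in range(5)]).data
        np.testing.assert_allclose(got, expected, atol=5e-8)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            tree = ea.simulate_tree(6, seed=int(rng.integers(2**31)))
            table = random_table(rng, 6, 4)
            table = CommunityTable(table.counts, [t.name for t in tree.tips()],
                                   table.sample_ids)
            dist = ea.patristic_distances(tree).filter(table.taxon_ids).data
            got = ea.beta_mntd(table, tree, abundance_weighted=weighted).data
            want = brute_beta_mntd(table.counts, dist, weighted)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_extra_tree_tips_pruned_missing_taxa_fatal(self, small_tree):
        table = CommunityTable(np.array([[1, 2], [3, 4]]), ["A", "B"], ["s1", "s2"])
        ea.beta_mntd(table, small_tree)  # C pruned silently
        bad = CommunityTable(np.array([[1, 2], [3, 4]]), ["A", "Z"], ["s1", "s2"])
        with pytest.raises(ValueError, match="Z"):
            ea.beta_mntd(bad, small_tree)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

class TestBnti:
    def test_identical_samples_flagged_undefined(self):
        table = CommunityTable(np.array([[3, 3], [2, 2]]), ["A", "B"], ["s1", "s2"])
        tree = tree_from_newick("(A:1,B:1);")
        res = ea.bnti(table, tree, NullModelConfig(n_null=49, seed=0))
        assert np.isnan(res.bnti.loc["s1", "s2"])

    def test_star_tree_undefined_by_symmetry(self):
        star = tree_from_newick("(A:1,B:1,C:1,D:1);")
        table = CommunityTable(
            np.array([[5, 0], [1, 0], [0, 2], [0, 7]]), list("ABCD"), ["s1", "s2"]
        )
        res = ea.bnti(table, star, NullModelConfig(n_null=49, seed=0))
        assert np.isnan(res.bnti.loc["s1", "s2"])

    def test_clade_restricted_communities_give_strong_negative_bnti(self):
        # both samples confined to sister taxa of the same shallow cherries on
        # a tree of many deep clades: observed nearest-taxon turnover sits far
        # below the tip-shuffle null, the signature of homogeneous selection
        parts = ",".join(f"(c{i}a:0.1,c{i}b:0.1):10" for i in range(1, 17))
        tree = tree_from_newick(f"({parts});")
        taxa = [t.name for t in tree.tips()]
        idx = {t: i for i, t in enumerate(taxa)}
        counts = np.zeros((32, 2), dtype=int)
        for t in ("c1a", "c2a"):
            counts[idx[t], 0] = 5
        for t in ("c1b", "c2b"):
            counts[idx[t], 1] = 5
        table = CommunityTable(counts, taxa, ["s1", "s2"])
        res = ea.bnti(table, tree, NullModelConfig(n_null=999, seed=7))
        assert res.bnti.loc["s1", "s2"] < -2

    def test_symmetry_and_reseeding_stability(self, reference_fixture):
        table, tree = reference_fixture
        zs = []
        for seed in range(20):
            res = ea.bnti(table, tree, NullModelConfig(n_null=999, seed=seed))
            z = res.bnti.to_numpy()
            np.testing.assert_allclose(z, z.T, equal_nan=True)
            zs.append(z)
        stack = np.stack(zs)
        off = ~np.eye(stack.shape[1], dtype=bool)
        spread = np.nanstd(stack[:, off], axis=0)
        assert np.nanmax(spread) < 0.2

    def test_requires_two_nulls(self, reference_fixture):
        table, tree = reference_fixture
        with pytest.raises(ValueError, match="n_null"):
            ea.bnti(table, tree, NullModelConfig(n_null=1, seed=0))


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

class TestRaupCrick:
    def test_single_taxon_metacommunity_all_ties(self):
        table = CommunityTable(np.array([[10, 20]]), ["A"], ["s1", "s2"])
        rc = ea.raup_crick_bray(table, NullModelConfig(n_null=99, seed=0))
        assert rc.loc["s1", "s2"] == pytest.approx(0.0)

    def test_bounds_property(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            table = random_table(rng, 5, 3)
            rc = ea.raup_crick_bray(
                table, NullModelConfig(n_null=19, seed=int(rng.integers(2**31)))
            ).to_numpy()
            assert (np.abs(rc) <= 1 + 1e-12).all()
            np.testing.assert_allclose(rc, rc.T)

    def test_brute_force_oracle_shared_stream(self):
        rng = np.random.default_rng(5)
        for seed in (1, 2, 3):
            table = random_table(rng, 4, 3, max_count=30)
            got = ea.raup_crick_bray(table, NullModelConfig(n_null=20, seed=seed))
            want = brute_raup_crick(table, n_null=20, seed=seed)
            np.testing.assert_allclose(got.to_numpy(), want, atol=1e-12)

    def test_order_independent_pair_streams(self):
        # permuting sample order permutes the matrix but pairs keep their values
        rng = np.random.default_rng(9)
        table = random_table(rng, 6, 4)
        rc = ea.raup_crick_bray(table, NullModelConfig(n_null=49, seed=4))
        assert rc.loc["s1", "s2"] == rc.loc["s2", "s1"]

    def test_null_sample_conserves_richness_and_total(self):
        rng = _stream(0, 1, 0)
        log_occ = np.log(np.array([3.0, 2.0, 1.0, 2.0, 1.0]))
        meta_p = np.array([0.4, 0.3, 0.1, 0.15, 0.05])
        vec = _null_sample(rng, log_occ, meta_p, richness=3, total=50)
        assert (vec > 0).sum() == 3
        assert vec.sum() == 50


# ---------------------------------------------------------------------------
# classification and partitioning
# ---------------------------------------------------------------------------

class TestClassification:
    @pytest.mark.parametrize(
        "b,rc,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (3.0, -1.0, "heterogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (0.3, 0.97, "dispersal_limitation"),
            (0.0, -0.96, "homogenizing_dispersal"),
            (1.9, 0.5, "undominated"),
            # boundary rule: values exactly at a threshold are not extreme
            (2.0, 0.0, "undominated"),
            (-2.0, 0.96, "dispersal_limitation"),
            (0.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
            (float("nan"), 0.99, "undefined"),
        ],
    )
    def test_rule(self, b, rc, expected):
        assert classify_pair(b, rc) == expected

    def test_fraction_normalization(self):
        pairs = pd.DataFrame(
            {
                "sample_i": ["a", "a", "b"],
                "sample_j": ["b", "c", "c"],
                "process": ["heterogeneous_selection", "undominated", "undefined"],
            }
        )
        fr = ea.partition_fractions(pairs, {"a": "G", "b": "G", "c": "G"})
        row = fr.loc["G"]
        assert row["n_pairs"] == 2 and row["n_undefined"] == 1
        assert sum(row[p] for p in ea.PROCESSES) == pytest.approx(1.0)

    def test_all_one_process(self):
        pairs = pd.DataFrame(
            {
                "sample_i": ["a"],
                "sample_j": ["b"],
                "process": ["heterogeneous_selection"],
            }
        )
        fr = ea.partition_fractions(pairs, {"a": "G", "b": "G"})
        assert fr.loc["G", "heterogeneous_selection"] == 1.0

    def test_small_group_rejected(self):
        pairs = pd.DataFrame(
            {"sample_i": ["a"], "sample_j": ["b"], "process": ["undominated"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            ea.partition_fractions(pairs, {"a": "G", "b": "G", "c": "H"})


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted():
    ds = ea.generate_dataset(
        ea.scenario_preset("mr_like", n_taxa=60, n_sites=8, reads_per_sample=2000),
        seed=11,
    )
    model = AssemblyModel(ds.table, ds.tree, ds.metadata,
                          config=NullModelConfig(n_null=99, seed=11))
    return model.fit()


class TestAssemblyModel:

    def test_pairs_consistent_with_rule(self, fitted):
        for _, row in fitted.pairs.iterrows():
            assert row.process == classify_pair(row.bnti, row.rc_bray)

    def test_selection_scenario_pushes_bnti_up(self, fitted):
        # even at this small problem size, environmental filtering inflates
        # phylogenetic turnover relative to the null and does so most for
        # environmentally distant site pairs (full-scale modal-process
        # recovery is exercised in the end-to-end suite)
        assert np.nanmean(fitted.pairs.bnti) > 0
        assert (fitted.pairs.bnti > 2).sum() > 0
        assert (fitted.pairs.process == "heterogeneous_selection").sum() > 0

    def test_summary_mentions_fractions(self, fitted):
        text = fitted.summary()
        assert "heterogeneous_selection" in text and "group MR" in text

    def test_results_written(self, fitted, tmp_path):
        fitted.to_files(tmp_path)
        assert (tmp_path / "pairs.tsv").exists()
        assert (tmp_path / "fractions.json").exists()

    def test_same_seed_bit_reproducible(self):
        ds = ea.generate_dataset(
            ea.scenario_preset("lr_like", n_taxa=40, n_sites=6, reads_per_sample=1000),
            seed=3,
        )
        cfg = NullModelConfig(n_null=49, seed=21)
        r1 = AssemblyModel(ds.table, ds.tree, ds.metadata, config=cfg).fit()
        r2 = AssemblyModel(ds.table, ds.tree, ds.metadata, config=cfg).fit()
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)
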