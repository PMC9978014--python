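import itertools

import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.assembly import (
    DISPERSAL_LIMITATION,
    HETEROGENEOUS_SELECTION,
    HOMOGENEOUS_SELECTION,
    HOMOGENIZING_DISPERSAL,
    UNDOMINATED,
    beta_mntd_matrix,
)
from ecoassembly.io import OtuTable
from tests.conftest import random_table


def brute_force_beta_mntd(pa, pb, dist):
    """Independent oracle: explicit double loop over present OTUs."""
    term_a = 0.0
    for j in np.flatnonzero(pa > 0):
        term_a += pa[j] * min(dist[j, k] for k in np.flatnonzero(pb > 0))
    term_b = 0.0
    for j in np.flatnonzero(pb > 0):
        term_b += pb[j] * min(dist[k, j] for k in np.flatnonzero(pa > 0))
    return 0.5 * (term_a + term_b)


class TestBetaMntd:
    def test_hand_path_sum(self, three_tip_tree):
        # samples {A} and {B} on ((A:1,B:1):1,C:2); -> 0.5*(2+2) = 2
        df = pd.DataFrame(
            [[10, 0, 0], [0, 10, 0]], index=["s1", "s2"], columns=["A", "B", "C"]
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.beta_mntd(rel, three_tip_tree, ("s1", "s2")) == pytest.approx(2.0)

    def test_identical_profiles_zero(self, three_tip_tree):
        df = pd.DataFrame(
            [[5, 3, 2], [5, 3, 2]], index=["s1", "s2"], columns=["A", "B", "C"]
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.beta_mntd(rel, three_tip_tree, ("s1", "s2")) == pytest.approx(0.0)

    def test_symmetry(self, three_tip_tree):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(1, 20, size=(2, 3)), index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.beta_mntd(rel, three_tip_tree, ("s1", "s2")) == pytest.approx(
            ea.beta_mntd(rel, three_tip_tree, ("s2", "s1"))
        )

    def test_missing_otu_alignment_error(self, three_tip_tree):
        df = pd.DataFrame(
            [[5, 1], [1, 5]], index=["s1", "s2"], columns=["A", "Zmissing"]
        )
        rel = OtuTable(df).relative_abundance()
        with pytest.raises(ea.AlignmentError, match="Zmissing"):
            ea.beta_mntd(rel, three_tip_tree, ("s1", "s2"))

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_samples, n_otus = 4, 8
            props = rng.dirichlet(np.ones(n_otus), size=n_samples)
            props[rng.random(size=props.shape) < 0.3] = 0.0
            props[:, 0] += 1e-3  # keep rows non-degenerate
            props /= props.sum(axis=1, keepdims=True)
            d = rng.random((n_otus, n_otus))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            mat = beta_mntd_matrix(props, d)
            for i, j in itertools.combinations(range(n_samples), 2):
                assert mat[i, j] == pytest.approx(
                    brute_force_beta_mntd(props[i], props[j], d), abs=1e-10
                )


@pytest.fixture(scope="module")
def four_tip_setup():
    tree = ea.tree_from_string("((A:0.3,B:0.7):0.5,(C:0.4,D:0.9):0.2);")
    df = pd.DataFrame(
        [[8, 4, 0, 1], [0, 2, 9, 5], [3, 0, 1, 7]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return tree, OtuTable(df).relative_abundance()


class TestBetaNti:

    def test_monte_carlo_close_to_exhaustive(self, four_tip_setup):
        """On 4 tips the tip-shuffle null has only 4! = 24 states; the
        Monte-Carlo betaNTI must approach the exhaustive value."""
        tree, rel = four_tip_setup
        props = rel.proportions.to_numpy()
        dist = tree.patristic_matrix(rel.otu_ids).to_numpy()
        obs = beta_mntd_matrix(props, dist)
        null_vals = np.array(
            [
                beta_mntd_matrix(props, dist[np.ix_(perm, perm)])
                for perm in itertools.permutations(range(4))
            ]
        )
        with np.errstate(invalid="ignore"):  # diagonal is 0/0
            exact_nti = (obs - null_vals.mean(axis=0)) / null_vals.std(
                axis=0, ddof=1
            )
        bnti, *_ = ea.beta_nti(rel, tree, n_null=999, seed=3)
        for i, j in itertools.combinations(range(3), 2):
            assert bnti.iloc[i, j] == pytest.approx(exact_nti[i, j], abs=0.2)

    def test_null_values_bounded_by_distance_hull(self, four_tip_setup):
        # every null betaMNTD is a convex combination of patristic distances
        tree, rel = four_tip_setup
        props = rel.proportions.to_numpy()
        dist = tree.patristic_matrix(rel.otu_ids).to_numpy()
        dmax = dist.max()
        for perm in itertools.permutations(range(4)):
            null = beta_mntd_matrix(props, dist[np.ix_(perm, perm)])
            assert np.all(null >= 0)
            assert np.all(null <= dmax + 1e-12)

    def test_invariant_to_branch_length_scaling(self, four_tip_setup):
        tree, rel = four_tip_setup
        scaled = ea.tree_from_string("((A:3,B:7):5,(C:4,D:9):2);")  # x10
        b1, *_ = ea.beta_nti(rel, tree, n_null=199, seed=7)
        b2, *_ = ea.beta_nti(rel, scaled, n_null=199, seed=7)
        pd.testing.assert_frame_equal(b1, b2, atol=1e-9, check_exact=False)

    def test_zero_null_sd_flagged(self):
        # star tree with equal branch lengths: every tip shuffle is identical
        tree = ea.tree_from_string("(A:1,B:1,C:1);")
        df = pd.DataFrame(
            [[5, 1, 0], [0, 1, 5]], index=["s1", "s2"], columns=["A", "B", "C"]
        )
        rel = OtuTable(df).relative_abundance()
        bnti, *_ = ea.beta_nti(rel, tree, n_null=99, seed=0)
        assert np.isnan(bnti.loc["s1", "s2"])


class TestRcBray:
    def test_bounded(self, neutral_dataset):
        rc = ea.rc_bray(neutral_dataset.table, n_null=99, seed=1)
        vals = rc.to_numpy()[np.triu_indices(rc.shape[0], k=1)]
        assert np.all(vals >= -1 - 1e-12)
        assert np.all(vals <= 1 + 1e-12)

    def test_identical_samples_of_common_otus(self):
        # duplicated profiles of OTUs common everywhere: obs Bray = 0 sits
        # below essentially every null -> RC ~ -1
        rng = np.random.default_rng(2)
        base = rng.integers(20, 60, size=8)
        counts = np.tile(base, (4, 1))
        table = OtuTable(
            pd.DataFrame(counts, index=[f"S{i}" for i in range(4)],
                         columns=[f"O{j}" for j in range(8)])
        )
        rc = ea.rc_bray(table, n_null=199, seed=3)
        assert rc.loc["S0", "S1"] < -0.95

    def test_disjoint_samples_of_frequent_otus(self):
        # two sample groups with disjoint OTU sets, every OTU frequent in the
        # metacommunity -> obs Bray = 1 above essentially every null -> RC ~ +1
        a = [40, 40, 40, 40, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 40, 40, 40, 40]
        counts = np.array([a, a, b, b])
        table = OtuTable(
            pd.DataFrame(counts, index=[f"S{i}" for i in range(4)],
                         columns=[f"O{j}" for j in range(8)])
        )
        rc = ea.rc_bray(table, n_null=199, seed=4)
        assert rc.loc["S0", "S2"] > 0.95

    def test_single_sample_rejected(self):
        table = OtuTable(pd.DataFrame([[1, 2]], index=["s"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            ea.rc_bray(table, n_null=99)


class TestClassifyProcesses:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-2.3, 0.1, HOMOGENEOUS_SELECTION),
            (2.6, 0.0, HETEROGENEOUS_SELECTION),
            (0.4, 0.99, DISPERSAL_LIMITATION),
            (0.4, -0.99, HOMOGENIZING_DISPERSAL),
            (1.0, 0.2, UNDOMINATED),
            (0.0, 0.95, UNDOMINATED),  # RC boundary is strict
        ],
    )
    def test_threshold_scheme(self, bnti, rc, expected):
        m1 = pd.DataFrame([[0, bnti], [bnti, 0]], index=["a", "b"], columns=["a", "b"])
        m2 = pd.DataFrame([[0, rc], [rc, 0]], index=["a", "b"], columns=["a", "b"])
        res = ea.classify_processes(m1, m2)
        assert res.pairs.iloc[0]["process"] == expected

    def test_fractions_are_probability_vector(self, neutral_dataset):
        res = ea.assembly_analysis(
            neutral_dataset.table, neutral_dataset.tree, n_null=99, seed=5
        )
        fr = res.process_fractions()
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in fr.values())

    def test_undefined_pairs_excluded(self):
        m1 = pd.DataFrame(
            [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
            index=list("abc"), columns=list("abc"),
        )
        m2 = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = ea.classify_processes(m1, m2)
        assert res.excluded_pairs == [("a", "b")]
        assert sum(res.process_fractions().values()) == pytest.approx(1.0)

    def test_mismatched_samples_rejected(self):
        m1 = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        m2 = pd.DataFrame(np.zeros((2, 2)), index=["a", "c"], columns=["a", "c"])
        with pytest.raises(ea.AlignmentError):
            ea.classify_processes(m1, m2)
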