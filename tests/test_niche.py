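import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.io import OtuTable
from ecoassembly.niche import GENERALIST, NEUTRAL, SPECIALIST, count_swap_null
from tests.conftest import random_table


def brute_force_levins(props: pd.DataFrame, otu: str) -> float:
    """Independent oracle: explicit loop over the printed definition."""
    col = props[otu].to_numpy(dtype=float)
    total = col.sum()
    q = [p / total for p in col]
    return 1.0 / sum(qi**2 for qi in q)


class TestLevinsB:
    def test_uniform_over_n_samples_gives_n(self):
        n = 12
        df = pd.DataFrame(
            {"uni": [10] * n, "other": [5] * n}, index=[f"S{i}" for i in range(n)]
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.levins_b(rel, "uni") == pytest.approx(float(n))

    def test_single_sample_otu_gives_one(self):
        df = pd.DataFrame(
            {"solo": [20, 0, 0, 0], "bg": [5, 5, 5, 5]},
            index=[f"S{i}" for i in range(4)],
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.levins_b(rel, "solo") == pytest.approx(1.0)

    def test_even_split_over_two_samples_gives_two(self):
        # equal proportions in two samples, absent elsewhere -> B = 2
        df = pd.DataFrame(
            {"split": [10, 10, 0, 0], "bg": [10, 10, 20, 20]},
            index=[f"S{i}" for i in range(4)],
        )
        rel = OtuTable(df).relative_abundance()
        assert ea.levins_b(rel, "split") == pytest.approx(2.0)

    def test_matches_brute_force_on_random_otus(self):
        rng = np.random.default_rng(42)
        table = random_table(rng, n_samples=8, n_otus=100)
        rel = table.relative_abundance()
        b = ea.levins_b(rel)
        for otu in rel.otu_ids:
            if table.counts[otu].sum() == 0:
                continue
            assert b[otu] == pytest.approx(
                brute_force_levins(rel.proportions, otu), abs=1e-12
            )

    def test_bounds_one_to_n(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n_samples=7, n_otus=30)
        b = ea.levins_b(table.relative_abundance()).dropna()
        assert (b >= 1 - 1e-12).all()
        assert (b <= 7 + 1e-12).all()

    def test_invariant_to_depth_rescaling(self):
        rng = np.random.default_rng(10)
        table = random_table(rng, n_samples=6, n_otus=15)
        doubled = OtuTable(table.counts * 2)
        b1 = ea.levins_b(table.relative_abundance())
        b2 = ea.levins_b(doubled.relative_abundance())
        pd.testing.assert_series_equal(b1, b2)

    def test_absent_otu_errors(self):
        df = pd.DataFrame({"a": [1, 1], "b": [0, 0], "c": [1, 1]},
                          index=["S1", "S2"])
        rel = ea.RelAbundanceTable(df.div(df.sum(axis=1), axis=0))
        with pytest.raises(ValueError):
            ea.levins_b(rel, "b")


class TestCommunityBm:
    def test_identical_b_zero_sd(self):
        # every OTU uniform -> all B equal n_samples -> sd 0
        df = pd.DataFrame(np.full((5, 4), 3), index=[f"S{i}" for i in range(5)],
                          columns=list("wxyz"))
        rel = OtuTable(df).relative_abundance()
        mean, sd = ea.community_bm(rel, n_boot=100, seed=0)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(0.0)

    def test_single_bootstrap_warns(self):
        rng = np.random.default_rng(1)
        rel = random_table(rng).relative_abundance()
        with pytest.warns(UserWarning):
            _, sd = ea.community_bm(rel, n_boot=1, seed=0)
        assert sd == 0.0

    def test_bootstrap_sd_near_analytic_se(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n_samples=8, n_otus=5)
        rel = table.relative_abundance()
        b = ea.levins_b(rel).dropna().to_numpy()
        analytic_se = b.std(ddof=1) / np.sqrt(len(b))
        _, sd = ea.community_bm(rel, n_boot=100, seed=3)
        assert sd <= 3 * analytic_se
        assert sd >= analytic_se / 3

    def test_empty_otu_set_rejected(self):
        rng = np.random.default_rng(3)
        rel = random_table(rng).relative_abundance()
        with pytest.raises(ValueError):
            ea.community_bm(rel, otus=[])


class TestCountSwapNull:
    def test_preserves_margins_every_replicate(self):
        rng_table = np.random.default_rng(4)
        table = random_table(rng_table, n_samples=6, n_otus=10)
        counts = table.counts.to_numpy()
        rng = np.random.default_rng(5)
        for _ in range(25):
            null = count_swap_null(counts, rng)
            assert np.array_equal(null.sum(axis=0), counts.sum(axis=0))
            assert np.array_equal(null.sum(axis=1), counts.sum(axis=1))
            assert np.all(null >= 0)

    def test_chain_actually_moves(self):
        rng_table = np.random.default_rng(6)
        counts = random_table(rng_table, n_samples=6, n_otus=10).counts.to_numpy()
        null = count_swap_null(counts, np.random.default_rng(7))
        assert not np.array_equal(null, counts)


@pytest.fixture(scope="module")
def contrast_table():
    """A proportionally even OTU and a fully concentrated one against a
    heterogeneous background at equal sample depths: the even OTU sits at
    the B = N maximum (above any noisy null draw) and the concentrated
    one at B = 1 (below any null draw)."""
    rng = np.random.default_rng(8)
    n = 8
    bg = rng.integers(0, 60, size=(n, 10))
    df = pd.DataFrame(bg, index=[f"S{i}" for i in range(n)],
                      columns=[f"bg{j}" for j in range(10)])
    df["solo"] = [320] + [0] * (n - 1)
    df["filler"] = (df.sum(axis=1).max() + 50) - df.sum(axis=1)
    df["uniform"] = 40
    return OtuTable(df)


class TestClassifySpecialists:
    def test_generalist_and_specialist_recovered(self, contrast_table):
        res = ea.classify_specialists(contrast_table, n_perm=199, seed=0)
        assert res.per_otu.loc["uniform", "category"] == GENERALIST
        assert res.per_otu.loc["solo", "category"] == SPECIALIST

    def test_categories_partition_otus(self, contrast_table):
        res = ea.classify_specialists(contrast_table, n_perm=99, seed=1)
        cats = res.per_otu["category"]
        n_classified = cats.isin([GENERALIST, SPECIALIST, NEUTRAL]).sum()
        assert n_classified + (cats == "undefined").sum() == contrast_table.n_otus

    def test_envelope_consistent_with_categories(self, contrast_table):
        res = ea.classify_specialists(contrast_table, n_perm=99, seed=2)
        df = res.per_otu.dropna()
        gen = df[df["category"] == GENERALIST]
        spec = df[df["category"] == SPECIALIST]
        assert (gen["B"] > gen["null_upper"]).all()
        assert (spec["B"] < spec["null_lower"]).all()

    def test_confidence_monotonicity(self, contrast_table):
        # raising conf widens the envelope: generalist/specialist sets shrink
        sets = {}
        for conf in (0.80, 0.95, 0.999):
            res = ea.classify_specialists(contrast_table, n_perm=199, conf=conf, seed=3)
            cats = res.per_otu["category"]
            sets[conf] = (
                set(cats.index[cats == GENERALIST]),
                set(cats.index[cats == SPECIALIST]),
            )
        assert sets[0.999][0] <= sets[0.95][0] <= sets[0.80][0]
        assert sets[0.999][1] <= sets[0.95][1] <= sets[0.80][1]

    def test_sparse_matrix_falls_back_to_row_proportion(self):
        # both samples support only one OTU: no 2x2 checkerboard move exists
        df = pd.DataFrame(
            [[5, 0], [3, 0]], index=["S1", "S2"], columns=["a", "b"]
        )
        with pytest.warns(UserWarning, match="row_proportion"):
            res = ea.classify_specialists(OtuTable(df), n_perm=99, seed=4)
        assert res.null_model == "row_proportion"

    def test_exhaustive_null_envelope_on_tiny_matrix(self):
        """Oracle: enumerate every 3x3 count matrix with the observed margins
        and check the sampled null envelope sits inside the exact support."""
        df = pd.DataFrame(
            [[3, 1, 0], [1, 2, 1], [0, 1, 3]],
            index=["S1", "S2", "S3"],
            columns=["a", "b", "c"],
        )
        counts = df.to_numpy()
        row_sums, col_sums = counts.sum(axis=1), counts.sum(axis=0)

        def enumerate_matrices():
            # the upper-left 2x2 block determines the rest of a 3x3 matrix
            for a00 in range(row_sums[0] + 1):
                for a01 in range(row_sums[0] - a00 + 1):
                    for a10 in range(row_sums[1] + 1):
                        for a11 in range(row_sums[1] - a10 + 1):
                            m = np.array(
                                [
                                    [a00, a01, row_sums[0] - a00 - a01],
                                    [a10, a11, row_sums[1] - a10 - a11],
                                    [col_sums[0] - a00 - a10,
                                     col_sums[1] - a01 - a11, 0],
                                ]
                            )
                            m[2, 2] = row_sums[2] - m[2, 0] - m[2, 1]
                            if np.all(m >= 0) and np.array_equal(
                                m.sum(axis=0), col_sums
                            ):
                                yield m

        exact_b = []
        for m in enumerate_matrices():
            props = m / m.sum(axis=1, keepdims=True)
            col = props[:, 0]
            q = col / col.sum()
            exact_b.append(1.0 / (q**2).sum())
        exact_b = np.array(exact_b)
        assert len(exact_b) > 10
        res = ea.classify_specialists(OtuTable(df), n_perm=999, seed=5)
        lo, hi = res.per_otu.loc["a", ["null_lower", "null_upper"]]
        assert exact_b.min() - 1e-9 <= lo <= hi <= exact_b.max() + 1e-9
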