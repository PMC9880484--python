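import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crosstaxa as ct
from crosstaxa.io import TraitTable
from crosstaxa.metrics import UndefinedMetricError, gower_distance


def _tree(newick: str):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick")


class TestShannon:
    @pytest.mark.parametrize(
        "abundances, expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([5, 0, 0], 0.0),
            ([4, 2, 1], -(4 / 7 * math.log(4 / 7)
                          + 2 / 7 * math.log(2 / 7)
                          + 1 / 7 * math.log(1 / 7))),
        ],
    )
    def test_against_direct_formula(self, abundances, expected):
        assert ct.shannon(abundances) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ct.shannon([0, 0])

    def test_agrees_with_skbio(self, rng):
        skbio_div = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 50, 30)
        counts[0] = 3  # ensure nonzero
        assert ct.shannon(counts) == pytest.approx(
            float(skbio_div.shannon(counts, base=math.e)), abs=1e-10
        )

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariant(self, abundances, factor):
        a = np.array(abundances)
        assert ct.shannon(a * factor) == pytest.approx(ct.shannon(a), abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=15))
    def test_uniform_is_maximal(self, abundances):
        n = len(abundances)
        assert ct.shannon(abundances) <= math.log(n) + 1e-9


class TestRarefiedShannon:
    def test_full_depth_equals_shannon(self):
        counts = [7, 3, 2, 1]
        assert ct.rarefied_shannon(counts, sum(counts), repeats=3, seed=0) == (
            pytest.approx(ct.shannon(counts), abs=1e-12)
        )

    def test_single_taxon_zero(self):
        assert ct.rarefied_shannon([9], 4, repeats=5, seed=0) == 0.0

    def test_matches_exhaustive_enumeration(self):
        """E[H] for counts [3,1] at depth 2 by enumerating all C(4,2)
        subsamples: (2,0) w.p. 1/2 gives H=0, (1,1) w.p. 1/2 gives H=ln2."""
        reads = ["a", "a", "a", "b"]
        values = []
        for combo in itertools.combinations(range(4), 2):
            sub = [reads[i] for i in combo]
            counts = [sub.count("a"), sub.count("b")]
            values.append(ct.shannon(counts) if sum(counts) else 0.0)
        exact = float(np.mean(values))
        assert exact == pytest.approx(0.5 * math.log(2), abs=1e-12)
        repeats = 4000
        mc = ct.rarefied_shannon([3, 1], 2, repeats=repeats, seed=1)
        se = 0.5 * math.log(2) / math.sqrt(repeats)  # sd of H here = ln2/2
        assert abs(mc - exact) < 3 * se

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            ct.rarefied_shannon([2, 1], 10, repeats=2, seed=0)

    def test_non_integer_counts_error(self):
        with pytest.raises(ValueError):
            ct.rarefied_shannon([2.5, 1.0], 2, repeats=2, seed=0)


def _css_oracle(mat: np.ndarray, quantile: float) -> np.ndarray:
    """Independent re-implementation of quantile-threshold cumulative-sum
    scaling, written directly from the definition."""
    factors = []
    for row in mat:
        positive = sorted(v for v in row if v > 0)
        if not positive:
            factors.append(0.0)
            continue
        q = float(np.quantile(positive, quantile))
        factors.append(sum(v for v in row if v <= q))
    factors = np.array(factors)
    ref = float(np.median(factors[factors > 0]))
    out = mat.astype(float).copy()
    for i, s in enumerate(factors):
        if s > 0:
            out[i] = mat[i] * (ref / s)
    return out


class TestCssNormalize:
    def test_identical_samples_unchanged(self):
        df = pd.DataFrame([[3, 1, 0, 6]] * 4, index=[1, 2, 3, 4],
                          columns=list("abcd"))
        out = ct.css_normalize(ct.CommunityTable(df))
        pd.testing.assert_frame_equal(out.data, ct.CommunityTable(df).data.astype(float))

    def test_doubling_a_sample_leaves_its_profile(self):
        base = np.array([[4, 1, 0, 7], [2, 2, 3, 1], [9, 0, 1, 2]])
        doubled = base.copy()
        doubled[1] *= 2
        t1 = ct.CommunityTable(pd.DataFrame(base, index=[1, 2, 3]))
        t2 = ct.CommunityTable(pd.DataFrame(doubled, index=[1, 2, 3]))
        out1 = ct.css_normalize(t1).data.loc[2].to_numpy()
        out2 = ct.css_normalize(t2).data.loc[2].to_numpy()
        assert np.allclose(out1, out2)

    def test_matches_independent_reimplementation(self, rng):
        mat = rng.integers(0, 60, (6, 25))
        mat[:, 0] += 1
        table = ct.CommunityTable(pd.DataFrame(mat, index=range(1, 7)))
        for q in (0.3, 0.5, 0.75):
            ours = ct.css_normalize(table, quantile=q).data.to_numpy()
            oracle = _css_oracle(mat, q)
            assert np.allclose(ours, oracle, atol=1e-9)

    def test_sample_permutation_equivariance(self, rng):
        mat = rng.integers(0, 40, (5, 10)) + 1
        table = ct.CommunityTable(pd.DataFrame(mat, index=[1, 2, 3, 4, 5]))
        out = ct.css_normalize(table).data
        perm = ct.CommunityTable(
            pd.DataFrame(mat[::-1], index=[5, 4, 3, 2, 1])
        )
        out_perm = ct.css_normalize(perm).data
        assert np.allclose(out.loc[3].to_numpy(), out_perm.loc[3].to_numpy())

    def test_bad_quantile(self, toy_community):
        with pytest.raises(ValueError):
            ct.css_normalize(toy_community, quantile=1.5)

    def test_adaptive_quantile_in_range_and_usable(self, rng):
        from crosstaxa.metrics import css_adaptive_quantile

        mat = rng.negative_binomial(2, 0.01, (8, 60))
        table = ct.CommunityTable(pd.DataFrame(mat, index=range(1, 9)))
        q = css_adaptive_quantile(table)
        assert 0 < q < 1
        out = ct.css_normalize(table, quantile=q)
        assert out.data.shape == table.data.shape

    def test_zero_row_passes_through_with_warning(self):
        df = pd.DataFrame([[0, 0], [3, 1]], index=[1, 2], columns=["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            out = ct.css_normalize(ct.CommunityTable(df))
        assert (out.data.loc[1] == 0).all()


class TestFaithPd:
    NEWICK = "((A:1,B:2):1,(C:1,D:1):2);"

    def test_all_tips_total_length(self):
        tree = _tree(self.NEWICK)
        assert ct.faith_pd(tree, {"A", "B", "C", "D"}) == pytest.approx(8.0)

    def test_single_tip_root_path(self):
        tree = _tree(self.NEWICK)
        assert ct.faith_pd(tree, {"A"}) == pytest.approx(2.0)

    def test_hand_traced_pair(self):
        # {A, C}: edges A:1 + inner:1 + C:1 + inner:2 = 5
        tree = _tree(self.NEWICK)
        assert ct.faith_pd(tree, {"A", "C"}) == pytest.approx(5.0)

    def test_root_exclusion_flag(self):
        # without the root anchor, {A, B} spans only A:1 + B:2
        tree = _tree(self.NEWICK)
        assert ct.faith_pd(tree, {"A", "B"}, include_root=False) == (
            pytest.approx(3.0)
        )

    def test_unknown_species_listed(self):
        tree = _tree(self.NEWICK)
        with pytest.raises(ValueError, match="ZZZ"):
            ct.faith_pd(tree, {"A", "ZZZ"})

    def test_monotone_in_species(self, small_dataset, rng):
        tree = small_dataset["tree"]
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        subset = set(rng.choice(tips, 5, replace=False))
        pd_small = ct.faith_pd(tree, subset)
        extra = next(t for t in tips if t not in subset)
        assert ct.faith_pd(tree, subset | {extra}) >= pd_small

    def test_agrees_with_skbio(self, small_dataset, rng):
        skbio_beta = pytest.importorskip("skbio.diversity.alpha")
        from io import StringIO

        from skbio import TreeNode

        tree = small_dataset["tree"]
        newick = tree.as_string(schema="newick", suppress_rooting=True)
        sk_tree = TreeNode.read(StringIO(newick))
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        present = sorted(rng.choice(tips, 8, replace=False))
        counts = [1] * len(present)
        expected = float(
            skbio_beta.faith_pd(counts, taxa=present, tree=sk_tree)
        )
        assert ct.faith_pd(tree, set(present)) == pytest.approx(expected, rel=1e-9)


class TestFunctionalDispersion:
    @staticmethod
    def _traits(df):
        return TraitTable(df)

    def test_identical_traits_zero(self):
        traits = self._traits(
            pd.DataFrame({"t": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        )
        ab = pd.Series([2.0, 3.0, 1.0], index=["a", "b", "c"])
        assert ct.functional_dispersion(traits, ab) == pytest.approx(0.0)

    def test_single_species_zero(self):
        traits = self._traits(pd.DataFrame({"t": [1.0]}, index=["a"]))
        assert ct.functional_dispersion(
            traits, pd.Series([5.0], index=["a"])
        ) == pytest.approx(0.0)

    def test_two_species_half_gower_distance(self):
        traits = self._traits(
            pd.DataFrame({"t": [0.0, 3.0]}, index=["a", "b"])
        )
        ab = pd.Series([1.0, 1.0], index=["a", "b"])
        d = gower_distance(traits).iloc[0, 1]  # = 1 after range normalization
        assert ct.functional_dispersion(traits, ab, correction="none") == (
            pytest.approx(d / 2)
        )

    def test_duplicated_species_with_split_abundance_invariant(self):
        traits3 = self._traits(
            pd.DataFrame(
                {"t": [0.0, 2.0, 5.0], "c": ["x", "y", "x"]},
                index=["a", "b", "c"],
            )
        )
        ab = pd.Series([4.0, 2.0, 1.0], index=["a", "b", "c"])
        base = ct.functional_dispersion(traits3, ab)
        traits4 = self._traits(
            pd.DataFrame(
                {"t": [0.0, 0.0, 2.0, 5.0], "c": ["x", "x", "y", "x"]},
                index=["a1", "a2", "b", "c"],
            )
        )
        ab4 = pd.Series([2.0, 2.0, 2.0, 1.0], index=["a1", "a2", "b", "c"])
        # Gower ranges are unchanged, so splitting a species' abundance over
        # two identical entries must not move the index
        assert ct.functional_dispersion(traits4, ab4) == pytest.approx(
            base, abs=1e-9
        )

    def test_no_covered_species_errors(self):
        traits = self._traits(pd.DataFrame({"t": [1.0]}, index=["a"]))
        with pytest.raises(UndefinedMetricError):
            ct.functional_dispersion(traits, pd.Series([1.0], index=["zz"]))


class TestCwmAndComposition:
    def test_equal_abundance_is_mean(self):
        traits = TraitTable(
            pd.DataFrame({"h": [1.0, 3.0, 8.0]}, index=["a", "b", "c"])
        )
        ab = pd.Series([2.0, 2.0, 2.0], index=["a", "b", "c"])
        assert ct.cwm(traits, ab)["h"] == pytest.approx(4.0)

    def test_weighted(self):
        traits = TraitTable(pd.DataFrame({"h": [0.0, 10.0]}, index=["a", "b"]))
        ab = pd.Series([1.0, 3.0], index=["a", "b"])
        assert ct.cwm(traits, ab)["h"] == pytest.approx(7.5)

    def test_single_species_single_level(self):
        cover = ct.CommunityTable(
            pd.DataFrame({"a": [10.0], "b": [0.0]}, index=[1])
        )
        traits = TraitTable(
            pd.DataFrame({"life_span": ["annual", "perennial"]},
                         index=["a", "b"])
        )
        comp = ct.categorical_composition(cover, traits)
        assert comp.data.loc[1, "life_span=annual"] == 10.0
        assert comp.data.loc[1, "life_span=perennial"] == 0.0

    def test_default_trait_set_yields_39_columns(self, small_dataset):
        comp = ct.categorical_composition(
            small_dataset["plants"], small_dataset["traits"]
        )
        assert comp.data.shape[1] == 39
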