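"""The four rank-based scorers are checked against independent brute-force
oracles (explicit step-function / running-sum loops) on exhaustive
enumerations of all C(8,2) two-gene placements at N=8, plus the closed-form
worked micro-examples."""

from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ranks_from_placement
from lactoscore.io import CountMatrix, GeneSet
from lactoscore.scoring import (
    METHODS,
    ScoringParams,
    rank_descending,
    score_all,
    score_aucell,
    score_modulescore,
    score_singscore,
    score_ssgsea,
    score_ucell,
)

SET_IDX = np.array([0, 1])


# ----------------------------------------------------------- oracles ----


def oracle_aucell(ranks, set_ranks, k):
    """Literal step-function integration of the recovery curve."""
    n_s = len(set_ranks)
    num = sum(sum(1 for r in set_ranks if r <= x) for x in range(1, k + 1))
    denom = sum(min(x, n_s) for x in range(1, k + 1))
    return num / denom


def oracle_ucell(set_ranks, r_max):
    n_s = len(set_ranks)
    capped = [min(r, r_max + 1) for r in set_ranks]
    u = sum(capped) - n_s * (n_s + 1) / 2
    return max(0.0, min(1.0, 1 - u / (n_s * r_max)))


def oracle_singscore(set_ranks, n):
    """Normalize the mean ascending rank by its enumerated extremes."""
    n_s = len(set_ranks)
    rho = [n + 1 - r for r in set_ranks]
    mr = sum(rho) / n_s
    worst = sum(range(1, n_s + 1)) / n_s          # set at the bottom ranks
    best = sum(range(n - n_s + 1, n + 1)) / n_s   # set at the top ranks
    return (mr - worst) / (best - worst)


def oracle_ssgsea(ranks, set_idx, alpha):
    """Step-by-step walk down the ranking."""
    n = len(ranks)
    order = sorted(range(n), key=lambda i: (ranks[i], i))
    in_set = set(set_idx.tolist())
    w = {i: (n - ranks[i] + 1) ** alpha for i in order if i in in_set}
    w_tot = sum(w.values())
    running, es = 0.0, 0.0
    for i in order:
        if i in in_set:
            running += w[i] / w_tot
        else:
            running -= 1.0 / (n - len(in_set))
        es += running
    return es


def all_two_gene_placements(n=8):
    return list(combinations(range(1, n + 1), 2))


# ------------------------------------------------- worked micro-cases ----


class TestWorkedExamples:
    def test_aucell_top_ranks_is_one(self):
        r = ranks_from_placement(10, (1, 2))
        assert score_aucell(r, SET_IDX, 0.5) == 1.0

    def test_aucell_ranks_3_and_6(self):
        r = ranks_from_placement(10, (3, 6))
        assert score_aucell(r, SET_IDX, 0.5) == pytest.approx(1 / 3, abs=1e-12)

    def test_aucell_set_below_k_is_zero(self):
        r = ranks_from_placement(10, (8, 9))
        assert score_aucell(r, SET_IDX, 0.5) == 0.0

    def test_ucell_perfect_ranks(self):
        r = ranks_from_placement(10, (1, 2))
        assert score_ucell(r, SET_IDX, 5) == 1.0

    def test_ucell_capped_rank(self):
        r = ranks_from_placement(10, (3, 6))  # rank 6 capped to 6 (r_max=5)
        assert score_ucell(r, SET_IDX, 5) == pytest.approx(0.4, abs=1e-12)

    def test_ucell_floor_when_all_beyond_rmax(self):
        n_s, r_max = 2, 5
        r = ranks_from_placement(10, (9, 10))
        floor = 1 - (n_s * (r_max + 1) - n_s * (n_s + 1) / 2) / (n_s * r_max)
        assert score_ucell(r, SET_IDX, r_max) == pytest.approx(max(0, floor))

    def test_singscore_extremes(self):
        assert score_singscore(ranks_from_placement(10, (1, 2)), SET_IDX) == 1.0
        assert score_singscore(ranks_from_placement(10, (9, 10)), SET_IDX) == 0.0

    def test_singscore_mid_example(self):
        # descending ranks {3, 6} = ascending ranks {8, 5}
        r = ranks_from_placement(10, (3, 6))
        assert score_singscore(r, SET_IDX) == pytest.approx(0.625, abs=1e-12)

    def test_ssgsea_five_gene_hand_oracle(self):
        r = ranks_from_placement(5, (1, 3))  # set = {g1, g3} by rank
        expected = oracle_ssgsea(r, SET_IDX, 0.25)
        assert score_ssgsea(r, SET_IDX, 0.25) == pytest.approx(expected, abs=1e-9)

    def test_ssgsea_alpha_zero_symmetric_split(self):
        # N=4, set at ranks {1, 4}: +1/2, -1/2, -1/2(+...) walk nets zero sum
        r = ranks_from_placement(4, (1, 4))
        assert score_ssgsea(r, SET_IDX, 0.0) == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------- exhaustive oracle sweeps ----


@pytest.mark.parametrize("placement", all_two_gene_placements())
def test_scorers_match_oracles_exhaustively(placement):
    n = 8
    r = ranks_from_placement(n, placement)
    assert score_aucell(r, SET_IDX, 0.5) == pytest.approx(
        oracle_aucell(r, placement, k=4), abs=1e-9
    )
    assert score_ucell(r, SET_IDX, 6) == pytest.approx(
        oracle_ucell(placement, r_max=6), abs=1e-9
    )
    assert score_singscore(r, SET_IDX) == pytest.approx(
        oracle_singscore(placement, n), abs=1e-9
    )
    assert score_ssgsea(r, SET_IDX, 0.25) == pytest.approx(
        oracle_ssgsea(r, SET_IDX, 0.25), abs=1e-9
    )


def test_ssgsea_monotone_in_set_rank():
    """Moving a set gene up in rank strictly increases the enrichment score."""
    n = 8
    es = {}
    for placement in all_two_gene_placements(n):
        r = ranks_from_placement(n, placement)
        es[placement] = score_ssgsea(r, SET_IDX, 0.25)
    for (a, b), v in es.items():
        if a > 1 and (a - 1, b) in es:
            assert es[(a - 1, b)] > v
        if b > a + 1 and (a, b - 1) in es:
            assert es[(a, b - 1)] > v


# -------------------------------------------------------- properties ----


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 50.0), min_size=8, max_size=8, unique=True),
       st.floats(0.2, 3.0))
def test_rank_scorers_invariant_under_monotone_transform(expr, power):
    """Rank-based scores depend on expression only through the ranking."""
    x = np.array(expr)
    r1 = rank_descending(x)
    r2 = rank_descending(x**power)  # strictly monotone on positives
    idx = np.array([0, 3])
    for fn, args in [
        (score_aucell, (0.5,)),
        (score_ucell, (6,)),
        (score_singscore, ()),
        (score_ssgsea, (0.25,)),
    ]:
        assert fn(r1, idx, *args) == pytest.approx(fn(r2, idx, *args))


def test_ranks_sum_identity(rng):
    x = rng.poisson(2.0, size=(5, 30)).astype(float)
    r = rank_descending(x)
    n = x.shape[1]
    np.testing.assert_allclose(r.sum(axis=1), n * (n + 1) / 2)


def test_spiked_cell_is_argmax_of_every_rank_scorer(rng):
    counts = rng.poisson(2.0, size=(30, 40)) + 1
    counts[7, :4] = [1000, 999, 998, 997]  # signature at ranks 1..4 of cell 7
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=[f"c{i}" for i in range(30)],
        gene_ids=[f"g{i}" for i in range(40)],
        layer_tag="counts",
    )
    from lactoscore.qc import lognormalize

    norm = lognormalize(cm)
    gs = GeneSet("s", ["g0", "g1", "g2", "g3"])
    panel = score_all(norm, gs, ScoringParams(ucell_max_rank=20))
    for method in ("aucell", "ucell", "singscore", "ssgsea"):
        assert panel[method].idxmax() == "c7", method


class TestModuleScore:
    def _matrix(self, values, n_genes):
        return CountMatrix(
            values=sp.csr_matrix(values),
            cell_ids=[f"c{i}" for i in range(values.shape[0])],
            gene_ids=[f"g{i}" for i in range(n_genes)],
            layer_tag="lognorm",
        )

    def test_identical_expression_scores_zero(self):
        x = np.full((10, 30), 2.5)
        cm = self._matrix(x, 30)
        s = score_modulescore(cm, GeneSet("s", ["g0", "g1"]), n_bins=5,
                              n_controls=10, seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_reproducible_given_seed(self, rng):
        x = rng.gamma(2.0, 1.0, size=(20, 50))
        cm = self._matrix(x, 50)
        gs = GeneSet("s", ["g3", "g8", "g11"])
        a = score_modulescore(cm, gs, seed=42)
        b = score_modulescore(cm, gs, seed=42)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_planted_high_cells_score_higher(self):
        from lactoscore import qc, synth

        cfg = synth.SimulationConfig(n_cells=500, n_genes=600,
                                     lactylation_set_size=25, seed=3)
        cm, truth = synth.simulate_sc_counts(cfg)
        norm = qc.lognormalize(cm)
        gs = GeneSet("sig", sorted(truth.signature_genes))
        s = score_modulescore(norm, gs, seed=0)
        high = np.isin(norm.cell_ids, sorted(truth.planted_high_cells))
        import scipy.stats

        p = scipy.stats.mannwhitneyu(
            s[high], s[~high], alternative="greater"
        ).pvalue
        assert p < 1e-6


class TestScoreAll:
    def test_panel_shape_and_missing_set(self, small_counts):
        from lactoscore.qc import lognormalize

        norm = lognormalize(small_counts)
        with pytest.warns(UserWarning, match="zero matched"):
            panel = score_all(norm, GeneSet("none", ["ZZZ"]),
                              ScoringParams(ucell_max_rank=10))
        assert len(panel) == small_counts.n_cells
        assert panel.isna().all().all()

    def test_absent_set_member_does_not_change_scores(self, rng):
        """A signature member missing from the matrix is dropped, so deleting
        it from the set leaves every score identical."""
        counts = rng.poisson(3.0, size=(15, 20)) + 1
        cm = CountMatrix(
            values=sp.csr_matrix(counts),
            cell_ids=[f"c{i}" for i in range(15)],
            gene_ids=[f"g{i}" for i in range(20)],
        )
        from lactoscore.qc import lognormalize

        norm = lognormalize(cm)
        params = ScoringParams(ucell_max_rank=10)
        with_absent = score_all(norm, GeneSet("s", ["g1", "g2", "NOTAGENE"]),
                                params)
        without = score_all(norm, GeneSet("s", ["g1", "g2"]), params)
        for m in METHODS:
            np.testing.assert_array_equal(
                with_absent[m].to_numpy(), without[m].to_numpy()
            )
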