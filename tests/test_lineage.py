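import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from mitolineage import (LineageParams, SimConfig, SimVariant, VariantCall,
                         assign_cells, binarize, coincidence_probability,
                         expected_cooccurrence, group_variants_into_clone_sets,
                         independent_origin_probability, population_hierarchy,
                         recount_in_cells, simulate_cells)


class TestIndependentOrigin:
    @pytest.mark.parametrize("n,r,expected", [(10_000, 1e-7, 1e-3),
                                              (100, 1e-7, 1e-5)])
    def test_copy_number_times_rate(self, n, r, expected):
        assert independent_origin_probability(LineageParams(r=r, n=n)) == \
            pytest.approx(expected)

    def test_capped_at_one(self):
        assert independent_origin_probability(LineageParams(r=1e-2, n=1000)) == 1.0

    def test_zero_copies_rejected(self):
        with pytest.raises(ValueError):
            LineageParams(n=0)


class TestCoincidence:
    @pytest.mark.parametrize("p,n,expected", [(1e-3, 3, 1e-9), (1.0, 5, 1.0),
                                              (1e-5, 2, 1e-10)])
    def test_power_law(self, p, n, expected):
        assert coincidence_probability(p, n) == pytest.approx(expected)

    @given(st.floats(1e-6, 1 - 1e-6), st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_cell_count(self, p, n):
        assert coincidence_probability(p, n + 1) < coincidence_probability(p, n)


class TestExpectedCooccurrence:
    def test_product_formula(self):
        assert expected_cooccurrence(0.1, 0.1, 100) == pytest.approx(1.0)

    def test_zero_probability_gives_zero(self):
        assert expected_cooccurrence(0.0, 0.9, 10_000) == 0.0

    def test_depth_weights_sum(self):
        w = [0.5, 1.0, 0.25]
        assert expected_cooccurrence(0.2, 0.4, 3, w) == \
            pytest.approx(0.2 * 0.4 * 1.75)

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            expected_cooccurrence(0.2, 0.4, 3, [1.0, 1.0])

    def test_independent_variants_within_poisson_interval(self):
        # variants of truly independent origin: the mixed-cell count sits
        # inside the Poisson interval around p1*p2*N
        rng = np.random.default_rng(21)
        n, p1, p2 = 2000, 0.25, 0.15
        det1 = rng.random(n) < p1
        det2 = rng.random(n) < p2
        mu = expected_cooccurrence(p1, p2, n)
        observed = int((det1 & det2).sum())
        from scipy import stats
        lo, hi = stats.poisson.interval(0.999, mu)
        assert lo <= observed <= hi


class TestCloneGrouping:
    def test_block_diagonal_recovers_two_sets(self):
        # 60 cells: first 30 carry v1+v2, last 30 carry v3 — perfectly split
        det = np.zeros((60, 3), dtype=bool)
        det[:30, 0] = det[:30, 1] = True
        det[30:, 2] = True
        vids = [(1000, "A", "G"), (2000, "C", "T"), (3000, "G", "A")]
        sets = group_variants_into_clone_sets(det, vids)
        assert sets == [frozenset(vids[:2]), frozenset([vids[2]])]

    def test_simulated_two_clones_recovered_exactly(self, two_clone_config):
        cells, _ = simulate_cells(two_clone_config)
        cands = [VariantCall(v.position, v.ref, v.alt, v.vaf_mean, 100, 5, 5)
                 for v in two_clone_config.variants]
        m = recount_in_cells(cells, cands)
        det = binarize(m, 1).astype(bool)
        sets = group_variants_into_clone_sets(det, m.variant_ids, m.site_depth)
        truth = [frozenset(v.variant_id for v in vs)
                 for vs in two_clone_config.clone_variants]
        assert sorted(sets, key=len) == sorted(truth, key=len)

    def test_depth_adjusted_grouping_matches(self, two_clone_config):
        cells, _ = simulate_cells(two_clone_config)
        cands = [VariantCall(v.position, v.ref, v.alt, v.vaf_mean, 100, 5, 5)
                 for v in two_clone_config.variants]
        m = recount_in_cells(cells, cands)
        det = binarize(m, 1).astype(bool)
        sets = group_variants_into_clone_sets(det, m.variant_ids, m.site_depth,
                                              depth_adjust=True)
        assert len(sets) == 2

    def test_single_cell_variant_left_ungrouped(self):
        det = np.zeros((10, 1), dtype=bool)
        det[0, 0] = True
        with pytest.warns(UserWarning, match="nothing to group"):
            sets = group_variants_into_clone_sets(det, [(1000, "A", "G")])
        assert sets == []

    def test_returned_sets_are_disjoint(self, two_clone_config):
        cells, _ = simulate_cells(two_clone_config)
        cands = [VariantCall(v.position, v.ref, v.alt, v.vaf_mean, 100, 5, 5)
                 for v in two_clone_config.variants]
        m = recount_in_cells(cells, cands)
        sets = group_variants_into_clone_sets(binarize(m, 1).astype(bool),
                                              m.variant_ids)
        seen = set()
        for s in sets:
            assert not (s & seen)
            seen |= s


class TestAssignCells:
    VIDS = [(1000, "A", "G"), (2000, "C", "T"), (3000, "G", "A")]
    SETS = [frozenset(VIDS[:2]), frozenset([VIDS[2]])]

    def test_single_set_detection_assigns_clone(self):
        det = np.array([[True, False, False]])
        model = assign_cells(det, self.VIDS, self.SETS, ["c0"])
        assert model.assignments["c0"] == "clone_1"

    def test_mixture_across_sets_is_doublet(self):
        det = np.array([[True, False, True]])
        model = assign_cells(det, self.VIDS, self.SETS, ["c0"])
        assert model.assignments["c0"] == "doublet"

    def test_no_detection_uses_wt_rule(self):
        det = np.zeros((2, 3), dtype=bool)
        model = assign_cells(det, self.VIDS, self.SETS, ["c0", "c1"],
                             wt_labels=["WT", "insufficient"])
        assert model.assignments == {"c0": "WT", "c1": "unassigned"}

    def test_detection_only_in_ungrouped_variant_is_unassigned(self):
        det = np.array([[False, False, True]])
        model = assign_cells(det, self.VIDS, [self.SETS[0]], ["c0"],
                             wt_labels=["WT"])
        assert model.assignments["c0"] == "unassigned"

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            assign_cells(np.zeros((1, 3), dtype=bool), self.VIDS,
                         [frozenset(self.VIDS[:2]), frozenset(self.VIDS[1:])])

    def test_never_assigns_clone_with_outside_detection(self, two_clone_config):
        cells, _ = simulate_cells(two_clone_config)
        cands = [VariantCall(v.position, v.ref, v.alt, v.vaf_mean, 100, 5, 5)
                 for v in two_clone_config.variants]
        m = recount_in_cells(cells, cands)
        det = binarize(m, 1).astype(bool)
        sets = group_variants_into_clone_sets(det, m.variant_ids)
        model = assign_cells(det, m.variant_ids, sets, m.cell_ids)
        for ci, cell in enumerate(m.cell_ids):
            label = model.assignments[cell]
            if label.startswith("clone_"):
                k = int(label.split("_")[1]) - 1
                hits = {m.variant_ids[vi] for vi in np.where(det[ci])[0]}
                grouped_hits = hits & set().union(*sets)
                assert grouped_hits <= sets[k]

    def test_clone_recovery_agreement(self, two_clone_config):
        cells, truth = simulate_cells(two_clone_config)
        cands = [VariantCall(v.position, v.ref, v.alt, v.vaf_mean, 100, 5, 5)
                 for v in two_clone_config.variants]
        m = recount_in_cells(cells, cands)
        det = binarize(m, 1).astype(bool)
        sets = group_variants_into_clone_sets(det, m.variant_ids)
        model = assign_cells(det, m.variant_ids, sets, m.cell_ids)
        pred = [model.assignments[c] for c in m.cell_ids]
        true = [truth.label(i) for i in range(len(cells))]
        keep = [i for i, p in enumerate(pred) if p != "doublet"]
        ari = adjusted_rand_score([true[i] for i in keep],
                                  [pred[i] for i in keep])
        assert ari >= 0.95

    def test_doublet_fraction_matches_configured_rate(self):
        rate, n = 0.10, 1500
        cfg = SimConfig(n_cells=n, clone_fractions=[0.5, 0.5],
                        clone_variants=[[SimVariant(1000, "A", "G", 0.9)],
                                        [SimVariant(2000, "C", "T", 0.9)]],
                        depth_model="constant", depth_mean=200,
                        doublet_rate=rate, seed=31)
        cells, truth = simulate_cells(cfg)
        cands = [VariantCall(1000, "A", "G", 0.9, 200, 5, 5),
                 VariantCall(2000, "C", "T", 0.9, 200, 5, 5)]
        m = recount_in_cells(cells, cands)
        det = binarize(m, 1).astype(bool)
        sets = [frozenset([m.variant_ids[0]]), frozenset([m.variant_ids[1]])]
        model = assign_cells(det, m.variant_ids, sets, m.cell_ids)
        flagged = sum(1 for v in model.assignments.values() if v == "doublet")
        # only cross-clone doublets are visible as mixtures
        cross = float(np.mean(truth.is_doublet
                              & (truth.partner_labels != truth.clone_labels)))
        se = np.sqrt(cross * (1 - cross) / n)
        assert abs(flagged / n - cross) <= 3 * se + 1e-9


class TestPopulationHierarchy:
    def _call(self, pos, ref, alt, vaf, cls="heteroplasmic"):
        n_alt = max(int(vaf * 1000), 1)
        return VariantCall(pos, ref, alt, vaf, 1000, n_alt // 2,
                           n_alt - n_alt // 2, cls,
                           frozenset() if cls != "filtered" else frozenset({"x"}))

    def test_variant_in_all_populations_is_shared(self):
        tables = {pop: [self._call(3243, "A", "G", 0.05)]
                  for pop in ("pHSC", "LSC", "blast")}
        out = population_hierarchy(tables).table
        assert out.category.iloc[0] == "shared_across_populations"
        assert out.n_populations.iloc[0] == 3

    def test_single_population_variant_is_specific(self):
        tables = {"pHSC": [self._call(2967, "G", "A", 0.04)],
                  "LSC": [], "blast": []}
        out = population_hierarchy(tables).table
        assert out.category.iloc[0] == "population_specific:pHSC"

    def test_subtree_sharing_recorded(self):
        tables = {"pHSC": [],
                  "LSC": [self._call(5000, "T", "C", 0.08)],
                  "blast": [self._call(5000, "T", "C", 0.06)]}
        out = population_hierarchy(tables).table
        assert out.category.iloc[0] == "shared_across_populations"
        assert out.populations.iloc[0] == "LSC,blast"

    def test_below_report_cut_not_present(self):
        tables = {"pHSC": [self._call(5000, "T", "C", 0.005)],
                  "LSC": [self._call(5000, "T", "C", 0.06)]}
        out = population_hierarchy(tables).table
        assert out.category.iloc[0] == "population_specific:LSC"

    def test_inconsistent_refs_rejected(self):
        tables = {"pHSC": [self._call(5000, "T", "C", 0.1)],
                  "LSC": [self._call(5000, "G", "C", 0.1)]}
        with pytest.raises(ValueError, match="inconsistent ref"):
            population_hierarchy(tables)

    def test_two_populations_required(self):
        with pytest.raises(ValueError):
            population_hierarchy({"pHSC": []})

    def test_ordering_by_sharing_then_position(self):
        tables = {
            "pHSC": [self._call(9000, "A", "G", 0.1), self._call(100, "C", "T", 0.1)],
            "LSC": [self._call(9000, "A", "G", 0.1)],
        }
        out = population_hierarchy(tables).table
        assert list(out.pos) == [9000, 100]
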