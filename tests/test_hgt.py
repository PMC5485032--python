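"""HGT classification: clade scanning, rule application, feature statistics."""

import numpy as np
import pytest

from diatomevo import hgt, io, simulate, trees
from diatomevo.io import TaxonMap


def build_taxon_map(groups: dict[str, str], focal: str) -> TaxonMap:
    return TaxonMap(entries=groups, focal_species=focal)


def oracle_verdict(tree, taxon_map, focal, rule=hgt.RuleParameters(), scope="diatom"):
    """Independent exhaustive bipartition evaluation of the rule."""
    target_groups = rule.donor_groups | hgt.SCOPE_GROUPS[scope]
    all_leaves = frozenset(trees.leaf_names(tree))
    mean_vals = [
        n.support for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.support is not None
    ]
    tree_mean = float(np.mean(mean_vals)) if mean_vals else None
    sides = {all_leaves: None}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = trees.subtree_leaves(node)
        side = below if focal in below else all_leaves - below
        if side == all_leaves:
            continue
        sup = node.support if not node.is_leaf() else None
        if side not in sides or (sides[side] is None and sup is not None):
            sides[side] = sup
    for side, sup in sides.items():
        groups = [taxon_map.group(leaf) for leaf in side]
        frac = sum(g in target_groups for g in groups) / len(side)
        forbidden = sum(g in rule.forbidden_groups for g in groups)
        donors = sum(g in rule.donor_groups for g in groups)
        euks = [
            leaf for leaf, g in zip(side, groups) if g in hgt.EUKARYOTE_GROUPS
        ]
        sole = bool(euks) and all(leaf == focal for leaf in euks)
        minimum = rule.min_donor_sole_eukaryote if sole else rule.min_donor
        sup_ok = (sup is not None and sup >= rule.support_cutoff) or (
            tree_mean is not None and tree_mean >= rule.support_cutoff
        )
        if frac >= rule.min_target_fraction and forbidden == 0 and donors >= minimum and sup_ok:
            return "candidate"
    return "rejected"


def random_labelled_tree(rng, max_leaves=12):
    """Random gene tree over a random taxon composition; at least one
    diatom leaf (the focal gene) is always present."""
    pool = [
        "bacteria", "bacteria", "bacteria", "archaea", "diatom",
        "other-stramenopile", "metazoa", "plantae", "fungi", "other-eukaryote",
    ]
    n = int(rng.integers(4, max_leaves + 1))
    groups = ["diatom"] + [pool[i] for i in rng.integers(0, len(pool), size=n - 1)]
    entries = {}
    names = []
    for i, g in enumerate(groups):
        name = f"{g}_{i}"
        entries[name] = g
        names.append(name)
    tree = trees.random_binary_tree(names, rng)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node.support = None if rng.random() < 0.2 else float(rng.uniform(0, 1))
    tree.seed_node.support = None
    tm = build_taxon_map(entries, "diatom_0")
    return tree, tm, "diatom_0"


class TestScanClades:
    def test_four_leaf_tree_max_fraction_one(self, rng):
        entries = {"d": "diatom", "b1": "bacteria", "b2": "bacteria", "b3": "bacteria"}
        tree = io.tree_from_string("((d,b1)0.9,(b2,b3)0.8);")
        tm = build_taxon_map(entries, "d")
        reports = hgt.scan_clades(tree, tm, "d")
        assert reports[0].target_fraction == 1.0
        assert all(r.leaves and "d" in r.leaves for r in reports)

    def test_star_tree_only_trivial_clade(self):
        tree = io.tree_from_string("(d,b1,b2,b3);")
        tm = build_taxon_map(
            {"d": "diatom", "b1": "bacteria", "b2": "bacteria", "b3": "bacteria"}, "d"
        )
        reports = hgt.scan_clades(tree, tm, "d")
        sizes = {r.size for r in reports}
        assert 4 in sizes  # the all-leaf clade is present
        assert all(r.size in (1, 3, 4) for r in reports)

    def test_unresolvable_leaf_named_in_error(self):
        tree = io.tree_from_string("((d,x),(b1,b2));")
        tm = build_taxon_map({"d": "diatom", "b1": "bacteria", "b2": "bacteria"}, "d")
        with pytest.raises(ValueError, match="x"):
            hgt.scan_clades(tree, tm, "d")

    def test_matches_bipartition_enumeration(self, rng):
        for rep in range(30):
            tree, tm, focal = random_labelled_tree(rng)
            reports = hgt.scan_clades(tree, tm, focal)
            all_leaves = frozenset(trees.leaf_names(tree))
            expected_sides = {all_leaves}
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                below = trees.subtree_leaves(node)
                side = below if focal in below else all_leaves - below
                expected_sides.add(side)
            assert {r.leaves for r in reports} == expected_sides


class TestClassify:
    def test_sole_eukaryote_needs_ten_bacteria(self):
        # 10 bacteria + focal as only eukaryote, well supported -> candidate
        entries = {"Pmu": "diatom"} | {f"b{i}": "bacteria" for i in range(12)}
        clade = "((((((((((Pmu,b0)0.9,b1)0.9,b2)0.9,b3)0.9,b4)0.9,b5)0.9,b6)0.9,b7)0.9,b8)0.9,b9)"
        tree = io.tree_from_string(f"({clade}0.9,(b10,b11)0.8);")
        tm = build_taxon_map(entries, "Pmu")
        call = hgt.classify_tree(tree, tm, "Pmu")
        assert call.is_candidate and call.confidence == "high"
        assert call.best.donor_count >= 10

    def test_sole_eukaryote_with_six_bacteria_rejected(self):
        entries = {"Pmu": "diatom"} | {f"b{i}": "bacteria" for i in range(6)}
        newick = "(((((((Pmu,b0)0.9,b1)0.9,b2)0.9,b3)0.9,b4)0.9,b5));"
        tree = io.tree_from_string(newick)
        tm = build_taxon_map(entries, "Pmu")
        call = hgt.classify_tree(tree, tm, "Pmu")
        assert not call.is_candidate

    def test_forbidden_member_rejects_clade(self):
        entries = (
            {"Pmu": "diatom", "m": "metazoa"}
            | {f"b{i}": "bacteria" for i in range(10)}
        )
        inner = "(((((((((Pmu,m)0.9,b1)0.9,b2)0.9,b3)0.9,b4)0.9,b5)0.9,b6)0.9,b7)0.9,b8)"
        tree = io.tree_from_string(f"({inner}0.9,b0);")
        tm = build_taxon_map(entries, "Pmu")
        call = hgt.classify_tree(tree, tm, "Pmu")
        assert not call.is_candidate

    def test_weak_clade_strong_tree_is_medium(self):
        tree, tm, truth = simulate.simulate_gene_tree_with_hgt(
            seed=3, planted=True, clade_support=(0.3, 0.4), other_support=(0.8, 1.0)
        )
        call = hgt.classify_tree(tree, tm, "Pmultistriata")
        assert call.is_candidate and call.confidence == "medium"

    def test_verdicts_match_oracle(self, rng):
        agree = 0
        for rep in range(100):
            tree, tm, focal = random_labelled_tree(rng)
            call = hgt.classify_tree(tree, tm, focal)
            assert call.verdict == oracle_verdict(tree, tm, focal)
            agree += 1
        assert agree == 100

    def test_monotone_in_thresholds(self, rng):
        calls = {}
        trees_data = [simulate.simulate_gene_tree_with_hgt(seed=500 + i, planted=i % 2 == 0)
                      for i in range(40)]
        for frac in (0.8, 0.9, 0.95):
            for min_b in (3, 5, 10):
                rule = hgt.RuleParameters(min_target_fraction=frac, min_donor=min_b)
                calls[(frac, min_b)] = {
                    i
                    for i, (tree, tm, _) in enumerate(trees_data)
                    if hgt.classify_tree(tree, tm, "Pmultistriata", rule=rule).is_candidate
                }
        for f1 in (0.8, 0.9, 0.95):
            for f2 in (0.8, 0.9, 0.95):
                for b1 in (3, 5, 10):
                    for b2 in (3, 5, 10):
                        if f2 >= f1 and b2 >= b1:
                            assert calls[(f2, b2)] <= calls[(f1, b1)]


class TestScopesAndRedAlgae:
    def _scoped_tree(self, recipient_group):
        # 6 bacteria keep the all-leaf clade below the 90% fraction and the
        # sole-eukaryote complement clade below the 10-bacteria minimum, so
        # only the planted clade {Pmu, rec, b1..b5} can qualify
        entries = {"Pmu": "diatom", "rec": recipient_group} | {
            f"b{i}": "bacteria" for i in range(6)
        }
        inner = "((((((Pmu,rec)0.9,b1)0.9,b2)0.9,b3)0.9,b4)0.9,b5)"
        tree = io.tree_from_string(f"({inner}0.9,b0);")
        return tree, build_taxon_map(entries, "Pmu")

    def test_narrowest_scope_reported(self):
        tree, tm = self._scoped_tree("other-stramenopile")
        calls = {
            scope: hgt.classify_tree(tree, tm, "Pmu", scope=scope)
            for scope in ("diatom", "stramenopile", "SAR")
        }
        label, qualifying = hgt.classify_lineage_origin(calls)
        # a stramenopile partner dilutes the diatom-scope fraction below 90%
        assert label == "stramenopile-HGT"
        assert qualifying == ["stramenopile", "SAR"]

    def test_diatom_scope_qualifies_directly(self):
        tree, tm = self._scoped_tree("diatom")
        calls = {
            scope: hgt.classify_tree(tree, tm, "Pmu", scope=scope)
            for scope in ("diatom", "stramenopile", "SAR")
        }
        label, qualifying = hgt.classify_lineage_origin(calls)
        assert label == "diatom-HGT" and qualifying[0] == "diatom"

    def test_no_scope_qualifies(self):
        tree, tm, _ = simulate.simulate_gene_tree_with_hgt(seed=9, planted=False)
        calls = {
            scope: hgt.classify_tree(tree, tm, "Pmultistriata", scope=scope)
            for scope in ("diatom",)
        }
        assert hgt.classify_lineage_origin(calls) == ("none", [])

    def test_red_algal_clade_called(self):
        entries = {"Pmu": "diatom"} | {f"r{i}": "red-alga" for i in range(5)}
        newick = "((((((Pmu,r0)0.9,r1)0.9,r2)0.9,r3)0.9,r4));"
        tree = io.tree_from_string(newick)
        tm = build_taxon_map(entries, "Pmu")
        call = hgt.red_algal_origin(tree, tm, "Pmu")
        assert call.is_candidate

    def test_red_algal_plantae_member_rejected(self):
        # two plantae leaves in separate subtrees: every bipartition side
        # containing the focal gene and ≥2 red algae also contains one
        entries = {"Pmu": "diatom", "pl1": "plantae", "pl2": "plantae"} | {
            f"r{i}": "red-alga" for i in range(5)
        }
        inner = "((((((Pmu,pl1)0.9,r0)0.9,r1)0.9,r2)0.9,r3)0.9,r4)"
        tree = io.tree_from_string(f"({inner}0.9,pl2);")
        tm = build_taxon_map(entries, "Pmu")
        assert not hgt.red_algal_origin(tree, tm, "Pmu").is_candidate

    def test_null_trees_yield_no_red_algal_calls(self):
        for seed in range(10):
            tree, tm, _ = simulate.simulate_gene_tree_with_hgt(seed=seed, planted=False)
            assert not hgt.red_algal_origin(tree, tm, "Pmultistriata").is_candidate


class TestFeatureCompare:
    def test_identical_sets_p_one(self):
        res = hgt.feature_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9) or res.direction == "none"

    def test_t_statistic_matches_textbook_formula(self):
        a = [5.0, 6.0, 7.0, 8.0, 9.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = hgt.feature_compare(a, b, feature="gene length")
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        expected = (np.mean(a) - np.mean(b)) / np.sqrt(va / 5 + vb / 5)
        assert res.statistic == pytest.approx(expected)
        assert res.direction == "A>B"

    def test_count_feature_uses_mann_whitney(self):
        res = hgt.feature_compare([1, 2, 2, 3], [2, 3, 3, 4], feature="exon count")
        assert res.test == "mann-whitney"

    def test_shifted_normals_detected(self, rng):
        hits = 0
        for rep in range(50):
            a = rng.normal(0.0, 1.0, size=100)
            b = rng.normal(1.0, 1.0, size=100)
            res = hgt.feature_compare(a, b)
            hits += res.p_value < 0.01
        assert hits >= 49

    def test_singleton_set_rejected_for_t(self):
        with pytest.raises(ValueError):
            hgt.feature_compare([1.0], [1.0, 2.0])
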