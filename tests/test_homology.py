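"""Homology graph, Markov clustering, orphans, Z-scores, RBH, Fisher."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from diatomevo import homology, simulate
from diatomevo.io import SimilarityEdge


def _edge(q, s, score, ev=1e-20, cov=1.0, pid=50.0):
    return SimilarityEdge(q, s, score, ev, cov, pid)


class TestBuildGraph:
    def test_symmetrization_keeps_best_score(self):
        g = homology.build_graph([_edge("a", "b", 100.0), _edge("b", "a", 90.0)])
        assert g.edges["a", "b"]["weight"] == 100.0

    def test_failing_both_directions_removed(self):
        g = homology.build_graph(
            [_edge("a", "b", 100.0, ev=1.0), _edge("b", "a", 90.0, ev=1.0)],
            max_evalue=1e-5,
        )
        assert not g.has_edge("a", "b") and g.has_node("a")

    def test_self_hits_dropped(self):
        g = homology.build_graph([_edge("a", "a", 500.0)])
        assert g.number_of_edges() == 0

    def test_degree_sequence_matches_recount(self, rng):
        names = [f"p{i}" for i in range(30)]
        raw = []
        for _ in range(200):
            q, s = rng.choice(names, size=2, replace=False)
            raw.append(_edge(q, s, float(rng.uniform(50, 300))))
        g = homology.build_graph(raw)
        expected = {n: set() for n in names}
        for e in raw:
            expected[e.query].add(e.subject)
            expected[e.subject].add(e.query)
        for n in names:
            assert g.degree(n) == len(expected[n] - {n})


class TestMcl:
    def test_disconnected_triangles_never_merged(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        res = homology.mcl_cluster(g)
        assert sorted(sorted(c) for c in res.clusters) == [list("abc"), list("xyz")]

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        res = homology.mcl_cluster(g)
        assert frozenset({"lonely"}) in res.clusters

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            homology.mcl_cluster(nx.Graph(), inflation=1.0)

    def test_order_invariance(self, rng):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("x", "y")]
        g1, g2 = nx.Graph(), nx.Graph()
        g1.add_edges_from(edges)
        g2.add_edges_from(reversed(edges))
        c1 = homology.mcl_cluster(g1).clusters
        c2 = homology.mcl_cluster(g2).clusters
        assert sorted(map(sorted, c1)) == sorted(map(sorted, c2))

    def test_column_stochastic_after_every_inflation(self, rng):
        g = nx.gnp_random_graph(40, 0.2, seed=4)
        res = homology.mcl_cluster(g, debug=True)
        assert res.column_sum_error and max(res.column_sum_error) < 1e-9

    def test_clusters_partition_nodes(self, rng):
        g = nx.gnp_random_graph(60, 0.1, seed=9)
        res = homology.mcl_cluster(g)
        seen = [n for c in res.clusters for n in c]
        assert sorted(seen) == sorted(g.nodes)


class TestOrphans:
    SPECIES = {
        "f1": "focal", "f2": "focal", "f3": "focal", "f4": "focal", "f5": "focal",
        "o1": "other", "o2": "other",
    }

    def test_single_species_cluster_members_are_orphans(self):
        report = homology.call_orphans(
            [frozenset({"f1", "f2"})], self.SPECIES, "focal", ["f1", "f2"]
        )
        assert report.orphans == {"f1", "f2"}
        assert report.n_clusters_single_species == 1

    def test_mixed_cluster_members_are_not_orphans(self):
        report = homology.call_orphans(
            [frozenset({"f1", "o1"})], self.SPECIES, "focal", ["f1"]
        )
        assert report.n_orphans == 0

    def test_unclustered_proteins_are_singletons(self):
        report = homology.call_orphans([], self.SPECIES, "focal", ["f1", "f2"])
        assert report.singletons == {"f1", "f2"}

    def test_counts_match_recount(self, rng):
        proteome = [f"f{i}" for i in range(40)]
        others = [f"o{i}" for i in range(40)]
        species = {p: "focal" for p in proteome} | {p: "other" for p in others}
        pool = proteome + others
        rng.shuffle(pool)
        clusters, i = [], 0
        while i < len(pool):
            size = int(rng.integers(1, 5))
            clusters.append(frozenset(pool[i : i + size]))
            i += size
        report = homology.call_orphans(clusters, species, "focal", proteome)
        brute = set()
        for c in clusters:
            if all(species[p] == "focal" for p in c):
                brute |= {p for p in c}
        assert report.orphans == brute
        assert report.n_orphans + len(set(proteome) - report.orphans) == len(proteome)


class TestSingleCopy:
    SPECIES = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}

    def test_duplicate_member_excluded(self):
        out = homology.select_single_copy_clusters(
            [frozenset({"a1", "a2", "b1"})], self.SPECIES, {"A", "B"}
        )
        assert out == []

    def test_missing_species_excluded(self):
        out = homology.select_single_copy_clusters(
            [frozenset({"a1", "b1"})], self.SPECIES, {"A", "B", "C"}
        )
        assert out == []

    def test_planted_clusters_recovered(self, rng):
        species = {}
        clusters = []
        for i in range(10):  # planted one-to-one clusters
            members = {f"sc{i}_{sp}" for sp in "ABC"}
            for m in members:
                species[m] = m.split("_")[1]
            clusters.append(frozenset(members))
        for i in range(20):  # assorted decoy clusters
            members = {f"d{i}_{j}" for j in range(int(rng.integers(1, 4)))}
            for m in members:
                species[m] = rng.choice(list("ABC"))
            clusters.append(frozenset(members))
        out = homology.select_single_copy_clusters(clusters, species, {"A", "B", "C"})
        planted = [c for c in clusters if any("sc" in m for m in c)]
        for c in planted:
            assert c in out


class TestExpansionZscore:
    def test_direct_formula(self):
        counts = pd.DataFrame({"focal": [10], "s1": [1], "s2": [2], "s3": [3]})
        # mean 4, population SD sqrt((36+9+4+1)/4) = sqrt(12.5)
        z = homology.expansion_zscore(counts, "focal")
        assert z["z"].iloc[0] == pytest.approx((10 - 4) / np.sqrt(12.5))

    def test_zero_sd_flagged_not_error(self):
        counts = pd.DataFrame({"focal": [3], "s1": [3], "s2": [3]})
        z = homology.expansion_zscore(counts, "focal")
        assert not z["defined"].iloc[0] and np.isnan(z["z"].iloc[0])

    def test_missing_focal_errors(self):
        with pytest.raises(ValueError, match="focal"):
            homology.expansion_zscore(pd.DataFrame({"a": [1], "b": [2]}), "zz")

    def test_matches_plain_python_recomputation(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(50, 13)),
            columns=[f"sp{i}" for i in range(13)],
        )
        z = homology.expansion_zscore(counts, "sp0")
        for fam in counts.index:
            row = [float(x) for x in counts.loc[fam]]
            mean = sum(row) / len(row)
            sd = (sum((x - mean) ** 2 for x in row) / len(row)) ** 0.5
            if sd > 0:
                assert z.loc[fam, "z"] == pytest.approx(
                    (row[0] - mean) / sd, abs=1e-12
                )

    def test_mean_over_focal_choices_is_zero(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 9, size=(20, 6)), columns=list("abcdef")
        )
        zs = np.array(
            [homology.expansion_zscore(counts, sp)["z"].to_numpy() for sp in counts]
        )
        defined = ~np.isnan(zs).any(axis=0)
        assert np.allclose(zs[:, defined].mean(axis=0), 0.0, atol=1e-10)


class TestRbh:
    SPECIES = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_mutual_best_returned(self):
        edges = [_edge("a1", "b1", 200.0), _edge("b1", "a1", 190.0)]
        assert homology.rbh_orthologs(edges, self.SPECIES, "A", "B") == [("a1", "b1")]

    def test_non_reciprocal_not_returned(self):
        edges = [
            _edge("a1", "b1", 200.0),
            _edge("b1", "a2", 300.0),
            _edge("b1", "a1", 100.0),
        ]
        assert homology.rbh_orthologs(edges, self.SPECIES, "A", "B") == []

    def test_tie_disqualifies(self):
        edges = [
            _edge("a1", "b1", 200.0),
            _edge("a1", "b2", 200.0),
            _edge("b1", "a1", 150.0),
        ]
        assert homology.rbh_orthologs(edges, self.SPECIES, "A", "B") == []

    def test_low_coverage_pair_filtered(self):
        edges = [_edge("a1", "b1", 200.0, cov=0.25), _edge("b1", "a1", 190.0)]
        assert homology.rbh_orthologs(edges, self.SPECIES, "A", "B") == []

    def test_output_is_partial_matching(self):
        edges, truth = simulate.simulate_similarity_table(
            seed=5, n_a=100, n_b=100, n_pairs=40, decoy_rate=4
        )
        species = {}
        for e in edges:
            for p in (e.query, e.subject):
                species[p] = "Pmu" if p.startswith("Pmu") else "Pms"
        pairs = homology.rbh_orthologs(edges, species, "Pmu", "Pms")
        seen: set[str] = set()
        for a, b in pairs:
            assert a not in seen and b not in seen
            seen |= {a, b}


class TestDivergenceProfile:
    def test_all_identical_hits_step_function(self):
        edges = [_edge(f"q{i}", "s", 100.0, pid=100.0) for i in range(4)]
        prof = homology.divergence_profile(edges)
        assert list(prof["identity"]) == [100.0]
        assert list(prof["cumulative_fraction"]) == [1.0]

    def test_two_level_curve(self):
        edges = [_edge("q1", "s", 100.0, pid=50.0), _edge("q2", "s", 100.0, pid=70.0)]
        prof = homology.divergence_profile(edges)
        assert list(prof["identity"]) == [50.0, 70.0]
        assert list(prof["cumulative_fraction"]) == [0.5, 1.0]

    def test_matches_brute_force(self, rng):
        edges = []
        for q in range(30):
            for _ in range(int(rng.integers(1, 5))):
                edges.append(
                    _edge(
                        f"q{q}", f"s{rng.integers(50)}",
                        float(rng.uniform(50, 300)), pid=float(rng.uniform(20, 100)),
                    )
                )
        prof = homology.divergence_profile(edges)
        brute = {}
        for e in edges:
            cur = brute.get(e.query)
            if cur is None or (e.bitscore, e.percent_identity) > cur:
                brute[e.query] = (e.bitscore, e.percent_identity)
        values = sorted(pid for _, pid in brute.values())
        at = lambda x: sum(v <= x for v in values) / len(values)
        for _, row in prof.iterrows():
            assert row["cumulative_fraction"] == pytest.approx(at(row["identity"]))
        assert prof["cumulative_fraction"].is_monotonic_increasing
        assert prof["cumulative_fraction"].iloc[-1] == 1.0


class TestFisher:
    def test_balanced_table_odds_one(self):
        background = [f"g{i}" for i in range(40)]
        gene_set = background[:20]
        labelled = background[:10] + background[20:30]
        odds, p = homology.set_enrichment_fisher(gene_set, background, labelled)
        assert odds == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        # table [[10,0],[0,10]]: exact two-sided p from hypergeometric enumeration
        background = [f"g{i}" for i in range(20)]
        gene_set = background[:10]
        labelled = background[:10]
        _, p = homology.set_enrichment_fisher(gene_set, background, labelled)
        probs = [
            comb(10, k) * comb(10, 10 - k) / comb(20, 10) for k in range(11)
        ]
        expected = sum(pr for pr in probs if pr <= probs[10] * (1 + 1e-9))
        assert p == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            homology.set_enrichment_fisher([], ["g1"], ["g1"])

    def test_power_on_simulated_enrichment(self, rng):
        detected = 0
        for rep in range(50):
            background = [f"g{i}" for i in range(400)]
            in_set = background[:100]
            labelled = set()
            for g in background:
                p_lab = 0.5 if g in set(in_set) else 0.1  # strong planted odds
                if rng.random() < p_lab:
                    labelled.add(g)
            _, p = homology.set_enrichment_fisher(in_set, background, labelled)
            detected += p < 0.05
        assert detected >= 45
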