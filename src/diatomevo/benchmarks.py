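"""Recovery and equivalence experiments on synthetic data.

Each function runs one planted-truth experiment end to end — generate
inputs, run the analysis, score the result — and returns a flat dict of
metrics. Where an experiment checks an algorithm against an exhaustive
alternative, the brute-force comparator is written here from scratch
(enumeration over the full search space) and shares no code with the
implementation it checks.

Problem sizes are chosen so the whole suite runs in a few minutes on one
CPU; they are stated per function.
"""

from __future__ import annotations

import numpy as np

from . import cne, dollo, hgt, homology, molevo, simulate, trees


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def _brute_force_dollo_events(tree, present) -> int:
    """Minimum event count over every single-gain placement, by exhaustive
    enumeration: a gain node is valid when all present leaves sit below it;
    its loss count is the number of maximal fully-absent subtrees below."""
    present = frozenset(present)
    below = trees.leafsets_below(tree)
    best = None
    for node in tree.preorder_node_iter():
        if not present <= below[node]:
            continue

        def losses(n):
            if not (below[n] & present):
                return 1
            if n.is_leaf():
                return 0
            return sum(losses(c) for c in n.child_nodes())

        events = 1 + (
            sum(losses(c) for c in node.child_nodes()) if not node.is_leaf() else 0
        )
        if best is None or events < best:
            best = events
    return best


def dollo_oracle_equivalence(seed: int, n_trees: int = 200, rows_per_tree: int = 5) -> dict:
    """Reconstruction event counts vs exhaustive minimal single-gain
    enumeration on random rooted trees of up to 10 leaves."""
    rng = np.random.default_rng(seed)
    checked = agree = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, 11))
        tree = trees.random_binary_tree([f"s{i}" for i in range(n)], rng)
        names = trees.leaf_names(tree)
        for _ in range(rows_per_tree):
            k = int(rng.integers(1, n + 1))
            present = set(rng.choice(names, size=k, replace=False))
            rec = dollo.dollo_reconstruct(tree, present)
            checked += 1
            ok = (
                rec.n_events == _brute_force_dollo_events(tree, present)
                and dollo.implied_leaf_states(tree, rec) == frozenset(present)
            )
            agree += ok
    return {"agreement_pct": 100.0 * agree / checked, "n": checked}


def dollo_simulation_recovery(
    seed: int, n_species: int = 8, n_families: int = 500, loss_prob: float = 0.1
) -> dict:
    """Per-edge gain/loss aggregates vs planted truth on an 8-taxon tree.

    Rows whose planted history is not the minimal one (simulation
    homoplasy: losses that mimic a later gain) are flagged ambiguous; the
    aggregate comparison covers the unambiguous rows.
    """
    rng = np.random.default_rng(seed)
    tree = trees.random_binary_tree([f"s{i}" for i in range(n_species)], rng)
    matrix, truths = simulate.simulate_dollo_families(
        tree, n_families, seed=int(rng.integers(2**31)), loss_prob=loss_prob
    )
    recons = dollo.reconstruct_matrix(tree, matrix)
    unambiguous = []
    mismatches = 0
    for rec, truth in zip(recons, truths):
        if rec.gain_edge == truth.gain_edge and rec.n_events == 1 + len(truth.loss_edges):
            unambiguous.append((rec, truth))
            if rec.loss_edges != truth.loss_edges:
                mismatches += 1
    table = dollo.aggregate_events([r for r, _ in unambiguous], tree)
    truth_table = dollo.aggregate_events(
        [
            dollo.DolloReconstruction(t.family_id, t.gain_edge, t.loss_edges, t.presence)
            for _, t in unambiguous
        ],
        tree,
    )
    return {
        "n_families": n_families,
        "n_unambiguous": len(unambiguous),
        "loss_set_mismatches": mismatches,
        "aggregates_match": float(
            table.per_edge.equals(truth_table.per_edge)
            and table.orphans.equals(truth_table.orphans)
        ),
        "unambiguous_match_pct": 100.0 * (len(unambiguous) - mismatches) / max(1, len(unambiguous)),
    }


# ---------------------------------------------------------------------------
# HGT classification
# ---------------------------------------------------------------------------

def hgt_simulation_recovery(seed: int, n_planted: int = 200, n_null: int = 200) -> dict:
    """Recall on planted bacteria→diatom transfers (≥10 bacterial leaves,
    clade supports ≥0.7) and false-positive rate on null trees, at the
    default rule parameters."""
    rng = np.random.default_rng(seed)
    recalled = 0
    for _ in range(n_planted):
        tree, tm, _ = simulate.simulate_gene_tree_with_hgt(
            seed=int(rng.integers(2**31)), planted=True, n_bacteria_in_clade=10
        )
        recalled += hgt.classify_tree(tree, tm, "Pmultistriata").is_candidate
    false_pos = 0
    for _ in range(n_null):
        tree, tm, _ = simulate.simulate_gene_tree_with_hgt(
            seed=int(rng.integers(2**31)), planted=False
        )
        false_pos += hgt.classify_tree(tree, tm, "Pmultistriata").is_candidate
    return {
        "recall": recalled / n_planted,
        "false_positive_rate": false_pos / n_null,
        "n_planted": n_planted,
        "n_null": n_null,
    }


def hgt_threshold_monotonicity(seed: int, n_trees: int = 40) -> dict:
    """Raising any rule threshold must never enlarge the candidate set
    (checked over a 3×3 grid of fraction × donor-minimum)."""
    rng = np.random.default_rng(seed)
    data = [
        simulate.simulate_gene_tree_with_hgt(
            seed=int(rng.integers(2**31)), planted=(i % 2 == 0)
        )
        for i in range(n_trees)
    ]
    grid_f = (0.8, 0.9, 0.95)
    grid_b = (3, 5, 10)
    candidate_sets: dict[tuple[float, int], set[int]] = {}
    for f in grid_f:
        for b in grid_b:
            rule = hgt.RuleParameters(min_target_fraction=f, min_donor=b)
            candidate_sets[(f, b)] = {
                i
                for i, (tree, tm, _) in enumerate(data)
                if hgt.classify_tree(tree, tm, "Pmultistriata", rule=rule).is_candidate
            }
    holds = all(
        candidate_sets[(f2, b2)] <= candidate_sets[(f1, b1)]
        for f1 in grid_f
        for f2 in grid_f
        if f2 >= f1
        for b1 in grid_b
        for b2 in grid_b
        if b2 >= b1
    )
    return {"monotone": float(holds), "n_trees": n_trees}


_GROUP_POOL = [
    "bacteria", "bacteria", "bacteria", "archaea", "diatom",
    "other-stramenopile", "metazoa", "plantae", "fungi", "other-eukaryote",
]


def _random_labelled_gene_tree(rng, max_leaves=12):
    n = int(rng.integers(4, max_leaves + 1))
    groups = ["diatom"] + [
        _GROUP_POOL[i] for i in rng.integers(0, len(_GROUP_POOL), size=n - 1)
    ]
    entries = {f"{g}_{i}": g for i, g in enumerate(groups)}
    tree = trees.random_binary_tree(sorted(entries), rng)
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.support = None if rng.random() < 0.2 else float(rng.uniform(0, 1))
    tree.seed_node.support = None
    from .io import TaxonMap

    return tree, TaxonMap(entries=entries, focal_species="diatom_0"), "diatom_0"


def _brute_force_hgt_verdict(tree, taxon_map, focal, rule, scope="diatom") -> str:
    """Exhaustive evaluation of every focal-containing bipartition side."""
    target = rule.donor_groups | hgt.SCOPE_GROUPS[scope]
    all_leaves = frozenset(trees.leaf_names(tree))
    sup_vals = [
        n.support for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.support is not None
    ]
    tree_mean = float(np.mean(sup_vals)) if sup_vals else None
    sides: dict[frozenset, float | None] = {all_leaves: None}
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
        frac = sum(g in target for g in groups) / len(side)
        forbidden = sum(g in rule.forbidden_groups for g in groups)
        donors = sum(g in rule.donor_groups for g in groups)
        euks = [lf for lf, g in zip(side, groups) if g in hgt.EUKARYOTE_GROUPS]
        sole = bool(euks) and all(lf == focal for lf in euks)
        minimum = rule.min_donor_sole_eukaryote if sole else rule.min_donor
        supported = (sup is not None and sup >= rule.support_cutoff) or (
            tree_mean is not None and tree_mean >= rule.support_cutoff
        )
        if frac >= rule.min_target_fraction and forbidden == 0 and donors >= minimum and supported:
            return "candidate"
    return "rejected"


def hgt_oracle_equivalence(seed: int, n_trees: int = 500) -> dict:
    """Classifier verdicts vs exhaustive bipartition evaluation on random
    gene trees of up to 12 leaves."""
    rng = np.random.default_rng(seed)
    rule = hgt.RuleParameters()
    agree = 0
    for _ in range(n_trees):
        tree, tm, focal = _random_labelled_gene_tree(rng)
        verdict = hgt.classify_tree(tree, tm, focal, rule=rule).verdict
        agree += verdict == _brute_force_hgt_verdict(tree, tm, focal, rule)
    return {"agreement_pct": 100.0 * agree / n_trees, "n": n_trees}


# ---------------------------------------------------------------------------
# CNE scan
# ---------------------------------------------------------------------------

def _brute_force_window_hits(block, genes, window, step, min_identity):
    """Independent per-offset evaluation (gap-free blocks)."""
    ref = block.reference
    out = {}
    for offset in range(0, len(ref.text) - window + 1, step):
        lo, hi = ref.start + offset, ref.start + offset + window
        if any(
            g.interval.seq_id == ref.seq_id and lo < g.interval.end and g.interval.start < hi
            for g in genes.get(ref.species, [])
        ):
            continue
        passing = {}
        for row in block.rows[1:]:
            ident = sum(
                a == b
                for a, b in zip(
                    ref.text[offset : offset + window], row.text[offset : offset + window]
                )
            ) / window
            if ident < min_identity:
                continue
            slo, shi = row.start + offset, row.start + offset + window
            if any(
                g.interval.seq_id == row.seq_id and slo < g.interval.end and g.interval.start < shi
                for g in genes.get(row.species, [])
            ):
                continue
            passing[row.species] = ident
        if passing:
            out[offset] = passing
    return out


def cne_scan_benchmark(seed: int, n_blocks: int = 100) -> dict:
    """Scan-vs-brute-force equality, planted-element recovery within one
    step of the grid-resolved coordinates, and genic-overlap count on 100
    synthetic blocks (plus 20 background-only blocks for false positives)."""
    blocks, genes, truth = simulate.simulate_alignment_with_cnes(
        seed=seed, n_blocks=n_blocks
    )
    hits = cne.scan_windows(blocks, genes)
    by_block: dict[int, dict] = {}
    for h in hits:
        by_block.setdefault(h.block_id, {})[h.ref_offset] = dict(h.species_identity)
    oracle_agree = all(
        by_block.get(b.block_id, {})
        == _brute_force_window_hits(
            b, genes, cne.DEFAULT_WINDOW, cne.DEFAULT_STEP, cne.DEFAULT_MIN_IDENTITY
        )
        for b in blocks
    )
    records = cne.merge_windows(hits, blocks)
    step = cne.DEFAULT_STEP
    recovered = 0
    for planted in truth.planted:
        g0 = (planted.interval.start // step) * step
        g1 = -(-planted.interval.end // step) * step
        recovered += any(
            abs(r.interval.start - g0) <= step and abs(r.interval.end - g1) <= step
            for r in records
        )
    overlaps = sum(
        r.interval.overlaps(g.interval)
        for r in records
        for gene_list in genes.values()
        for g in gene_list
    )
    null_blocks, null_genes, _ = simulate.simulate_alignment_with_cnes(
        seed=seed + 1, n_blocks=20, cne_specs=[[]] * 20, gene_specs=[[(100, 160)]] * 20
    )
    null_records = cne.merge_windows(
        cne.scan_windows(null_blocks, null_genes), null_blocks
    )
    return {
        "oracle_agreement": float(oracle_agree),
        "planted_recovery_pct": 100.0 * recovered / len(truth.planted),
        "n_planted": len(truth.planted),
        "genic_overlaps": overlaps,
        "false_cnes_in_null_blocks": len(null_records),
    }


def tss_test_calibration(
    seed: int, n_null: int = 500, n_power: int = 100, n_controls: int = 200
) -> dict:
    """Type-I error with null elements drawn from the control distribution
    and power with elements planted within 200 bp of transcription starts."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_null):
        genes, elements = simulate.simulate_tss_dataset(
            seed=int(rng.integers(2**31)), n_cnes=30
        )
        res = cne.tss_proximity_test(
            elements, genes, 100_000, n_controls=n_controls,
            seed=int(rng.integers(2**31)),
        )
        rejections += res.p_value < 0.05
    power_hits = 0
    for _ in range(n_power):
        genes, elements = simulate.simulate_tss_dataset(
            seed=int(rng.integers(2**31)), n_cnes=30, max_tss_distance=200
        )
        res = cne.tss_proximity_test(
            elements, genes, 100_000, n_controls=n_controls,
            seed=int(rng.integers(2**31)),
        )
        power_hits += res.p_value < 0.01 and res.direction == "closer"
    return {
        "type_i_error": rejections / n_null,
        "power": power_hits / n_power,
        "n_null": n_null,
        "n_power": n_power,
    }


# ---------------------------------------------------------------------------
# Markov clustering and RBH
# ---------------------------------------------------------------------------

def mcl_planted_partition(
    seed: int, n_seeds: int = 20, n_blocks: int = 5, block_size: int = 20,
    p_intra: float = 0.9, p_inter: float = 0.01,
) -> dict:
    """Adjusted Rand index of MCL (inflation 2.0) against a planted 5-block
    partition, plus the column-stochasticity check after every inflation."""
    import networkx as nx
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    aris = []
    max_col_err = 0.0
    for _ in range(n_seeds):
        g = nx.Graph()
        labels = {}
        for b in range(n_blocks):
            for i in range(block_size):
                node = f"b{b}n{i}"
                g.add_node(node)
                labels[node] = b
        nodes = sorted(g.nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                p = p_intra if labels[nodes[i]] == labels[nodes[j]] else p_inter
                if rng.random() < p:
                    g.add_edge(nodes[i], nodes[j], weight=1.0)
        result = homology.mcl_cluster(g, inflation=2.0, debug=True)
        max_col_err = max(max_col_err, max(result.column_sum_error))
        assignment = {}
        for ci, cluster in enumerate(result.clusters):
            for node in cluster:
                assignment[node] = ci
        aris.append(
            adjusted_rand_score(
                [labels[n] for n in nodes], [assignment[n] for n in nodes]
            )
        )
    return {
        "ari_min": float(min(aris)),
        "ari_mean": float(np.mean(aris)),
        "max_column_sum_error": max_col_err,
        "n_seeds": n_seeds,
    }


def rbh_exact_recovery(
    seed: int, n_seeds: int = 20, n_pairs: int = 300, decoy_rate: float = 5.0,
    low_coverage_fraction: float = 0.1,
) -> dict:
    """Exact recovery of planted reciprocal-best pairs across seeds; pairs
    planted below 30% focal coverage must be filtered out, decoys must
    never produce an extra pair."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_seeds):
        edges, truth = simulate.simulate_similarity_table(
            seed=int(rng.integers(2**31)), n_pairs=n_pairs, decoy_rate=decoy_rate,
            low_coverage_fraction=low_coverage_fraction,
        )
        species_of = {}
        for e in edges:
            for p in (e.query, e.subject):
                species_of[p] = "Pmu" if p.startswith("Pmu") else "Pms"
        pairs = homology.rbh_orthologs(edges, species_of, "Pmu", "Pms")
        expected = sorted(
            (t.protein_a, t.protein_b) for t in truth if t.coverage_a >= 0.30
        )
        exact += pairs == expected
    return {"exact_recovery_pct": 100.0 * exact / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Molecular evolution
# ---------------------------------------------------------------------------

def ng86_omega_recovery(
    seed: int, omegas=(0.2, 1.0, 2.0), n_reps: int = 100,
    n_codons: int = 500, target_ks: float = 0.3,
) -> dict:
    """Median NG86 Ka:Ks against the simulated dN/dS."""
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {"n_reps": n_reps}
    for omega in omegas:
        ratios = []
        for _ in range(n_reps):
            s1, s2, _ = simulate.simulate_codon_pair(
                n_codons, target_ks, omega, seed=int(rng.integers(2**31))
            )
            r = molevo.ng86_kaks(s1, s2)
            if r.ratio is not None:
                ratios.append(r.ratio)
        med = float(np.median(ratios))
        key = format(omega, "g").replace(".", "_")
        out[f"median_ratio_omega_{key}"] = med
        out[f"rel_error_omega_{key}"] = abs(med - omega) / omega
    return out


def k2p_ltr_benchmark(seed: int, n_pairs: int = 50, ltr_length: int = 5000) -> dict:
    """Closed-form agreement of the two-parameter distance on constructed
    (P, Q) grids, exactness of T = K/(2r), and median insertion-age
    recovery on simulated 5 kb sister-LTR pairs of known age."""
    import math

    max_dev = 0.0
    for p10 in range(0, 20, 3):
        for q10 in range(0, 15, 3):
            p, q = p10 / 100.0, q10 / 100.0
            n = 200
            n_ts, n_tv = int(p * n), int(q * n)
            seq1 = "A" * n
            seq2 = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
            r = molevo.k2p_distance(seq1, seq2)
            expected = -0.5 * math.log((1 - 2 * r.p - r.q) * math.sqrt(1 - 2 * r.q))
            max_dev = max(max_dev, abs(r.k - expected))
    age_exact = molevo.ltr_age(0.02, 1e-8).age
    rng = np.random.default_rng(seed)
    true_age, rate = 1e6, 1e-8
    ages = []
    for _ in range(n_pairs):
        s1, s2, _ = simulate.simulate_ltr_pair(
            ltr_length, true_age, rate, seed=int(rng.integers(2**31))
        )
        ages.append(molevo.ltr_age(molevo.k2p_distance(s1, s2), rate).age)
    return {
        "closed_form_max_dev": max_dev,
        "age_formula_dev": abs(age_exact - 1e6),
        "median_age_rel_error": abs(float(np.median(ages)) - true_age) / true_age,
        "n_pairs": n_pairs,
    }


def zscore_benchmark(seed: int, n_matrices: int = 20) -> dict:
    """Expansion Z-scores vs plain-python recomputation on random 50×13
    count matrices, and zero-SD handling."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_matrices):
        counts = pd.DataFrame(
            rng.integers(0, 25, size=(50, 13)), columns=[f"sp{i}" for i in range(13)]
        )
        z = homology.expansion_zscore(counts, "sp0")
        for fam in counts.index:
            row = [float(x) for x in counts.loc[fam]]
            mean = sum(row) / len(row)
            sd = (sum((x - mean) ** 2 for x in row) / len(row)) ** 0.5
            if sd > 0:
                max_dev = max(max_dev, abs(z.loc[fam, "z"] - (row[0] - mean) / sd))
            else:
                assert not z.loc[fam, "defined"]
    flat = pd.DataFrame({"sp0": [4], "sp1": [4], "sp2": [4]})
    z_flat = homology.expansion_zscore(flat, "sp0")
    return {
        "max_abs_dev": max_dev,
        "zero_sd_undefined": float(not z_flat["defined"].iloc[0]),
        "n_matrices": n_matrices,
    }
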