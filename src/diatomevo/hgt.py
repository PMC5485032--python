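"""Horizontal-gene-transfer classification from gene-tree topology.

A gene is called an HGT candidate when its gene tree contains a clade that
is dominated (≥ 90% of leaves by default) by the donor side — bacteria and
archaea — together with the taxonomic scope group (diatoms, or all
stramenopiles, or the SAR supergroup), contains no metazoan, plantae or
fungal leaves, holds a minimum number of bacterial members (5, or 10 when
the focal species is the clade's only eukaryote), and is supported either
at the clade itself or on average over the tree (bootstrap/local support
≥ 0.5). Candidates whose qualifying clade is weakly supported but whose
tree is well supported on average are retained at medium confidence.

Gene trees are treated as unrooted: every bipartition side containing the
focal gene is evaluated as a candidate clade, so no rooting procedure is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .io import TaxonMap
from .trees import leaf_label, subtree_leaves

FORBIDDEN_GROUPS = frozenset({"metazoa", "plantae", "fungi"})
DONOR_GROUPS = frozenset({"bacteria", "archaea"})
EUKARYOTE_GROUPS = frozenset(
    {"diatom", "other-stramenopile", "red-alga", "plantae", "fungi", "metazoa", "other-eukaryote"}
)

#: Taxonomic scope → groups counted on the recipient side of the rule.
#: At SAR scope, eukaryotes outside the named groups ("other-eukaryote")
#: stand in for the alveolate/rhizarian members of the supergroup.
SCOPE_GROUPS: dict[str, frozenset[str]] = {
    "diatom": frozenset({"diatom"}),
    "stramenopile": frozenset({"diatom", "other-stramenopile"}),
    "SAR": frozenset({"diatom", "other-stramenopile", "other-eukaryote"}),
}

_SCOPE_ORDER = ["diatom", "stramenopile", "SAR"]


@dataclass(frozen=True)
class RuleParameters:
    min_target_fraction: float = 0.90
    min_donor: int = 5
    min_donor_sole_eukaryote: int = 10
    support_cutoff: float = 0.5
    donor_groups: frozenset[str] = DONOR_GROUPS
    forbidden_groups: frozenset[str] = FORBIDDEN_GROUPS


#: Analogous rule for genes of red-algal origin. The membership minimum of
#: 2 is an assumption, not a reconstruction: no explicit criteria exist for
#: this classification, so the bacterial-HGT machinery is reused with red
#: algae as the donor group.
RED_ALGAL_RULE = RuleParameters(
    min_donor=2,
    min_donor_sole_eukaryote=2,
    donor_groups=frozenset({"red-alga"}),
)


@dataclass(frozen=True)
class CladeReport:
    tree_id: str
    leaves: frozenset[str]
    composition: dict[str, int]
    target_fraction: float
    forbidden_count: int
    donor_count: int
    eukaryotes: frozenset[str]
    support: float | None
    tree_mean_support: float | None

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class HgtCall:
    gene_id: str
    verdict: str  # "candidate" | "rejected"
    confidence: str | None  # "high" | "medium" | None
    scope: str
    best: CladeReport | None
    qualifying: tuple[CladeReport, ...] = ()

    @property
    def is_candidate(self) -> bool:
        return self.verdict == "candidate"


def tree_mean_support(tree: dendropy.Tree) -> float | None:
    """Mean support over internal edges that carry a support value."""
    values = [
        node.support
        for node in tree.preorder_node_iter()
        if not node.is_leaf() and getattr(node, "support", None) is not None
    ]
    if not values:
        return None
    return float(np.mean(values))


def scan_clades(
    tree: dendropy.Tree,
    taxon_map: TaxonMap,
    focal_gene: str,
    scope: str = "diatom",
    species_of_leaf: Mapping[str, str] | None = None,
    rule: RuleParameters = RuleParameters(),
) -> list[CladeReport]:
    """Evaluate every bipartition side containing the focal gene.

    ``species_of_leaf`` resolves leaf labels to species when labels are not
    species names themselves. Each edge of the (unrooted) tree defines one
    bipartition; the side holding the focal gene is scored for donor-side
    fraction, forbidden members and donor count. The full leaf set is also
    reported (the only clade of a star tree). Reports are sorted by target
    fraction, then size, both descending.
    """
    if scope not in SCOPE_GROUPS:
        raise ValueError(f"unknown scope {scope!r}; expected one of {_SCOPE_ORDER}")
    target_groups = rule.donor_groups | SCOPE_GROUPS[scope]

    def group_of(leaf: str) -> str:
        species = species_of_leaf[leaf] if species_of_leaf else leaf
        try:
            return taxon_map.group(species)
        except KeyError:
            raise ValueError(f"leaf {leaf!r} cannot be resolved to a taxon group") from None

    all_leaves = frozenset(leaf_label(lf) for lf in tree.leaf_node_iter())
    if focal_gene not in all_leaves:
        raise ValueError(f"focal gene {focal_gene!r} is not a leaf of the tree")
    for leaf in all_leaves:
        group_of(leaf)  # fail fast on unresolvable leaves

    mean_support = tree_mean_support(tree)
    tree_id = getattr(tree, "label", None) or ""
    sides: dict[frozenset[str], float | None] = {all_leaves: None}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = subtree_leaves(node)
        side = below if focal_gene in below else all_leaves - below
        if len(side) < 1 or side == all_leaves:
            continue
        support = node.support if not node.is_leaf() else None
        # bipartition support belongs to the edge; keep the best-known value
        if side not in sides or (sides[side] is None and support is not None):
            sides[side] = support

    reports = []
    for side, support in sides.items():
        composition: dict[str, int] = {}
        for leaf in side:
            g = group_of(leaf)
            composition[g] = composition.get(g, 0) + 1
        target = sum(composition.get(g, 0) for g in target_groups)
        forbidden = sum(composition.get(g, 0) for g in rule.forbidden_groups)
        donor = sum(composition.get(g, 0) for g in rule.donor_groups)
        eukaryotes = frozenset(
            leaf for leaf in side if group_of(leaf) in EUKARYOTE_GROUPS
        )
        reports.append(
            CladeReport(
                tree_id=tree_id,
                leaves=side,
                composition=composition,
                target_fraction=target / len(side),
                forbidden_count=forbidden,
                donor_count=donor,
                eukaryotes=eukaryotes,
                support=support,
                tree_mean_support=mean_support,
            )
        )
    reports.sort(key=lambda r: (-r.target_fraction, -r.size, sorted(r.leaves)[0]))
    return reports


def _clade_qualifies(
    report: CladeReport,
    rule: RuleParameters,
    focal_gene: str,
    focal_species_leaves: frozenset[str],
) -> bool:
    if report.target_fraction < rule.min_target_fraction:
        return False
    if report.forbidden_count > 0:
        return False
    sole = report.eukaryotes <= focal_species_leaves and bool(report.eukaryotes)
    minimum = rule.min_donor_sole_eukaryote if sole else rule.min_donor
    if report.donor_count < minimum:
        return False
    supported_at_clade = (
        report.support is not None and report.support >= rule.support_cutoff
    )
    supported_on_average = (
        report.tree_mean_support is not None
        and report.tree_mean_support >= rule.support_cutoff
    )
    return supported_at_clade or supported_on_average


def classify_hgt(
    reports: Sequence[CladeReport],
    focal_gene: str,
    rule: RuleParameters = RuleParameters(),
    scope: str = "diatom",
    focal_species_leaves: Iterable[str] | None = None,
) -> HgtCall:
    """Apply the clade-composition rule to the reports of one tree.

    ``focal_species_leaves`` names the leaves belonging to the focal
    species (defaults to just the focal gene); the stricter donor minimum
    applies when these are the only eukaryotes inside the qualifying clade.
    Confidence is medium when the chosen clade's own support is missing or
    ≤ the cutoff and the call rests on the tree-average support.
    """
    focal_leaves = frozenset(focal_species_leaves or {focal_gene})
    qualifying = tuple(
        r for r in reports if _clade_qualifies(r, rule, focal_gene, focal_leaves)
    )
    if not qualifying:
        return HgtCall(
            gene_id=focal_gene, verdict="rejected", confidence=None, scope=scope,
            best=None,
        )
    # highest target fraction wins; ties go to clades supported at the clade
    # itself (so confidence reflects the strongest evidence), then to size
    best = max(
        qualifying,
        key=lambda r: (
            r.target_fraction,
            r.support is not None and r.support >= rule.support_cutoff,
            r.size,
        ),
    )
    weak_clade = best.support is None or best.support <= rule.support_cutoff
    avg_ok = (
        best.tree_mean_support is not None
        and best.tree_mean_support >= rule.support_cutoff
    )
    confidence = "medium" if (weak_clade and avg_ok) else "high"
    return HgtCall(
        gene_id=focal_gene,
        verdict="candidate",
        confidence=confidence,
        scope=scope,
        best=best,
        qualifying=qualifying,
    )


def classify_tree(
    tree: dendropy.Tree,
    taxon_map: TaxonMap,
    focal_gene: str,
    scope: str = "diatom",
    rule: RuleParameters = RuleParameters(),
    species_of_leaf: Mapping[str, str] | None = None,
) -> HgtCall:
    """Scan and classify one gene tree in a single call."""
    reports = scan_clades(
        tree, taxon_map, focal_gene, scope=scope,
        species_of_leaf=species_of_leaf, rule=rule,
    )
    if species_of_leaf:
        focal_leaves = {
            leaf for leaf, sp in species_of_leaf.items()
            if sp == taxon_map.focal_species
        }
    else:
        focal_leaves = {taxon_map.focal_species}
    return classify_hgt(
        reports, focal_gene, rule=rule, scope=scope,
        focal_species_leaves=focal_leaves,
    )


def red_algal_origin(
    tree: dendropy.Tree,
    taxon_map: TaxonMap,
    focal_gene: str,
    scope: str = "diatom",
    rule: RuleParameters = RED_ALGAL_RULE,
    species_of_leaf: Mapping[str, str] | None = None,
) -> HgtCall:
    """Classify a gene as of red-algal origin: the HGT machinery with red
    algae as the donor group and a lower membership minimum (assumed)."""
    return classify_tree(
        tree, taxon_map, focal_gene, scope=scope, rule=rule,
        species_of_leaf=species_of_leaf,
    )


def classify_lineage_origin(calls: Mapping[str, HgtCall]) -> tuple[str, list[str]]:
    """Combine per-scope calls into one origin label.

    Returns the narrowest qualifying scope (label ``"<scope>-HGT"``) plus
    the list of all qualifying scopes; ``("none", [])`` when no scope
    qualifies.
    """
    qualifying = [s for s in _SCOPE_ORDER if s in calls and calls[s].is_candidate]
    if not qualifying:
        return "none", []
    return f"{qualifying[0]}-HGT", qualifying


# ---------------------------------------------------------------------------
# Supporting feature statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    test: str  # "t" | "mann-whitney"
    statistic: float
    p_value: float
    direction: str  # "A>B" | "A<B" | "none"


_COUNT_FEATURES = {"exon count"}


def feature_compare(
    set_a: Sequence[float],
    set_b: Sequence[float],
    feature: str = "gene length",
) -> FeatureComparison:
    """Compare a gene feature between two gene sets.

    Continuous features (lengths, GC fraction) use Welch's two-sample
    t-test; count features (exon count) use the Mann–Whitney U test.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene sets must be non-empty")
    use_mw = feature in _COUNT_FEATURES
    if use_mw:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
        delta = float(np.median(a) - np.median(b))
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test requires at least two observations per set")
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        test = "t"
        delta = float(a.mean() - b.mean())
        if np.isnan(stat):  # zero variance in both samples
            stat, p = 0.0, 1.0
    direction = "none" if delta == 0 or p == 1.0 else ("A>B" if delta > 0 else "A<B")
    return FeatureComparison(
        feature=feature, test=test, statistic=float(stat), p_value=float(p),
        direction=direction,
    )
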