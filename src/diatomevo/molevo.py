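"""Molecular-evolution statistics.

Implements the Nei–Gojobori (1986) counting estimator of Ka and Ks with
pathway averaging and Jukes–Cantor correction, the Kimura two-parameter
nucleotide distance, and LTR insertion-age dating from sister-LTR
divergence (T = K / 2r).

Conventions: the universal genetic code is assumed throughout; potential
synonymous/nonsynonymous sites are counted per codon position as the
fraction of synonymous changes among the non-stop alternatives at that
position, so S + N equals exactly three sites per codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_table = unambiguous_dna_by_id[1]  # the standard (universal) code
CODON_TABLE: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _syn_fraction(codon: str, position: int) -> float:
    """Fraction of non-stop single-base changes at ``position`` that are
    synonymous."""
    aa = CODON_TABLE[codon]
    syn = total = 0
    for base in "ACGT":
        if base == codon[position]:
            continue
        alt = codon[:position] + base + codon[position + 1 :]
        if alt in STOP_CODONS:
            continue
        total += 1
        if CODON_TABLE[alt] == aa:
            syn += 1
    if total == 0:  # cannot happen with the universal code
        return 0.0
    return syn / total


def count_sites(cds: str) -> tuple[float, float]:
    """Potential synonymous and nonsynonymous sites of one CDS (NG86).

    Returns ``(S, N)`` with ``S + N == len(cds)`` exactly; stop codons are
    not permitted.
    """
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    s_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon at codon index {i // 3}")
        if codon not in CODON_TABLE:
            raise ValueError(f"unrecognized codon {codon!r} at codon index {i // 3}")
        for pos in range(3):
            s_sites += _syn_fraction(codon, pos)
    return s_sites, len(cds) - s_sites


def _pathway_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged with equal weight over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all are used (the standard fallback for stop-bracketed pairs).
    """
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon2:
                valid = False
            if CODON_TABLE.get(nxt, "*") == CODON_TABLE.get(current, "*"):
                sd += 1
            else:
                nd += 1
            current = nxt
        (paths if valid else blocked).append((sd, nd))
    use = paths or blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """Correct a raw proportion of differences for multiple hits; ``None``
    signals saturation (p ≥ 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    ka: float | None
    ks: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def ratio(self) -> float | None:
        """Ka:Ks; ``None`` when Ks is zero or either estimate is saturated."""
        if self.ka is None or self.ks is None or self.ks == 0.0:
            return None
        return self.ka / self.ks


def ng86_kaks(cds1: str, cds2: str, pair_id: str = "") -> KaKsResult:
    """Nei–Gojobori (1986) Ka and Ks for one aligned CDS pair.

    Both sequences must have equal length, a multiple of three, and no
    stop codons; codons containing a gap in either sequence are excluded
    pairwise. Potential sites are averaged over the two sequences;
    observed differences are averaged with equal weight over all minimal
    mutational pathways; the Jukes–Cantor correction maps proportions to
    distances, with saturation (p ≥ 0.75) reported as ``None``.
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned CDS pair has unequal lengths")
    if len(cds1) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    kept1: list[str] = []
    kept2: list[str] = []
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        for name, codon in (("first", c1), ("second", c2)):
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon in {name} sequence at codon index {i // 3}")
        kept1.append(c1)
        kept2.append(c2)
    s1, n1 = count_sites("".join(kept1))
    s2, n2 = count_sites("".join(kept2))
    s_sites, n_sites = (s1 + s2) / 2.0, (n1 + n2) / 2.0
    sd = nd = 0.0
    for c1, c2 in zip(kept1, kept2):
        if c1 != c2:
            psd, pnd = _pathway_counts(c1, c2)
            sd += psd
            nd += pnd
    ks = _jukes_cantor(sd / s_sites) if s_sites > 0 else 0.0
    ka = _jukes_cantor(nd / n_sites) if n_sites > 0 else 0.0
    return KaKsResult(
        pair_id=pair_id,
        ka=ka,
        ks=ks,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        n_codons=len(kept1),
    )


def flag_positive_selection(
    results: Iterable[KaKsResult], threshold: float = 1.0
) -> tuple[list[KaKsResult], list[KaKsResult]]:
    """Split results into (flagged, undefined): flagged pairs have a defined
    ratio strictly above ``threshold``; pairs with Ks = 0 or saturated
    estimates are reported separately, never flagged."""
    flagged: list[KaKsResult] = []
    undefined: list[KaKsResult] = []
    for r in results:
        if r.ratio is None:
            undefined.append(r)
        elif r.ratio > threshold:
            flagged.append(r)
    return flagged, undefined


# ---------------------------------------------------------------------------
# Kimura two-parameter distance and LTR ages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class K2PResult:
    p: float  # transition proportion
    q: float  # transversion proportion
    k: float | None  # corrected distance; None when saturated
    n_sites: int

    @property
    def saturated(self) -> bool:
        return self.k is None


def k2p_distance(seq1: str, seq2: str) -> K2PResult:
    """Kimura two-parameter distance K = −½·ln((1−2P−Q)·√(1−2Q)).

    Sites with a gap or ambiguity code in either sequence are excluded
    from the denominator. A non-positive logarithm argument means the
    sequences are saturated; K is then reported as ``None``.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences have unequal lengths")
    transitions = transversions = valid = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        valid += 1
        if a == b:
            continue
        same_class = (a in _PURINES) == (b in _PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ValueError("no comparable sites")
    p = transitions / valid
    q = transversions / valid
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(p=p, q=q, k=None, n_sites=valid)
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(p=p, q=q, k=k, n_sites=valid)


@dataclass(frozen=True)
class LtrAgeResult:
    element_id: str
    k: float | None
    rate: float
    age: float | None  # years; None when the distance is saturated


def ltr_age(k: float | K2PResult | None, rate: float, element_id: str = "") -> LtrAgeResult:
    """Insertion age of an LTR element from sister-LTR divergence: T = K/(2r).

    ``rate`` is the substitution rate in substitutions/site/year and must
    be supplied explicitly; a saturated distance propagates as a missing
    age.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if isinstance(k, K2PResult):
        k = k.k
    if k is None:
        return LtrAgeResult(element_id=element_id, k=None, rate=rate, age=None)
    if k < 0:
        raise ValueError("distance must be non-negative")
    return LtrAgeResult(element_id=element_id, k=k, rate=rate, age=k / (2.0 * rate))


def age_histogram(
    results: Sequence[LtrAgeResult | float], bin_width: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin insertion ages into ``bin_width``-year bins.

    Returns ``(counts, proportions, edges)``; proportions sum to 1 over the
    datable elements (saturated ones are excluded).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ages = [
        r.age if isinstance(r, LtrAgeResult) else float(r)
        for r in results
        if not (isinstance(r, LtrAgeResult) and r.age is None)
    ]
    if not ages:
        raise ValueError("no datable elements")
    n_bins = max(1, int(math.ceil((max(ages) + 1e-9) / bin_width)))
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(ages, bins=edges)
    proportions = counts / counts.sum()
    return counts, proportions, edges
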