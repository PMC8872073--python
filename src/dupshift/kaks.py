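"""Ka/Ks estimation, ancestral reconstruction and lineage rate tests.

Substitutions are counted with Nei-Gojobori (1986) pathway counting: each
codon position contributes its fraction of synonymous single-nucleotide
changes to the synonymous site count (changes to stop codons count as
nonsynonymous, so La + Ls = 3 per codon), and multi-hit codon pairs are
averaged over all minimal substitution paths with equal weights, excluding
paths through stop codons whenever a stop-free path exists.  Rates are
Jukes-Cantor corrected.

The duplicates' ancestral sequence is reconstructed column-wise by parsimony
on the (original, derived, outgroup) star alignment, with the outgroup
breaking ties.  All comparisons are made in the ORIGINAL copy's reading
frame, including inside frameshifted regions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from Bio import Align
from scipy import stats

from ._codon import CODON_TO_AA, STOP_CODONS, codons_of
from .records import InvalidInputError


@dataclass
class SubstCounts:
    na: float = 0.0  # nonsynonymous differences (fractional)
    ns: float = 0.0  # synonymous differences
    la: float = 0.0  # nonsynonymous sites
    ls: float = 0.0  # synonymous sites
    n_skipped: int = 0  # codon pairs skipped (stop/gap/ambiguity)

    def __iadd__(self, other: "SubstCounts") -> "SubstCounts":
        self.na += other.na
        self.ns += other.ns
        self.la += other.la
        self.ls += other.ls
        self.n_skipped += other.n_skipped
        return self


@dataclass
class RegionKaKs:
    region: str  # common / frameshifted / entire
    lineage: str  # between-copies / ancestor->original / ancestor->derived
    ka: float
    ks: float
    ratio: float | None  # None when Ks = 0
    counts: SubstCounts
    saturated: bool = False
    low_power: bool = False  # region shorter than 10 codons


# ---------------------------------------------------------------------------
# NG86 primitives
# ---------------------------------------------------------------------------

_NTS = "ACGT"


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible changes at ``pos`` that are synonymous.

    Changes creating a stop codon count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for nt in _NTS:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if CODON_TO_AA[alt] == aa and alt not in STOP_CODONS:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, k) for k in range(3))
    return s, 3.0 - s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsyn, syn) differences averaged over minimal substitution paths."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        na = ns = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                ns += 1
            else:
                na += 1
            cur = nxt
        paths.append((through_stop, na, ns))
    usable = [p for p in paths if not p[0]] or paths
    na = sum(p[1] for p in usable) / len(usable)
    ns = sum(p[2] for p in usable) / len(usable)
    return na, ns


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_codon_counts(codons1, codons2) -> SubstCounts:
    """Pathway-counted substitutions and sites for two equal-length codon lists.

    Codon pairs containing a stop codon or a non-ACGT character are skipped
    and tallied in ``n_skipped``.
    """
    if len(codons1) != len(codons2):
        raise InvalidInputError("codon lists must have equal length")
    out = SubstCounts()
    for c1, c2 in zip(codons1, codons2):
        c1, c2 = c1.upper(), c2.upper()
        if (
            len(c1) != 3
            or len(c2) != 3
            or set(c1 + c2) - set(_NTS)
            or c1 in STOP_CODONS
            or c2 in STOP_CODONS
        ):
            out.n_skipped += 1
            continue
        key = (c1, c2)
        hit = _PAIR_CACHE.get(key)
        if hit is None:
            na, ns = _path_counts(c1, c2)
            s1, n1 = codon_sites(c1)
            s2, n2 = codon_sites(c2)
            hit = (na, ns, (s1 + s2) / 2.0, (n1 + n2) / 2.0)
            _PAIR_CACHE[key] = hit
        out.na += hit[0]
        out.ns += hit[1]
        out.ls += hit[2]
        out.la += hit[3]
    return out


def jukes_cantor(p: float) -> float:
    """JC69 distance for proportion ``p``; infinite at saturation (p >= 3/4)."""
    if p < 0:
        raise InvalidInputError("proportion must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_from_counts(
    counts: SubstCounts, region: str = "entire", lineage: str = "between-copies"
) -> RegionKaKs:
    pa = counts.na / counts.la if counts.la > 0 else 0.0
    ps = counts.ns / counts.ls if counts.ls > 0 else 0.0
    ka = jukes_cantor(pa)
    ks = jukes_cantor(ps)
    saturated = math.isinf(ka) or math.isinf(ks)
    ratio = None
    if ks > 0 and not math.isinf(ks) and not math.isinf(ka):
        ratio = ka / ks
    n_codons = (counts.la + counts.ls) / 3.0
    return RegionKaKs(
        region=region,
        lineage=lineage,
        ka=ka,
        ks=ks,
        ratio=ratio,
        counts=counts,
        saturated=saturated,
        low_power=n_codons < 10,
    )


def ka_ks(seq1: str, seq2: str, frame_offset: int = 0) -> RegionKaKs:
    """Pairwise Ka/Ks of two aligned, gap-free sequences in a given frame.

    ``frame_offset`` positions the codon grid (the original copy's frame is
    used even inside frameshifted regions).
    """
    if len(seq1) != len(seq2):
        raise InvalidInputError("sequences must be aligned to equal length")
    s1 = seq1[frame_offset:]
    s2 = seq2[frame_offset:]
    counts = ng86_codon_counts(codons_of(s1), codons_of(s2))
    return kaks_from_counts(counts)


# ---------------------------------------------------------------------------
# Star alignment + ancestral reconstruction
# ---------------------------------------------------------------------------


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -10
    a.extend_gap_score = -1
    a.mode = "global"
    return a


_NT_ALIGNER = _nt_aligner()


def _project(center: str, other: str) -> tuple[list[str], list[str]]:
    """Align ``other`` to ``center``; return per-center-position characters and
    insertions (relative to center) keyed by the center position they precede.
    """
    aln = _NT_ALIGNER.align(center, other)[0]
    rc, ro = str(aln[0]), str(aln[1])
    at = []  # other char aligned to each center position ('-' for deletion)
    inserts = [""] * (len(center) + 1)
    c = 0
    for x, y in zip(rc, ro):
        if x == "-":
            inserts[c] += y
        else:
            at.append(y)
            c += 1
    return at, inserts


@dataclass
class AncestralSeq:
    """Duplicates' ancestor on the 3-way alignment (original copy as center)."""

    original_row: str
    derived_row: str
    outgroup_row: str
    ancestor_row: str
    support: list[str] = field(default_factory=list)  # per-column labels
    original_colmap: dict[int, int] = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return self.ancestor_row.replace("-", "")


def reconstruct_ancestor(
    original_cds: str, derived_cds: str, outgroup_cds: str | None
) -> AncestralSeq:
    """Column-wise parsimony ancestor of the two duplicates.

    Where the duplicates agree the ancestor takes their state; where they
    disagree, the outgroup state if it matches either duplicate; where all
    three differ, the outgroup state.  A gap in exactly one duplicate is
    resolved toward the outgroup (gap or base).
    """
    if outgroup_cds is None:
        raise InvalidInputError("ancestral reconstruction requires an outgroup")
    at_d, ins_d = _project(original_cds, derived_cds)
    at_o, ins_o = _project(original_cds, outgroup_cds)
    rows = {"orig": [], "der": [], "og": []}
    colmap: dict[int, int] = {}
    col = 0
    L = len(original_cds)
    for c in range(L + 1):
        nd, no = len(ins_d[c]), len(ins_o[c])
        for k in range(max(nd, no)):
            rows["orig"].append("-")
            rows["der"].append(ins_d[c][k] if k < nd else "-")
            rows["og"].append(ins_o[c][k] if k < no else "-")
            col += 1
        if c < L:
            rows["orig"].append(original_cds[c])
            rows["der"].append(at_d[c])
            rows["og"].append(at_o[c])
            colmap[c] = col
            col += 1
    anc = []
    support = []
    for x, y, z in zip(rows["orig"], rows["der"], rows["og"]):
        if x == y:
            anc.append(x)
            support.append("unanimous" if z == x else "majority")
        elif z in (x, y):
            anc.append(z)
            support.append("outgroup-tiebreak")
        else:
            anc.append(z)
            support.append("outgroup-tiebreak")
    return AncestralSeq(
        original_row="".join(rows["orig"]),
        derived_row="".join(rows["der"]),
        outgroup_row="".join(rows["og"]),
        ancestor_row="".join(anc),
        support=support,
        original_colmap=colmap,
    )


# ---------------------------------------------------------------------------
# Region x lineage machinery
# ---------------------------------------------------------------------------


def _codon_pairs_in(
    anc: AncestralSeq, intervals, row_a: str, row_b: str
) -> tuple[list[str], list[str]]:
    """Codon pairs (original-frame grid) from rows a and b over original-CDS
    nt intervals; codons with a gap or unknown base in either row are dropped.
    """
    ca, cb = [], []
    for a, b in intervals:
        start = a + (-a) % 3  # first original-frame codon start inside [a, b)
        for x in range(start, b - 2, 3):
            cols = [anc.original_colmap.get(x + k) for k in range(3)]
            if any(c is None for c in cols):
                continue
            c1 = "".join(row_a[c] for c in cols)
            c2 = "".join(row_b[c] for c in cols)
            if set(c1 + c2) - set(_NTS):
                continue
            ca.append(c1)
            cb.append(c2)
    return ca, cb


def region_lineage_kaks(partition, anc: AncestralSeq) -> list[RegionKaKs]:
    """All region x lineage Ka/Ks values for one polarized case.

    Regions are taken on the original copy's coordinates (the frameshifted
    region's counterpart is the original-frame region); every comparison reads
    codons on the original copy's frame.
    """
    common = [tuple(iv) for iv in partition.common_original]
    fshift = [tuple(iv) for iv in partition.original_frame_original]
    entire = [(min(a for a, _ in common + fshift), max(b for _, b in common + fshift))] \
        if common + fshift else []
    rows = {
        "between-copies": (anc.original_row, anc.derived_row),
        "ancestor->original": (anc.ancestor_row, anc.original_row),
        "ancestor->derived": (anc.ancestor_row, anc.derived_row),
    }
    spec = [
        ("common", "between-copies", common),
        ("entire", "ancestor->original", entire),
        ("entire", "ancestor->derived", entire),
        ("frameshifted", "ancestor->original", fshift),
        ("frameshifted", "ancestor->derived", fshift),
        ("common", "ancestor->original", common),
        ("common", "ancestor->derived", common),
    ]
    out = []
    for region, lineage, intervals in spec:
        ra, rb = rows[lineage]
        ca, cb = _codon_pairs_in(anc, intervals, ra, rb)
        counts = ng86_codon_counts(ca, cb)
        out.append(kaks_from_counts(counts, region=region, lineage=lineage))
    return out


def pool_counts(results: list[RegionKaKs], region: str, lineage: str) -> RegionKaKs:
    """Sum Na/Ns/La/Ls across cases before forming rates (pooled mode)."""
    total = SubstCounts()
    for r in results:
        if r.region == region and r.lineage == lineage:
            total += r.counts
    return kaks_from_counts(total, region=region, lineage=lineage)


# ---------------------------------------------------------------------------
# Lineage rate tests
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ratio_equality_test(
    counts_original: SubstCounts, counts_derived: SubstCounts
) -> float:
    """Fisher's exact test (two-sided) of equal Ka/Ks on the two lineages.

    The 2x2 table is lineage x (nonsynonymous, synonymous) with fractional
    pathway counts rounded half-up.
    """
    table = [
        [_round_half_up(counts_original.na), _round_half_up(counts_original.ns)],
        [_round_half_up(counts_derived.na), _round_half_up(counts_derived.ns)],
    ]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def positive_selection_test(counts: SubstCounts) -> float:
    """One-sided binomial test of Na excess over the site-count expectation."""
    na = _round_half_up(counts.na)
    ns = _round_half_up(counts.ns)
    trials = na + ns
    if trials == 0 or counts.la + counts.ls == 0:
        return 1.0
    p0 = counts.la / (counts.la + counts.ls)
    return float(stats.binom.sf(na - 1, trials, p0))
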