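"""Polarization, region partitioning and C/N/M typing of frameshifted pairs.

The canonical alignment direction throughout is: protein of the ORIGINAL copy
(global) mapped onto the CDS of the DERIVED copy (local).  With that
orientation the protein coordinate axis is the original copy and the CDS axis
is the derived copy, so a matched codon sits in the common frame exactly when
its derived-CDS offset is a multiple of 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .fsalign import AlignmentPath, FrameshiftEvent, call_frameshift_events, protein_to_cds_align
from .records import GeneRecord, InvalidInputError, UnresolvedPolarityError


@dataclass
class PolarizedPair:
    original: GeneRecord
    derived: GeneRecord
    outgroup: GeneRecord | None
    polarization_basis: str  # outgroup-frame / shorter-copy-fallback / declared
    events: list[FrameshiftEvent] = field(default_factory=list)


@dataclass
class Region:
    """One maximal run of the alignment in a fixed frame relationship."""

    frameshifted: bool
    derived_nt: tuple[int, int]  # on the derived CDS
    original_nt: tuple[int, int]  # on the original CDS (3 x protein coords)

    @property
    def derived_len_aa(self) -> int:
        return (self.derived_nt[1] - self.derived_nt[0]) // 3

    @property
    def original_len_aa(self) -> int:
        return (self.original_nt[1] - self.original_nt[0]) // 3


@dataclass
class RegionPartition:
    regions: list[Region]
    events: list[FrameshiftEvent] = field(default_factory=list)

    @property
    def common(self) -> list[Region]:
        return [r for r in self.regions if not r.frameshifted]

    @property
    def frameshifted(self) -> list[Region]:
        return [r for r in self.regions if r.frameshifted]

    @property
    def common_derived(self) -> list[tuple[int, int]]:
        return [r.derived_nt for r in self.common]

    @property
    def common_original(self) -> list[tuple[int, int]]:
        return [r.original_nt for r in self.common]

    @property
    def frameshifted_derived(self) -> list[tuple[int, int]]:
        return [r.derived_nt for r in self.frameshifted]

    @property
    def original_frame_original(self) -> list[tuple[int, int]]:
        return [r.original_nt for r in self.frameshifted]


@dataclass
class TypeLabel:
    value: str  # C, N, M or composite like "N&C"
    n_events: int


_POLARITY_ALIGNER = Align.PairwiseAligner()
_POLARITY_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_POLARITY_ALIGNER.open_gap_score = -11
_POLARITY_ALIGNER.extend_gap_score = -1
_POLARITY_ALIGNER.mode = "local"


def polarize_pair(
    a: GeneRecord,
    b: GeneRecord,
    outgroup: GeneRecord | None = None,
    declared: str | None = None,
    score_margin: float = 5.0,
) -> PolarizedPair:
    """Decide which copy is original and which derived.

    With an outgroup, the copy whose frameshift-free protein alignment to the
    outgroup scores higher retains the ancestral reading frame and is the
    original; the margin must exceed ``score_margin`` (half-bits).  Without an
    outgroup the shorter canonical protein is assumed derived.  ``declared``
    ("a" or "b" = the derived copy) overrides both, for curated exceptions.
    """
    if declared is not None:
        der, orig = (a, b) if declared == "a" else (b, a)
        return PolarizedPair(orig, der, outgroup, "declared")
    if outgroup is not None:
        # primary criterion: whose full reading frame matches the outgroup.
        # The derived copy needs frameshift step(s) to align to the outgroup
        # protein; the original aligns without any.  This is far less noisy
        # than a raw score margin, which branch-specific substitutions swamp
        # when the frameshifted region is short.
        po = outgroup.protein
        ev_a = call_frameshift_events(protein_to_cds_align(po, a.cds))
        ev_b = call_frameshift_events(protein_to_cds_align(po, b.cds))
        if len(ev_a) != len(ev_b):
            orig, der = (a, b) if len(ev_a) < len(ev_b) else (b, a)
            return PolarizedPair(orig, der, outgroup, "outgroup-frame")
        sa = float(_POLARITY_ALIGNER.align(a.protein, po).score)
        sb = float(_POLARITY_ALIGNER.align(b.protein, po).score)
        if abs(sa - sb) <= score_margin:
            raise UnresolvedPolarityError(
                f"{a.gene_id}/{b.gene_id}: outgroup scores within margin"
            )
        orig, der = (a, b) if sa > sb else (b, a)
        return PolarizedPair(orig, der, outgroup, "outgroup-frame")
    la, lb = len(a.protein), len(b.protein)
    if la == lb:
        raise UnresolvedPolarityError(
            f"{a.gene_id}/{b.gene_id}: no outgroup and equal lengths"
        )
    orig, der = (a, b) if la > lb else (b, a)
    return PolarizedPair(orig, der, None, "shorter-copy-fallback")


def align_polarized(pair: PolarizedPair) -> AlignmentPath:
    """Canonical alignment: original protein (global) onto derived CDS (local).

    Event positions are refined at nucleotide level against the original CDS.
    """
    path = protein_to_cds_align(pair.original.protein, pair.derived.cds)
    pair.events = call_frameshift_events(
        path, cds=pair.derived.cds, protein_cds=pair.original.cds
    )
    return path


def partition_regions(pair: PolarizedPair, path: AlignmentPath) -> RegionPartition:
    """Frame-tracking walk along the path.

    Runs where the derived CDS is read on its own codon grid (offset divisible
    by 3) are common-frame; all other runs are frameshifted, with their aligned
    counterpart on the original copy as the original-frame region.
    """
    i = path.protein_span[0]
    j = path.cds_span[0]
    runs: list[Region] = []
    cur: Region | None = None
    for st in path.steps:
        if st.kind == "match" or st.kind.startswith("fs"):
            shifted = (j + st.nt) % 3 != 0 if st.kind.startswith("fs") else j % 3 != 0
        else:
            shifted = cur.frameshifted if cur is not None else (j % 3 != 0)
        if cur is None or cur.frameshifted != shifted:
            cur = Region(
                frameshifted=shifted,
                derived_nt=(j, j + st.nt),
                original_nt=(3 * i, 3 * (i + st.aa)),
            )
            runs.append(cur)
        else:
            cur.derived_nt = (cur.derived_nt[0], j + st.nt)
            cur.original_nt = (cur.original_nt[0], 3 * (i + st.aa))
        i += st.aa
        j += st.nt
    if not runs:
        raise InvalidInputError("empty alignment path")
    # tiling check: original-side aa lengths must cover the whole protein
    total_aa = sum(r.original_nt[1] - r.original_nt[0] for r in runs) // 3
    if total_aa != path.protein_span[1] - path.protein_span[0]:
        raise AssertionError("partition does not tile the aligned protein")
    return RegionPartition(regions=runs, events=list(pair.events))


def classify_type(partition: RegionPartition, n_events: int | None = None) -> TypeLabel:
    """C / N / M per the position of each frameshifted region; composites with '&'.

    A frameshifted region that is last in the partition runs to the derived
    stop (type C); one that is first starts at the derived start codon (type
    N); strictly internal regions are type M.
    """
    regions = partition.regions
    comps: list[str] = []
    for k, r in enumerate(regions):
        if not r.frameshifted:
            continue
        if k == len(regions) - 1:
            comps.append("C" if k > 0 else "C")
        elif k == 0:
            comps.append("N")
        else:
            comps.append("M")
    n_ev = n_events if n_events is not None else len(partition.events)
    return TypeLabel(value="&".join(comps), n_events=n_ev)


def relative_location(
    partition: RegionPartition, polarized: PolarizedPair
) -> float:
    """First event's position projected on the original copy, rescaled to (0,1)."""
    if not partition.events:
        raise InvalidInputError("no events to locate")
    ev = min(partition.events, key=lambda e: e.protein_position)
    frac = 3 * ev.protein_position / len(polarized.original.cds)
    return min(max(frac, 0.0), 1.0)


def case_lengths(
    partition: RegionPartition, polarized: PolarizedPair
) -> tuple[int, int, int, int]:
    """(fs_len_aa, of_len_aa, derived_len_aa, original_len_aa), stop excluded."""
    fs = sum(r.derived_len_aa for r in partition.frameshifted)
    of = sum(r.original_len_aa for r in partition.frameshifted)
    return fs, of, len(polarized.derived.protein), len(polarized.original.protein)


def region_length_stats(cases, normalization: str = "original"):
    """Per-type means of relative frameshifted / original-frame region lengths.

    ``cases`` is an iterable of mappings with keys ``type``, ``fs_len_aa``,
    ``of_len_aa``, ``original_len_aa`` and ``derived_len_aa``.  Relative
    lengths are normalized by the original-copy protein length by default
    (``normalization="derived"`` uses the derived copy instead).  Types with
    no cases are absent from the result.
    """
    if normalization not in ("original", "derived"):
        raise InvalidInputError("normalization must be 'original' or 'derived'")
    denom_key = "original_len_aa" if normalization == "original" else "derived_len_aa"
    acc: dict[str, list[tuple[float, float]]] = {}
    for c in cases:
        denom = c[denom_key]
        if denom <= 0:
            continue
        acc.setdefault(c["type"], []).append(
            (c["fs_len_aa"] / denom, c["of_len_aa"] / denom)
        )
    return {
        t: {
            "n": len(v),
            "mean_fs": sum(x for x, _ in v) / len(v),
            "mean_of": sum(y for _, y in v) / len(v),
        }
        for t, v in acc.items()
    }
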