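"""Duplicate-pair discovery by translated local similarity.

All 3x3 reading-frame pairs of the canonical transcripts are compared by
Smith-Waterman over BLOSUM62; candidate pairs must clear identity, overlap and
raw-score thresholds.  A transcript-consistency filter then requires every
transcript-vs-transcript comparison of a candidate pair to report the same
frameshift events, which removes frameshifts introduced by alternative
transcripts rather than by mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import translate
from .fsalign import call_frameshift_events, protein_to_cds_align
from .records import GeneRecord, InvalidInputError

translate_frame = translate  # re-export under the module's operation name


@dataclass
class HSPCandidate:
    gene_id_a: str
    gene_id_b: str
    best_frame_a: int
    best_frame_b: int
    aligned_cols: int
    identity: float
    overlap: float
    score: float


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    a.mode = "local"
    return a


_ALIGNER = _protein_aligner()


def _align_stats(pa: str, pb: str):
    """(aligned_cols, identity, score, blocks) of the best local alignment."""
    alns = _ALIGNER.align(pa, pb)
    best = alns[0]
    cols = 0
    ident = 0
    blocks = tuple(tuple(map(tuple, side)) for side in best.aligned)
    for (a0, a1), (b0, b1) in zip(*blocks):
        cols += a1 - a0
        ident += sum(1 for x, y in zip(pa[a0:a1], pb[b0:b1]) if x == y)
    identity = ident / cols if cols else 0.0
    return cols, identity, float(alns.score), blocks


def translated_pair_score(a: GeneRecord, b: GeneRecord) -> HSPCandidate:
    """Best frame pair over all 3x3 translated Smith-Waterman comparisons.

    Identity, score and frames come from the single best local alignment.  A
    frameshifted pair aligns its common and shifted segments in *different*
    frame pairs, so overlap is the union coverage of the shorter copy by all
    frame-pair alignments scoring at least half the best score, in the spirit
    of multi-HSP reporting.
    """
    entries = []
    shorter_is_a = len(a.cds) <= len(b.cds)
    for fa in range(3):
        pa = translate(a.cds, fa)
        if not pa:
            continue
        for fb in range(3):
            pb = translate(b.cds, fb)
            if not pb:
                continue
            cols, identity, score, blocks = _align_stats(pa, pb)
            if cols == 0:
                continue
            side, frame = (0, fa) if shorter_is_a else (1, fb)
            nt_iv = [(frame + 3 * s, frame + 3 * e) for s, e in blocks[side]]
            entries.append((score, fa, fb, cols, identity, nt_iv))
    if not entries:
        raise InvalidInputError(
            f"empty translation for pair {a.gene_id}/{b.gene_id}"
        )
    best = max(entries, key=lambda e: e[0])
    # coverage pools every frame-pair HSP that is clearly non-noise; a short
    # shifted segment of a mostly-common pair must still count toward overlap
    floor = min(best[0] / 2.0, 25.0)
    ivs = sorted(
        iv for entry in entries if entry[0] >= floor for iv in entry[5]
    )
    covered, end = 0, -1
    for s, e in ivs:
        s = max(s, end)
        if e > s:
            covered += e - s
        end = max(end, e)
    shorter_nt = min(len(a.cds), len(b.cds))
    overlap = min(1.0, covered / (3 * (shorter_nt // 3)))
    return HSPCandidate(
        gene_id_a=a.gene_id,
        gene_id_b=b.gene_id,
        best_frame_a=best[1],
        best_frame_b=best[2],
        aligned_cols=best[3],
        identity=best[4],
        overlap=overlap,
        score=best[0],
    )


def _frame_kmers(g: GeneRecord, k: int = 5) -> set[str]:
    """Amino-acid k-mers of all three frame translations (stop-free ones)."""
    out: set[str] = set()
    for f in range(3):
        p = translate(g.cds, f)
        for s in range(len(p) - k + 1):
            w = p[s : s + k]
            if "*" not in w:
                out.add(w)
    return out


def find_duplicate_pairs(
    genes: Iterable[GeneRecord],
    min_identity: float = 0.70,
    min_overlap: float = 0.70,
    min_score: float = 50.0,
    prefilter: bool = True,
    seed_kmers_min: int = 3,
) -> list[HSPCandidate]:
    """All same-species unordered pairs clearing the three thresholds.

    Pairs are reported once, in lexicographic gene-id order.  With
    ``prefilter`` (the default) only pairs sharing at least
    ``seed_kmers_min`` translated 5-mers (over all three frames) are scored
    by full Smith-Waterman - the usual seed-and-extend shortcut, which leaves
    the reported set unchanged for any pair that could clear a 70% identity
    filter.
    """
    gs = sorted(genes, key=lambda g: g.gene_id)
    kmers = [_frame_kmers(g) for g in gs] if prefilter else None
    out: list[HSPCandidate] = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            if gs[i].species != gs[j].species:
                continue
            if kmers is not None and len(kmers[i] & kmers[j]) < seed_kmers_min:
                continue
            cand = translated_pair_score(gs[i], gs[j])
            if (
                cand.identity >= min_identity
                and cand.overlap >= min_overlap
                and cand.score >= min_score
            ):
                out.append(cand)
    return out


def _default_event_caller(protein: str, cds: str):
    path = protein_to_cds_align(protein, cds)
    return call_frameshift_events(path)


def transcript_consistency_filter(
    pair: HSPCandidate,
    genes: dict[str, GeneRecord],
    detector: Callable[[str, str], list] | None = None,
    pos_tol_aa: int = 2,
) -> bool:
    """True iff all transcript-vs-transcript comparisons agree on the events.

    Events are compared as multisets of (phase, approximate aa position), with
    positions allowed to differ by ``pos_tol_aa`` (DP placement of an indel
    within a repeat run is ambiguous).
    """
    if detector is None:
        detector = _default_event_caller
    ga = genes[pair.gene_id_a]
    gb = genes[pair.gene_id_b]
    if not ga.transcripts or not gb.transcripts:
        raise InvalidInputError("gene with zero transcripts")

    def protein_of(cds: str) -> str:
        aa = translate(cds)
        return aa[:-1] if aa.endswith("*") else aa

    reference = None
    for ta in ga.transcripts:
        pa = protein_of(ta)
        for tb in gb.transcripts:
            events = detector(pa, tb)
            sig = sorted((e.phase, e.cds_position // 3) for e in events)
            if reference is None:
                reference = sig
                continue
            if len(sig) != len(reference):
                return False
            for (ph1, pos1), (ph2, pos2) in zip(sig, reference):
                if ph1 != ph2 or abs(pos1 - pos2) > pos_tol_aa:
                    return False
    return True
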