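"""Frameshift-aware protein-to-CDS alignment.

Aligns the protein of one duplicate to the CDS of the other with a dynamic
program whose step set includes frameshift transitions: a protein residue may
consume 1, 2, 4 or 5 nucleotides instead of a codon's 3, at a fixed penalty.
The alignment is global in the protein and local in the CDS, so a derived copy
with a novel terminus (e.g. a new upstream start) does not pay terminal gap
costs on the CDS side.

Coordinates are 0-based, half-open.  Event sizes are signed relative to the
CDS being aligned to: a nucleotide insertion in that CDS is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from ._codon import BLOSUM62, CODON_AA_IDX, encode_nt, encode_protein
from .records import DegenerateAlignmentError, InvalidInputError

_NEG = np.int64(-(1 << 40))
_FS_SIZES = (1, 2, 4, 5)


def _build_fs_emit_tables() -> tuple[np.ndarray, ...]:
    """Emission tables for frameshift steps.

    A frameshift step consuming k nucleotides for one protein residue is
    scored against the best codon *consistent* with those nucleotides:
    for insertions (k = 4, 5) the codon is obtained by deleting the inserted
    run (any contiguous k-3 nucleotides); for deletions (k = 1, 2) by
    restoring the deleted bases (any contiguous 3-k bases at any position).
    Windows are indexed base-4 (A=0 C=1 G=2 T=3).
    """
    n_aa = BLOSUM62.shape[0]

    def best(aa_idx: int, codons: list[tuple[int, int, int]]) -> int:
        return max(
            BLOSUM62[aa_idx, CODON_AA_IDX[16 * a + 4 * b + c]] for a, b, c in codons
        )

    e1 = np.zeros((n_aa, 4), dtype=np.int64)
    e2 = np.zeros((n_aa, 16), dtype=np.int64)
    e4 = np.zeros((n_aa, 256), dtype=np.int64)
    e5 = np.zeros((n_aa, 1024), dtype=np.int64)
    for aa in range(n_aa):
        for n1 in range(4):
            # 2-nt deletion: the surviving base sat first or last in its codon
            cands = [(n1, x, y) for x in range(4) for y in range(4)]
            cands += [(x, y, n1) for x in range(4) for y in range(4)]
            e1[aa, n1] = best(aa, cands)
        for n1 in range(4):
            for n2 in range(4):
                cands = [(x, n1, n2) for x in range(4)]
                cands += [(n1, x, n2) for x in range(4)]
                cands += [(n1, n2, x) for x in range(4)]
                e2[aa, 4 * n1 + n2] = best(aa, cands)
        for w in range(256):
            nts = [(w >> s) & 3 for s in (6, 4, 2, 0)]
            cands = [tuple(nts[:i] + nts[i + 1 :]) for i in range(4)]
            e4[aa, w] = best(aa, cands)
        for w in range(1024):
            nts = [(w >> s) & 3 for s in (8, 6, 4, 2, 0)]
            cands = [tuple(nts[:i] + nts[i + 2 :]) for i in range(4)]
            e5[aa, w] = best(aa, cands)
    return e1, e2, e4, e5


_FS_EMIT_1, _FS_EMIT_2, _FS_EMIT_4, _FS_EMIT_5 = _build_fs_emit_tables()


@dataclass(frozen=True)
class FsScoring:
    """Scoring for the frameshift-aware DP, in BLOSUM62 half-bit units.

    ``gap_open`` is charged for the first position of a gap and ``gap_extend``
    for each further position.  ``frameshift_penalty`` is charged once per
    frameshift step, on top of the substitution score of the best codon
    consistent with the consumed nucleotides (see ``_build_fs_emit_tables``),
    which anchors the step at the true indel junction.
    """

    gap_open: int = -11
    gap_extend: int = -1
    frameshift_penalty: int = -15


class Step(NamedTuple):
    kind: str  # "match", "ins" (aa insertion), "del" (codon deletion), "fs1/2/4/5"
    aa: int  # aa consumed, 0 or 1
    nt: int  # nt consumed, 0..5


@dataclass
class AlignmentPath:
    steps: list[Step]
    score: int
    protein_span: tuple[int, int]  # always (0, len(protein)): global in protein
    cds_span: tuple[int, int]

    def check_conservation(self) -> None:
        nt = sum(s.nt for s in self.steps)
        aa = sum(s.aa for s in self.steps)
        if nt != self.cds_span[1] - self.cds_span[0]:
            raise AssertionError("nt consumed does not match cds span")
        if aa != self.protein_span[1] - self.protein_span[0]:
            raise AssertionError("aa consumed does not match protein span")


@dataclass
class FrameshiftEvent:
    """A point where the running reading frame of the aligned CDS changes.

    ``cds_position`` approximates the first nucleotide read in the new frame
    (on the aligned CDS); ``protein_position`` is the aa index on the aligned
    protein at the event.  ``size`` is the net indel size after merging,
    ``phase = size mod 3`` is in {1, 2}.
    """

    cds_position: int
    size: int
    phase: int
    protein_position: int


@njit(cache=True)
def _fill(prot, cds, sub, codon_aa, go, ge, fp, e1, e2, e4, e5):  # pragma: no cover - numba
    m = prot.shape[0]
    n = cds.shape[0]
    NEG = _NEG
    M = np.full((m + 1, n + 1), NEG, np.int64)
    X = np.full((m + 1, n + 1), NEG, np.int64)
    Y = np.full((m + 1, n + 1), NEG, np.int64)
    PM = np.zeros((m + 1, n + 1), np.uint8)
    PX = np.zeros((m + 1, n + 1), np.uint8)
    PY = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0  # local in CDS: free start at any offset
    for i in range(1, m + 1):
        a = prot[i - 1]
        for j in range(n + 1):
            # X: protein residue unaligned (gap in CDS)
            bx = M[i - 1, j] + go
            px = 1
            t = X[i - 1, j] + ge
            if t > bx:
                bx = t
                px = 2
            X[i, j] = bx
            PX[i, j] = px
            # M: codon match or frameshift step ending here
            bm = NEG
            pm = 0
            if j >= 3:
                ci = (cds[j - 3] << 4) | (cds[j - 2] << 2) | cds[j - 1]
                e = sub[a, codon_aa[ci]]
                v = M[i - 1, j - 3] + e
                if v > bm:
                    bm = v
                    pm = 1
                v = Y[i - 1, j - 3] + e
                if v > bm:
                    bm = v
                    pm = 2
                v = X[i - 1, j - 3] + e
                if v > bm:
                    bm = v
                    pm = 3
            for ki in range(4):
                k = 1
                if ki == 1:
                    k = 2
                elif ki == 2:
                    k = 4
                elif ki == 3:
                    k = 5
                if j >= k:
                    if k == 1:
                        emit = fp + e1[a, cds[j - 1]]
                    elif k == 2:
                        emit = fp + e2[a, 4 * cds[j - 2] + cds[j - 1]]
                    elif k == 4:
                        w4 = (
                            (cds[j - 4] << 6)
                            | (cds[j - 3] << 4)
                            | (cds[j - 2] << 2)
                            | cds[j - 1]
                        )
                        emit = fp + e4[a, w4]
                    else:
                        w5 = (
                            (cds[j - 5] << 8)
                            | (cds[j - 4] << 6)
                            | (cds[j - 3] << 4)
                            | (cds[j - 2] << 2)
                            | cds[j - 1]
                        )
                        emit = fp + e5[a, w5]
                    v = M[i - 1, j - k] + emit
                    if v > bm:
                        bm = v
                        pm = 4 + ki * 3
                    v = Y[i - 1, j - k] + emit
                    if v > bm:
                        bm = v
                        pm = 4 + ki * 3 + 1
                    v = X[i - 1, j - k] + emit
                    if v > bm:
                        bm = v
                        pm = 4 + ki * 3 + 2
            M[i, j] = bm
            PM[i, j] = pm
            # Y: codon deleted from the protein (3 nt, no aa)
            if j >= 3:
                by = M[i, j - 3] + go
                py = 1
                t = Y[i, j - 3] + ge
                if t > by:
                    by = t
                    py = 2
                Y[i, j] = by
                PY[i, j] = py
    return M, X, Y, PM, PX, PY


_ST_M, _ST_X, _ST_Y = 0, 1, 2
_STATES = (_ST_M, _ST_Y, _ST_X)  # decode order for "from" codes


def protein_to_cds_align(
    protein: str, cds: str, scoring: FsScoring | None = None
) -> AlignmentPath:
    """Best frameshift-aware alignment of ``protein`` (global) onto ``cds`` (local).

    Traceback ties are broken preferring match > codon deletion > aa insertion
    > frameshift, which places indels at their 5'-most equivalent position.
    """
    if scoring is None:
        scoring = FsScoring()
    if len(protein) < 2:
        raise InvalidInputError("protein must be at least 2 aa")
    if len(cds) < 6:
        raise InvalidInputError("cds must be at least 6 nt")
    p = encode_protein(protein)
    c = encode_nt(cds)
    M, X, Y, PM, PX, PY = _fill(
        p,
        c,
        BLOSUM62,
        CODON_AA_IDX,
        np.int64(scoring.gap_open),
        np.int64(scoring.gap_extend),
        np.int64(scoring.frameshift_penalty),
        _FS_EMIT_1,
        _FS_EMIT_2,
        _FS_EMIT_4,
        _FS_EMIT_5,
    )
    m, n = len(p), len(c)
    # final cell: max over CDS end positions; prefer M over X, leftmost j on ties
    best = _NEG
    jend, state = 0, _ST_M
    for j in range(n + 1):
        if M[m, j] > best:
            best = M[m, j]
            jend, state = j, _ST_M
        if X[m, j] > best:
            best = X[m, j]
            jend, state = j, _ST_X
    steps: list[Step] = []
    i, j = m, jend
    while not (i == 0 and state == _ST_M):
        if state == _ST_M:
            code = PM[i, j]
            if code == 0:
                raise DegenerateAlignmentError("traceback hit an unreachable cell")
            if code <= 3:
                steps.append(Step("match", 1, 3))
                state = _STATES[code - 1]
                i -= 1
                j -= 3
            else:
                ki, s = divmod(code - 4, 3)
                k = _FS_SIZES[ki]
                steps.append(Step(f"fs{k}", 1, k))
                state = _STATES[s]
                i -= 1
                j -= k
        elif state == _ST_X:
            code = PX[i, j]
            steps.append(Step("ins", 1, 0))
            state = _ST_M if code == 1 else _ST_X
            i -= 1
        else:
            code = PY[i, j]
            steps.append(Step("del", 0, 3))
            state = _ST_M if code == 1 else _ST_Y
            j -= 3
    steps.reverse()
    path = AlignmentPath(
        steps=steps, score=int(best), protein_span=(0, m), cds_span=(j, jend)
    )
    if jend == j:
        raise DegenerateAlignmentError("alignment consumes no CDS nucleotides")
    path.check_conservation()
    return path


def call_frameshift_events(
    path: AlignmentPath,
    merge_window_nt: int = 6,
    cds: str | None = None,
    protein_cds: str | None = None,
) -> list[FrameshiftEvent]:
    """Merge adjacent frameshift/gap steps into net indel events.

    Gap and frameshift steps whose CDS footprints lie within ``merge_window_nt``
    (two codons) of each other are pooled; a pooled event whose net size is a
    multiple of 3 is an in-frame indel, not a frameshift, and is discarded.

    When both ``cds`` (the aligned CDS) and ``protein_cds`` (the nucleotide
    sequence underlying the aligned protein) are given, each event position is
    refined at nucleotide level: codon-level scoring leaves the junction
    ambiguous up to wobble-equivalent codons, whereas direct base agreement of
    the two flanks pins it down (see :func:`_refine_position`).
    """
    # atoms: (start_nt, end_nt, size, aa_start, aa_end)
    atoms: list[tuple[int, int, int, int, int]] = []
    i = path.protein_span[0]
    j = path.cds_span[0]
    for st in path.steps:
        if st.kind.startswith("fs"):
            atoms.append((j, j + st.nt, st.nt - 3, i, i + 1))
        elif st.kind == "ins":
            atoms.append((j, j, -3, i, i + 1))
        elif st.kind == "del":
            atoms.append((j, j + 3, 3, i, i))
        i += st.aa
        j += st.nt
    events: list[FrameshiftEvent] = []
    k = 0
    while k < len(atoms):
        start, end, size, aa0, aa = atoms[k]
        k += 1
        while k < len(atoms) and atoms[k][0] - end <= merge_window_nt:
            end = max(end, atoms[k][1])
            size += atoms[k][2]
            aa = atoms[k][4]
            k += 1
        if size % 3 != 0:
            pos = max(path.cds_span[0], end - 2)
            if cds is not None and protein_cds is not None:
                u_before = 3 * aa0 - start
                pos = _refine_position(cds, protein_cds, pos, size, u_before)
            events.append(
                FrameshiftEvent(
                    cds_position=pos, size=size, phase=size % 3, protein_position=aa
                )
            )
    events.sort(key=lambda e: e.cds_position)
    return events


def _refine_position(
    cds: str,
    protein_cds: str,
    pos: int,
    size: int,
    u_before: int,
    window: int = 12,
    flank: int = 15,
) -> int:
    """Re-locate an event's changepoint by direct nucleotide agreement.

    Upstream of the junction ``c`` the aligned CDS maps to the protein's CDS
    with offset ``u_before``; downstream with ``u_before - size`` (skipping
    inserted bases when ``size > 0``).  Score-maximal changepoints often form
    an interval (repeats and chance base coincidences make neighbouring
    placements equivalent); the true junction always belongs to it, so the
    median of the tie set minimizes the worst-case placement error.
    """
    ins = max(size, 0)
    lo = max(0, pos - window)
    hi = min(len(cds) - ins, pos + window) + 1
    scored: list[tuple[int, int]] = []
    for c in range(lo, hi):
        sc = 0
        for x in range(max(0, c - flank), c):
            o = x + u_before
            if 0 <= o < len(protein_cds) and cds[x] == protein_cds[o]:
                sc += 1
        for x in range(c + ins, min(len(cds), c + ins + flank)):
            o = x + u_before - size
            if 0 <= o < len(protein_cds) and cds[x] == protein_cds[o]:
                sc += 1
        scored.append((sc, c))
    if not scored:
        return pos
    best = max(sc for sc, _ in scored)
    ties = [c for sc, c in scored if sc == best]
    return ties[len(ties) // 2]
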