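"""Independent reference implementations used as test oracles.

These deliberately re-derive the scoring/counting models from scratch
(plain Python, string-based) rather than reusing package internals.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_BL = substitution_matrices.load("BLOSUM62")
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA_OF = dict(_TABLE.forward_table)
for _s in _TABLE.stop_codons:
    _AA_OF[_s] = "*"
_NTS = "ACGT"


def blosum(a: str, b: str) -> int:
    return int(_BL[a, b])


def fs_emission(aa: str, window: str) -> int:
    """Best codon consistent with the consumed nucleotides, scored vs ``aa``."""
    k = len(window)
    cands: set[str] = set()
    if k == 1:
        for x in _NTS:
            for y in _NTS:
                cands.add(window + x + y)
                cands.add(x + y + window)
    elif k == 2:
        for x in _NTS:
            cands.add(x + window)
            cands.add(window[0] + x + window[1])
            cands.add(window + x)
    elif k == 4:
        for i in range(4):
            cands.add(window[:i] + window[i + 1 :])
    elif k == 5:
        for i in range(4):
            cands.add(window[:i] + window[i + 2 :])
    return max(blosum(aa, _AA_OF[c]) for c in cands)


def oracle_align_score(
    protein: str,
    cds: str,
    gap_open: int = -11,
    gap_extend: int = -1,
    fs_penalty: int = -15,
) -> int:
    """Exact maximum over all alignment paths, computed top-down.

    Global in the protein, local in the CDS; states M (match/frameshift end),
    X (protein residue unaligned), Y (codon deleted).
    """
    m, n = len(protein), len(cds)
    NEG = -(10**9)

    @lru_cache(maxsize=None)
    def end_at(i: int, j: int, st: str) -> int:
        if st == "M":
            if i == 0:
                return 0
            best = NEG
            aa = protein[i - 1]
            if j >= 3:
                e = blosum(aa, _AA_OF[cds[j - 3 : j]])
                for ps in ("M", "Y", "X"):
                    v = end_at(i - 1, j - 3, ps)
                    if v + e > best:
                        best = v + e
            for k in (1, 2, 4, 5):
                if j >= k:
                    e = fs_penalty + fs_emission(aa, cds[j - k : j])
                    for ps in ("M", "Y", "X"):
                        v = end_at(i - 1, j - k, ps)
                        if v + e > best:
                            best = v + e
            return best
        if st == "X":
            if i == 0:
                return NEG
            return max(
                end_at(i - 1, j, "M") + gap_open,
                end_at(i - 1, j, "X") + gap_extend,
            )
        # Y
        if j < 3 or i == 0:
            return NEG
        return max(
            end_at(i, j - 3, "M") + gap_open,
            end_at(i, j - 3, "Y") + gap_extend,
        )

    best = NEG
    for j in range(n + 1):
        for st in ("M", "X"):
            v = end_at(m, j, st)
            if v > best:
                best = v
    end_at.cache_clear()
    return best


def oracle_ng86_pair(c1: str, c2: str):
    """(na, ns) averaged over minimal substitution paths, stop paths excluded
    when avoidable; recursive formulation (independent of the package's
    permutation-based counting)."""

    def walk(cur: str, target: str):
        # returns list of (na, ns, hit_stop) over all orders of remaining fixes
        diffs = [k for k in range(3) if cur[k] != target[k]]
        if not diffs:
            return [(0, 0, False)]
        out = []
        for k in diffs:
            nxt = cur[:k] + target[k] + cur[k + 1 :]
            step_stop = nxt in _STOPS
            step_na = 0 if _AA_OF[cur] == _AA_OF[nxt] else 1
            for na, ns, hs in walk(nxt, target):
                out.append((na + step_na, ns + (1 - step_na), hs or step_stop))
        return out

    paths = walk(c1, c2)
    ok = [p for p in paths if not p[2]] or paths
    na = sum(p[0] for p in ok) / len(ok)
    ns = sum(p[1] for p in ok) / len(ok)
    return na, ns


def oracle_codon_sites(codon: str):
    """(syn, nonsyn) site fractions by explicit neighbor enumeration."""
    syn = 0.0
    for pos, nt_obs in enumerate(codon):
        for nt in _NTS:
            if nt == nt_obs:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in _STOPS and _AA_OF[alt] == _AA_OF[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def exact_sign_test_p(diffs) -> float:
    """P(mean of +-diffs <= observed mean) by full 2^n enumeration."""
    n = len(diffs)
    obs = sum(diffs) / n
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        if sum(s * d for s, d in zip(signs, diffs)) / n <= obs + 1e-12:
            hits += 1
    return hits / 2**n


def sense_codons():
    return [
        a + b + c
        for a in _NTS
        for b in _NTS
        for c in _NTS
        if a + b + c not in _STOPS
    ]


def random_cds_from_protein(protein: str, rng) -> str:
    """Reverse-translate with uniformly chosen synonymous codons."""
    by_aa: dict[str, list[str]] = {}
    for cod in sense_codons():
        by_aa.setdefault(_AA_OF[cod], []).append(cod)
    return "".join(
        by_aa[aa][rng.integers(0, len(by_aa[aa]))] for aa in protein
    )
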