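"""Synthetic duplicate-gene generator with controlled frameshift scenarios.

Each simulated pair descends from a random ancestor CDS: an outgroup branch
diverges for ``t_pre`` expected substitutions/site, and two post-duplication
branches each diverge for ``t_post``.  One duplicate (the derived copy)
additionally receives a frameshift scenario:

* type C  - an indel of size not divisible by 3 shifts the frame from the
  indel to a premature stop in the new frame (possibly inside the 3' flank);
* type N  - an indel near the 5' end plus a new upstream ATG create an ORF
  that reads through the indel back into the original frame;
* type M  - two compensating indels bracket an internally frameshifted region;
* multi-C - two non-compensating indels, frame still shifted at the terminus.

The generator is fully deterministic given a :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._codon import NT_ALPHABET, STOP_CODONS, codons_of, is_valid_cds, translate
from .records import (
    GeneRecord,
    InvalidConfigError,
    ScenarioDegenerateError,
)

#: 12-mer carrying a stop codon in all three reading frames; prepended to the
#: 3' flank so that any shifted ORF is guaranteed to terminate.
_TRIPLE_STOP = "TTAATTAATTAA"

# frameshifted regions shorter than this are rejected and redrawn: a handful
# of shifted codons cannot outweigh a frameshift penalty in any aligner, and
# observed frameshifted regions in real surveys are longer (>= 9 aa)
_MIN_FS_AA = 8


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic survey.

    Defaults emulate the observed survey: ~80 pairs, paralog synonymous
    divergence mostly below 0.3 (t_post = 0.1 per branch), background
    dN/dS ~ 0.5, mildly elevated dN/dS inside frameshifted regions, and a
    scenario mix dominated by type C.
    """

    seed: int = 0
    n_pairs: int = 80
    ancestor_len_codons: int = 300
    flank5_len_nt: int = 90
    flank3_len_nt: int = 90
    t_pre: float = 0.25
    t_post: float = 0.1
    omega_background: float = 0.5
    omega_frameshifted: float = 1.1
    scenario_mix: dict[str, float] = field(
        default_factory=lambda: {"C": 0.64, "N": 0.22, "M": 0.09, "multi-C": 0.05}
    )
    indel_sizes: tuple[int, ...] = (-4, -2, -1, 1, 2)
    location_quantile_range: tuple[float, float] = (0.05, 0.95)
    n_transcripts: int = 1

    def validate(self) -> None:
        if self.ancestor_len_codons < 10:
            raise InvalidConfigError("ancestor_len_codons must be >= 10")
        if self.n_pairs < 0:
            raise InvalidConfigError("n_pairs must be >= 0")
        if self.flank3_len_nt < len(_TRIPLE_STOP):
            raise InvalidConfigError(
                f"flank3_len_nt must be >= {len(_TRIPLE_STOP)} to seed stops"
            )
        if any(s % 3 == 0 for s in self.indel_sizes):
            raise InvalidConfigError("all indel sizes must satisfy s mod 3 != 0")
        total = sum(self.scenario_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise InvalidConfigError("scenario_mix proportions must sum to 1")
        lo, hi = self.location_quantile_range
        if not (0.0 < lo < hi < 1.0):
            raise InvalidConfigError("location_quantile_range must be within (0,1)")


@dataclass
class TruthRecord:
    """Ground truth for one simulated pair."""

    pair_id: str
    original_gene_id: str
    derived_gene_id: str
    outgroup_gene_id: str
    events: list[tuple[int, int, int]]  # (position_nt pre-indel, size, phase)
    type_label: str
    frameshifted_interval_aa: tuple[int, int]
    positions_derived_nt: list[int] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(NT_ALPHABET[k] for k in rng.integers(0, 4, length))


def simulate_ancestor_cds(
    len_codons: int,
    seed,
    flank5_len_nt: int = 90,
    flank3_len_nt: int = 90,
    gene_id: str = "anc",
    species: str = "sim",
) -> GeneRecord:
    """Random valid CDS: ATG, uniform sense codons, one stop; random flanks.

    The 3' flank begins with stop codons in all three frames so that any
    frameshifted ORF walking into it terminates.
    """
    if len_codons < 10:
        raise InvalidConfigError("len_codons must be >= 10")
    rng = _rng_of(seed)
    codons = ["ATG"]
    while len(codons) < len_codons - 1:
        cod = "".join(NT_ALPHABET[k] for k in rng.integers(0, 4, 3))
        if cod not in STOP_CODONS:
            codons.append(cod)
    codons.append(sorted(STOP_CODONS)[rng.integers(0, 3)])
    flank5 = _random_flank(rng, flank5_len_nt)
    flank3 = _TRIPLE_STOP + _random_flank(rng, max(0, flank3_len_nt - len(_TRIPLE_STOP)))
    return GeneRecord(
        gene_id=gene_id,
        species=species,
        transcripts=["".join(codons)],
        flank5=flank5,
        flank3=flank3,
    )


def evolve_cds(
    cds: str,
    t: float,
    omega: float,
    seed,
    *,
    regions: list[tuple[int, int, float, int]] | None = None,
) -> str:
    """Apply Poisson(t x length) proposed substitutions under dN/dS control.

    A proposal that is nonsynonymous is accepted with probability min(1, omega)
    and a synonymous one with min(1, 1/omega), so the realized dN/dS equals
    omega on either side of 1.  Proposals destroying the start codon, turning
    the stop into a sense codon, or creating an internal in-frame stop are
    rejected.

    ``regions`` optionally overrides omega inside half-open nt intervals:
    each entry is ``(start, end, omega_region, frame_offset)`` where
    ``frame_offset`` gives the codon-grid offset used to classify a change as
    synonymous or not inside that region (the native frame is always used for
    stop-codon protection).
    """
    if t < 0 or omega < 0:
        raise InvalidConfigError("t and omega must be >= 0")
    rng = _rng_of(seed)
    seq = list(cds.upper())
    n = len(seq)
    if n % 3 != 0:
        raise InvalidConfigError("cds length must be divisible by 3")
    n_prop = rng.poisson(t * n)
    for _ in range(n_prop):
        pos = int(rng.integers(0, n))
        cur = seq[pos]
        alts = [c for c in NT_ALPHABET if c != cur]
        new = alts[rng.integers(0, 3)]
        if pos < 3:
            continue  # any change destroys the ATG start
        if pos >= n - 3:
            cand = "".join(seq[n - 3 :])
            cand = cand[: pos - (n - 3)] + new + cand[pos - (n - 3) + 1 :]
            if cand not in STOP_CODONS:
                continue
            seq[pos] = new  # stop-to-stop change: no coding consequence
            continue
        c0 = 3 * (pos // 3)
        native_old = "".join(seq[c0 : c0 + 3])
        native_new = native_old[: pos - c0] + new + native_old[pos - c0 + 1 :]
        if native_new in STOP_CODONS:
            continue
        om, frame_off = omega, 0
        if regions:
            for a, b, om_r, fo in regions:
                if a <= pos < b:
                    om, frame_off = om_r, fo
                    break
        # classify synonymous/nonsynonymous on the codon grid offset by frame_off
        g0 = pos - ((pos - frame_off) % 3)
        if g0 < 0 or g0 + 3 > n:
            syn = translate(native_old) == translate(native_new)
        else:
            grid_old = "".join(seq[g0 : g0 + 3])
            grid_new = grid_old[: pos - g0] + new + grid_old[pos - g0 + 1 :]
            syn = translate(grid_old) == translate(grid_new)
        if syn:
            accept = om == 0 or rng.random() < min(1.0, 1.0 / om)
        else:
            accept = rng.random() < min(1.0, om)
        if accept:
            seq[pos] = new
    return "".join(seq)


def _first_stop_from(full: str, start: int) -> int | None:
    """Offset of the first stop codon reading in frame from ``start``."""
    for c in range(start, len(full) - 2, 3):
        if full[c : c + 3] in STOP_CODONS:
            return c
    return None


def _apply_indel(seq: str, pos: int, size: int, rng: np.random.Generator) -> str:
    if size > 0:
        ins = _random_flank(rng, size)
        return seq[:pos] + ins + seq[pos:]
    return seq[:pos] + seq[pos - size :]


def apply_frameshift_scenario(
    gene: GeneRecord, scenario: dict, seed
) -> tuple[GeneRecord, TruthRecord]:
    """Create the derived copy of ``gene`` under a frameshift scenario.

    ``scenario`` maps ``type`` to one of C/N/M/multi-C, ``sizes`` to the indel
    sizes and ``location_quantiles`` to placement quantiles on (0,1).  Raises
    :class:`ScenarioDegenerateError` when the construction yields an ORF
    shorter than 3 codons or a frameshifted region too short to detect; the
    caller is expected to retry with fresh randomness.
    """
    rng = _rng_of(seed)
    stype = scenario["type"]
    sizes = list(scenario["sizes"])
    quants = list(scenario["location_quantiles"])
    cds = gene.cds
    L = len(cds)
    if stype in ("C", "multi-C"):
        if sum(sizes) % 3 == 0:
            raise InvalidConfigError("type C sizes must not sum to a multiple of 3")
        return _scenario_c(gene, cds, L, sizes, quants, rng)
    if stype == "N":
        if sum(sizes) % 3 == 0:
            raise InvalidConfigError("type N sizes must not sum to a multiple of 3")
        return _scenario_n(gene, cds, L, sizes[0], quants[0], rng)
    if stype == "M":
        if sum(sizes) % 3 != 0:
            raise InvalidConfigError("type M sizes must sum to a multiple of 3")
        return _scenario_m(gene, cds, L, sizes, quants, rng)
    raise InvalidConfigError(f"unknown scenario type {stype!r}")


def _scenario_c(gene, cds, L, sizes, quants, rng):
    positions = sorted(
        max(4, min(L - 7, int(q * L))) for q in quants
    )
    if len(set(positions)) != len(positions):
        raise ScenarioDegenerateError("indel positions collide")
    mutated = cds
    for p, s in sorted(zip(positions, sizes), reverse=True):
        mutated = _apply_indel(mutated, p, s, rng)
    full = mutated + gene.flank3
    stop = _first_stop_from(full, 0)
    if stop is None:
        raise ScenarioDegenerateError("no stop found")  # pragma: no cover
    derived_cds = full[: stop + 3]
    # derived coordinates of each indel, and of the first post-event nucleotide
    shift = 0
    derived_pos = []
    for p, s in zip(positions, sizes):
        derived_pos.append(p + shift)
        shift += s
    if derived_cds[:3] != "ATG":  # pragma: no cover - prefix untouched
        raise ScenarioDegenerateError("start codon lost")
    if stop < derived_pos[-1] + 3:
        raise ScenarioDegenerateError("ORF ends before the last indel")
    fs_start_aa = derived_pos[0] // 3
    fs_end_aa = len(derived_cds) // 3 - 1  # exclude stop codon
    if fs_end_aa - fs_start_aa < _MIN_FS_AA or fs_start_aa < 2:
        raise ScenarioDegenerateError("frameshifted region too short")
    if len(derived_cds) < 9 or not is_valid_cds(derived_cds):
        raise ScenarioDegenerateError("derived ORF invalid")
    derived = replace(
        gene,
        transcripts=[derived_cds],
        flank3=full[stop + 3 :],
        role="derived",
    )
    truth = TruthRecord(
        pair_id="",
        original_gene_id="",
        derived_gene_id="",
        outgroup_gene_id="",
        events=[(p, s, s % 3) for p, s in zip(positions, sizes)],
        type_label="C",
        frameshifted_interval_aa=(fs_start_aa, fs_end_aa),
        positions_derived_nt=list(derived_pos),
    )
    return derived, truth


def _scenario_n(gene, cds, L, size, quant, rng):
    p = max(4, min(int(quant * L), L // 3))
    flank5 = gene.flank5
    F = len(flank5)
    mutated = _apply_indel(cds, p, size, rng)
    # new ATG position a in the 5' flank; reading from a merges into the
    # original frame downstream of the indel iff a == F + size (mod 3)
    want = (F + size) % 3
    cands = [a for a in range(F - 3, -1, -1) if a % 3 == want]
    if not cands:
        raise ScenarioDegenerateError("no frame-compatible start position")
    merge_point = F + p + max(size, 0)
    for a in cands:
        full = flank5[:a] + "ATG" + flank5[a + 3 :] + mutated + gene.flank3
        ok = True
        for c in range(a, len(full) - 2, 3):
            if c >= merge_point - 2:
                break
            if full[c : c + 3] in STOP_CODONS:
                ok = False
                break
        if not ok:
            continue
        end = F + L + size  # original stop, shifted by the indel
        derived_cds = full[a:end]
        if not is_valid_cds(derived_cds):
            continue
        fs_end_aa = (merge_point - a + 2) // 3
        if fs_end_aa < _MIN_FS_AA or len(derived_cds) // 3 - 1 - fs_end_aa < 2:
            continue
        derived = replace(
            gene,
            transcripts=[derived_cds],
            flank5=full[:a],
            flank3=full[end:],
            role="derived",
        )
        truth = TruthRecord(
            pair_id="",
            original_gene_id="",
            derived_gene_id="",
            outgroup_gene_id="",
            events=[(p, size, size % 3)],
            type_label="N",
            frameshifted_interval_aa=(0, fs_end_aa),
            positions_derived_nt=[F - a + p],
        )
        return derived, truth
    raise ScenarioDegenerateError("no stop-free shifted prefix found")


def _scenario_m(gene, cds, L, sizes, quants, rng):
    s1, s2 = sizes
    q1, q2 = sorted(quants)
    p1 = max(4, min(L - 16, int(q1 * L)))
    p2 = max(p1 + 3 * _MIN_FS_AA + 2, min(L - 7, int(q2 * L)))
    if p2 >= L - 6:
        raise ScenarioDegenerateError("second indel too close to the stop")
    mutated = _apply_indel(cds, p2, s2, rng)
    mutated = _apply_indel(mutated, p1, s1, rng)
    d1, d2 = p1, p2 + s1
    # the running frame is shifted on [d1, d2); the full scan below rejects any
    # stop codon arising there or at the indel junctions
    stop = _first_stop_from(mutated + gene.flank3, 0)
    expected_len = L + s1 + s2
    if stop is None or stop + 3 != expected_len:
        raise ScenarioDegenerateError("shifted interior region hits a stop")
    derived_cds = mutated[:expected_len]
    if not is_valid_cds(derived_cds):
        raise ScenarioDegenerateError("derived ORF invalid")
    fs_start_aa = d1 // 3
    fs_end_aa = (d2 + 2) // 3
    if fs_end_aa - fs_start_aa < _MIN_FS_AA:
        raise ScenarioDegenerateError("frameshifted region too short")
    derived = replace(gene, transcripts=[derived_cds], role="derived")
    truth = TruthRecord(
        pair_id="",
        original_gene_id="",
        derived_gene_id="",
        outgroup_gene_id="",
        events=[(p1, s1, s1 % 3), (p2, s2, s2 % 3)],
        type_label="M",
        frameshifted_interval_aa=(fs_start_aa, fs_end_aa),
        positions_derived_nt=[d1, d2],
    )
    return derived, truth


def _draw_scenario_type(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    names = sorted(cfg.scenario_mix)
    probs = np.array([cfg.scenario_mix[k] for k in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _draw_scenario(cfg: SimulationConfig, rng: np.random.Generator, stype: str) -> dict:
    sizes = list(cfg.indel_sizes)
    lo, hi = cfg.location_quantile_range
    s1 = sizes[rng.integers(0, len(sizes))]
    if stype == "C":
        return {
            "type": "C",
            "sizes": [s1],
            "location_quantiles": [rng.uniform(lo, hi)],
        }
    if stype == "N":
        return {
            "type": "N",
            "sizes": [s1],
            "location_quantiles": [rng.uniform(0.03, 0.12)],
        }
    if stype == "M":
        q1 = rng.uniform(0.25, 0.6)
        return {
            "type": "M",
            "sizes": [s1, -s1],
            "location_quantiles": [q1, q1 + rng.uniform(0.06, 0.15)],
        }
    # multi-C: two indels, frame still shifted at the end
    s2 = sizes[rng.integers(0, len(sizes))]
    while (s1 + s2) % 3 == 0:
        s2 = sizes[rng.integers(0, len(sizes))]
    q1 = min(rng.uniform(lo, hi), 0.8)
    return {
        "type": "multi-C",
        "sizes": [s1, s2],
        "location_quantiles": [q1, q1 + rng.uniform(0.03, 0.08)],
    }


def _frameshift_region_spec(truth: TruthRecord) -> tuple[int, int, int]:
    """(start_nt, end_nt, original-frame offset) of the fs region on the derived CDS."""
    a_aa, b_aa = truth.frameshifted_interval_aa
    shift = sum(s for _, s, _ in truth.events[:1]) if truth.type_label != "N" else None
    if truth.type_label == "N":
        # prefix region: original-frame grid offset = first derived position - p
        off = (truth.positions_derived_nt[0] - truth.events[0][0]) % 3
    else:
        off = truth.events[0][1] % 3
    return 3 * a_aa, 3 * b_aa, off


def generate_pairs(cfg: SimulationConfig) -> tuple[list[GeneRecord], list[TruthRecord]]:
    """Simulate ``cfg.n_pairs`` duplicate pairs plus outgroups, with truth."""
    cfg.validate()
    genes: list[GeneRecord] = []
    truths: list[TruthRecord] = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_pairs)
    for idx in range(cfg.n_pairs):
        rng = np.random.default_rng(seeds[idx])
        pair_id = f"P{idx:04d}"
        # the scenario TYPE is drawn once so the realized mix follows
        # scenario_mix; degenerate draws retry only the ancestor/placement
        stype = _draw_scenario_type(cfg, rng)
        for _attempt in range(200):
            anc = simulate_ancestor_cds(
                cfg.ancestor_len_codons,
                rng,
                cfg.flank5_len_nt,
                cfg.flank3_len_nt,
                gene_id=f"{pair_id}_anc",
            )
            scenario = _draw_scenario(cfg, rng, stype)
            try:
                derived0, truth = apply_frameshift_scenario(anc, scenario, rng)
            except ScenarioDegenerateError:
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise ScenarioDegenerateError(f"pair {pair_id}: no viable scenario")
        if scenario["type"] == "multi-C":
            truth.type_label = "C"
        og_cds = evolve_cds(anc.cds, cfg.t_pre, cfg.omega_background, rng)
        orig_cds = evolve_cds(anc.cds, cfg.t_post, cfg.omega_background, rng)
        fs_a, fs_b, fs_off = _frameshift_region_spec(truth)
        der_cds = evolve_cds(
            derived0.cds,
            cfg.t_post,
            cfg.omega_background,
            rng,
            regions=[(fs_a, fs_b, cfg.omega_frameshifted, fs_off)],
        )
        # randomize which duplicate carries which id, so naming leaks nothing
        flip = bool(rng.integers(0, 2))
        id_orig = f"{pair_id}_{'y' if flip else 'x'}"
        id_der = f"{pair_id}_{'x' if flip else 'y'}"
        n_t = max(1, cfg.n_transcripts)
        orig = GeneRecord(
            gene_id=id_orig,
            species="sp1",
            transcripts=[orig_cds] * n_t,
            flank5=anc.flank5,
            flank3=anc.flank3,
            role="original",
        )
        der = GeneRecord(
            gene_id=id_der,
            species="sp1",
            transcripts=[der_cds] * n_t,
            flank5=derived0.flank5,
            flank3=derived0.flank3,
            role="derived",
        )
        og = GeneRecord(
            gene_id=f"{pair_id}_og",
            species="sp0",
            transcripts=[og_cds],
            flank5=anc.flank5,
            flank3=anc.flank3,
            role="outgroup",
        )
        truth.pair_id = pair_id
        truth.original_gene_id = id_orig
        truth.derived_gene_id = id_der
        truth.outgroup_gene_id = og.gene_id
        if flip:
            genes.extend([der, orig, og])
        else:
            genes.extend([orig, der, og])
        truths.append(truth)
    return genes, truths


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "pair_id": t.pair_id,
                "original_id": t.original_gene_id,
                "derived_id": t.derived_gene_id,
                "outgroup_id": t.outgroup_gene_id,
                "n_events": t.n_events,
                "positions": ";".join(str(p) for p, _, _ in t.events),
                "sizes": ";".join(str(s) for _, s, _ in t.events),
                "type": t.type_label,
                "fs_start_aa": t.frameshifted_interval_aa[0],
                "fs_end_aa": t.frameshifted_interval_aa[1],
                "positions_derived_nt": ";".join(
                    str(p) for p in t.positions_derived_nt
                ),
            }
        )
    cols = [
        "pair_id",
        "original_id",
        "derived_id",
        "outgroup_id",
        "n_events",
        "positions",
        "sizes",
        "type",
        "fs_start_aa",
        "fs_end_aa",
        "positions_derived_nt",
    ]
    return pd.DataFrame(rows, columns=cols)


def generate_dataset(cfg: SimulationConfig, out_dir=None):
    """Simulate pairs and optionally write FASTA + truth TSV to ``out_dir``.

    Returns ``(genes, truth_dataframe)``.
    """
    from .io import write_fasta  # local import to avoid a cycle

    genes, truths = generate_pairs(cfg)
    df = truth_frame(truths)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genes, out / "genes.fa")
        df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return genes, df
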