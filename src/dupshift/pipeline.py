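"""End-to-end survey pipeline: detect -> polarize -> align -> classify -> Ka/Ks."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import pandas as pd

from .classify import (
    PolarizedPair,
    align_polarized,
    case_lengths,
    classify_type,
    partition_regions,
    polarize_pair,
    relative_location,
)
from .detect import find_duplicate_pairs, transcript_consistency_filter
from .kaks import (
    RegionKaKs,
    kaks_from_counts,
    pool_counts,
    reconstruct_ancestor,
    region_lineage_kaks,
)
from .records import (
    DegenerateAlignmentError,
    GeneRecord,
    UnresolvedPolarityError,
)

log = logging.getLogger("dupshift")


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def find_outgroup(
    pair_genes: tuple[GeneRecord, GeneRecord], genes: list[GeneRecord]
) -> GeneRecord | None:
    """Outgroup = other-species gene sharing the longest gene-id prefix with
    both copies (the naming convention of the synthetic datasets)."""
    a, b = pair_genes
    best, best_n = None, 0
    for g in genes:
        if g.species == a.species or not g.transcripts:
            continue
        n = min(_common_prefix(g.gene_id, a.gene_id), _common_prefix(g.gene_id, b.gene_id))
        if n > best_n:
            best, best_n = g, n
    return best if best_n >= 1 else None


@dataclass
class CaseResult:
    pair_id: str
    pair: PolarizedPair
    partition: object
    label: object
    kaks: list[RegionKaKs]


def analyze_polarized(
    pair: PolarizedPair,
    pair_id: str,
    outgroup_ks_factor: float = 1.5,
    kaks: bool = True,
) -> tuple[dict, list[dict], CaseResult] | None:
    """Classify one polarized pair; returns (case row, kaks rows, objects).

    Returns ``None`` when no frameshift event is detected.  Ka/Ks rows are
    only produced when an outgroup passed the divergence vetting (its
    synonymous distance to the original copy must exceed
    ``outgroup_ks_factor`` times the copies' common-frame Ks).
    """
    try:
        path = align_polarized(pair)
    except DegenerateAlignmentError:
        return None
    if not pair.events:
        return None
    partition = partition_regions(pair, path)
    label = classify_type(partition)
    fs_len, of_len, der_len, orig_len = case_lengths(partition, pair)
    row = {
        "pair_id": pair_id,
        "original_id": pair.original.gene_id,
        "derived_id": pair.derived.gene_id,
        "outgroup_id": pair.outgroup.gene_id if pair.outgroup else "",
        "polarization_basis": pair.polarization_basis,
        "n_events": len(pair.events),
        "type": label.value,
        "length_triple": f"{fs_len}/{der_len}/{orig_len}",
        "fs_len_aa": fs_len,
        "of_len_aa": of_len,
        "derived_len_aa": der_len,
        "original_len_aa": orig_len,
        "relative_location": relative_location(partition, pair),
        "relative_fs_length": fs_len / orig_len if orig_len else float("nan"),
        "relative_of_length": of_len / orig_len if orig_len else float("nan"),
        "event_positions_nt": ";".join(str(e.cds_position) for e in pair.events),
        "event_sizes": ";".join(str(e.size) for e in pair.events),
        "event_phases": ";".join(str(e.phase) for e in pair.events),
        "ks_c": None,
        "ka_c": None,
    }
    kaks_rows: list[dict] = []
    results: list[RegionKaKs] = []
    if kaks and pair.outgroup is not None:
        anc = reconstruct_ancestor(
            pair.original.cds, pair.derived.cds, pair.outgroup.cds
        )
        results = region_lineage_kaks(partition, anc)
        between = next(
            r for r in results if r.region == "common" and r.lineage == "between-copies"
        )
        row["ks_c"] = between.ks
        row["ka_c"] = between.ka
        # outgroup vetting: its divergence must comfortably predate duplication
        from ._codon import codons_of
        from .kaks import ng86_codon_counts

        og_at_orig = "".join(
            o for o, c in zip(anc.outgroup_row, anc.original_row) if c != "-"
        )
        og_counts = ng86_codon_counts(
            codons_of(anc.original_row.replace("-", "")), codons_of(og_at_orig)
        )
        ks_og = kaks_from_counts(og_counts).ks
        vetted = between.ks == 0 or ks_og > outgroup_ks_factor * between.ks
        if vetted:
            for r in results:
                kaks_rows.append(
                    {
                        "pair_id": pair_id,
                        "region": r.region,
                        "lineage": r.lineage,
                        "na": r.counts.na,
                        "ns": r.counts.ns,
                        "la": r.counts.la,
                        "ls": r.counts.ls,
                        "ka": r.ka,
                        "ks": r.ks,
                        "ratio": r.ratio,
                        "saturated": r.saturated,
                        "low_power": r.low_power,
                    }
                )
        else:
            log.info("pair %s: outgroup failed Ks vetting", pair_id)
    return row, kaks_rows, CaseResult(pair_id, pair, partition, label, results)


def run_survey(
    genes: list[GeneRecord],
    min_identity: float = 0.70,
    min_overlap: float = 0.70,
    min_score: float = 50.0,
    kaks: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CaseResult]]:
    """Full survey on a gene set: returns (cases table, kaks table, objects).

    ``kaks=False`` skips ancestral reconstruction and rate estimation (useful
    when only detection/classification is of interest).
    """
    by_id = {g.gene_id: g for g in genes}
    ingroup = [g for g in genes if g.role != "outgroup"]
    pairs = find_duplicate_pairs(ingroup, min_identity, min_overlap, min_score)
    log.info("%d candidate pairs passed identity/overlap/score filters", len(pairs))
    case_rows, kaks_rows, objects = [], [], []
    n_inconsistent = n_unresolved = 0
    for cand in pairs:
        if not transcript_consistency_filter(cand, by_id):
            n_inconsistent += 1
            continue
        a, b = by_id[cand.gene_id_a], by_id[cand.gene_id_b]
        outgroup = find_outgroup((a, b), genes)
        try:
            pp = polarize_pair(a, b, outgroup)
        except UnresolvedPolarityError:
            n_unresolved += 1
            continue
        res = analyze_polarized(
            pp, pair_id=f"{cand.gene_id_a}~{cand.gene_id_b}", kaks=kaks
        )
        if res is None:
            continue
        row, krows, obj = res
        case_rows.append(row)
        kaks_rows.extend(krows)
        objects.append(obj)
    log.info(
        "%d frameshift cases (%d inconsistent, %d unresolved polarity dropped)",
        len(case_rows),
        n_inconsistent,
        n_unresolved,
    )
    case_cols = [
        "pair_id", "original_id", "derived_id", "outgroup_id",
        "polarization_basis", "n_events", "type", "length_triple",
        "fs_len_aa", "of_len_aa", "derived_len_aa", "original_len_aa",
        "relative_location", "relative_fs_length", "relative_of_length",
        "event_positions_nt", "event_sizes", "event_phases", "ks_c", "ka_c",
    ]
    kaks_cols = [
        "pair_id", "region", "lineage", "na", "ns", "la", "ls",
        "ka", "ks", "ratio", "saturated", "low_power",
    ]
    cases = pd.DataFrame(case_rows, columns=case_cols)
    kaks = pd.DataFrame(kaks_rows, columns=kaks_cols)
    return cases, kaks, objects


def pooled_region_ratios(objects: list[CaseResult]) -> dict[str, float | None]:
    """Pooled (summed-count) Ka/Ks per region x lineage across cases."""
    all_results = [r for o in objects for r in o.kaks]
    out: dict[str, float | None] = {}
    for region, lineage, key in [
        ("frameshifted", "ancestor->original", "pooled_kaks_frameshifted_original"),
        ("frameshifted", "ancestor->derived", "pooled_kaks_frameshifted_derived"),
        ("common", "ancestor->original", "pooled_kaks_common_original"),
        ("common", "ancestor->derived", "pooled_kaks_common_derived"),
    ]:
        out[key] = pool_counts(all_results, region, lineage).ratio
    return out
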