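"""Polarization, region partitioning, C/N/M typing, length statistics."""

import pytest

from dupshift.classify import (
    PolarizedPair,
    Region,
    RegionPartition,
    align_polarized,
    case_lengths,
    classify_type,
    partition_regions,
    polarize_pair,
    region_length_stats,
    relative_location,
)
from dupshift.fsalign import FrameshiftEvent
from dupshift.records import GeneRecord, InvalidInputError, UnresolvedPolarityError
from dupshift.simulate import simulate_ancestor_cds, generate_pairs, SimulationConfig


def _gene(gid, cds, species="sp1"):
    return GeneRecord(gene_id=gid, species=species, transcripts=[cds])


def test_outgroup_identical_to_one_copy_polarizes_it_original(small_dataset):
    _, genes, truths, _ = small_dataset
    by_id = {g.gene_id: g for g in genes}
    t = truths[0]
    a = by_id[t.original_gene_id]
    b = by_id[t.derived_gene_id]
    og = GeneRecord("og", "sp0", [a.cds], role="outgroup")
    pp = polarize_pair(a, b, og)
    assert pp.original.gene_id == a.gene_id
    assert pp.polarization_basis == "outgroup-frame"


def test_shorter_copy_fallback():
    long = simulate_ancestor_cds(300, seed=1).cds
    short = simulate_ancestor_cds(100, seed=1).cds
    pp = polarize_pair(_gene("a", long), _gene("b", short))
    assert pp.derived.gene_id == "b"
    assert pp.polarization_basis == "shorter-copy-fallback"


def test_equal_lengths_without_outgroup_is_unresolved():
    cds = simulate_ancestor_cds(100, seed=2).cds
    with pytest.raises(UnresolvedPolarityError):
        polarize_pair(_gene("a", cds), _gene("b", cds))


def test_declared_override():
    cds = simulate_ancestor_cds(100, seed=3).cds
    pp = polarize_pair(_gene("a", cds), _gene("b", cds), declared="a")
    assert pp.derived.gene_id == "a"
    assert pp.polarization_basis == "declared"


def test_simulated_polarity_recovery(small_dataset):
    _, genes, truths, _ = small_dataset
    by_id = {g.gene_id: g for g in genes}
    correct = 0
    for t in truths:
        pp = polarize_pair(
            by_id[t.original_gene_id],
            by_id[t.derived_gene_id],
            by_id[t.outgroup_gene_id],
        )
        correct += pp.original.gene_id == t.original_gene_id
    assert correct == len(truths)


def test_partition_zero_events_single_common_region(small_dataset):
    _, genes, _, _ = small_dataset
    by_id = {g.gene_id: g for g in genes}
    t0 = [g for g in genes if g.role == "original"][0]
    og = [g for g in genes if g.role == "outgroup"][0]
    pp = PolarizedPair(t0, GeneRecord("d", "sp1", [t0.cds]), og, "declared")
    path = align_polarized(pp)
    assert pp.events == []
    part = partition_regions(pp, path)
    assert len(part.regions) == 1
    assert not part.regions[0].frameshifted


@pytest.mark.parametrize(
    "stype,expected",
    [("C", "C"), ("N", "N"), ("M", "M")],
)
def test_partition_and_label_geometry(stype, expected):
    cfg = SimulationConfig(
        seed=202,
        n_pairs=6,
        ancestor_len_codons=200,
        t_post=0.03,
        scenario_mix={stype: 1.0},
    )
    genes, truths = generate_pairs(cfg)
    by_id = {g.gene_id: g for g in genes}
    for t in truths:
        pp = polarize_pair(
            by_id[t.original_gene_id],
            by_id[t.derived_gene_id],
            by_id[t.outgroup_gene_id],
        )
        path = align_polarized(pp)
        part = partition_regions(pp, path)
        label = classify_type(part)
        assert label.value == expected
        if stype == "M":
            # frameshifted region strictly between common regions
            kinds = [r.frameshifted for r in part.regions]
            assert kinds == [False, True, False]


def test_classify_composite_labels():
    def reg(fs, a, b):
        return Region(frameshifted=fs, derived_nt=(a, b), original_nt=(a, b))

    part = RegionPartition(
        regions=[reg(True, 0, 30), reg(False, 30, 200), reg(True, 200, 260)]
    )
    assert classify_type(part, n_events=2).value == "N&C"
    part = RegionPartition(
        regions=[reg(True, 0, 30), reg(False, 30, 100), reg(True, 100, 160), reg(False, 160, 300)]
    )
    assert classify_type(part, n_events=3).value == "N&M"


def test_partition_tiling_invariant(small_dataset):
    _, genes, truths, _ = small_dataset
    by_id = {g.gene_id: g for g in genes}
    for t in truths[:8]:
        pp = polarize_pair(
            by_id[t.original_gene_id],
            by_id[t.derived_gene_id],
            by_id[t.outgroup_gene_id],
        )
        path = align_polarized(pp)
        part = partition_regions(pp, path)
        aa_total = sum(r.original_len_aa for r in part.regions)
        assert aa_total == len(pp.original.protein)
        # derived-side regions tile the aligned CDS span
        spans = sorted(r.derived_nt for r in part.regions)
        assert spans[0][0] == path.cds_span[0]
        assert spans[-1][1] == path.cds_span[1]
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == b0


def test_relative_location_endpoints():
    orig = simulate_ancestor_cds(100, seed=5)
    pp = PolarizedPair(orig, orig, None, "declared")
    part = RegionPartition(regions=[], events=[FrameshiftEvent(0, 1, 1, 0)])
    assert relative_location(part, pp) == 0.0
    part = RegionPartition(regions=[], events=[FrameshiftEvent(150, 1, 1, 50)])
    assert relative_location(part, pp) == 0.5
    with pytest.raises(InvalidInputError):
        relative_location(RegionPartition(regions=[]), pp)


def test_region_length_stats_arithmetic():
    cases = [
        {"type": "C", "fs_len_aa": 15, "of_len_aa": 30, "derived_len_aa": 223, "original_len_aa": 385},
    ]
    out = region_length_stats(cases)
    assert out["C"]["n"] == 1
    assert out["C"]["mean_fs"] == pytest.approx(15 / 385)
    assert out["C"]["mean_of"] == pytest.approx(30 / 385)
    alt = region_length_stats(cases, normalization="derived")
    assert alt["C"]["mean_fs"] == pytest.approx(15 / 223)
    assert "N" not in out  # empty class reported as absent
    with pytest.raises(InvalidInputError):
        region_length_stats(cases, normalization="bogus")


def test_region_length_stats_all_empty_regions():
    cases = [
        {"type": "C", "fs_len_aa": 0, "of_len_aa": 0, "derived_len_aa": 100, "original_len_aa": 100}
    ] * 3
    out = region_length_stats(cases)
    assert out["C"]["mean_fs"] == 0.0


def test_simulated_relative_location_recovery():
    cfg = SimulationConfig(
        seed=303,
        n_pairs=10,
        ancestor_len_codons=300,
        t_post=0.05,
        scenario_mix={"C": 1.0},
        location_quantile_range=(0.795, 0.805),
    )
    genes, truths = generate_pairs(cfg)
    by_id = {g.gene_id: g for g in genes}
    hits = 0
    for t in truths:
        pp = polarize_pair(
            by_id[t.original_gene_id],
            by_id[t.derived_gene_id],
            by_id[t.outgroup_gene_id],
        )
        path = align_polarized(pp)
        part = partition_regions(pp, path)
        if abs(relative_location(part, pp) - 0.8) <= 0.02:
            hits += 1
    assert hits >= 9
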