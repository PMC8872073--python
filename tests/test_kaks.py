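"""NG86 counting, JC correction, ancestral reconstruction, lineage tests."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from dupshift._codon import codons_of
from dupshift.kaks import (
    SubstCounts,
    codon_sites,
    jukes_cantor,
    ka_ks,
    kaks_from_counts,
    ng86_codon_counts,
    pool_counts,
    positive_selection_test,
    ratio_equality_test,
    reconstruct_ancestor,
    region_lineage_kaks,
)
from dupshift.records import InvalidInputError
from dupshift.simulate import SimulationConfig, evolve_cds, generate_pairs, simulate_ancestor_cds

from helpers import oracle_codon_sites, oracle_ng86_pair, sense_codons


def test_codon_sites_reference_values():
    s, n = codon_sites("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_site_counts_sum_to_three_for_all_sense_codons():
    for cod in sense_codons():
        s, n = codon_sites(cod)
        assert s + n == pytest.approx(3.0)
        so, no = oracle_codon_sites(cod)
        assert s == pytest.approx(so)


def test_single_difference_counts():
    c = ng86_codon_counts(["TTT"], ["TTC"])
    assert (c.na, c.ns) == (0.0, 1.0)
    c = ng86_codon_counts(["ATG"], ["ATA"])
    assert (c.na, c.ns) == (1.0, 0.0)


def test_identical_codons_give_zero_counts():
    c = ng86_codon_counts(["ATG", "TTT"], ["ATG", "TTT"])
    assert c.na == c.ns == 0.0
    assert c.la + c.ls == pytest.approx(6.0)


def test_counting_symmetry(rng):
    cods = sense_codons()
    for _ in range(60):
        c1 = cods[rng.integers(0, len(cods))]
        c2 = cods[rng.integers(0, len(cods))]
        a = ng86_codon_counts([c1], [c2])
        b = ng86_codon_counts([c2], [c1])
        assert a.na == pytest.approx(b.na)
        assert a.ns == pytest.approx(b.ns)


def test_pathway_counts_match_oracle_sample(rng):
    cods = sense_codons()
    for _ in range(80):
        c1 = cods[rng.integers(0, len(cods))]
        c2 = cods[rng.integers(0, len(cods))]
        got = ng86_codon_counts([c1], [c2])
        na, ns = oracle_ng86_pair(c1, c2)
        assert got.na == pytest.approx(na)
        assert got.ns == pytest.approx(ns)


def test_stop_codons_are_skipped_with_tally():
    c = ng86_codon_counts(["TAA", "TTT"], ["TTT", "TTC"])
    assert c.n_skipped == 1
    assert c.ns == 1.0


def test_jukes_cantor_behaviour():
    assert jukes_cantor(0.0) == 0.0
    assert math.isinf(jukes_cantor(0.8))
    assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))


def test_ka_ks_synonymous_only_gives_zero_ratio():
    a = "CTTCGACTTCGAAAAGGGCCCTTTATGGAT"
    b = "CTCCGACTTCGAAAAGGACCCTTTATGGAT"  # two synonymous changes only
    r = ka_ks(a, b)
    assert r.ka == 0.0
    assert r.ks > 0.0
    assert r.ratio == 0.0


def test_ka_ks_identical_is_undefined_ratio():
    r = ka_ks("ATGCTTCGA", "ATGCTTCGA")
    assert r.ka == r.ks == 0.0
    assert r.ratio is None


def test_ka_ks_requires_equal_lengths():
    with pytest.raises(InvalidInputError):
        ka_ks("ATGCTT", "ATG")


def test_parameter_recovery_single_branch(rng):
    total = SubstCounts()
    for _ in range(60):
        anc = simulate_ancestor_cds(300, rng, 12, 12)
        out = evolve_cds(anc.cds, 0.1, 0.5, rng)
        total += ng86_codon_counts(codons_of(anc.cds)[1:-1], codons_of(out)[1:-1])
    r = kaks_from_counts(total)
    assert r.ratio == pytest.approx(0.5, rel=0.2)
    assert r.ks == pytest.approx(0.1, rel=0.2)


def test_reconstruct_ancestor_trivial_rules():
    a = "ATGCTTCGATTTAAACCCTAA"
    rec = reconstruct_ancestor(a, a, a)
    assert rec.sequence == a
    assert set(rec.support) == {"unanimous"}
    # duplicates agree, outgroup differs -> duplicate state
    og = "ATGCTACGATTTAAACCCTAA"
    rec = reconstruct_ancestor(a, a, og)
    assert rec.sequence == a
    # duplicates disagree, outgroup matches one -> outgroup state
    b = "ATGCTGCGATTTAAACCCTAA"
    rec = reconstruct_ancestor(a, b, og)
    assert rec.sequence[5] == "A"  # og base at the disputed column
    assert "outgroup-tiebreak" in rec.support


def test_reconstruct_ancestor_requires_outgroup():
    with pytest.raises(InvalidInputError):
        reconstruct_ancestor("ATGAAATAA", "ATGAAATAA", None)


def test_ancestor_quality_on_simulated_triples(rng):
    match = tot = 0
    for _ in range(10):
        anc = simulate_ancestor_cds(200, rng, 12, 12)
        og = evolve_cds(anc.cds, 0.05, 0.5, rng)
        a = evolve_cds(anc.cds, 0.05, 0.5, rng)
        b = evolve_cds(anc.cds, 0.05, 0.5, rng)
        rec = reconstruct_ancestor(a, b, og)
        match += sum(x == y for x, y in zip(rec.sequence, anc.cds))
        tot += len(anc.cds)
    assert match / tot >= 0.99


def test_region_counts_are_additive(small_dataset):
    # Na/Ns over the entire span equal the sum over common + frameshifted
    from dupshift.classify import align_polarized, partition_regions, polarize_pair

    _, genes, truths, _ = small_dataset
    by_id = {g.gene_id: g for g in genes}
    t = truths[0]
    pp = polarize_pair(
        by_id[t.original_gene_id], by_id[t.derived_gene_id], by_id[t.outgroup_gene_id]
    )
    path = align_polarized(pp)
    part = partition_regions(pp, path)
    anc = reconstruct_ancestor(pp.original.cds, pp.derived.cds, pp.outgroup.cds)
    res = {(r.region, r.lineage): r for r in region_lineage_kaks(part, anc)}
    for lin in ("ancestor->original", "ancestor->derived"):
        whole = res[("entire", lin)].counts
        parts = res[("common", lin)].counts, res[("frameshifted", lin)].counts
        assert whole.na == pytest.approx(sum(p.na for p in parts), abs=1e-9)
        assert whole.ns == pytest.approx(sum(p.ns for p in parts), abs=1e-9)
        assert whole.la + whole.ls == pytest.approx(
            sum(p.la + p.ls for p in parts), abs=1e-9
        )


def test_derived_equals_ancestor_gives_zero_rates():
    a = simulate_ancestor_cds(100, seed=9).cds
    og = evolve_cds(a, 0.1, 0.5, seed=10)
    rec = reconstruct_ancestor(a, a, og)
    # both duplicates identical to the ancestor: zero divergence
    assert rec.sequence == a


def test_pool_counts_sums_before_rates():
    r1 = kaks_from_counts(SubstCounts(na=2, ns=0, la=200, ls=100), "common", "x")
    r2 = kaks_from_counts(SubstCounts(na=0, ns=3, la=200, ls=100), "common", "x")
    pooled = pool_counts([r1, r2], "common", "x")
    assert pooled.counts.na == 2 and pooled.counts.ns == 3
    assert pooled.ratio == pytest.approx(
        jukes_cantor(2 / 400) / jukes_cantor(3 / 200)
    )


def test_ratio_equality_test_degenerate_tables():
    c = SubstCounts(na=5, ns=3, la=100, ls=50)
    assert ratio_equality_test(c, c) == 1.0
    zero = SubstCounts()
    assert ratio_equality_test(zero, zero) == 1.0
    # zero margin in one row: no information, p = 1
    assert ratio_equality_test(SubstCounts(na=0, ns=0, la=10, ls=5), c) == 1.0


def test_ratio_equality_matches_hypergeometric_enumeration():
    # table [[10, 0], [0, 10]]: two-sided Fisher p by explicit tail sums
    a = SubstCounts(na=10, ns=0, la=100, ls=50)
    b = SubstCounts(na=0, ns=10, la=100, ls=50)
    got = ratio_equality_test(a, b)
    rv = hypergeom(20, 10, 10)
    p_obs = rv.pmf(10)
    expected = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= p_obs + 1e-12)
    assert got == pytest.approx(expected, rel=1e-6)


def test_positive_selection_test_directionality():
    # all-nonsynonymous observed vs mostly-synonymous opportunity
    c = SubstCounts(na=10, ns=0, la=150, ls=150)
    assert positive_selection_test(c) < 0.01
    assert positive_selection_test(SubstCounts()) == 1.0
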