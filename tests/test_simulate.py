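"""Synthetic duplicate-gene generator: validity, determinism, scenarios."""

import numpy as np
import pytest

from dupshift._codon import STOP_CODONS, codons_of, is_valid_cds, translate
from dupshift.fsalign import call_frameshift_events, protein_to_cds_align
from dupshift.records import InvalidConfigError
from dupshift.simulate import (
    SimulationConfig,
    apply_frameshift_scenario,
    evolve_cds,
    generate_dataset,
    generate_pairs,
    simulate_ancestor_cds,
)


def test_ancestor_cds_is_valid_and_stop_free():
    g = simulate_ancestor_cds(500, seed=7)
    cds = g.cds
    assert len(cds) == 1500
    assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
    assert all(c not in STOP_CODONS for c in codons_of(cds)[1:-1])
    assert is_valid_cds(cds)


def test_ancestor_determinism():
    a = simulate_ancestor_cds(50, seed=1)
    b = simulate_ancestor_cds(50, seed=1)
    assert a.cds == b.cds and a.flank5 == b.flank5 and a.flank3 == b.flank3


def test_ancestor_flank3_stops_in_all_frames():
    g = simulate_ancestor_cds(20, seed=3)
    for f in range(3):
        assert "*" in translate(g.flank3, f)


def test_ancestor_min_length_enforced():
    with pytest.raises(InvalidConfigError):
        simulate_ancestor_cds(9, seed=0)


def test_evolve_zero_branch_length_is_identity():
    g = simulate_ancestor_cds(60, seed=2)
    assert evolve_cds(g.cds, 0.0, 1.0, seed=5) == g.cds


def test_evolve_omega_zero_changes_are_synonymous():
    g = simulate_ancestor_cds(200, seed=4)
    out = evolve_cds(g.cds, 0.08, 0.0, seed=9)
    assert len(out) == len(g.cds)
    diffs = 0
    for c1, c2 in zip(codons_of(g.cds), codons_of(out)):
        if c1 != c2:
            diffs += 1
            assert translate(c1) == translate(c2)
    assert diffs > 0  # the branch is long enough that something happened
    assert is_valid_cds(out)


def test_evolve_preserves_validity_at_high_divergence():
    g = simulate_ancestor_cds(150, seed=6)
    out = evolve_cds(g.cds, 0.5, 1.0, seed=10)
    assert is_valid_cds(out)


def _scenario(stype, sizes, quants, seed=0, len_codons=200):
    # degenerate draws (e.g. premature stop inside the shifted region) raise;
    # callers redraw the randomness, as generate_pairs does
    from dupshift.records import ScenarioDegenerateError

    for attempt in range(30):
        gene = simulate_ancestor_cds(len_codons, seed=seed + attempt)
        try:
            der, truth = apply_frameshift_scenario(
                gene,
                {"type": stype, "sizes": sizes, "location_quantiles": quants},
                np.random.default_rng(seed + attempt),
            )
            return gene, der, truth
        except ScenarioDegenerateError:
            continue
    raise AssertionError("no viable scenario in 30 attempts")


def test_scenario_c_prefix_identity_and_shifted_tail():
    g, der, truth = _scenario("C", [-4], [0.9], seed=11)
    p = truth.events[0][0]
    assert der.cds[:p] == g.cds[:p]
    assert truth.type_label == "C"
    assert truth.events[0][2] == 2
    assert is_valid_cds(der.cds)
    # tail of the derived ORF reads the ancestral sequence in a shifted frame
    assert der.cds[p : p + 30] == g.cds[p + 4 : p + 34]


def test_scenario_m_compensation_preserves_length():
    g, der, truth = _scenario("M", [1, -1], [0.4, 0.55], seed=12)
    assert len(der.cds) == len(g.cds)
    assert truth.type_label == "M"
    # protein differs only between the two indels
    pa, pb = translate(g.cds), translate(der.cds)
    a_aa, b_aa = truth.frameshifted_interval_aa
    assert pa[: a_aa] == pb[: a_aa]
    assert pa[b_aa + 1 :] == pb[b_aa + 1 :]


def test_scenario_n_new_start_and_aligner_phase():
    g, der, truth = _scenario("N", [-1], [0.05], seed=13)
    assert is_valid_cds(der.cds)
    assert truth.type_label == "N"
    assert truth.frameshifted_interval_aa[0] == 0
    # the alignment oracle sees one event of phase 2 near the N-terminus
    prot = translate(g.cds)[:-1]
    events = call_frameshift_events(protein_to_cds_align(prot, der.cds))
    assert len(events) == 1
    assert events[0].phase == 2
    assert events[0].cds_position < len(der.cds) // 4


def test_scenario_precondition_errors():
    g = simulate_ancestor_cds(100, seed=14)
    with pytest.raises(InvalidConfigError):
        apply_frameshift_scenario(
            g, {"type": "C", "sizes": [3], "location_quantiles": [0.5]}, 1
        )  # in-frame size
    with pytest.raises(InvalidConfigError):
        apply_frameshift_scenario(
            g, {"type": "M", "sizes": [1, 1], "location_quantiles": [0.4, 0.5]}, 1
        )  # does not compensate


def test_generate_dataset_empty_and_deterministic(tmp_path):
    cfg = SimulationConfig(seed=42, n_pairs=0)
    genes, truth = generate_dataset(cfg, tmp_path / "a")
    assert genes == [] and truth.empty
    cfg = SimulationConfig(seed=42, n_pairs=6, ancestor_len_codons=120)
    generate_dataset(cfg, tmp_path / "b1")
    generate_dataset(cfg, tmp_path / "b2")
    for name in ("genes.fa", "truth.tsv"):
        assert (tmp_path / "b1" / name).read_bytes() == (
            tmp_path / "b2" / name
        ).read_bytes()


def test_scenario_mix_all_type_c():
    cfg = SimulationConfig(
        seed=8, n_pairs=10, ancestor_len_codons=120, scenario_mix={"C": 1.0}
    )
    _, truths = generate_pairs(cfg)
    assert all(t.type_label == "C" for t in truths)


def test_frame_bookkeeping_invariant(small_dataset):
    _, _, truths, _ = small_dataset
    for t in truths:
        total = sum(size for _, size, _ in t.events)
        if t.type_label == "M":
            assert total % 3 == 0
        else:
            assert total % 3 != 0
        for _, size, phase in t.events:
            assert phase == size % 3 and phase in (1, 2)


def test_all_emitted_cds_are_valid(small_dataset):
    _, genes, _, _ = small_dataset
    assert all(g.is_valid() for g in genes)


def test_config_validation():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(indel_sizes=(3,)).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(scenario_mix={"C": 0.5}).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(ancestor_len_codons=5).validate()
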