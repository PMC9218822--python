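"""Intergenic extraction, frame translation, fragment gates, and
disruption reconstruction."""

from __future__ import annotations

import pytest

from propamp.assembly import PropellerAnnotation
from propamp.fragments import (IntergenicRegion, extract_intergenic,
                               reconstruct_disruption, scan_fragments,
                               translate_frames)
from propamp.profiles import SearchConfig, build_profile
from propamp.simulate import (Disruption, EvolutionSpec, GeneRecord,
                              amplify_and_diverge, build_genome,
                              inject_disruption, make_ancestral_blade)


def test_translate_frames_with_stops():
    translations, stops = translate_frames("ATGTAAGGG")
    assert translations[0] == "MXG"
    assert stops[0] == [1]
    assert translations[1] == "CK"  # TGT AAG (+ leftover GG)
    assert stops[1] == []


def test_intergenic_regions_have_expected_lengths():
    genes = [GeneRecord("a", 300, 600), GeneRecord("b", 900, 1200),
             GeneRecord("c", 1350, 1650)]
    regions = extract_intergenic("N" * 2000, genes, "b")
    sides = {r.side: r for r in regions}
    assert sides["five_prime"].length == 300
    assert sides["three_prime"].length == 150
    # abutting genes: that side is omitted
    regions2 = extract_intergenic(
        "N" * 2000, [GeneRecord("a", 300, 900)] + genes[1:], "b")
    assert [r.side for r in regions2] == ["three_prime"]


def test_unknown_anchor_rejected():
    with pytest.raises(KeyError):
        extract_intergenic("N" * 100, [GeneRecord("a", 0, 30)], "zz")


def test_generator_truth_intervals_recovered():
    spec = EvolutionSpec(n_blades=10, per_site_sub_rate=0.04, rng_seed=6,
                         disruption=Disruption("inframe_stop", 5))
    blade = make_ancestral_blade(spec)
    _, orf, truth = amplify_and_diverge(blade, spec, protein_id="g")
    segment, truth = inject_disruption(orf, spec.disruption, truth)
    genome = build_genome([("g", segment, truth)], spacer_nt=120,
                          rng_seed=3)
    regions = extract_intergenic(genome.sequence, genome.genes, "g")
    three = next(r for r in regions if r.side == "three_prime")
    tr = genome.truths["g"]
    for s, e in tr.intergenic_fragment_intervals:
        assert three.start <= s < e <= three.end
    # every stranded blade re-translates to protein sequence in exactly
    # one forward frame (no stops inside)
    for s, e in tr.intergenic_fragment_intervals:
        frames_clean = 0
        for f in range(3):
            aa, stops = translate_frames(genome.sequence[s + f:e])
            frames_clean += "X" not in aa[0][: (e - s) // 3 - 1]
        assert frames_clean >= 1


def test_fragment_gates_behave_at_boundaries(search_config):
    aa, _ = make_ancestral_blade(EvolutionSpec(blade_length_aa=40,
                                               rng_seed=2))
    profile = build_profile([aa], search_config)

    def region(translation, stop_positions):
        return IntergenicRegion("g", 0, 3 * len(translation),
                                "three_prime", "+",
                                "N" * (3 * len(translation)),
                                [translation, "", ""],
                                [stop_positions, [], []])

    # length gate: >=20 residues inclusive by default, strict on demand
    ok20 = scan_fragments([region(aa[:20], [])], {"b": profile},
                          search_config, min_len=20)
    no19 = scan_fragments([region(aa[:19], [])], {"b": profile},
                          search_config, min_len=20)
    strict20 = scan_fragments([region(aa[:20], [])], {"b": profile},
                              search_config, min_len=20, strict_len=True)
    assert len(ok20) == 1 and not no19 and not strict20

    # stop-content gate: 15% retained, above 15% rejected
    ok15 = scan_fragments([region(aa[:20], [2, 9, 15])], {"b": profile},
                          search_config)
    no20pct = scan_fragments([region(aa[:20], [2, 6, 9, 15])],
                             {"b": profile}, search_config)
    assert len(ok15) == 1
    assert ok15[0].stop_content == pytest.approx(0.15)
    assert not no20pct


def _disruption_case(kind: str, seed: int):
    spec = EvolutionSpec(n_blades=12, per_site_sub_rate=0.05,
                         rng_seed=seed, disruption=Disruption(kind, 6))
    blade = make_ancestral_blade(spec)
    _, orf, truth = amplify_and_diverge(blade, spec,
                                        protein_id=f"g{seed}")
    segment, truth = inject_disruption(orf, spec.disruption, truth)
    genome = build_genome([(f"g{seed}", segment, truth)], spacer_nt=150,
                          rng_seed=seed)
    return blade, genome


def _reconstruct(blade, genome, config):
    anchor = genome.genes[0]
    truth = genome.truths[anchor.gene_id]
    prop = PropellerAnnotation(anchor.gene_id, truth.blade_intervals[0])
    profile = build_profile([blade[0]], config)
    regions = extract_intergenic(genome.sequence, genome.genes,
                                 anchor.gene_id)
    frs = scan_fragments(regions, {"blade": profile}, config, max_p=0.5)
    return truth, reconstruct_disruption(anchor, prop, frs,
                                         genome.sequence)


def test_inframe_stop_reconstructed_as_six_plus_six(search_config):
    """The emulated half-way stop: six annotated blades plus six stranded
    ones reconstruct a 12-bladed propeller."""
    blade, genome = _disruption_case("inframe_stop", seed=41)
    truth, report = _reconstruct(blade, genome, search_config)
    assert report.kind == "inframe_stop"
    assert len(truth.blade_intervals[0]) == 6
    assert truth.n_fragment_blades == 6
    assert report.reconstructed_blade_count == 12
    assert report.inferred_event_position == truth.disruption_events[0][1]


def test_frameshift_event_position_within_3nt(search_config):
    hits = 0
    trials = 10
    for seed in range(trials):
        blade, genome = _disruption_case("frameshift_deletion",
                                         seed=700 + seed)
        truth, report = _reconstruct(blade, genome,
                                     SearchConfig(rng_seed=seed))
        want_kind, want_pos = truth.disruption_events[0]
        hits += (report.kind == want_kind
                 and report.inferred_event_position is not None
                 and abs(report.inferred_event_position - want_pos) <= 3)
    assert hits >= trials - 1


def test_no_fragments_means_no_disruption(search_config):
    anchor = GeneRecord("g", 100, 600)
    prop = PropellerAnnotation("g", [(1, 41), (43, 83)])
    report = reconstruct_disruption(anchor, prop, [], "N" * 1000)
    assert report.kind == "none"
    assert report.evidence == []
    assert report.reconstructed_blade_count == 0


def test_undisrupted_genome_reports_none(search_config):
    spec = EvolutionSpec(n_blades=7, per_site_sub_rate=0.05, rng_seed=8)
    blade = make_ancestral_blade(spec)
    _, orf, truth = amplify_and_diverge(blade, spec, protein_id="g8")
    genome = build_genome([("g8", orf, truth)], spacer_nt=150, rng_seed=8)
    truth2, report = _reconstruct(blade, genome, search_config)
    assert report.kind == "none"
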