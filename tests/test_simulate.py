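"""The generator's outputs must obey the evolutionary model they emulate."""

from __future__ import annotations

import numpy as np
import pytest

from propamp.alphabet import STOP_CODONS, translate
from propamp.msa import pairwise_identity
from propamp.simulate import (ConfigurationError, Disruption,
                              EvolutionSpec, amplify_and_diverge,
                              build_genome, inject_disruption,
                              make_ancestral_blade, mutate_dna)


@pytest.mark.parametrize("length,seed", [(40, 1), (45, 2), (50, 3)])
def test_ancestral_blade_translates_and_is_deterministic(length, seed):
    spec = EvolutionSpec(blade_length_aa=length, rng_seed=seed)
    aa, dna = make_ancestral_blade(spec)
    assert len(aa) == length and len(dna) == 3 * length
    assert translate(dna) == aa
    assert make_ancestral_blade(spec) == (aa, dna)


def test_default_blade_length_in_range():
    for seed in range(8):
        aa, _ = make_ancestral_blade(EvolutionSpec(rng_seed=seed))
        assert 40 <= len(aa) <= 50


@pytest.mark.parametrize("bad", [
    dict(n_blades=0), dict(unit_blades=3), dict(per_site_sub_rate=1.5),
    dict(unit_blades=2, n_blades=7), dict(synonymous_fraction=-0.1)])
def test_invalid_specs_rejected(bad):
    with pytest.raises(ConfigurationError):
        EvolutionSpec(**bad).validate()


def test_zero_rate_gives_identical_blades():
    spec = EvolutionSpec(blade_length_aa=40, n_blades=7,
                         per_site_sub_rate=0.0, rng_seed=5)
    protein, orf, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                              spec)
    assert truth.true_median_identity == 1.0
    blades = [protein[s:e] for s, e in truth.blade_intervals[0]]
    assert len(set(blades)) == 1
    assert translate(orf[:-3]) == protein
    assert orf.startswith("ATG") and orf[-3:] in STOP_CODONS


def test_realized_identity_matches_independent_aligner(seven_blade):
    """Truth identity must equal an all-pairs global-alignment recount."""
    truth = seven_blade["truth"]
    protein = seven_blade["protein"]
    blades = [protein[s:e] for s, e in truth.blade_intervals[0]]
    ids = [pairwise_identity(a, b)
           for i, a in enumerate(blades) for b in blades[i + 1:]]
    assert abs(truth.true_median_identity - float(np.median(ids))) < 1e-9


def test_two_blade_unit_structure():
    """With diverged odd/even blades, consecutive 2-blade units are more
    alike than consecutive single blades."""
    spec = EvolutionSpec(blade_length_aa=40, n_blades=6, unit_blades=2,
                         per_site_sub_rate=0.02, unit_divergence=0.3,
                         rng_seed=7)
    protein, _, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                            spec)
    ivs = truth.blade_intervals[0]
    assert len(ivs) == 6
    blades = [protein[s:e] for s, e in ivs]
    units = [blades[i] + blades[i + 1] for i in range(0, 6, 2)]
    unit_ids = [pairwise_identity(a, b)
                for i, a in enumerate(units) for b in units[i + 1:]]
    cross_ids = [pairwise_identity(blades[i], blades[i + 1])
                 for i in range(1, 5, 2)]  # odd->even neighbours
    assert min(unit_ids) > max(cross_ids)


def test_identity_decreases_with_rate():
    """Mean realized identity is monotone in the substitution rate."""
    means = []
    for rate in (0.0, 0.05, 0.15, 0.30):
        vals = []
        for rep in range(25):
            spec = EvolutionSpec(blade_length_aa=40, n_blades=5,
                                 per_site_sub_rate=rate,
                                 rng_seed=1000 + rep)
            _, _, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                              spec)
            vals.append(truth.true_median_identity)
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_fully_synonymous_divergence_keeps_protein_identical():
    spec = EvolutionSpec(blade_length_aa=40, n_blades=6,
                         per_site_sub_rate=0.3, synonymous_fraction=1.0,
                         rng_seed=3)
    protein, orf, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                              spec)
    assert truth.true_median_identity == 1.0
    ivs = truth.blade_intervals[0]
    dnas = [orf[3 * s:3 * e] for s, e in ivs]
    assert len(set(dnas)) > 1  # DNA has diverged, protein has not


def test_high_rate_warns():
    spec = EvolutionSpec(per_site_sub_rate=0.9, synonymous_fraction=0.0,
                         rng_seed=1)
    with pytest.warns(UserWarning):
        amplify_and_diverge(make_ancestral_blade(spec), spec)


def test_mutate_dna_never_creates_stops():
    rng = np.random.default_rng(0)
    spec = EvolutionSpec(blade_length_aa=60, rng_seed=8)
    _, dna = make_ancestral_blade(spec)
    for _ in range(20):
        out = mutate_dna(dna, 0.5, 0.3, rng)
        assert "*" not in translate(out)


# --------------------------------------------------------------------------
# disruption


def _disrupted(kind, n_blades=7, blade_index=4, seed=17):
    spec = EvolutionSpec(blade_length_aa=40, n_blades=n_blades,
                         per_site_sub_rate=0.05, rng_seed=seed,
                         disruption=Disruption(kind, blade_index))
    blade = make_ancestral_blade(spec)
    protein, orf, truth = amplify_and_diverge(blade, spec)
    segment, truth = inject_disruption(orf, spec.disruption, truth)
    return orf, segment, truth


def test_frameshift_strands_downstream_blades():
    orf, segment, truth = _disrupted("frameshift_deletion")
    assert len(segment) < len(orf)
    assert (len(orf) - len(segment)) % 3 != 0
    # observed protein ends near the event; later blades persist as
    # out-of-frame DNA downstream of the observed stop
    assert truth.observed_orf_end is not None
    assert len(truth.blade_intervals[0]) < 7
    assert truth.intergenic_fragment_intervals
    for s, e in truth.intergenic_fragment_intervals:
        assert s >= truth.observed_orf_end


def test_inframe_stop_splits_blades_six_six():
    """A stop planted before blade 7 of 12 leaves 6 translated blades and
    6 blade-coding fragments beyond the stop."""
    _, segment, truth = _disrupted("inframe_stop", n_blades=12,
                                   blade_index=6)
    assert len(truth.blade_intervals[0]) == 6
    assert truth.n_fragment_blades == 6
    kind, pos = truth.disruption_events[0]
    assert kind == "inframe_stop"
    assert segment[pos:pos + 3] == "TAA"
    assert truth.observed_orf_end == pos + 3


def test_no_disruption_keeps_segment_identical(seven_blade):
    assert seven_blade["truth"].disruption_events == []


def test_disruption_position_outside_orf_rejected(seven_blade):
    with pytest.raises(ConfigurationError):
        inject_disruption(seven_blade["orf"],
                          Disruption("inframe_stop", 99),
                          seven_blade["truth"])


# --------------------------------------------------------------------------
# genome assembly


def _two_gene_genome(spacer=200, seed=4):
    genes = []
    for i in range(2):
        spec = EvolutionSpec(blade_length_aa=40, n_blades=4 + i,
                             per_site_sub_rate=0.03, rng_seed=seed + i)
        _, orf, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                            spec, protein_id=f"g{i}")
        genes.append((f"g{i}", orf, truth))
    return genes, build_genome(genes, spacer_nt=spacer, rng_seed=seed)


def test_genome_length_arithmetic():
    genes, genome = _two_gene_genome()
    total = sum(len(seg) for _, seg, _ in genes) + 3 * 200
    assert len(genome.sequence) == total
    for (gid, seg, _), rec in zip(genes, genome.genes):
        assert genome.sequence[rec.start:rec.end] == seg
        assert translate(genome.sequence[rec.start:rec.end - 3]) == \
            genome.protein_of(gid)


def test_genome_roundtrip_and_determinism(tmp_path):
    from propamp.io import (read_fasta, read_gene_table, read_truth,
                            write_genome)

    _, genome = _two_gene_genome()
    paths = write_genome(genome, tmp_path)
    assert read_fasta(paths["genome"])[genome.genome_id] == genome.sequence
    _, genes = read_gene_table(paths["genes"])
    assert [(g.gene_id, g.start, g.end) for g in genes] == \
        [(g.gene_id, g.start, g.end) for g in genome.genes]
    truths = read_truth(paths["truth"])
    assert truths["g0"] == genome.truths["g0"]
    # byte-identical regeneration
    _, genome2 = _two_gene_genome()
    assert genome2.sequence == genome.sequence


def test_duplicate_gene_ids_rejected():
    genes, _ = _two_gene_genome()
    dup = [genes[0], (genes[0][0], genes[1][1], genes[1][2])]
    with pytest.raises(ValueError):
        build_genome(dup)
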