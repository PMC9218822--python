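"""Codon-level mutation calls and the independence criterion."""

from __future__ import annotations

import numpy as np
import pytest

from propamp.codons import (AlignmentError, CodonBladeAlignment,
                            amplification_independence_report,
                            build_codon_alignment, call_mutations,
                            extract_blade_dna, find_diagnostic_positions)
from propamp.simulate import (EvolutionSpec, amplify_and_diverge,
                              make_ancestral_blade, make_independent_pair,
                              make_shared_pair)


def test_blade_dna_extraction_arithmetic(seven_blade):
    truth = seven_blade["truth"]
    orf, prot = seven_blade["orf"], seven_blade["protein"]
    dnas = extract_blade_dna(orf, truth.blade_intervals[0], prot)
    for (s, e), dna in zip(truth.blade_intervals[0], dnas):
        assert dna == orf[3 * s:3 * e]
        assert len(dna) == 3 * (e - s)


def test_frame_shifted_interval_raises(seven_blade):
    truth = seven_blade["truth"]
    (s, e) = truth.blade_intervals[0][0]
    with pytest.raises(AlignmentError):
        extract_blade_dna(seven_blade["orf"], [(s + 1, e + 1)],
                          seven_blade["protein"][1:] + "A")


def test_synonymous_and_nonsynonymous_calls():
    # GCT (Ala) consensus; GCC stays Ala, GAT becomes Asp
    aln = CodonBladeAlignment(["b1", "b2", "b3"], ["P"] * 3,
                              ["GCT", "GCT", "GCC"])
    calls = call_mutations(aln, "P")
    assert [(c.blade_id, c.kind, c.column)
            for c in calls] == [("b3", "synonymous", 2)]
    aln2 = CodonBladeAlignment(["b1", "b2", "b3"], ["P"] * 3,
                               ["GCT", "GCT", "GAT"])
    calls2 = call_mutations(aln2, "P")
    assert [(c.blade_id, c.kind, c.column)
            for c in calls2] == [("b3", "nonsynonymous", 1)]


def test_non_acgt_rejected():
    aln = CodonBladeAlignment(["a", "b"], ["P", "P"], ["GNT", "GCT"])
    with pytest.raises(AlignmentError):
        call_mutations(aln, "P")


def test_calls_match_exhaustive_codon_oracle():
    """Every single-base codon variant agrees with translate-and-compare."""
    from propamp.experiments import oracle_codon_calls

    assert oracle_codon_calls() == 1.0


def test_conservation_of_mismatch_counts(seven_blade):
    truth, prot, orf = (seven_blade["truth"], seven_blade["protein"],
                        seven_blade["orf"])
    ivs = truth.blade_intervals[0]
    dnas = extract_blade_dna(orf, ivs, prot)
    rows = [(f"b{i}", "P", prot[s:e], d)
            for i, ((s, e), d) in enumerate(zip(ivs, dnas))]
    aln = build_codon_alignment(rows)
    calls = call_mutations(aln, "P")
    mismatches = 0
    seqs = aln.rows
    for c in range(aln.n_columns):
        bases = [r[c] for r in seqs if r[c] != "-"]
        if not bases:
            continue
        counts = {b: bases.count(b) for b in set(bases)}
        top = max(counts.values())
        cons = sorted(b for b, n in counts.items() if n == top)[0]
        mismatches += sum(1 for b in bases if b != cons)
    assert len(calls) == mismatches


def test_blade_order_does_not_change_counts(seven_blade):
    truth, prot, orf = (seven_blade["truth"], seven_blade["protein"],
                        seven_blade["orf"])
    ivs = truth.blade_intervals[0]
    dnas = extract_blade_dna(orf, ivs, prot)
    rows = [(f"b{i}", "P", prot[s:e], d)
            for i, ((s, e), d) in enumerate(zip(ivs, dnas))]
    base = call_mutations(build_codon_alignment(rows), "P")
    rng = np.random.default_rng(1)
    for _ in range(3):
        perm = list(rows)
        rng.shuffle(perm)
        calls = call_mutations(build_codon_alignment(perm), "P")
        assert sorted((c.kind, c.column) for c in calls) == \
            sorted((c.kind, c.column) for c in base)


# --------------------------------------------------------------------------
# diagnostic positions


def _aln(columns: dict[str, list[str]]) -> CodonBladeAlignment:
    """Build a 3-base-per-blade alignment from per-propeller codon rows."""
    blade_ids, prop_ids, rows = [], [], []
    for pid, blades in columns.items():
        for i, row in enumerate(blades):
            blade_ids.append(f"{pid}b{i}")
            prop_ids.append(pid)
            rows.append(row)
    return CodonBladeAlignment(blade_ids, prop_ids, rows)


def test_diagnostic_position_flagged():
    aln = _aln({"P1": ["AAA"] * 3, "P2": ["GAA"] * 3, "P3": ["GAA"] * 3})
    calls = find_diagnostic_positions(aln)
    flagged = {(c.blade_id, c.column) for c in calls}
    assert ("P1", 0) in flagged
    # column 1 and 2 are identical everywhere: never diagnostic
    assert all(c.column == 0 for c in calls)


def test_identical_columns_not_diagnostic():
    aln = _aln({"P1": ["ACG"] * 2, "P2": ["ACG"] * 2, "P3": ["ACG"] * 2})
    assert find_diagnostic_positions(aln) == []


def test_two_propellers_require_explicit_min_other():
    aln = _aln({"P1": ["AAA"] * 2, "P2": ["GAA"] * 2})
    with pytest.raises(AlignmentError):
        find_diagnostic_positions(aln)
    calls = find_diagnostic_positions(aln, min_other=1)
    assert any(c.blade_id == "P1" and c.column == 0 for c in calls)


def test_two_thirds_threshold_is_inclusive():
    # 4 of 6 blades share the base: exactly 2/3, qualifies
    aln = _aln({"P1": ["A"] * 4 + ["G"] * 2, "P2": ["G"] * 3,
                "P3": ["G"] * 3})
    assert any(c.blade_id == "P1"
               for c in find_diagnostic_positions(aln))
    # 3 of 6 falls below 2/3: does not qualify
    aln2 = _aln({"P1": ["A"] * 3 + ["G"] * 3, "P2": ["G"] * 3,
                 "P3": ["G"] * 3})
    assert not any(c.blade_id == "P1"
                   for c in find_diagnostic_positions(aln2))


# --------------------------------------------------------------------------
# independence report


def _report(pair):
    props = []
    for prot, orf, truth in pair:
        ivs = truth.blade_intervals[0]
        dnas = extract_blade_dna(orf, ivs, prot)
        props.append((truth.protein_id,
                      [(f"{truth.protein_id}b{i}", prot[s:e], d)
                       for i, ((s, e), d) in enumerate(zip(ivs, dnas))]))
    return amplification_independence_report(props)


def test_identical_propellers_are_indistinguishable():
    spec = EvolutionSpec(n_blades=5, per_site_sub_rate=0.0, rng_seed=3)
    prot, orf, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                           spec, protein_id="t")
    from dataclasses import replace
    rep = _report([(prot, orf, truth),
                   (prot, orf, replace(truth, protein_id="t2"))])
    assert rep["verdict"] == "indistinguishable"
    assert rep["n_diagnostic_positions"] == 0
    for stats in rep["per_propeller"].values():
        assert stats["synonymous"] == stats["nonsynonymous"] == 0


def test_independent_pair_detected():
    spec = EvolutionSpec(n_blades=7, per_site_sub_rate=0.03, rng_seed=5)
    rep = _report(make_independent_pair(spec))
    assert rep["verdict"] == "independent"
    assert rep["n_diagnostic_positions"] >= 1
    # blades of the pair stayed closely related overall
    assert min(rep["ungapped_protein_identity"].values()) > 0.7


def test_shared_pair_shows_fewer_diagnostics_than_independent():
    wins = 0
    trials = 20
    for rep_i in range(trials):
        spec = EvolutionSpec(n_blades=7, per_site_sub_rate=0.03,
                             rng_seed=4000 + rep_i)
        ind = _report(make_independent_pair(spec))
        sha = _report(make_shared_pair(spec))
        wins += (ind["n_diagnostic_positions"]
                 > sha["n_diagnostic_positions"])
    assert wins >= 0.95 * trials


def test_fully_synonymous_amplification_signature():
    """No synonymous substitutions at the DNA level: the signature of a
    very recent amplification."""
    spec = EvolutionSpec(n_blades=8, per_site_sub_rate=0.0, rng_seed=9)
    prot, orf, truth = amplify_and_diverge(make_ancestral_blade(spec),
                                           spec, protein_id="w")
    ivs = truth.blade_intervals[0]
    dnas = extract_blade_dna(orf, ivs, prot)
    aln = build_codon_alignment(
        [(f"b{i}", "W", prot[s:e], d)
         for i, ((s, e), d) in enumerate(zip(ivs, dnas))])
    assert call_mutations(aln, "W") == []
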