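"""End-to-end orchestration: search → assemble → refine → classify → DNA.

The pipeline ties the stages together on one input set: iterative profile
search for blade matches, robust linker-based grouping into propellers
with the strict 60% median-identity filter, de-novo repeat refinement,
family/locality classification, and — when coding DNA and a gene table
are available — the codon-level independence analysis and the intergenic
fragment scan. Every threshold decision is counted in the run log, and
the bundle embeds the exact configuration and seed used, so a rerun at
the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from propamp import assembly, classify, codons, fragments, refine
from propamp.assembly import PropellerAnnotation, UndefinedStatsError
from propamp.classify import DomainMatch
from propamp.config import RunConfig
from propamp.fragments import DisruptionReport, FragmentMatch
from propamp.io import (matches_to_frame, propellers_to_frame,
                        write_fragments_bed, write_matches_bed,
                        write_propellers_gff3)
from propamp.profiles import (BladeMatch, Profile, build_profile,
                              iterate_search, rescan_unmatched)
from propamp.simulate import GeneRecord
from propamp.stats import median


@dataclass
class ResultBundle:
    config: RunConfig
    matches: list[BladeMatch] = field(default_factory=list)
    propellers: list[PropellerAnnotation] = field(default_factory=list)
    domain_maps: dict[str, list[DomainMatch]] = field(default_factory=dict)
    independence: dict | None = None
    fragments: list[FragmentMatch] = field(default_factory=list)
    disruptions: list[DisruptionReport] = field(default_factory=list)
    log: dict[str, int | str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "matches": [vars(m) for m in self.matches],
            "propellers": [p.to_dict() for p in self.propellers],
            "domain_maps": {k: [vars(d) for d in v]
                            for k, v in self.domain_maps.items()},
            "independence": self.independence,
            "fragments": [vars(f) for f in self.fragments],
            "disruptions": [{
                "anchor_protein_id": d.anchor_protein_id,
                "kind": d.kind,
                "inferred_event_position": d.inferred_event_position,
                "reconstructed_blade_count": d.reconstructed_blade_count,
                "n_fragments": len(d.evidence),
            } for d in self.disruptions],
            "log": self.log,
        }


def run_pipeline(seeds: list[str], proteins: dict[str, str] | None = None,
                 genome_seq: str | None = None,
                 genes: list[GeneRecord] | None = None,
                 orf_dna: dict[str, str] | None = None,
                 family_profiles: dict[str, Profile] | None = None,
                 config: RunConfig | None = None) -> ResultBundle:
    """Run the full analysis on proteins or on a genome with a gene table.

    With a genome, proteins and coding DNA are derived from the CDS
    records; with proteins only, the DNA-level stages are skipped (noted
    in the run log).
    """
    from propamp.alphabet import translate

    config = config or RunConfig()
    scfg = config.search_config()
    bundle = ResultBundle(config=config)
    log = bundle.log

    if genome_seq is not None:
        if genes is None:
            raise ValueError("a genome needs a gene table")
        proteins = {g.gene_id: translate(genome_seq[g.start:g.end - 3])
                    for g in genes}
        orf_dna = {g.gene_id: genome_seq[g.start:g.end] for g in genes}
    if not proteins:
        raise ValueError("no input proteins")

    # --- search ------------------------------------------------------------
    matches = iterate_search(seeds, proteins, scfg)
    log["matches_after_iteration"] = len(matches)
    blade_seqs = sorted({proteins[m.protein_id][m.start:m.end]
                         for m in matches}) or list(seeds)
    profile = build_profile(blade_seqs, scfg)
    matches = rescan_unmatched(matches, proteins, profile, scfg)
    log["matches_after_rescan"] = len(matches)
    bundle.matches = matches

    # --- assembly ----------------------------------------------------------
    try:
        stats = assembly.linker_statistics(matches)
    except UndefinedStatsError:
        log["note"] = "no linkers; no propellers assembled"
        return bundle
    candidates = assembly.group_into_propellers(
        matches, stats, mades=config.linker_mades,
        two_sided=config.linker_two_sided)
    assembly.annotate_identity(candidates, proteins)
    retained = assembly.filter_highly_repetitive(
        candidates, config.identity_threshold)
    log["propellers_candidate"] = len(candidates)
    log["propellers_rejected_identity"] = len(candidates) - len(retained)

    # --- refinement --------------------------------------------------------
    refined: list[PropellerAnnotation] = []
    for pid in sorted({p.protein_id for p in retained}):
        props = [p for p in retained if p.protein_id == pid]
        seq = proteins[pid]
        mbl = median([e - s for p in props for s, e in p.blade_intervals])
        units = refine.detect_self_repeats(
            seq, scfg, repeat_p=config.repeat_p,
            min_period=config.min_repeat_period, protein_id=pid)
        units = refine.decompose_units(units, mbl, seq, scfg,
                                       repeat_p=config.repeat_p,
                                       max_depth=config.max_decompose_depth)
        refined.extend(refine.merge_annotations(
            props, units, seq, protein_id=pid,
            identity_threshold=config.identity_threshold))
    log["propellers_retained"] = len(refined)
    bundle.propellers = refined

    # --- classification ----------------------------------------------------
    for p in refined:
        seq = proteins[p.protein_id]
        if family_profiles:
            p.family, _ = classify.assign_family(
                seq[p.start:p.end], family_profiles, scfg,
                family_gate=config.family_gate)
        if family_profiles:
            bundle.domain_maps[p.protein_id] = classify.annotate_flanks(
                seq, [(q.start, q.end) for q in refined
                      if q.protein_id == p.protein_id],
                family_profiles, scfg, family_gate=config.family_gate,
                min_len=config.flank_min_len, min_cov=config.flank_min_cov,
                max_iter=config.flank_max_iter)
        p.locality = classify.classify_locality(
            p, seq, profile, scfg,
            identity_threshold=config.identity_threshold,
            retained=refined)
    classify.terminus_census(
        refined, {pid: len(s) for pid, s in proteins.items()},
        config.termini_thresholds)

    # --- DNA-level stages ---------------------------------------------------
    if orf_dna is None:
        log["dna_stages"] = "skipped (no coding DNA supplied)"
        return bundle

    with_dna = []
    for p in refined:
        dna = orf_dna.get(p.protein_id)
        if dna is None:
            continue
        try:
            blade_dnas = codons.extract_blade_dna(
                dna, p.blade_intervals, proteins[p.protein_id])
        except codons.AlignmentError:
            continue
        blades = [(f"{p.protein_id}:b{i}",
                   proteins[p.protein_id][s:e], d)
                  for i, ((s, e), d) in enumerate(zip(p.blade_intervals,
                                                      blade_dnas))]
        with_dna.append((f"{p.protein_id}:{p.start}", blades))
    if len(with_dna) >= 2:
        bundle.independence = codons.amplification_independence_report(
            with_dna, min_diagnostic=config.min_diagnostic_positions)
    log["propellers_with_dna"] = len(with_dna)

    if genome_seq is not None and genes is not None:
        for g in sorted(genes, key=lambda g: g.gene_id):
            props = [p for p in refined if p.protein_id == g.gene_id]
            if not props:
                continue
            anchor_prop = max(props, key=lambda p: p.n_blades)
            regions = fragments.extract_intergenic(genome_seq, genes,
                                                   g.gene_id)
            frs = fragments.scan_fragments(
                regions, {"blade": profile}, scfg,
                min_len=config.fragment_min_len,
                strict_len=config.fragment_min_len_strict,
                max_stop=config.fragment_max_stop,
                max_p=config.fragment_max_p,
                min_cov=config.fragment_min_cov)
            bundle.fragments.extend(frs)
            bundle.disruptions.append(fragments.reconstruct_disruption(
                g, anchor_prop, frs, genome_seq))
        log["fragments_found"] = len(bundle.fragments)
    return bundle


# --------------------------------------------------------------------------
# summaries


def summarize(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """Summary tables: blade-count histogram split by locality class,
    identity distribution, terminal-distance histogram, and fragment
    confidence histogram."""
    props = bundle.propellers
    blade_hist = (pd.DataFrame([{"n_blades": p.n_blades,
                                 "locality": p.locality} for p in props])
                  .groupby(["locality", "n_blades"]).size()
                  .rename("count").reset_index()
                  if props else pd.DataFrame(
                      columns=["locality", "n_blades", "count"]))
    identity = pd.DataFrame(
        [{"protein_id": p.protein_id,
          "median_identity": p.median_blade_identity} for p in props])
    termdist = pd.DataFrame(
        [{"protein_id": p.protein_id,
          "min_terminus_distance": p.min_terminus_distance}
         for p in props])
    frag_conf = pd.DataFrame(
        [{"confidence": f.confidence} for f in bundle.fragments])
    return {"blade_histogram": blade_hist, "identity": identity,
            "terminus_distance": termdist,
            "fragment_confidence": frag_conf}


def write_bundle(bundle: ResultBundle, outdir: str | Path) -> None:
    """Write the GFF3 + TSV + BED + JSON result files for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_propellers_gff3(bundle.propellers, outdir / "propellers.gff3")
    propellers_to_frame(bundle.propellers).to_csv(
        outdir / "propellers.tsv", sep="\t", index=False)
    matches_to_frame(bundle.matches).to_csv(
        outdir / "matches.tsv", sep="\t", index=False)
    write_matches_bed(bundle.matches, outdir / "matches.bed")
    write_fragments_bed(bundle.fragments, outdir / "fragments.bed")
    (outdir / "report.json").write_text(
        json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True,
                   default=str) + "\n")
    for name, frame in summarize(bundle).items():
        frame.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)
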