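# propamp

Detection and evolutionary analysis of **recently amplified, highly
repetitive β-propeller domains** in protein and genome sequences.

β-propellers are toroidal folds of 4–12 tandem "blades" — four-stranded
antiparallel β-meanders of typically 40–50 residues. New propellers arise
by **amplification** of the DNA coding for a single blade (or a two-blade
unit) followed by **differentiation** of the copies through substitutions.
A propeller caught early in this cycle has near-identical blades at both
the protein and DNA level; later events leave local runs of identical
blades inside otherwise divergent domains, and some amplified genes are
subsequently disrupted, stranding blade-coding DNA in non-coding regions.

`propamp` implements the complete desk-scale analysis of this process:

1. **simulate** — a synthetic-genome generator that emulates blade
   amplification, controlled synonymous/non-synonymous divergence,
   independent amplification of homologs, and gene disruption, emitting
   FASTA/GFF3/JSON with full ground truth;
2. **search** — iterative PSSM construction (half-bit log-odds, BLOSUM62
   background, pseudocounts) and Smith–Waterman scanning with empirical
   shuffle-null significance, plus second-pass rescans of over-long
   matches, long linkers, and termini;
3. **assemble** — grouping of consecutive blade matches into propellers by
   robust linker statistics (median ± 3 MADe), with the strict
   \>60% median blade-identity criterion for "highly repetitive";
4. **refine** — de-novo repeat detection by masked self-alignment,
   blades-per-unit estimation, recursive unit decomposition, and merging
   with the profile-based annotation to recover degenerate blades;
5. **classify** — family assignment against user-supplied profiles, flank
   domain annotation, global/local/mixed locality labels, and
   terminal-proximity statistics;
6. **dna** — codon-aware comparison of blade DNA: synonymous vs
   non-synonymous calls against the majority-rule consensus and
   *diagnostic positions* (a base fixed in ≥2/3 of one propeller's blades
   but absent from the others' consensus) that reveal **independent
   amplification events** among close homologs;
7. **fragments** — three-frame translation of intergenic DNA (stops → X),
   permissive profile scanning with the ≥20-residue / ≤15%-stop filters,
   and reconstruction of **disrupted propellers** (frameshift vs in-frame
   stop, event position, total blade count).

## Worked example

Simulate a three-gene genome whose genes amplify sibling blades of one
family into 12-blade propellers, with the last gene disrupted by an
in-frame stop half-way:

```bash
propamp simulate --n-genes 3 --n-blades 12 --disrupt inframe_stop \
        --seed 11 --out sim
propamp run --genome sim/genome.fna --genes sim/genome.gff3 \
        --seeds sim/seeds.faa --seed 11 --out results
```

`results/propellers.tsv`:

```text
protein_id  start  end  n_blades  median_identity  family   locality  min_terminus_distance
gene0       1      513  12        0.95             UNKNOWN  global    0
gene1       1      512  12        0.9268           UNKNOWN  global    0
gene2       1      256  6         0.878            UNKNOWN  global    1
```

The two intact genes are recovered with all 12 blades and ~93–95% median
blade identity; the disrupted gene shows only the 6 blades still
translated. The disruption report (`results/report.json`) completes the
picture:

```json
{"anchor_protein_id": "gene2", "kind": "inframe_stop",
 "inferred_event_position": 4455, "n_fragments": 6,
 "reconstructed_blade_count": 12}
```

Six blade-coding fragments were found beyond the premature stop, in the
anchor's reading frame, reconstructing the original 12-bladed propeller —
and the DNA-level comparison of the three propellers finds 6 diagnostic
positions, verdict `independent`: each gene amplified its blade in a
separate event, even though the proteins are close homologs.

The same stages are available as a library
(`propamp.pipeline.run_pipeline`, `propamp.profiles.iterate_search`,
`propamp.codons.amplification_independence_report`, …) returning plain
dataclasses and pandas tables.

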