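# Methods

## The evolutionary model

The package analyses the amplification–differentiation cycle of
β-propellers. Its unit of analysis is the *blade*, a ~40–50 residue
four-stranded β-meander; a propeller is a closed ring of 4–12 (sometimes
many more) blades. The signature of a *recent* amplification is a run of
consecutive blades whose median pairwise sequence identity exceeds 60% —
a level essentially absent from long-diverged natural propellers — often
accompanied by near-identity at the DNA level and a deficit of synonymous
substitutions. Three derived observations organise the pipeline:

* **Global vs local repetitiveness.** When the whole blade set of a
  domain is highly similar, the entire propeller was amplified in one
  recent event ("globally repetitive"); when a short run of near-identical
  blades sits inside an otherwise divergent propeller, a blade was
  re-amplified locally ("locally repetitive"); both signals can coexist
  ("mixed").
* **Independence of amplification.** Close homologs can each have
  amplified their own copy of an ancestral blade. Then the substitutions
  private to one homolog's ancestral blade are shared by *all* its blades
  — alignment columns where one propeller's blades agree on a base that
  differs from the other propellers' consensus ("diagnostic positions").
  Such propellers are homologous at the blade level but analogous as
  amplified domains.
* **Disruption.** Highly repetitive propellers concentrate near protein
  termini, suggesting truncation of once-longer genes. Frameshifting
  deletions and in-frame stop codons strand blade-coding DNA in the
  flanking intergenic region, recoverable by translated profile search.

## Synthetic data generator

`propamp.simulate` draws an ancestral blade (residues from BLOSUM62
background frequencies, codons uniform over synonymous alternatives,
default length uniform in 40–50 aa), tandemly amplifies it (optionally as
a 2-blade unit with an internally diverged second blade), and mutates each
copy independently. Substitution events occur per codon with probability
`per_site_sub_rate` (default 0.05 per copy, giving ~90% realized blade
identity — the upper part of the >60% regime the analysis targets; the
rate maps to identity roughly as 1 − 1.5·rate at the default synonymous
fraction). An event is synonymous with probability `synonymous_fraction`
(default 0.25, near the fraction expected of random coding changes);
synonymous events are skipped at codons without synonymous single-base
neighbours, non-synonymous events never create stops. Linkers (median
2 aa, spread 1) are copied with the amplified unit and length-jittered by
whole codons, which keeps the DNA self-alignment honest while giving the
linker-length statistics realistic spread.

Disruptions: an in-frame stop substitutes TAA at a stated blade offset
(default the linker codon before the target blade); a frameshift deletes
1–2 nt there. Because the emulated scenario is, by definition, a deletion
that *placed a premature stop in frame*, the generator searches nearby
positions/lengths for a variant whose shifted frame terminates within
about one blade — without it, roughly one in eight frameshifts would
produce a longer garbled protein instead of a pseudogene fragment, a
different biological outcome. Genomes are single forward-strand
concatenations of gene segments with random spacers; gene tables are GFF3
(1-based inclusive on disk, 0-based half-open internally); truth records
(blade intervals, realized identity, event positions, fragment intervals)
are JSON.

What the generator does **not** model: indels inside blades,
recombination, codon-usage bias, reverse-strand genes, overlapping genes,
sequencing error. Passing benchmarks therefore demonstrate the decision
logic of the pipeline under its stated assumptions, not robustness to
assembly artifacts or deep divergence.

## Search machinery

Profiles are position-specific scoring matrices: per-column residue
frequencies with background-weighted pseudocounts (weight 1.0), scored as
2·log2(p/q) half-bits against BLOSUM62 background frequencies; the unknown
residue X scores 0 everywhere. Input blades are filtered to within one
MADe of the median length, aligned by center-star (center = sequence with
the highest summed pairwise BLOSUM62 alignment score; pairwise alignments
via Biopython's PairwiseAligner, gap open −11 / extend −1), trimmed of
columns with >70% gaps, and purged of sequences overlapping <75% of the
columns populated by ≥80% of sequences.

Scanning is Smith–Waterman local alignment of the profile against the
protein (affine gaps, open 11 / extend 1 half-bits, numba kernels), with
matches extracted greedily by score and masked so reported matches never
overlap. Significance is an empirical p-value against the best scores of
200 seeded shuffles of the same protein: inclusion gate p ≤ 0.005 (for
growing the profile), reporting gate p ≤ 0.05, first-pass query coverage
≥ 0.80. Iteration repeats build → scan → include until no new inclusion
matches (≤15 rounds). The second pass rescans matches longer than the
median + 1 MADe (splitting those containing ≥2 hits), linkers at least one
median blade length long, and both termini; rescans use a relaxed 0.50
coverage gate because degenerate blades align partially — the 0.80
coverage requirement belongs to first-pass collection only.

MADe is 1.4826 × median(|x − median|) throughout (the conventional
normal-consistency constant; scipy's exact constant differs only in the
5th decimal and is used as the independent oracle in tests).

## Assembly, refinement, classification

Consecutive matches chain into a propeller while the linker is **less
than 3 MADe** from the median linker length (two-sided; one-sided
available). When MADe is 0 — common in synthetic data with tight linkers
— the criterion degenerates to the median ± 1 residue, inclusive, so
single-residue jitter does not split a chain. Chains of ≥2 blades whose
median pairwise blade identity (center-star alignment, identity counted
over mutually non-gap columns, end gaps excluded) is **strictly greater
than 0.60** are retained.

De-novo repeats are found by aligning the protein against itself with
cells within `min_period` (15 aa) of the main diagonal masked; the best
off-diagonal alignment votes a period (median offset of its aligned
pairs) and a span, units are tiled across the span, and significance is an
empirical p ≤ 0.10 against shuffled-sequence self-alignments. A genuine
tandem repeat must align at least one full period of residues against the
next copy; shorter off-diagonal hits are rejected, which keeps the
false-positive rate of the detector below its nominal gate. Units that
could hold ≥2 blades (nearest-integer of unit/median-blade-length) are
recursively re-analysed, falling back to an even split; single-blade
units merge with the profile annotation: repeat types overlapping
annotated blades link their propellers, the merged blade set is the union
plus units covering new sequence (clipped against existing blades; a unit
must remain ≥60% intact), and merged propellers are re-scored and
re-filtered at 0.60 — originals are kept when the merge fails the filter,
so coverage never decreases and the operation is idempotent.

Family and flank annotation replace HMM-HMM "probability" with an
empirical confidence, 1 − p against the shuffle null, gated at 0.50.
Flank annotation runs ≤5 iterations over still-unannotated regions,
accepting per region the best match ≥40 residues long covering ≥30% of
its profile. Locality: *local* if blade-profile matches (coverage ≥0.5,
confidence ≥0.5) lie within two blade lengths of the propeller and belong
to no retained propeller; else *mixed* if some consecutive blade pair is
≥0.90 identical and exceeds the propeller's median identity by ≥0.15;
else *global*. The terminal census reports distances to both termini and
counts below the 50- and 30-residue thresholds.

## DNA-level analyses

Blade DNA is lifted from residue intervals as `orf[3s:3e]` with an
enforced translation check. The codon alignment is the protein-level
center-star alignment expanded to codons (gaps come in triples). Within a
propeller, the majority-rule consensus base is computed per column (ties
broken alphabetically and flagged); a mismatching base is synonymous iff
substituting it into the consensus codon preserves the amino acid. Across
≥3 propellers aligned at equivalent positions, a column is diagnostic for
propeller P when one base occurs in ≥2/3 (inclusive) of P's blades and
differs from the majority base of ≥2 other propellers; for homolog pairs
the "≥2 others" requirement is reduced to the only available other. The
independence report counts calls and diagnostic positions, reports
ungapped inter-propeller protein identity, and renders a verdict:
`independent` at ≥1 diagnostic position (configurable),
`indistinguishable` with no substitutions at all, `shared` otherwise.

## Fragment scan and disruption reconstruction

Intergenic regions run from the anchor ORF to the nearest flanking ORF in
the same direction (or the genome edge) on both sides. Each region is
translated in three forward frames, stops rendered as X, and scanned
iteratively (≤5 passes) with the blade profiles under a permissive gate —
empirical p ≤ 0.5, profile coverage ≥ 0.30 — then filtered to matches of
≥20 residues (inclusive; strict mode available) with ≤15% stop content.
The permissive gate mirrors the weak-evidence regime this search operates
in: most genuine stranded fragments score poorly. Matches from different
frames overlapping on the genome are echoes of the same locus and only
the most confident is kept; a stranded-blade cluster shared between two
genes' regions is attributed to the gene whose ORF is nearer.

Reconstruction: merged fragment spans that can hold at least half a blade
unit are evidence; spans in the anchor's frame imply an in-frame stop
(event = the anchor's stop codon), spans in a shifted frame imply a
frameshift, both together report "both". The frameshift position is
located by globally aligning (edlib) the observed genomic span — from the
anchor's first blade to the fragment end — against an idealised tandem
repeat of the anchor's own first blade unit: indel operations are
clustered per linker junction (≤15 nt apart); linker-length jitter nets
to a multiple of three, the event does not, and the event position is the
first frame-breaking operation of the offending cluster. The
reconstructed blade count adds, per span, the larger of the merged match
count and the span-length estimate to the anchor's blades.

## Benchmarks and problem sizes

`scripts/acceptance.py` (seeded; every random stream derives from the one
`--seed`) runs: parameter recovery on 100 proteins (4–9 blades, target
identities 0.70–0.95, random terminal flanks); oracle agreement on 300
random linker-grouping instances, 200 MADe samples, 50 identity
instances, and all 549 single-base codon variants; 12 threshold boundary
checks; 100 independent-vs-shared homolog pairs; 100 disruption
replicates (12-blade genes, alternating frameshift / in-frame stop); and
a determinism check on a 3-gene genome. These sizes make the whole script
a few minutes on one CPU while keeping binomial noise well inside the
margins the results show.

## Known limitations

* The PSSM/shuffle-null machinery is a deterministic, desk-scale stand-in
  for published profile tools (PSI-BLAST, HMM-HMM comparison); empirical
  p-values saturate at 1/(N+1) for N shuffles, so very strong and
  merely strong matches are not distinguished by significance.
* Center-star alignment is adequate above ~60% identity but inferior to
  progressive aligners for divergent blades; since the pipeline's object
  of study is the >60% regime, this bias is immaterial here.
* Locality classification depends on blade profiles detecting degenerate
  flanking blades; below ~40% identity the "local" signal fades into
  UNKNOWN flanks.
* The frameshift locator assumes substitution-only divergence between
  blade copies; real insertions within blades would add non-multiple-of-
  three noise it would misread.
* Reverse-strand genes, nested genes, and multi-propeller single genes
  with distinct families are out of scope of the generator and untested.
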