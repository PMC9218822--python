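"""Synthetic genomes with recently amplified β-propeller genes.

The generator emulates the evolutionary scenario the analysis targets: a
single ancestral blade (or a two-blade unit) is tandemly amplified into a
propeller-coding ORF, the copies then differentiate by nucleotide
substitutions with a controlled synonymous fraction, and, optionally, the
gene is disrupted by a small deletion (frameshift) or an in-frame stop,
stranding blade-coding DNA in the downstream intergenic region. Every
emitted record carries a :class:`TruthRecord` so downstream stages can be
scored against known ground truth.

Substitutions only — no indel evolution inside blades, no recombination,
no codon-usage bias (codons are uniform over synonymous alternatives).
All genes are on the forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from propamp.alphabet import (AA_TO_CODONS, AMINO_ACIDS, BACKGROUND,
                              CODON_TO_AA, translate)


class ConfigurationError(ValueError):
    """Raised when an EvolutionSpec or disruption request is invalid."""


# --------------------------------------------------------------------------
# specs and truth records


@dataclass
class Disruption:
    """A gene-disrupting event.

    ``blade_index`` selects the blade before which the event happens;
    ``offset_codons`` (default -1, i.e. the linker codon immediately
    upstream of that blade) positions the event relative to the blade
    start. ``delete_nt`` applies to frameshift deletions and must not be a
    multiple of three.
    """

    kind: str  # "frameshift_deletion" | "inframe_stop"
    blade_index: int
    offset_codons: int = -1
    delete_nt: int = 1

    def validate(self) -> None:
        if self.kind not in ("frameshift_deletion", "inframe_stop"):
            raise ConfigurationError(f"unknown disruption kind {self.kind!r}")
        if self.kind == "frameshift_deletion" and self.delete_nt % 3 == 0:
            raise ConfigurationError(
                "frameshift deletion length must not be a multiple of 3")


@dataclass
class EvolutionSpec:
    """Parameters of one simulated amplification event.

    ``per_site_sub_rate`` is the expected number of nucleotide substitution
    events per amino-acid site per blade copy; with the default synonymous
    fraction of 0.25 the realized median blade identity at the default rate
    of 0.05 is ~0.9, in the upper part of the >60% identity regime the
    pipeline is built for.
    """

    blade_length_aa: int | None = None  # None -> drawn uniformly in 40..50
    n_blades: int = 7
    unit_blades: int = 1
    per_site_sub_rate: float = 0.05
    synonymous_fraction: float = 0.25
    linker_length_distribution: tuple[int, int] = (2, 1)  # (median aa, spread)
    n_propellers: int = 1
    disruption: Disruption | None = None
    rng_seed: int = 0
    unit_divergence: float = 0.2  # blade1->blade2 divergence for 2-blade units
    n_term_flank_aa: int = 0
    c_term_flank_aa: int = 0

    def validate(self) -> None:
        if self.blade_length_aa is not None and self.blade_length_aa < 4:
            raise ConfigurationError("blade_length_aa must be >= 4")
        if self.n_blades < 1:
            raise ConfigurationError("n_blades must be >= 1")
        if self.unit_blades not in (1, 2):
            raise ConfigurationError("unit_blades must be 1 or 2")
        if self.n_blades % self.unit_blades != 0:
            raise ConfigurationError(
                "n_blades must be a multiple of unit_blades")
        for name in ("per_site_sub_rate", "synonymous_fraction",
                     "unit_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.disruption is not None:
            self.disruption.validate()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene/protein.

    Intervals are 0-based half-open: residue coordinates on the (observed)
    protein for blades/propellers, forward-strand nucleotide coordinates
    for disruption events and intergenic fragments (gene-segment local
    until lifted to genome coordinates by :func:`build_genome`).
    """

    protein_id: str
    propeller_intervals: list[tuple[int, int]] = field(default_factory=list)
    blade_intervals: list[list[tuple[int, int]]] = field(default_factory=list)
    true_median_identity: float = 1.0
    amplification_event_ids: list[str] = field(default_factory=list)
    disruption_events: list[tuple[str, int]] = field(default_factory=list)
    intergenic_fragment_intervals: list[tuple[int, int]] = \
        field(default_factory=list)
    # bookkeeping beyond the minimal record
    n_blades_original: int = 0
    n_fragment_blades: int = 0
    observed_orf_end: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        d = dict(d)
        d["propeller_intervals"] = [tuple(x) for x in
                                    d.get("propeller_intervals", [])]
        d["blade_intervals"] = [[tuple(x) for x in p]
                                for p in d.get("blade_intervals", [])]
        d["disruption_events"] = [tuple(x) for x in
                                  d.get("disruption_events", [])]
        d["intergenic_fragment_intervals"] = [
            tuple(x) for x in d.get("intergenic_fragment_intervals", [])]
        return cls(**d)


# --------------------------------------------------------------------------
# sequence-level helpers


def _random_aa(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(20, size=n, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _codons_for(aa_seq: str, rng: np.random.Generator) -> str:
    """Back-translate with codons uniform over synonymous alternatives."""
    out = []
    for aa in aa_seq:
        codons = AA_TO_CODONS[aa]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _single_base_variants(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                out.append(codon[:pos] + base + codon[pos + 1:])
    return out


def mutate_dna(dna: str, rate_per_codon: float, synonymous_fraction: float,
               rng: np.random.Generator) -> str:
    """Apply per-codon substitution events to coding DNA.

    Each codon suffers at most one event, with probability
    ``rate_per_codon``. An event is synonymous with probability
    ``synonymous_fraction`` (skipped when the codon has no synonymous
    single-base neighbour, e.g. ATG/TGG); otherwise a random
    non-synonymous, non-stop single-base change is applied. Stop codons in
    the input are left untouched.
    """
    if len(dna) % 3:
        raise ValueError("coding DNA length must be a multiple of 3")
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    hit = rng.random(len(codons)) < rate_per_codon
    syn = rng.random(len(codons)) < synonymous_fraction
    for k, codon in enumerate(codons):
        if not hit[k] or CODON_TO_AA[codon] == "*":
            continue
        aa = CODON_TO_AA[codon]
        variants = _single_base_variants(codon)
        if syn[k]:
            choices = [v for v in variants if CODON_TO_AA[v] == aa]
        else:
            choices = [v for v in variants
                       if CODON_TO_AA[v] not in (aa, "*")]
        if choices:
            codons[k] = choices[rng.integers(len(choices))]
    return "".join(codons)


def _pairwise_identity_equal_len(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def median_pairwise_identity(blades: list[str]) -> float:
    """Median all-pairs identity of equal-length blade sequences."""
    ids = [_pairwise_identity_equal_len(blades[i], blades[j])
           for i in range(len(blades)) for j in range(i + 1, len(blades))]
    return float(np.median(ids))


# --------------------------------------------------------------------------
# operations


def make_ancestral_blade(spec: EvolutionSpec) -> tuple[str, str]:
    """Draw the ancestral blade: an amino-acid sequence plus coding DNA.

    DNA length is exactly three times the residue length and translates
    back to the amino-acid sequence under the standard code.
    """
    spec.validate()
    rng = spec.rng()
    length = spec.blade_length_aa
    if length is None:
        length = int(rng.integers(40, 51))
    aa = _random_aa(rng, length)
    dna = _codons_for(aa, rng)
    return aa, dna


def amplify_and_diverge(blade: tuple[str, str], spec: EvolutionSpec,
                        protein_id: str = "prot1",
                        event_id: str = "amp1",
                        rng: np.random.Generator | None = None,
                        ) -> tuple[str, str, TruthRecord]:
    """Tandemly amplify a blade into a propeller-coding ORF and diverge it.

    Returns ``(protein_aa, orf_dna, truth)``. The ORF starts with ATG, ends
    with TAA and contains no internal in-frame stop; the protein is its
    exact translation. Linker lengths are drawn per copy from the (median,
    spread) distribution; inter-copy linker sequence is fresh random
    sequence (linker identity is never used downstream).
    """
    spec.validate()
    if rng is None:
        rng = spec.rng()
    blade_aa, blade_dna = blade

    q = spec.per_site_sub_rate * (1.0 - spec.synonymous_fraction)
    if (1.0 - q) ** 2 < 0.2:
        warnings.warn(
            "per_site_sub_rate implies expected blade identity < 0.2, "
            "outside the highly repetitive regime this analysis targets",
            stacklevel=2)

    med_link, spread = spec.linker_length_distribution
    anc_linker = _codons_for(_random_aa(rng, max(0, med_link)), rng)

    def jittered_linker(base: str) -> str:
        """The amplified copy of the linker, length-jittered by +/-spread
        codons (amplification copies the linker; its length then drifts)."""
        target = max(0, med_link + int(rng.integers(-spread, spread + 1)))
        codons = [base[i:i + 3] for i in range(0, len(base), 3)]
        while len(codons) > target:
            codons.pop()
        while len(codons) < target:
            codons.append(_codons_for(_random_aa(rng, 1), rng))
        return "".join(codons)

    # ancestral amplified unit (one or two blades plus internal linker)
    if spec.unit_blades == 2:
        sibling = mutate_dna(blade_dna, spec.unit_divergence,
                             spec.synonymous_fraction, rng)
        intra = _codons_for(_random_aa(rng, max(0, med_link)), rng)
        unit_dna = blade_dna + intra + sibling
        unit_blade_offsets = [(0, len(blade_aa)),
                              (len(blade_aa) + len(intra) // 3,
                               2 * len(blade_aa) + len(intra) // 3)]
    else:
        unit_dna = blade_dna
        unit_blade_offsets = [(0, len(blade_aa))]

    n_units = spec.n_blades // spec.unit_blades
    body_dna_parts: list[str] = []
    blade_ivs: list[tuple[int, int]] = []
    aa_cursor = 1 + spec.n_term_flank_aa  # leading Met + optional flank
    for c in range(n_units):
        copy_dna = mutate_dna(unit_dna + anc_linker,
                              spec.per_site_sub_rate,
                              spec.synonymous_fraction, rng)
        blades_part = copy_dna[:len(unit_dna)]
        linker_part = copy_dna[len(unit_dna):]
        body_dna_parts.append(blades_part)
        for (s, e) in unit_blade_offsets:
            blade_ivs.append((aa_cursor + s, aa_cursor + e))
        aa_cursor += len(blades_part) // 3
        if c < n_units - 1:
            lnk = jittered_linker(linker_part)
            body_dna_parts.append(lnk)
            aa_cursor += len(lnk) // 3

    n_flank = _codons_for(_random_aa(rng, spec.n_term_flank_aa), rng) \
        if spec.n_term_flank_aa else ""
    c_flank = _codons_for(_random_aa(rng, spec.c_term_flank_aa), rng) \
        if spec.c_term_flank_aa else ""
    orf = "ATG" + n_flank + "".join(body_dna_parts) + c_flank + "TAA"
    protein = translate(orf[:-3])
    assert "*" not in protein, "internal stop generated"

    blades_aa = [protein[s:e] for s, e in blade_ivs]
    truth = TruthRecord(
        protein_id=protein_id,
        propeller_intervals=[(blade_ivs[0][0], blade_ivs[-1][1])],
        blade_intervals=[blade_ivs],
        true_median_identity=(median_pairwise_identity(blades_aa)
                              if len(blades_aa) > 1 else 1.0),
        amplification_event_ids=[event_id],
        n_blades_original=spec.n_blades,
    )
    return protein, orf, truth


def _first_stop_end(dna: str) -> int | None:
    """End (exclusive, incl. stop codon) of the frame-0 ORF in ``dna``."""
    for i in range(0, len(dna) - 2, 3):
        if CODON_TO_AA.get(dna[i:i + 3]) == "*":
            return i + 3
    return None


def inject_disruption(orf_dna: str, disruption: Disruption,
                      truth: TruthRecord) -> tuple[str, TruthRecord]:
    """Disrupt a propeller ORF, stranding downstream blades beyond a stop.

    A frameshift deletion removes ``delete_nt`` nucleotides (not a multiple
    of three) so translation runs out of register until a fortuitous stop;
    an in-frame stop substitutes TAA at the event position. In both cases
    the blade-coding DNA beyond the new ORF end is retained and recorded as
    intergenic fragment intervals (segment-local coordinates).
    """
    disruption.validate()
    blades = truth.blade_intervals[0]
    if not 0 <= disruption.blade_index < len(blades):
        raise ConfigurationError("disruption blade index out of range")
    blade_start_aa = blades[disruption.blade_index][0]
    pos = 3 * (blade_start_aa + disruption.offset_codons)
    if not 0 < pos < len(orf_dna) - 3:
        raise ConfigurationError("disruption position outside the ORF")

    if disruption.kind == "frameshift_deletion":
        # the emulated event is a deletion that placed a premature stop in
        # frame: scan nearby positions/lengths for a variant whose shifted
        # frame actually terminates within about one blade, preferring the
        # requested coordinates
        blade_len = blades[0][1] - blades[0][0]
        chosen = None
        for k in (disruption.delete_nt, 1, 2):
            if k % 3 == 0:
                continue
            for p in [pos] + [pos + d for d in (-3, 3, -6, 6)]:
                if not 0 < p < len(orf_dna) - 3 - k:
                    continue
                cand = orf_dna[:p] + orf_dna[p + k:]
                end = _first_stop_end(cand)
                if end is not None and end <= p + 3 * blade_len:
                    chosen = (p, k, cand)
                    break
            if chosen:
                break
        if chosen:
            pos, k, segment = chosen
        else:
            k = disruption.delete_nt
            segment = orf_dna[:pos] + orf_dna[pos + k:]
        shift = -k
    else:
        segment = orf_dna[:pos] + "TAA" + orf_dna[pos + 3:]
        shift = 0

    obs_end = _first_stop_end(segment)
    if obs_end is None:  # no stop reached (rare): ORF runs to segment end
        obs_end = len(segment) - len(segment) % 3

    def shifted(x: int) -> int:
        return x + shift if x > pos else x

    # blades still translated in the observed protein: entirely upstream of
    # the event and of the observed stop
    kept = [(s, e) for s, e in blades
            if 3 * e <= pos and 3 * e <= obs_end - 3]
    # blades stranded beyond the observed ORF end (counting a partially
    # truncated blade when most of it survives downstream of the stop)
    frag = []
    for s, e in blades:
        ns, ne = shifted(3 * s), shifted(3 * e)
        beyond = ne - max(ns, obs_end)
        if beyond >= 0.5 * (ne - ns):
            frag.append((max(ns, obs_end), ne))

    new = replace(
        truth,
        propeller_intervals=[(kept[0][0], kept[-1][1])] if kept else [],
        blade_intervals=[kept] if kept else [],
        disruption_events=list(truth.disruption_events) +
        [(("frameshift" if disruption.kind == "frameshift_deletion"
           else "inframe_stop"), pos)],
        intergenic_fragment_intervals=list(
            truth.intergenic_fragment_intervals) + frag,
        n_fragment_blades=len(frag),
        observed_orf_end=obs_end,
    )
    if len(kept) > 1:
        protein = translate(segment[:obs_end - 3])
        blades_aa = [protein[s:e] for s, e in kept]
        new.true_median_identity = median_pairwise_identity(blades_aa)
    return segment, new


# --------------------------------------------------------------------------
# genome assembly


@dataclass
class GeneRecord:
    gene_id: str
    start: int  # CDS start on the genome, 0-based half-open, incl. stop
    end: int
    strand: str = "+"


@dataclass
class Genome:
    genome_id: str
    sequence: str
    genes: list[GeneRecord]
    truths: dict[str, TruthRecord]

    def protein_of(self, gene_id: str) -> str:
        g = next(g for g in self.genes if g.gene_id == gene_id)
        return translate(self.sequence[g.start:g.end - 3])


def build_genome(genes: list[tuple[str, str, TruthRecord]],
                 spacer_nt: int = 200, rng_seed: int = 0,
                 genome_id: str = "synthetic_genome") -> Genome:
    """Concatenate gene segments into a forward-strand genome.

    ``genes`` are ``(gene_id, segment_dna, truth)`` triples as produced by
    :func:`amplify_and_diverge` / :func:`inject_disruption`. Random spacer
    DNA of ``spacer_nt`` separates consecutive segments and pads both
    genome ends, so every gene has 5' and 3' intergenic sequence. Truth
    coordinates (disruption events, fragment intervals) are lifted to
    genome coordinates.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if spacer_nt < 0:
        raise ValueError("spacer must be non-negative")
    rng = np.random.default_rng(rng_seed)

    def spacer() -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, spacer_nt))

    parts: list[str] = [spacer()]
    cursor = len(parts[0])
    records: list[GeneRecord] = []
    truths: dict[str, TruthRecord] = {}
    seen: set[str] = set()
    for gene_id, segment, truth in genes:
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        obs_end = truth.observed_orf_end
        if obs_end is None:
            obs_end = len(segment)
        cds_start = cursor
        cds_end = cursor + obs_end
        if records and cds_start < records[-1].end:
            raise ValueError("overlapping ORFs")
        records.append(GeneRecord(gene_id, cds_start, cds_end))
        lifted = replace(
            truth,
            disruption_events=[(k, p + cursor)
                               for k, p in truth.disruption_events],
            intergenic_fragment_intervals=[
                (s + cursor, e + cursor)
                for s, e in truth.intergenic_fragment_intervals],
        )
        truths[gene_id] = lifted
        parts.append(segment)
        cursor += len(segment)
        parts.append(spacer())
        cursor += spacer_nt
    return Genome(genome_id, "".join(parts), records, truths)


# --------------------------------------------------------------------------
# homolog-pair scenarios for the DNA-level independence analysis


def make_independent_pair(spec: EvolutionSpec, sibling_divergence: float = 0.1
                          ) -> list[tuple[str, str, TruthRecord]]:
    """Two homologs amplified independently from sibling blades.

    Both proteins descend from one ancestral blade (they are homologous at
    the blade level) but each was amplified in its own event, so blades
    within one propeller share their sibling's private substitutions —
    the source of amplification-diagnostic positions.
    """
    spec.validate()
    rng = spec.rng()
    _, anc_dna = make_ancestral_blade(spec)
    out = []
    for k in (1, 2):
        sib_dna = mutate_dna(anc_dna, sibling_divergence,
                             spec.synonymous_fraction, rng)
        sib_aa = translate(sib_dna)
        prot, orf, truth = amplify_and_diverge(
            (sib_aa, sib_dna), spec, protein_id=f"indep{k}",
            event_id=f"amp_indep{k}", rng=rng)
        out.append((prot, orf, truth))
    return out


def make_shared_pair(spec: EvolutionSpec, post_divergence: float = 0.1
                     ) -> list[tuple[str, str, TruthRecord]]:
    """Two homologs descending from one shared amplification event.

    The propeller is amplified once, then the full ORF diverges
    independently in the two lineages; substitutions land on individual
    blade copies rather than on all blades of one propeller at once.
    """
    spec.validate()
    rng = spec.rng()
    blade = make_ancestral_blade(spec)
    prot0, orf0, truth0 = amplify_and_diverge(blade, spec,
                                              protein_id="shared0",
                                              event_id="amp_shared",
                                              rng=rng)
    out = []
    for k in (1, 2):
        body = mutate_dna(orf0[3:-3], post_divergence,
                          spec.synonymous_fraction, rng)
        dna = orf0[:3] + body + orf0[-3:]
        prot = translate(dna[:-3])
        truth = replace(truth0, protein_id=f"shared{k}")
        blades_aa = [prot[s:e] for s, e in truth.blade_intervals[0]]
        truth.true_median_identity = median_pairwise_identity(blades_aa)
        out.append((prot, dna, truth))
    return out
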