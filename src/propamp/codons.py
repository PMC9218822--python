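"""Codon-level comparison of blade DNA: the amplification-independence test.

Within one propeller, every blade is compared to the majority-rule
nucleotide consensus of that propeller; a mismatching base is synonymous
when substituting it into the consensus codon leaves the encoded amino
acid unchanged. Across propellers, a column is *diagnostic* for propeller
P when some base occurs in at least two thirds of P's blades but differs
from the majority base of at least two of the other propellers — shared
substitutions marking the blade that was amplified, the signature of
independent amplification events.

Standard genetic code only; no dN/dS rate modelling, counting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

from propamp import msa
from propamp.alphabet import CODON_TO_AA


class AlignmentError(ValueError):
    pass


@dataclass
class MutationCall:
    column: int            # nucleotide column in the alignment
    blade_id: str          # blade (or propeller, for diagnostic calls)
    kind: str              # synonymous | nonsynonymous | diagnostic
    consensus_base: str
    observed_base: str
    tie: bool = False      # consensus tie broken alphabetically


@dataclass
class CodonBladeAlignment:
    """Codon-aware alignment of blade DNA, possibly across propellers.

    Rows are gapped DNA strings of equal column count whose gaps come in
    codon-sized triples (the alignment is lifted from a protein-level
    alignment of the blades), so each row stripped of gaps translates to
    its blade's amino-acid sequence.
    """

    blade_ids: list[str]
    propeller_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        ncol = {len(r) for r in self.rows}
        if len(ncol) > 1:
            raise AlignmentError("rows have differing column counts")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def propellers(self) -> list[str]:
        seen: list[str] = []
        for p in self.propeller_ids:
            if p not in seen:
                seen.append(p)
        return seen

    def rows_of(self, propeller_id: str) -> list[tuple[str, str]]:
        return [(b, r) for b, p, r in
                zip(self.blade_ids, self.propeller_ids, self.rows)
                if p == propeller_id]


def extract_blade_dna(orf_dna: str, blade_intervals: list[tuple[int, int]],
                      protein: str | None = None) -> list[str]:
    """Lift residue intervals to codon intervals on the ORF.

    Each blade's DNA is ``orf[3*start : 3*end]``; a translation check
    against the protein guards against frame bugs.
    """
    from propamp.alphabet import translate

    if protein is None:
        protein = translate(orf_dna)
        if protein.endswith("*"):
            protein = protein[:-1]
    out = []
    for s, e in blade_intervals:
        dna = orf_dna[3 * s:3 * e]
        if translate(dna) != protein[s:e]:
            raise AlignmentError(
                f"blade interval ({s}, {e}) does not translate to the "
                "protein subsequence — frame mismatch")
        out.append(dna)
    return out


def build_codon_alignment(blades: list[tuple[str, str, str, str]]
                          ) -> CodonBladeAlignment:
    """Build a codon alignment from (blade_id, propeller_id, aa, dna) rows.

    The amino-acid sequences are center-star aligned and each aligned
    residue is replaced by its codon (gaps by ``---``).
    """
    for _, _, aa, dna in blades:
        if len(dna) != 3 * len(aa):
            raise AlignmentError("DNA length must be 3x the blade length")
        if any(c not in "ACGT" for c in dna):
            raise AlignmentError("non-ACGT character in blade DNA")
    aligned = msa.center_star_align([aa for _, _, aa, _ in blades])
    rows = []
    for (bid, pid, aa, dna), row in zip(blades, aligned):
        codons = [dna[3 * i:3 * i + 3] for i in range(len(aa))]
        it = iter(codons)
        rows.append("".join("---" if c == "-" else next(it) for c in row))
    return CodonBladeAlignment(
        blade_ids=[b for b, _, _, _ in blades],
        propeller_ids=[p for _, p, _, _ in blades],
        rows=rows)


def _column_consensus(rows: list[str], col: int) -> tuple[str | None, bool]:
    """Majority base at a column (ties alphabetical), or None if all-gap."""
    bases = [r[col] for r in rows if r[col] != "-"]
    if not bases:
        return None, False
    counts = Counter(bases)
    top = max(counts.values())
    winners = sorted(b for b, c in counts.items() if c == top)
    return winners[0], len(winners) > 1


def call_mutations(aln: CodonBladeAlignment, propeller_id: str | None = None
                   ) -> list[MutationCall]:
    """Classify consensus mismatches as synonymous or non-synonymous.

    Single-propeller mode: the consensus is the majority-rule base per
    column over the propeller's blades; a blade's mismatching base is
    synonymous iff substituting it into the consensus codon preserves the
    encoded amino acid.
    """
    if propeller_id is None:
        props = aln.propellers()
        if len(props) != 1:
            raise AlignmentError(
                "call_mutations needs a single propeller (or propeller_id)")
        propeller_id = props[0]
    rows = aln.rows_of(propeller_id)
    if len(rows) < 2:
        raise AlignmentError("need at least two blades")
    for _, r in rows:
        if any(c not in "ACGT-" for c in r):
            raise AlignmentError("non-ACGT character in alignment")
    seqs = [r for _, r in rows]
    ncol = len(seqs[0])
    cons: list[str | None] = []
    ties: list[bool] = []
    for c in range(ncol):
        b, tie = _column_consensus(seqs, c)
        cons.append(b)
        ties.append(tie)

    calls: list[MutationCall] = []
    for c in range(ncol):
        if cons[c] is None:
            continue
        c0 = c - c % 3
        cons_codon = [cons[c0], cons[c0 + 1], cons[c0 + 2]]
        for bid, row in rows:
            base = row[c]
            if base == "-" or base == cons[c]:
                continue
            if None in cons_codon:
                continue
            ref = "".join(cons_codon)  # type: ignore[arg-type]
            var = ref[:c % 3] + base + ref[c % 3 + 1:]
            same = (CODON_TO_AA.get(ref) == CODON_TO_AA.get(var)
                    and CODON_TO_AA.get(ref) != "*")
            calls.append(MutationCall(
                column=c, blade_id=bid,
                kind="synonymous" if same else "nonsynonymous",
                consensus_base=cons[c], observed_base=base, tie=ties[c]))
    return calls


def find_diagnostic_positions(aln: CodonBladeAlignment,
                              min_other: int | None = None
                              ) -> list[MutationCall]:
    """Columns where one propeller's shared base sets it apart.

    For propeller P, a column is diagnostic when some base occurs in at
    least two thirds (inclusive) of P's blades and differs from the
    majority base of at least ``min_other`` (default 2) of the other
    propellers. Requires at least three propellers under the default
    criterion.
    """
    props = aln.propellers()
    if min_other is None:
        if len(props) < 3:
            raise AlignmentError(
                "diagnostic criterion references at least two other "
                "propellers; supply min_other for pairwise comparisons")
        min_other = 2
    if len(props) < 2:
        raise AlignmentError("need at least two propellers")

    per_prop = {p: [r for _, r in aln.rows_of(p)] for p in props}
    ncol = aln.n_columns
    calls: list[MutationCall] = []
    for c in range(ncol):
        majority: dict[str, str | None] = {}
        for p in props:
            majority[p], _ = _column_consensus(per_prop[p], c)
        for p in props:
            bases = [r[c] for r in per_prop[p] if r[c] != "-"]
            if not bases:
                continue
            need = math.ceil(2 * len(per_prop[p]) / 3 - 1e-9)
            counts = Counter(bases)
            base, cnt = sorted(counts.items(),
                               key=lambda kv: (-kv[1], kv[0]))[0]
            if cnt < need:
                continue
            others = [q for q in props if q != p
                      and majority[q] is not None and majority[q] != base]
            if len(others) >= min_other:
                calls.append(MutationCall(
                    column=c, blade_id=p, kind="diagnostic",
                    consensus_base=base,
                    observed_base=",".join(
                        str(majority[q]) for q in others)))
    return calls


def amplification_independence_report(
        propellers: list[tuple[str, list[tuple[str, str, str]]]],
        min_diagnostic: int = 1) -> dict:
    """Summarise the DNA-level evidence for independent amplification.

    ``propellers`` maps each propeller id to its blades as
    ``(blade_id, aa, dna)`` triples. The report counts synonymous and
    non-synonymous substitutions per propeller, the diagnostic positions
    of the joint alignment, and the ungapped pairwise protein identity
    between propellers; the verdict is "independent" when the number of
    diagnostic positions reaches ``min_diagnostic``, "indistinguishable"
    when the propellers carry no substitutions at all, "shared" otherwise.
    """
    if len(propellers) < 2:
        raise ValueError("need at least two propellers")
    per_prop: dict[str, dict] = {}
    total_mismatches = 0
    for pid, blades in propellers:
        aln = build_codon_alignment([(b, pid, aa, dna)
                                     for b, aa, dna in blades])
        calls = call_mutations(aln, pid)
        syn = sum(1 for c in calls if c.kind == "synonymous")
        non = sum(1 for c in calls if c.kind == "nonsynonymous")
        per_prop[pid] = {"synonymous": syn, "nonsynonymous": non,
                         "n_blades": len(blades)}
        total_mismatches += len(calls)

    joint = build_codon_alignment(
        [(b, pid, aa, dna) for pid, blades in propellers
         for b, aa, dna in blades])
    n_other = min(2, len(propellers) - 1)
    diags = find_diagnostic_positions(joint, min_other=n_other)
    diag_columns = sorted({d.column for d in diags})
    for pid in per_prop:
        per_prop[pid]["diagnostic"] = sum(1 for d in diags
                                          if d.blade_id == pid)

    # ungapped pairwise protein identity between propellers
    identities = {}
    concat = {pid: "".join(aa for _, aa, _ in blades)
              for pid, blades in propellers}
    pids = [pid for pid, _ in propellers]
    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            a, b = concat[pids[i]], concat[pids[j]]
            n = min(len(a), len(b))
            identities[f"{pids[i]}|{pids[j]}"] = (
                sum(a[k] == b[k] for k in range(n)) / n if n else 0.0)

    if total_mismatches == 0 and not diag_columns:
        verdict = "indistinguishable"
    elif len(diag_columns) >= min_diagnostic:
        verdict = "independent"
    else:
        verdict = "shared"
    return {"per_propeller": per_prop,
            "diagnostic_positions": diag_columns,
            "n_diagnostic_positions": len(diag_columns),
            "ungapped_protein_identity": identities,
            "verdict": verdict}
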