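"""Center-star multiple alignment of blade-sized sequences.

Blades that survive the pipeline's filters share >60% identity, a regime in
which the classic center-star construction (align everything to the
sequence with the highest summed pairwise score, then merge by
"once a gap, always a gap") is an adequate, fully deterministic stand-in
for a progressive aligner. Pairwise alignments use BLOSUM62 with affine
gaps via Biopython's PairwiseAligner.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@lru_cache(maxsize=1)
def _aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def pairwise_global(a: str, b: str) -> tuple[str, str, float]:
    """Globally align two sequences; return (aligned_a, aligned_b, score).

    The first co-optimal alignment reported by Biopython is taken, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both are non-gap.

    End gaps are implicitly excluded because gap columns never count in the
    denominator.
    """
    aa, bb, _ = pairwise_global(a, b)
    same = 0
    both = 0
    for x, y in zip(aa, bb):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                same += 1
    if both == 0:
        return 0.0
    return same / both


def center_star_align(seqs: list[str]) -> list[str]:
    """Multiple-align ``seqs``; returns aligned rows in the input order.

    The center is the sequence maximising the summed pairwise alignment
    score against all others (ties broken by input order).
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if any(not s for s in seqs):
        raise ValueError("empty sequence in alignment input")
    k = len(seqs)
    if k == 1:
        return [seqs[0]]

    # pairwise scores to pick the center
    scores = [[0.0] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            _, _, s = pairwise_global(seqs[i], seqs[j])
            scores[i][j] = scores[j][i] = s
    sums = [sum(row) for row in scores]
    center = max(range(k), key=lambda i: (sums[i], -i))

    # master alignment: center row accumulates gaps as new rows are merged
    master_center = seqs[center]
    rows: list[tuple[int, str]] = [(center, seqs[center])]
    for i in range(k):
        if i == center:
            continue
        c_aln, s_aln, _ = pairwise_global(seqs[center], seqs[i])
        master_center, rows, new_row = _merge(master_center, rows, c_aln,
                                              s_aln)
        rows.append((i, new_row))

    out = [""] * k
    for idx, row in rows:
        out[idx] = row
    return out


def _merge(master_center: str, rows: list[tuple[int, str]], c_aln: str,
           s_aln: str) -> tuple[str, list[tuple[int, str]], str]:
    """Merge one pairwise (center, seq) alignment into the master alignment.

    Walks the master center and the freshly aligned center in parallel;
    wherever one has a gap the other lacks, a gap column is inserted into
    the opposite side ("once a gap, always a gap").
    """
    i = j = 0
    new_master = []
    new_rows = [[] for _ in rows]
    new_row = []
    n_master, n_pair = len(master_center), len(c_aln)
    while i < n_master or j < n_pair:
        mc = master_center[i] if i < n_master else None
        pc = c_aln[j] if j < n_pair else None
        if mc is not None and pc is not None and \
                (mc == pc or (mc != "-" and pc != "-")):
            new_master.append(mc)
            for r, (_, row) in zip(new_rows, rows):
                r.append(row[i])
            new_row.append(s_aln[j])
            i += 1
            j += 1
        elif mc == "-" and (pc is None or pc != "-"):
            # master has an extra gap column: pad the new row
            new_master.append("-")
            for r, (_, row) in zip(new_rows, rows):
                r.append(row[i])
            new_row.append("-")
            i += 1
        else:
            # pairwise alignment opened a new gap in the center
            new_master.append("-")
            for r in new_rows:
                r.append("-")
            new_row.append(s_aln[j])
            j += 1
    merged_rows = [(idx, "".join(r))
                   for (idx, _), r in zip(rows, new_rows)]
    return "".join(new_master), merged_rows, "".join(new_row)


def column_identity(row_a: str, row_b: str) -> float:
    """Identity between two aligned rows over mutually non-gap columns."""
    same = both = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                same += 1
    return same / both if both else 0.0
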