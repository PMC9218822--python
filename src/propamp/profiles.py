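"""Iterative profile construction and blade scanning.

This is the sequence-search stage of the pipeline: blade seeds are
multiple-aligned into a position-specific scoring matrix (log-odds in
half-bits against BLOSUM62 background frequencies, with pseudocounts), the
PSSM is Smith–Waterman-scanned against every protein, matches above the
inclusion significance feed the next profile, and the loop repeats until no
new inclusion matches appear. Significance is an empirical p-value from a
seeded null of shuffled sequences; with the default 200 shuffles the
inclusion and reporting gates are p <= 0.005 and p <= 0.05.

A second pass (:func:`rescan_unmatched`) hunts for blades the first pass
missed: unusually long matches are split if they contain more than one
profile hit, linkers long enough to hold a blade are re-scanned, and so are
the sequence termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from propamp import msa
from propamp._sw import alloc_dp, sw_fill, sw_score_batch, sw_traceback
from propamp.alphabet import BACKGROUND, N_AA, encode_protein
from propamp.stats import made, median, stable_seed


#: profile-coverage gate for second-pass rescans of long matches,
#: linkers and termini; the 0.80 coverage requirement applies to
#: first-pass matches only, while rescans hunt degenerate blades whose
#: alignments are often partial
RESCAN_COVERAGE = 0.5


class ProfileError(RuntimeError):
    """Raised when profile construction leaves no usable sequences."""


@dataclass
class SearchConfig:
    """Thresholds of the iterative search (see module docstring)."""

    max_iterations: int = 15
    inclusion_p: float = 0.005
    report_p: float = 0.05
    min_query_coverage: float = 0.80
    trim_max_gap_fraction: float = 0.70  # drop columns with >70% gaps
    trim_min_overlap: float = 0.75       # of well-populated columns
    trim_occupancy: float = 0.80         # defines well-populated columns
    length_filter_mades: float = 1.0
    n_shuffles: int = 200
    gap_open: float = 11.0
    gap_extend: float = 1.0
    pseudocount_weight: float = 1.0
    rng_seed: int = 0


@dataclass
class Profile:
    """Position-specific scoring matrix over the 20-residue alphabet.

    ``scores`` has one row per column and 21 entries per row (index 20 is
    the unknown residue X, always scored 0). Units are half-bits.
    """

    scores: np.ndarray
    pseudocount_weight: float
    background: np.ndarray
    source_count: int

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def max_score(self, seq: str) -> float:
        """Score of ``seq`` aligned gap-free along the whole profile."""
        idx = encode_protein(seq)
        n = min(len(idx), self.length)
        return float(sum(self.scores[i, idx[i]] for i in range(n)))


@dataclass
class BladeMatch:
    """A scored blade-like interval on one protein (0-based half-open)."""

    protein_id: str
    start: int
    end: int
    score: float
    significance: float
    query_coverage: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "BladeMatch":
        return BladeMatch(self.protein_id, self.start + offset,
                          self.end + offset, self.score, self.significance,
                          self.query_coverage)


# --------------------------------------------------------------------------
# profile construction


def build_profile(blades: list[str], config: SearchConfig | None = None
                  ) -> Profile:
    """Align blade sequences and compile them into a PSSM.

    Input sequences are first filtered to within one MADe of the median
    length, multiple-aligned (center-star), trimmed of columns with more
    than 70% gaps, and purged of sequences overlapping fewer than 75% of
    the columns populated by at least 80% of the others. Raises
    :class:`ProfileError` if nothing survives.
    """
    config = config or SearchConfig()
    if not blades:
        raise ProfileError("no blade sequences supplied")
    lens = [len(b) for b in blades]
    med, md = median(lens), made(lens)
    kept = [b for b in blades
            if abs(len(b) - med) <= md * config.length_filter_mades + 1e-9]
    if not kept:
        raise ProfileError("length filter removed every sequence")

    rows = msa.center_star_align(kept)
    ncols = len(rows[0])
    nrows = len(rows)

    gap_frac = [sum(r[c] == "-" for r in rows) / nrows for c in range(ncols)]
    col_keep = [c for c in range(ncols)
                if gap_frac[c] <= config.trim_max_gap_fraction]
    if not col_keep:
        raise ProfileError("column trimming removed every column")

    if nrows > 1:
        occ = [1.0 - gap_frac[c] for c in col_keep]
        well = [c for c, o in zip(col_keep, occ)
                if o >= config.trim_occupancy]
        if well:
            surv = []
            for r in rows:
                overlap = sum(r[c] != "-" for c in well) / len(well)
                if overlap >= config.trim_min_overlap:
                    surv.append(r)
            if not surv:
                raise ProfileError(
                    "overlap filter removed every sequence "
                    f"({nrows} sequences, {len(well)} well-populated "
                    "columns)")
            rows = surv
    return _profile_from_alignment(rows, col_keep, config)


def _profile_from_alignment(rows: list[str], col_keep: list[int],
                            config: SearchConfig) -> Profile:
    from propamp.alphabet import AA_INDEX

    w = config.pseudocount_weight
    scores = np.zeros((len(col_keep), N_AA + 1))
    for out_c, c in enumerate(col_keep):
        counts = np.zeros(N_AA)
        for r in rows:
            i = AA_INDEX.get(r[c])
            if i is not None:
                counts[i] += 1.0
        total = counts.sum()
        probs = (counts + w * BACKGROUND) / (total + w)
        scores[out_c, :N_AA] = 2.0 * np.log2(probs / BACKGROUND)
        scores[out_c, N_AA] = 0.0  # X
    return Profile(scores=scores, pseudocount_weight=w,
                   background=BACKGROUND.copy(), source_count=len(rows))


# --------------------------------------------------------------------------
# scanning


def _shuffle_null(idx: np.ndarray, profile: Profile, config: SearchConfig,
                  seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    tiled = np.tile(idx, (config.n_shuffles, 1))
    shuffled = rng.permuted(tiled, axis=1)
    return sw_score_batch(shuffled, profile.scores, config.gap_open,
                          config.gap_extend)


def scan_sequence(profile: Profile, protein: str,
                  config: SearchConfig | None = None,
                  protein_id: str = "",
                  min_coverage: float | None = None,
                  max_p: float | None = None) -> list[BladeMatch]:
    """Find non-overlapping profile matches in one protein.

    Local alignments are extracted greedily by score, each matched region
    is blocked before the next extraction, and every candidate is assigned
    an empirical p-value against shuffles of the same protein. Matches are
    reported while p stays within ``max_p`` (default: the report gate) and
    their profile coverage reaches ``min_coverage``.
    """
    config = config or SearchConfig()
    if min_coverage is None:
        min_coverage = config.min_query_coverage
    if max_p is None:
        max_p = config.report_p
    if len(protein) < 4:
        return []
    idx = encode_protein(protein)
    seed = stable_seed(config.rng_seed, "scan", protein_id, len(protein),
                       profile.length)
    null = np.sort(_shuffle_null(idx, profile, config, seed))

    n, ncols = len(idx), profile.length
    blocked = np.zeros(n, dtype=np.uint8)
    H, E, F = alloc_dp(n, ncols)
    matches: list[BladeMatch] = []
    for _ in range(200):
        best, bi, bj = sw_fill(idx, profile.scores, config.gap_open,
                               config.gap_extend, -(10 ** 9), blocked,
                               H, E, F)
        if best <= 0.0:
            break
        p = float(1 + np.sum(null >= best - 1e-9)) / (config.n_shuffles + 1)
        if p > max_p:
            break
        ai, aj, k = sw_traceback(idx, profile.scores, config.gap_open,
                                 config.gap_extend, H, E, F, bi, bj)
        if k == 0:
            break
        i0, i1 = int(ai[0]), int(ai[k - 1]) + 1
        j0, j1 = int(aj[0]), int(aj[k - 1]) + 1
        blocked[i0:i1] = 1
        coverage = (j1 - j0) / ncols
        if coverage >= min_coverage:
            matches.append(BladeMatch(protein_id, i0, i1, float(best),
                                      p, coverage))
    matches.sort(key=lambda m: m.start)
    return matches


# --------------------------------------------------------------------------
# iteration


def iterate_search(seed_blades: list[str], proteins: dict[str, str],
                   config: SearchConfig | None = None
                   ) -> list[BladeMatch]:
    """Iterate profile building and scanning to convergence.

    Matches passing the inclusion gate extend the blade set used to build
    the next round's profile; the loop stops when a round contributes no
    new inclusion matches or after ``max_iterations``. Returns the
    reporting-threshold matches of the final scan, sorted by protein and
    position.
    """
    config = config or SearchConfig()
    if not seed_blades:
        raise ProfileError("no seed blades")
    if not proteins:
        return []
    included: dict[tuple[str, int, int], str] = {}
    report: list[BladeMatch] = []
    for _ in range(max(1, config.max_iterations)):
        blades = list(seed_blades) + [included[k] for k in sorted(included)]
        profile = build_profile(blades, config)
        report = []
        new = 0
        for pid in sorted(proteins):
            seq = proteins[pid]
            for m in scan_sequence(profile, seq, config, protein_id=pid):
                report.append(m)
                if m.significance <= config.inclusion_p:
                    key = (pid, m.start, m.end)
                    if key not in included:
                        included[key] = seq[m.start:m.end]
                        new += 1
        if new == 0:
            break
    report.sort(key=lambda m: (m.protein_id, m.start))
    return report


def rescan_unmatched(matches: list[BladeMatch], proteins: dict[str, str],
                     profile: Profile, config: SearchConfig | None = None
                     ) -> list[BladeMatch]:
    """Split over-long matches and rescan long linkers and termini.

    (a) matches longer than the median match length plus one MADe are
    re-scanned and replaced by their sub-matches when at least two profile
    hits fit inside; the profile is then rebuilt once from the updated
    blade set; (b) linkers at least one median blade length long and
    (c) both termini are scanned with the updated profile. The union is
    returned, non-overlapping, sorted by protein and position.
    """
    config = config or SearchConfig()
    if not matches:
        return []
    lengths = [m.length for m in matches]
    med_len, md = median(lengths), made(lengths)
    long_cut = med_len + md * config.length_filter_mades

    updated: list[BladeMatch] = []
    for m in matches:
        if m.length > long_cut + 1e-9:
            sub = proteins[m.protein_id][m.start:m.end]
            hits = scan_sequence(profile, sub, config,
                                 protein_id=f"{m.protein_id}|long@{m.start}",
                                 min_coverage=RESCAN_COVERAGE)
            if len(hits) >= 2:
                updated.extend(
                    BladeMatch(m.protein_id, h.start + m.start,
                               h.end + m.start, h.score, h.significance,
                               h.query_coverage) for h in hits)
                continue
        updated.append(m)

    try:
        blade_seqs = [proteins[m.protein_id][m.start:m.end] for m in updated]
        profile2 = build_profile(blade_seqs, config)
    except ProfileError:
        profile2 = profile

    by_protein: dict[str, list[BladeMatch]] = {}
    for m in updated:
        by_protein.setdefault(m.protein_id, []).append(m)

    extra: list[BladeMatch] = []
    for pid, ms in sorted(by_protein.items()):
        ms.sort(key=lambda m: m.start)
        seq = proteins[pid]
        regions: list[tuple[int, int, str]] = []
        for a, b in zip(ms, ms[1:]):
            if b.start - a.end >= med_len:  # room for at least one blade
                regions.append((a.end, b.start, "linker"))
        if ms[0].start >= 4:
            regions.append((0, ms[0].start, "nterm"))
        if len(seq) - ms[-1].end >= 4:
            regions.append((ms[-1].end, len(seq), "cterm"))
        for s, e, tag in regions:
            hits = scan_sequence(profile2, seq[s:e], config,
                                 protein_id=f"{pid}|{tag}@{s}",
                                 min_coverage=RESCAN_COVERAGE)
            extra.extend(
                BladeMatch(pid, h.start + s, h.end + s, h.score,
                           h.significance, h.query_coverage) for h in hits)

    return resolve_overlaps(updated + extra)


def resolve_overlaps(matches: list[BladeMatch]) -> list[BladeMatch]:
    """Greedy score-first selection of mutually non-overlapping matches."""
    out: list[BladeMatch] = []
    by_protein: dict[str, list[BladeMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.protein_id, []).append(m)
    for pid in sorted(by_protein):
        chosen: list[BladeMatch] = []
        for m in sorted(by_protein[pid], key=lambda m: (-m.score, m.start)):
            if all(m.end <= c.start or m.start >= c.end for c in chosen):
                chosen.append(m)
        out.extend(sorted(chosen, key=lambda m: m.start))
    out.sort(key=lambda m: (m.protein_id, m.start))
    return out
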