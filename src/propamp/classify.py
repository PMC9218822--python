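"""Family assignment, flank annotation, and locality classification.

A highly repetitive propeller is *globally* repetitive when its whole blade
set descends from one recent amplification, and *locally* repetitive when a
short run of near-identical blades is embedded in an otherwise divergent
propeller — operationally, when blade-like matches below the 60% identity
criterion flank the repetitive block. A recent local amplification nested
inside a still-recognisable global one is labelled *mixed*.

Profile "probability" gates are empirical confidences, 1 minus the
empirical p-value of the profile score against a shuffled null, gateable at
0.50 like the HMM-search probabilities they stand in for.
"""

from __future__ import annotations

from dataclasses import dataclass

from propamp import msa
from propamp.assembly import PropellerAnnotation
from propamp.profiles import Profile, SearchConfig, scan_sequence
from propamp.stats import median


@dataclass
class DomainMatch:
    """A non-propeller domain annotation in a flanking region."""

    name: str
    start: int
    end: int
    confidence: float
    profile_coverage: float

    @property
    def length(self) -> int:
        return self.end - self.start


def assign_family(propeller_seq: str, family_profiles: dict[str, Profile],
                  config: SearchConfig | None = None,
                  family_gate: float = 0.50) -> tuple[str, float]:
    """Assign the best-matching family profile, or UNKNOWN.

    The best-scoring profile wins when its match passes the standard
    coverage gate and its confidence (1 - empirical p) reaches
    ``family_gate``; otherwise the propeller is labelled UNKNOWN with the
    best confidence seen.
    """
    config = config or SearchConfig()
    if not family_profiles:
        raise ValueError("no family profiles supplied")
    best: tuple[float, str, float] | None = None  # (score, name, conf)
    for name in sorted(family_profiles):
        hits = scan_sequence(family_profiles[name], propeller_seq, config,
                             protein_id=f"family:{name}", max_p=0.9)
        for h in hits:
            conf = 1.0 - h.significance
            if best is None or h.score > best[0]:
                best = (h.score, name, conf)
    if best is None:
        return "UNKNOWN", 0.0
    _, name, conf = best
    if conf >= family_gate:
        return name, conf
    return "UNKNOWN", conf


def annotate_flanks(protein: str, propeller_intervals: list[tuple[int, int]],
                    domain_profiles: dict[str, Profile],
                    config: SearchConfig | None = None,
                    family_gate: float = 0.50, min_len: int = 40,
                    min_cov: float = 0.30, max_iter: int = 5
                    ) -> list[DomainMatch]:
    """Iteratively annotate non-propeller domains outside the propellers.

    Up to ``max_iter`` rounds: every still-unannotated region of at least
    ``min_len`` residues is scanned against all domain profiles; the best
    match per region is accepted if it is at least ``min_len`` residues
    long, covers at least ``min_cov`` of its profile, and reaches the
    confidence gate. Accepted matches become annotated regions for the
    next round.
    """
    config = config or SearchConfig()
    annotated: list[tuple[int, int]] = sorted(propeller_intervals)
    domains: list[DomainMatch] = []

    def unannotated_regions() -> list[tuple[int, int]]:
        regions = []
        cursor = 0
        for s, e in sorted(annotated):
            if s - cursor >= min_len:
                regions.append((cursor, s))
            cursor = max(cursor, e)
        if len(protein) - cursor >= min_len:
            regions.append((cursor, len(protein)))
        return regions

    for _ in range(max_iter):
        new: list[DomainMatch] = []
        for rs, re_ in unannotated_regions():
            sub = protein[rs:re_]
            best: DomainMatch | None = None
            best_score = float("-inf")
            for name in sorted(domain_profiles):
                hits = scan_sequence(domain_profiles[name], sub, config,
                                     protein_id=f"flank:{name}@{rs}",
                                     min_coverage=min_cov,
                                     max_p=1.0 - family_gate)
                for h in hits:
                    if h.length < min_len:
                        continue
                    conf = 1.0 - h.significance
                    if conf < family_gate:
                        continue
                    if h.score > best_score:
                        best_score = h.score
                        best = DomainMatch(name, h.start + rs, h.end + rs,
                                           conf, h.query_coverage)
            if best is not None:
                new.append(best)
        if not new:
            break
        domains.extend(new)
        annotated.extend((d.start, d.end) for d in new)
    domains.sort(key=lambda d: d.start)
    return domains


def classify_locality(propeller: PropellerAnnotation, protein: str,
                      blade_profile: Profile,
                      config: SearchConfig | None = None,
                      identity_threshold: float = 0.60,
                      retained: list[PropellerAnnotation] | None = None,
                      near_identical: float = 0.90,
                      excess_over_median: float = 0.15) -> str:
    """Label one retained propeller as global, local, or mixed.

    *local*: blade-like matches (below the identity criterion, hence not
    part of any retained propeller) sit adjacent to the repetitive block —
    the block is a recent amplification inside a larger degenerate
    propeller. *mixed*: the propeller as a whole passes the identity
    criterion but contains a consecutive run of near-identical blades well
    above its own median — a local re-amplification nested in a global
    one. *global*: everything else.
    """
    config = config or SearchConfig()
    blade_lens = [e - s for s, e in propeller.blade_intervals]
    window = 2 * int(median(blade_lens))
    retained_ivs = [(q.start, q.end) for q in (retained or [])
                    if q is not propeller]

    def adjacent_blade_match(rs: int, re_: int) -> bool:
        if re_ - rs < 4:
            return False
        hits = scan_sequence(blade_profile, protein[rs:re_], config,
                             protein_id=f"loc:{propeller.protein_id}@{rs}",
                             min_coverage=0.5, max_p=0.5)
        for h in hits:
            s, e = h.start + rs, h.end + rs
            if any(s < qe and qs < e for qs, qe in retained_ivs):
                continue
            if s - propeller.end <= window and propeller.start - e <= window:
                return True
        return False

    n_flank_start = max(0, propeller.start - 3 * window)
    if adjacent_blade_match(n_flank_start, propeller.start) or \
            adjacent_blade_match(propeller.end,
                                 min(len(protein),
                                     propeller.end + 3 * window)):
        return "local"

    blades = propeller.blades(protein)
    med = propeller.median_blade_identity
    for a, b in zip(blades, blades[1:]):
        pid = msa.pairwise_identity(a, b)
        if pid >= near_identical and pid > med + excess_over_median:
            return "mixed"
    return "global"


def terminus_distance(propeller: PropellerAnnotation, protein_length: int
                      ) -> tuple[int, int, int]:
    """(min distance, N-terminal distance, C-terminal distance) in residues."""
    n_dist = propeller.start
    c_dist = protein_length - propeller.end
    return min(n_dist, c_dist), n_dist, c_dist


def terminus_census(propellers: list[PropellerAnnotation],
                    protein_lengths: dict[str, int],
                    thresholds: tuple[int, int] = (50, 30)) -> dict:
    """Count propellers near the termini of their host proteins.

    Reports how many lie less than ``thresholds[0]`` residues from at
    least one terminus and less than ``thresholds[1]`` from both.
    """
    near_one = near_both = 0
    for p in propellers:
        mn, nd, cd = terminus_distance(p, protein_lengths[p.protein_id])
        p.min_terminus_distance = mn
        if mn < thresholds[0]:
            near_one += 1
        if nd < thresholds[1] and cd < thresholds[1]:
            near_both += 1
    return {"n": len(propellers),
            f"near_one_lt_{thresholds[0]}": near_one,
            f"near_both_lt_{thresholds[1]}": near_both}
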