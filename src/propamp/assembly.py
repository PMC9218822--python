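"""Grouping blade matches into candidate β-propellers.

Consecutive blade matches on one protein belong to the same propeller when
the linker between them is less than three MADe away from the median linker
length of the whole dataset; chains of at least two blades become candidate
propellers, which are kept only if the median pairwise identity of their
blades (computed on a center-star multiple alignment) is strictly higher
than 60% — the operational definition of a recently amplified, highly
repetitive propeller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from propamp import msa
from propamp.profiles import BladeMatch
from propamp.stats import made, median


class UndefinedStatsError(ValueError):
    """Raised when linker statistics are requested without any linkers."""


@dataclass
class LinkerStats:
    median_linker: float
    made_linker: float
    n_linkers: int


@dataclass
class PropellerAnnotation:
    """An ordered set of blade intervals on one protein."""

    protein_id: str
    blade_intervals: list[tuple[int, int]]
    median_blade_identity: float = float("nan")
    family: str = "UNKNOWN"
    locality: str = "unassigned"  # global | local | mixed | unassigned
    min_terminus_distance: int | None = None

    @property
    def start(self) -> int:
        return self.blade_intervals[0][0]

    @property
    def end(self) -> int:
        return self.blade_intervals[-1][1]

    @property
    def n_blades(self) -> int:
        return len(self.blade_intervals)

    @property
    def coverage(self) -> int:
        return sum(e - s for s, e in self.blade_intervals)

    def blades(self, protein: str) -> list[str]:
        return [protein[s:e] for s, e in self.blade_intervals]

    def to_dict(self) -> dict:
        return asdict(self)


def linker_lengths(matches: list[BladeMatch]) -> list[int]:
    """Inter-match gaps (residues) between consecutive matches, per protein."""
    gaps: list[int] = []
    by_protein: dict[str, list[BladeMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.protein_id, []).append(m)
    for pid in sorted(by_protein):
        ms = sorted(by_protein[pid], key=lambda m: m.start)
        gaps.extend(b.start - a.end for a, b in zip(ms, ms[1:]))
    return gaps


def linker_statistics(matches: list[BladeMatch]) -> LinkerStats:
    """Median and MADe of all linkers in the dataset.

    Pooled over every protein in the run, mirroring per-cluster pooling of
    the search; raises :class:`UndefinedStatsError` with zero linkers.
    """
    gaps = linker_lengths(matches)
    if not gaps:
        raise UndefinedStatsError("no linkers between consecutive matches")
    return LinkerStats(median_linker=median(gaps), made_linker=made(gaps),
                       n_linkers=len(gaps))


def _same_propeller(gap: float, stats: LinkerStats, mades: float,
                    two_sided: bool) -> bool:
    if stats.made_linker == 0.0:
        # degenerate spread: accept single-residue jitter (inclusive)
        if two_sided:
            return abs(gap - stats.median_linker) <= 1.0
        return gap <= stats.median_linker + 1.0
    tol = mades * stats.made_linker
    if two_sided:
        return abs(gap - stats.median_linker) < tol
    return gap < stats.median_linker + tol


def group_into_propellers(matches: list[BladeMatch], stats: LinkerStats,
                          mades: float = 3.0, two_sided: bool = True
                          ) -> list[PropellerAnnotation]:
    """Chain consecutive matches into candidate propellers.

    A chain extends while the linker stays within ``mades`` MADe of the
    median linker (two-sided by default); chains with fewer than two blades
    are dropped. Identity is not yet computed here.
    """
    out: list[PropellerAnnotation] = []
    by_protein: dict[str, list[BladeMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.protein_id, []).append(m)
    for pid in sorted(by_protein):
        ms = sorted(by_protein[pid], key=lambda m: m.start)
        chain: list[BladeMatch] = [ms[0]]
        for prev, cur in zip(ms, ms[1:]):
            if _same_propeller(cur.start - prev.end, stats, mades,
                               two_sided):
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    out.append(PropellerAnnotation(
                        pid, [m.interval for m in chain]))
                chain = [cur]
        if len(chain) >= 2:
            out.append(PropellerAnnotation(pid,
                                           [m.interval for m in chain]))
    return out


def median_blade_identity(blades: list[str]) -> float:
    """Median pairwise identity over all blade pairs of one propeller.

    Blades are center-star multiple-aligned; each pair's identity is the
    fraction of identical residues over columns where both blades are
    non-gap (end gaps therefore never count).
    """
    if len(blades) < 2:
        raise ValueError("need at least two blades")
    rows = msa.center_star_align(blades)
    ids = [msa.column_identity(rows[i], rows[j])
           for i in range(len(rows)) for j in range(i + 1, len(rows))]
    return float(np.median(ids))


def annotate_identity(propellers: list[PropellerAnnotation],
                      proteins: dict[str, str]
                      ) -> list[PropellerAnnotation]:
    for p in propellers:
        p.median_blade_identity = median_blade_identity(
            p.blades(proteins[p.protein_id]))
    return propellers


def filter_highly_repetitive(propellers: list[PropellerAnnotation],
                             threshold: float = 0.60
                             ) -> list[PropellerAnnotation]:
    """Keep propellers with median blade identity strictly above threshold."""
    return [p for p in propellers if p.median_blade_identity > threshold]
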