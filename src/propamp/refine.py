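"""De-novo repeat detection and merging with profile-based annotations.

Profile search can miss strongly diverged blades. This stage detects
repeats directly, by locally aligning each protein against itself with the
main diagonal masked: for a tandem repeat the optimal off-diagonal
self-alignment pairs the array with a copy of itself shifted by one repeat
unit, so the median offset of the aligned pairs estimates the period and
the aligned span delimits the repeat region. Units that could hold two or
more blades (judged against the median annotated blade length) are
decomposed recursively; surviving single-blade units are merged with the
profile-based propellers to maximise coverage, and merged propellers are
re-scored and re-filtered at the 60% identity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from propamp._sw import (alloc_dp, sw_fill, sw_self_score_batch,
                         sw_traceback)
from propamp.alphabet import BLOSUM62_21, encode_protein
from propamp.assembly import PropellerAnnotation, median_blade_identity
from propamp.profiles import SearchConfig
from propamp.stats import median, stable_seed


@dataclass
class RepeatUnit:
    """One tiled unit of a detected self-repeat (0-based half-open)."""

    start: int
    end: int
    repeat_type: int
    period: int
    significance: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def _self_null(idx: np.ndarray, min_sep: int, config: SearchConfig,
               seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    tiled = np.tile(idx, (config.n_shuffles, 1))
    shuffled = rng.permuted(tiled, axis=1)
    return np.sort(sw_self_score_batch(shuffled, BLOSUM62_21, min_sep,
                                       config.gap_open, config.gap_extend))


def detect_self_repeats(protein: str, config: SearchConfig | None = None,
                        repeat_p: float = 0.10, min_period: int = 15,
                        protein_id: str = "", max_types: int = 3
                        ) -> list[RepeatUnit]:
    """Detect tandem repeats in one protein by masked self-alignment.

    Repeats are extracted greedily: the best off-diagonal self-alignment
    votes a period (median offset of its aligned pairs) and a covered
    span, units are tiled across the span at that period, the span is
    masked, and the search repeats for further repeat types. Significance
    is an empirical p-value against shuffled sequences; types with
    p > ``repeat_p`` are not reported.
    """
    config = config or SearchConfig()
    n = len(protein)
    if n < 2 * min_period:
        return []
    idx = encode_protein(protein)
    seed = stable_seed(config.rng_seed, "selfrep", protein_id, n)
    null = _self_null(idx, min_period, config, seed)

    prof = BLOSUM62_21[idx].copy()  # column j scores residue pairs with j
    blocked = np.zeros(n, dtype=np.uint8)
    H, E, F = alloc_dp(n, n)
    units: list[RepeatUnit] = []
    for rep_type in range(1, max_types + 1):
        best, bi, bj = sw_fill(idx, prof, config.gap_open,
                               config.gap_extend, min_period, blocked,
                               H, E, F)
        if best <= 0.0:
            break
        p = float(1 + np.sum(null >= best - 1e-9)) / (config.n_shuffles + 1)
        if p > repeat_p:
            break
        ai, aj, k = sw_traceback(idx, prof, config.gap_open,
                                 config.gap_extend, H, E, F, bi, bj)
        if k < min_period:
            break
        offsets = ai[:k] - aj[:k]
        period = int(round(float(np.median(offsets))))
        if k < period:
            # a real tandem repeat aligns at least one full period of
            # residues against the next copy; shorter off-diagonal hits
            # are spurious
            break
        span_start = int(aj[0])
        span_end = int(ai[k - 1]) + 1
        span = span_end - span_start
        n_units = max(2, int(np.floor(span / period + 0.5)))
        for t in range(n_units):
            s = span_start + t * period
            e = min(span_start + (t + 1) * period, n)
            if e - s >= max(4, period // 2):
                units.append(RepeatUnit(s, e, rep_type, period, p))
        blocked[span_start:span_end] = 1
        prof[span_start:span_end, :] = -1e9
    return units


def blades_per_unit(unit_length: float, median_blade_length: float) -> int:
    """Number of blades a repeat unit can accommodate (nearest integer,
    at least one)."""
    if unit_length <= 0 or median_blade_length <= 0:
        raise ValueError("lengths must be positive")
    return max(1, int(np.floor(unit_length / median_blade_length + 0.5)))


def decompose_units(units: list[RepeatUnit], median_blade_length: float,
                    protein: str, config: SearchConfig | None = None,
                    repeat_p: float = 0.10, max_depth: int = 5
                    ) -> list[RepeatUnit]:
    """Recursively break multi-blade repeat units into single-blade units.

    A unit accommodating two or more blades is re-analysed by self-repeat
    detection on its own subsequence; if that fails to resolve it, the
    unit is split evenly into the predicted number of blades.
    """
    config = config or SearchConfig()

    def _decompose(unit: RepeatUnit, depth: int) -> list[RepeatUnit]:
        nb = blades_per_unit(unit.length, median_blade_length)
        if nb < 2 or depth >= max_depth:
            return [unit]
        sub_seq = protein[unit.start:unit.end]
        min_p = max(8, int(median_blade_length * 0.5))
        subs = detect_self_repeats(
            sub_seq, config, repeat_p=repeat_p, min_period=min_p,
            protein_id=f"decomp@{unit.start}")
        subs = [s for s in subs if s.period < unit.length]
        if not subs:
            # even split fallback
            bounds = [unit.start +
                      int(round(t * unit.length / nb)) for t in range(nb + 1)]
            return [replace(unit, start=a, end=b,
                            period=unit.length // nb)
                    for a, b in zip(bounds, bounds[1:])]
        out: list[RepeatUnit] = []
        for s in subs:
            lifted = replace(s, start=s.start + unit.start,
                             end=s.end + unit.start,
                             repeat_type=unit.repeat_type)
            out.extend(_decompose(lifted, depth + 1))
        return out

    result: list[RepeatUnit] = []
    for u in units:
        result.extend(_decompose(u, 0))
    result.sort(key=lambda u: u.start)
    return result


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def merge_annotations(propellers: list[PropellerAnnotation],
                      repeat_units: list[RepeatUnit], protein: str,
                      protein_id: str = "",
                      identity_threshold: float = 0.60
                      ) -> list[PropellerAnnotation]:
    """Merge de-novo repeat units into the profile-based propellers.

    Only repeat types whose units overlap already annotated blades count;
    a type spanning several propellers merges them into one whose blade
    set is the union plus any units not previously annotated, maximising
    protein coverage. Merged propellers are re-scored and re-filtered at
    the identity threshold (strict >). Unreferenced repeat types are
    ignored; propellers untouched by any repeat type pass through.
    """
    if not propellers:
        return []
    props = sorted(propellers, key=lambda p: p.start)
    blades_of = [list(p.blade_intervals) for p in props]

    # map repeat types to the propellers they touch
    by_type: dict[int, list[RepeatUnit]] = {}
    for u in repeat_units:
        by_type.setdefault(u.repeat_type, []).append(u)
    type_to_props: dict[int, set[int]] = {}
    for t, units in by_type.items():
        touched = {i for i, blades in enumerate(blades_of)
                   if any(_overlaps(u.interval, b)
                          for u in units for b in blades)}
        if touched:
            type_to_props[t] = touched

    # union-find over propellers linked by a shared repeat type
    parent = list(range(len(props)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for members in type_to_props.values():
        it = iter(sorted(members))
        first = next(it)
        for j in it:
            parent[find(j)] = find(first)

    groups: dict[int, list[int]] = {}
    for i in range(len(props)):
        groups.setdefault(find(i), []).append(i)

    out: list[PropellerAnnotation] = []
    for members in groups.values():
        members = sorted(members)
        group_types = [t for t, touched in type_to_props.items()
                       if touched & set(members)]
        existing = sorted({iv for i in members for iv in blades_of[i]})
        if not group_types:
            out.extend(props[i] for i in members)
            continue
        candidates = sorted(
            (u.interval for t in group_types for u in by_type[t]),
            key=lambda iv: (-(iv[1] - iv[0]), iv[0]))
        blades = list(existing)
        for iv in candidates:
            # clip boundary jitter against already accepted blades; a unit
            # is added when most of it is genuinely new sequence
            s, e = iv
            for b in sorted(blades):
                if not _overlaps((s, e), b):
                    continue
                if b[0] <= s:
                    s = max(s, b[1])
                elif b[1] >= e:
                    e = min(e, b[0])
                else:  # blade strictly inside the unit: reject the unit
                    s = e
                    break
            if e - s >= 0.6 * (iv[1] - iv[0]):
                blades.append((s, e))
        blades.sort()
        merged = PropellerAnnotation(
            protein_id=props[members[0]].protein_id or protein_id,
            blade_intervals=blades,
            family=props[members[0]].family,
        )
        merged.median_blade_identity = median_blade_identity(
            merged.blades(protein))
        if merged.median_blade_identity > identity_threshold:
            out.append(merged)
        else:
            # merged candidate fails the filter: keep the originals
            out.extend(props[i] for i in members)
    out.sort(key=lambda p: p.start)
    return out
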