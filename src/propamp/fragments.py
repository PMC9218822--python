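"""Blade-coding fragments in non-coding DNA and disruption reconstruction.

Highly repetitive propellers concentrate near protein termini, which
suggests many are remnants of longer, since-disrupted propeller genes. To
find the missing blades, the intergenic regions flanking a propeller gene
are translated in all three frames in the gene's direction (stop codons
rendered as X), scanned with the blade profiles under a permissive
confidence gate, and filtered to matches of at least 20 residues with at
most 15% stop content. Fragment frames relative to the anchor ORF then
tell the story: in-frame fragments beyond the ORF's stop indicate a
premature in-frame stop codon; fragments in a shifted frame indicate a
frameshifting deletion, whose position is pinned down by aligning the
observed genomic span against an idealised tandem repeat of the anchor's
own first blade unit and locating the indel whose length is not a
multiple of three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from propamp.alphabet import STOP_CODONS, translate
from propamp.assembly import PropellerAnnotation
from propamp.profiles import Profile, SearchConfig, scan_sequence
from propamp.simulate import GeneRecord
from propamp.stats import median


@dataclass
class IntergenicRegion:
    """A forward-strand non-coding interval flanking an anchor gene."""

    genome_id: str
    start: int
    end: int
    side: str                     # five_prime | three_prime
    direction: str                # of the anchor gene
    sequence: str
    translations: list[str] = field(default_factory=list)
    stop_positions: list[list[int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentMatch:
    """A blade-like match inside a translated intergenic frame."""

    genome_id: str
    region_start: int
    region_end: int
    side: str
    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    confidence: float
    stop_content: float
    profile_name: str = ""

    @property
    def length(self) -> int:
        return self.aa_end - self.aa_start


@dataclass
class DisruptionReport:
    anchor_protein_id: str
    kind: str                     # frameshift | inframe_stop | both | none
    evidence: list[FragmentMatch] = field(default_factory=list)
    inferred_event_position: int | None = None
    reconstructed_blade_count: int = 0


# --------------------------------------------------------------------------


def translate_frames(seq: str) -> tuple[list[str], list[list[int]]]:
    """Three forward-frame translations with stops rendered as X.

    Returns (translations, stop positions per frame); stop positions are
    residue indices within each translation.
    """
    translations: list[str] = []
    stops: list[list[int]] = []
    for f in range(3):
        sub = seq[f:]
        aa = translate(sub, to_x=True)
        translations.append(aa)
        stops.append([i for i in range(len(aa))
                      if sub[3 * i:3 * i + 3] in STOP_CODONS])
    return translations, stops


def extract_intergenic(genome_seq: str, genes: list[GeneRecord],
                       anchor_id: str, genome_id: str = "genome"
                       ) -> list[IntergenicRegion]:
    """The 5' and 3' intergenic regions of the anchor gene.

    Regions run from the anchor ORF to the closest flanking ORF in the
    same direction (or the genome edge); sides with no room for a codon
    are omitted.
    """
    ordered = sorted(genes, key=lambda g: g.start)
    idx = next((i for i, g in enumerate(ordered)
                if g.gene_id == anchor_id), None)
    if idx is None:
        raise KeyError(f"anchor gene {anchor_id!r} not in gene table")
    anchor = ordered[idx]
    five_start = ordered[idx - 1].end if idx > 0 else 0
    three_end = (ordered[idx + 1].start if idx + 1 < len(ordered)
                 else len(genome_seq))
    out: list[IntergenicRegion] = []
    for start, end, side in ((five_start, anchor.start, "five_prime"),
                             (anchor.end, three_end, "three_prime")):
        if end - start < 3:
            continue
        seq = genome_seq[start:end]
        translations, stops = translate_frames(seq)
        out.append(IntergenicRegion(genome_id, start, end, side,
                                    anchor.strand, seq, translations,
                                    stops))
    return out


def scan_fragments(regions: list[IntergenicRegion],
                   profiles: dict[str, Profile],
                   config: SearchConfig | None = None,
                   min_len: int = 20, strict_len: bool = False,
                   max_stop: float = 0.15, max_p: float = 0.5,
                   min_cov: float = 0.30, max_passes: int = 5
                   ) -> list[FragmentMatch]:
    """Scan translated intergenic frames for blade-like fragments.

    Each frame is scanned iteratively (annotated stretches masked between
    passes, up to ``max_passes``); accepted matches are at least
    ``min_len`` residues (strictly more with ``strict_len``), contain at
    most ``max_stop`` stop-codon-derived X, and pass the permissive
    empirical confidence gate ``max_p``.
    """
    config = config or SearchConfig()
    if not profiles:
        raise ValueError("no profiles supplied")
    out: list[FragmentMatch] = []
    for region in regions:
        region_hits: list[FragmentMatch] = []
        for frame in range(3):
            aa = region.translations[frame]
            stops = set(region.stop_positions[frame])
            masked = aa
            accepted: list[tuple[int, int]] = []
            for _ in range(max_passes):
                new: list[FragmentMatch] = []
                for name in sorted(profiles):
                    hits = scan_sequence(
                        profiles[name], masked, config,
                        protein_id=(f"frag:{region.genome_id}:"
                                    f"{region.start}:{frame}:{name}"),
                        min_coverage=min_cov, max_p=max_p)
                    for h in hits:
                        long_enough = (h.length > min_len if strict_len
                                       else h.length >= min_len)
                        if not long_enough:
                            continue
                        n_stop = sum(1 for s in stops
                                     if h.start <= s < h.end)
                        stop_frac = n_stop / h.length
                        if stop_frac > max_stop + 1e-9:
                            continue
                        if any(h.start < e and s < h.end
                               for s, e in accepted):
                            continue
                        new.append(FragmentMatch(
                            genome_id=region.genome_id,
                            region_start=region.start,
                            region_end=region.end,
                            side=region.side, frame=frame,
                            aa_start=h.start, aa_end=h.end,
                            nt_start=region.start + frame + 3 * h.start,
                            nt_end=region.start + frame + 3 * h.end,
                            confidence=1.0 - h.significance,
                            stop_content=stop_frac,
                            profile_name=name))
                if not new:
                    break
                # keep the best per overlapping cluster, then mask
                new.sort(key=lambda m: -m.confidence)
                for m in new:
                    if any(m.aa_start < e and s < m.aa_end
                           for s, e in accepted):
                        continue
                    accepted.append((m.aa_start, m.aa_end))
                    region_hits.append(m)
                chars = list(masked)
                for s, e in accepted:
                    for i in range(s, e):
                        chars[i] = "X"
                masked = "".join(chars)
        # a genomic locus codes in one frame only: matches from different
        # frames that overlap on the genome are echoes of the same blade
        # DNA; keep the most confident one
        region_hits.sort(key=lambda m: (-m.confidence,
                                        -(m.nt_end - m.nt_start), m.frame))
        kept_hits: list[FragmentMatch] = []
        for m in region_hits:
            clash = False
            for k in kept_hits:
                ov = min(m.nt_end, k.nt_end) - max(m.nt_start, k.nt_start)
                if ov > 0.3 * min(m.nt_end - m.nt_start,
                                  k.nt_end - k.nt_start):
                    clash = True
                    break
            if not clash:
                kept_hits.append(m)
        out.extend(kept_hits)
    out.sort(key=lambda m: (m.genome_id, m.nt_start))
    return out


# --------------------------------------------------------------------------


def _merge_same_frame(frags: list[FragmentMatch], max_gap_aa: int
                      ) -> list[tuple[int, int, int, int]]:
    """Merge same-frame fragments separated by less than a blade.

    Returns (frame, nt_start, nt_end, n_matches) spans.
    """
    spans: list[tuple[int, int, int, int]] = []
    by_frame: dict[tuple[int, int], list[FragmentMatch]] = {}
    for f in frags:
        by_frame.setdefault((f.region_start, f.frame), []).append(f)
    for (_, frame), ms in sorted(by_frame.items()):
        ms.sort(key=lambda m: m.nt_start)
        cur_s, cur_e, cur_n = ms[0].nt_start, ms[0].nt_end, 1
        for m in ms[1:]:
            if m.nt_start - cur_e <= 3 * max_gap_aa:
                cur_e = max(cur_e, m.nt_end)
                cur_n += 1
            else:
                spans.append((frame, cur_s, cur_e, cur_n))
                cur_s, cur_e, cur_n = m.nt_start, m.nt_end, 1
        spans.append((frame, cur_s, cur_e, cur_n))
    return spans


def locate_frameshift(genome_seq: str, anchor: GeneRecord,
                      propeller: PropellerAnnotation,
                      span_end_nt: int, edge_nt: int = 12) -> int | None:
    """Locate a frame-changing indel by tandem-template alignment.

    The anchor's first blade unit (blade plus following linker) is tiled
    into an idealised undisrupted repeat and globally aligned to the
    observed genomic span from the first anchor blade to the end of the
    downstream fragment; the first indel whose length is not a multiple
    of three (ignoring ``edge_nt`` at either end, where end effects live)
    marks the event. Returns a genome coordinate or None.
    """
    blades = propeller.blade_intervals
    if len(blades) < 2:
        return None
    unit_s = anchor.start + 3 * blades[0][0]
    unit_e = anchor.start + 3 * blades[1][0]
    unit = genome_seq[unit_s:unit_e]
    if not unit:
        return None
    obs = genome_seq[unit_s:span_end_nt]
    if len(obs) < len(unit):
        return None
    reps = math.ceil((len(obs) + 3) / len(unit)) + 1
    template = (unit * reps)[:len(obs) + 2]
    res = edlib.align(template, obs, task="path", mode="NW")
    cigar = res.get("cigar") or ""
    # collect indels as (observed position, signed length): +k for bases
    # missing from the observed sequence, -k for extra observed bases
    indels: list[tuple[int, int]] = []
    opos = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch in "=XM":
            opos += length
        elif ch == "I":  # extra template bases: deletion in the observed
            indels.append((opos, length))
        elif ch == "D":  # extra observed bases: insertion in the observed
            indels.append((opos, -length))
            opos += length
    # indel ops at one linker junction (within ~15 nt of each other)
    # jointly encode that junction's length change: linker-length jitter
    # nets to a multiple of three, the frameshift event does not. The
    # event position is the first frame-breaking op of its cluster.
    clusters: list[list[tuple[int, int]]] = []
    for pos, ln in indels:
        if clusters and pos - clusters[-1][-1][0] <= 15:
            clusters[-1].append((pos, ln))
        else:
            clusters.append([(pos, ln)])
    for ops in clusters:
        net = sum(ln for _, ln in ops)
        if net % 3 == 0:
            continue
        frame_breaking = [pos for pos, ln in ops if ln % 3]
        pos = frame_breaking[0] if frame_breaking else ops[0][0]
        if edge_nt <= pos <= len(obs) - edge_nt:
            return unit_s + pos
    return None


def reconstruct_disruption(anchor: GeneRecord,
                           propeller: PropellerAnnotation,
                           fragments: list[FragmentMatch],
                           genome_seq: str) -> DisruptionReport:
    """Infer the disruption event linking an anchor ORF to its fragments.

    Fragments in the anchor's reading frame beyond its stop imply an
    in-frame stop codon; fragments in a shifted frame imply a frameshift;
    both signals together are reported as "both". The reconstructed blade
    count adds the blades accommodated by the (merged) fragment spans to
    the anchor's own.
    """
    if not fragments:
        return DisruptionReport(propeller.protein_id, "none")
    blade_lens = [e - s for s, e in propeller.blade_intervals]
    mbl = median(blade_lens)
    gaps = [b[0] - a[1] for a, b in zip(propeller.blade_intervals,
                                        propeller.blade_intervals[1:])]
    mlink = median(gaps) if gaps else 2.0
    unit_aa = mbl + mlink

    # an intergenic region is shared with the next/previous gene, so a
    # stranded blade run must be attributed to one of them: fragments are
    # clustered (gaps over ~2 blade units split clusters) and a cluster
    # counts for this anchor only when its nearest end lies at least as
    # close to the anchor ORF as to the other flanking ORF
    def cluster_near_anchor(cluster: list[FragmentMatch]) -> bool:
        lo = min(f.nt_start for f in cluster)
        hi = max(f.nt_end for f in cluster)
        region = cluster[0]
        if region.side == "three_prime":
            return lo - region.region_start <= region.region_end - hi
        return region.region_end - hi <= lo - region.region_start

    kept: list[FragmentMatch] = []
    by_region: dict[tuple[int, str], list[FragmentMatch]] = {}
    for f in fragments:
        by_region.setdefault((f.region_start, f.side), []).append(f)
    for ms in by_region.values():
        ms.sort(key=lambda m: m.nt_start)
        cluster: list[FragmentMatch] = [ms[0]]
        for m in ms[1:]:
            if m.nt_start - cluster[-1].nt_end > 2 * 3 * unit_aa:
                if cluster_near_anchor(cluster):
                    kept.extend(cluster)
                cluster = [m]
            else:
                cluster.append(m)
        if cluster_near_anchor(cluster):
            kept.extend(cluster)
    fragments = kept
    if not fragments:
        return DisruptionReport(propeller.protein_id, "none")

    # only merged spans that can hold at least about half a blade count as
    # propeller-fragment evidence; shorter permissive-gate matches in
    # random intergenic sequence are noise
    spans = _merge_same_frame(fragments, max_gap_aa=int(mbl))
    spans = [sp for sp in spans if sp[2] - sp[1] >= 0.5 * 3 * unit_aa]
    if not spans:
        return DisruptionReport(propeller.protein_id, "none",
                                evidence=sorted(fragments,
                                                key=lambda f: f.nt_start))
    offsets = {(s - anchor.start) % 3 for _, s, _, _ in spans}
    shifted = offsets - {0}
    if shifted and 0 in offsets:
        kind = "both"
    elif shifted:
        kind = "frameshift"
    else:
        kind = "inframe_stop"

    # per span, the blade count is the larger of the number of merged
    # matches and the span-length estimate (matches can clip blade
    # boundaries; long matches can hold more than one blade)
    frag_blades = sum(
        max(1, n, int(math.floor((e - s) / 3 / unit_aa + 0.5)))
        for _, s, e, n in spans)
    total = propeller.n_blades + frag_blades

    if kind == "inframe_stop":
        event: int | None = anchor.end - 3
    else:
        span_end = max(e for _, _, e, _ in spans)
        event = locate_frameshift(genome_seq, anchor, propeller, span_end)
        if event is None:
            event = anchor.end - 3
    return DisruptionReport(propeller.protein_id, kind,
                            evidence=sorted(fragments,
                                            key=lambda f: f.nt_start),
                            inferred_event_position=event,
                            reconstructed_blade_count=total)
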