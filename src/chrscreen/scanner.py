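"""Promoter-window construction and conservation-filtered CHR motif scanning.

The screen looks for a CHR element within 1000 bp upstream or downstream of
each annotated TSS, on both strands. Windows are clipped so they never
extend into the gene's own coding sequence, into any other annotated gene,
or past a chromosome edge. A hit counts only when its mean per-base
conservation score over the 6 bp reaches the threshold (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .conservation import ConservationTrack
from .genome import GeneAnnotation, GeneModel
from .motifs import ChrMotifSet, DEFAULT_MOTIFS

DEFAULT_FLANK = 1000
DEFAULT_MIN_CONSERVATION = 0.9


@dataclass(frozen=True)
class ClipEvent:
    side: str  # "upstream" | "downstream" (transcription orientation)
    cause: str  # "cds" | "neighbor_gene" | "chrom_edge"
    removed_bp: int


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    interval: tuple[int, int]  # 0-based half-open; start == end when empty
    clip_events: tuple[ClipEvent, ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.interval[0] >= self.interval[1]

    def __len__(self) -> int:
        return max(0, self.interval[1] - self.interval[0])


@dataclass(frozen=True)
class ConservedMotifHit:
    """One CHR occurrence: strand-normalized motif, position and conservation."""

    gene_id: str
    motif: str  # canonical (forward) motif string
    chrom: str
    start: int  # 0-based half-open genomic interval of length 6
    end: int
    hit_strand: str  # strand of the genome carrying the canonical string
    mean_conservation: float | None = None
    partially_covered: bool = False


def _side(strand: str, genomic_side: str) -> str:
    """Map a genomic side (left/right) to transcription orientation."""
    if strand == "+":
        return "upstream" if genomic_side == "left" else "downstream"
    return "downstream" if genomic_side == "left" else "upstream"


def build_promoter_window(
    gene: GeneModel,
    annotation: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
    tss: int | None = None,
    clip_neighbors: str = "both",
) -> PromoterWindow:
    """Clip [tss - flank, tss + flank) against CDS, neighbors and edges.

    ``clip_neighbors`` selects whether other genes' intervals are excluded
    on both sides of the TSS (default, the strict reading) or only on the
    transcriptionally upstream side. An empty window is a valid result —
    the gene simply cannot have a CHR hit — never an error.
    """
    if clip_neighbors not in ("both", "upstream_only"):
        raise ValueError("clip_neighbors must be 'both' or 'upstream_only'")
    tss = gene.tss if tss is None else tss
    events: list[ClipEvent] = []
    start, end = tss - flank, tss + flank

    # chromosome edges
    chrom_len = annotation.chrom_sizes.get(gene.chrom)
    if start < 0:
        events.append(ClipEvent(_side(gene.strand, "left"), "chrom_edge", -start))
        start = 0
    if chrom_len is not None and end > chrom_len:
        events.append(ClipEvent(_side(gene.strand, "right"), "chrom_edge", end - chrom_len))
        end = chrom_len

    # the gene's own coding sequence: stop at the first coding base in
    # transcription direction (the CDS boundary nearest the TSS)
    first_cds = gene.cds_first_base()
    if first_cds is not None:
        if gene.strand == "+" and first_cds < end:
            removed = end - max(first_cds, start)
            if removed > 0:
                events.append(ClipEvent("downstream", "cds", removed))
            end = max(first_cds, start)
        elif gene.strand == "-" and first_cds >= start:
            removed = min(first_cds + 1, end) - start
            if removed > 0:
                events.append(ClipEvent("downstream", "cds", removed))
            start = min(first_cds + 1, end)

    # other genes' intervals (either strand)
    for other in annotation.overlapping(gene.chrom, start, end):
        if other.gene_id == gene.gene_id or start >= end:
            continue
        o_start, o_end = other.gene_interval
        if o_start <= tss < o_end:
            # neighbor covers the TSS itself: nothing scannable remains
            events.append(ClipEvent("upstream", "neighbor_gene", end - start))
            start = end = tss
            break
        if o_end <= tss:
            keep = clip_neighbors == "both" or _side(gene.strand, "left") == "upstream"
            removed = min(o_end, end) - start
            if keep and removed > 0:
                events.append(ClipEvent(_side(gene.strand, "left"), "neighbor_gene", removed))
                start = min(o_end, end)
        else:
            keep = clip_neighbors == "both" or _side(gene.strand, "right") == "upstream"
            removed = end - max(o_start, start)
            if keep and removed > 0:
                events.append(ClipEvent(_side(gene.strand, "right"), "neighbor_gene", removed))
                end = max(o_start, start)

    if start >= end:
        start = end = tss
    return PromoterWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        tss=tss,
        strand=gene.strand,
        interval=(start, end),
        clip_events=tuple(events),
    )


def scan_motifs(
    window: PromoterWindow,
    sequence: str,
    motifs: ChrMotifSet = DEFAULT_MOTIFS,
) -> list[ConservedMotifHit]:
    """Exact-match scan of both strands of a window (pre-conservation filter).

    ``sequence`` is the full chromosome sequence covering the window;
    matching is case-insensitive (soft-masked lowercase is scanned), and
    positions containing non-ACGT characters (e.g. N) never match. A
    minus-strand occurrence is reported with its motif field normalized to
    the canonical forward string. Overlapping hits are all reported.
    """
    if window.is_empty:
        return []
    start, end = window.interval
    if len(sequence) < end:
        raise ValueError(
            f"sequence of length {len(sequence)} does not cover window "
            f"[{start}, {end}) of gene {window.gene_id}"
        )
    region = sequence[start:end].upper()
    forward = motifs.forward()
    rc_index = motifs.rc_index()
    width = motifs.width
    hits: list[ConservedMotifHit] = []
    for off in range(len(region) - width + 1):
        word = region[off : off + width]
        if word in forward:
            hits.append(
                ConservedMotifHit(
                    gene_id=window.gene_id,
                    motif=word,
                    chrom=window.chrom,
                    start=start + off,
                    end=start + off + width,
                    hit_strand="+",
                )
            )
        if word in rc_index:
            hits.append(
                ConservedMotifHit(
                    gene_id=window.gene_id,
                    motif=rc_index[word],
                    chrom=window.chrom,
                    start=start + off,
                    end=start + off + width,
                    hit_strand="-",
                )
            )
    return hits


def mean_conservation(
    track: ConservationTrack, chrom: str, start: int, end: int
) -> tuple[float, bool]:
    """Mean per-base score over a motif interval; uncovered bases count 0."""
    return track.mean_score(chrom, start, end)


def filter_conserved(
    hits: list[ConservedMotifHit],
    track: ConservationTrack,
    min_mean: float = DEFAULT_MIN_CONSERVATION,
) -> list[ConservedMotifHit]:
    """Retain hits whose mean conservation reaches min_mean (inclusive)."""
    retained = []
    for hit in hits:
        mean, partial = track.mean_score(hit.chrom, hit.start, hit.end)
        if mean >= min_mean:
            retained.append(
                replace(hit, mean_conservation=mean, partially_covered=partial)
            )
    return retained


def _best_hit(hits: list[ConservedMotifHit], tss: int) -> ConservedMotifHit:
    # highest conservation; tie -> nearest TSS; tie -> smaller coordinate
    def distance(h: ConservedMotifHit) -> int:
        if h.start <= tss < h.end:
            return 0
        return min(abs(h.start - tss), abs(h.end - 1 - tss))

    return min(hits, key=lambda h: (-h.mean_conservation, distance(h), h.start))


def gene_has_conserved_chr(
    gene: GeneModel,
    annotation: GeneAnnotation,
    sequence: str,
    track: ConservationTrack,
    motifs: ChrMotifSet = DEFAULT_MOTIFS,
    flank: int = DEFAULT_FLANK,
    min_mean: float = DEFAULT_MIN_CONSERVATION,
    clip_neighbors: str = "both",
) -> tuple[bool, ConservedMotifHit | None]:
    """Scan every TSS window of a gene; True iff any retained hit exists.

    The reported best hit has the highest mean conservation across all of
    the gene's windows (ties broken toward the TSS, then by coordinate).
    """
    retained: list[ConservedMotifHit] = []
    best: ConservedMotifHit | None = None
    for tss in gene.tss_sites:
        window = build_promoter_window(
            gene, annotation, flank=flank, tss=tss, clip_neighbors=clip_neighbors
        )
        window_hits = filter_conserved(
            scan_motifs(window, sequence, motifs), track, min_mean
        )
        if window_hits:
            candidate = _best_hit(window_hits, tss)
            retained.extend(window_hits)
            if best is None or (-candidate.mean_conservation, candidate.start) < (
                -best.mean_conservation,
                best.start,
            ):
                best = candidate
    return bool(retained), best


def scan_annotation(
    annotation: GeneAnnotation,
    sequences: dict[str, str],
    track: ConservationTrack,
    motifs: ChrMotifSet = DEFAULT_MOTIFS,
    flank: int = DEFAULT_FLANK,
    min_mean: float = DEFAULT_MIN_CONSERVATION,
    clip_neighbors: str = "both",
) -> pd.DataFrame:
    """Per-gene conserved-CHR summary over a whole annotation.

    Returns a frame with one row per gene: conserved_chr flag plus the
    best hit's motif, coordinates, strand and mean conservation.
    """
    rows = []
    for gene in sorted(annotation, key=lambda g: g.gene_id):
        seq = sequences[gene.chrom]
        has, best = gene_has_conserved_chr(
            gene, annotation, seq, track, motifs, flank, min_mean, clip_neighbors
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "conserved_chr": has,
                "best_motif": best.motif if best else "",
                "best_start": best.start if best else -1,
                "best_end": best.end if best else -1,
                "best_strand": best.hit_strand if best else "",
                "best_mean_conservation": best.mean_conservation if best else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def write_hits_bed(hits: list[ConservedMotifHit], path: str) -> None:
    """BED6 of retained hits: name = gene_id|motif, score = 1000 x mean."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.gene_id)):
            score = int(round(1000 * (h.mean_conservation or 0.0)))
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.gene_id}|{h.motif}\t{score}\t{h.hit_strand}\n"
            )
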