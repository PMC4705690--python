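"""Synthetic input bundles with exact, planted ground truth.

Generates the complete set of inputs the screen consumes — gene annotation
(GFF3 + BED12), genome FASTA, a per-base conservation bedGraph, per-gene
ChIP detections for the four DREAM components, a six-study expression-call
matrix and a cell-cycle annotation — together with a ground-truth table
recording, for every gene, which criteria it was constructed to satisfy.

Background sequence is i.i.d. uniform over ACGT and then rejection-cleaned
so that no CHR motif (nor any reverse complement) occurs in any promoter
window except where planted: ground truth is exact, not probabilistic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conservation import ConservationTrack, write_bedgraph
from .genome import GeneAnnotation, GeneModel, write_bed12, write_gff3
from .motifs import ChrMotifSet, DEFAULT_MOTIFS, reverse_complement
from .scanner import DEFAULT_FLANK, DEFAULT_MIN_CONSERVATION

CHROM = "chrS"
STUDIES = tuple(f"study{i}" for i in range(1, 7))

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# gene architecture (bp): CDS begins one flank downstream of the TSS so the
# default +/-1000 window is never clipped by the gene's own CDS
_CDS_LEN = 600
_UTR_TAIL = 100


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Fractions give the share of genes constructed to satisfy each
    criterion independently; the expected final list is their random
    intersection. ``conservation_high`` scores the planted motif bases,
    ``conservation_low`` everything else.
    """

    n_genes: int
    chrom_length: int | None = None  # None: computed to fit the layout
    flank_intended: int = DEFAULT_FLANK
    planted_fraction_chr: float = 0.5
    planted_fraction_dream: float = 0.5
    planted_fraction_repressed: float = 0.5
    conservation_high: float = 1.0
    conservation_low: float = 0.0
    motif_offset_range: tuple[int, int] = (-900, 894)
    cellcycle_fraction_final: float = 0.75
    cellcycle_fraction_other: float = 0.2
    crowded: bool = False  # halve inter-gene spacing to exercise clipping
    multi_tss_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in (
            "planted_fraction_chr",
            "planted_fraction_dream",
            "planted_fraction_repressed",
            "cellcycle_fraction_final",
            "cellcycle_fraction_other",
            "multi_tss_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("conservation_high", "conservation_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.conservation_high < self.conservation_low:
            raise ValueError("conservation_high must be >= conservation_low")
        lo, hi = self.motif_offset_range
        if lo > hi:
            raise ValueError("motif_offset_range must be (lo, hi) with lo <= hi")
        if lo < -self.flank_intended or hi + 6 > self.flank_intended:
            raise ValueError(
                "motif_offset_range infeasible: planted motif "
                f"[{lo}, {hi}+6) must lie within the +/-{self.flank_intended} bp window"
            )

    @property
    def gene_length(self) -> int:
        return self.flank_intended + _CDS_LEN + _UTR_TAIL

    @property
    def spacing(self) -> int:
        # default keeps every intended window clear of neighbors; the
        # crowded layout forces neighbor clipping on purpose
        return self.flank_intended // 2 if self.crowded else 2 * self.flank_intended

    @property
    def pitch(self) -> int:
        return self.gene_length + self.spacing

    def required_length(self) -> int:
        return self.n_genes * self.pitch + 4 * self.flank_intended

    def resolved_chrom_length(self) -> int:
        need = self.required_length()
        if self.chrom_length is None:
            return need
        if self.chrom_length < need:
            raise ValueError(
                f"spec infeasible: chrom_length={self.chrom_length} cannot hold "
                f"{self.n_genes} genes with flank {self.flank_intended} "
                f"(need >= {need} bp so no intended window is truncated)"
            )
        return self.chrom_length


@dataclass
class GroundTruth:
    """Per-gene construction record; the oracle for the whole pipeline."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def expected_final(self) -> pd.Series:
        return self.table.set_index("gene_id")["expected_in_final_list"]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def plant_motif(
    sequence: np.ndarray,
    track_scores: np.ndarray,
    start: int,
    strand: str,
    motif: str,
    conservation: float,
    motifs: ChrMotifSet = DEFAULT_MOTIFS,
    window: tuple[int, int] | None = None,
) -> None:
    """Write a motif (its reverse complement on '-') at a genomic position.

    Mutates the sequence array and sets the conservation track over the six
    motif bases. Fails if the motif is not in the canonical set or would
    fall outside the stated promoter window (an undetectable "truth").
    """
    if motif not in motifs.forward():
        raise ValueError(f"{motif!r} is not in the canonical motif set")
    if window is not None and not (window[0] <= start and start + 6 <= window[1]):
        raise ValueError(
            f"planted motif at [{start}, {start + 6}) falls outside the "
            f"promoter window [{window[0]}, {window[1]})"
        )
    written = motif if strand == "+" else reverse_complement(motif)
    sequence[start : start + 6] = np.frombuffer(written.encode(), dtype="S1")
    track_scores[start : start + 6] = conservation


def _clean_windows(
    rng: np.random.Generator,
    sequence: np.ndarray,
    windows: list[tuple[int, int]],
    frozen: set[int],
    motifs: ChrMotifSet,
) -> None:
    """Redraw background bases until no motif occurs unplanted in a window.

    ``frozen`` holds base positions of planted motifs, which are never
    redrawn; any other occurrence of one of the 10 motifs or a reverse
    complement has its non-frozen bases resampled, iterating to a clean
    state (local redraws converge quickly even in long windows).
    """
    words = motifs.forward() | set(motifs.rc_index())
    planted_spans = set(frozen)

    # merge overlapping windows so a redraw can never dirty an
    # already-cleaned neighboring window
    merged: list[tuple[int, int]] = []
    for w_start, w_end in sorted(windows):
        if merged and w_start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w_end))
        else:
            merged.append((w_start, w_end))

    for w_start, w_end in merged:
        while True:
            dirty = []
            region = sequence[w_start:w_end].tobytes().decode()
            for off in range(len(region) - 5):
                if region[off : off + 6] in words:
                    g = w_start + off
                    span = set(range(g, g + 6))
                    if span <= planted_spans:
                        continue  # the planted motif itself
                    dirty.append(g)
            if not dirty:
                break
            for g in dirty:
                for pos in range(g, g + 6):
                    if pos not in planted_spans:
                        sequence[pos] = _BASES[rng.integers(0, 4)]


def _calls_for_score(rng: np.random.Generator, target: int) -> list[int]:
    """Six study calls in {-1,0,+1} summing to ``target``."""
    n_extra = int(rng.integers(0, (6 - abs(target)) // 2 + 1))
    n_minus = n_extra + max(0, -target)
    n_plus = n_extra + max(0, target)
    calls = [-1] * n_minus + [1] * n_plus + [0] * (6 - n_minus - n_plus)
    rng.shuffle(calls)
    return calls


def generate_cohort(spec: CohortSpec, outdir: str | Path) -> GroundTruth:
    """Write a full input bundle plus ground truth; byte-stable per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    flank = spec.flank_intended
    chrom_len = spec.resolved_chrom_length()

    # --- gene layout --------------------------------------------------
    genes: dict[str, GeneModel] = {}
    cursor = 2 * flank
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    multi_tss = rng.random(spec.n_genes) < spec.multi_tss_fraction
    for i in range(spec.n_genes):
        gid = f"G{i + 1:04d}"
        strand = str(strands[i])
        if strand == "+":
            g_start = cursor
            tss = g_start
            g_end = g_start + spec.gene_length
            cds = (tss + flank, tss + flank + _CDS_LEN)
        else:
            g_start = cursor
            g_end = g_start + spec.gene_length
            tss = g_end - 1
            cds = (tss - flank - _CDS_LEN, tss - flank)
        tss_sites = [tss]
        if multi_tss[i]:
            # a second, internal start 200 bp into the gene body
            delta = 200 if strand == "+" else -200
            tss_sites.append(tss + delta)
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=CHROM,
            strand=strand,
            tss_sites=tuple(sorted(tss_sites)),
            gene_interval=(g_start, g_end),
            cds_interval=cds,
        )
        cursor += spec.pitch
    annotation = GeneAnnotation(genes=genes, chrom_sizes={CHROM: chrom_len})

    # --- criterion assignment ----------------------------------------
    ids = list(genes)
    n = spec.n_genes

    def pick(fraction: float) -> set[str]:
        k = int(round(fraction * n))
        return set(rng.choice(ids, size=k, replace=False)) if k else set()

    chr_set = pick(spec.planted_fraction_chr)
    dream_set = pick(spec.planted_fraction_dream)
    repressed_set = pick(spec.planted_fraction_repressed)

    # --- sequence, planting, cleaning --------------------------------
    sequence = _random_sequence(rng, chrom_len)
    scores = np.full(chrom_len, spec.conservation_low, dtype=float)

    planted: dict[str, tuple[str, int, str]] = {}  # gid -> motif, offset, strand
    frozen: set[int] = set()
    windows = []
    windows_by_gene: dict[str, list[tuple[int, int]]] = {}
    for gid in ids:
        g = genes[gid]
        for tss in g.tss_sites:
            windows.append((tss - flank, tss + flank))
            windows_by_gene.setdefault(gid, []).append((tss - flank, tss + flank))
    motif_list = list(DEFAULT_MOTIFS.motifs)
    from .scanner import build_promoter_window

    for gid in ids:
        if gid not in chr_set:
            continue
        g = genes[gid]
        clipped = build_promoter_window(g, annotation, flank=flank).interval
        if clipped[1] - clipped[0] < 6:
            raise ValueError(
                f"spec infeasible: clipped promoter window of {gid} "
                f"({clipped[1] - clipped[0]} bp) cannot hold a planted motif"
            )
        motif = motif_list[int(rng.integers(0, len(motif_list)))]
        hit_strand = str(rng.choice(["+", "-"]))
        lo, hi = spec.motif_offset_range
        # transcription-direction offset -> genomic start of the 6-mer;
        # rejection-sample until the motif lies in the clipped window
        # the site must also stay out of every other gene's intended
        # window, else a crowded layout would hand the neighbor an
        # unplanned hit and falsify its ground truth
        foreign = [
            w
            for other_id, wins in windows_by_gene.items()
            if other_id != gid
            for w in wins
        ]
        for _ in range(1000):
            offset = int(rng.integers(lo, hi + 1))
            if g.strand == "+":
                start = g.tss + offset
            else:
                start = g.tss - offset - 5
            if clipped[0] <= start and start + 6 <= clipped[1] and not any(
                start < w_end and w_start < start + 6 for w_start, w_end in foreign
            ):
                break
        else:
            raise ValueError(
                f"spec infeasible: motif_offset_range {spec.motif_offset_range} "
                f"never falls inside the clipped window {clipped} of {gid}"
            )
        plant_motif(
            sequence,
            scores,
            start,
            hit_strand,
            motif,
            spec.conservation_high,
            window=clipped,
        )
        planted[gid] = (motif, offset, hit_strand)
        frozen.update(range(start, start + 6))
    _clean_windows(rng, sequence, windows, frozen, DEFAULT_MOTIFS)

    # --- per-gene evidence tables ------------------------------------
    comp_rows, call_rows, truth_rows, cc_rows = [], [], [], []
    min_cons = DEFAULT_MIN_CONSERVATION
    for gid in ids:
        in_dream = gid in dream_set
        n_comp = int(rng.integers(3, 5)) if in_dream else int(rng.integers(0, 3))
        pattern = np.zeros(4, dtype=int)
        pattern[rng.choice(4, size=n_comp, replace=False)] = 1
        comp_rows.append([gid, *pattern.tolist()])

        if gid in repressed_set:
            target = int(rng.integers(-6, -2))  # score in [-6, -3]
        else:
            target = int(rng.integers(-2, 7))  # score in [-2, +6]
        for study, call in zip(STUDIES, _calls_for_score(rng, target)):
            call_rows.append([gid, study, call])

        expected_chr = gid in chr_set and spec.conservation_high >= min_cons
        expected_dream = n_comp >= 3
        expected_rep = target <= -3
        expected_final = expected_chr and expected_dream and expected_rep
        motif, offset, hit_strand = planted.get(gid, ("", "", ""))
        truth_rows.append(
            [
                gid,
                motif,
                offset,
                hit_strand,
                target,
                expected_rep,
                expected_dream,
                expected_chr,
                expected_final,
            ]
        )
        p_cc = (
            spec.cellcycle_fraction_final
            if expected_final
            else spec.cellcycle_fraction_other
        )
        is_cc = bool(rng.random() < p_cc)
        phase = str(rng.choice(["G2", "M", "G2/M"])) if is_cc else ""
        cc_rows.append([gid, int(is_cc), phase])

    # --- serialize ----------------------------------------------------
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{CHROM}\n")
        seq = sequence.tobytes().decode()
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    write_gff3(annotation, str(outdir / "annotation.gff3"))
    write_bed12(annotation, str(outdir / "annotation.bed12"))

    # run-length encode the conservation track
    change = np.flatnonzero(np.diff(scores)) + 1
    bounds = np.concatenate([[0], change, [chrom_len]])
    intervals = [
        (int(s), int(e), float(scores[s]))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]
    write_bedgraph(
        ConservationTrack(intervals={CHROM: intervals}),
        str(outdir / "conservation.bedgraph"),
    )

    pd.DataFrame(
        comp_rows, columns=["gene_id", "e2f4", "lin9", "lin54", "p130"]
    ).to_csv(outdir / "dream_chip.tsv", sep="\t", index=False)
    pd.DataFrame(call_rows, columns=["gene_id", "study_id", "call"]).to_csv(
        outdir / "expression_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(cc_rows, columns=["symbol", "cell_cycle_regulated", "peak_phase"]).to_csv(
        outdir / "cell_cycle.tsv", sep="\t", index=False
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "planted_motif",
            "planted_offset",
            "planted_strand",
            "expected_score",
            "expected_repressed",
            "expected_dream",
            "expected_conserved_chr",
            "expected_in_final_list",
        ],
    )
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

    manifest = {
        "spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
        "chrom": CHROM,
        "chrom_length": chrom_len,
        "files": {},
    }
    for name in sorted(p.name for p in outdir.iterdir() if p.name != "manifest.yaml"):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return GroundTruth(table=truth)
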