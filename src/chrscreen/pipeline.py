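"""End-to-end screen: load inputs, run the three criteria, integrate.

Thin orchestration over the expression, DREAM-binding, scanner and
integration stages, with a bundle-directory convenience entry point
matching the layout the synthetic generator writes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import dream, expression, integrate, scanner
from .conservation import read_track
from .genome import GeneAnnotation, read_bed12, read_gff3
from .motifs import ChrMotifSet, DEFAULT_MOTIFS


@dataclass(frozen=True)
class ScreenConfig:
    flank: int = scanner.DEFAULT_FLANK
    min_conservation: float = scanner.DEFAULT_MIN_CONSERVATION
    repression_threshold: int = expression.DEFAULT_REPRESSION_THRESHOLD
    min_dream_components: int = dream.DEFAULT_MIN_COMPONENTS
    clip_neighbors: str = "both"


def load_sequences(fasta_path: str | Path) -> dict[str, str]:
    fa = Fasta(str(fasta_path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_annotation(path: str | Path, chrom_sizes: dict[str, int]) -> GeneAnnotation:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_gff3(path, chrom_sizes)
    return read_bed12(path, chrom_sizes)


def run_screen(
    annotation_path: str | Path,
    fasta_path: str | Path,
    conservation_path: str | Path,
    dream_path: str | Path,
    expression_path: str | Path,
    config: ScreenConfig = ScreenConfig(),
    motifs: ChrMotifSet = DEFAULT_MOTIFS,
    curation: list[integrate.CurationEntry] | None = None,
) -> pd.DataFrame:
    """Run the full screen from file paths; returns the candidate records."""
    sequences = load_sequences(fasta_path)
    chrom_sizes = {name: len(seq) for name, seq in sequences.items()}
    annotation = load_annotation(annotation_path, chrom_sizes)
    track = read_track(str(conservation_path))

    scores = expression.score_table(
        expression.read_calls_tsv(str(expression_path)),
        threshold=config.repression_threshold,
    )
    dream_calls = dream.call_table(
        dream.read_detections_tsv(str(dream_path)),
        min_components=config.min_dream_components,
    )
    chr_calls = scanner.scan_annotation(
        annotation,
        sequences,
        track,
        motifs=motifs,
        flank=config.flank,
        min_mean=config.min_conservation,
        clip_neighbors=config.clip_neighbors,
    )
    records = integrate.intersect_criteria(scores, dream_calls, chr_calls)
    if curation:
        records = integrate.apply_curation(records, curation)
    return records


def run_screen_on_bundle(
    bundle_dir: str | Path, config: ScreenConfig = ScreenConfig()
) -> pd.DataFrame:
    """Run the screen on a directory laid out like a synthetic cohort."""
    d = Path(bundle_dir)
    return run_screen(
        annotation_path=d / "annotation.gff3",
        fasta_path=d / "genome.fa",
        conservation_path=d / "conservation.bedgraph",
        dream_path=d / "dream_chip.tsv",
        expression_path=d / "expression_calls.tsv",
        config=config,
    )


def write_outputs(records: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    records[records["in_final_list"]].to_csv(
        outdir / "final_list.tsv", sep="\t", index=False
    )
    integrate.summarize_venn(records).to_csv(
        outdir / "venn_summary.tsv", sep="\t", index=False
    )
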