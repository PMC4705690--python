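"""Gene models and annotation input/output.

All coordinates are 0-based, half-open (BED convention) internally; GFF3 is
converted on read. A gene model carries every distinct annotated TSS so
downstream promoter scanning can work per-TSS while reporting per-gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: TSS position(s), strand, gene and CDS extent."""

    gene_id: str
    chrom: str
    strand: str
    tss_sites: tuple[int, ...]
    gene_interval: tuple[int, int]
    cds_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        start, end = self.gene_interval
        if not self.tss_sites:
            raise ValueError(f"{self.gene_id}: at least one TSS required")
        for tss in self.tss_sites:
            if not start <= tss < end:
                raise ValueError(f"{self.gene_id}: TSS {tss} outside gene interval")
        if self.cds_interval is not None:
            cs, ce = self.cds_interval
            if not (start <= cs and ce <= end):
                raise ValueError(f"{self.gene_id}: CDS not contained in gene interval")

    @property
    def tss(self) -> int:
        return self.tss_sites[0]

    def cds_first_base(self) -> int | None:
        """First coding base in transcription direction, or None (non-coding)."""
        if self.cds_interval is None:
            return None
        return self.cds_interval[0] if self.strand == "+" else self.cds_interval[1] - 1


@dataclass
class GeneAnnotation:
    """All gene models of a run, indexed by id and by genomic interval."""

    genes: dict[str, GeneModel]
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._trees = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.gene_interval[0], g.gene_interval[1], g.gene_id)

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} absent from annotation") from None

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose interval overlaps [start, end) on either strand."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree.overlap(start, end))]


def read_gff3(path: str, chrom_sizes: dict[str, int] | None = None) -> GeneAnnotation:
    """Load gene models from GFF3 (gene + mRNA + CDS features).

    GFF3 is 1-based, closed; converted to 0-based, half-open. Each mRNA
    contributes one TSS (its 5' end in transcription direction); the CDS
    extent is the union of CDS features of the gene.
    """
    gene_rows: dict[str, tuple[str, str, int, int]] = {}
    tss_by_gene: dict[str, set[int]] = {}
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    mrna_parent: dict[str, str] = {}

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            start, end = int(start1) - 1, int(end1)
            adict = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = adict["ID"]
                gene_rows[gid] = (chrom, strand, start, end)
            elif ftype == "mRNA":
                parent = adict["Parent"]
                mrna_parent[adict["ID"]] = parent
                tss = start if strand == "+" else end - 1
                tss_by_gene.setdefault(parent, set()).add(tss)
            elif ftype == "CDS":
                gid = mrna_parent.get(adict["Parent"], adict["Parent"])
                cds_by_gene.setdefault(gid, []).append((start, end))

    genes = {}
    for gid, (chrom, strand, start, end) in gene_rows.items():
        tss_set = tss_by_gene.get(gid) or {start if strand == "+" else end - 1}
        cds = None
        if gid in cds_by_gene:
            spans = cds_by_gene[gid]
            cds = (min(s for s, _ in spans), max(e for _, e in spans))
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            tss_sites=tuple(sorted(tss_set)),
            gene_interval=(start, end),
            cds_interval=cds,
        )
    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes or {})


def read_bed12(path: str, chrom_sizes: dict[str, int] | None = None) -> GeneAnnotation:
    """Load gene models from BED12; thickStart/thickEnd give the CDS extent."""
    genes: dict[str, GeneModel] = {}
    tss_acc: dict[str, set[int]] = {}
    rows: dict[str, tuple[str, str, int, int, tuple[int, int] | None]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            tss = start if strand == "+" else end - 1
            if name in rows:
                # additional transcript of an already-seen gene: widen + add TSS
                pchrom, pstrand, pstart, pend, pcds = rows[name]
                start, end = min(start, pstart), max(end, pend)
                if pcds and cds:
                    cds = (min(cds[0], pcds[0]), max(cds[1], pcds[1]))
                cds = cds or pcds
            rows[name] = (chrom, strand, start, end, cds)
            tss_acc.setdefault(name, set()).add(tss)
    for name, (chrom, strand, start, end, cds) in rows.items():
        genes[name] = GeneModel(
            gene_id=name,
            chrom=chrom,
            strand=strand,
            tss_sites=tuple(sorted(tss_acc[name])),
            gene_interval=(start, end),
            cds_interval=cds,
        )
    return GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes or {})


def write_gff3(annotation: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in sorted(annotation, key=lambda g: (g.chrom, g.gene_interval)):
            s, e = g.gene_interval
            base = f"{g.chrom}\tchrscreen"
            fh.write(f"{base}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, tss in enumerate(g.tss_sites):
                mid = f"{g.gene_id}.t{i + 1}"
                ms, me = (tss, e) if g.strand == "+" else (s, tss + 1)
                fh.write(
                    f"{base}\tmRNA\t{ms + 1}\t{me}\t.\t{g.strand}\t.\t"
                    f"ID={mid};Parent={g.gene_id}\n"
                )
                if g.cds_interval is not None:
                    cs, ce = g.cds_interval
                    fh.write(
                        f"{base}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                        f"ID={mid}.cds;Parent={mid}\n"
                    )


def write_bed12(annotation: GeneAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(annotation, key=lambda g: (g.chrom, g.gene_interval)):
            s, e = g.gene_interval
            cs, ce = g.cds_interval if g.cds_interval else (s, s)
            fh.write(
                f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{cs}\t{ce}\t0\t1\t{e - s}\t0\n"
            )
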