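import pandas as pd
import pytest

from chrscreen.genome import GeneAnnotation, GeneModel


@pytest.fixture
def isolated_gene_annotation():
    """One + strand gene with TSS at 50000 and CDS far from the window."""
    gene = GeneModel(
        gene_id="geneA",
        chrom="chr1",
        strand="+",
        tss_sites=(50_000,),
        gene_interval=(50_000, 55_000),
        cds_interval=(52_000, 54_000),
    )
    return gene, GeneAnnotation(genes={"geneA": gene}, chrom_sizes={"chr1": 100_000})


def make_records(rows):
    """Candidate records from (gene_id, repressed, dream, chr) tuples."""
    from chrscreen.integrate import intersect_criteria

    scores = pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "score": [-4 if r[1] else 0 for r in rows],
            "repressed": [r[1] for r in rows],
        }
    )
    dream = pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "n_components": [3 if r[2] else 1 for r in rows],
            "bound": [r[2] for r in rows],
        }
    )
    chrc = pd.DataFrame(
        {"gene_id": [r[0] for r in rows], "conserved_chr": [r[3] for r in rows]}
    )
    return intersect_criteria(scores, dream, chrc)
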