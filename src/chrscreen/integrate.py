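"""Intersection of the three screening criteria and candidate-list assembly.

A gene enters the final candidate list when it is (i) repressed by p53
(Expression Score <= -3), (ii) bound by DREAM (>= 3 of 4 components) and
(iii) carries a phylogenetically conserved CHR element in its promoter.
The three boolean criteria partition the gene universe into seven Venn
regions plus "none"; manual curation can override the screen with full
provenance, mirroring how individually validated targets are added to a
screen's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import pandas as pd

#: The seven Venn partitions over (repressed, dream, chr), plus "none".
PARTITIONS: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "all_three",
    (True, True, False): "repressed_dream",
    (True, False, True): "repressed_chr",
    (False, True, True): "dream_chr",
    (True, False, False): "repressed_only",
    (False, True, False): "dream_only",
    (False, False, True): "chr_only",
    (False, False, False): "none",
}

PARTITION_ORDER = [
    "all_three",
    "repressed_dream",
    "repressed_chr",
    "dream_chr",
    "repressed_only",
    "dream_only",
    "chr_only",
    "none",
]


@dataclass(frozen=True)
class CurationEntry:
    symbol: str
    action: str  # "include" | "exclude"
    reason: str = ""


def round_half_up_pct(numerator: int, denominator: int) -> float | None:
    """Percentage to one decimal, round-half-up; None when undefined.

    Half-up (not banker's) rounding is used so printed integer pairs
    reproduce their published percentages exactly.
    """
    if denominator == 0:
        return None
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate gene id(s) in {name} input: "
            f"{sorted(df.loc[dup, 'gene_id'].unique())[:5]}"
        )


def intersect_criteria(
    scores: pd.DataFrame,
    dream_calls: pd.DataFrame,
    chr_calls: pd.DataFrame,
    symbols: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join the three per-gene criterion tables into candidate records.

    The gene universe is the union of ids across the three inputs. A gene
    missing from one input is treated as negative for that criterion
    (score 0 / unbound / no conserved CHR) and flagged in the
    ``missing_evidence`` column rather than dropped, so Venn identities
    hold over the full universe. ``symbols`` optionally maps gene_id to a
    reporting symbol (defaults to the id itself).
    """
    _check_unique(scores, "expression scores")
    _check_unique(dream_calls, "dream calls")
    _check_unique(chr_calls, "chr calls")

    universe = sorted(
        set(scores["gene_id"])
        | set(dream_calls["gene_id"])
        | set(chr_calls["gene_id"])
    )
    rec = pd.DataFrame({"gene_id": universe})
    rec = rec.merge(
        scores[["gene_id", "score", "repressed"]], on="gene_id", how="left"
    )
    rec = rec.merge(
        dream_calls[["gene_id", "n_components", "bound"]], on="gene_id", how="left"
    )
    chr_cols = ["gene_id", "conserved_chr"] + [
        c for c in chr_calls.columns if c.startswith("best_")
    ]
    rec = rec.merge(chr_calls[chr_cols], on="gene_id", how="left")

    missing = []
    for _, row in rec.iterrows():
        absent = []
        if pd.isna(row["repressed"]):
            absent.append("expression")
        if pd.isna(row["bound"]):
            absent.append("dream")
        if pd.isna(row["conserved_chr"]):
            absent.append("chr")
        missing.append(",".join(absent))
    rec["missing_evidence"] = missing
    rec["expression_score"] = rec.pop("score").fillna(0).astype(int)
    rec["n_dream_components"] = rec.pop("n_components").fillna(0).astype(int)
    rec["repressed"] = rec["repressed"].astype("boolean").fillna(False).astype(bool)
    rec["dream_bound"] = rec.pop("bound").astype("boolean").fillna(False).astype(bool)
    rec["conserved_chr"] = rec["conserved_chr"].astype("boolean").fillna(False).astype(bool)

    if symbols is not None:
        rec = rec.merge(symbols[["gene_id", "symbol"]], on="gene_id", how="left")
        rec["symbol"] = rec["symbol"].fillna(rec["gene_id"])
    else:
        rec["symbol"] = rec["gene_id"]

    rec["partition"] = [
        PARTITIONS[(r, d, c)]
        for r, d, c in zip(rec["repressed"], rec["dream_bound"], rec["conserved_chr"])
    ]
    rec["in_final_list"] = rec["repressed"] & rec["dream_bound"] & rec["conserved_chr"]
    rec["curation"] = ["screen" if f else "none" for f in rec["in_final_list"]]
    front = [
        "gene_id",
        "symbol",
        "expression_score",
        "repressed",
        "n_dream_components",
        "dream_bound",
        "conserved_chr",
        "partition",
        "in_final_list",
        "curation",
        "missing_evidence",
    ]
    return rec[front + [c for c in rec.columns if c not in front]]


def partition_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = records["partition"].value_counts().to_dict()
    return {p: int(counts.get(p, 0)) for p in PARTITION_ORDER}


def validate_curation(entries: list[CurationEntry]) -> list[CurationEntry]:
    by_symbol: dict[str, set[str]] = {}
    for e in entries:
        if e.action not in ("include", "exclude"):
            raise ValueError(f"curation action {e.action!r} for {e.symbol} invalid")
        by_symbol.setdefault(e.symbol.upper(), set()).add(e.action)
    conflicts = [s for s, actions in by_symbol.items() if len(actions) > 1]
    if conflicts:
        raise ValueError(f"symbol(s) both included and excluded: {sorted(conflicts)}")
    return entries


def apply_curation(
    records: pd.DataFrame, curation: list[CurationEntry]
) -> pd.DataFrame:
    """Apply manual include/exclude overrides, recording provenance.

    Symbol matching is case-insensitive. A curated symbol absent from the
    records produces a warning, not a failure. Screen-passing genes not
    touched by curation keep curation="screen".
    """
    validate_curation(curation)
    records = records.copy()
    symbol_index = {s.upper(): i for i, s in zip(records.index, records["symbol"])}
    for entry in curation:
        idx = symbol_index.get(entry.symbol.upper())
        if idx is None:
            warnings.warn(f"curated symbol {entry.symbol!r} not in records", stacklevel=2)
            continue
        records.at[idx, "in_final_list"] = entry.action == "include"
        records.at[idx, "curation"] = f"manual_{entry.action}"
    return records


def read_curation_tsv(path: str) -> list[CurationEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = [
        CurationEntry(symbol=r["symbol"], action=r["action"], reason=r.get("reason", ""))
        for _, r in df.iterrows()
    ]
    return validate_curation(entries)


def summarize_venn(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages for every Venn partition and marginal set.

    Partition rows use the universe size as denominator; marginal and
    pairwise rows additionally report nested percentages of the stated
    denominator (e.g. repressed-and-DREAM-bound as a share of DREAM-bound).
    Percentages are one-decimal, round-half-up; an undefined percentage
    (zero denominator) is left empty rather than reported as 0.
    """
    n_universe = len(records)
    rows = []

    def add(set_name: str, count: int, denom_name: str, denom: int) -> None:
        rows.append(
            {
                "set": set_name,
                "count": count,
                "denominator": denom_name,
                "denominator_count": denom,
                "percent": round_half_up_pct(count, denom),
            }
        )

    counts = partition_counts(records)
    for part in PARTITION_ORDER:
        add(f"partition:{part}", counts[part], "universe", n_universe)

    n_rep = int(records["repressed"].sum())
    n_dream = int(records["dream_bound"].sum())
    n_chr = int(records["conserved_chr"].sum())
    add("repressed", n_rep, "universe", n_universe)
    add("dream_bound", n_dream, "universe", n_universe)
    add("conserved_chr", n_chr, "universe", n_universe)

    n_rep_dream = int((records["repressed"] & records["dream_bound"]).sum())
    n_rep_chr = int((records["repressed"] & records["conserved_chr"]).sum())
    n_dream_chr = int((records["dream_bound"] & records["conserved_chr"]).sum())
    n_all = counts["all_three"]
    add("repressed&dream_bound", n_rep_dream, "dream_bound", n_dream)
    add("repressed&conserved_chr", n_rep_chr, "conserved_chr", n_chr)
    add("dream_bound&conserved_chr", n_dream_chr, "dream_bound", n_dream)
    add("all_three", n_all, "dream_bound", n_dream)
    add("final_list", int(records["in_final_list"].sum()), "universe", n_universe)
    return pd.DataFrame(rows)


def annotate_cell_cycle(
    final_records: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[float | None, pd.DataFrame]:
    """Join cell-cycle regulation annotation onto the final candidate list.

    ``annotation`` has columns symbol, cell_cycle_regulated (bool) and
    optionally peak_phase. Returns (percentage of final-list genes that are
    cell-cycle regulated, per-gene join). Unmatched symbols count as
    not annotated and are flagged; an empty final list yields None.
    """
    ann = annotation.copy()
    ann["symbol"] = ann["symbol"].astype(str)
    if "peak_phase" not in ann.columns:
        ann["peak_phase"] = ""
    bad = ann[(ann["peak_phase"].fillna("") != "") & (~ann["cell_cycle_regulated"].astype(bool))]
    if not bad.empty:
        raise ValueError(
            f"peak_phase given for non-cell-cycle-regulated symbol "
            f"{bad.iloc[0]['symbol']}"
        )
    joined = final_records.merge(
        ann[["symbol", "cell_cycle_regulated", "peak_phase"]], on="symbol", how="left"
    )
    joined["cc_annotated"] = ~joined["cell_cycle_regulated"].isna()
    joined["cell_cycle_regulated"] = (
        joined["cell_cycle_regulated"].astype("boolean").fillna(False).astype(bool)
    )
    joined["peak_phase"] = joined["peak_phase"].fillna("")
    n_final = len(joined)
    fraction = round_half_up_pct(int(joined["cell_cycle_regulated"].sum()), n_final)
    return fraction, joined


def load_table1_fixture() -> list[str]:
    """The packaged list of the 210 published candidate target genes."""
    ref = resources.files("chrscreen.data").joinpath("table1_symbols.txt")
    symbols = [s.strip() for s in ref.read_text().splitlines() if s.strip()]
    if len(symbols) != len(set(symbols)):
        raise ValueError("packaged candidate-gene fixture contains duplicates")
    if not symbols:
        raise ValueError("packaged candidate-gene fixture is empty")
    return symbols
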