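"""Per-gene p53 Expression Score from a multi-study regulation-call matrix.

Each of up to six genome-wide p53 expression studies contributes a per-gene
direction call: +1 (activated by p53), -1 (repressed), or 0 (no call /
not significant). The Expression Score is the sum of the calls over all
studies, an integer in [-6, +6] encoding both direction and reproducibility.
A score at or below the repression threshold (default -3) classifies the
gene as repressed by p53.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

DEFAULT_REPRESSION_THRESHOLD = -3
MAX_STUDIES = 6

VALID_CALLS = {-1, 0, 1}


@dataclass(frozen=True)
class ExpressionScore:
    gene_id: str
    score: int
    n_studies_observed: int

    def __post_init__(self) -> None:
        if abs(self.score) > self.n_studies_observed:
            raise ValueError(
                f"{self.gene_id}: |score| {abs(self.score)} exceeds "
                f"n_studies_observed {self.n_studies_observed}"
            )


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format call matrix (gene_id, study_id, call).

    Raises ValueError naming the offending gene/study on an out-of-range
    call or a duplicate (gene, study) pair. Warns if more than six studies
    are present (the score range widens beyond [-6, +6]).
    """
    required = {"gene_id", "study_id", "call"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"call matrix missing columns: {sorted(missing)}")
    bad = calls[~calls["call"].isin(VALID_CALLS)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"invalid call {row['call']!r} for gene {row['gene_id']} "
            f"in study {row['study_id']} (must be -1, 0 or +1)"
        )
    dup = calls.duplicated(subset=["gene_id", "study_id"], keep=False)
    if dup.any():
        row = calls[dup].iloc[0]
        raise ValueError(
            f"duplicate call for gene {row['gene_id']} in study {row['study_id']}"
        )
    n_studies = calls["study_id"].nunique()
    if n_studies > MAX_STUDIES:
        warnings.warn(
            f"{n_studies} studies supplied; Expression Score range widens "
            f"beyond [-{MAX_STUDIES}, +{MAX_STUDIES}]",
            stacklevel=2,
        )
    return calls


def compute_expression_score(calls: pd.DataFrame, gene_id: str) -> ExpressionScore:
    """Sum a single gene's direction calls over all studies.

    Studies in which the gene has no call contribute 0; a gene absent from
    the matrix altogether scores 0 with zero studies observed.
    """
    validate_calls(calls)
    sub = calls[calls["gene_id"] == gene_id]
    nonzero = sub[sub["call"] != 0]
    return ExpressionScore(
        gene_id=gene_id,
        score=int(sub["call"].sum()),
        n_studies_observed=int(len(nonzero)),
    )


def classify_repressed(
    score: ExpressionScore | int, threshold: int = DEFAULT_REPRESSION_THRESHOLD
) -> bool:
    """True iff the Expression Score is at or below the threshold (inclusive)."""
    value = score.score if isinstance(score, ExpressionScore) else int(score)
    return value <= threshold


def score_table(
    calls: pd.DataFrame, threshold: int = DEFAULT_REPRESSION_THRESHOLD
) -> pd.DataFrame:
    """Score every gene in a call matrix.

    Returns a frame with columns gene_id, score, n_studies_observed,
    repressed — one row per distinct gene, sorted by gene_id.
    """
    validate_calls(calls)
    grouped = calls.groupby("gene_id", sort=True)
    out = grouped.agg(
        score=("call", "sum"),
        n_studies_observed=("call", lambda c: int((c != 0).sum())),
    ).reset_index()
    out["score"] = out["score"].astype(int)
    out["repressed"] = out["score"] <= threshold
    return out


def read_calls_tsv(path: str) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "study_id": str})
    calls["call"] = calls["call"].astype(int)
    return validate_calls(calls)


def write_scores_tsv(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t", index=False)
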