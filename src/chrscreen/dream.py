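"""DREAM complex binding calls from per-component ChIP detections.

A gene is scored positive for DREAM binding when at least three of the four
assayed components — E2F4, LIN9, LIN54 and p130 — were detected at its
promoter. Detections arrive as booleans; upstream peak calling and
peak-to-TSS assignment are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DREAM_COMPONENTS: tuple[str, ...] = ("E2F4", "LIN9", "LIN54", "p130")
DEFAULT_MIN_COMPONENTS = 3

_TSV_COLUMNS = ("e2f4", "lin9", "lin54", "p130")


@dataclass(frozen=True)
class DreamProfile:
    """Per-gene detection status for each of the four DREAM components."""

    gene_id: str
    detected: dict[str, bool]

    def __post_init__(self) -> None:
        missing = set(DREAM_COMPONENTS) - set(self.detected)
        extra = set(self.detected) - set(DREAM_COMPONENTS)
        if missing:
            raise ValueError(
                f"{self.gene_id}: missing component slot(s) {sorted(missing)}; "
                "detections are not imputed"
            )
        if extra:
            raise ValueError(f"{self.gene_id}: unknown component(s) {sorted(extra)}")


@dataclass(frozen=True)
class DreamCall:
    gene_id: str
    n_components: int
    bound: bool


def call_dream_binding(
    profile: DreamProfile, min_components: int = DEFAULT_MIN_COMPONENTS
) -> DreamCall:
    """Count detected components and call binding at the given threshold."""
    n = sum(bool(profile.detected[c]) for c in DREAM_COMPONENTS)
    return DreamCall(gene_id=profile.gene_id, n_components=n, bound=n >= min_components)


def call_table(
    profiles: pd.DataFrame, min_components: int = DEFAULT_MIN_COMPONENTS
) -> pd.DataFrame:
    """Call DREAM binding for every row of a per-gene detection table.

    Expects columns gene_id plus e2f4, lin9, lin54, p130 (0/1 or bool);
    returns gene_id, n_components, bound.
    """
    missing = set(_TSV_COLUMNS) - set(profiles.columns)
    if missing:
        raise ValueError(f"detection table missing component column(s): {sorted(missing)}")
    for col in _TSV_COLUMNS:
        vals = set(pd.unique(profiles[col]))
        if not vals <= {0, 1, True, False}:
            raise ValueError(f"column {col} must be 0/1, found {sorted(map(repr, vals))}")
    n = profiles[list(_TSV_COLUMNS)].astype(bool).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "gene_id": profiles["gene_id"].astype(str),
            "n_components": n,
            "bound": n >= min_components,
        }
    )


def read_detections_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_calls_tsv(calls: pd.DataFrame, path: str) -> None:
    calls.to_csv(path, sep="\t", index=False)
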