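"""The CHR (cell cycle genes homology region) motif vocabulary.

The CHR is a 6-bp promoter element bound by the MuvB core of the repressive
DREAM complex. Ten functional sequence variants are known; the canonical
element is TTTGAA, whose reverse complement TTCAAA is the functional
inverse site found on the opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The ten known functional CHR variants, canonical element first.
CHR_MOTIFS: tuple[str, ...] = (
    "TTTGAA",
    "TTTAAA",
    "TTCGAA",
    "TTTGTA",
    "CTTGAA",
    "TTTGAG",
    "TTTGAT",
    "TTCGAG",
    "TTCGAT",
    "TAGGAA",
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ChrMotifSet:
    """An ordered set of 6-mer motifs scanned on both strands.

    ``rc_index`` maps each motif's reverse complement back to the canonical
    (forward) string so minus-strand hits can be strand-normalized. Note
    TTTAAA is its own reverse complement: a TTTAAA occurrence is reported
    once per strand.
    """

    motifs: tuple[str, ...] = CHR_MOTIFS
    _rc_index: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("motif set contains duplicates")
        for m in self.motifs:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} is not a 6-mer over ACGT")
        object.__setattr__(
            self, "_rc_index", {reverse_complement(m): m for m in self.motifs}
        )

    @property
    def width(self) -> int:
        return 6

    def forward(self) -> frozenset[str]:
        return frozenset(self.motifs)

    def rc_index(self) -> dict[str, str]:
        """Map reverse-complemented motif -> canonical motif string."""
        return dict(self._rc_index)

    @classmethod
    def from_file(cls, path: str) -> "ChrMotifSet":
        """Read one motif per line (blank lines and '#' comments ignored)."""
        motifs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    motifs.append(line.upper())
        return cls(tuple(motifs))


DEFAULT_MOTIFS = ChrMotifSet()
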