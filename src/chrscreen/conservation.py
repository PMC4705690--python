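"""Per-base conservation tracks (PhastCons-style scores in [0, 1]).

Scores are phylogenetic conservation probabilities per base, as produced
from multiple genome alignments. Bases not covered by the track are
distinguishable from an explicit score of 0: when averaging over a motif
they contribute 0 but the hit is flagged as partially covered, so
unalignable regions can never look spuriously conserved.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field


@dataclass
class ConservationTrack:
    """Run-length conservation scores over non-overlapping intervals.

    ``intervals[chrom]`` is a sorted list of (start, end, score) with
    0-based half-open coordinates.
    """

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    _starts: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort()
            prev_end = -1
            for start, end, score in ivs:
                if start >= end:
                    raise ValueError(f"{chrom}: empty interval [{start}, {end})")
                if start < prev_end:
                    raise ValueError(f"{chrom}: overlapping intervals at {start}")
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"{chrom}:{start}: score {score} outside [0, 1]")
                prev_end = end
        self._starts = {c: [iv[0] for iv in ivs] for c, ivs in self.intervals.items()}

    def mean_score(self, chrom: str, start: int, end: int) -> tuple[float, bool]:
        """Arithmetic mean score over [start, end); uncovered bases count 0.

        Returns (mean, partially_covered) where the flag is set when any
        base in the interval is absent from the track.
        """
        if end <= start:
            raise ValueError("empty interval")
        length = end - start
        ivs = self.intervals.get(chrom, [])
        starts = self._starts.get(chrom, [])
        total = 0.0
        covered = 0
        i = max(0, bisect.bisect_right(starts, start) - 1)
        while i < len(ivs) and ivs[i][0] < end:
            s, e, score = ivs[i]
            overlap = min(e, end) - max(s, start)
            if overlap > 0:
                total += score * overlap
                covered += overlap
            i += 1
        return total / length, covered < length


def read_bedgraph(path: str) -> ConservationTrack:
    """Parse a bedGraph file (0-based, half-open intervals)."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, score = line.split()[:4]
            intervals.setdefault(chrom, []).append(
                (int(start), int(end), float(score))
            )
    return ConservationTrack(intervals=intervals)


def read_wiggle(path: str) -> ConservationTrack:
    """Parse fixedStep / variableStep wiggle (1-based starts, per wig spec)."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    mode = chrom = None
    pos = step = span = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
            elif line.startswith("variableStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
            elif mode == "fixed":
                intervals.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
            elif mode == "variable":
                start1, value = line.split()
                start = int(start1) - 1
                intervals.setdefault(chrom, []).append((start, start + span, float(value)))
            else:
                raise ValueError("wiggle data before any step declaration")
    return ConservationTrack(intervals=intervals)


def read_track(path: str) -> ConservationTrack:
    """Load a conservation track, sniffing bedGraph vs wiggle."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                if line.startswith(("fixedStep", "variableStep")):
                    return read_wiggle(path)
                return read_bedgraph(path)
    return ConservationTrack()


def write_bedgraph(track: ConservationTrack, path: str) -> None:
    """Write one line per run of equal score, merging adjacent equal runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            merged: list[tuple[int, int, float]] = []
            for start, end, score in track.intervals[chrom]:
                if merged and merged[-1][1] == start and merged[-1][2] == score:
                    merged[-1] = (merged[-1][0], end, score)
                else:
                    merged.append((start, end, score))
            for start, end, score in merged:
                fh.write(f"{chrom}\t{start}\t{end}\t{score:g}\n")
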