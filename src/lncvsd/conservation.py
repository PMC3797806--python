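"""phastCons-style conservation scoring of transcripts.

A conservation track assigns each covered base a score in [0, 1],
interpretable as the probability that the base lies in a conserved element.
Per-transcript statistics are computed over *exonic* bases only (the mature
transcript is the unit of interest); bases absent from the track are treated
as unaligned and excluded from denominators rather than scored zero.  A base
counts as conserved when its score is >= 0.5 (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genomic_context import ClassifiedLncRNA, TranscriptModel

CONSERVED_SCORE = 0.5


class ConservationTrack:
    """Sparse per-base scores: chrom -> (positions, scores), positions
    strictly increasing, scores in [0, 1]."""

    def __init__(self, data: Optional[dict[str, tuple[np.ndarray, np.ndarray]]] = None):
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, sc) in (data or {}).items():
            self._add(chrom, np.asarray(pos, dtype=np.int64), np.asarray(sc, dtype=float))

    def _add(self, chrom: str, pos: np.ndarray, sc: np.ndarray) -> None:
        if len(pos) == 0:
            return
        if chrom in self.data:
            p0, s0 = self.data[chrom]
            pos = np.concatenate([p0, pos])
            sc = np.concatenate([s0, sc])
            order = np.argsort(pos, kind="stable")
            pos, sc = pos[order], sc[order]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: positions must be strictly increasing")
        if np.any((sc < 0) | (sc > 1)):
            raise ValueError(f"{chrom}: scores outside [0, 1]")
        self.data[chrom] = (pos, sc)

    def scores_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores of covered positions within [start, end)."""
        if chrom not in self.data:
            return np.empty(0)
        pos, sc = self.data[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return sc[i:j]

    def n_covered(self) -> int:
        return sum(len(p) for p, _ in self.data.values())


@dataclass
class ConservationSummary:
    transcript_id: str
    n_bases_covered: int
    median_score: Optional[float]
    conserved_fraction: float
    overlaps_conserved_element: bool


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------


def read_track(path: str, format: str = "fixedStep_wig") -> ConservationTrack:
    """Parse a fixedStep WIG or bedGraph file into a ConservationTrack.

    WIG coordinates are 1-based; bedGraph is 0-based half-open. Both are
    converted to 0-based positions. Malformed lines raise with the line
    number; scores outside [0, 1] are rejected.
    """
    if format == "fixedStep_wig":
        return _read_fixedstep(path)
    if format == "bedGraph":
        return _read_bedgraph(path)
    raise ValueError(f"unknown track format: {format}")


def _read_fixedstep(path: str) -> ConservationTrack:
    track = ConservationTrack()
    chrom, nxt, step, span = None, 0, 1, 1
    positions: list[int] = []
    scores: list[float] = []

    def flush():
        nonlocal positions, scores
        if chrom is not None and positions:
            track._add(chrom, np.asarray(positions, dtype=np.int64), np.asarray(scores))
        positions, scores = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                try:
                    chrom = fields["chrom"]
                    nxt = int(fields["start"]) - 1  # WIG is 1-based
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed fixedStep header: {exc}")
                continue
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: value line before fixedStep header")
            try:
                value = float(line)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected a score, got {line!r}")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {value} outside [0, 1]")
            for k in range(span):
                positions.append(nxt + k)
                scores.append(value)
            nxt += step
    flush()
    return track


def _read_bedgraph(path: str) -> ConservationTrack:
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line: {exc}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {v} outside [0, 1]")
            pos, sc = per_chrom.setdefault(chrom, ([], []))
            pos.extend(range(s, e))
            sc.extend([v] * (e - s))
    track = ConservationTrack()
    for chrom, (pos, sc) in per_chrom.items():
        order = np.argsort(pos, kind="stable")
        track._add(chrom, np.asarray(pos, dtype=np.int64)[order], np.asarray(sc)[order])
    return track


def write_track(track: ConservationTrack, path: str) -> None:
    """Write as fixedStep WIG (step 1), one block per contiguous run."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, sc = track.data[chrom]
            run_start = 0
            for i in range(1, len(pos) + 1):
                if i == len(pos) or pos[i] != pos[i - 1] + 1:
                    fh.write(f"fixedStep chrom={chrom} start={pos[run_start] + 1} step=1\n")
                    for v in sc[run_start:i]:
                        fh.write(f"{v:.6g}\n")
                    run_start = i


def read_elements_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Conserved-element intervals from a BED file (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_transcript(
    transcript: TranscriptModel,
    track: ConservationTrack,
    element_bed: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> ConservationSummary:
    """Median score and conserved-base fraction over covered exonic bases."""
    chunks = [track.scores_in(transcript.chrom, s, e) for s, e in transcript.exons]
    scores = np.concatenate(chunks) if chunks else np.empty(0)
    n = len(scores)
    overlaps = False
    if element_bed:
        for es, ee in element_bed.get(transcript.chrom, ()):
            if any(min(ee, xe) > max(es, xs) for xs, xe in transcript.exons):
                overlaps = True
                break
    if n == 0:
        return ConservationSummary(transcript.id, 0, None, 0.0, overlaps)
    return ConservationSummary(
        transcript_id=transcript.id,
        n_bases_covered=n,
        median_score=float(np.median(scores)),
        conserved_fraction=float(np.count_nonzero(scores >= CONSERVED_SCORE) / n),
        overlaps_conserved_element=overlaps,
    )


def category_median(
    summaries: Sequence[ConservationSummary],
    classified: Sequence[ClassifiedLncRNA],
) -> dict[str, Optional[float]]:
    """Per positional class, the median of member transcripts' median scores."""
    cls_of = {c.lncrna_id: c.positional_class for c in classified}
    per_class: dict[str, list[float]] = {}
    for s in summaries:
        if s.n_bases_covered == 0 or s.transcript_id not in cls_of:
            continue
        per_class.setdefault(cls_of[s.transcript_id], []).append(s.median_score)
    classes = {c.positional_class for c in classified}
    return {
        c: (float(np.median(per_class[c])) if c in per_class else None) for c in classes
    }


def conservation_filter(
    candidates: Sequence[str],
    summaries: Sequence[ConservationSummary],
    min_conserved_fraction: float = 0.1,
) -> list[str]:
    """Keep candidates whose conserved-base fraction meets the threshold."""
    by_id = {s.transcript_id: s for s in summaries}
    out = []
    for cid in candidates:
        if cid not in by_id:
            raise KeyError(f"no conservation summary for candidate {cid}")
        if by_id[cid].conserved_fraction >= min_conserved_fraction:
            out.append(cid)
    return out


def write_summary_tsv(summaries: Sequence[ConservationSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tn_bases_covered\tmedian_score\tconserved_fraction\toverlaps_element\n")
        for s in summaries:
            med = f"{s.median_score:.6g}" if s.median_score is not None else "NA"
            fh.write(
                f"{s.transcript_id}\t{s.n_bases_covered}\t{med}\t"
                f"{s.conserved_fraction:.6g}\t{int(s.overlaps_conserved_element)}\n"
            )
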