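"""Positional classification of lncRNAs relative to protein-coding genes.

Every dysregulated lncRNA is placed into one of six genomic-context classes
depending on how its locus relates to the nearest coding gene:

* ``exon_sense_overlapping``   — same strand, >=1 bp overlap with a coding exon
* ``intron_sense_overlapping`` — same strand, contained in a coding gene span,
  zero exonic overlap
* ``natural_antisense``        — opposite strand, overlapping coding sequence
  (exonic overlap, or partial intronic overlap without containment)
* ``intronic_antisense``       — opposite strand, contained in the gene span
  with zero exonic overlap
* ``bidirectional``            — opposite strand, no overlap, transcription
  start sites within a short head-to-head gap (default 1 kb)
* ``intergenic``               — none of the above; the nearest coding gene
  within 100 kb (if any) is recorded as the neighbor

Rules are applied in the precedence order listed above: exonic evidence beats
intronic, overlap beats proximity.  Coordinates are 0-based half-open
throughout; GTF's 1-based closed intervals are converted on read.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

CLASSES = (
    "intergenic",
    "intronic_antisense",
    "natural_antisense",
    "bidirectional",
    "exon_sense_overlapping",
    "intron_sense_overlapping",
)

#: length-distribution bins (bp), lower inclusive, upper exclusive
LENGTH_BINS = ((0, 200), (200, 1000), (1000, 2000), (2000, 3000), (3000, 5000), (5000, None))

DEFAULT_WINDOW_BP = 100_000
DEFAULT_BIDIRECTIONAL_GAP_BP = 1_000


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-resolved transcript locus (0-based half-open)."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str  # "coding" | "lncRNA"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end ({self.start}, {self.end})")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"{self.id}: exon ({s},{e}) outside span or empty")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e
        if self.biotype not in ("coding", "lncRNA"):
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Transcription start site position (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def span_overlap(self, other: "TranscriptModel") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "TranscriptModel") -> Optional[int]:
        """Gap in bp between the two spans; 0 if they overlap; None if on
        different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.span_overlap(other) > 0:
            return 0
        return max(other.start - self.end, self.start - other.end)


@dataclass
class ClassifiedLncRNA:
    lncrna_id: str
    positional_class: str
    neighbor_gene_id: Optional[str]
    distance_bp: Optional[int]


@dataclass
class ContextSummary:
    counts_by_class: dict[str, int]
    length_histogram: dict[str, int]
    median_distance_by_class: dict[str, Optional[float]]


# ---------------------------------------------------------------------------
# GTF I/O (1-based closed on disk <-> 0-based half-open in memory)
# ---------------------------------------------------------------------------

_BIOTYPE_OUT = {"coding": "protein_coding", "lncRNA": "lncRNA"}
_BIOTYPE_IN = {"protein_coding": "coding", "lncRNA": "lncRNA", "lincRNA": "lncRNA"}


def write_gtf(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Write transcripts as GTF with gene, transcript and exon features."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            bt = _BIOTYPE_OUT[t.biotype]
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}.t1"; gene_biotype "{bt}";'
            for feature, s, e in [("gene", t.start, t.end), ("transcript", t.start, t.end)]:
                fh.write(f"{t.chrom}\tlncvsd\t{feature}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tlncvsd\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")


def read_gtf(path: str) -> list[TranscriptModel]:
    """Read a GTF into TranscriptModels, one per transcript.

    The ``gene_biotype`` attribute distinguishes coding from lncRNA records.
    Transcript ids of the form ``<gene>.t1`` collapse back to the gene id.
    """
    db = gffutils.create_db(
        path, ":memory:", disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    out = []
    for t in db.features_of_type("transcript"):
        bt_raw = (t.attributes.get("gene_biotype") or ["protein_coding"])[0]
        biotype = _BIOTYPE_IN.get(bt_raw, "coding")
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
        )
        gene_id = (t.attributes.get("gene_id") or [t.id])[0]
        out.append(
            TranscriptModel(
                id=gene_id, chrom=t.seqid, strand=t.strand,
                start=t.start - 1, end=t.end,
                exons=exons or ((t.start - 1, t.end),),
                biotype=biotype,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Interval index
# ---------------------------------------------------------------------------


class GenomeIndex:
    """Per-chromosome interval trees over coding-gene spans and exons.

    Supports overlap and windowed nearest-gene queries in O(log n + k).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.genes: dict[str, TranscriptModel] = {}
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            if t.id in self.genes:
                raise ValueError(f"duplicate transcript id: {t.id}")
            self.genes[t.id] = t
            self._span_trees.setdefault(t.chrom, IntervalTree())[t.start:t.end] = t.id
            et = self._exon_trees.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                et[s:e] = t.id

    def __len__(self) -> int:
        return len(self.genes)

    def span_overlaps(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end)}
        return [self.genes[i] for i in ids]

    def exon_overlaps(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start, end)}
        return [self.genes[i] for i in ids]

    def nearby(self, chrom: str, start: int, end: int, window_bp: int) -> list[TranscriptModel]:
        """All genes whose span lies within ``window_bp`` of [start, end)."""
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        ids = {iv.data for iv in tree.overlap(start - window_bp, end + window_bp)}
        return [self.genes[i] for i in ids]


def build_index(annotation: Iterable[TranscriptModel]) -> GenomeIndex:
    """Build the coding-gene interval index used by :func:`classify_lncrna`."""
    return GenomeIndex(annotation)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _pick(genes: Sequence[TranscriptModel]) -> TranscriptModel:
    # deterministic representative among equally qualifying genes
    return min(genes, key=lambda g: (g.start, g.id))


def classify_lncrna(
    lncrna: TranscriptModel,
    index: GenomeIndex,
    window_bp: int = DEFAULT_WINDOW_BP,
    bidirectional_gap_bp: int = DEFAULT_BIDIRECTIONAL_GAP_BP,
) -> ClassifiedLncRNA:
    """Assign the positional class and nearest coding neighbor of one lncRNA.

    Precedence: exon_sense_overlapping > intron_sense_overlapping >
    natural_antisense > intronic_antisense > bidirectional > intergenic.
    The neighbor is the overlapping gene for overlap classes (distance 0),
    the head-to-head partner for bidirectional, else the nearest coding gene
    with span gap strictly below ``window_bp``.
    """
    if lncrna.biotype != "lncRNA":
        raise ValueError(f"{lncrna.id} is not a lncRNA")

    overlapping = index.span_overlaps(lncrna.chrom, lncrna.start, lncrna.end)
    exonic = {g.id for g in index.exon_overlaps(lncrna.chrom, lncrna.start, lncrna.end)}

    sense = [g for g in overlapping if g.strand == lncrna.strand]
    anti = [g for g in overlapping if g.strand != lncrna.strand]

    def contained_in(g: TranscriptModel) -> bool:
        return g.start <= lncrna.start and lncrna.end <= g.end

    cands = [g for g in sense if g.id in exonic]
    if cands:
        return ClassifiedLncRNA(lncrna.id, "exon_sense_overlapping", _pick(cands).id, 0)

    cands = [g for g in sense if contained_in(g) and g.id not in exonic]
    if cands:
        return ClassifiedLncRNA(lncrna.id, "intron_sense_overlapping", _pick(cands).id, 0)

    # antisense overlap: exonic, or partial (not contained) intronic overlap
    cands = [g for g in anti if g.id in exonic or not contained_in(g)]
    if cands:
        return ClassifiedLncRNA(lncrna.id, "natural_antisense", _pick(cands).id, 0)

    cands = [g for g in anti if contained_in(g) and g.id not in exonic]
    if cands:
        return ClassifiedLncRNA(lncrna.id, "intronic_antisense", _pick(cands).id, 0)

    if not overlapping:
        near = index.nearby(lncrna.chrom, lncrna.start, lncrna.end, bidirectional_gap_bp)
        bidir = [
            g for g in near
            if g.strand != lncrna.strand
            and lncrna.span_overlap(g) == 0
            and abs(lncrna.tss - g.tss) <= bidirectional_gap_bp
        ]
        if bidir:
            g = min(bidir, key=lambda g: (abs(lncrna.tss - g.tss), g.start, g.id))
            return ClassifiedLncRNA(lncrna.id, "bidirectional", g.id, lncrna.gap_to(g))

    return ClassifiedLncRNA(lncrna.id, "intergenic", *_nearest(lncrna, index, window_bp))


def _nearest(
    lncrna: TranscriptModel, index: GenomeIndex, window_bp: int
) -> tuple[Optional[str], Optional[int]]:
    best: Optional[TranscriptModel] = None
    best_gap: Optional[int] = None
    for g in index.nearby(lncrna.chrom, lncrna.start, lncrna.end, window_bp):
        gap = lncrna.gap_to(g)
        if gap is None or gap >= window_bp:
            continue
        if best is None or gap < best_gap or (gap == best_gap and _upstream_of(best, g, lncrna)):
            best, best_gap = g, gap
    return (best.id, best_gap) if best is not None else (None, None)


def _upstream_of(current: TranscriptModel, challenger: TranscriptModel, lnc: TranscriptModel) -> bool:
    """Tie-break toward the 5' gene on the lncRNA's strand (then id order)."""
    if lnc.strand == "+":
        key = lambda g: (g.start, g.id)
    else:
        key = lambda g: (-g.end, g.id)
    return key(challenger) < key(current)


def classify_all(
    annotation: Iterable[TranscriptModel],
    window_bp: int = DEFAULT_WINDOW_BP,
    bidirectional_gap_bp: int = DEFAULT_BIDIRECTIONAL_GAP_BP,
) -> list[ClassifiedLncRNA]:
    """Classify every lncRNA in an annotation against its coding genes."""
    transcripts = list(annotation)
    index = build_index(t for t in transcripts if t.biotype == "coding")
    return [
        classify_lncrna(t, index, window_bp, bidirectional_gap_bp)
        for t in transcripts
        if t.biotype == "lncRNA"
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _bin_label(lo: int, hi: Optional[int]) -> str:
    return f"[{lo},{hi})" if hi is not None else f">={lo}"


def summarize_context(
    classified: Sequence[ClassifiedLncRNA], annotation: Iterable[TranscriptModel]
) -> ContextSummary:
    """Class counts, exonic-length histogram and per-class median neighbor distance."""
    by_id = {t.id: t for t in annotation}
    counts = {c: 0 for c in CLASSES}
    hist = {_bin_label(lo, hi): 0 for lo, hi in LENGTH_BINS}
    dists: dict[str, list[int]] = {c: [] for c in CLASSES}
    for c in classified:
        counts[c.positional_class] += 1
        if c.distance_bp is not None:
            dists[c.positional_class].append(c.distance_bp)
        length = by_id[c.lncrna_id].exonic_length
        for lo, hi in LENGTH_BINS:
            if length >= lo and (hi is None or length < hi):
                hist[_bin_label(lo, hi)] += 1
                break
    medians = {
        c: (statistics.median(v) if v else None) for c, v in dists.items()
    }
    return ContextSummary(counts, hist, medians)


def write_classification_tsv(classified: Sequence[ClassifiedLncRNA], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lncrna_id\tclass\tneighbor_gene_id\tdistance_bp\n")
        for c in classified:
            nb = c.neighbor_gene_id if c.neighbor_gene_id is not None else "NA"
            d = c.distance_bp if c.distance_bp is not None else "NA"
            fh.write(f"{c.lncrna_id}\t{c.positional_class}\t{nb}\t{d}\n")
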