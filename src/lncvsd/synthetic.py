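"""Synthetic genomes, expression matrices, conservation tracks, gene sets
and qPCR tables with known ground truth.

The generator emulates the study design end-to-end: a two-condition
(VSD vs NC) expression experiment with a small number of biological
replicates per group and planted log2 fold-changes; lncRNAs planted so that
each satisfies exactly one of the six positional-class geometries
(intergenic, intronic antisense, natural antisense, bidirectional, exon
sense-overlapping, intron sense-overlapping); phastCons-like tracks with
planted conserved elements; and triplicate Ct tables over a five-tissue
panel with a GAPDH reference.  Every planted property is recorded in a
:class:`GroundTruth` object so downstream stages can be tested exactly.

Each generator draws from its own RNG stream seeded from
``(config.seed, stream offset)`` so modules can be regenerated
independently and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .enrichment import GeneSet
from .expression import ExpressionMatrix
from .genomic_context import TranscriptModel
from .qpcr import CtTable

# RNG stream offsets, one per generator
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_CONSERVATION = 3
_STREAM_CT = 4
_STREAM_GENESETS = 5

TISSUES = ("heart", "liver", "lung", "kidney", "muscle")


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic data bundle.

    Defaults mirror the profiled design: two biological replicates per
    condition, planted |log2 fold-change| of 2 (fold-change 4, comfortably
    past the screening threshold of 2), log2-scale noise SD of 0.2.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_coding_genes: int = 60
    n_lncrna_per_class: int = 10
    n_replicates_per_group: int = 2
    planted_log2fc: float = 2.0
    noise_sd: float = 0.2
    conserved_element_density: float = 0.2  # expected elements per kb of exon
    bidirectional_gap_bp: int = 1_000
    fraction_de: float = 0.1

    def __post_init__(self):
        for name in ("n_chromosomes", "chrom_length", "n_coding_genes",
                     "n_lncrna_per_class", "n_replicates_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fraction_de <= 1.0:
            raise ValueError("fraction_de must lie in [0, 1]")
        if self.noise_sd < 0 or self.conserved_element_density < 0:
            raise ValueError("noise_sd and conserved_element_density must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by transcript/gene id."""

    true_class_by_lncrna: dict[str, str] = field(default_factory=dict)
    true_de_probes: dict[str, int] = field(default_factory=dict)  # id -> ±1
    true_neighbor_by_lncrna: dict[str, Optional[str]] = field(default_factory=dict)
    true_distance_by_lncrna: dict[str, Optional[int]] = field(default_factory=dict)
    true_conserved_fraction: dict[str, float] = field(default_factory=dict)
    planted_ct_ratio: dict[str, float] = field(default_factory=dict)  # VSD/NC rq
    planted_tissue_level: dict[str, dict[str, float]] = field(default_factory=dict)
    candidate_ids: list[str] = field(default_factory=list)
    cardiac_set_id: Optional[str] = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _make_gene(gene_id: str, chrom: str, strand: str, pos: int, rng) -> tuple[TranscriptModel, dict]:
    """Three-exon coding gene starting at ``pos``; returns layout for planting."""
    e1 = int(rng.integers(400, 1200))
    i1 = int(rng.integers(4000, 8000))
    e2 = int(rng.integers(400, 1200))
    i2 = int(rng.integers(3000, 6000))
    e3 = int(rng.integers(400, 1200))
    exon1 = (pos, pos + e1)
    exon2 = (exon1[1] + i1, exon1[1] + i1 + e2)
    exon3 = (exon2[1] + i2, exon2[1] + i2 + e3)
    gene = TranscriptModel(
        id=gene_id, chrom=chrom, strand=strand, start=pos, end=exon3[1],
        exons=(exon1, exon2, exon3), biotype="coding",
    )
    layout = {
        "intron1": (exon1[1], exon2[0]),
        "intron2": (exon2[1], exon3[0]),
        "exon2": exon2,
    }
    return gene, layout


def _plant_embedded(lnc_id: str, klass: str, gene: TranscriptModel, layout: dict,
                    rng) -> TranscriptModel:
    """lncRNA inside/overlapping its host gene per the class geometry."""
    i1s, i1e = layout["intron1"]
    i2s, i2e = layout["intron2"]
    e2s, e2e = layout["exon2"]
    anti = "-" if gene.strand == "+" else "+"
    if klass in ("exon_sense_overlapping", "natural_antisense"):
        # overlap the second exon, extending back into intron 1
        back = int(rng.integers(200, min(1500, i1e - i1s - 100)))
        start = e2s - back
        end = e2s + int(rng.integers(50, e2e - e2s))
        strand = gene.strand if klass == "exon_sense_overlapping" else anti
    elif klass in ("intron_sense_overlapping", "intronic_antisense"):
        intron = layout["intron1"] if klass == "intron_sense_overlapping" else layout["intron2"]
        s, e = intron
        pad = 100
        max_len = (e - s) - 2 * pad
        length = int(rng.integers(300, max(301, max_len)))
        start = s + pad + int(rng.integers(0, max(1, max_len - length + 1)))
        end = start + length
        strand = gene.strand if klass == "intron_sense_overlapping" else anti
    else:  # pragma: no cover - internal misuse
        raise ValueError(klass)
    return TranscriptModel(lnc_id, gene.chrom, strand, start, end,
                           ((start, end),), "lncRNA")


def generate_annotation(config: SimulationConfig) -> tuple[list[TranscriptModel], GroundTruth]:
    """Place coding genes and class-planted lncRNAs on synthetic chromosomes.

    Coding genes are non-overlapping with >=2 exons (three here) on
    alternating strands.  Each positional class receives exactly
    ``n_lncrna_per_class`` lncRNAs constructed to satisfy that class's
    geometry and no other's; intergenic lncRNAs alternate between having a
    nearest neighbor at a known gap and being isolated (>100 kb from any
    gene).  Raises a sizing error when a chromosome cannot hold its share.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    n = config.n_lncrna_per_class

    # tasks that need a host coding gene
    host_tasks: list[str] = []
    for klass in ("exon_sense_overlapping", "intron_sense_overlapping",
                  "natural_antisense", "intronic_antisense", "bidirectional"):
        host_tasks += [klass] * n
    n_iso = n // 2
    host_tasks += ["intergenic_neighbor"] * (n - n_iso)
    if len(host_tasks) > config.n_coding_genes:
        raise ValueError(
            f"n_coding_genes={config.n_coding_genes} too small: planting "
            f"{len(host_tasks)} host-anchored lncRNAs needs at least that many coding genes"
        )
    rng.shuffle(host_tasks)

    # units: (kind, task) — one coding gene each, plus standalone isolated lncRNAs
    units: list[tuple[str, Optional[str]]] = [
        ("gene", host_tasks[i] if i < len(host_tasks) else None)
        for i in range(config.n_coding_genes)
    ]
    iso_positions = np.linspace(0, len(units), n_iso, endpoint=False).astype(int) if n_iso else []
    for off, p in enumerate(sorted(iso_positions)):
        units.insert(p + off, ("isolated", "intergenic_isolated"))

    per_chrom: dict[str, list] = {f"chr{c + 1}": [] for c in range(config.n_chromosomes)}
    for i, u in enumerate(units):
        per_chrom[f"chr{(i % config.n_chromosomes) + 1}"].append(u)

    truth = GroundTruth()
    transcripts: list[TranscriptModel] = []
    gene_counter = 0
    lnc_counter = 0
    gap_cap = config.bidirectional_gap_bp

    def next_gene_id():
        nonlocal gene_counter
        gene_counter += 1
        return f"G{gene_counter:04d}"

    def next_lnc_id():
        nonlocal lnc_counter
        lnc_counter += 1
        return f"L{lnc_counter:04d}"

    for chrom, chrom_units in per_chrom.items():
        cursor = 10_000
        strand_flip = 0
        for kind, task in chrom_units:
            spacing_lo = max(3_000, gap_cap + 1_000)
            cursor += int(rng.integers(spacing_lo, spacing_lo + 7_000))
            if kind == "isolated":
                cursor += 110_000
                length = int(rng.integers(300, 3_000))
                lid = next_lnc_id()
                strand = "+" if rng.integers(2) == 0 else "-"
                transcripts.append(TranscriptModel(lid, chrom, strand, cursor,
                                                   cursor + length,
                                                   ((cursor, cursor + length),), "lncRNA"))
                truth.true_class_by_lncrna[lid] = "intergenic"
                truth.true_neighbor_by_lncrna[lid] = None
                truth.true_distance_by_lncrna[lid] = None
                cursor += length + 110_000
            else:
                strand = "+" if strand_flip % 2 == 0 else "-"
                strand_flip += 1
                gene_pos = cursor
                lnc_before = None
                if task == "bidirectional" and strand == "+":
                    # lncRNA first, head-to-head with the gene's TSS
                    length = int(rng.integers(300, 2_000))
                    gap = int(rng.integers(20, gap_cap + 1))
                    lnc_before = (cursor, cursor + length, gap)
                    gene_pos = cursor + length + gap
                gid = next_gene_id()
                gene, layout = _make_gene(gid, chrom, strand, gene_pos, rng)
                transcripts.append(gene)
                cursor = gene.end

                if task in ("exon_sense_overlapping", "natural_antisense",
                            "intron_sense_overlapping", "intronic_antisense"):
                    lid = next_lnc_id()
                    lnc = _plant_embedded(lid, task, gene, layout, rng)
                    transcripts.append(lnc)
                    truth.true_class_by_lncrna[lid] = task
                    truth.true_neighbor_by_lncrna[lid] = gid
                    truth.true_distance_by_lncrna[lid] = 0
                elif task == "bidirectional":
                    lid = next_lnc_id()
                    if strand == "+":
                        s, e, gap = lnc_before
                        lnc = TranscriptModel(lid, chrom, "-", s, e, ((s, e),), "lncRNA")
                    else:
                        # gene TSS at its right end; lncRNA downstream on '+'
                        length = int(rng.integers(300, 2_000))
                        gap = int(rng.integers(20, gap_cap + 1))
                        s = gene.end + gap
                        lnc = TranscriptModel(lid, chrom, "+", s, s + length,
                                              ((s, s + length),), "lncRNA")
                        cursor = lnc.end
                    transcripts.append(lnc)
                    truth.true_class_by_lncrna[lid] = "bidirectional"
                    truth.true_neighbor_by_lncrna[lid] = gid
                    truth.true_distance_by_lncrna[lid] = gap
                elif task == "intergenic_neighbor":
                    lid = next_lnc_id()
                    d = int(rng.integers(2_000, 40_000))
                    length = int(rng.integers(300, 3_000))
                    s = gene.end + d
                    lnc = TranscriptModel(lid, chrom, strand, s, s + length,
                                          ((s, s + length),), "lncRNA")
                    transcripts.append(lnc)
                    truth.true_class_by_lncrna[lid] = "intergenic"
                    truth.true_neighbor_by_lncrna[lid] = gid
                    truth.true_distance_by_lncrna[lid] = d
                    # keep the host gene the nearest one
                    cursor = lnc.end + d + 5_000

            if cursor > config.chrom_length - 10_000:
                raise ValueError(
                    f"chromosome {chrom} too short: placement reached {cursor} bp "
                    f"but chrom_length={config.chrom_length}; increase chrom_length "
                    f"or reduce n_coding_genes/n_lncrna_per_class"
                )

    transcripts.sort(key=lambda t: (t.chrom, t.start, t.id))
    return transcripts, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: SimulationConfig,
    annotation: Sequence[TranscriptModel],
    truth: Optional[GroundTruth] = None,
    force_de: Optional[dict[str, int]] = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Linear-scale intensity matrix with planted group effects.

    log2 intensity = baseline + group effect + N(0, noise_sd); the VSD group
    of differential probes is shifted by ±planted_log2fc.  The matrix is
    stored on the linear scale (2^x), mimicking scanner output.
    ``force_de`` pins specific probes (lncRNA or coding) to a given sign on
    top of the random ``fraction_de`` draw among lncRNAs.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    if config.n_replicates_per_group < 2:
        raise ValueError("n_replicates_per_group must be >= 2 (differential test undefined)")
    rng = config.rng(_STREAM_EXPRESSION)
    truth = truth if truth is not None else GroundTruth()

    probe_ids = [t.id for t in annotation]
    lnc_ids = [t.id for t in annotation if t.biotype == "lncRNA"]
    force_de = dict(force_de or {})

    eligible = [i for i in lnc_ids if i not in force_de]
    n_de = int(round(config.fraction_de * len(lnc_ids)))
    n_random = max(0, n_de - len(force_de))
    chosen = list(rng.choice(eligible, size=min(n_random, len(eligible)), replace=False))
    signs = {i: int(rng.choice([-1, 1])) for i in chosen}
    signs.update(force_de)
    truth.true_de_probes = signs

    n_rep = config.n_replicates_per_group
    samples = [f"VSD_{i + 1}" for i in range(n_rep)] + [f"NC_{i + 1}" for i in range(n_rep)]
    groups = {s: ("VSD" if s.startswith("VSD") else "NC") for s in samples}

    baseline = rng.uniform(6.0, 12.0, size=len(probe_ids))
    # differential probes sit in the interior of the intensity range so that
    # their shifted values stay within the distribution's support (real
    # arrays have ~60k probes and a wide span; at synthetic scale an edge
    # probe would be clamped by quantile normalization)
    margin = min(config.planted_log2fc + 0.5, 2.9)
    for row, pid in enumerate(probe_ids):
        if pid in signs:
            baseline[row] = rng.uniform(6.0 + margin, 12.0 - margin)
    log2 = np.tile(baseline[:, None], (1, len(samples)))
    for row, pid in enumerate(probe_ids):
        if pid in signs:
            log2[row, :n_rep] += signs[pid] * config.planted_log2fc
    log2 += rng.normal(0.0, config.noise_sd, size=log2.shape) if config.noise_sd > 0 else 0.0

    linear = pd.DataFrame(2.0 ** log2, index=probe_ids, columns=samples)
    return ExpressionMatrix(linear, groups, log2=False), truth


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path: str, design_path: str) -> None:
    """Write the matrix on the linear scale plus the sample->group design."""
    linear = (2.0 ** matrix.values) - 1.0
    linear.index.name = "probe_id"
    linear.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(design_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.group_of_sample[s]}\n")


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------


def generate_conservation_track(
    config: SimulationConfig,
    annotation: Sequence[TranscriptModel],
    truth: Optional[GroundTruth] = None,
    fully_conserved: Optional[Iterable[str]] = None,
) -> tuple[ConservationTrack, dict[str, list[tuple[int, int]]], GroundTruth]:
    """Score every exonic base; plant conserved elements (score >= 0.5).

    Background bases draw scores uniformly below 0.5; planted element bases
    uniformly in [0.5, 1].  Elements arrive at a Poisson rate of
    ``conserved_element_density`` per kb of exon.  Transcripts listed in
    ``fully_conserved`` get one element covering their whole exonic span.
    Returns the track, the element intervals per chromosome, and the truth
    with per-transcript conserved fractions recorded.
    """
    rng = config.rng(_STREAM_CONSERVATION)
    truth = truth if truth is not None else GroundTruth()
    fully = set(fully_conserved or ())

    score_of: dict[str, dict[int, float]] = {}
    conserved_pos: dict[str, set[int]] = {}
    elements: dict[str, list[tuple[int, int]]] = {}

    for t in sorted(annotation, key=lambda t: (t.chrom, t.start, t.id)):
        sc = score_of.setdefault(t.chrom, {})
        for s, e in t.exons:
            for p in range(s, e):
                if p not in sc:
                    sc[p] = float(rng.uniform(0.0, 0.5))

    def plant(chrom: str, s: int, e: int):
        sc = score_of[chrom]
        cp = conserved_pos.setdefault(chrom, set())
        for p in range(s, e):
            sc[p] = float(rng.uniform(0.5, 1.0))
            cp.add(p)
        elements.setdefault(chrom, []).append((s, e))

    for t in sorted(annotation, key=lambda t: (t.chrom, t.start, t.id)):
        if t.id in fully:
            for s, e in t.exons:
                plant(t.chrom, s, e)
            continue
        n_elem = int(rng.poisson(config.conserved_element_density * t.exonic_length / 1000.0))
        for _ in range(n_elem):
            xs, xe = t.exons[int(rng.integers(len(t.exons)))]
            max_len = min(200, xe - xs)
            length = int(rng.integers(20, max(21, max_len)))
            length = min(length, xe - xs)
            s = xs + int(rng.integers(0, xe - xs - length + 1))
            plant(t.chrom, s, s + length)

    # truth fractions over exonic bases
    for t in annotation:
        cp = conserved_pos.get(t.chrom, set())
        sc = score_of.get(t.chrom, {})
        total = conserved = 0
        for s, e in t.exons:
            for p in range(s, e):
                total += 1
                if p in cp or sc[p] >= 0.5:
                    conserved += 1
        truth.true_conserved_fraction[t.id] = conserved / total if total else 0.0

    data = {}
    for chrom, sc in score_of.items():
        pos = np.array(sorted(sc), dtype=np.int64)
        data[chrom] = (pos, np.array([sc[p] for p in pos]))
    merged = {c: _merge_intervals(v) for c, v in elements.items()}
    return ConservationTrack(data), merged, truth


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_elements_bed(elements: dict[str, list[tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(elements):
            for s, e in elements[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    config: SimulationConfig,
    genes: Optional[Sequence[str]] = None,
    group_ratio: Optional[dict[str, float]] = None,
    tissue_level: Optional[dict[str, dict[str, float]]] = None,
    truth: Optional[GroundTruth] = None,
    reference_gene: str = "GAPDH",
    ct_noise_sd: float = 0.0,
) -> tuple[CtTable, GroundTruth]:
    """Triplicate Ct table over VSD/NC heart samples plus a tissue panel.

    ``group_ratio`` plants the VSD-vs-NC relative quantity per gene (default
    1.0); ``tissue_level`` plants relative abundance per tissue for the panel
    samples (default flat).  The reference gene is measured in every sample
    at a fixed Ct, so planted ratios are exactly recoverable when
    ``ct_noise_sd`` is 0.
    """
    rng = config.rng(_STREAM_CT)
    truth = truth if truth is not None else GroundTruth()
    genes = list(genes) if genes is not None else [f"T{i + 1}" for i in range(4)]
    group_ratio = dict(group_ratio or {})
    tissue_level = {g: dict(v) for g, v in (tissue_level or {}).items()}

    n_rep = config.n_replicates_per_group
    samples = (
        [(f"VSD_{i + 1}", "heart", "VSD") for i in range(n_rep)]
        + [(f"NC_{i + 1}", "heart", "NC") for i in range(n_rep)]
        + [(f"PANEL_{t}", t, "panel") for t in TISSUES]
    )

    base_dct = {g: float(rng.uniform(2.0, 8.0)) for g in genes}
    ref_ct = 18.0
    rows = []

    def add(sample, tissue, group, gene, ct):
        for rep in range(3):
            jitter = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
            rows.append((sample, tissue, group, gene, rep + 1, ct + jitter))

    for sample, tissue, group, _ in [(s, t, g, None) for s, t, g in samples]:
        add(sample, tissue, group, reference_gene, ref_ct)
        for gene in genes:
            dct = base_dct[gene]
            if group == "VSD":
                ratio = group_ratio.get(gene, 1.0)
                dct = dct - math.log2(ratio)
            elif group == "panel":
                level = tissue_level.get(gene, {}).get(tissue, 1.0)
                if level <= 0:
                    raise ValueError(f"planted tissue level for {gene}/{tissue} must be > 0")
                dct = dct - math.log2(level)
            add(sample, tissue, group, gene, ref_ct + dct)

    truth.planted_ct_ratio = {g: group_ratio.get(g, 1.0) for g in genes}
    truth.planted_tissue_level = {
        g: {t: tissue_level.get(g, {}).get(t, 1.0) for t in TISSUES} for g in genes
    }
    df = pd.DataFrame(rows, columns=["sample", "tissue", "group", "gene", "replicate", "ct"])
    return CtTable(df, reference_gene), truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    config: SimulationConfig,
    annotation: Sequence[TranscriptModel],
    truth: GroundTruth,
    n_decoy_sets: int = 24,
    cardiac_size: int = 10,
) -> tuple[list[GeneSet], GroundTruth]:
    """Decoy gene sets plus one "cardiac" set enriched among DE neighbors.

    The cardiac set contains the coding neighbors of every planted
    differentially-expressed lncRNA (padded with random non-neighbor genes
    up to ``cardiac_size``), so downstream over-representation tests have a
    planted positive.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    rng = config.rng(_STREAM_GENESETS)
    coding = sorted(t.id for t in annotation if t.biotype == "coding")

    de_neighbors = sorted({
        g for l, g in truth.true_neighbor_by_lncrna.items()
        if g is not None and l in truth.true_de_probes
    })
    non_neighbors = [g for g in coding if g not in set(de_neighbors)]
    pad = list(rng.choice(non_neighbors, size=min(max(0, cardiac_size - len(de_neighbors)),
                                                  len(non_neighbors)), replace=False))
    cardiac = GeneSet("GS_CARDIAC", "regulation of heart growth",
                      frozenset(de_neighbors + pad))
    sets = [cardiac]
    for i in range(n_decoy_sets):
        size = int(rng.integers(5, 16))
        members = rng.choice(coding, size=min(size, len(coding)), replace=False)
        sets.append(GeneSet(f"GS{i + 1:03d}", f"decoy process {i + 1}", frozenset(members)))
    truth.cardiac_set_id = cardiac.set_id
    return sets, truth


# ---------------------------------------------------------------------------
# Full pipeline bundle
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """File paths of a written synthetic input bundle."""

    outdir: str
    gtf: str
    matrix: str
    design: str
    wig: str
    elements: str
    gmt: str
    ct: str
    truth_json: str
    truth: GroundTruth


def generate_bundle(config: SimulationConfig, outdir: str, n_candidates: int = 2) -> Bundle:
    """Write a complete synthetic input set with planted stage-5 candidates.

    ``n_candidates`` lncRNAs are constructed to clear every prioritization
    stage: dysregulated past the volcano thresholds, neighbor gene in the
    cardiac functional set, fully conserved exons, heart-predominant in the
    tissue panel, and a cis-concordant dysregulated neighbor.  All other
    planted DE lncRNAs fail the functional filter because their neighbors
    are kept out of the cardiac set.
    """
    from .conservation import write_track
    from .enrichment import write_gmt
    from .genomic_context import write_gtf

    os.makedirs(outdir, exist_ok=True)
    annotation, truth = generate_annotation(config)

    # candidates: prefer a natural antisense and a bidirectional lncRNA,
    # alternating down/up — the SMAD1-antisense / FGF10-bidirectional motif
    preferred = ["natural_antisense", "bidirectional", "intergenic",
                 "exon_sense_overlapping", "intronic_antisense", "intron_sense_overlapping"]
    candidates: list[str] = []
    for klass in preferred:
        for lid in sorted(truth.true_class_by_lncrna):
            if len(candidates) >= n_candidates:
                break
            if (truth.true_class_by_lncrna[lid] == klass
                    and truth.true_neighbor_by_lncrna.get(lid) is not None
                    and lid not in candidates):
                candidates.append(lid)
                break
    if len(candidates) < n_candidates:
        raise ValueError("not enough neighbor-bearing lncRNAs to plant candidates")
    truth.candidate_ids = candidates

    force_de: dict[str, int] = {}
    for i, lid in enumerate(candidates):
        sign = -1 if i % 2 == 0 else 1
        force_de[lid] = sign
        force_de[truth.true_neighbor_by_lncrna[lid]] = sign  # cis-concordant neighbor

    matrix, truth = generate_expression(config, annotation, truth, force_de=force_de)

    # cardiac set must contain exactly the candidates' neighbors among
    # DE-lncRNA neighbors, so only candidates survive the functional filter
    sets, truth = generate_gene_sets(config, annotation, truth)
    cand_neighbors = {truth.true_neighbor_by_lncrna[c] for c in candidates}
    other_de_neighbors = {
        g for l, g in truth.true_neighbor_by_lncrna.items()
        if g is not None and l in truth.true_de_probes and l not in candidates
    }
    rebuilt = []
    for s in sets:
        if s.set_id == truth.cardiac_set_id:
            members = (s.members - other_de_neighbors) | cand_neighbors
        else:
            members = s.members - other_de_neighbors - cand_neighbors
        rebuilt.append(GeneSet(s.set_id, s.name, frozenset(members)))
    sets = rebuilt

    track, elements, truth = generate_conservation_track(
        config, annotation, truth, fully_conserved=candidates
    )

    ct_genes = candidates + sorted(cand_neighbors)
    group_ratio = {g: float(2.0 ** (force_de[g] * config.planted_log2fc))
                   for g in ct_genes if g in force_de}
    heart_high = {t: (8.0 if t == "heart" else 0.5) for t in TISSUES}
    tissue_level = {g: dict(heart_high) for g in ct_genes}
    ct, truth = generate_ct_table(config, genes=ct_genes, group_ratio=group_ratio,
                                  tissue_level=tissue_level, truth=truth)

    paths = Bundle(
        outdir=outdir,
        gtf=os.path.join(outdir, "annotation.gtf"),
        matrix=os.path.join(outdir, "expression.tsv"),
        design=os.path.join(outdir, "design.tsv"),
        wig=os.path.join(outdir, "phastcons.wig"),
        elements=os.path.join(outdir, "elements.bed"),
        gmt=os.path.join(outdir, "genesets.gmt"),
        ct=os.path.join(outdir, "ct.tsv"),
        truth_json=os.path.join(outdir, "ground_truth.json"),
        truth=truth,
    )
    write_gtf(annotation, paths.gtf)
    write_expression_tsv(matrix, paths.matrix, paths.design)
    write_track(track, paths.wig)
    write_elements_bed(elements, paths.elements)
    write_gmt(sets, paths.gmt)
    ct.to_tsv(paths.ct)
    truth.to_json(paths.truth_json)
    return paths
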