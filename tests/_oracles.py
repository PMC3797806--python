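"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's interval index and vectorised code:
every quantity is recomputed by direct enumeration so the tests check the
implementation against a second, simpler route.
"""

import numpy as np

from lncvsd.genomic_context import TranscriptModel


def _span_overlap(a_start, a_end, b_start, b_end):
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _exonic_overlap(lnc, gene):
    return any(
        _span_overlap(lnc.start, lnc.end, s, e) > 0 for s, e in gene.exons
    )


def brute_force_classify(lnc, coding, window_bp=100_000, bidirectional_gap_bp=1_000):
    """All-pairs positional classification of one lncRNA.

    Returns (class, neighbor_gene_id, distance_bp) by looping over every
    coding gene and applying the class definitions in precedence order.
    """
    genes = [g for g in coding if g.chrom == lnc.chrom]

    def pick(cands):
        return min(cands, key=lambda g: (g.start, g.id))

    overlapping = [g for g in genes if _span_overlap(lnc.start, lnc.end, g.start, g.end) > 0]

    same = [g for g in overlapping if g.strand == lnc.strand]
    opp = [g for g in overlapping if g.strand != lnc.strand]

    exon_sense = [g for g in same if _exonic_overlap(lnc, g)]
    if exon_sense:
        return "exon_sense_overlapping", pick(exon_sense).id, 0

    intron_sense = [
        g for g in same
        if g.start <= lnc.start and lnc.end <= g.end and not _exonic_overlap(lnc, g)
    ]
    if intron_sense:
        return "intron_sense_overlapping", pick(intron_sense).id, 0

    nat = [
        g for g in opp
        if _exonic_overlap(lnc, g) or not (g.start <= lnc.start and lnc.end <= g.end)
    ]
    if nat:
        return "natural_antisense", pick(nat).id, 0

    intronic_anti = [
        g for g in opp
        if g.start <= lnc.start and lnc.end <= g.end and not _exonic_overlap(lnc, g)
    ]
    if intronic_anti:
        return "intronic_antisense", pick(intronic_anti).id, 0

    if not overlapping:
        lnc_tss = lnc.start if lnc.strand == "+" else lnc.end
        bidir = []
        for g in genes:
            g_tss = g.start if g.strand == "+" else g.end
            if (g.strand != lnc.strand
                    and _span_overlap(lnc.start, lnc.end, g.start, g.end) == 0
                    and abs(lnc_tss - g_tss) <= bidirectional_gap_bp):
                bidir.append((abs(lnc_tss - g_tss), g))
        if bidir:
            _, g = min(bidir, key=lambda x: (x[0], x[1].start, x[1].id))
            gap = max(g.start - lnc.end, lnc.start - g.end, 0)
            return "bidirectional", g.id, gap

    best = None
    for g in genes:
        gap = max(g.start - lnc.end, lnc.start - g.end, 0)
        if gap >= window_bp:
            continue
        if lnc.strand == "+":
            key = (gap, g.start, g.id)
        else:
            key = (gap, -g.end, g.id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is not None:
        g = best[1]
        return "intergenic", g.id, max(g.start - lnc.end, lnc.start - g.end, 0)
    return "intergenic", None, None


def random_genome(rng, max_genes=40, max_lnc=30, span=400_000):
    """Arbitrary (possibly overlapping) coding genes and lncRNAs on one
    chromosome — deliberately messier than the planted generator output."""
    coding, lnc = [], []
    n_genes = int(rng.integers(1, max_genes + 1))
    n_lnc = int(rng.integers(1, max_lnc + 1))
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1_000, 20_000))
        end = start + length
        n_ex = int(rng.integers(2, 5))
        cuts = sorted(rng.choice(np.arange(start + 1, end), size=2 * n_ex - 2, replace=False))
        bounds = [start] + [int(c) for c in cuts] + [end]
        exons = tuple((bounds[2 * k], bounds[2 * k + 1]) for k in range(n_ex))
        strand = "+" if rng.integers(2) == 0 else "-"
        coding.append(TranscriptModel(f"G{i}", "chr1", strand, start, end, exons, "coding"))
    for i in range(n_lnc):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 5_000))
        strand = "+" if rng.integers(2) == 0 else "-"
        lnc.append(TranscriptModel(f"L{i}", "chr1", strand, start, start + length,
                                   ((start, start + length),), "lncRNA"))
    return coding, lnc


def brute_force_conserved_fraction(transcript, wig_path, threshold=0.5):
    """Base-by-base conserved fraction read directly from a written WIG file."""
    scores = {}
    chrom = None
    nxt = step = None
    with open(wig_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                nxt = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
            elif line and chrom == transcript.chrom:
                scores[nxt] = float(line)
                nxt += step
            elif line:
                nxt += step
    covered = conserved = 0
    for s, e in transcript.exons:
        for p in range(s, e):
            if p in scores:
                covered += 1
                if scores[p] >= threshold:
                    conserved += 1
    return covered, (conserved / covered if covered else 0.0)


def brute_force_hypergeom_tail(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for x in range(k, min(n, K) + 1):
        if n - x > N - K:
            continue
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom
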