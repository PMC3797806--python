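"""Gene-set over-representation among the coding neighbors of dysregulated
lncRNAs.

The query set is the deduplicated list of nearest coding neighbors of the
up- (or down-) regulated lncRNAs; the universe is, by default, every coding
gene that is the neighbor of any profiled lncRNA — not the whole genome —
matching the restriction of the analysis to closest coding genes.  The
primary test is the one-sided hypergeometric upper tail (Fisher's exact test
for over-representation); a Pearson chi-square alternative is provided, and
P-values are corrected with Benjamini–Hochberg FDR.  Gene-set annotations
are flat (no ontology-ancestor propagation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_context import ClassifiedLncRNA


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


class GeneSetCollection:
    """Named gene sets restricted to a gene universe (GMT semantics)."""

    def __init__(self, sets: Iterable[GeneSet], universe: Iterable[str]):
        self.universe = frozenset(universe)
        self.sets: dict[str, GeneSet] = {}
        for s in sets:
            members = frozenset(s.members) & self.universe
            if members:
                self.sets[s.set_id] = GeneSet(s.set_id, s.name, members)

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str, universe: Optional[Iterable[str]] = None) -> "GeneSetCollection":
        sets = read_gmt(path)
        if universe is None:
            universe = set().union(*(s.members for s in sets)) if sets else set()
        return cls(sets, universe)


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    k: int          # overlap of query with the set
    n: int          # query size
    K: int          # set size within the universe
    N: int          # universe size
    p_value: float
    fdr: float
    odds_ratio: float
    unreliable: bool = False  # chi-square small-expected-cell flag


def read_gmt(path: str) -> list[GeneSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return out


def write_gmt(sets: Sequence[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name] + sorted(s.members)) + "\n")


def neighbor_gene_sets(
    classified: Sequence[ClassifiedLncRNA],
    up_ids: Iterable[str],
    down_ids: Iterable[str],
) -> tuple[set[str], set[str], set[str]]:
    """Neighbor-gene query sets for up/down lncRNAs plus the neighbor universe."""
    neighbor_of = {c.lncrna_id: c.neighbor_gene_id for c in classified}
    up_genes = {neighbor_of[i] for i in up_ids if neighbor_of.get(i) is not None}
    down_genes = {neighbor_of[i] for i in down_ids if neighbor_of.get(i) is not None}
    universe = {g for g in neighbor_of.values() if g is not None}
    return up_genes, down_genes, universe


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_enrichment(query: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentResult]:
    """One-sided hypergeometric upper-tail test P(X >= k) per gene set.

    Results are sorted by ascending p-value (set id as tie-break) and carry
    BH-FDR adjusted values.
    """
    q = set(query) & collection.universe
    N = len(collection.universe)
    n = len(q)
    if n == 0:
        warnings.warn("empty query set; no enrichment computed")
        return []
    results = []
    for s in sorted(collection.sets.values(), key=lambda s: s.set_id):
        K = len(s.members)
        k = len(q & s.members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(s.set_id, s.name, k, n, K, N, min(p, 1.0), math.nan,
                             _odds_ratio(k, n, K, N))
        )
    _attach_fdr(results)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def chi2_enrichment(query: Iterable[str], collection: GeneSetCollection) -> list[EnrichmentResult]:
    """Pearson chi-square test (no continuity correction) on each 2x2 table.

    Flagged unreliable when any expected cell count is below 5; degenerate
    margins yield p = 1 with the flag set.
    """
    q = set(query) & collection.universe
    N = len(collection.universe)
    n = len(q)
    if n == 0:
        warnings.warn("empty query set; no enrichment computed")
        return []
    results = []
    for s in sorted(collection.sets.values(), key=lambda s: s.set_id):
        K = len(s.members)
        k = len(q & s.members)
        table = np.array([[k, n - k], [K - k, N - n - K + k]], dtype=float)
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            p, unreliable = 1.0, True
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            unreliable = bool(expected.min() < 5)
        results.append(
            EnrichmentResult(s.set_id, s.name, k, n, K, N, float(p), math.nan,
                             _odds_ratio(k, n, K, N), unreliable)
        )
    _attach_fdr(results)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _attach_fdr(results: list[EnrichmentResult]) -> None:
    if not results:
        return
    adjusted = bh_fdr([r.p_value for r in results])
    for r, f in zip(results, adjusted):
        r.fdr = float(f)


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tname\tk\tn\tK\tN\tp_value\tfdr\todds_ratio\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.odds_ratio:.6g}\n"
            )
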