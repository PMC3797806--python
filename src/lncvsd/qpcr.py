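"""Relative qPCR quantification by the 2^-ΔΔCt method.

Replicate Ct values are averaged on the Ct (cycle) scale; each target gene
is normalized to a reference gene (GAPDH in the study design) within its
sample, then to a calibrator — either a named sample or the mean ΔCt of a
group (the normal-control group for case/control comparisons). Amplification
efficiency is taken as perfect doubling, so relative quantity is
rq = 2^-ΔΔCt. Replicate scatter above 0.5 cycles is flagged, not dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import DifferentialRecord

CT_COLUMNS = ["sample", "tissue", "group", "gene", "replicate", "ct"]
REPLICATE_SD_WARN = 0.5


class CtTable:
    """Long-format qPCR cycle-threshold table.

    Columns: sample, tissue, group (VSD/NC/panel), gene, replicate, ct.
    """

    def __init__(self, df: pd.DataFrame, reference_gene: str = "GAPDH"):
        missing = [c for c in CT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if (df["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        self.df = df.copy()
        self.reference_gene = reference_gene
        samples_with_ref = set(df.loc[df["gene"] == reference_gene, "sample"])
        missing_ref = sorted(set(df["sample"]) - samples_with_ref)
        if missing_ref:
            raise ValueError(
                f"reference gene {reference_gene} missing for samples: {missing_ref}"
            )

    @classmethod
    def from_tsv(cls, path: str, reference_gene: str = "GAPDH") -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene)

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def genes(self) -> list[str]:
        return sorted(set(self.df["gene"]) - {self.reference_gene})


@dataclass
class RelativeExpression:
    sample_id: str
    gene_id: str
    tissue: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    high_replicate_sd: bool = False


def _mean_ct(table: CtTable) -> pd.DataFrame:
    g = table.df.groupby(["sample", "gene"], sort=True)
    out = g.agg(
        ct=("ct", "mean"), ct_sd=("ct", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        tissue=("tissue", "first"), group=("group", "first"),
    ).reset_index()
    return out


def ddct_quantify(
    table: CtTable,
    reference_gene: Optional[str] = None,
    calibrator: str = "NC",
) -> list[RelativeExpression]:
    """Compute per (sample, gene) relative expression 2^-ΔΔCt.

    ``calibrator`` names either a group (its mean ΔCt per gene is the
    baseline) or a single sample id.
    """
    ref = reference_gene or table.reference_gene
    means = _mean_ct(table)
    ref_rows = means[means["gene"] == ref].set_index("sample")
    targets = means[means["gene"] != ref].copy()

    def _ref_ct(sample: str) -> float:
        if sample not in ref_rows.index:
            raise ValueError(f"reference gene {ref} not measured in sample {sample}")
        return float(ref_rows.loc[sample, "ct"])

    targets["delta_ct"] = [
        row.ct - _ref_ct(row.sample) for row in targets.itertuples()
    ]

    is_group = (means["group"] == calibrator).any()
    is_sample = (means["sample"] == calibrator).any()
    if not is_group and not is_sample:
        raise ValueError(f"calibrator {calibrator!r} is neither a group nor a sample")

    cal_dct: dict[str, float] = {}
    for gene, sub in targets.groupby("gene"):
        if is_group:
            rows = sub[sub["group"] == calibrator]
        else:
            rows = sub[sub["sample"] == calibrator]
        if rows.empty:
            raise ValueError(f"calibrator {calibrator!r} has no measurement of {gene}")
        cal_dct[gene] = float(rows["delta_ct"].mean())

    out = []
    for row in targets.itertuples():
        ddct = row.delta_ct - cal_dct[row.gene]
        sd_flag = row.ct_sd > REPLICATE_SD_WARN
        out.append(
            RelativeExpression(
                sample_id=row.sample, gene_id=row.gene, tissue=row.tissue,
                group=row.group, delta_ct=float(row.delta_ct),
                delta_delta_ct=float(ddct), rq=float(2.0 ** (-ddct)),
                high_replicate_sd=bool(sd_flag),
            )
        )
    return out


@dataclass
class TissueProfile:
    gene_id: str
    shares: dict[str, float]
    predominant_tissue: Optional[str]  # None when tied or undefined
    heart_share: float


def tissue_predominance(
    rel: Sequence[RelativeExpression], heart_label: str = "heart",
    strict_majority: bool = False,
) -> dict[str, TissueProfile]:
    """Per-gene tissue shares of relative expression across a tissue panel.

    share(tissue) = rq(tissue) / sum of rq over the panel (rq averaged over
    samples of the same tissue). The predominant tissue is the argmax share;
    with ``strict_majority`` a gene is heart-predominant only when the heart
    share exceeds 0.5. Exact ties leave ``predominant_tissue`` as None.
    """
    by_gene: dict[str, dict[str, list[float]]] = {}
    for r in rel:
        by_gene.setdefault(r.gene_id, {}).setdefault(r.tissue, []).append(r.rq)
    out: dict[str, TissueProfile] = {}
    for gene, tissues in sorted(by_gene.items()):
        if len(tissues) < 2:
            raise ValueError(f"gene {gene}: need >=2 tissues for a predominance call")
        mean_rq = {t: float(np.mean(v)) for t, v in sorted(tissues.items())}
        total = sum(mean_rq.values())
        if total == 0:
            warnings.warn(f"gene {gene}: all relative quantities zero; shares undefined")
            out[gene] = TissueProfile(gene, {t: math.nan for t in mean_rq}, None, math.nan)
            continue
        shares = {t: v / total for t, v in mean_rq.items()}
        best = max(shares.values())
        winners = [t for t, v in shares.items() if v == best]
        predominant = winners[0] if len(winners) == 1 else None
        if strict_majority and predominant is not None and best <= 0.5:
            predominant = None
        out[gene] = TissueProfile(gene, shares, predominant, shares.get(heart_label, 0.0))
    return out


def concordance_check(
    lnc_diff: DifferentialRecord,
    neighbor_diff: DifferentialRecord,
    alpha: float = 0.05,
) -> str:
    """Cis-regulation concordance between a lncRNA and its coding neighbor.

    Returns ``no_association`` when the neighbor shows no significant change,
    otherwise ``cis_concordant`` when both move in the same direction and
    ``discordant`` when they move oppositely.
    """
    if neighbor_diff.p_value >= alpha:
        return "no_association"
    if math.copysign(1.0, lnc_diff.log2fc) == math.copysign(1.0, neighbor_diff.log2fc):
        return "cis_concordant"
    return "discordant"


def write_rq_tsv(rel: Sequence[RelativeExpression], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\ttissue\tgroup\tdelta_ct\tddct\trq\tflags\n")
        for r in rel:
            flag = "high_replicate_sd" if r.high_replicate_sd else ""
            fh.write(
                f"{r.sample_id}\t{r.gene_id}\t{r.tissue}\t{r.group}\t"
                f"{r.delta_ct:.6g}\t{r.delta_delta_ct:.6g}\t{r.rq:.6g}\t{flag}\n"
            )
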