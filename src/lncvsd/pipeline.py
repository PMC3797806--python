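"""Candidate-prioritization cascade.

Five stages, each consuming the previous stage's survivors:

1. differential (volcano) filter — fold-change > 2, P < 0.05
2. functional filter — neighbor coding gene annotated to a selected
   heart-development / proliferation / apoptosis / differentiation term
3. conservation filter — conserved-base fraction at the >=0.5 score
   criterion meets a configurable minimum
4. tissue predominance — relative expression across a tissue panel peaks
   in heart (only lncRNAs measured in the Ct table are testable; unmeasured
   survivors are carried as "untested", not failed)
5. cis-regulation concordance — the neighbor gene is itself significantly
   dysregulated in the same direction

Every profiled lncRNA appears in the output with the number of consecutive
stages it passed; the run report records counts and thresholds per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import conservation as cons
from . import enrichment as enr
from . import expression as expr
from . import genomic_context as ctx
from . import qpcr

log = logging.getLogger(__name__)

STAGES = ("differential", "functional", "conservation", "tissue_predominance", "cis_check")


@dataclass
class PipelineConfig:
    matrix: str
    design: str
    annotation: str
    track: str
    elements: Optional[str]
    gene_sets: str
    ct_table: Optional[str]
    functional_terms: list[str] = field(default_factory=lambda: ["GS_CARDIAC"])
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    window_bp: int = ctx.DEFAULT_WINDOW_BP
    bidirectional_gap_bp: int = ctx.DEFAULT_BIDIRECTIONAL_GAP_BP
    min_conserved_fraction: float = 0.1
    alpha: float = 0.05
    reference_gene: str = "GAPDH"
    heart_label: str = "heart"
    seed: int = 0

    def __post_init__(self):
        for name in ("fc_threshold", "p_threshold", "window_bp",
                     "bidirectional_gap_bp", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_conserved_fraction < 0:
            raise ValueError("min_conserved_fraction must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class CandidateRecord:
    lncrna_id: str
    direction: str
    fold_change: float
    p_value: float
    positional_class: str
    neighbor_gene_id: Optional[str]
    passed_differential: bool
    passed_functional: bool
    passed_conservation: bool
    heart_predominant: str  # "yes" | "no" | "untested"
    cis_status: str         # cis_concordant | discordant | no_association | untested
    stage_reached: int      # consecutive filters passed, 0..5


def functional_filter(
    classified: Sequence[ctx.ClassifiedLncRNA],
    up_ids: Sequence[str],
    down_ids: Sequence[str],
    terms: Sequence[str],
    collection: enr.GeneSetCollection,
    records: Optional[Sequence[expr.DifferentialRecord]] = None,
) -> list[str]:
    """Dysregulated lncRNAs whose neighbor belongs to >=1 selected term.

    Output ordered by |log2fc| descending (when records are supplied), id
    ascending as tie-break.
    """
    if not terms:
        raise ValueError("functional term list is empty")
    missing = [t for t in terms if t not in collection.sets]
    if missing:
        raise ValueError(f"functional term id(s) absent from collection: {missing}")
    members = set().union(*(collection.sets[t].members for t in terms))
    neighbor_of = {c.lncrna_id: c.neighbor_gene_id for c in classified}
    keep = [
        i for i in list(up_ids) + list(down_ids)
        if neighbor_of.get(i) is not None and neighbor_of[i] in members
    ]
    if records is not None:
        fc = {r.probe_id: abs(r.log2fc) for r in records}
        keep.sort(key=lambda i: (-fc.get(i, 0.0), i))
    else:
        keep.sort()
    return keep


def run_pipeline(config: PipelineConfig, outdir: str):
    """Execute the full cascade; returns (candidate records, report dict).

    Writes candidates.tsv, per-stage survivor TSVs and report.json into
    ``outdir``. Reruns with identical inputs produce byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    t0 = time.time()
    for label, path in [("matrix", config.matrix), ("design", config.design),
                        ("annotation", config.annotation), ("track", config.track),
                        ("gene_sets", config.gene_sets)]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"pipeline input '{label}' missing: {path}")

    annotation = ctx.read_gtf(config.annotation)
    lnc = [t for t in annotation if t.biotype == "lncRNA"]
    coding = [t for t in annotation if t.biotype == "coding"]
    matrix = expr.ExpressionMatrix.from_tsv(config.matrix, config.design)
    matrix = expr.quantile_normalize(matrix)
    records = expr.differential_test(matrix)
    rec_of = {r.probe_id: r for r in records}

    # stage 1: volcano on lncRNA probes
    lnc_ids = {t.id for t in lnc}
    lnc_records = [r for r in records if r.probe_id in lnc_ids]
    up, down = expr.volcano_filter(lnc_records, config.fc_threshold, config.p_threshold)
    s1 = sorted(up) + sorted(down)

    # stage 2: neighbor-gene functional membership
    index = ctx.build_index(coding)
    classified = [
        ctx.classify_lncrna(t, index, config.window_bp, config.bidirectional_gap_bp)
        for t in lnc
    ]
    cls_of = {c.lncrna_id: c for c in classified}
    collection = enr.GeneSetCollection.from_gmt(
        config.gene_sets, universe={t.id for t in coding}
    )
    s2 = functional_filter(classified, up, down, config.functional_terms,
                           collection, lnc_records)

    # stage 3: conservation
    track = cons.read_track(config.track, "fixedStep_wig")
    elements = cons.read_elements_bed(config.elements) if config.elements else None
    summaries = [cons.summarize_transcript(t, track, elements) for t in lnc]
    s3 = cons.conservation_filter(s2, summaries, config.min_conserved_fraction)

    # stage 4: tissue predominance (only measurable survivors advance)
    heart_status: dict[str, str] = {}
    s4: list[str] = []
    if config.ct_table and os.path.exists(config.ct_table):
        table = qpcr.CtTable.from_tsv(config.ct_table, config.reference_gene)
        panel = table.df[table.df["group"] == "panel"]
        measured = set(panel["gene"])
        rel = qpcr.ddct_quantify(table, config.reference_gene, calibrator="NC")
        panel_rel = [r for r in rel if r.group == "panel"]
        profiles = qpcr.tissue_predominance(panel_rel, config.heart_label) if panel_rel else {}
        for i in s3:
            if i in measured and i in profiles:
                ok = profiles[i].predominant_tissue == config.heart_label
                heart_status[i] = "yes" if ok else "no"
                if ok:
                    s4.append(i)
            else:
                heart_status[i] = "untested"
    else:
        heart_status = {i: "untested" for i in s3}

    # stage 5: cis-regulation concordance via the expression matrix
    cis_status: dict[str, str] = {}
    s5: list[str] = []
    for i in s4:
        nb = cls_of[i].neighbor_gene_id
        if nb is None or nb not in rec_of:
            cis_status[i] = "untested"
            continue
        status = qpcr.concordance_check(rec_of[i], rec_of[nb], config.alpha)
        cis_status[i] = status
        if status == "cis_concordant":
            s5.append(i)

    stage_sets = [set(s1), set(s2), set(s3), set(s4), set(s5)]
    candidates = []
    for t in sorted(lnc, key=lambda t: t.id):
        r = rec_of[t.id]
        c = cls_of[t.id]
        reached = 0
        for s in stage_sets:
            if t.id in s:
                reached += 1
            else:
                break
        candidates.append(CandidateRecord(
            lncrna_id=t.id,
            direction=r.direction,
            fold_change=r.fold_change,
            p_value=r.p_value,
            positional_class=c.positional_class,
            neighbor_gene_id=c.neighbor_gene_id,
            passed_differential=t.id in stage_sets[0],
            passed_functional=t.id in stage_sets[1],
            passed_conservation=t.id in stage_sets[2],
            heart_predominant=heart_status.get(t.id, "untested"),
            cis_status=cis_status.get(t.id, "untested"),
            stage_reached=reached,
        ))

    survivors = [len(s1), len(s2), len(s3), len(s4), len(s5)]
    report = {
        "n_lncrna_profiled": len(lnc),
        "n_coding_genes": len(coding),
        "stages": list(STAGES),
        "survivors_per_stage": survivors,
        "eliminated_per_stage": [
            (len(lnc) if k == 0 else survivors[k - 1]) - survivors[k] for k in range(5)
        ],
        "n_up": len(up),
        "n_down": len(down),
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "window_bp": config.window_bp,
            "bidirectional_gap_bp": config.bidirectional_gap_bp,
            "min_conserved_fraction": config.min_conserved_fraction,
            "alpha": config.alpha,
        },
        "final_candidates": sorted(s5),
        "seed": config.seed,
    }
    for k, n_surv in enumerate(survivors):
        if n_surv == 0:
            log.warning("stage %s eliminated all candidates", STAGES[k])
            break

    _write_outputs(outdir, candidates, report, [s1, s2, s3, s4, s5])
    report["runtime_s"] = round(time.time() - t0, 3)
    return candidates, report


def _write_outputs(outdir, candidates, report, stage_lists):
    with open(os.path.join(outdir, "candidates.tsv"), "w") as fh:
        fh.write("lncrna_id\tdirection\tfold_change\tp_value\tclass\tneighbor_gene_id\t"
                 "passed_differential\tpassed_functional\tpassed_conservation\t"
                 "heart_predominant\tcis_status\tstage_reached\n")
        for c in candidates:
            nb = c.neighbor_gene_id or "NA"
            fh.write(
                f"{c.lncrna_id}\t{c.direction}\t{c.fold_change:.6g}\t{c.p_value:.6g}\t"
                f"{c.positional_class}\t{nb}\t{int(c.passed_differential)}\t"
                f"{int(c.passed_functional)}\t{int(c.passed_conservation)}\t"
                f"{c.heart_predominant}\t{c.cis_status}\t{c.stage_reached}\n"
            )
    for name, ids in zip(STAGES, stage_lists):
        with open(os.path.join(outdir, f"stage_{name}.tsv"), "w") as fh:
            fh.write("lncrna_id\n")
            for i in ids:
                fh.write(f"{i}\n")
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
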