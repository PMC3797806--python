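"""Expression-matrix processing: quantile normalization, differential
testing, and the volcano filter (fold-change > 2, P < 0.05) that defines the
up-/down-regulated lncRNA lists.

Intensities arrive on the linear scanner scale; :class:`ExpressionMatrix`
log2-transforms them (pseudocount 1.0) at load.  The differential test is an
unpaired Welch t-test by default — a paired t-test is available where a
pairing structure actually exists — with a small variance floor so noiseless
fixtures yield finite statistics instead of NaN p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GROUPS = ("VSD", "NC")
VARIANCE_FLOOR = 1e-8


class ExpressionMatrix:
    """Probe x sample intensity matrix with a two-group design.

    Parameters
    ----------
    values : DataFrame
        Probes in rows, samples in columns; no missing values.
    group_of_sample : mapping sample id -> group label ("VSD" or "NC").
    log2 : bool
        Whether ``values`` is already log2 scale. Linear input is
        transformed as log2(x + 1).
    """

    def __init__(self, values: pd.DataFrame, group_of_sample: dict[str, str], log2: bool = False):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values; impute or filter first")
        missing = [s for s in values.columns if s not in group_of_sample]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.values = values.astype(float) if log2 else np.log2(values.astype(float) + 1.0)
        self.group_of_sample = {s: group_of_sample[s] for s in values.columns}

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of_sample[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path: str, design_path: str, log2: bool = False) -> "ExpressionMatrix":
        """Load matrix TSV (probe_id + one column per sample) and design TSV
        (columns: sample, group)."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        groups = dict(zip(design["sample"], design["group"]))
        return cls(values, groups, log2=log2)


@dataclass
class DifferentialRecord:
    probe_id: str
    log2fc: float      # mean(VSD) - mean(NC), log2 scale
    fold_change: float  # 2 ** |log2fc|
    p_value: float
    direction: str     # "up" | "down"
    variance_floored: bool = False


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the same intensity distribution.

    Each column is replaced by the cross-sample mean of the per-rank sorted
    values; ties within a column receive the average of their tied ranks'
    values. Row (probe) identity is preserved.
    """
    X = matrix.values.to_numpy()
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    ranks_grid = np.arange(1, n + 1)
    for j in range(X.shape[1]):
        r = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(r, ranks_grid, mean_sorted)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, matrix.group_of_sample, log2=True)


def _welch(m1, v1, n1, m2, v2, n2):
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def differential_test(
    matrix: ExpressionMatrix,
    group_of_sample: Optional[dict[str, str]] = None,
    paired: bool = False,
) -> list[DifferentialRecord]:
    """Two-sided per-probe t-test of VSD vs NC on the log2 matrix.

    Welch's unequal-variance test by default; ``paired=True`` pairs samples
    by their order within each group. Within-group variances below 1e-8 are
    floored (and the record flagged) so that noiseless data yields extreme
    but finite p-values.
    """
    groups = group_of_sample or matrix.group_of_sample
    vsd = [s for s in matrix.sample_ids if groups[s] == "VSD"]
    nc = [s for s in matrix.sample_ids if groups[s] == "NC"]
    if len(vsd) < 2 or len(nc) < 2:
        raise ValueError("need >=2 samples per group for a differential test")

    A = matrix.values[vsd].to_numpy()
    B = matrix.values[nc].to_numpy()
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    log2fc = m1 - m2

    if paired:
        if len(vsd) != len(nc):
            raise ValueError("paired test requires equal group sizes")
        D = A - B
        n = D.shape[1]
        vd = D.var(axis=1, ddof=1)
        floored = vd < VARIANCE_FLOOR
        vd = np.maximum(vd, VARIANCE_FLOOR)
        t = D.mean(axis=1) / np.sqrt(vd / n)
        df = np.full_like(t, n - 1)
    else:
        v1 = A.var(axis=1, ddof=1)
        v2 = B.var(axis=1, ddof=1)
        floored = (v1 < VARIANCE_FLOOR) | (v2 < VARIANCE_FLOOR)
        v1 = np.maximum(v1, VARIANCE_FLOOR)
        v2 = np.maximum(v2, VARIANCE_FLOOR)
        t, df = _welch(m1, v1, len(vsd), m2, v2, len(nc))

    p = 2.0 * stats.t.sf(np.abs(t), df)
    return [
        DifferentialRecord(
            probe_id=pid,
            log2fc=float(log2fc[i]),
            fold_change=float(2.0 ** abs(log2fc[i])),
            p_value=float(p[i]),
            direction="up" if log2fc[i] > 0 else "down",
            variance_floored=bool(floored[i]),
        )
        for i, pid in enumerate(matrix.probe_ids)
    ]


def volcano_filter(
    records: Sequence[DifferentialRecord],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split probes into up/down lists at fold-change > fc and P < p.

    Both inequalities are strict, so a probe sitting exactly on either
    threshold is excluded.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    up = [r.probe_id for r in records
          if r.fold_change > fc_threshold and r.p_value < p_threshold and r.direction == "up"]
    down = [r.probe_id for r in records
            if r.fold_change > fc_threshold and r.p_value < p_threshold and r.direction == "down"]
    return up, down


def sample_dendrogram(matrix: ExpressionMatrix):
    """Average-linkage clustering of samples at distance 1 - Pearson r.

    Returns (linkage matrix in scipy format, ordered sample labels).
    """
    X = matrix.values.to_numpy()
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(
                f"sample {matrix.sample_ids[j]} has constant expression; correlation undefined"
            )
    corr = np.corrcoef(X.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.sample_ids[i] for i in order]


def write_differential_tsv(records: Sequence[DifferentialRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tlog2fc\tfold_change\tp_value\tdirection\n")
        for r in records:
            fh.write(f"{r.probe_id}\t{r.log2fc:.6g}\t{r.fold_change:.6g}\t{r.p_value:.6g}\t{r.direction}\n")


def read_differential_tsv(path: str) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialRecord(r.probe_id, r.log2fc, r.fold_change, r.p_value, r.direction)
        for r in df.itertuples()
    ]
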