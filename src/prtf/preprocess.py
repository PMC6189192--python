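"""Expression preprocessing: probe collapse, quantile normalization, centering.

The pipeline expects gene-level, per-gene mean-centered expression. Microarray
inputs arrive at probe level and are collapsed to one probe per gene (the most
variable by interquartile range). Multi-study cohorts are centered per batch so
that study-level offsets do not masquerade as biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix
from .errors import DataError

# Quantile convention used for the probe IQR: linear interpolation, the
# default of R's quantile() / numpy's "linear" method. Pinned so tests can
# rely on it.
IQR_METHOD = "linear"


def collapse_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Unannotated probes are dropped; for each gene the probe with the largest
    interquartile range across samples is kept. Ties are broken by input
    order (first probe wins).
    """
    annotated = [p for p in pm.values.index if p in pm.probe_to_gene]
    if not annotated:
        raise DataError("no annotated probes after filtering")
    vals = pm.values.loc[annotated]
    q75 = vals.quantile(0.75, axis=1, interpolation=IQR_METHOD)
    q25 = vals.quantile(0.25, axis=1, interpolation=IQR_METHOD)
    iqr = q75 - q25
    genes = pd.Series([pm.probe_to_gene[p] for p in annotated], index=annotated, name="gene")
    # stable sort keeps input order among equal-IQR probes; idxmax-like pick
    order = np.argsort(-iqr.to_numpy(), kind="stable")
    best: dict[str, str] = {}
    for probe in np.asarray(annotated)[order]:
        gene = genes[probe]
        best.setdefault(gene, probe)
    chosen = pd.Series(best)  # gene -> probe
    out = vals.loc[chosen.to_numpy()]
    out.index = chosen.index
    return ExpressionMatrix(out.sort_index(), centered=False)


def quantile_normalize(m: ExpressionMatrix, log2: bool = False) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Within-column ties receive the mean of the order-statistic means they
    span (the behaviour of the standard Bioconductor implementation with
    average-rank tie handling). Optionally log2-transform afterwards.
    """
    vals = m.values.to_numpy(dtype=float)
    if log2 and np.nanmin(vals) <= 0:
        raise DataError("non-positive values present; cannot log2 transform")
    n_genes, n_samples = vals.shape
    order_stats = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        # average rank over ties -> mean of the spanned order-statistic means
        sorter = np.argsort(col, kind="stable")
        ranks = np.empty(n_genes)
        ranks[sorter] = np.arange(n_genes)
        # group equal values: assign each the mean of order_stats at its tied span
        col_sorted = col[sorter]
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [n_genes]])
        normalized_sorted = np.empty(n_genes)
        for s, e in zip(starts, ends):
            normalized_sorted[s:e] = order_stats[s:e].mean()
        out[:, j] = normalized_sorted[ranks.astype(int)]
    if log2:
        out = np.log2(out)
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, centered=False, batch=m.batch)


def mean_center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean (within batch when a batch map is present)."""
    vals = m.values
    if m.batch is None:
        centered = vals.sub(vals.mean(axis=1), axis=0)
    else:
        centered = vals.copy()
        for _, samples in m.batch.groupby(m.batch).groups.items():
            cols = vals.columns.intersection(samples)
            block = vals[cols]
            centered[cols] = block.sub(block.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, centered=True, batch=m.batch)
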