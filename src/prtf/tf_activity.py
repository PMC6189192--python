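"""TF activity inference by least squares over a ternary regulatory design.

The model is G_ik = sum_j T_ij A_jk per sample: expression of each annotated
target gene is explained by the summed signed activities of its regulators,
where T encodes activation (+1), no regulation (0) or repression (-1). The
per-sample coefficient vector A_.k is the TF activity profile of sample k.
Significance comes from a pooled permutation null: shuffling each sample's
expression across genes, re-fitting, and pooling the resulting scores over
samples and permutations per TF.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import (
    ACTIVATION,
    REPRESSION,
    ActivityMatrix,
    ExpressionMatrix,
    RegulatoryNetwork,
    TernaryMatrix,
    TFNull,
)
from .errors import DataError, FitError, ParseError, UsageError

logger = logging.getLogger(__name__)

_MODE_MAP = {"activation": ACTIVATION, "repression": REPRESSION}


def parse_trrust(path) -> RegulatoryNetwork:
    """Parse a TRRUST-style TSV (TF, target, mode, reference).

    Unknown-mode rows are dropped; duplicate (tf, target) rows with the same
    mode collapse to one edge; pairs annotated with conflicting modes are
    excluded entirely with a warning.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            tf, target, mode = fields[0], fields[1], fields[2].strip().lower()
            if mode == "unknown":
                continue
            if mode not in _MODE_MAP:
                raise ParseError(f"{path}: line {lineno}: unrecognised mode {fields[2]!r}")
            records.append((tf, target, _MODE_MAP[mode]))
    if not records:
        raise DataError(f"{path}: no usable regulatory edges")
    df = pd.DataFrame(records, columns=["tf", "target", "mode"]).drop_duplicates()
    conflict = df.duplicated(["tf", "target"], keep=False)
    n_conflicts = int(df.loc[conflict, ["tf", "target"]].drop_duplicates().shape[0])
    if n_conflicts:
        logger.warning("%d TF-target pairs with conflicting modes excluded", n_conflicts)
    df = df.loc[~conflict].reset_index(drop=True)
    logger.info("parsed %d edges (%d conflicting pairs dropped)", len(df), n_conflicts)
    return RegulatoryNetwork(df, provenance=str(path))


def build_ternary_matrix(
    net: RegulatoryNetwork, expression_genes: set[str] | pd.Index
) -> TernaryMatrix:
    """Pivot the edge list into a target-genes x TFs ternary design.

    Targets absent from the expression universe are dropped; TFs left with no
    expressed target lose their column (and are reported in the log).
    """
    genes = set(expression_genes)
    edges = net.edges[net.edges["target"].isin(genes)]
    if edges.empty:
        raise DataError("no network targets present in the expression universe")
    mat = (
        edges.pivot_table(index="target", columns="tf", values="mode", fill_value=0)
        .astype(int)
        .sort_index()
    )
    dropped = sorted(set(net.edges["tf"]) - set(mat.columns))
    if dropped:
        logger.info("%d TFs dropped (no expressed targets): %s", len(dropped), dropped[:10])
    return TernaryMatrix(mat)


def _design(T: TernaryMatrix, intercept: bool) -> tuple[np.ndarray, list[str]]:
    X = T.values.to_numpy(dtype=float)
    names = list(T.values.columns)
    if intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
        names = ["(intercept)"] + names
    return X, names


def _identifiable_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal independent column subset via pivoted QR."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        raise FitError("design matrix has rank zero")
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    rank = int(np.count_nonzero(diag > tol))
    return np.sort(piv[:rank])


def infer_activities(
    G: ExpressionMatrix, T: TernaryMatrix, intercept: bool = True
) -> ActivityMatrix:
    """Per-sample least-squares TF activities.

    Each sample column is fit independently; the shared design allows one
    decomposition for all samples. Collinear (non-identifiable) TF columns
    are excluded via pivoted QR and their activities reported as NaN. The
    intercept, when fitted, is estimated but not reported as an activity.
    """
    common = T.values.index.intersection(G.genes)
    if len(common) == 0:
        raise DataError("expression shares no genes with the regulatory targets")
    Tsub = TernaryMatrix(T.values.loc[common])
    Gmat = G.values.loc[common].to_numpy(dtype=float)
    X, names = _design(Tsub, intercept)
    keep = _identifiable_columns(X)
    if len(keep) == 0:
        raise FitError("no identifiable TF coefficients")
    coef_kept, *_ = np.linalg.lstsq(X[:, keep], Gmat, rcond=None)
    coef = np.full((X.shape[1], Gmat.shape[1]), np.nan)
    coef[keep] = coef_kept
    dropped = [n for i, n in enumerate(names) if i not in set(keep) and n != "(intercept)"]
    if dropped:
        logger.warning("non-identifiable TF coefficients (reported NaN): %s", dropped[:10])
    values = pd.DataFrame(coef, index=names, columns=G.samples)
    if intercept:
        values = values.drop(index="(intercept)")
    return ActivityMatrix(values, dropped_tfs=[(t, "non-identifiable") for t in dropped])


def filter_constant_tfs(A: ActivityMatrix, tol: float = 1e-12) -> ActivityMatrix:
    """Drop TFs whose activity is constant (or entirely missing) across samples."""
    dropped = list(A.dropped_tfs)
    keep = []
    for tf, row in A.values.iterrows():
        if row.isna().all():
            if (tf, "non-identifiable") not in dropped:
                dropped.append((tf, "non-identifiable"))
        elif row.std(ddof=0) <= tol:
            dropped.append((tf, "zero standard deviation"))
        else:
            keep.append(tf)
    if not keep:
        raise DataError("all TFs dropped by the zero-variance filter")
    pv = A.pvalues.loc[keep] if A.pvalues is not None else None
    return ActivityMatrix(A.values.loc[keep], pvalues=pv, dropped_tfs=dropped)


def build_tf_null(
    G: ExpressionMatrix, T: TernaryMatrix, n_perm: int = 100, seed: int = 0
) -> TFNull:
    """Pooled permutation null of activity scores.

    For every sample, the expression vector is shuffled across genes n_perm
    times and activities re-inferred; per-TF scores are pooled over all
    samples and permutations into one reference vector (length
    n_perm x n_samples). Degenerate draws are kept: they are legitimate
    realisations of the null.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    common = T.values.index.intersection(G.genes)
    Tsub = TernaryMatrix(T.values.loc[common])
    Gmat = G.values.loc[common].to_numpy(dtype=float)
    X, names = _design(Tsub, intercept=True)
    keep = _identifiable_columns(X)
    solver = np.linalg.pinv(X[:, keep])  # r x n_genes; shared across samples
    rng = np.random.default_rng(seed)
    n_samples = Gmat.shape[1]
    out = np.full((len(names), n_perm * n_samples), np.nan)
    for k in range(n_samples):
        perms = rng.permuted(
            np.broadcast_to(Gmat[:, k], (n_perm, Gmat.shape[0])).copy(), axis=1
        )
        out[keep, k * n_perm : (k + 1) * n_perm] = solver @ perms.T
    scores = pd.DataFrame(np.sort(out, axis=1), index=names)
    if "(intercept)" in scores.index:
        scores = scores.drop(index="(intercept)")
    return TFNull(scores=scores, n_perm=n_perm, seed=seed)


def tf_pvalues_and_calls(
    A: ActivityMatrix,
    null: TFNull,
    alpha: float = 0.05,
    designated_tf: str | None = None,
) -> tuple[ActivityMatrix, pd.Series | None]:
    """Pooled-null empirical p-values per (TF, sample), and K+/K- calls.

    p = (1 + #{null >= observed}) / (1 + n_total), with n_total the pooled
    null size. A sample is K+ for the designated TF iff p < alpha (strict:
    p exactly at alpha is a negative call). NaN activities give NaN p-values
    and negative calls.
    """
    missing = A.tfs.difference(null.scores.index)
    if len(missing):
        raise UsageError(f"TFs missing from the null: {list(missing)[:5]}")
    pvals = pd.DataFrame(np.nan, index=A.tfs, columns=A.samples)
    for tf in A.tfs:
        ref = null.scores.loc[tf].to_numpy()
        ref = ref[~np.isnan(ref)]  # sorted ascending; NaN rows are non-identifiable
        if len(ref) == 0:
            continue
        obs = A.values.loc[tf].to_numpy(dtype=float)
        ok = ~np.isnan(obs)
        ge = len(ref) - np.searchsorted(ref, obs[ok], side="left")
        pvals.loc[tf, A.samples[ok]] = (1 + ge) / (1 + len(ref))
    result = ActivityMatrix(A.values, pvalues=pvals, dropped_tfs=list(A.dropped_tfs))
    calls = None
    if designated_tf is not None:
        if designated_tf not in pvals.index:
            raise UsageError(f"designated TF {designated_tf!r} not among retained TFs")
        p = pvals.loc[designated_tf]
        calls = (p < alpha).fillna(False)
        calls.name = "K_pos"
    return result, calls
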