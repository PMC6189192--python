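"""Correlation analyses, subtype-overlap tests and sustaining-TF discovery.

Genes and TF activities are related to the per-sample proliferation (P) and
remodelling (R) enrichment scores by Spearman correlation with permutation
p-values. A TF "sustains" a programme (P->P or R->R) when its activity
correlates with that programme's score AND its annotated targets are enriched
among the genes most correlated with the same score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import EnrichmentResult, GeneSet
from .errors import DataError, UsageError
from .scoring import build_null, running_enrichment, signature_pvalues
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_with_permutation_p",
    "correlation_tables",
    "subtype_overlap",
    "target_set_enrichment",
    "find_sustaining_tfs",
    "bh_adjust",
    "SustainingTFResult",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if p.size == 0 or not ok.any():
        return np.full_like(p, np.nan) if p.size else p
    if p[ok].min() <= 0 or p[ok].max() > 1:
        raise UsageError("p-values must lie in (0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _rank_center(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, axis=-1)
    r = r - r.mean(axis=-1, keepdims=True)
    return r


def spearman_with_permutation_p(
    x,
    y,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman correlation with a least-bias permutation p-value.

    S is the Pearson correlation of midranks. The p-value permutes one
    vector's sample assignment n_perm times; with +1 smoothing its floor is
    1/(n_perm + 1) (1e-5 at the default n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise DataError("need at least 3 paired observations")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rx = _rank_center(x)
    ry = _rank_center(y)
    nx, ny = np.linalg.norm(rx), np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        return float("nan"), float("nan")
    s_obs = float(rx @ ry / (nx * ny))
    rng = np.random.default_rng(seed)
    if alternative not in ("two-sided", "greater", "less"):
        raise UsageError(f"unknown alternative {alternative!r}")
    exceed = 0
    chunk = max(1, min(n_perm, 20_000_000 // max(len(ry), 1)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(ry, (c, len(ry))).copy(), axis=1)
        s_null = perms @ rx / (nx * ny)
        if alternative == "two-sided":
            exceed += np.count_nonzero(np.abs(s_null) >= abs(s_obs))
        elif alternative == "greater":
            exceed += np.count_nonzero(s_null >= s_obs)
        else:
            exceed += np.count_nonzero(s_null <= s_obs)
        done += c
    p = (1 + exceed) / (1 + n_perm)
    return s_obs, float(p)


def _table_for_matrix(
    M: pd.DataFrame,
    p_scores: pd.Series,
    r_scores: pd.Series,
    n_perm: int,
    seed: int,
    alternative: str,
) -> pd.DataFrame:
    """Row-wise Spearman of M (entities x samples) against P and R scores.

    One shared set of score-vector permutations serves every row, which is
    valid (rows are tested marginally) and orders of magnitude faster.
    """
    samples = M.columns
    rm = rankdata(M.to_numpy(dtype=float), axis=1, nan_policy="omit")
    rows_ok = ~np.isnan(M.to_numpy(dtype=float)).any(axis=1)
    rm = np.where(np.isnan(rm), 0.0, rm)
    rm = rm - rm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rm, axis=1)
    rows_ok &= norms > 0
    norms[~rows_ok] = 1.0

    out = {}
    rng = np.random.default_rng(seed)
    for tag, scores in (("P", p_scores), ("R", r_scores)):
        rs = _rank_center(scores.loc[samples].to_numpy(dtype=float))
        ns = np.linalg.norm(rs)
        s_obs = rm @ rs / (norms * ns)
        exceed = np.zeros(rm.shape[0], dtype=np.int64)
        chunk = max(1, min(n_perm, 50_000_000 // max(rm.shape[0], 1)))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            perms = rng.permuted(np.broadcast_to(rs, (c, len(rs))).copy(), axis=1)
            s_null = rm @ perms.T / (norms[:, None] * ns)
            if alternative == "two-sided":
                exceed += np.count_nonzero(np.abs(s_null) >= np.abs(s_obs)[:, None], axis=1)
            elif alternative == "greater":
                exceed += np.count_nonzero(s_null >= s_obs[:, None], axis=1)
            else:
                exceed += np.count_nonzero(s_null <= s_obs[:, None], axis=1)
            done += c
        p = (1 + exceed) / (1 + n_perm)
        s_obs[~rows_ok] = np.nan
        p = np.where(rows_ok, p, np.nan)
        out[f"S_with_{tag}"] = s_obs
        out[f"p_{tag}"] = p
    df = pd.DataFrame(out, index=M.index)
    df["q_P"] = bh_adjust(df["p_P"])
    df["q_R"] = bh_adjust(df["p_R"])
    return df


def correlation_tables(
    G_values: pd.DataFrame,
    A_values: pd.DataFrame,
    p_scores: pd.Series,
    r_scores: pd.Series,
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene and per-TF correlation records against the P and R scores.

    BH adjustment is applied within each table separately. Constant rows are
    reported with NaN statistics.
    """
    samples = G_values.columns
    for other in (A_values.columns, p_scores.index, r_scores.index):
        if not samples.isin(other).all():
            raise UsageError("gene, TF and score tables must share the sample universe")
    gene_table = _table_for_matrix(
        G_values, p_scores, r_scores, n_perm, derive_seed(seed, "gene-corr"), alternative
    )
    tf_table = _table_for_matrix(
        A_values[samples], p_scores, r_scores, n_perm, derive_seed(seed, "tf-corr"), alternative
    )
    return gene_table, tf_table


def subtype_overlap(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-tailed overlap enrichment between two categorical labelings.

    For each (category_a, category_b) pair the hypergeometric upper-tail
    probability of seeing the observed overlap or more. Returns the per-pair
    table and, per category_a, its best and second-best matching category_b.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise UsageError("labelings share no samples")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    if a.nunique() < 2 or b.nunique() < 2:
        raise DataError("each labeling needs >= 2 categories")
    N = len(common)
    rows = []
    for ca, idx_a in a.groupby(a).groups.items():
        if len(idx_a) == 0:
            logger.warning("empty category %r skipped", ca)
            continue
        for cb, idx_b in b.groupby(b).groups.items():
            if len(idx_b) == 0:
                logger.warning("empty category %r skipped", cb)
                continue
            k = len(set(idx_a) & set(idx_b))
            p = float(hypergeom.sf(k - 1, N, len(idx_a), len(idx_b)))
            rows.append({"category_a": ca, "category_b": cb, "overlap": k, "p": p})
    table = pd.DataFrame(rows)
    best_rows = []
    for ca, grp in table.groupby("category_a"):
        ranked = grp.sort_values(["p", "category_b"]).reset_index(drop=True)
        best_rows.append(
            {
                "category_a": ca,
                "best_match": ranked.loc[0, "category_b"],
                "best_p": ranked.loc[0, "p"],
                "second_match": ranked.loc[1, "category_b"] if len(ranked) > 1 else None,
                "second_p": ranked.loc[1, "p"] if len(ranked) > 1 else np.nan,
            }
        )
    return table, pd.DataFrame(best_rows)


def target_set_enrichment(
    gene_correlations: pd.Series,
    targets: GeneSet,
    n_perm: int = 100_000,
    seed: int = 0,
    null=None,
) -> EnrichmentResult:
    """Enrichment of a TF's targets among correlation-ranked genes.

    Genes are ranked by decreasing correlation value and the running-score
    machinery applied; the returned extrema are the enrichment statistics and
    their permutation p-values come from the (n, m) rank null.
    """
    vals = gene_correlations.dropna()
    present = targets.members & set(vals.index)
    if not present:
        raise DataError("no targets present in the correlation ranking")
    obs = running_enrichment(vals, targets)
    n, m = len(vals), len(present)
    if null is None or (null.n, null.m) != (n, m):
        null = build_null(n, m, n_perm, seed)
    return signature_pvalues(obs, null, sample_id=targets.name)


@dataclass
class SustainingTFResult:
    tf_id: str
    programme: str  # "P->P" or "R->R"
    tf_activity_correlation: float
    tf_activity_q: float
    target_set_enrichment: float
    target_set_q: float


def find_sustaining_tfs(
    tf_table: pd.DataFrame,
    enrichments_p: dict[str, EnrichmentResult],
    enrichments_r: dict[str, EnrichmentResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """TFs sustaining a programme: correlated activity AND enriched targets.

    A TF is labelled P->P when its activity-vs-P correlation is positive and
    BH-significant and its target set is positively and BH-significantly
    enriched against the gene-vs-P correlation ranking; R->R analogously.
    Both criteria are BH-adjusted across TFs within each programme.
    """
    results: list[SustainingTFResult] = []
    for programme, tag, enrichments in (
        ("P->P", "P", enrichments_p),
        ("R->R", "R", enrichments_r),
    ):
        tfs = [tf for tf in tf_table.index if tf in enrichments]
        if not tfs:
            continue
        sub = tf_table.loc[tfs]
        q_act = pd.Series(bh_adjust(sub[f"p_{tag}"]), index=tfs)
        q_enr = pd.Series(bh_adjust([enrichments[tf].p_plus for tf in tfs]), index=tfs)
        for tf in tfs:
            res = enrichments[tf]
            if (
                sub.loc[tf, f"S_with_{tag}"] > 0
                and q_act[tf] < alpha
                and res.e_plus > 0
                and q_enr[tf] < alpha
            ):
                results.append(
                    SustainingTFResult(
                        tf_id=tf,
                        programme=programme,
                        tf_activity_correlation=float(sub.loc[tf, f"S_with_{tag}"]),
                        tf_activity_q=float(q_act[tf]),
                        target_set_enrichment=float(res.e_plus),
                        target_set_q=float(q_enr[tf]),
                    )
                )
    if not results:
        return pd.DataFrame(
            columns=[
                "tf_id",
                "programme",
                "tf_activity_correlation",
                "tf_activity_q",
                "target_set_enrichment",
                "target_set_q",
            ]
        )
    return pd.DataFrame([vars(r) for r in results])
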