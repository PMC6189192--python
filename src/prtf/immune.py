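"""Immune-infiltration association for a TF activity score.

Deconvolved cell-type fractions (e.g. a CIBERSORT output table) are consumed
as input, never computed. The module correlates each cell type's fraction
with a per-sample activity score, compares fraction distributions between
K+ and K- samples (tail behaviour via Kolmogorov-Smirnov), and validates the
score on sorted immune-cell profiles via a one-tailed myeloid-vs-lymphoid
Welch t-test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust, spearman_with_permutation_p
from .containers import FractionTable
from .errors import DataError, UsageError
from .utils import derive_seed

logger = logging.getLogger(__name__)


def correlate_fractions_with_score(
    fractions: FractionTable,
    scores: pd.Series,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of every cell-type fraction with the score.

    Returns a per-cell-type table (S, p, q, lineage); BH adjustment is across
    cell types. Constant fraction columns are reported as missing.
    """
    common = fractions.values.index.intersection(scores.index)
    if len(common) == 0:
        raise UsageError("fractions and scores share no samples")
    sc = scores.loc[common].to_numpy(dtype=float)
    rows = []
    for i, cell_type in enumerate(fractions.values.columns):
        col = fractions.values.loc[common, cell_type].to_numpy(dtype=float)
        if np.all(col == col[0]):
            logger.warning("cell type %r has constant fraction; flagged missing", cell_type)
            s, p = np.nan, np.nan
        else:
            s, p = spearman_with_permutation_p(
                col, sc, n_perm=n_perm, seed=derive_seed(seed, f"fraction-{cell_type}")
            )
        rows.append(
            {
                "cell_type": cell_type,
                "S": s,
                "p": p,
                "lineage": fractions.lineage.get(cell_type, "other"),
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"] = bh_adjust(out["p"])
    return out


def ks_tail_test(values_group1, values_group2) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF1 - ECDF2| with the asymptotic p-value; used to compare a
    cell type's fraction distribution between K+ and K- samples (optionally
    within P strata).
    """
    a = np.asarray(values_group1, dtype=float)
    b = np.asarray(values_group2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UsageError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def lineage_score_test(scores: pd.Series, lineage_labels: pd.Series) -> tuple[float, float]:
    """One-tailed Welch t-test for myeloid > lymphoid activity scores.

    Validates an activity score on sorted immune-cell profiles: a myeloid
    master regulator should score higher in the myeloid compartment.
    Identical groups give t = 0, p = 0.5; a lymphoid excess gives p > 0.5.
    """
    common = scores.index.intersection(lineage_labels.index)
    lab = lineage_labels.loc[common].str.lower()
    myeloid = scores.loc[common][lab == "myeloid"].to_numpy(dtype=float)
    lymphoid = scores.loc[common][lab == "lymphoid"].to_numpy(dtype=float)
    if len(myeloid) < 2 or len(lymphoid) < 2:
        raise DataError("need >= 2 samples per lineage for a variance estimate")
    res = stats.ttest_ind(myeloid, lymphoid, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)
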