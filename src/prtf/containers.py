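"""In-memory containers for the analysis.

Everything tabular is a pandas object; the dataclasses here only add the
metadata and invariants that a bare DataFrame cannot carry (centering state,
batch maps, dropped-TF logs, permutation-null provenance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

ACTIVATION = 1
REPRESSION = -1


@dataclass
class ProbeMatrix:
    """Probe-level expression (probes x samples) with a probe->gene map.

    Probes absent from ``probe_to_gene`` are considered unannotated and are
    dropped at collapse time.
    """

    values: pd.DataFrame
    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate probe identifiers")
        if any(not g for g in self.probe_to_gene.values()):
            raise DataError("empty gene identifier in probe map")


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes x samples.

    ``batch`` maps sample id -> batch id; when present, mean-centering is
    applied within batch (multi-study cohorts are centered per study before
    being combined).
    """

    values: pd.DataFrame
    centered: bool = False
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample identifiers")
        if self.batch is not None:
            self.batch = pd.Series(self.batch)
            missing = self.values.columns.difference(self.batch.index)
            if len(missing):
                raise DataError(f"samples missing from batch map: {list(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 1:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PermutationNull:
    """Null distribution of the running-score extrema for a (n, m) geometry.

    The signature score depends only on the ranks of the member genes, so the
    null is a function of the universe size n and the set size m alone and can
    be shared across samples.
    """

    n: int
    m: int
    n_perm: int
    scores_minus: np.ndarray
    scores_plus: np.ndarray
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if len(self.scores_minus) != self.n_perm or len(self.scores_plus) != self.n_perm:
            raise ConfigError("null vectors must have length n_perm")


@dataclass
class EnrichmentResult:
    """Low/high-tail extrema of the running score with permutation p-values."""

    sample_id: str
    e_minus: float
    e_plus: float
    p_minus: float
    p_plus: float

    @property
    def tail(self) -> str:
        return "low" if self.p_minus < self.p_plus else "high"

    @property
    def e_reported(self) -> float:
        return self.e_minus if self.p_minus < self.p_plus else self.e_plus


@dataclass
class RegulatoryNetwork:
    """Signed TF->target edges; ``mode`` is +1 (Activation) or -1 (Repression)."""

    edges: pd.DataFrame  # columns: tf, target, mode
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"tf", "target", "mode"}
        if not required.issubset(self.edges.columns):
            raise DataError(f"edge table needs columns {sorted(required)}")
        if not set(self.edges["mode"]).issubset({ACTIVATION, REPRESSION}):
            raise DataError("edge modes must be +1 (activation) or -1 (repression)")
        if self.edges.duplicated(["tf", "target"]).any():
            raise DataError("duplicate (tf, target) pairs after resolution")

    @property
    def tfs(self) -> list[str]:
        return list(pd.unique(self.edges["tf"]))


@dataclass
class TernaryMatrix:
    """Target-genes x TFs design with entries in {-1, 0, +1}."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            raise DataError("ternary matrix entries must be in {-1, 0, +1}")
        if (arr != 0).sum(axis=0).min(initial=1) == 0:
            raise DataError("ternary matrix has an all-zero TF column")
        if arr.size and (arr != 0).sum(axis=1).min() == 0:
            raise DataError("ternary matrix has an all-zero target row")


@dataclass
class ActivityMatrix:
    """Inferred TF activities, TFs x samples.

    ``pvalues`` (same shape) are pooled-permutation empirical p-values; NaN
    activities mark non-identifiable coefficients. ``dropped_tfs`` records
    (tf, reason) pairs removed by filtering.
    """

    values: pd.DataFrame
    pvalues: pd.DataFrame | None = None
    dropped_tfs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def tfs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class TFNull:
    """Pooled permutation reference scores per TF.

    ``scores`` rows are sorted ascending; length n_perm * n_samples each.
    """

    scores: pd.DataFrame  # TFs x (n_perm * n_samples), sorted within row
    n_perm: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n_total = self.scores.shape[1]


@dataclass
class FractionTable:
    """Deconvolved immune-cell fractions (samples x cell types) plus lineage map."""

    values: pd.DataFrame
    lineage: pd.Series  # cell type -> {myeloid, lymphoid, other}

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if np.nanmin(arr, initial=0.0) < -1e-9 or np.nanmax(arr, initial=0.0) > 1 + 1e-9:
            raise DataError("fractions must lie in [0, 1]")
        sums = np.nansum(arr, axis=1)
        if (sums > 1 + 1e-6).any():
            raise DataError("per-sample fraction sums exceed 1")


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald tests from a proportional-hazards fit."""

    summary: pd.DataFrame  # index: covariate; columns: hazard_ratio, ci95_low, ci95_high, wald_p
    log_likelihood: float
    n: int
    n_events: int


@dataclass
class SyntheticCohort:
    """A generated cohort with its planted ground truth."""

    expression: ExpressionMatrix
    network: RegulatoryNetwork
    true_activities: ActivityMatrix
    true_labels: pd.DataFrame  # index: sample; columns P_pos, R_pos, K_pos (bool), pr_label
    clinical: pd.DataFrame
    fractions: FractionTable
    p_signature: GeneSet
    r_signature: GeneSet
    designated_tf: str
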