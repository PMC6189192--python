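"""End-to-end orchestration: preprocess -> score -> TF activity -> association
-> survival -> immune, from a config object pointing at plain-text inputs.

Every stage consumes a named seed stream derived from the master seed, so the
run is fully deterministic and any stage can be reproduced in isolation. All
outputs are TSV plus a YAML manifest recording the config and output list.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import association, immune, preprocess, scoring, survival, tf_activity
from . import io as pio
from .containers import GeneSet
from .errors import ConfigError, PRTFError
from .synthetic import SyntheticConfig, generate_cohort
from .utils import derive_seed

logger = logging.getLogger(__name__)

COX_COVARIATE_SETS = {
    "P_and_R": ["P_score", "R_score", "stage", "age", "gender"],
    "P_only": ["P_score", "stage", "age", "gender"],
    "R_only": ["R_score", "stage", "age", "gender"],
}


@dataclass
class PipelineConfig:
    """Inputs, permutation budgets and flags for a full run."""

    expression: str
    gene_sets: str  # GMT containing the P and R signatures
    regulatory: str
    clinical: str
    out_dir: str
    fractions: str | None = None
    lineage: str | None = None
    external_labels: str | None = None  # e.g. CMS assignments, one column
    p_signature: str = "proliferation"
    r_signature: str = "remodelling"
    designated_tf: str = "KLF4"
    n_perm_signature: int = 100_000
    n_perm_tf: int = 100
    n_perm_spearman: int = 100_000
    alpha: float = 0.05
    seed: int = 0
    intercept: bool = True
    sidedness: str = "two-sided"
    stratified_ks: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        for attr in ("n_perm_signature", "n_perm_tf", "n_perm_spearman"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be >= 1")

    def validate_paths(self) -> None:
        required = {
            "expression": self.expression,
            "gene_sets": self.gene_sets,
            "regulatory": self.regulatory,
            "clinical": self.clinical,
        }
        optional = {
            "fractions": self.fractions,
            "lineage": self.lineage,
            "external_labels": self.external_labels,
        }
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise ConfigError(f"missing input: {name} ({path})")


def _save(out_dir: Path, name: str, df: pd.DataFrame, index_label: str, outputs: list[str]):
    path = out_dir / name
    df.to_csv(path, sep="\t", index_label=index_label)
    outputs.append(name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns a summary dict (also written to the manifest). Any stage failure
    aborts with a stage-tagged error; partial outputs are kept alongside a
    FAILED marker naming the stage.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    summary: dict = {}
    stage = "setup"
    t0 = time.time()
    try:
        # ---------------- preprocess ----------------
        stage = "preprocess"
        expr = pio.read_expression(config.expression)
        if not expr.centered:
            expr = preprocess.mean_center_genes(expr)
        pio.write_expression(out_dir / "expression_centered.tsv", expr)
        outputs.append("expression_centered.tsv")

        gene_sets = pio.read_gmt(config.gene_sets)
        for name in (config.p_signature, config.r_signature):
            if name not in gene_sets:
                raise ConfigError(f"gene set {name!r} not found in {config.gene_sets}")
        p_set, r_set = gene_sets[config.p_signature], gene_sets[config.r_signature]

        # ---------------- signature scoring ----------------
        stage = "signature_scoring"
        p_scores = scoring.score_signature(
            expr.values, p_set, config.n_perm_signature, derive_seed(config.seed, "gsea-P")
        )
        r_scores = scoring.score_signature(
            expr.values, r_set, config.n_perm_signature, derive_seed(config.seed, "gsea-R")
        )
        _save(out_dir, "signature_scores_P.tsv", p_scores, "sample", outputs)
        _save(out_dir, "signature_scores_R.tsv", r_scores, "sample", outputs)
        pr = scoring.classify_samples(p_scores, r_scores, config.alpha)
        _save(out_dir, "pr_labels.tsv", pr, "sample", outputs)
        summary["n_P_pos"] = int(pr["P_pos"].sum())
        summary["n_R_pos"] = int(pr["R_pos"].sum())

        # ---------------- TF activity ----------------
        stage = "tf_activity"
        net = tf_activity.parse_trrust(config.regulatory)
        T = tf_activity.build_ternary_matrix(net, set(expr.genes))
        A = tf_activity.infer_activities(expr, T, intercept=config.intercept)
        A = tf_activity.filter_constant_tfs(A)
        null = tf_activity.build_tf_null(
            expr, T, n_perm=config.n_perm_tf, seed=derive_seed(config.seed, "tf-null")
        )
        designated = config.designated_tf
        if designated not in A.values.index:
            raise ConfigError(f"designated TF {designated!r} absent from retained TFs")
        A, k_calls = tf_activity.tf_pvalues_and_calls(
            A, null, alpha=config.alpha, designated_tf=designated
        )
        _save(out_dir, "tf_activities.tsv", A.values, "tf", outputs)
        _save(out_dir, "tf_pvalues.tsv", A.pvalues, "tf", outputs)
        _save(
            out_dir,
            "dropped_tfs.tsv",
            pd.DataFrame(A.dropped_tfs, columns=["tf", "reason"]),
            "row",
            outputs,
        )
        _save(out_dir, "k_calls.tsv", k_calls.to_frame(), "sample", outputs)
        summary["n_K_pos"] = int(k_calls.sum())

        # ---------------- association ----------------
        stage = "association"
        p_vec = p_scores["e_reported"]
        r_vec = r_scores["e_reported"]
        gene_table, tf_table = association.correlation_tables(
            expr.values,
            A.values,
            p_vec,
            r_vec,
            n_perm=config.n_perm_spearman,
            seed=derive_seed(config.seed, "correlations"),
            alternative=config.sidedness,
        )
        _save(out_dir, "gene_correlations.tsv", gene_table, "gene", outputs)
        _save(out_dir, "tf_correlations.tsv", tf_table, "tf", outputs)
        summary["frac_genes_signif_R_raw"] = float((gene_table["p_R"] < 0.05).mean())

        targets_by_tf = {
            tf: GeneSet(tf, frozenset(grp["target"]))
            for tf, grp in net.edges.groupby("tf")
            if tf in tf_table.index
        }
        enr_p, enr_r = {}, {}
        null_cache: dict = {}
        for tag, ranking, store in (
            ("P", gene_table["S_with_P"], enr_p),
            ("R", gene_table["S_with_R"], enr_r),
        ):
            for tf, targets in targets_by_tf.items():
                vals = ranking.dropna()
                m = len(targets.members & set(vals.index))
                if m == 0 or m >= len(vals):
                    continue
                key = (len(vals), m)
                if key not in null_cache:
                    null_cache[key] = scoring.build_null(
                        *key,
                        config.n_perm_signature,
                        derive_seed(config.seed, f"target-null-{key}"),
                    )
                store[tf] = association.target_set_enrichment(
                    vals, targets, null=null_cache[key]
                )
        sustaining = association.find_sustaining_tfs(tf_table, enr_p, enr_r, config.alpha)
        _save(out_dir, "sustaining_tfs.tsv", sustaining.set_index("tf_id"), "tf", outputs)
        summary["sustaining_P"] = sorted(
            sustaining.loc[sustaining["programme"] == "P->P", "tf_id"]
        )
        summary["sustaining_R"] = sorted(
            sustaining.loc[sustaining["programme"] == "R->R", "tf_id"]
        )

        overlap_labels = None
        if config.external_labels:
            overlap_labels = pio.read_labels(config.external_labels).iloc[:, 0]
            table, mapping = association.subtype_overlap(overlap_labels, pr["pr_label"])
            _save(out_dir, "subtype_overlap.tsv", table, "row", outputs)
            _save(out_dir, "subtype_overlap_best.tsv", mapping, "row", outputs)

        # ---------------- survival ----------------
        stage = "survival"
        clinical = pio.read_clinical(config.clinical)
        clinical = clinical.loc[clinical.index.intersection(pr.index)]
        strat = pd.DataFrame(index=clinical.index)
        strat["PR"] = pr.loc[clinical.index, "pr_label"]
        strat["PK"] = (
            pr.loc[clinical.index, "P_pos"].map({True: "P+", False: "P-"})
            + "/"
            + k_calls.loc[clinical.index].map({True: "K+", False: "K-"})
        )
        if overlap_labels is not None:
            strat["CMS"] = overlap_labels.reindex(clinical.index)

        logrank_rows, km_frames = [], []
        for scheme in strat.columns:
            labels = strat[scheme].dropna()
            for outcome, (tcol, ecol) in survival.OUTCOME_COLUMNS.items():
                if tcol not in clinical.columns:
                    continue
                sub = clinical.loc[labels.index, [tcol, ecol]].dropna()
                if labels.loc[sub.index].nunique() < 2:
                    continue
                chi2, df_, p = survival.logrank_test(
                    sub[tcol], sub[ecol], labels.loc[sub.index]
                )
                logrank_rows.append(
                    {"scheme": scheme, "outcome": outcome, "chi2": chi2, "df": df_, "p": p}
                )
                if outcome == "OS":
                    for grp, idx in labels.loc[sub.index].groupby(
                        labels.loc[sub.index]
                    ).groups.items():
                        km = survival.kaplan_meier(
                            sub.loc[idx, tcol], sub.loc[idx, ecol]
                        ).reset_index()
                        km.insert(0, "group", grp)
                        km.insert(0, "scheme", scheme)
                        km_frames.append(km)
        _save(out_dir, "survival_logrank.tsv", pd.DataFrame(logrank_rows), "row", outputs)
        _save(out_dir, "km_curves.tsv", pd.concat(km_frames, ignore_index=True), "row", outputs)
        summary["logrank_p"] = {
            f"{r['scheme']}_{r['outcome']}": float(r["p"]) for r in logrank_rows
        }

        cox_in = clinical.copy()
        cox_in["P_score"] = p_vec.reindex(cox_in.index)
        cox_in["R_score"] = r_vec.reindex(cox_in.index)
        cox_rows = []
        for model, covs in COX_COVARIATE_SETS.items():
            usable = [c for c in covs if c in cox_in.columns]
            for outcome, (tcol, ecol) in survival.OUTCOME_COLUMNS.items():
                if tcol not in cox_in.columns:
                    continue
                fit = survival.cox_fit(cox_in, usable, outcome=outcome)
                tab = fit.summary.reset_index(names="covariate")
                tab.insert(0, "outcome", outcome)
                tab.insert(0, "model", model)
                cox_rows.append(tab)
        _save(out_dir, "cox_models.tsv", pd.concat(cox_rows, ignore_index=True), "row", outputs)

        # ---------------- immune association ----------------
        stage = "immune_association"
        if config.fractions:
            fractions = pio.read_fractions(config.fractions, config.lineage)
            k_scores = A.values.loc[designated]
            frac_corr = immune.correlate_fractions_with_score(
                fractions,
                k_scores,
                n_perm=config.n_perm_spearman,
                seed=derive_seed(config.seed, "fractions"),
            )
            _save(out_dir, "fraction_correlations.tsv", frac_corr, "cell_type", outputs)
            summary["fraction_correlations"] = {
                ct: float(row["S"]) for ct, row in frac_corr.iterrows()
            }

            ks_rows = []
            shared = fractions.values.index.intersection(k_calls.index)
            strata = [("all", pd.Series(True, index=shared))]
            if config.stratified_ks:
                strata += [
                    ("P+", pr.loc[shared, "P_pos"]),
                    ("P-", ~pr.loc[shared, "P_pos"]),
                ]
            for ct in fractions.values.columns:
                for stratum, mask in strata:
                    idx = shared[mask.loc[shared].astype(bool)]
                    pos = idx[k_calls.loc[idx]]
                    neg = idx[~k_calls.loc[idx]]
                    if len(pos) == 0 or len(neg) == 0:
                        continue
                    d, p = immune.ks_tail_test(
                        fractions.values.loc[pos, ct], fractions.values.loc[neg, ct]
                    )
                    ks_rows.append(
                        {"cell_type": ct, "stratum": stratum, "D": d, "p": p}
                    )
            _save(out_dir, "ks_tests.tsv", pd.DataFrame(ks_rows), "row", outputs)

        # ---------------- manifest ----------------
        stage = "manifest"
        manifest = {
            "package": "prtf",
            "version": __version__,
            "config": asdict(config),
            "outputs": outputs,
            "summary": summary,
        }
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        logger.info("pipeline finished in %.1fs (%d outputs)", time.time() - t0, len(outputs))
        return summary
    except PRTFError:
        (out_dir / "FAILED").write_text(f"stage: {stage}\n")
        raise
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\n")
        raise PRTFError(f"stage {stage!r} failed: {exc}") from exc


def make_demo(
    seed: int,
    out_dir,
    cohort_config: SyntheticConfig | None = None,
    n_perm_signature: int = 1000,
    n_perm_tf: int = 50,
    n_perm_spearman: int = 1000,
) -> dict:
    """Generate a default synthetic cohort, run the full pipeline on it.

    Inputs are written under ``out_dir/inputs`` and results under
    ``out_dir/results``; a summary (subtype counts, sustaining TFs, log-rank
    p-values, fraction correlations) lands in ``out_dir/summary.yaml``.
    """
    out_dir = Path(out_dir)
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    cfg = cohort_config or SyntheticConfig(seed=seed)
    cohort = generate_cohort(cfg)

    pio.write_expression(inputs / "expression.tsv", cohort.expression)
    pio.write_gmt(inputs / "signatures.gmt", [cohort.p_signature, cohort.r_signature])
    pio.write_trrust(inputs / "regulatory.tsv", cohort.network)
    pio.write_clinical(inputs / "clinical.tsv", cohort.clinical)
    pio.write_fractions(
        inputs / "fractions.tsv", cohort.fractions, lineage_path=inputs / "lineage.tsv"
    )
    pio.write_labels(inputs / "true_labels.tsv", cohort.true_labels)

    pipe_cfg = PipelineConfig(
        expression=str(inputs / "expression.tsv"),
        gene_sets=str(inputs / "signatures.gmt"),
        regulatory=str(inputs / "regulatory.tsv"),
        clinical=str(inputs / "clinical.tsv"),
        fractions=str(inputs / "fractions.tsv"),
        lineage=str(inputs / "lineage.tsv"),
        out_dir=str(out_dir / "results"),
        p_signature=cohort.p_signature.name,
        r_signature=cohort.r_signature.name,
        designated_tf=cohort.designated_tf,
        n_perm_signature=n_perm_signature,
        n_perm_tf=n_perm_tf,
        n_perm_spearman=n_perm_spearman,
        seed=seed,
    )
    summary = run_pipeline(pipe_cfg)
    summary["designated_tf"] = cohort.designated_tf
    (out_dir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return summary
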