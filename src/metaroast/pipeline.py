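"""End-to-end orchestration: preprocess -> per-metabolite test -> pathway test
-> summaries, with a run manifest for reproducibility.

The per-metabolite result table covers uniquely identified metabolites; its
BH adjustment runs over exactly that set (m is recorded in the manifest and
log).  Pathway testing consumes z scores from the same moderated fit and a
prior frozen at the observed-data estimate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import shutil
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffstats import bh_adjust, differential_analysis
from .io_formats import (
    read_annotation,
    read_feature_matrix,
    read_gmt,
    read_sample_info,
    write_results,
)
from .pathways import (
    MIN_SET_SIZE,
    RotationConfig,
    build_pathway_sets,
    make_rotation_frames,
    roast_test,
)
from .preprocess import preprocess, write_provenance
from .summaries import cluster_heatmap, pca_scores, phenotype_stats, volcano_table

logger = logging.getLogger("metaroast")

# exit codes used by the CLI
EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_FORMAT = 3
EXIT_NUMERIC = 4


@dataclasses.dataclass
class RunConfig:
    matrix: Path
    metadata: Path
    annotation: Path
    gmt: Path
    output_dir: Path
    alpha: float = 0.05
    log_base: float = 2.0
    pseudocount: float = 0.0
    rotations: int = 9999
    seed: int = 0
    min_set_size: int = MIN_SET_SIZE
    alternative: str = "directional"
    shrink: bool = True
    full_columns: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for p in (self.matrix, self.metadata, self.annotation, self.gmt):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def run_all(cfg: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory.

    On any stage failure, partial outputs are removed and the error is
    re-raised with the failing stage in its message chain.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_all_inner(cfg, out)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run_all_inner(cfg: RunConfig, out: Path) -> Path:
    stage = "read"
    try:
        fm = read_feature_matrix(cfg.matrix)
        samples = read_sample_info(cfg.metadata)
        ann = read_annotation(cfg.annotation)
        db = read_gmt(cfg.gmt)
        logger.info(
            "read %d features x %d samples, %d annotations, %d pathways",
            len(fm.feature_ids), len(fm.sample_ids), len(ann.compounds), len(db.members),
        )

        stage = "preprocess"
        nm = preprocess(fm, log_base=cfg.log_base, pseudocount=cfg.pseudocount)
        logger.info("imputed %d missing cells", nm.n_imputed)
        write_provenance(nm, out / "provenance.tsv")

        stage = "diffstats"
        stats_all, prior, design = differential_analysis(
            nm, samples, shrink=cfg.shrink
        )
        if prior is not None:
            logger.info("prior: d0=%.4g s0_2=%.4g", prior.d0, prior.s0_2)

        # metabolite table: uniquely identified features, BH over that m
        unique = ann.unique_features
        unique_tested = [f for f in stats_all.index if f in unique]
        diff = stats_all.loc[unique_tested].copy()
        diff.insert(0, "compound", [unique[f] for f in unique_tested])
        diff["adjP"] = bh_adjust(diff["p"].to_numpy())
        diff = diff.rename(columns={"df_total": "df"})
        logger.info("BH over m=%d uniquely identified metabolites", len(diff))

        stage = "pathways"
        frames = make_rotation_frames(nm, samples)
        sets, discarded = build_pathway_sets(
            db, ann, set(stats_all.index), min_size=cfg.min_set_size
        )
        logger.info("testing %d pathway sets (%d discarded)", len(sets), discarded)
        rot_cfg = RotationConfig(
            n_rotations=cfg.rotations, seed=cfg.seed, alternative=cfg.alternative
        )
        pw = roast_test(frames, sets, prior, rot_cfg)

        stage = "summaries"
        pca_all = pca_scores(nm)
        pca_df = pca_all.scores.copy()
        pca_df.columns = [
            f"{c} ({pct:.1f}%)" for c, pct in zip(pca_df.columns, pca_all.explained_pct)
        ]
        pca_df.to_csv(out / "pca_scores.tsv", sep="\t")
        volcano = volcano_table(diff, alpha=cfg.alpha)
        volcano.to_csv(out / "volcano.tsv", sep="\t")
        sig = diff.index[diff["adjP"] < cfg.alpha]
        if len(sig) >= 2:
            order = cluster_heatmap(nm.values.loc[sig])
            pd.DataFrame({"row_order": order.row_order}).to_csv(
                out / "heatmap_rows.tsv", sep="\t", index=False
            )
            pd.DataFrame({"col_order": order.col_order}).to_csv(
                out / "heatmap_cols.tsv", sep="\t", index=False
            )
        if any(s.phenotype for s in samples):
            phenotype_stats(samples).to_csv(out / "phenotype_stats.tsv", sep="\t")

        stage = "write"
        write_results(
            diff.reset_index(names="feature_id"), pw, out, full=cfg.full_columns
        )
        summary = summarize_tables(diff, pw, alpha=cfg.alpha)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        manifest = {
            "package": "metaroast",
            "version": __version__,
            "seed": cfg.seed,
            "rotations": cfg.rotations,
            "alpha": cfg.alpha,
            "log_base": cfg.log_base,
            "min_set_size": cfg.min_set_size,
            "alternative": cfg.alternative,
            "shrink": cfg.shrink,
            "bh_m_metabolites": int(len(diff)),
            "prior_d0": None if prior is None else (None if math.isinf(prior.d0) else prior.d0),
            "prior_d0_infinite": bool(prior is not None and math.isinf(prior.d0)),
            "prior_s0_2": None if prior is None else prior.s0_2,
            "n_features": len(fm.feature_ids),
            "n_samples": len(fm.sample_ids),
            "design": {"n_wt": design.n1, "n_ko": design.n2},
            "inputs": {
                "matrix": str(cfg.matrix),
                "metadata": str(cfg.metadata),
                "annotation": str(cfg.annotation),
                "gmt": str(cfg.gmt),
            },
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out
    except Exception as err:
        if hasattr(err, "add_note"):
            err.add_note(f"pipeline stage: {stage}")
        logger.error("stage %s failed: %s", stage, err)
        raise


def summarize_tables(
    diff: pd.DataFrame,
    pathways: pd.DataFrame,
    alpha: float = 0.05,
    pathway_alpha: float | None = None,
) -> dict:
    """Headline counts: significant metabolites (adjP < alpha, strict) split
    by fold-change sign, and tested/significant pathways (adjP <= alpha)
    split by direction."""
    pathway_alpha = alpha if pathway_alpha is None else pathway_alpha
    out = {
        "n_metabolites": int(len(diff)),
        "n_significant": 0,
        "n_up": 0,
        "n_down": 0,
        "n_pathways_tested": int(len(pathways)),
        "n_pathways_significant": 0,
        "n_pathways_up": 0,
        "n_pathways_down": 0,
    }
    if len(diff):
        sig = diff[diff["adjP"] < alpha]
        out["n_significant"] = int(len(sig))
        out["n_up"] = int((sig["logFC"] > 0).sum())
        out["n_down"] = int((sig["logFC"] < 0).sum())
    if len(pathways):
        sig = pathways[pathways["adjP"] <= pathway_alpha]
        out["n_pathways_significant"] = int(len(sig))
        out["n_pathways_up"] = int((sig["direction"] == "Up").sum())
        out["n_pathways_down"] = int((sig["direction"] == "Down").sum())
    return out


def summarize_run(run_dir: str | Path, alpha: float = 0.05) -> dict:
    """Recompute the counts report from a completed run directory."""
    run_dir = Path(run_dir)
    diff_path = run_dir / "metabolites.tsv"
    pw_path = run_dir / "pathways.tsv"
    if not diff_path.exists() or not pw_path.exists():
        raise FileNotFoundError(f"incomplete run directory: {run_dir}")
    diff = pd.read_csv(diff_path, sep="\t")
    pw = pd.read_csv(pw_path, sep="\t")
    return summarize_tables(diff, pw, alpha=alpha)
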