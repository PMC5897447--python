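"""End-to-end orchestration: ingest, filter, select, summarize, compare.

The pipeline chains the package's modules into the standard workflow
for a longitudinal serum LFQ study:

``simulate``/``ingest`` -> identification and coverage filtering ->
per-protein 16-model GP selection -> Z-score / clustering summaries ->
cord-vs-follow-up rank comparison,

writing plain TSV reports plus a JSON run manifest that records seeds,
thresholds, library versions and the protein counts after every
filtering step. All stages are deterministic given the config, so a
rerun with the same config reproduces byte-identical outputs; stages
whose outputs already exist can be skipped with ``resume=True``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import yaml

from . import __version__
from .io import (
    DEFAULT_AGE_BINS,
    ExpressionMatrix,
    average_zscores_by_age,
    collapse_replicates,
    filter_identifications,
    filter_sample_coverage,
    per_child_zscore,
    read_protein_groups,
    read_sample_annotation,
)
from .ranks import cord_followup_correlation, intensity_ranks, rank_product_test
from .selection import (
    InsufficientDataError,
    SelectionThresholds,
    select_effects,
)
from .simulate import (
    EffectConfig,
    StudyDesign,
    design_matrix,
    simulate_dataset,
    simulate_design,
)

__all__ = ["PipelineConfig", "run_pipeline", "cluster_age_profiles"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, loadable from a YAML file.

    Input paths may be omitted when ``simulate`` is true, in which case
    the synthetic generator provides the dataset. Every random stage
    has an explicit seed derived from ``seed``.
    """

    # inputs
    simulate: bool = True
    protein_groups: str | None = None
    annotation: str | None = None
    replicate_map: str | None = None

    # synthetic-data settings
    n_proteins: int = 24
    class_mix: dict = field(default_factory=lambda: {
        "age": 0.4, "location": 0.1, "id": 0.2, "null": 0.3})
    missing_prob: float = 0.1
    cord_offset_sd: float = 1.0

    # filtering thresholds
    min_unique_peptides: int = 2
    min_run_fraction: float = 0.25
    min_sample_fraction: float = 0.5

    # selection
    delta: float = 0.05
    rho: float = 0.01
    restarts: int = 2

    # summaries
    age_bins: tuple = DEFAULT_AGE_BINS
    n_clusters: int = 6

    # cord comparison
    permutations: int = 10_000
    pfp_alpha: float = 0.05
    correlation_fdr: float = 0.1

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for key in ("protein_groups", "annotation"):
                path = getattr(self, key)
                if path is None:
                    raise ValueError(f"config requires {key} when not "
                                     "simulating")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{key} file not found: {path}")
        if not (0 < self.min_run_fraction <= 1):
            raise ValueError("min_run_fraction must lie in (0, 1]")
        if not (0 <= self.min_sample_fraction <= 1):
            raise ValueError("min_sample_fraction must lie in [0, 1]")
        if self.delta < 0 or not (0 <= self.rho <= 1):
            raise ValueError("selection thresholds out of range")


def cluster_age_profiles(avg_zscores: pd.DataFrame, k: int = 6) -> pd.Series:
    """Hierarchical clustering of average Z-score age profiles.

    Agglomerative clustering with Euclidean distance and Ward linkage,
    cut at ``k`` clusters; deterministic. Rows must be complete (the
    averaged profiles of retained proteins normally are).
    """
    if k > len(avg_zscores):
        raise ValueError(f"k={k} exceeds {len(avg_zscores)} proteins")
    if avg_zscores.isna().any().any():
        raise ValueError("average Z-score matrix must have no missing rows")
    Z = sch.linkage(avg_zscores.to_numpy(), method="ward",
                    metric="euclidean")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=avg_zscores.index, name="cluster")


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", **kw)


def _split_cord(matrix: ExpressionMatrix
                ) -> tuple[ExpressionMatrix, ExpressionMatrix | None]:
    ann = matrix.annotation
    if ann is None or "is_cord" not in ann.columns:
        return matrix, None
    cord_samples = ann.index[ann["is_cord"].astype(bool)]
    cord_cols = [c for c in matrix.values.columns if c in set(cord_samples)]
    fu_cols = [c for c in matrix.values.columns if c not in set(cord_samples)]
    fu = ExpressionMatrix(matrix.values[fu_cols], ann.loc[fu_cols])
    cord = (ExpressionMatrix(matrix.values[cord_cols], ann.loc[cord_cols])
            if cord_cols else None)
    return fu, cord


def run_pipeline(config: PipelineConfig, outdir,
                 stages: tuple[str, ...] = ("ingest", "select", "summarize",
                                            "cordcompare"),
                 resume: bool = False) -> dict:
    """Run the requested stages and return the manifest dictionary.

    Reports are written under ``outdir``; the manifest (also written as
    ``manifest.json``) records versions, seeds, thresholds and the
    protein counts along the filter chain. On a stage failure the
    outputs of completed stages are retained and the manifest records
    the failure point.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {"serumgp": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "seed": config.seed,
        "thresholds": {
            "min_unique_peptides": config.min_unique_peptides,
            "min_run_fraction": config.min_run_fraction,
            "min_sample_fraction": config.min_sample_fraction,
            "delta": config.delta, "rho": config.rho,
            "pfp_alpha": config.pfp_alpha,
            "correlation_fdr": config.correlation_fdr,
        },
        "counts": {},
        "stages": {},
    }

    def _done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        matrix = _stage_ingest(config, outdir, manifest, resume)
        _done("ingest", n_samples=len(matrix.samples))
        if "select" in stages:
            selection = _stage_select(config, outdir, matrix)
            _done("select", n_proteins=int(len(selection)))
        else:
            selection = None
        if "summarize" in stages:
            n = _stage_summarize(config, outdir, matrix, selection)
            _done("summarize", n_profiles=n)
        if "cordcompare" in stages:
            info = _stage_cordcompare(config, outdir, matrix)
            _done("cordcompare", **info)
    except Exception as exc:
        manifest["stages"]["failed"] = {"status": "error", "error": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise
    return manifest


def _stage_ingest(config: PipelineConfig, outdir: Path, manifest: dict,
                  resume: bool) -> ExpressionMatrix:
    matrix_path = outdir / "expression_matrix.tsv"
    ann_path = outdir / "sample_annotation.tsv"
    if resume and matrix_path.exists() and ann_path.exists():
        ann = pd.read_csv(ann_path, sep="\t").set_index("sample_id")
        matrix = ExpressionMatrix.from_tsv(matrix_path, annotation=ann)
        manifest["counts"]["after_coverage_filter"] = matrix.n_proteins
        return matrix

    if config.simulate:
        design = StudyDesign(missing_prob=config.missing_prob,
                             seed=config.seed)
        ann = simulate_design(design)
        effects = EffectConfig(cord_offset_sd=config.cord_offset_sd)
        matrix, truth = simulate_dataset(
            ann, config.class_mix, config.n_proteins,
            seed=config.seed, effects=effects,
            missing_prob=config.missing_prob)
        _write_tsv(truth, outdir / "truth_labels.tsv")
        manifest["counts"]["simulated"] = matrix.n_proteins
    else:
        table = read_protein_groups(config.protein_groups)
        manifest["counts"]["parsed"] = table.n_proteins
        table = filter_identifications(
            table, config.min_unique_peptides, config.min_run_fraction)
        manifest["counts"]["after_identification_filter"] = table.n_proteins
        ann = read_sample_annotation(config.annotation)
        if config.replicate_map:
            rmap = pd.read_csv(config.replicate_map, sep="\t")
            replicate_map = dict(zip(rmap["run_id"], rmap["sample_id"]))
        else:
            replicate_map = {r: r for r in table.runs}
        matrix = collapse_replicates(table, replicate_map, annotation=ann)

    fu, cord = _split_cord(matrix)
    fu = filter_sample_coverage(fu, config.min_sample_fraction)
    manifest["counts"]["after_coverage_filter"] = fu.n_proteins
    if cord is not None:
        keep = fu.values.index.union(cord.values.index)
        values = matrix.values.loc[
            matrix.values.index.isin(keep)]
        matrix = ExpressionMatrix(values, matrix.annotation)
    else:
        matrix = fu
    ann_out = matrix.annotation.reset_index()
    _write_tsv(ann_out, ann_path, index=False)
    matrix.to_tsv(matrix_path)
    return matrix


def _stage_select(config: PipelineConfig, outdir: Path,
                  matrix: ExpressionMatrix) -> pd.DataFrame:
    fu, _ = _split_cord(matrix)
    ann = fu.annotation.loc[fu.values.columns]
    X = design_matrix(ann).reset_index(drop=True)
    thresholds = SelectionThresholds(delta=config.delta, rho=config.rho,
                                     n_restarts=config.restarts)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        fu.n_proteins)
    rows = []
    for (pid, y), s in zip(fu.values.iterrows(), seeds):
        try:
            res = select_effects(X, y.to_numpy(float), thresholds,
                                 seed=int(s % 2**31))
        except InsufficientDataError as exc:
            log.info("select: %s skipped (%s)", pid, exc)
            rows.append({"protein_id": pid, "status": f"skipped: {exc}"})
            continue
        log.info("select: %s best=%s flags=%s", pid,
                 "+".join(sorted(res.best_model)) or "null",
                 sorted(res.flagged))
        row = {
            "protein_id": pid, "status": "ok",
            "best_model": "+".join(sorted(res.best_model)) or "null",
        }
        for _, m in res.scores.iterrows():
            row[f"loocv[{m['model']}]"] = m["loocv_mlpd"]
            row[f"scv[{m['model']}]"] = m["scv_mlpd"]
        for cov in ("age", "season", "gender", "location"):
            row[f"delta[{cov}]"] = res.delta_mlpd[cov]
            row[f"share[{cov}]"] = res.covariate_shares[cov]
            row[f"significant[{cov}]"] = bool(res.significant[cov])
        for comp, share in res.best_shares.items():
            row[f"best_share[{comp}]"] = share
        rows.append(row)
    report = pd.DataFrame(rows).set_index("protein_id")
    _write_tsv(report, outdir / "selection_report.tsv")
    return report


def _stage_summarize(config: PipelineConfig, outdir: Path,
                     matrix: ExpressionMatrix,
                     selection: pd.DataFrame | None) -> int:
    fu, _ = _split_cord(matrix)
    z = per_child_zscore(fu)
    avg = average_zscores_by_age(z, config.age_bins)
    avg = avg.drop(columns=["cord"], errors="ignore")
    _write_tsv(avg, outdir / "average_zscores_by_age.tsv",
               index_label="protein_id")
    complete = avg.dropna()
    if len(complete) >= max(config.n_clusters, 2):
        clusters = cluster_age_profiles(complete, config.n_clusters)
        _write_tsv(clusters.to_frame(), outdir / "age_profile_clusters.tsv",
                   index_label="protein_id")
    return int(len(complete))


def _stage_cordcompare(config: PipelineConfig, outdir: Path,
                       matrix: ExpressionMatrix) -> dict:
    fu, cord = _split_cord(matrix)
    if cord is None:
        return {"skipped": "no cord samples"}
    ann = fu.annotation.loc[fu.values.columns]
    # earliest follow-up visit per subject (the 3-month samples)
    first = ann.sort_values("age_months").groupby("subject_id").head(1)
    fu3 = fu.values[first.index]
    fu3.columns = first["subject_id"].to_numpy()
    cord_vals = cord.values.copy()
    cord_vals.columns = cord.annotation.loc[
        cord.values.columns, "subject_id"].to_numpy()

    ranks_cord = intensity_ranks(cord_vals)
    ranks_fu3 = intensity_ranks(fu3)
    medians = pd.DataFrame({
        "median_rank_cord": ranks_cord.median(axis=1),
        "median_rank_3m": ranks_fu3.median(axis=1),
    })
    _write_tsv(medians, outdir / "median_ranks.tsv",
               index_label="protein_id")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # negate so that larger = more abundant; "up" then means higher
        # relative expression in cord blood
        rp = rank_product_test(-ranks_cord, -ranks_fu3,
                               B=config.permutations,
                               seed=config.seed, alpha=config.pfp_alpha)
    _write_tsv(rp.table, outdir / "rank_product.tsv",
               index_label="protein_id")

    by_tp: dict = {}
    for age_bin in config.age_bins:
        cols = ann.index[(ann["age_months"] - age_bin).abs() <= 1.5]
        if len(cols) == 0:
            continue
        sub = fu.values[cols]
        sub.columns = ann.loc[cols, "subject_id"].to_numpy()
        by_tp[f"{age_bin:g}m"] = sub
    corr = cord_followup_correlation(cord_vals, by_tp,
                                     fdr=config.correlation_fdr)
    _write_tsv(corr.table, outdir / "cord_correlations.tsv", index=False)
    return {
        "n_pairs": rp.n_pairs,
        "n_rank_product_significant": int(rp.table["significant"].sum()),
        "n_correlation_significant": int(corr.table["significant"].sum()),
    }
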