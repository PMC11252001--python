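"""End-to-end orchestration of the statistical pipeline for one sample type.

Stage order (fixed): sparsity filter -> zero replacement -> ALR reference
selection -> ALR transform -> Procrustes isometry check -> autoscaling ->
iterative VIP-pruned PLS-DA -> observed/permuted confusion matrices ->
Bayesian posterior summaries on the selected genera -> alpha diversity +
Bray-Curtis/NMDS/PERMANOVA -> optional taxon-to-function profile. All
outputs are TSV/JSON under ``output_dir`` plus a JSON run manifest that
fully determines the run; re-running with the same config and seed
reproduces every report file byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, ecology, functions, io, plsda, preprocess

logger = logging.getLogger("farmbiome.pipeline")


@dataclass
class PipelineConfig:
    """Everything a run needs; the seed is mandatory by position.

    ``scale_profile`` switches between desk-scale defaults and the
    full-size analysis profile (cross-validation repeated 100 times for
    component choice either way; confusion matrices 500 vs 10,000
    repetitions; MCMC 4 x 5,000 vs 4 x 50,000 iterations; PERMANOVA
    999 vs 9,999 permutations).
    """

    counts_path: str
    metadata_path: str
    output_dir: str
    seed: int
    function_map_path: str | None = None
    zero_mode: str = "pseudocount_one"
    filter_threshold: float = 0.25
    folds: int = 4
    reps_cv: int = 100
    reps_confusion: int | None = None
    vip_threshold: float = 1.0
    mcmc: bayes.McmcConfig | None = None
    permanova_permutations: int | None = None
    nmds_restarts: int = 20
    scale_profile: str = "desk"

    def __post_init__(self) -> None:
        if self.scale_profile not in ("desk", "full"):
            raise ValueError("scale_profile must be 'desk' or 'full'")
        full = self.scale_profile == "full"
        if self.reps_confusion is None:
            self.reps_confusion = 10_000 if full else 500
        if self.permanova_permutations is None:
            self.permanova_permutations = 9_999 if full else 999
        if self.mcmc is None:
            self.mcmc = (
                bayes.McmcConfig.full_scale(seed=self.seed)
                if full
                else bayes.McmcConfig(seed=self.seed)
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mcmc_raw = raw.pop("mcmc", None)
        cfg = cls(**raw)
        if mcmc_raw:
            cfg.mcmc = bayes.McmcConfig(**{**mcmc_raw, "seed": cfg.seed})
        return cfg

    def to_jsonable(self) -> dict:
        out = asdict(self)
        return out


@dataclass
class PipelineResult:
    """In-memory handles to the main per-stage outputs of one run."""

    reference_genus: str
    procrustes_correlation: float
    n_retained_genera: int
    selection: plsda.SelectionTrace
    confusion_observed: plsda.ConfusionSummary
    confusion_permuted: plsda.ConfusionSummary
    bayes_table: pd.DataFrame
    alpha_table: pd.DataFrame
    alpha_tests: pd.DataFrame
    permanova_f: float
    permanova_p: float
    nmds_stress: float
    function_table: pd.DataFrame | None
    manifest: dict
    output_files: dict[str, Path] = field(default_factory=dict)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for one sample type and write the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    t0 = time.perf_counter()

    counts = io.read_counts(config.counts_path)
    metadata = io.read_metadata(config.metadata_path)
    io.cross_check(counts, metadata)
    status = metadata.set_index("sample_id")["status"].loc[counts.index]
    t0 = _stage("read", t0)

    filtered = preprocess.filter_sparse_genera(
        counts, metadata, config.filter_threshold
    )
    replaced = preprocess.replace_zeros(filtered, config.zero_mode)
    reference = preprocess.select_alr_reference(replaced)
    alr = preprocess.alr_transform(replaced, reference)
    pro_corr = preprocess.procrustes_isometry_check(alr, replaced)
    scaled, scaling = preprocess.autoscale(alr)
    files["filtered_counts"] = io.write_table(filtered, out_dir / "filtered_counts.tsv")
    files["alr"] = io.write_table(alr.values, out_dir / "alr.tsv")
    files["scaled_alr"] = io.write_table(scaled, out_dir / "scaled_alr.tsv")
    sidecar = {
        "reference_genus": reference,
        "procrustes_correlation": pro_corr,
        "filter_threshold": config.filter_threshold,
        "zero_mode": config.zero_mode,
        "scaling_means": {k: float(v) for k, v in scaling.means.items()},
        "scaling_sds": {k: float(v) for k, v in scaling.sds.items()},
    }
    files["preprocess_json"] = out_dir / "preprocess.json"
    files["preprocess_json"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    t0 = _stage("preprocess", t0)

    trace = plsda.iterative_vip_selection(
        scaled,
        status.to_numpy(),
        folds=config.folds,
        repetitions=config.reps_cv,
        vip_threshold=config.vip_threshold,
        seed=config.seed,
    )
    files["selection_json"] = out_dir / "selection_trace.json"
    files["selection_json"].write_text(
        json.dumps(trace.to_jsonable(), indent=2, sort_keys=True)
    )
    vip = plsda.vip_scores(trace.final_model)
    selection_table = pd.DataFrame(
        {
            "genus": list(scaled.columns),
            "selected": [g in set(trace.final_selected) for g in scaled.columns],
            "vip_final": [
                float(vip[g]) if g in vip.index else float("nan")
                for g in scaled.columns
            ],
        }
    )
    files["selection_table"] = io.write_table(
        selection_table, out_dir / "selection_table.tsv", index=False
    )
    t0 = _stage("plsda_selection", t0)

    observed, permuted = plsda.confusion_matrices(
        scaled[trace.final_selected],
        status.to_numpy(),
        n_components=trace.final_model.n_components,
        folds=config.folds,
        repetitions=config.reps_confusion,
        seed=config.seed + 1,
    )
    conf = pd.concat(
        {
            "observed": observed.matrix,
            "permuted": permuted.matrix,
        },
        names=["variant", "true_class"],
    )
    files["confusion"] = io.write_table(conf, out_dir / "confusion_matrices.tsv")
    t0 = _stage("confusion", t0)

    bayes_table = bayes.summarise_all(
        scaled[trace.final_selected], status.to_numpy(), config.mcmc
    )
    files["bayes"] = io.write_table(bayes_table, out_dir / "bayes_summaries.tsv", index=False)
    t0 = _stage("bayes", t0)

    rel = replaced.div(replaced.sum(axis=1), axis=0)
    alpha_table, alpha_tests = ecology.diversity_report(rel, metadata)
    bc = ecology.bray_curtis(rel)
    ord_result = ecology.nmds(
        bc, restarts=config.nmds_restarts, seed=config.seed + 2
    )
    f_stat, p_value = ecology.permanova_on_axes(
        ord_result.coordinates,
        status.to_numpy(),
        n_permutations=config.permanova_permutations,
        seed=config.seed + 3,
    )
    files["alpha"] = io.write_table(alpha_table, out_dir / "alpha_diversity.tsv")
    files["alpha_tests"] = io.write_table(
        alpha_tests, out_dir / "alpha_tests.tsv", index=False
    )
    files["bray_curtis"] = io.write_table(bc, out_dir / "bray_curtis.tsv")
    files["nmds"] = io.write_table(ord_result.coordinates, out_dir / "nmds_coords.tsv")
    beta_summary = pd.DataFrame(
        [
            {
                "pseudo_F": f_stat,
                "p_value": p_value,
                "n_permutations": config.permanova_permutations,
                "nmds_stress": ord_result.stress,
            }
        ]
    )
    files["permanova"] = io.write_table(
        beta_summary, out_dir / "permanova.tsv", index=False
    )
    t0 = _stage("ecology", t0)

    function_table = None
    if config.function_map_path:
        fmap = functions.load_function_map(config.function_map_path)
        function_table = functions.function_profile(filtered, metadata, fmap)
        files["functions"] = io.write_table(
            function_table, out_dir / "function_profile.tsv", index=False
        )
        t0 = _stage("functions", t0)

    manifest = {
        "config": config.to_jsonable(),
        "reference_genus": reference,
        "procrustes_correlation": pro_corr,
        "n_genera_input": int(counts.shape[1]),
        "n_genera_retained": int(filtered.shape[1]),
        "n_columns_into_plsda": int(scaled.shape[1]),
        "n_selected": len(trace.final_selected),
        "final_ber": trace.final_ber,
        "final_n_components": int(trace.final_model.n_components),
        "permanova_p": p_value,
        "nmds_stress": ord_result.stress,
        "n_relevant_genera": int((bayes_table["relevant"] == "*").sum()),
    }
    files["manifest"] = out_dir / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        reference_genus=reference,
        procrustes_correlation=pro_corr,
        n_retained_genera=int(filtered.shape[1]),
        selection=trace,
        confusion_observed=observed,
        confusion_permuted=permuted,
        bayes_table=bayes_table,
        alpha_table=alpha_table,
        alpha_tests=alpha_tests,
        permanova_f=f_stat,
        permanova_p=p_value,
        nmds_stress=ord_result.stress,
        function_table=function_table,
        manifest=manifest,
        output_files=files,
    )
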