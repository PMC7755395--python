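"""Pipeline orchestration: configuration, per-stage seeding, the synthetic
end-to-end benchmark, and input validation.

The benchmark runner composes the stages in analysis order — simulate ->
PSD -> spectral fit -> electrode projection -> surrogate nulls -> spatial
correlation -> PLS gene selection -> enrichment, with the working-memory
and aging tracks alongside — entirely on synthetic data with known ground
truth, and writes every artifact with provenance (stage, config hash,
seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from . import synthetic as syn
from .projection import aggregate_to_parcels, combine_subjects, coverage_report, project_subject
from .spatial import inverse_distance_weights, msr_nulls, sa_corrected_correlation
from .spectra import compute_psd_median_welch
from .specparam import fit_spectral_model
from .transcriptomics import go_enrichment, null_pls_gene_selection
from .cohort import (
    aging_age_correlation,
    aging_subject_means,
    wm_behavior_correlation,
    wm_cohort_features,
    wm_region_stats,
)

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

# fixed stage order; per-stage seeds derive from (global seed, stage index)
STAGES = (
    "simulate", "spectra", "fit", "geometry", "projection",
    "nulls", "correlation", "expression", "pls", "goea", "wm", "aging",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((int(global_seed), idx)).generate_state(1)[0]
               % (2**31))


@dataclass
class RunConfig:
    """Benchmark configuration (flat key-value text with dotted sections)."""

    seed: int = 0
    out_dir: str = "run"
    log_level: str = "INFO"
    # simulate / fit
    sim_n_signals: int = 8
    sim_duration_s: float = 30.0
    sim_fs: float = 1000.0
    sim_tau_min_s: float = 0.005
    sim_tau_max_s: float = 0.1
    # geometry / projection
    geom_n_parcels: int = 120
    geom_points_per_parcel: int = 4
    map_length_scale_mm: float = 20.0
    proj_n_subjects: int = 30
    proj_electrodes_per_subject: int = 20
    proj_value_noise_std: float = 0.1
    # nulls / correlation
    n_null: int = 200
    # transcriptomics
    expr_n_genes: int = 300
    expr_n_associated: int = 30
    expr_effect_size: float = 1.0
    expr_noise_sd: float = 0.5
    # working memory
    wm_n_subjects: int = 6
    wm_n_trials: int = 8
    wm_delay_expansion: float = 1.2
    # aging
    aging_n_subjects: int = 60
    aging_compression_per_year: float = 0.005

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse ``section.key = value`` lines; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip().replace(".", "_")
            val = val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = known[key]
            cast = {"int": int, "float": float, "str": str}[
                typ if isinstance(typ, str) else typ.__name__
            ]
            kwargs[key] = cast(val)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(out: Path, stage: str, cfg: RunConfig, seed: int) -> None:
    path = out / f"{stage}.provenance.json"
    path.write_text(json.dumps(
        {"stage": stage, "config_hash": cfg.config_hash(), "seed": seed}, indent=1))


def run_pipeline(config: RunConfig) -> Path:
    """Run the synthetic end-to-end benchmark; returns the run directory.

    Deterministic given ``config.seed``; a stage failure halts the run with
    the failing stage named while earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in sorted(config.__dict__.items()))
    )
    stage = "start"
    try:
        # -- timescale recovery track ---------------------------------
        stage = "simulate"
        seed = stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        taus = np.geomspace(config.sim_tau_min_s, config.sim_tau_max_s,
                            config.sim_n_signals)
        rows = []
        for i, tau in enumerate(taus):
            ts = syn.simulate_synaptic_current(syn.SimSignalConfig(
                fs=config.sim_fs, duration=config.sim_duration_s, tau_syn=tau,
                seed=seed + i))
            psd = compute_psd_median_welch(ts)
            res = fit_spectral_model(psd)
            rows.append({"id": f"sim{i:02d}", "tau_true_s": tau,
                         "fk_hz": res.knee_frequency, "tau_s": res.tau,
                         "exponent": res.aperiodic.exponent, "error": res.rmse,
                         "r2": res.r_squared, "n_peaks": len(res.peaks)})
        recovery = pd.DataFrame(rows)
        recovery.to_csv(out / "timescale_recovery.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        # -- spatial track --------------------------------------------
        stage = "geometry"
        seed = stage_seed(config.seed, stage)
        geom = syn.make_sphere_geometry(config.geom_n_parcels,
                                        config.geom_points_per_parcel, seed=seed)
        nio.write_geometry(geom, out / "points.tsv", out / "distances.tsv")
        true_map = syn.generate_sa_map(geom, config.map_length_scale_mm, seed=seed + 1)
        nio.write_parcel_map(true_map, out / "true_map.tsv")
        _provenance(out, stage, config, seed)

        stage = "projection"
        seed = stage_seed(config.seed, stage)
        electrodes = syn.generate_electrode_dataset(
            geom, true_map, config.proj_n_subjects,
            config.proj_electrodes_per_subject,
            config.proj_value_noise_std * float(np.std(true_map.values)), seed=seed)
        nio.write_electrodes(electrodes, out / "electrodes.tsv")
        subject_maps = []
        for es in electrodes:
            pv, pc = project_subject(es, geom)
            subject_maps.append(aggregate_to_parcels(pv, pc, geom))
        group = combine_subjects(subject_maps)
        nio.write_parcel_map(group, out / "group_map.tsv")
        counts, bound = coverage_report(subject_maps)
        pd.DataFrame({"parcel_id": geom.parcel_ids, "n_subjects": counts}).to_csv(
            out / "coverage.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        stage = "nulls"
        seed = stage_seed(config.seed, stage)
        W = inverse_distance_weights(geom.parcel_distance)
        nulls = msr_nulls(true_map, W, n_null=config.n_null, seed=seed,
                          source_map_id="true_map")
        nio.write_null_ensemble(nulls, out / "nulls.tsv", out / "nulls.json")
        _provenance(out, stage, config, seed)

        stage = "correlation"
        seed = stage_seed(config.seed, stage)
        corr = sa_corrected_correlation(true_map, group, nulls)
        pd.DataFrame([{"map_x": "true_map", "map_y": "group_map",
                       "rho": corr.rho, "p_sa": corr.p_sa,
                       "n_null": corr.n_null, "n_parcels": corr.n_parcels}]).to_csv(
            out / "spatial_correlation.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        # -- transcriptomics track ------------------------------------
        stage = "expression"
        seed = stage_seed(config.seed, stage)
        expr, truth = syn.generate_expression_matrix(
            geom, true_map, config.expr_n_genes, config.expr_n_associated,
            config.expr_effect_size, config.expr_noise_sd, seed=seed)
        nio.write_expression(expr, out / "expression.tsv")
        _provenance(out, stage, config, seed)

        stage = "pls"
        seed = stage_seed(config.seed, stage)
        sel = null_pls_gene_selection(expr.normalize().X, true_map.values, nulls,
                                      gene_ids=expr.gene_ids)
        sel["planted"] = sel["gene_id"].isin(truth.associated_genes)
        sel.to_csv(out / "pls_genes.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        stage = "goea"
        seed = stage_seed(config.seed, stage)
        ann = syn.generate_toy_ontology(
            expr.gene_ids, seed=seed,
            extra_terms={"TOY:PLANTED": (set(truth.associated_genes),
                                         "planted gene set", "BP")})
        study = sel.loc[sel["significant"], "gene_id"].tolist()
        if study:
            enr = go_enrichment(study, expr.gene_ids, ann)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        # -- behavioral tracks ----------------------------------------
        stage = "wm"
        seed = stage_seed(config.seed, stage)
        records, accuracy, wm_truth = syn.generate_trial_dataset(
            n_subjects=config.wm_n_subjects, regions=("PC", "PFC"),
            n_trials=config.wm_n_trials,
            delay_expansion=config.wm_delay_expansion, seed=seed)
        features = wm_cohort_features(records, fit_kwargs={"max_peaks": 2})
        features.to_csv(out / "wm_features.tsv", sep="\t", index=False)
        stats_out = wm_region_stats(features)
        stats_out["delay_change"].to_csv(out / "wm_delay_change.tsv", sep="\t",
                                         index=False)
        stats_out["baseline_pairwise"].to_csv(out / "wm_baseline_pairwise.tsv",
                                              sep="\t", index=False)
        behav = wm_behavior_correlation(features, accuracy)
        behav.to_csv(out / "wm_behavior.tsv", sep="\t", index=False)
        _provenance(out, stage, config, seed)

        stage = "aging"
        seed = stage_seed(config.seed, stage)
        matrix, _ = syn.generate_aging_cohort(
            geom, n_subjects=config.aging_n_subjects,
            compression_per_year=config.aging_compression_per_year, seed=seed)
        means = aging_subject_means(matrix)
        means.to_csv(out / "aging_subject_means.tsv", sep="\t")
        age_corr = aging_age_correlation(means)
        pd.DataFrame([age_corr]).to_csv(out / "aging_age_correlation.tsv",
                                        sep="\t", index=False)
        _provenance(out, stage, config, seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def validate_inputs(paths: dict) -> list[str]:
    """Schema checks for the file dialects; returns a list of issues.

    ``paths`` maps kind -> path for any of: electrodes, points, distances,
    expression, map, epochs, annotation_pairs, annotation_meta. Issues are
    collected, not raised one at a time.
    """
    issues: list[str] = []

    def check(kind, fn, *args):
        try:
            fn(*args)
        except Exception as exc:
            issues.append(f"{kind}: {exc}")

    if "electrodes" in paths:
        check("electrodes", nio.read_electrodes, paths["electrodes"])
    if "points" in paths and "distances" in paths:
        check("geometry", nio.read_geometry, paths["points"], paths["distances"])
    if "expression" in paths:
        check("expression", nio.read_expression, paths["expression"])
    if "map" in paths:
        check("map", nio.read_parcel_map, paths["map"])
    if "epochs" in paths:
        check("epochs", nio.read_epochs, paths["epochs"])
    if "annotation_pairs" in paths and "annotation_meta" in paths:
        check("annotation", nio.read_annotation,
              paths["annotation_pairs"], paths["annotation_meta"])
    return issues
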