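"""End-to-end orchestration of the two-platform fusion analysis.

Stage order is fixed: simulate (or load) -> NMR spectral processing -> MS
drift correction -> per-block z-scoring -> fusion -> OPLS with
cross-validated component selection -> response-permutation validation ->
VIP selection -> pathway analysis -> univariate screen / clinical
correlations. Every random stage draws its seed deterministically from the
run seed, so a repeated run is byte-identical. Every discard decision
(excluded spectral points, noise-thresholded variables, overlap-dropped
annotations, uncorrectable metabolites) is counted in the run log.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import ms as msmod
from . import nmr as nmrmod
from . import opls as oplsmod
from . import pathways as pwmod
from . import stats as statsmod
from . import synthetic as synmod
from .tables import FeatureTable, fuse_blocks, zscore

__all__ = ["RunConfig", "run_pipeline", "simulate_dataset", "default_effects"]


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    profile: Literal["mouse", "human"] = "mouse"
    seed: int = 0
    outdir: str = "runs/default"

    # synthetic design
    n_metabolites: int = 30
    n_per_arm: Optional[int] = None  # profile default: mouse 8, human 23
    n_affected: int = 6
    effect: float = 1.0
    sigma: float = 0.3

    # NMR rendering + processing
    grid_step_ppm: float = 0.0005
    jitter_ppm: float = 0.005
    spectrum_noise_sd: float = 0.01
    reference_ppm: float = 6.5
    search_window: tuple[float, float] = (6.3, 6.7)
    threshold_factor: float = 2.0
    discard_fraction: float = 0.5

    # MS rendering + correction
    drift_shape: str = "linear"
    drift_magnitude: float = -0.3
    qc_every: int = Field(default=5, ge=2)
    technical_cv: float = 0.10
    loess_span: float = 0.75
    loess_degree: int = 1

    # multivariate analysis
    folds: int = 7
    max_orth: int = 8
    n_perm: int = 100
    vip_threshold: float = 1.0
    alpha: float = 0.05
    n_pathways: int = 5
    annotation_tol_ppm: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def default_effects(
    library, factors, n_affected: int, effect: float
) -> synmod.EffectSpec:
    """Plant ``n_affected`` responders cycling over ``factors`` (a name or a
    list of names), with blocks cycling nmr_only / ms_only / both so both
    platforms carry complementary signal."""
    if isinstance(factors, str):
        factors = [factors]
    ids = [s.metabolite_id for s in library][:n_affected]
    cycle = ("nmr_only", "ms_only", "both")
    return synmod.EffectSpec(
        affected={m: (factors[i % len(factors)], effect) for i, m in enumerate(ids)},
        block_assignment={m: cycle[i % 3] for i, m in enumerate(ids)},
    )


def _seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["design", "spectra", "ms", "clinical", "permutation", "library", "pathways"]
    vals = ss.generate_state(len(names)) % (2**31 - 1)
    return {n: int(v) for n, v in zip(names, vals)}


def simulate_dataset(config: RunConfig):
    """Generate the full paired dataset for a config; returns a dict of parts."""
    sd = _seeds(config.seed)
    library = synmod.make_library(config.n_metabolites, sd["library"])
    if config.profile == "mouse":
        n = config.n_per_arm or 8
        design = synmod.mouse_design(n_per_arm=n, seed=sd["design"])
        factor = ["diet", "week"]
        responses = ["diet", "week"]
    else:
        n = config.n_per_arm or 23
        design = synmod.human_design(n_per_arm=n, seed=sd["design"])
        factor = "diabetes"
        responses = ["diabetes"]
    effects = default_effects(library, factor, config.n_affected, config.effect)
    truth = synmod.simulate_concentrations(design, library, effects, sigma=config.sigma)
    spectra = synmod.render_spectra(
        truth,
        library,
        grid_step_ppm=config.grid_step_ppm,
        jitter_ppm=config.jitter_ppm,
        noise_sd=config.spectrum_noise_sd,
        seed=sd["spectra"],
    )
    ms_table = synmod.render_ms_table(
        truth,
        drift=(config.drift_shape, config.drift_magnitude),
        qc_every=config.qc_every,
        seed=sd["ms"],
        technical_cv=config.technical_cv,
    )
    clinical = None
    if config.profile == "human":
        clinical = synmod.make_clinical_table(
            truth,
            seed=sd["clinical"],
            outcome_factor=factor,
            linked_metabolites=list(truth.affected)[:2],
        )
    return {
        "library": library,
        "design": design,
        "effects": effects,
        "truth": truth,
        "spectra": spectra,
        "ms_table": ms_table,
        "clinical": clinical,
        "responses": responses,
        "seeds": sd,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all outputs under ``config.outdir``.

    Returns the run directory. Any stage failure is re-raised wrapped with
    the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "discards": {}}
    t0 = time.time()

    def stage(name):
        log["stages"][name] = round(time.time() - t0, 3)

    try:
        data = simulate_dataset(config)
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage=simulate error={e}") from e
    stage("simulate")
    truth, spectra, ms_raw = data["truth"], data["spectra"], data["ms_table"]

    try:
        nmr_table, nmr_log = nmrmod.process_spectra(
            spectra,
            profile=config.profile,
            ref_ppm=config.reference_ppm,
            search_window=config.search_window,
            factor=config.threshold_factor,
            discard_fraction=config.discard_fraction,
        )
    except Exception as e:
        raise RuntimeError(f"stage=nmr_processing error={e}") from e
    nmr_table = nmr_table.with_metadata(truth.metadata)
    log["discards"]["nmr_excluded_points"] = nmr_log["excluded_points"]
    log["discards"]["nmr_thresholded_variables"] = nmr_log["n_variables_discarded"]
    log["nmr_variables"] = nmr_log["n_variables_retained"]
    stage("nmr_processing")

    try:
        ms_corr, ms_report = msmod.correct_table(
            ms_raw, span=config.loess_span, degree=config.loess_degree
        )
        ms_table = msmod.ms_feature_table(ms_corr, metadata=truth.metadata)
    except Exception as e:
        raise RuntimeError(f"stage=ms_processing error={e}") from e
    log["discards"]["ms_uncorrectable"] = int(ms_report["flagged"].sum())
    stage("ms_processing")

    try:
        nmr_z = zscore(nmr_table)
        ms_z = zscore(ms_table)
        fused = fuse_blocks(nmr_z, ms_z)
    except Exception as e:
        raise RuntimeError(f"stage=fusion error={e}") from e
    stage("fusion")

    responses = data["responses"]
    Y = truth.metadata[responses].to_numpy(dtype=float)
    X = fused.matrix()
    try:
        q2s, n_orth = oplsmod.cross_validate(X, Y, folds=config.folds, max_orth=config.max_orth)
        model = oplsmod.fit_opls(
            X, Y, n_orth, variable_ids=list(fused.data.columns), response_ids=responses
        )
        model.q2_cum = float(q2s[n_orth])
    except Exception as e:
        raise RuntimeError(f"stage=opls error={e}") from e
    stage("opls")

    try:
        perm = oplsmod.permutation_test(
            X,
            Y,
            n_orth,
            folds=config.folds,
            n_perm=config.n_perm,
            seed=data["seeds"]["permutation"],
            response_ids=responses,
        )
    except Exception as e:
        raise RuntimeError(f"stage=permutation error={e}") from e
    stage("permutation")

    try:
        nmr_positions = [float(c.split("_", 1)[1]) for c in fused.data.columns if c.startswith("nmr_")]
        annotation = synmod.annotate_peaks(
            nmr_positions, data["library"], tol_ppm=config.annotation_tol_ppm, truth=truth
        )
        annotation.update(
            {c: [c.split("_", 1)[1]] for c in fused.data.columns if c.startswith("ms_")}
        )
        library = pwmod.make_toy_library(
            list(truth.concentrations.columns), config.n_pathways, seed=data["seeds"]["pathways"]
        )
        pw_res, pw_status = pwmod.run_pathway_analysis(
            model, annotation, library, threshold=config.vip_threshold, alpha=config.alpha
        )
        selected = pwmod.select_variables(model, config.vip_threshold)
        n_overlap_dropped = sum(
            1 for v in selected if len(annotation.get(v, [])) > 1
        )
    except Exception as e:
        raise RuntimeError(f"stage=pathways error={e}") from e
    log["discards"]["overlap_dropped_annotations"] = n_overlap_dropped
    log["pathway_status"] = pw_status
    stage("pathways")

    try:
        if config.profile == "mouse":
            meta = fused.metadata
            tabs = {
                wk: (
                    fused.data.loc[meta["week"] == wk],
                    meta.loc[meta["week"] == wk, "arm"],
                )
                for wk in sorted(meta["week"].unique())
            }
            screen = statsmod.select_mouse_variables(tabs, alpha=config.alpha)
            screen_df = pd.DataFrame({"variable": screen})
            corr_df = None
        else:
            selected_vars = pwmod.select_variables(model, config.vip_threshold)
            sub = fused.data[selected_vars] if selected_vars else fused.data
            corr = statsmod.correlation_matrix(sub, data["clinical"])
            corr_df = corr.table
            screen_df = None
    except Exception as e:
        raise RuntimeError(f"stage=univariate error={e}") from e
    stage("univariate")

    # ---- outputs ----
    nmr_table.to_csv(outdir / "nmr_features.csv")
    ms_corr.to_csv(outdir / "ms_corrected.csv", index=False)
    ms_report.to_csv(outdir / "ms_correction_report.csv")
    fused.to_csv(outdir / "fused_features.csv")
    model.to_json(outdir / "opls_model.json")
    model.vip_series().to_csv(outdir / "vip.csv", header=True)
    scores = pd.DataFrame(
        np.hstack([model.T, model.T_o]),
        index=fused.data.index,
        columns=[f"t{a + 1}" for a in range(model.n_pred)]
        + [f"to{a + 1}" for a in range(model.n_orth)],
    )
    scores.join(truth.metadata).to_csv(outdir / "scores.csv")
    perm.records.to_csv(outdir / "permutation.csv", index=False)
    pw_res.to_csv(outdir / "pathway_results.csv", index=False)
    if config.profile == "mouse":
        screen_df.to_csv(outdir / "selected_variables.csv", index=False)
    else:
        corr_df.to_csv(outdir / "correlations.csv", index=False)
    config.to_yaml(outdir / "config_resolved.yaml")
    log["summary"] = {
        "r2y_cum": model.r2y_cum,
        "q2_cum": model.q2_cum,
        "n_orth": model.n_orth,
        "n_pred": model.n_pred,
        "n_vip_selected": int((model.vip > config.vip_threshold).sum()),
        "q2_intercepts": perm.q2_intercept,
        "r2_intercepts": perm.r2_intercept,
    }
    stage("total")
    with open(outdir / "log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return outdir
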