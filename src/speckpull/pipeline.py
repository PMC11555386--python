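"""End-to-end pipeline driver.

Chains the assay stages — diffraction-limited counting, super-resolution
morphometrics, two-group threshold statistics and cohort biomarker search —
on configured inputs (real files or synthetic data), and emits one JSON
report plus per-stage CSVs.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .biomarker import auc, cohort_to_wide, composite_search, fold_change, \
    permutation_exact_test
from .config import PARAMETER_PROVENANCE, PipelineConfig
from .diststats import threshold_search
from .morphology import morphology_pipeline
from .simulate import GroundTruthAggregate, MorphologyPopulation, \
    simulate_cohort, simulate_localizations, simulate_morphologies, \
    simulate_tirf_stack
from .spotcount import FovCount, average_stack, control_assessment, \
    detect_spots, summarize_sample

__all__ = ["run_pipeline"]


def _package_version() -> str:
    try:
        return version("speckpull")
    except PackageNotFoundError:
        return "unknown"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sanitize(obj):
    """Strict-JSON form: non-finite floats become None."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _spot_grid(n: int, fov_px: tuple[int, int], margin: int = 20,
               brightness: float = 400.0):
    """Well-separated bright spots on a regular grid inside the FOV."""
    per_row = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(margin, fov_px[0] - margin, per_row)
    ys = np.linspace(margin, fov_px[1] - margin, per_row)
    spots = []
    for i in range(n):
        spots.append(((float(xs[i % per_row]), float(ys[i // per_row])),
                      brightness))
    return spots


def _stage_counting(config: PipelineConfig, rng: np.random.Generator) -> dict:
    if config.stack_path is not None:
        stack = spio.read_stack(config.stack_path)
        truth_n = None
    else:
        spots = _spot_grid(config.tirf_n_spots, config.acquisition.fov_px)
        stack, truth = simulate_tirf_stack(
            spots, config.acquisition, config.tirf_background,
            rng, n_frames=config.tirf_n_frames)
        truth_n = len(truth)
    fov = detect_spots(average_stack(stack), config.detection, "fov0")
    # background-only control well (the no-capture control)
    control_stack, _ = simulate_tirf_stack(
        [], config.acquisition, config.tirf_background, rng,
        n_frames=config.tirf_n_frames)
    control_fov = detect_spots(average_stack(control_stack),
                               config.detection, "no_capture")
    summary = summarize_sample([fov])
    controls = control_assessment(summary["mean_count"],
                                  {"no_capture": float(control_fov.count)})
    result = {"summary": summary, "controls": controls}
    if truth_n is not None:
        result["true_spot_count"] = truth_n
    return result, fov


def _stage_morphology(config: PipelineConfig, rng: np.random.Generator):
    if config.locs_path is not None:
        table = spio.read_localizations(config.locs_path)
    else:
        # one synthetic FOV of aggregates drawn from the control morphology
        pop = MorphologyPopulation(
            small_round_weight=config.cohort.base_small_round_weight)
        n_agg = 30
        draws = simulate_morphologies(rng, n_agg, pop)
        w, h = config.acquisition.fov_nm
        margin = 1200.0
        truths = []
        for _, row in draws.iterrows():
            r_nm = 1000.0 * np.sqrt(row["area_um2"] / np.pi)
            # squash the ellipse to roughly match the drawn circularity
            ratio = max(row["circularity"], 0.05)
            a = r_nm / np.sqrt(ratio)
            b = r_nm * np.sqrt(ratio)
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            area_px = np.pi * a * b / config.acquisition.render_pixel_nm ** 2
            n_locs = max(30.0, 2.0 * area_px)
            truths.append(GroundTruthAggregate(
                center_nm=(cx, cy), semi_axes_nm=(a, b),
                theta_rad=rng.uniform(0, np.pi),
                n_fluorophores=max(4, int(n_locs / 7)),
                expected_localizations=n_locs))
        table, _ = simulate_localizations(truths, config.acquisition, rng)
    morph, meta = morphology_pipeline(
        table, config.acquisition,
        min_localizations=config.min_localizations,
        min_diameter_um=config.min_diameter_um)
    return {"meta": meta,
            "median_d_area_um": float(morph["d_area_um"].median())
            if len(morph) else None}, morph


def _stage_threshold(config: PipelineConfig,
                     morphologies: dict[str, pd.DataFrame],
                     groups: dict[str, str]) -> tuple[dict, pd.DataFrame]:
    result = threshold_search(
        morphologies, groups, alpha=config.alpha,
        n_permutations=config.n_permutations, seed=config.seed)
    report = {
        "area_max_um2": result.area_max,
        "circ_min": result.circ_min,
        "delta_fraction": result.delta_fraction,
        "p_value": result.p_value,
        "significant": result.significant,
        "multiple_testing_corrected": result.multiple_testing_corrected,
    }
    return report, result.fractions


def _stage_biomarker(config: PipelineConfig, cohort: pd.DataFrame,
                     fractions: pd.DataFrame | None):
    wide = cohort_to_wide(cohort)
    labels = wide["group"].to_numpy() == "disease"
    markers = [c for c in wide.columns if c not in ("subject", "group")]
    per_marker = {}
    for mk in markers:
        v = wide[mk].to_numpy(dtype=float)
        entry = {"auc": auc(v, labels),
                 "fold_change": fold_change(v[labels], v[~labels])}
        if mk == "ASC":
            entry["permutation_p"] = permutation_exact_test(
                v[labels], v[~labels], seed=config.seed)
        per_marker[mk] = entry
    extra = None
    if fractions is not None:
        extra = fractions.rename(columns={"fraction": "morph_fraction"})[
            ["subject", "morph_fraction"]]
    ranking = composite_search(cohort, extra_metrics=extra)
    top = ranking.head(10).to_dict(orient="records")
    return {"per_marker": per_marker, "top_composites": top}, ranking


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write a report bundle to ``config.outdir``.

    Stages: count -> morph -> stats -> biomarker.  A stage failure aborts
    with the stage named; outputs of completed stages are retained.
    Returns the report dict (also written as ``report.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    yaml_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    # hash the analysis parameters only — where the bundle is written must
    # not change what it contains
    hashed = config.to_dict()
    hashed.pop("outdir", None)
    param_hash = hashlib.sha256(
        yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest()[:16]

    report: dict = {"metadata": {
        "seed": config.seed,
        "package_version": _package_version(),
        "parameter_hash": param_hash,
        "parameter_provenance": PARAMETER_PROVENANCE,
    }}
    rng = np.random.default_rng(config.seed)

    stage = "count"
    try:
        counting, fov = _stage_counting(config, rng)
        report["counting"] = counting
        pd.DataFrame({"fov": [fov.fov_id], "count": [fov.count]}).to_csv(
            outdir / "fov_counts.csv", index=False)

        stage = "morph"
        morph_report, morph = _stage_morphology(config, rng)
        report["morphology"] = morph_report
        morph.to_csv(outdir / "morphology.csv", index=False)

        stage = "stats"
        if config.cohort_path is not None:
            cohort = spio.read_cohort(config.cohort_path)
            morphologies = {}
        else:
            cohort, morphologies = simulate_cohort(dataclasses.replace(
                config.cohort, seed=config.seed))
        spio.write_cohort(cohort, outdir / "cohort.csv")
        fractions = None
        if morphologies:
            groups = dict(cohort.groupby("subject")["group"].first())
            threshold_report, fractions = _stage_threshold(
                config, morphologies, groups)
            report["threshold"] = threshold_report
            fractions.to_csv(outdir / "subject_fractions.csv", index=False)

        stage = "biomarker"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            biomarker_report, ranking = _stage_biomarker(
                config, cohort, fractions)
        report["biomarker"] = biomarker_report
        ranking.to_csv(outdir / "composites.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(_sanitize(report), indent=2, sort_keys=True,
                   default=_json_default) + "\n")
    (outdir / "config.yaml").write_text(yaml_text)
    return report
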