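"""End-to-end orchestration: simulate → extract → model → optimize → report.

``run_all`` drives the whole analysis from one seeded configuration:
synthetic-experiment generation (or externally supplied data), spectral and
structural feature extraction, the 3 models × 3 feature sets × 3 targets
regression grid, SVR feature relevance, per-feature dose-response fits with
optimal-dosage aggregation, and the 24×24 feature correlation matrix. Every
random decision is derived from the master seed, so a fixed config yields
byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, doseresp, regression, spectral, structural
from .synthetic import ExperimentConfig, SyntheticPlant, TraitCurve, generate_experiment

__all__ = ["RunConfig", "RunResult", "run_all",
           "extract_spectral_features", "extract_structural_features",
           "correlation_matrix"]

#: features entering the optimal-dosage aggregation, by modality group
DEFAULT_DOSE_GROUPS: dict[str, str] = {
    "ExR": "spectral", "VARI": "spectral", "GMRI": "spectral",
    "HT": "structural", "CV": "structural",
}


@dataclass(frozen=True)
class RunConfig:
    """One self-contained, seeded configuration for the full pipeline."""

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    grid_edge: float = 0.01
    min_count: int = 4
    hull: structural.HullConfig = field(default_factory=structural.HullConfig)
    index_config: spectral.IndexConfig = field(default_factory=spectral.IndexConfig)
    min_leaf_area: int = 25
    use_true_masks: bool = False
    models: Sequence[str] = ("SVR", "RF", "Lasso")
    feature_sets: Sequence[str] = ("spectral", "structural", "combined")
    targets: Sequence[str] = ("TRN", "NO3", "DW")
    split_fraction: float = 0.7
    grid_search: bool = False
    relevance_iterations: int = 100
    dose_groups: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_GROUPS))

    def to_json(self) -> str:
        d = asdict(self)
        d["experiment"]["trait_curves"] = {
            k: [v.a, v.b, v.c] for k, v in self.experiment.trait_curves.items()
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        exp = d.pop("experiment")
        exp["trait_curves"] = {k: TraitCurve(*v) for k, v in exp["trait_curves"].items()}
        exp["doses_ppm"] = tuple(exp["doses_ppm"])
        exp["replicates_per_dose"] = tuple(exp["replicates_per_dose"])
        hull = structural.HullConfig(**d.pop("hull"))
        idx = spectral.IndexConfig(**d.pop("index_config"))
        d["models"] = tuple(d["models"])
        d["feature_sets"] = tuple(d["feature_sets"])
        d["targets"] = tuple(d["targets"])
        return cls(experiment=ExperimentConfig(**exp), hull=hull, index_config=idx, **d)


@dataclass(frozen=True)
class RunResult:
    """All tables produced by one pipeline run."""

    traits: pd.DataFrame
    spectral_features: pd.DataFrame
    structural_features: pd.DataFrame
    features: pd.DataFrame        # joined on plant_id, with traits
    metrics: pd.DataFrame         # target × feature set × model rows
    relevance: pd.DataFrame       # feature × target
    dose_fits: pd.DataFrame
    optimum: doseresp.OptimalDoseResult
    correlation: pd.DataFrame
    mean_iou: float


def extract_spectral_features(
    plants: Sequence[SyntheticPlant],
    index_config: spectral.IndexConfig | None = None,
    min_leaf_area: int = 25,
    use_true_masks: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-plant calibrated vegetation-index table and mean segmentation IoU.

    Each plant's raw image is calibrated with its dark and white frames, the
    leaf mask comes from the classical ExG+Otsu segmenter (or the generator's
    ground-truth mask with ``use_true_masks``), and the 15 indices are
    averaged over the mask. IoU is scored against the true mask when present.
    """
    rows, ious = [], []
    for p in plants:
        refl = spectral.calibrate(p.image, p.dark_frame, p.white_frame)
        if use_true_masks:
            mask = p.true_leaf_mask
        else:
            mask = spectral.segment_leaves(refl, min_area=min_leaf_area)
        if p.true_leaf_mask is not None and mask.any():
            ious.append(spectral.iou(mask, p.true_leaf_mask))
        fv = spectral.compute_indices(refl, mask, index_config, plant_id=p.plant_id)
        rows.append({"plant_id": p.plant_id, **fv.values})
    df = pd.DataFrame(rows)
    return df, float(np.mean(ious)) if ious else float("nan")


def extract_structural_features(
    plants: Sequence[SyntheticPlant],
    grid_edge: float = 0.01,
    min_count: int = 4,
    hull: structural.HullConfig = structural.HullConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plant structural trait table: denoise → color K-means → 9 traits."""
    seeds = np.random.SeedSequence(seed).generate_state(len(plants)) % (2**31)
    rows = []
    for p, s in zip(plants, seeds):
        clean = structural.denoise(p.cloud, grid_edge=grid_edge, min_count=min_count)
        seg = structural.segment_plant(clean, seed=int(s))
        feats = structural.extract_features(
            seg.plant, grid_edge=grid_edge, hull=hull, plant_id=p.plant_id)
        rows.append({"plant_id": p.plant_id, **feats.as_dict()})
    return pd.DataFrame(rows)


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of all feature columns (plant_id/traits excluded)."""
    cols = [c for c in features.columns
            if c not in ("plant_id", "dose_ppm") + regression.TRAIT_NAMES]
    return features[cols].corr(method="pearson")


def _metrics_grid(cfg: RunConfig, table: pd.DataFrame, seeds: np.ndarray) -> pd.DataFrame:
    rows = []
    for t_i, target in enumerate(cfg.targets):
        for s_i, fset in enumerate(cfg.feature_sets):
            cols = regression.feature_columns(fset)
            for m_i, model in enumerate(cfg.models):
                mcfg = regression.ModelConfig(
                    model=model, grid_search=cfg.grid_search,
                    split_fraction=cfg.split_fraction,
                    seed=int(seeds[t_i * 9 + s_i * 3 + m_i]),
                )
                train, test = split_table_for(cfg, table, int(seeds[t_i]))
                result = regression.fit_predict(train, test, target, mcfg, features=cols)
                rows.append({"target": target, "feature_set": fset, "model": model,
                             **result.metrics.as_dict()})
    return pd.DataFrame(rows)


def split_table_for(cfg: RunConfig, table: pd.DataFrame, seed: int):
    return regression.split_table(table, cfg.split_fraction, seed=seed)


def run_all(cfg: RunConfig | None = None, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write all tables under ``out_dir``."""
    cfg = cfg or RunConfig()
    exp = replace(cfg.experiment, seed=cfg.seed)
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = master.generate_state(64) % (2**31)

    plants = generate_experiment(exp)
    traits = pd.DataFrame([
        {"plant_id": p.plant_id, "dose_ppm": p.dose_ppm,
         "TRN": p.traits.TRN, "NO3": p.traits.NO3, "DW": p.traits.DW}
        for p in plants
    ])

    spectral_df, mean_iou = extract_spectral_features(
        plants, cfg.index_config, cfg.min_leaf_area, cfg.use_true_masks)
    structural_df = extract_structural_features(
        plants, cfg.grid_edge, cfg.min_count, cfg.hull, seed=int(stage_seeds[0]))

    features = traits.merge(spectral_df, on="plant_id").merge(structural_df, on="plant_id")
    n_dropped = len(traits) - len(features)
    if n_dropped:
        import sys
        print(f"warning: {n_dropped} plants dropped in plant_id join", file=sys.stderr)

    metrics = _metrics_grid(cfg, features, stage_seeds[1:32])

    rel_cols = {}
    for i, target in enumerate(cfg.targets):
        rcfg = regression.ModelConfig(
            model="SVR", split_fraction=cfg.split_fraction, seed=int(stage_seeds[40 + i]))
        rel_cols[target] = regression.relevance(
            features, target, rcfg, iterations=cfg.relevance_iterations,
            features=regression.feature_columns("combined"))
    relevance_df = pd.DataFrame(rel_cols)

    fit_rows, fits = [], []
    feature_cols = regression.feature_columns("combined")
    for col in feature_cols + regression.TRAIT_NAMES:
        extremum = "either" if col in cfg.dose_groups else "max"
        fit = doseresp.fit_curve(features["dose_ppm"], features[col],
                                 feature=col, extremum=extremum)
        fits.append(fit)
        fit_rows.append({"feature": col, "a": fit.a, "b": fit.b, "c": fit.c,
                         "R2": fit.r2, "SE": fit.se, "peak_dose_ppm": fit.peak_dose_ppm,
                         "peak_type": fit.peak_type})
    dose_fits = pd.DataFrame(fit_rows)
    optimum = doseresp.aggregate_optimal(fits, cfg.dose_groups)

    corr = correlation_matrix(features)

    result = RunResult(
        traits=traits, spectral_features=spectral_df,
        structural_features=structural_df, features=features,
        metrics=metrics, relevance=relevance_df, dose_fits=dose_fits,
        optimum=optimum, correlation=corr, mean_iou=mean_iou,
    )
    if out_dir is not None:
        _write_result(cfg, result, Path(out_dir))
    return result


def _write_result(cfg: RunConfig, result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.traits.to_csv(out / "traits.csv", index=False)
    result.spectral_features.to_csv(out / "spectral_features.csv", index=False)
    result.structural_features.to_csv(out / "structural_features.csv", index=False)
    result.features.to_csv(out / "features.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.relevance.to_csv(out / "relevance.csv")
    result.dose_fits.to_csv(out / "dose_fits.csv", index=False)
    result.correlation.to_csv(out / "correlation.csv")
    (out / "optimum.json").write_text(json.dumps({
        "optimal_dose_ppm": result.optimum.optimal_dose_ppm,
        "group_peaks_ppm": dict(result.optimum.group_peaks),
        "contributing": {k: list(v) for k, v in result.optimum.contributing.items()},
        "excluded": list(result.optimum.excluded),
        "mean_segmentation_iou": result.mean_iou,
    }, indent=2))
    (out / "run_config.json").write_text(cfg.to_json())


# DGCI / leaf-area baseline comparison used by the analysis drivers
def baseline_comparison(
    plants: Sequence[SyntheticPlant],
    features: pd.DataFrame,
    cfg: RunConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Test-set RMSE of SoA-NC (DGCI→TRN) and SoA-DW (leaf area→DW) vs RF.

    Both baselines are calibrated on the training split only, mirroring the
    regression protocol, and compared with the structural-feature random
    forest for DW and the spectral-feature random forest for TRN.
    """
    cam = baselines.CameraSpec(pixel_length_um=1.9, magnification=2000.0)
    per_plant = {}
    for p in plants:
        refl = spectral.calibrate(p.image, p.dark_frame, p.white_frame)
        mask = spectral.segment_leaves(refl, min_area=cfg.min_leaf_area)
        per_plant[p.plant_id] = {
            "dgci": baselines.dgci(refl, mask).value,
            "leaf_area": baselines.leaf_area(refl, cam),
        }
    aux = pd.DataFrame.from_dict(per_plant, orient="index").rename_axis("plant_id").reset_index()
    table = features.merge(aux, on="plant_id")
    train, test = regression.split_table(table, cfg.split_fraction, seed=seed)

    rows = []
    for target, predictor in (("TRN", "dgci"), ("DW", "leaf_area")):
        ic, sl = np.polynomial.polynomial.polyfit(
            train[predictor].to_numpy(), train[target].to_numpy(), 1)
        pred = ic + sl * test[predictor].to_numpy()
        m = regression.compute_metrics(test[target].to_numpy(), pred)
        rows.append({"target": target, "method": f"SoA ({predictor})",
                     **m.as_dict()})
        fset = "spectral" if target == "TRN" else "structural"
        r = regression.fit_predict(
            train, test, target,
            regression.ModelConfig(model="RF", seed=seed),
            features=regression.feature_columns(fset))
        rows.append({"target": target, "method": f"RF ({fset})", **r.metrics.as_dict()})
    return pd.DataFrame(rows)
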