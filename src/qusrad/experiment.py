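"""End-to-end experiment orchestration: simulate -> maps -> features ->
fit -> stats -> report, driven by one :class:`ExperimentConfig`.

Every stage writes into the output directory; a run manifest records
the config, seeds, per-stage wall-clock and output checksums so that a
re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import phantom, spectral, stats
from .config import ExperimentConfig, config_to_dict, dump_config
from .phantom import AcquisitionGeometry
from .pipeline import RecurrenceModel, reduced_classifier_specs

__all__ = ["run_experiment", "write_report", "extract_cohort_features"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def acquisition_from_config(cfg: ExperimentConfig) -> AcquisitionGeometry:
    c = cfg.cohort
    return AcquisitionGeometry(
        depth_mm=c.frame_depth_mm,
        width_mm=c.frame_width_mm,
        fs_axial_mhz=c.fs_axial_mhz,
        lateral_pitch_mm=c.lateral_pitch_mm,
        fc_mhz=c.fc_mhz,
        band_mhz=c.band_mhz,
        sound_speed_m_s=c.sound_speed_m_s,
        snr_db=c.snr_db,
    )


def extract_cohort_features(
    patients: list[phantom.PatientData],
    reference: spectral.ReferenceSpectrum,
    cfg: ExperimentConfig,
) -> pd.DataFrame:
    """Maps + radiomics + per-patient aggregation for a simulated cohort."""
    vectors = {}
    clinical = {}
    for pat in patients:
        frame_vecs = []
        for frame, roi in zip(pat.frames, pat.rois):
            maps = spectral.build_parametric_maps(
                frame, roi, reference, cfg.spectral, cfg.form_factor
            )
            frame_vecs.append(feat.extract_frame_features(maps, roi, cfg.radiomics))
        vectors[pat.clinical.patient_id] = feat.aggregate_patient(frame_vecs)
        clinical[pat.clinical.patient_id] = pat.clinical
    return feat.build_feature_matrix(vectors, clinical)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage and write results + manifest; returns the out dir."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": cfg.seed}
    dump_config(cfg, out / "config.yaml")

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }
        logger.info("stage %s finished in %.1fs", name, time.time() - t0)

    acq = acquisition_from_config(cfg)

    t0 = stage("simulate")
    patients = phantom.generate_cohort(
        n_low=cfg.cohort.n_low,
        n_high=cfg.cohort.n_high,
        frames_per_patient=cfg.cohort.frames_per_patient,
        acq=acq,
        seed=cfg.seed,
        core_asd_um=cfg.cohort.core_asd_um,
        core_aac_db=cfg.cohort.core_aac_db,
        background_aac_db=cfg.cohort.background_aac_db,
        scatterer_density_mm2=cfg.cohort.scatterer_density_mm2,
        attenuation_db_cm_mhz=cfg.cohort.attenuation_db_cm_mhz,
        margin_heterogeneity_low=cfg.cohort.margin_heterogeneity_low,
        margin_heterogeneity_high=cfg.cohort.margin_heterogeneity_high,
        margin_aac_delta_db_high=cfg.cohort.margin_aac_delta_db_high,
        long_axis_range_cm=cfg.cohort.long_axis_range_cm,
        odxrs_threshold=cfg.odxrs_threshold,
    )
    ref_frames, ref_meta = phantom.generate_reference_frames(
        acq, n_frames=5, seed=cfg.seed + 1, b_ff=cfg.form_factor.b_ff
    )
    done("simulate", t0, [])

    t0 = stage("features")
    reference = spectral.reference_spectrum(ref_frames, ref_meta, cfg.spectral)
    df = extract_cohort_features(patients, reference, cfg)
    features_csv = out / "features.csv"
    df.to_csv(features_csv)
    done("features", t0, [features_csv])

    t0 = stage("fit")
    specs = reduced_classifier_specs()
    fit_results = {}
    for clf in cfg.classifiers:
        model = RecurrenceModel.from_feature_matrix(
            df, classifier=clf, config=cfg.pipeline, specs=specs
        )
        res = model.fit()
        fit_results[clf] = res
        (out / f"fit_{clf}.json").write_text(res.to_json())
    done("fit", t0, [out / f"fit_{c}.json" for c in cfg.classifiers])

    t0 = stage("stats")
    y = df["label"].to_numpy()
    X = df.drop(columns=["odxrs", "label"])
    from .pipeline import mrmr_select, standardize_fit_apply

    Xt, _, _, _, _ = standardize_fit_apply(X.to_numpy())
    k = min(cfg.stats.n_tests, X.shape[1])
    cols = mrmr_select(Xt, y, k, feature_names=list(X.columns))
    screen = stats.screen_features(X[cols], y, cfg.stats)
    stats_csv = out / "univariate.csv"
    screen.table.to_csv(stats_csv, index=False)
    done("stats", t0, [stats_csv])

    t0 = stage("report")
    report = write_report(fit_results, screen, out / "report.md")
    done("report", t0, [report])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def write_report(
    fit_results: dict,
    screen: stats.ScreenResult | None,
    path: str | Path,
) -> Path:
    """Markdown report: metric table per classifier, selection
    frequencies, univariate screen."""
    path = Path(path)
    lines = ["# QUS radiomics recurrence-risk run report", ""]
    if fit_results:
        lines += [
            "## Test-set classification performance (aggregated LOO folds)",
            "",
            "| Classifier | Recall | Specificity | Accuracy | Balanced acc. | "
            "Precision | NPV | F1 | AUROC | AUPRC |",
            "|---|---|---|---|---|---|---|---|---|---|",
        ]
        for clf, res in fit_results.items():
            m = res.metrics
            r = m.rounded()
            c = res.counts
            cells = [
                f"{r['recall']} ({c.tp}/{c.tp + c.fn})",
                f"{r['specificity']} ({c.tn}/{c.tn + c.fp})",
                f"{r['accuracy']} ({c.tp + c.tn}/{c.n})",
                f"{r['balanced_accuracy']}",
                f"{r['precision']} ({c.tp}/{c.tp + c.fp})"
                if c.tp + c.fp
                else "undefined",
                f"{r['npv']} ({c.tn}/{c.tn + c.fn})" if c.tn + c.fn else "undefined",
                f"{r['f1']}",
                f"{r['auroc']}",
                f"{r['auprc']}",
            ]
            lines.append(f"| {clf} | " + " | ".join(str(x) for x in cells) + " |")
        lines.append("")
        lines.append("## Most frequently selected features")
        lines.append("")
        for clf, res in fit_results.items():
            top = sorted(
                res.feature_frequency.items(), key=lambda kv: (-kv[1], kv[0])
            )[:5]
            lines.append(f"- **{clf}**:")
            for name, cnt in top:
                lines.append(f"    - {cnt}x `{name}`")
        lines.append("")
    else:
        lines += ["## Classification", "", "_unavailable_", ""]
    lines.append("## Univariate screening")
    lines.append("")
    if screen is not None:
        lines.append(
            f"Bonferroni-adjusted threshold: {screen.adjusted_alpha:g}"
        )
        lines.append("")
        head = screen.table.head(10)
        lines.append("| feature | test | p | raw<0.05 | Bonferroni |")
        lines.append("|---|---|---|---|---|")
        for _, row in head.iterrows():
            lines.append(
                f"| `{row['feature']}` | {row['test']} | {row['p']:.2e} | "
                f"{bool(row['raw_pass'])} | {bool(row['bonferroni_pass'])} |"
            )
    else:
        lines.append("_unavailable_")
    path.write_text("\n".join(lines) + "\n")
    return path
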