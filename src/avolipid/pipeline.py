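"""End-to-end orchestration: simulate -> baseline -> detect -> isotopes ->
align -> gap-fill -> group -> annotate -> quantify -> stats.

Every stage is seeded from the single config seed; a manifest with stage
counts and artifact checksums makes re-runs comparable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as anno
from . import grouping, io, quant, signal, stats, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate(config: PipelineConfig, out_dir: Path):
    """Generate DB, profiles, scan maps, UV tables; write them all."""
    out_dir.mkdir(parents=True, exist_ok=True)
    db = synthetic.generate_lipid_db(config.seed, config.db_records)
    io.write_lipid_db_tsv(db, out_dir / "lipid_db.tsv")
    acq = config.acquisition()

    profiles = []
    maps = {}
    ledgers = {}
    uv_tables = {}
    for stage in config.stages:
        for rep in range(config.replicates):
            profile = synthetic.generate_sample_profile(
                config.tissue, stage, config.seed, replicate=rep,
                noise_cv=config.noise_cv, share_cv=config.share_cv,
            )
            profiles.append(profile)
            scan_map, ledger = synthetic.synthesize_scan_map(
                profile, db, acq, config.seed, dropout_p=config.dropout_p
            )
            maps[profile.sample_id] = scan_map
            ledgers[profile.sample_id] = ledger
            uv_tables[profile.sample_id] = synthetic.synthesize_uv_peak_table(
                profile, config.seed
            )
            io.write_scan_map_csv(scan_map, out_dir / f"{profile.sample_id}.scanmap.csv")
            io.write_ledger_csv(ledger, out_dir / f"{profile.sample_id}.ledger.csv")
    io.write_profiles_csv(profiles, out_dir / "profiles.csv")
    io.write_uv_table_csv(uv_tables, out_dir / "uv_areas.csv")
    logger.info("simulated %d samples, %d-record DB", len(profiles), len(db))
    return db, profiles, maps, ledgers, uv_tables


def process_maps(config: PipelineConfig, maps: dict) -> tuple[dict, signal.FeatureTable]:
    """Baseline-correct, detect, isotope-group and align all scan maps."""
    features_by_sample = {}
    corrected_maps = {}
    for sid, scan_map in maps.items():
        corrected = signal.correct_baseline(
            scan_map, config.baseline_mz_window, config.baseline_rt_window,
            config.baseline_quantile,
        )
        corrected_maps[sid] = corrected
        feats = signal.detect_peaks(
            corrected, config.min_height, config.detect_mz_tol,
            config.rt_min, config.rt_max, config.smoothing, config.similarity,
        )
        signal.group_isotopes(
            feats, config.isotope_mz_tol, config.isotope_ppm_tol,
            config.isotope_rt_tol, config.max_charge,
        )
        features_by_sample[sid] = signal.monoisotopic_only(feats)
        logger.info(
            "sample %s: %d features (%d monoisotopic)",
            sid, len(feats), len(features_by_sample[sid]),
        )
    table = signal.align_samples(
        features_by_sample, config.align_mz_tol, config.align_ppm_tol,
        config.rt_tol_before, config.rt_tol_after, config.min_inliers,
        config.inlier_threshold, seed=config.seed,
    )
    table = signal.fill_gaps(table, corrected_maps, config.align_mz_tol, config.align_ppm_tol)
    n_filled = int((table.provenance == "gap-filled").sum())
    logger.info("aligned %d features; %d cells gap-filled", table.n_features, n_filled)
    return features_by_sample, table


def annotate_sample(config: PipelineConfig, features, db) -> pd.DataFrame:
    """Group one sample's features and annotate each group member."""
    groups = grouping.group_by_correlation(
        features, threshold=config.correlation_threshold
    )
    for g in groups:
        grouping.curate_group(g, features)
    by_id = {f.feature_id: f for f in features}
    rows = []
    for group in groups:
        for fid in group.member_ids:
            feat = by_id[fid]
            hypotheses = anno.enumerate_adducts(feat.mean_mz, feat.charge)
            candidates = anno.search_db(hypotheses, db, feat.mz_sd, feature_id=fid)
            profile1 = anno.classify_composition(candidates, 1) if candidates else None
            profile2 = anno.classify_composition(candidates, 2) if candidates else None
            for cand in candidates:
                rows.append(
                    {
                        "feature_id": fid,
                        "group_rt": group.consensus_rt,
                        "mean_mz": feat.mean_mz,
                        "role": group.roles.get(fid, ""),
                        "adduct": cand.adduct_label,
                        "formula": cand.record.formula_string,
                        "name": cand.record.name,
                        "class_path": "/".join(
                            filter(None, [cand.record.category, cand.record.main_class,
                                          cand.record.subclass])
                        ),
                        "ppm_error": cand.mass_error_ppm,
                        "isotope_check": cand.isotope_check,
                        "level1_fixed": profile1.fixed,
                        "level1_weights": json.dumps(profile1.weights),
                        "level2_fixed": profile2.fixed,
                        "level2_weights": json.dumps(profile2.weights),
                    }
                )
            if not candidates:
                rows.append(
                    {
                        "feature_id": fid,
                        "group_rt": group.consensus_rt,
                        "mean_mz": feat.mean_mz,
                        "role": group.roles.get(fid, ""),
                        "adduct": "",
                        "formula": "",
                        "name": "",
                        "class_path": "",
                        "ppm_error": np.nan,
                        "isotope_check": "unannotated",
                        "level1_fixed": False,
                        "level1_weights": "{}",
                        "level2_fixed": False,
                        "level2_weights": "{}",
                    }
                )
    return pd.DataFrame(rows)


def quantify_samples(profiles, uv_tables) -> pd.DataFrame:
    curves = quant.default_calibration()
    rows = []
    for profile in profiles:
        result = quant.quantify(
            uv_tables[profile.sample_id], curves, profile.dw_fraction,
            sample_id=profile.sample_id,
        )
        shares = quant.profile_shares(result) if result.tac_fw > 0 else {}
        row = {
            "sample_id": profile.sample_id,
            "tissue": profile.tissue,
            "stage": profile.stage,
            "replicate": profile.replicate,
            "tac_mg_gfw": result.tac_fw,
            "tac_mg_gdw": result.tac_dw,
        }
        for analyte in synthetic.ACETOGENIN_ANALYTES:
            row[f"{analyte}_mg_gfw"] = result.concentrations_fw.get(analyte, 0.0)
            row[f"{analyte}_share_pct"] = shares.get(analyte, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(config: PipelineConfig, table: signal.FeatureTable, out_dir: Path):
    """Normalization, PCA, divergent-group selection, trend curves."""
    raw = pd.DataFrame(
        np.nan_to_num(table.intensities, nan=0.0),
        index=[f"F{i}" for i in range(table.n_features)],
        columns=table.sample_ids,
    )
    if raw.shape[1] < 3 or raw.shape[0] < 2:
        logger.warning("too few samples/features for statistics; skipping analyze stage")
        return None
    normalized = stats.normalize(raw)
    pca = stats.run_pca(normalized)
    selection = stats.select_divergent_groups(
        pca, normalized.feature_ids, 0, config.loading_quantile
    )
    covariate = np.arange(len(normalized.sample_ids), dtype=float)
    trends = stats.trend_curves(
        normalized,
        {"trend_up": selection.trend_up, "trend_down": selection.trend_down},
        covariate,
        span=config.lowess_span,
    )
    scores = pd.DataFrame(
        pca.scores[:, :2], index=normalized.sample_ids, columns=["PC1", "PC2"]
    )
    scores["variance_pc1"] = pca.variance_fractions[0]
    scores.to_csv(out_dir / "pca_scores.csv")
    pd.DataFrame(
        {
            "feature_id": normalized.feature_ids,
            "pc1_loading": pca.loadings[:, 0],
            "selected_up": [f in set(selection.trend_up) for f in normalized.feature_ids],
            "selected_down": [f in set(selection.trend_down) for f in normalized.feature_ids],
        }
    ).to_csv(out_dir / "pca_loadings.csv", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(scores["PC1"], scores["PC2"])
        for sid, row in scores.iterrows():
            ax.annotate(sid, (row["PC1"], row["PC2"]), fontsize=6)
        ax.set_xlabel(f"PC1 ({100 * pca.variance_fractions[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * pca.variance_fractions[1]:.0f}%)")
        fig.tight_layout()
        fig.savefig(out_dir / "pca_scores.png", dpi=100)
        plt.close(fig)
    except Exception as exc:  # plotting must never fail the pipeline
        logger.warning("PCA figure not written: %s", exc)
    return pca, selection, trends


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest (also written)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    stage = "simulate"
    try:
        db, profiles, maps, ledgers, uv_tables = simulate(config, out_dir)
        manifest["stages"]["simulate"] = {
            "samples": len(profiles),
            "db_records": len(db),
        }

        stage = "process"
        features_by_sample, table = process_maps(config, maps)
        io.write_feature_table_csv(table, out_dir / "feature_table.csv")
        manifest["stages"]["process"] = {
            "features": int(table.n_features),
            "gap_filled_cells": int((table.provenance == "gap-filled").sum()),
        }

        stage = "annotate"
        reference = max(features_by_sample, key=lambda s: len(features_by_sample[s]))
        report = annotate_sample(config, features_by_sample[reference], db)
        report.to_csv(out_dir / "annotation_report.csv", index=False, float_format="%.8g")
        manifest["stages"]["annotate"] = {
            "reference_sample": reference,
            "annotated_rows": int(len(report)),
        }

        stage = "quantify"
        quant_df = quantify_samples(profiles, uv_tables)
        quant_df.to_csv(out_dir / "quant_results.csv", index=False, float_format="%.8g")
        manifest["stages"]["quantify"] = {"samples": int(len(quant_df))}

        stage = "analyze"
        analyze(config, table, out_dir)
        manifest["stages"]["analyze"] = {"done": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed (inputs under {out_dir})") from exc

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out_dir.glob("*.csv"))
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
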