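"""End-to-end orchestration: one reproducible run of the whole analysis.

``run_pipeline`` ties the stages together — synthetic cohort (or files
on disk) -> MBLL conversion -> band-pass -> artifact screening ->
activation features -> chi-squared ranking -> incremental-subset SVM
cross-validation -> permutation nulls and significance -> topographic
maps — and writes a report bundle: summary tables, figures, a provenance
JSON (config hash, seed, package version) and a log with per-stage
counts. A single seed governs the cohort, the CV partitions and the
permutations through independently derived streams, so stages can be
rerun in isolation and a run's outputs are bit-identical under a fixed
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify_eval import CVConfig, incremental_subset_eval, results_long_table, summary_table
from .containers import FeatureMatrix, SubjectMeta
from .features import build_feature_matrix, windowed_activation
from .io import read_metadata_csv, read_snirf, write_layout_csv, write_metadata_csv, write_snirf
from .permstats import compare_to_null, permutation_null
from .preprocess import MBLLCoefficients, bandpass, detect_artifact_windows, mbll_convert
from .ranking import chi2_priority_scores
from .synthdata import SynthParams, generate_cohort, generate_layout
from .topomap import interpolate_topomap, plot_topomap

logger = logging.getLogger("fnirscreen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one pipeline run.

    When ``input_dir`` is None a synthetic cohort is generated from
    ``synth`` (its seed derived from the run seed); otherwise SNIRF files
    plus a ``metadata.csv`` are read from the directory.
    """

    seed: int = 0
    output_dir: str = "fnirscreen_out"
    input_dir: str | None = None
    label: str = "group"  # "group" | a neuropsychological test name
    tie_rule: str = "strict_greater"
    synth: SynthParams = field(default_factory=SynthParams)
    # filtering
    filter_low_hz: float = 0.01
    filter_high_hz: float = 0.5
    filter_order: int = 3
    # artifact screening
    artifact_window_s: float = 10.0
    artifact_mad_multiplier: float = 4.5
    # cross-validation
    n_folds: int = 5
    n_repetitions: int = 20
    k_range: tuple[int, ...] = tuple(range(2, 11))
    ranking_mode: str = "per-fold"
    n_bins: int = 10
    n_permutations: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_kwargs = raw.pop("synth", {})
        if "informative_channels" in synth_kwargs:
            synth_kwargs["informative_channels"] = tuple(synth_kwargs["informative_channels"])
        synth = SynthParams(**synth_kwargs)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(synth=synth, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        d["synth"]["informative_channels"] = list(d["synth"]["informative_channels"])
        return d

    @property
    def provenance_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def cv_config(self, seed: int) -> CVConfig:
        return CVConfig(
            n_folds=self.n_folds,
            n_repetitions=self.n_repetitions,
            k_range=tuple(self.k_range),
            seed=seed,
            ranking_mode=self.ranking_mode,
            n_bins=self.n_bins,
        )


def _derived_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    cohort, cv, perm = (int(s) for s in ss.generate_state(3) % (2**31))
    return {"cohort": cohort, "cv": cv, "perm": perm}


def _write_csv(df: pd.DataFrame, path: Path, provenance: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False, **kwargs)


def _load_inputs(cfg: RunConfig):
    input_dir = Path(cfg.input_dir)
    metas = read_metadata_csv(input_dir / "metadata.csv")
    recordings = []
    for m in metas:
        rec_path = input_dir / f"{m.subject_id}.snirf"
        if not rec_path.exists():
            raise FileNotFoundError(f"no recording for subject {m.subject_id}: {rec_path}")
        recordings.append(read_snirf(rec_path))
    layout = recordings[0].layout
    return recordings, metas, layout


def extract_features(cfg: RunConfig, recordings, metas) -> tuple[FeatureMatrix, dict, dict]:
    """Preprocess every recording and assemble the feature matrix.

    Returns the matrix, the per-subject activation dictionaries, and a
    counts dict (windows excluded per subject) for the run log.
    """
    coef = MBLLCoefficients.default()
    activations: dict[str, dict[int, np.ndarray]] = {}
    excluded: dict[str, int] = {}
    for rec in recordings:
        hemo = mbll_convert(rec, coef)
        filt = bandpass(hemo, cfg.filter_low_hz, cfg.filter_high_hz, cfg.filter_order)
        table = detect_artifact_windows(
            filt,
            window_s=cfg.artifact_window_s,
            threshold_multiplier=cfg.artifact_mad_multiplier,
        )
        activations[rec.subject_id] = windowed_activation(filt, table)
        excluded[rec.subject_id] = int(table.is_outlier.sum())
    fm = build_feature_matrix(activations, metas, label=cfg.label, tie_rule=cfg.tie_rule)
    return fm, activations, excluded


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a manifest dict mapping artifact names to file paths, plus
    the in-memory results under ``"results"``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance_hash
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _derived_seeds(cfg.seed)
    try:
        logger.info("run start: provenance=%s seed=%d", prov, cfg.seed)

        # --- stage: inputs -------------------------------------------------
        if cfg.input_dir is None:
            synth = replace(cfg.synth, seed=seeds["cohort"])
            layout = generate_layout(seeds["cohort"])
            recordings, metas = generate_cohort(synth, layout=layout)
            logger.info("synthesized cohort: %d recordings", len(recordings))
        else:
            recordings, metas, layout = _load_inputs(cfg)
            logger.info("loaded cohort from %s: %d recordings", cfg.input_dir, len(recordings))

        # --- stage: preprocess + features ---------------------------------
        fm, activations, excluded = extract_features(cfg, recordings, metas)
        total_excluded = sum(excluded.values())
        n_dropped = len(recordings) - fm.values.shape[0]
        logger.info(
            "features: %d x %d matrix, %d windows excluded, %d subjects dropped",
            fm.values.shape[0], fm.values.shape[1], total_excluded, n_dropped,
        )

        # --- stage: ranking -------------------------------------------------
        scores = chi2_priority_scores(fm, n_bins=cfg.n_bins)
        logger.info("ranking: top channels %s", scores.order[:5].tolist())

        # --- stage: classification -----------------------------------------
        cv_cfg = cfg.cv_config(seeds["cv"])
        results = incremental_subset_eval(fm, cv_cfg, scores=scores)
        logger.info("classification: k-sweep over %s", sorted(results))

        # --- stage: permutation statistics ---------------------------------
        null = permutation_null(fm, replace(cv_cfg, seed=seeds["perm"]), cfg.n_permutations)
        report = compare_to_null(results, null)
        n_sig = int(report.table["significant"].sum())
        logger.info("permutation: %d of %d comparisons significant", n_sig, len(report.table))

        # --- stage: outputs -------------------------------------------------
        manifest: dict = {}
        fm.to_csv(out / "features.csv", provenance=prov)
        manifest["features"] = out / "features.csv"
        _write_csv(scores.to_frame(), out / "scores.csv", prov)
        manifest["scores"] = out / "scores.csv"
        _write_csv(results_long_table(results), out / "results_by_k.csv", prov)
        manifest["results_by_k"] = out / "results_by_k.csv"
        _write_csv(results_long_table(null.results), out / "null_by_k.csv", prov)
        manifest["null_by_k"] = out / "null_by_k.csv"
        _write_csv(report.table, out / "significance.csv", prov)
        manifest["significance"] = out / "significance.csv"
        summary = summary_table(results)
        summary["sensitivity"] = [
            f"{m:.2f} ± {s:.2f}"
            for m, s in zip(summary["sensitivity_median"], summary["sensitivity_sd"])
        ]
        summary["specificity"] = [
            f"{m:.2f} ± {s:.2f}"
            for m, s in zip(summary["specificity_median"], summary["specificity_sd"])
        ]
        _write_csv(
            summary[["n_features", "sensitivity", "specificity"]],
            out / "summary_table.csv",
            prov,
        )
        manifest["summary_table"] = out / "summary_table.csv"
        write_layout_csv(layout, out / "layout.csv")
        manifest["layout"] = out / "layout.csv"
        write_metadata_csv(metas, out / "metadata.csv")
        manifest["metadata"] = out / "metadata.csv"

        # --- stage: topomaps -------------------------------------------------
        manifest["maps"] = _write_maps(fm, scores, layout, out)

        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "provenance": prov,
                    "seed": cfg.seed,
                    "derived_seeds": seeds,
                    "version": __version__,
                    "config": cfg.to_dict(),
                    "windows_excluded": excluded,
                },
                fh,
                indent=2,
            )
        manifest["provenance"] = out / "provenance.json"
        manifest["log"] = log_path
        manifest["results"] = {"by_k": results, "null": null, "significance": report}
        logger.info("run complete")
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_maps(fm: FeatureMatrix, scores, layout, out: Path) -> list[Path]:
    """Group-mean activation maps, their difference, and the score map."""
    paths = []
    values = fm.values.to_numpy(float)
    groups = {
        "activation_positive": values[fm.label == 1].mean(axis=0),
        "activation_negative": values[fm.label == 0].mean(axis=0),
    }
    groups["activation_difference"] = (
        groups["activation_negative"] - groups["activation_positive"]
    )
    for name, vals in groups.items():
        mapped = {int(c): float(v) for c, v in zip(fm.channel_ids, vals)}
        # channels dropped from the matrix render as the map median
        fill = float(np.median(vals))
        full = {int(c): mapped.get(int(c), fill) for c in layout.channel_ids}
        tm = interpolate_topomap(layout, full)
        paths.append(plot_topomap(tm, out / f"map_{name}.png", title=name, unit="mM"))
    score_map = {int(c): float(s) for c, s in zip(scores.channel_ids, scores.scores)}
    fill = float(np.median(scores.scores))
    full = {int(c): score_map.get(int(c), fill) for c in layout.channel_ids}
    tm = interpolate_topomap(layout, full)
    paths.append(plot_topomap(tm, out / "map_priority_scores.png", title="priority scores", unit="ln(1/p)"))
    return paths


def synthesize_to_dir(params: SynthParams, out_dir: str | Path) -> Path:
    """Generate a cohort and write SNIRF files + metadata/layout CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = generate_layout(params.seed)
    recordings, metas = generate_cohort(params, layout=layout)
    for rec in recordings:
        write_snirf(rec, out / f"{rec.subject_id}.snirf")
    write_metadata_csv(metas, out / "metadata.csv")
    write_layout_csv(layout, out / "layout.csv")
    return out
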