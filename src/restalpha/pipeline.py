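"""End-to-end pipeline: simulate (or load) -> preprocess -> features ->
MI performance -> association -> screening, with CSV/JSON outputs.

Per-subject work is streamed (raw trials are never all in memory at once)
and every output embeds the configuration hash and master seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, features, preprocessing, screening, synthetic
from .performance import PerformanceRecord, score_subject
from .preprocessing import BANDS, apply_car, epoch_rest
from .recordings import read_fixture

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    cohort: synthetic.CohortSpec
    input_mode: str = "simulate"  # simulate | fixtures
    fixture_dir: str | None = None
    filter_order: int = 4
    epoch_len: int = preprocessing.EPOCH_LEN
    mi_window: int = preprocessing.MI_WINDOW
    cv_folds: int = 10
    cv_reps: int = 10
    svm_c: float = 1.0
    screening_folds: int = 10
    channel_pairs: dict = field(
        default_factory=lambda: dict(association.DEFAULT_CHANNEL_PAIRS)
    )
    # subjects to drop before the association stage (real cohorts exclude
    # subjects with unusable labels; the list is user-supplied, never built in)
    exclude_subjects: tuple = ()

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "fixtures"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "fixtures" and not self.fixture_dir:
            raise ValueError("fixture_dir required in fixtures mode")
        for band in BANDS:
            band.validate(self.cohort.sample_rate)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        cohort_keys = {f.name for f in dataclasses.fields(synthetic.CohortSpec)}
        own_keys = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        cohort_raw = dict(raw.pop("cohort", {}))
        unknown = (set(raw) - own_keys) | (set(cohort_raw) - cohort_keys)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("separability_range", "alpha_range"):
            if key in cohort_raw and cohort_raw[key] is not None:
                cohort_raw[key] = tuple(cohort_raw[key])
        if "exclude_subjects" in raw:
            raw["exclude_subjects"] = tuple(raw["exclude_subjects"])
        return cls(cohort=synthetic.CohortSpec(**cohort_raw), **raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        # significant digits, not decimal places: tiny p-values stay nonzero
        return float(f"{obj:.{ndigits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def subject_resting_features(
    cfg: PipelineConfig, subject: int, channels=None, feature_names=features.FEATURE_NAMES
) -> pd.DataFrame:
    """Feature rows for one subject's two resting runs (CAR -> epoch -> features)."""
    frames = []
    for state in ("eyes_open", "eyes_closed"):
        rec = _load_recording(cfg, subject, state)
        rec = apply_car(rec)
        epochs = epoch_rest(rec, cfg.epoch_len)
        frames.append(
            features.epoch_set_features(
                epochs, BANDS, channels, feature_names, cfg.filter_order
            )
        )
    return pd.concat(frames, ignore_index=True)


def _load_recording(cfg: PipelineConfig, subject: int, state: str):
    if cfg.input_mode == "simulate":
        return synthetic.make_resting_recording(cfg.cohort, subject, state)
    run = "R01" if state == "eyes_open" else "R02"
    path = Path(cfg.fixture_dir) / f"S{subject + 1:03d}{run}.npz"
    return read_fixture(path)


def subject_performance(cfg: PipelineConfig, subject: int) -> PerformanceRecord:
    trial_set = synthetic.make_mi_trials(cfg.cohort, subject)
    return score_subject(
        trial_set,
        folds=cfg.cv_folds,
        reps=cfg.cv_reps,
        C=cfg.svm_c,
        seed=cfg.cohort.seed,
        filter_order=cfg.filter_order,
    )


def performance_table(cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for s in range(cfg.cohort.n_subjects):
        rec = subject_performance(cfg, s)
        rows.append(dataclasses.asdict(rec))
        log.info(
            "subject %s: 4-class %.1f%% (group %s)",
            rec.subject_id,
            rec.acc_4class_mean,
            rec.group,
        )
    return pd.DataFrame(rows).rename(columns={"subject_id": "subject"})


def feature_table(cfg: PipelineConfig, channels=None, feature_names=features.FEATURE_NAMES) -> pd.DataFrame:
    frames = [
        subject_resting_features(cfg, s, channels, feature_names)
        for s in range(cfg.cohort.n_subjects)
    ]
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns the summary dictionary that is also written to summary.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.cohort.seed}

    stage = "simulate"
    try:
        gt = synthetic.ground_truth(cfg.cohort)
        gt.to_csv(outdir / "ground_truth.csv", index=False)

        stage = "features"
        feats = feature_table(cfg)
        feats.to_csv(outdir / "features.csv", index=False)

        stage = "performance"
        perf = performance_table(cfg)
        perf.to_csv(outdir / "performance.csv", index=False)

        if cfg.exclude_subjects:
            log.info("excluding subjects: %s", list(cfg.exclude_subjects))
            feats = feats[~feats["subject"].isin(cfg.exclude_subjects)]
            perf = perf[~perf["subject"].isin(cfg.exclude_subjects)]

        stage = "association"
        cmap = association.correlation_map(feats, perf)
        cmap.to_csv(outdir / "correlations.csv", index=False)
        contrasts = {}
        for feat in features.FEATURE_NAMES:
            rep = association.band_contrast(cmap, feat, "eyes_open")
            contrasts[feat] = {
                "mauchly_p": rep.mauchly_p,
                "gg_epsilon": rep.gg_epsilon,
                "gg_p": rep.gg_p,
                "pairwise": rep.pairwise.to_dict(orient="records"),
            }
        pair_feats = association.channel_pair_average(feats, cfg.channel_pairs)
        groups = perf.set_index("subject")["group"]
        group_tests = association.group_contrasts(pair_feats, groups)
        group_tests.to_csv(outdir / "group_contrasts.csv", index=False)

        stage = "screening"
        counts = groups.value_counts()
        screen_summary: dict = {}
        if counts.get("H", 0) >= 2 and counts.get("L", 0) >= 2:
            binary = screening.screen_binary(
                pair_feats, groups, cfg.screening_folds, cfg.cohort.seed
            )
            screen_summary["binary_accuracy_pct"] = {
                name: res.cv_accuracy for name, res in binary.items()
            }
            if counts.get("M", 0) >= 2:
                three = screening.screen_three_class(
                    pair_feats, groups, cfg.screening_folds, cfg.cohort.seed
                )
                screen_summary["three_class_accuracy_pct"] = three.cv_accuracy
                screen_summary["three_class_confusion"] = {
                    t: three.confusion.loc[t].to_dict() for t in three.confusion.index
                }
        else:
            screen_summary["skipped"] = "H or L group has fewer than 2 subjects"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    gt_r = float(np.corrcoef(gt["alpha_fraction"], gt["separability"])[0, 1])
    alpha_cells = cmap[
        (cmap["state"] == "eyes_open")
        & (cmap["band"] == "alpha")
        & (cmap["feature"] == "RPL")
        & (cmap["channel"].isin(["C3", "C4"]))
    ]
    summary = {
        **meta,
        "n_subjects": cfg.cohort.n_subjects,
        "planted_rho": cfg.cohort.planted_rho,
        "ground_truth_alpha_separability_r": gt_r,
        "group_sizes": {g: int(counts.get(g, 0)) for g in ("H", "M", "L")},
        "mean_acc_4class_pct": float(perf["acc_4class_mean"].mean()),
        "alpha_rpl_c3c4_r": {
            row.channel: row.r for row in alpha_cells.itertuples()
        },
        "band_contrasts_eyes_open": contrasts,
        "screening": screen_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
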