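"""End-to-end orchestration: preprocess → DNM → sink map → markers →
classification → group statistics, with per-run provenance.

A run directory contains::

    sinkmaps/<subject>.tsv     channel × window sink indices
    markers.csv                one row per subject (si_ft, si_cpo, si_ratio, …)
    reports/<feature>_<clf>.json   LOOCV one-vs-rest metrics
    stats/<feature>.json       Kruskal–Wallis + Dunn pairwise results
    provenance.json            config echo, seeds, package versions

Reports are stable-key-ordered JSON so reruns with identical config and
seeds are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import evaluate_ovr
from .dnm import fit_dnm
from .exceptions import ConfigError, ValidationError
from .features import band_power, pca_reduce, timefreq_features
from .io import Recording, read_cohort, read_recording
from .preprocess import PreprocessConfig, preprocess
from .sink import DEFAULT_CONSTANT, RegionScheme, sink_map, subject_marker
from .stats import dunn_posthoc, kruskal_wallis
from .synth import SyntheticCohortConfig, generate_cohort

log = logging.getLogger("sinkindex")

FEATURE_COLUMNS = {
    "sink": "si_ratio",
    "bandpower": "alpha_ratio",
    "timefreq": None,  # 285-column block reduced per fold
}


@dataclass
class PipelineConfig:
    input_dir: str | None = None          # cohort directory; None → synthetic
    input_format: str | None = None       # edf | eeglab_set | array_csv (None = infer)
    output_dir: str = "run"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    apply_preprocess: bool = True
    T_ms: float = 125.0
    eq2_constant: float = DEFAULT_CONSTANT
    features: tuple[str, ...] = ("sink",)
    classifiers: tuple[str, ...] = ("random_forest",)
    loocv_repeats: int = 1
    seed: int = 0
    synthetic: SyntheticCohortConfig | None = None
    wavelet_template: str = "db4"

    def validate(self) -> None:
        for f in self.features:
            if f not in FEATURE_COLUMNS:
                raise ConfigError(f"unknown feature {f!r}")
        if self.T_ms <= 0:
            raise ConfigError("T_ms must be positive")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input directory {self.input_dir} does not exist")


def _load_subjects(cfg: PipelineConfig) -> tuple[list[Recording], pd.DataFrame]:
    if cfg.input_dir is None:
        synth_cfg = cfg.synthetic or SyntheticCohortConfig(seed=cfg.seed)
        return generate_cohort(synth_cfg)
    cohort = read_cohort(cfg.input_dir)
    recordings = []
    keep = []
    for _, row in cohort.iterrows():
        if not row["recording_path"]:
            log.warning("subject %s: no recording found, skipped", row["subject_id"])
            continue
        try:
            rec = read_recording(row["recording_path"], cfg.input_format,
                                 subject_id=row["subject_id"])
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.warning("subject %s: read failed (%s), skipped", row["subject_id"], exc)
            continue
        recordings.append(rec)
        keep.append(row["subject_id"])
    return recordings, cohort[cohort["subject_id"].isin(keep)].reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis and return the run directory."""
    cfg.validate()
    out = Path(cfg.output_dir)
    (out / "sinkmaps").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)

    recordings, cohort = _load_subjects(cfg)
    if len(recordings) < 2:
        raise ValidationError("need at least 2 readable subjects")

    scheme = RegionScheme()
    rows = []
    tf_rows = {}
    failed: list[str] = []
    for rec, (_, meta) in zip(recordings, cohort.iterrows()):
        sid = rec.subject_id
        try:
            proc = preprocess(rec, cfg.preprocess) if (
                cfg.apply_preprocess and rec.fs > cfg.preprocess.target_fs
            ) else rec
            model = fit_dnm(proc, cfg.T_ms)
            smap = sink_map(model, cfg.eq2_constant)
            marker = subject_marker(smap, scheme, sid, meta["group"])
            smap.to_frame(cfg.T_ms).to_csv(
                out / "sinkmaps" / f"{sid}.tsv", sep="\t", float_format="%.6f"
            )
            row = {
                "subject_id": sid,
                "group": meta["group"],
                "si_ft": marker.si_ft,
                "si_cpo": marker.si_cpo,
                "si_ratio": marker.si_ratio,
            }
            if "bandpower" in cfg.features:
                bp = band_power(proc, scheme)
                for band in bp.ratio:
                    row[f"{band}_ratio"] = bp.ratio[band]
            if "timefreq" in cfg.features:
                tf_rows[sid] = timefreq_features(proc, cfg.wavelet_template)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            log.warning("subject %s failed: %s", sid, exc)
            failed.append(sid)

    markers = pd.DataFrame(rows)
    markers.to_csv(out / "markers.csv", index=False, float_format="%.8f")

    labels = markers["group"].to_numpy()
    for feature in cfg.features:
        col = FEATURE_COLUMNS[feature]
        if feature == "timefreq":
            X = np.vstack([tf_rows[s] for s in markers["subject_id"]])
            from sklearn.decomposition import PCA
            from sklearn.pipeline import Pipeline as SkPipeline
        else:
            X = markers[[col]].to_numpy()
        if np.unique(labels).size >= 2:
            for clf in cfg.classifiers:
                if feature == "timefreq":
                    from .classify import make_classifier
                    est = SkPipeline([
                        ("pca", PCA(n_components=min(5, X.shape[0] - 1, X.shape[1]),
                                    svd_solver="full")),
                        ("clf", make_classifier(clf, cfg.seed)),
                    ])
                    report = evaluate_ovr(X, labels, seed=cfg.seed, estimator=est)
                    report.classifier_name = f"pca5+{clf}"
                else:
                    report = evaluate_ovr(X, labels, clf, seed=cfg.seed)
                with open(out / "reports" / f"{feature}_{clf}.json", "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        # group statistics on the scalar feature (timefreq uses first PC proxy)
        if feature != "timefreq":
            groups = [markers.loc[markers["group"] == g, col].to_numpy()
                      for g in sorted(markers["group"].unique())]
            names = sorted(markers["group"].unique())
            kw = kruskal_wallis(groups)
            dunn = dunn_posthoc(groups, names=names)
            payload = {
                "kruskal_wallis": {
                    "H": kw.statistic, "p": kw.p_value, "df": kw.df, "tier": kw.tier,
                },
                "dunn": [
                    {"pair": r.extra["pair"], "z": None if np.isnan(r.statistic) else r.statistic,
                     "p": r.p_value, "adjusted_p": r.adjusted_p, "tier": r.tier}
                    for r in dunn
                ],
            }
            with open(out / "stats" / f"{feature}.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)

    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "T_ms": cfg.T_ms,
        "eq2_constant": cfg.eq2_constant,
        "features": list(cfg.features),
        "classifiers": list(cfg.classifiers),
        "n_subjects": int(len(markers)),
        "failed_subjects": failed,
        "preprocess": {
            "target_fs": cfg.preprocess.target_fs,
            "bp": [cfg.preprocess.bp_lo, cfg.preprocess.bp_hi],
            "notch_base": cfg.preprocess.notch_base,
            "notch_stop_bw": cfg.preprocess.notch_stop_bw,
            "filter_order": cfg.preprocess.filter_order,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
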