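"""End-to-end identification pipeline and its run report.

Denoise -> delineate -> featurise -> (optionally IPSO-tune) -> train the
one-vs-one SVM -> evaluate on held-out beats.  The report carries per-subject
accuracies together with the cohort summary triple: the maximum and minimum
individual accuracy and the total accuracy over all test beats.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .denoise import DenoiseConfig, wt_ukf_denoise
from .features import Dataset, FeatureVector, extract_features, split_dataset
from .fiducials import DetectorConfig, detect_p_t_waves, detect_r_peaks
from .ipso import SwarmConfig, optimize
from .svm import OVOModel, SVMConfig, cross_validate, predict_ovo, train_ovo
from .synthetic import NoiseSpec, SyntheticRecord, generate_cohort

__all__ = ["PipelineConfig", "PipelineReport", "extract_cohort_features", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable via ``asdict``."""

    n_subjects: int = 10
    beats_per_subject: int = 150
    fs: float = 360.0
    train_fraction: float = 0.7
    tune: bool = True
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    # tuning swarm; scaled below the reference 20 x 50 so a full run stays
    # interactive — the full-size schedule is one replace() away
    swarm: SwarmConfig = field(default_factory=lambda: SwarmConfig(n_particles=8, max_iter=10))
    cv_folds: int = 3

    def to_dict(self) -> dict:
        return _config_dict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .fiducials import DetectorConfig
        from .svm import SVMConfig
        from .ukf import UKFConfig
        from .wavelet import WaveletSpec

        d = dict(d)
        d["noise"] = NoiseSpec(**d.get("noise", {}))
        den = dict(d.get("denoise", {}))
        if den:
            den["spec"] = WaveletSpec(**den.get("spec", {}))
            den["ukf"] = UKFConfig(**den.get("ukf", {}))
            for key in ("zero_approx_scales", "zero_detail_scales", "ukf_detail_scales"):
                if key in den:
                    den[key] = frozenset(den[key])
            d["denoise"] = DenoiseConfig(**den)
        det = dict(d.get("detector", {}))
        if det:
            for key in ("p_search", "t_search"):
                if key in det:
                    det[key] = tuple(det[key])
            d["detector"] = DetectorConfig(**det)
        d["svm"] = SVMConfig(**d.get("svm", {}))
        swarm = dict(d.get("swarm", {}))
        if swarm:
            if "bounds" in swarm:
                swarm["bounds"] = tuple(tuple(b) for b in swarm["bounds"])
            if swarm.get("init_position") is not None:
                swarm["init_position"] = tuple(swarm["init_position"])
            d["swarm"] = SwarmConfig(**swarm)
        return cls(**d)


@dataclass
class PipelineReport:
    """Per-subject accuracies, summary accuracies and provenance."""

    per_subject_accuracy: dict[int, float]
    accuracy_max: float
    accuracy_min: float
    accuracy_total: float
    chosen_c: float
    chosen_g: float
    cv_fitness: float | None
    n_train: int
    n_test: int
    beats_delineated: int
    beats_total: int
    stage_seconds: dict[str, float]
    config: dict

    def summary(self) -> str:
        lines = [
            f"subjects: {len(self.per_subject_accuracy)}",
            f"beats delineated: {self.beats_delineated}/{self.beats_total}",
            f"(c, g) = ({self.chosen_c:.3f}, {self.chosen_g:.4f})",
            f"Accuracy_max   = {100 * self.accuracy_max:.2f}%",
            f"Accuracy_min   = {100 * self.accuracy_min:.2f}%",
            f"Accuracy_total = {100 * self.accuracy_total:.2f}%",
        ]
        return "\n".join(lines)


def extract_cohort_features(
    records: list[SyntheticRecord],
    denoise: DenoiseConfig | None = None,
    detector: DetectorConfig | None = None,
) -> tuple[list[FeatureVector], int, int]:
    """Denoise, delineate and featurise every record.

    Returns (features, beats delineated, beats total).
    """
    feats: list[FeatureVector] = []
    n_del = 0
    n_tot = 0
    for rec in records:
        den = wt_ukf_denoise(rec.samples, rec.fs, denoise).denoised
        r_peaks = detect_r_peaks(den, rec.fs, detector)
        fids = detect_p_t_waves(den, rec.fs, r_peaks, detector)
        n_del += len(fids)
        n_tot += len(rec.fiducials)
        feats.extend(extract_features(fids, rec.fs, subject=rec.subject_id))
    return feats, n_del, n_tot


def _evaluate(model: OVOModel, ds: Dataset) -> tuple[dict[int, float], float]:
    pred = predict_ovo(model, ds.X_test)
    per_subject: dict[int, float] = {}
    for cls in np.unique(ds.y_test):
        rows = ds.y_test == cls
        per_subject[int(cls)] = float(np.mean(pred[rows] == cls))
    total = float(np.mean(pred == ds.y_test))
    return per_subject, total


def run_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full identification experiment on a synthetic cohort."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    records = generate_cohort(
        config.n_subjects,
        config.beats_per_subject,
        fs=config.fs,
        noise=config.noise,
        seed=config.seed,
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    feats, n_del, n_tot = extract_cohort_features(records, config.denoise, config.detector)
    timings["features"] = time.perf_counter() - t0

    ds = split_dataset(feats, train_fraction=config.train_fraction, seed=config.seed)

    cv_fitness: float | None = None
    svm_config = config.svm
    t0 = time.perf_counter()
    if config.tune:
        def fitness(c: float, g: float) -> float:
            return cross_validate(
                ds.X_train,
                ds.y_train,
                folds=config.cv_folds,
                config=replace(svm_config, c=c, g=g),
                seed=config.seed,
            )

        swarm = replace(config.swarm, seed=config.seed)
        best_c, best_g, cv_fitness, _ = optimize(fitness, swarm)
        svm_config = replace(svm_config, c=best_c, g=best_g)
    timings["tune"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = train_ovo(ds, svm_config)
    per_subject, total = _evaluate(model, ds)
    timings["train_eval"] = time.perf_counter() - t0

    return PipelineReport(
        per_subject_accuracy=per_subject,
        accuracy_max=max(per_subject.values()),
        accuracy_min=min(per_subject.values()),
        accuracy_total=total,
        chosen_c=svm_config.c,
        chosen_g=svm_config.g,
        cv_fitness=cv_fitness,
        n_train=len(ds.y_train),
        n_test=len(ds.y_test),
        beats_delineated=n_del,
        beats_total=n_tot,
        stage_seconds=timings,
        config=_config_dict(config),
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    # frozensets are not JSON-serialisable
    for key in ("zero_approx_scales", "zero_detail_scales", "ukf_detail_scales"):
        d["denoise"][key] = sorted(d["denoise"][key])
    for key in ("p_search", "t_search"):
        d["detector"][key] = list(d["detector"][key])
    d["swarm"]["bounds"] = [list(b) for b in d["swarm"]["bounds"]]
    if d["swarm"]["init_position"] is not None:
        d["swarm"]["init_position"] = list(d["swarm"]["init_position"])
    return d
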