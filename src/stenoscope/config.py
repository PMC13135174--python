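"""YAML run configuration.

A config file is a nested mapping with any of the sections below; every
key is optional and falls back to the package default::

    seed: 0
    preprocess: {target_fs: 2000, wavelet: sym3, levels: 3, threshold_mode: soft}
    ewt:        {boundaries_hz: [150, 500], tau_over_pi: 0.1, nfft: 1024}
    cohort:     {groups: [[0,0,10], ...], n_cycles: 14, n_keep: 10}
    sim:        {noise_snr_db: 50, murmur_gain_scale: 0.04, ...}
    segmentation: {use_r_times: true}
    classify:   {train_n: 60, test_n: 15, test_counts: {mild: 5, moderate: 4, severe: 6},
                 fast_grids: false, models: [svm, gbm]}
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from .classify import GBM_GRID_FAST, SVM_GRID_FAST, PipelineConfig
from .preprocess import DenoiseParams
from .synth import SimParams


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw or {})
    cfg = PipelineConfig(seed=int(raw.get("seed", 0)))

    pre = raw.get("preprocess", {})
    cfg.target_fs = float(pre.get("target_fs", cfg.target_fs))
    cfg.denoise = DenoiseParams(
        wavelet_name=pre.get("wavelet", "sym3"),
        levels=int(pre.get("levels", 3)),
        threshold_mode=pre.get("threshold_mode", "soft"),
    )

    ewt = raw.get("ewt", {})
    cfg.boundaries_hz = tuple(ewt.get("boundaries_hz", cfg.boundaries_hz))
    cfg.tau_over_pi = float(ewt.get("tau_over_pi", cfg.tau_over_pi))
    cfg.nfft = int(ewt.get("nfft", cfg.nfft))

    cohort = raw.get("cohort", {})
    if "groups" in cohort:
        cfg.cohort_groups = tuple(tuple(g) for g in cohort["groups"])
    cfg.n_cycles = int(cohort.get("n_cycles", cfg.n_cycles))
    cfg.n_keep = int(cohort.get("n_keep", cfg.n_keep))

    sim = raw.get("sim", {})
    if sim:
        cfg.sim_params = SimParams(**sim)

    segmentation = raw.get("segmentation", {})
    cfg.use_r_times = bool(segmentation.get("use_r_times", cfg.use_r_times))

    cls = raw.get("classify", {})
    cfg.train_n = int(cls.get("train_n", cfg.train_n))
    cfg.test_n = int(cls.get("test_n", cfg.test_n))
    cfg.cv_splits = int(cls.get("cv_splits", cfg.cv_splits))
    if cls.get("test_counts"):
        cfg.test_counts = {k: int(v) for k, v in cls["test_counts"].items()}
    if cls.get("models"):
        cfg.models = tuple(cls["models"])
    if cls.get("fast_grids"):
        cfg.svm_grid = dict(SVM_GRID_FAST)
        cfg.gbm_grid = dict(GBM_GRID_FAST)
    if cls.get("svm_grid"):
        cfg.svm_grid = dict(cls["svm_grid"])
    if cls.get("gbm_grid"):
        cfg.gbm_grid = dict(cls["gbm_grid"])
    return cfg


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
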