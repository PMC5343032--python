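"""Benchmark orchestration: traits × stages × environment sets × methods.

Produces the long-format comparison table — one row per (trait, trait stage,
spectra stage, environment set, method, metric) — covering spectral-index
screening, the four regressors, and the three classifiers, with reproducible
per-cell seeds derived from one master seed.  Environment sets are the two
hydric regimes alone (WS, FI) and pooled (WS+FI).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .classification import CLASSIFIER_FITTERS, dichotomize
from .errors import ConfigError
from .evaluation import (classification_metrics, make_folds,
                         regression_metrics, screen_indices)
from .indices import builtin_registry, compute_all
from .preprocess import preprocess
from .regression import FAMILY_FITTERS, predict
from .spectra_io import (DEFAULT_NOISE_REGIONS, SpectraMatrix, TraitTable,
                         align, trim_noise_bands)

logger = logging.getLogger(__name__)

#: measurable (trait, trait_stage) pairs and the environments they exist in —
#: encoded as data: LAI is measured at anthesis under irrigation only.
TRAIT_VALIDITY: dict[tuple[str, str], tuple[str, ...]] = {
    ("SM2", "m"): ("FI", "WS"), ("KPS", "m"): ("FI", "WS"),
    ("TKW", "m"): ("FI", "WS"), ("GY", "m"): ("FI", "WS"),
    ("Chl", "an"): ("FI", "WS"), ("Chl", "gf"): ("FI", "WS"),
    ("WSC", "an"): ("FI", "WS"), ("WSC", "m"): ("FI", "WS"),
    ("WSCC", "an"): ("FI", "WS"), ("WSCC", "m"): ("FI", "WS"),
    ("D13C", "m"): ("FI", "WS"), ("LAI", "an"): ("FI",),
}

ENVIRONMENT_SETS = {"WS": ("WS",), "FI": ("FI",), "WS+FI": ("WS", "FI")}

REGRESSION_METHODS = ("PCR", "PLSR", "RR", "SVR")
CLASSIFICATION_METHODS = ("PCA_LDA", "PLS_DA", "KNN")
ALL_METHODS = ("SRI",) + REGRESSION_METHODS + CLASSIFICATION_METHODS


@dataclass
class BenchmarkConfig:
    """What to run and under which seeds/sizes."""

    traits: list = field(default_factory=lambda: [("GY", "m")])
    spectra_stages: list = field(default_factory=lambda: ["AN", "GF"])
    environment_sets: list = field(default_factory=lambda: ["WS", "FI", "WS+FI"])
    methods: list = field(default_factory=lambda: list(ALL_METHODS))
    fraction: float = 0.8          # elite dichotomization cut
    cv_folds: int = 10
    master_seed: int = 0
    noise_regions: tuple = DEFAULT_NOISE_REGIONS
    band_step: int = 1             # keep every band_step-th wavelength
    lof_threshold: float = 1.5

    def validate(self) -> None:
        if not self.traits or not self.methods:
            raise ConfigError("empty trait or method selection")
        for pair in self.traits:
            if tuple(pair) not in TRAIT_VALIDITY:
                raise ConfigError(f"unmeasurable trait/stage pair {pair}")
        for env in self.environment_sets:
            if env not in ENVIRONMENT_SETS:
                raise ConfigError(f"unknown environment set {env!r}")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ConfigError(f"unknown method {m!r}")


def cell_seed(master_seed: int, *coordinates) -> int:
    """Stable per-cell seed from the master seed and cell coordinates.

    Method name is deliberately excluded by callers that want shared folds
    across methods.  CRC32-based, bounded below 2^31.
    """
    key = ":".join([str(master_seed), *map(str, coordinates)])
    return zlib.crc32(key.encode()) % (2 ** 31 - 1)


def _prepare_cell(spectra, traits, trait, tstage, sstage, envs, config):
    """Trim, subsample, align and preprocess one modeling dataset."""
    trimmed = trim_noise_bands(spectra, config.noise_regions)
    if config.band_step > 1:
        # thin the grid but keep every band a registry index refers to, so
        # SRI screening is never starved by the stride
        grid = set(trimmed.wavelengths.tolist())
        referenced = {nm for d in builtin_registry() for nm in d.wavelengths}
        keep = sorted(set(trimmed.wavelengths[::config.band_step].tolist())
                      | (referenced & grid))
        trimmed = SpectraMatrix(meta=trimmed.meta.copy(),
                                reflectance=trimmed.reflectance.loc[:, keep].copy())
    env_mask = trimmed.meta["environment"].isin(envs).to_numpy()
    sub = trimmed.select(env_mask)
    y_all = traits.get(trait, tstage)
    X, y = align(sub, y_all, stage=sstage)
    X, y, report = preprocess(X, y, lof_threshold=config.lof_threshold)
    return X, y, report


def run_cell(X: pd.DataFrame, y: pd.Series, method: str, seed: int,
             config: BenchmarkConfig, folds=None,
             fold_seed: int | None = None) -> list[dict]:
    """Evaluate one method on one prepared dataset; returns metric rows."""
    rows = []
    if method == "SRI":
        m = SpectraMatrix(
            meta=pd.DataFrame(
                {"genotype_id": "", "environment": "", "stage": ""},
                index=X.index),
            reflectance=X)
        table = compute_all(m, builtin_registry())
        ranked = screen_indices(table, y)
        best = ranked.iloc[0]
        rows.append({"metric": "best_sri", "value": best["index"]})
        rows.append({"metric": "r2", "value": float(best["r2"])})
        rows.append({"metric": "rmse", "value": float(best["rmse"])})
        return rows

    if method in FAMILY_FITTERS:
        fit = FAMILY_FITTERS[method](X, y, seed=seed, folds=folds)
        val = regression_metrics(y, fit.cv_predictions)
        cal = regression_metrics(y, predict(fit, X))
        for k, v in val.to_dict().items():
            rows.append({"metric": f"{k}_val", "value": v})
        for k, v in cal.to_dict().items():
            rows.append({"metric": f"{k}_cal", "value": v})
        rows.append({"metric": "selected",
                     "value": json.dumps(fit.selected)})
        return rows

    if method in CLASSIFIER_FITTERS:
        labeling = dichotomize(y, config.fraction)
        labels = labeling.labels.loc[X.index]
        # one stratified fold assignment per cell, shared by all classifiers
        cls_folds = make_folds(len(X), config.cv_folds,
                               fold_seed if fold_seed is not None else seed,
                               stratify_labels=labels)
        fit = CLASSIFIER_FITTERS[method](X, labels, seed=seed, folds=cls_folds)
        val = classification_metrics(labels, fit.cv_predictions)
        for k, v in val.to_dict().items():
            if k == "confusion":
                continue
            rows.append({"metric": f"{k}_val", "value": v})
        rows.append({"metric": "threshold", "value": labeling.threshold})
        rows.append({"metric": "selected", "value": json.dumps(fit.selected)})
        return rows

    raise ConfigError(f"unknown method {method!r}")  # pragma: no cover


def run_benchmark(spectra: SpectraMatrix, traits: TraitTable,
                  config: BenchmarkConfig | None = None):
    """Run the full comparison; returns (results DataFrame, manifest dict).

    A failing cell is recorded with status ``failed`` and its error message;
    other cells are unaffected.  Folds are shared across methods within a
    cell coordinate so the comparison is paired.
    """
    config = config or BenchmarkConfig()
    config.validate()
    rows = []
    manifest = {"version": __version__, "master_seed": config.master_seed,
                "config": {
                    "traits": [list(t) for t in config.traits],
                    "spectra_stages": list(config.spectra_stages),
                    "environment_sets": list(config.environment_sets),
                    "methods": list(config.methods),
                    "fraction": config.fraction,
                    "cv_folds": config.cv_folds,
                    "band_step": config.band_step,
                    "noise_regions": [list(r) for r in config.noise_regions],
                },
                "cells": []}
    for trait, tstage in (tuple(t) for t in config.traits):
        valid_envs = set(TRAIT_VALIDITY[(trait, tstage)])
        for sstage in config.spectra_stages:
            for env_name in config.environment_sets:
                envs = ENVIRONMENT_SETS[env_name]
                if not set(envs) <= valid_envs:
                    continue  # e.g. LAI outside FI
                coord = (trait, tstage, sstage, env_name)
                fold_seed = cell_seed(config.master_seed, *coord, "folds")
                try:
                    X, y, report = _prepare_cell(
                        spectra, traits, trait, tstage, sstage, envs, config)
                    folds_reg = make_folds(len(X), config.cv_folds, fold_seed)
                except Exception as exc:  # noqa: BLE001 - isolate cells
                    for method in config.methods:
                        rows.append(dict(zip(
                            ("trait", "trait_stage", "spectra_stage",
                             "environment", "method", "metric", "value"),
                            (*coord, method, "status", f"failed: {exc}"))))
                    continue
                manifest["cells"].append({
                    "coordinates": list(coord), "n": len(X),
                    "fold_seed": fold_seed,
                    "preprocess": report.to_dict()})
                for method in config.methods:
                    seed = cell_seed(config.master_seed, *coord, method)
                    base = {"trait": trait, "trait_stage": tstage,
                            "spectra_stage": sstage, "environment": env_name,
                            "method": method}
                    try:
                        folds = folds_reg if method in FAMILY_FITTERS else None
                        for row in run_cell(X, y, method, seed, config, folds,
                                            fold_seed=fold_seed):
                            rows.append({**base, **row})
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("cell %s/%s failed: %s", coord, method, exc)
                        rows.append({**base, "metric": "status",
                                     "value": f"failed: {exc}"})
    results = pd.DataFrame(
        rows, columns=["trait", "trait_stage", "spectra_stage", "environment",
                       "method", "metric", "value"])
    return results, manifest
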