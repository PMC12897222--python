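"""Configuration-driven experiment grid.

Runs every combination of preprocessing x selector x classifier on a
dataset (synthetic config, spectra CSV, or an ENVI cube set), with the
leakage-safe protocol: Kennard-Stone split first, then preprocessing
statistics fitted on the training rows only, then wavelength selection
on the (preprocessed) training rows only, then classifier tuning by
5-fold CV inside the training set, and a single final evaluation on the
untouched test rows.

Every artifact embeds a hash of the configuration so result tables from
different runs cannot be merged silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, evaluate, confusion_table, \
    kennard_stone_split, tune_and_train, _report_from_predictions
from .core import ParameterError, SpectraMatrix
from .preprocess import Preprocessor, PreprocessSpec
from .select import run_selector
from .synth import SynthConfig, generate_spectra

log = logging.getLogger(__name__)

RESULT_COLUMNS = ("preprocess", "selector", "classifier", "n_bands",
                  "train_acc", "test_acc", "f1", "kappa", "status")


@dataclass
class ExperimentConfig:
    """One experimental grid: data source and the three method axes."""

    data_csv: Optional[str] = None
    synth: Optional[dict] = None
    preprocess: Sequence[str] = ("msc",)
    selectors: Sequence[str] = ("cars",)
    classifiers: Sequence[str] = ("svm_rbf",)
    selector_params: dict = field(default_factory=dict)
    split_ratio: float = 0.7
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if (self.data_csv is None) == (self.synth is None):
            raise ParameterError(
                "config needs exactly one of data_csv or synth")
        for axis, name in ((self.preprocess, "preprocess"),
                           (self.selectors, "selectors"),
                           (self.classifiers, "classifiers")):
            if not axis:
                raise ParameterError(f"config axis '{name}' is empty")
        if not 0 < self.split_ratio < 1:
            raise ParameterError("split_ratio must be in (0, 1)")

    def to_dict(self) -> dict:
        return {"data_csv": self.data_csv, "synth": self.synth,
                "preprocess": list(self.preprocess),
                "selectors": list(self.selectors),
                "classifiers": list(self.classifiers),
                "selector_params": self.selector_params,
                "split_ratio": self.split_ratio, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_dataset(cfg: ExperimentConfig) -> SpectraMatrix:
    if cfg.data_csv is not None:
        data = SpectraMatrix.from_csv(cfg.data_csv)
    else:
        synth_cfg = SynthConfig.from_dict(cfg.synth)
        data, _ = generate_spectra(synth_cfg)
    if data.labels is None:
        raise ParameterError("dataset has no labels")
    return data


def _run_one(data: SpectraMatrix, pre_name: str, sel_name: str,
             clf_name: str, cfg: ExperimentConfig, out_dir: Optional[Path]):
    split = kennard_stone_split(data, ratio=cfg.split_ratio)
    train = data.subset_rows(split.train_idx)
    test = data.subset_rows(split.test_idx)

    pre = Preprocessor(PreprocessSpec(method=pre_name))
    Xtr = pre.fit(train).transform(train)
    Xte = pre.transform(test)

    if sel_name == "none":
        band_idx = np.arange(data.n_bands)
        selection = None
    else:
        params = dict(cfg.selector_params.get(sel_name, {}))
        selection = run_selector(sel_name, Xtr.X, train.labels,
                                 grid=data.grid, seed=cfg.seed, **params)
        band_idx = selection.selected
        if band_idx.size == 0:
            raise ParameterError(f"{sel_name} selected no bands")
    Xtr_b, Xte_b = Xtr.subset_bands(band_idx), Xte.subset_bands(band_idx)

    spec = ClassifierSpec(kind=clf_name, seed=cfg.seed)
    model = tune_and_train(Xtr_b, train.labels, spec)
    train_rep = _report_from_predictions(train.labels, model.predict(Xtr_b))
    test_rep = evaluate(model, Xte_b, test.labels)

    if out_dir is not None:
        tag = f"{pre_name}_{sel_name}_{clf_name}"
        if selection is not None:
            selection.to_json(out_dir / f"selection_{tag}.json")
        with open(out_dir / f"confusion_{tag}.json", "w") as fh:
            json.dump({"config_hash": cfg.config_hash(),
                       **confusion_table(test_rep),
                       "metrics": test_rep.to_dict()}, fh, indent=2)
    return {"preprocess": pre_name, "selector": sel_name,
            "classifier": clf_name, "n_bands": int(band_idx.size),
            "train_acc": train_rep.acc_pct, "test_acc": test_rep.acc_pct,
            "f1": test_rep.f1, "kappa": test_rep.kappa, "status": "ok"}


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid; one result row per combination.

    A failing combination is marked ``status='failed'`` and the grid
    continues.  The returned table carries the config hash in
    ``df.attrs`` and, when ``cfg.out_dir`` is set, is written to
    ``results.csv`` alongside selection/confusion artifacts.
    """
    data = load_dataset(cfg)
    out_dir = None
    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pre_name in cfg.preprocess:
        for sel_name in cfg.selectors:
            for clf_name in cfg.classifiers:
                try:
                    rows.append(_run_one(data, pre_name, sel_name, clf_name,
                                         cfg, out_dir))
                except Exception as e:  # noqa: BLE001 - grid robustness
                    log.error("combination %s/%s/%s failed: %s",
                              pre_name, sel_name, clf_name, e)
                    log.debug(traceback.format_exc())
                    rows.append({"preprocess": pre_name, "selector": sel_name,
                                 "classifier": clf_name, "n_bands": 0,
                                 "train_acc": np.nan, "test_acc": np.nan,
                                 "f1": np.nan, "kappa": np.nan,
                                 "status": "failed"})
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df.insert(0, "config_hash", cfg.config_hash())
    df.attrs["config_hash"] = cfg.config_hash()
    if out_dir is not None:
        df.to_csv(out_dir / "results.csv", index=False)
        with open(out_dir / "config.json", "w") as fh:
            json.dump({"hash": cfg.config_hash(), **cfg.to_dict()}, fh,
                      indent=2)
    return df


def summarize(result_csvs: Sequence) -> pd.DataFrame:
    """Merge result tables and report the best row per method combination.

    Refuses to merge tables produced under different configurations
    (mismatched config hashes).
    """
    frames = [pd.read_csv(p) for p in result_csvs]
    hashes = {str(f["config_hash"].iloc[0]) for f in frames if len(f)}
    if len(hashes) > 1:
        raise ParameterError(
            f"refusing to merge tables with different config hashes: {hashes}")
    merged = pd.concat(frames, ignore_index=True)
    ok = merged[merged["status"] == "ok"]
    return ok.sort_values("test_acc", ascending=False).reset_index(drop=True)
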