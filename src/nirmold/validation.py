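"""Model validation (Q², permutation test) and end-to-end pipeline orchestration.

The permutation test follows the SIMCA convention: the calibration R²Y and
the cross-validated Q² of the real model are compared against the same
quantities under label permutations; least-squares lines of R² and Q² versus
the absolute correlation between permuted and original labels (including the
original model at correlation 1) are extrapolated to correlation 0, and a
negative Q²-intercept indicates a model that is not a chance discrimination.

:func:`run_pipeline` wires the whole workflow together: generate or load
spectra → Kennard–Stone 2:1 split → per pretreatment branch: fit state on
calibration, transform every set, MCCV/Wold latent-variable selection, PLS-DA
fit → per selector branch: wavelength selection on calibration only, refit on
the reduced grid → confusion metrics on the test and independent-test sets,
with an optional permutation test per branch.  Everything is reproducible
from the config's master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectrumSet, classification_metrics, load_spectra
from .plsda import fit_plsda, predict_classes
from .pretreatment import METHODS, PretreatmentSpec, pretreat_sets
from .sampling import MCCVPlan, kennard_stone_split, select_latent_variables
from .selection import cars_select, mcuve_select, rt_select
from .simulate import GeneratorConfig, generate_dataset

__all__ = [
    "PermutationTestResult",
    "PipelineReport",
    "q2_cross_validation",
    "permutation_test",
    "run_pipeline",
    "DEFAULT_CONFIG",
]


def _cv_predictions(X, y, k, folds, rng):
    """Held-out predictions over random folds with both classes in every
    training part (bounded redraws)."""
    n = X.shape[0]
    folds = min(folds, n)
    if folds < 2:
        raise ValueError(f"need at least 2 folds, got {folds}")
    for _ in range(100):
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        if all(np.unique(y[np.setdiff1d(perm, part)]).size >= 2 for part in parts):
            break
    else:
        raise ValueError("could not build CV folds with both classes in training")
    pred = np.empty(n)
    for part in parts:
        train = np.setdiff1d(perm, part)
        k_eff = max(1, min(k, train.size - 1, X.shape[1]))
        model = fit_plsda(X[train], y[train], k_eff)
        pred[part] = (X[part] - model.x_mean) @ model.b + model.y_mean
    return pred


def q2_cross_validation(X, y, k: int, folds: int = 7, seed: int = 0) -> float:
    """Cross-validated explained variance Q² = 1 - PRESS / SS_tot."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response is constant; Q2 undefined")
    rng = np.random.default_rng(seed)
    pred = _cv_predictions(X, y, k, folds, rng)
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


@dataclass(frozen=True)
class PermutationTestResult:
    """Original vs permuted R²Y/Q² and the fitted-line intercepts."""

    r2_original: float
    q2_original: float
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    label_correlations: np.ndarray
    r2_intercept: float
    q2_intercept: float

    @property
    def valid(self) -> bool:
        """SIMCA-style validity: the Q² regression line crosses below zero."""
        return self.q2_intercept < 0.0


def _calibration_r2(X, y, k) -> float:
    model = fit_plsda(X, y, k)
    pred = (X - model.x_mean) @ model.b + model.y_mean
    return 1.0 - float(np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))


def permutation_test(X_cal, y_cal, k: int, n_perm: int = 200, folds: int = 7,
                     seed: int = 0) -> PermutationTestResult:
    """Label-permutation validation of a PLS-DA model at fixed k.

    For each of ``n_perm`` shuffles of the class labels the model is refitted
    and its calibration R²Y, cross-validated Q², and |corr| with the original
    labels recorded; lines of R² and Q² against correlation (original point
    included at correlation 1) give the reported intercepts.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    if n_perm < 20:
        raise ValueError(f"n_perm must be >= 20, got {n_perm}")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    k = max(1, min(k, X.shape[0] - 1, X.shape[1]))
    rng = np.random.default_rng(seed)
    r2_original = _calibration_r2(X, y, k)
    q2_original = q2_cross_validation(
        X, y, k, folds=folds, seed=int(rng.integers(2**31)))
    r2_perm = np.empty(n_perm)
    q2_perm = np.empty(n_perm)
    corr = np.empty(n_perm)
    y_c = y - y.mean()
    y_norm = float(np.sqrt(y_c @ y_c))
    for i in range(n_perm):
        y_p = rng.permutation(y)
        corr[i] = abs(float((y_p - y_p.mean()) @ y_c)) / y_norm**2
        r2_perm[i] = _calibration_r2(X, y_p, k)
        q2_perm[i] = q2_cross_validation(
            X, y_p, k, folds=folds, seed=int(rng.integers(2**31)))
    xs = np.append(corr, 1.0)
    r2_line = np.polyfit(xs, np.append(r2_perm, r2_original), 1)
    q2_line = np.polyfit(xs, np.append(q2_perm, q2_original), 1)
    return PermutationTestResult(
        r2_original=r2_original,
        q2_original=q2_original,
        r2_perm=r2_perm,
        q2_perm=q2_perm,
        label_correlations=corr,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
    )


# --------------------------------------------------------------------------
# pipeline orchestration
# --------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {},          # GeneratorConfig overrides; ignored when data.csv set
    "data": {},               # {"csv": path, "label_column": "label"} to load instead
    "independent": {"n_per_class": 100},  # fresh-seed batch; {} disables
    "split": {"calibration_fraction": 2.0 / 3.0},
    "model": {
        "k_max": 15,
        "wold_threshold": 0.95,
        "mccv": {"n_iterations": 100, "holdout_fraction": 0.25},
    },
    "pretreatments": list(METHODS),
    "selectors": ["none", "rt", "cars", "mcuve"],
    "selector_params": {
        "rt": {"n_perm": 1000, "alpha": 0.05},
        "cars": {"n_iterations": 50, "sampling_fraction": 0.8, "cv_folds": 5},
        "mcuve": {"n_runs": 500, "sampling_fraction": 0.8},
    },
    "validation": {"run": False, "n_perm": 200, "folds": 7},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class PipelineReport:
    """Tabular per-branch results plus the config that produced them."""

    records: list[dict]
    config: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(directory / "report.csv", index=False)
        payload = {"config": self.config, "records": self.records}
        (directory / "report.json").write_text(
            json.dumps(payload, indent=2, default=_json_default))

    def branch(self, pretreatment: str, selector: str) -> dict:
        for rec in self.records:
            if rec["pretreatment"] == pretreatment and rec["selector"] == selector:
                return rec
        raise KeyError(f"no branch ({pretreatment!r}, {selector!r}) in report")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _child_seeds(master: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _select(selector: str, X, y, k, params, seed):
    if selector == "rt":
        return rt_select(X, y, k, seed=seed, **params)
    if selector == "cars":
        return cars_select(X, y, k, seed=seed, **params)
    if selector == "mcuve":
        return mcuve_select(X, y, k, seed=seed, **params)
    raise ValueError(f"unknown selector {selector!r}")


def _metrics_fields(prefix: str, truth, predicted) -> dict:
    m = classification_metrics(truth, predicted)
    return {f"{prefix}_{key}": value for key, value in m.as_dict().items()}


def run_pipeline(config: dict | str | Path | None = None) -> PipelineReport:
    """Execute the full branch grid and return a :class:`PipelineReport`.

    ``config`` may be a dict of overrides to :data:`DEFAULT_CONFIG` or a path
    to a YAML file with the same structure.  Reruns with an identical config
    produce identical reports.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seeds = _child_seeds(int(cfg["seed"]), 8)
    (gen_seed, indep_seed, mccv_seed, rt_seed, cars_seed, mcuve_seed,
     perm_seed, _spare) = seeds

    if cfg["data"].get("csv"):
        pool = load_spectra(cfg["data"]["csv"],
                            cfg["data"].get("label_column", "label"))
        if pool.labels is None:
            raise ValueError("pipeline input CSV must carry a label column")
        independent = None
        if cfg["data"].get("independent_csv"):
            independent = load_spectra(cfg["data"]["independent_csv"],
                                       cfg["data"].get("label_column", "label"))
    else:
        gen_cfg = GeneratorConfig(**{**cfg["generator"], "seed": gen_seed})
        pool, _ = generate_dataset(gen_cfg)
        independent = None
        if cfg["independent"]:
            indep_cfg = GeneratorConfig(
                **{**cfg["generator"], **cfg["independent"], "seed": indep_seed})
            independent, _ = generate_dataset(indep_cfg)

    split = kennard_stone_split(pool.absorbance,
                                cfg["split"]["calibration_fraction"])
    cal = pool.subset(split.calibration_indices, role="calibration")
    test = pool.subset(split.test_indices, role="test")

    model_cfg = cfg["model"]
    plan = MCCVPlan(seed=mccv_seed, **model_cfg["mccv"])
    sel_seeds = {"rt": rt_seed, "cars": cars_seed, "mcuve": mcuve_seed}

    records = []
    for method in cfg["pretreatments"]:
        spec = PretreatmentSpec(method)
        others = [test] + ([independent] if independent is not None else [])
        (cal_t, *others_t), _state = pretreat_sets(spec, cal, *others)
        test_t = others_t[0]
        indep_t = others_t[1] if independent is not None else None

        lv = select_latent_variables(
            cal_t.absorbance, cal.labels, k_max=model_cfg["k_max"], plan=plan,
            threshold=model_cfg["wold_threshold"])

        for selector in cfg["selectors"]:
            record = {"pretreatment": spec.method, "selector": selector,
                      "n_calibration": cal.n_samples, "n_test": test.n_samples,
                      "n_independent":
                          0 if independent is None else independent.n_samples}
            if selector == "none":
                columns = np.arange(cal_t.n_wavelengths)
                k_fit = lv.chosen_k
                record["n_selected"] = int(columns.size)
            else:
                params = cfg["selector_params"].get(selector, {})
                result = _select(selector, cal_t.absorbance, cal.labels,
                                 lv.chosen_k, params, sel_seeds[selector])
                columns = result.selected_indices
                record["n_selected"] = result.n_selected
                if result.n_selected == 0:
                    record["k"] = 0
                    records.append(record)
                    continue
                if result.n_selected >= 2:
                    lv_red = select_latent_variables(
                        cal_t.absorbance[:, columns], cal.labels,
                        k_max=min(model_cfg["k_max"], result.n_selected),
                        plan=plan, threshold=model_cfg["wold_threshold"])
                    k_fit = lv_red.chosen_k
                else:
                    k_fit = 1
            model = fit_plsda(cal_t.absorbance[:, columns], cal.labels, k_fit)
            record["k"] = k_fit
            record.update(_metrics_fields(
                "test", test.labels,
                predict_classes(model, test_t.absorbance[:, columns])))
            if indep_t is not None:
                record.update(_metrics_fields(
                    "independent", independent.labels,
                    predict_classes(model, indep_t.absorbance[:, columns])))
            if cfg["validation"]["run"]:
                perm = permutation_test(
                    cal_t.absorbance[:, columns], cal.labels, k_fit,
                    n_perm=cfg["validation"]["n_perm"],
                    folds=cfg["validation"]["folds"], seed=perm_seed)
                record.update({
                    "r2_original": perm.r2_original,
                    "q2_original": perm.q2_original,
                    "r2_intercept": perm.r2_intercept,
                    "q2_intercept": perm.q2_intercept,
                    "permutation_valid": perm.valid,
                })
            records.append(record)
    return PipelineReport(records=records, config=cfg)
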