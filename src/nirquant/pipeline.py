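"""End-to-end calibration pipeline: pretreatment screening, SiPLS band
selection, rank screening, the final PLS model, the PLS-score-fed BP-ANN,
and evaluation on held-out data.

The fitted artifact is a :class:`CalibratedModel` bundling the frozen
pretreatment state, the wavenumber window, the PLS factorization and —
optionally — the neural net that reads the PLS scores.  Evaluation
always starts from raw spectra and pushes them through that frozen
pipeline; spectra that were preprocessed under a *different* fitted
state are refused, which is the leak guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import bpann, pls
from .evaluate import EvaluationReport, rmse
from .preprocess import FittedPretreatment, apply_pretreatments, parse_steps
from .spectra import ReferenceValues, SpectraSet, reference_table, select_range
from .synthetic import SyntheticConfig, simulate_dataset, split_dataset

__all__ = [
    "TABLE3_CHAINS",
    "CalibratedModel",
    "PipelineConfig",
    "PipelineResult",
    "calibrate",
    "evaluate_model",
    "screen_pretreatments",
    "run_pipeline",
]

# The pretreatment chains screened in the classical workflow this
# package reproduces (M4..M9 naming kept for the comparison table).
TABLE3_CHAINS: dict[str, str] = {
    "M4": "vn",
    "M5": "fd+sg:17",
    "M6": "sd+sg:17",
    "M7": "msc",
    "M8": "fd+vn+sg:17",
    "M9": "fd+msc+sg:17",
}


@dataclass
class CalibratedModel:
    """A frozen calibration pipeline: window -> pretreatment -> PLS [-> ANN]."""

    window: tuple[float, float]
    pretreatment: tuple
    state: FittedPretreatment
    pls_model: pls.PLSModel
    rank: int
    ann: bpann.ANNModel | None = None
    model_id: str = "pls"

    def _transform(self, spectra: SpectraSet) -> np.ndarray:
        if spectra.lineage is not None:
            if spectra.lineage != self.state.fingerprint():
                raise ValueError(
                    "spectra were preprocessed under a different fitted "
                    "state; pass raw spectra instead")
            windowed = select_range(spectra, *self.window)
            return windowed.absorbance
        windowed = select_range(spectra, *self.window)
        treated, _ = apply_pretreatments(windowed, self.pretreatment, self.state)
        return treated.absorbance

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        """Predict total content (mg/g) from raw spectra."""
        X = self._transform(spectra)
        if self.ann is None:
            return pls.pls_predict(self.pls_model, X, self.rank)
        scores = pls.pls_scores(self.pls_model, X, self.rank)
        return bpann.predict(self.ann, scores)

    def scores(self, spectra: SpectraSet) -> np.ndarray:
        return pls.pls_scores(self.pls_model, self._transform(spectra), self.rank)


def calibrate(cal_spectra: SpectraSet, y_cal: np.ndarray,
              window: tuple[float, float], pretreatment, rank: int,
              model_id: str = "pls") -> CalibratedModel:
    """Fit the frozen pipeline on calibration data at a fixed rank."""
    steps = parse_steps(pretreatment) if isinstance(pretreatment, str) \
        else tuple(pretreatment)
    windowed = select_range(cal_spectra, *window)
    treated, state = apply_pretreatments(windowed, steps)
    model = pls.fit_pls(treated.absorbance, np.asarray(y_cal, float), rank,
                        window=window, lineage=state.fingerprint())
    return CalibratedModel(window, steps, state, model, min(rank, model.rank),
                           model_id=model_id)


def evaluate_model(model: CalibratedModel, spectra: SpectraSet,
                   references: Sequence[ReferenceValues], context: str,
                   reference_sd: float, target: str = "total"
                   ) -> EvaluationReport:
    """Evaluate a frozen pipeline on a dataset; pure, never mutates."""
    y = reference_table(references, spectra.sample_ids, target)
    y_pred = model.predict(spectra)
    return EvaluationReport.from_predictions(
        model.model_id, context, y, y_pred, reference_sd,
        rank=model.rank,
        hidden_nodes=None if model.ann is None else model.ann.hidden_size)


def screen_pretreatments(cal_spectra: SpectraSet, y_cal: np.ndarray,
                         val_spectra: SpectraSet, y_val: np.ndarray,
                         chains: dict[str, str] | None = None,
                         A_max: int = 20) -> pd.DataFrame:
    """LOOCV + external validation for each pretreatment chain.

    Returns one row per chain with the RMSECV/R² (cross-validation) and
    RMSEP/R²/RPD (external validation) at the chain's best rank — the
    screening table of the classical workflow.
    """
    chains = dict(TABLE3_CHAINS) if chains is None else chains
    y_cal = np.asarray(y_cal, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    sd_cal = float(np.std(y_cal, ddof=1))
    rows = []
    for model_id, chain in chains.items():
        steps = parse_steps(chain)
        cv = pls.loocv_curve(cal_spectra, y_cal, A_max, steps)
        # external curve at each rank to pick the joint optimum
        treated, state = apply_pretreatments(cal_spectra, steps)
        val_t, _ = apply_pretreatments(val_spectra, steps, state)
        model = pls.fit_pls(treated.absorbance, y_cal, A_max)
        rmsep_curve = np.array([
            rmse(y_val, pls.pls_predict(model, val_t.absorbance, a))
            for a in range(1, model.rank + 1)])
        rank = pls.select_rank(cv.rmsecv[1:model.rank + 1], rmsep_curve)
        yhat = pls.pls_predict(model, val_t.absorbance, rank)
        rows.append({
            "model": model_id,
            "pretreatment": chain,
            "rmsecv": cv.rmsecv[rank],
            "r2_cv": cv.r2[rank],
            "rmsep": rmse(y_val, yhat),
            "r2_val": 100.0 * (1 - ((yhat - y_val) ** 2).sum()
                               / ((y_val - y_val.mean()) ** 2).sum()),
            "rpd": sd_cal / rmse(y_val, yhat),
            "rank": rank,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full driver.

    Either supply a :class:`SyntheticConfig` or pre-loaded data via
    ``run_pipeline(..., data=...)``.  ``target`` selects the regression
    target among oa / ua / total.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    target: str = "total"
    window: tuple[float, float] = (4000.0, 9000.0)
    pretreatment_chains: tuple = tuple(TABLE3_CHAINS.items())
    n_intervals: int = 5
    A_max: int = 20
    hidden_candidates: tuple = (2, 3, 4, 6, 8, 10)
    ann_config: bpann.TrainConfig = field(default_factory=bpann.TrainConfig)
    n_test: int = 32
    split_proportion: tuple = (2, 1)
    seed: int = 0
    screen_pretreatments: bool = True
    run_sipls: bool = True


@dataclass
class PipelineResult:
    """Everything the driver produces; frames mirror the screening tables."""

    pretreatment_table: pd.DataFrame | None
    sipls_best: pls.SiPLSRecord | None
    sipls_report: list
    rank: int
    rank_curve: pd.DataFrame
    hidden_nodes: int
    hidden_table: pd.DataFrame
    pls_cal_model: CalibratedModel
    ann_cal_model: CalibratedModel
    reports: list
    split: dict

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])


def run_pipeline(config: PipelineConfig, data=None) -> PipelineResult:
    """Execute the full calibration workflow.

    Stages: simulate (or accept) data; 2:1 calibration/validation split
    of the modeling samples with a held-out test set; pretreatment-chain
    screening; SiPLS interval search; rank selection; final PLS model;
    PLS-score BP-ANN with hidden-node screening; evaluation of both
    final models on the test set.  Every random draw derives from
    ``config.seed``.
    """
    if data is None:
        syn = replace(config.synthetic, seed=config.seed)
        spectra, references, _truth = simulate_dataset(syn)
    else:
        spectra, references = data

    n = spectra.n_samples
    n_test = min(config.n_test, n - 3)
    all_ids = list(spectra.sample_ids)
    modeling_ids, test_ids = all_ids[:n - n_test], all_ids[n - n_test:]
    cal_ids, val_ids = split_dataset(modeling_ids, config.split_proportion,
                                     seed=config.seed + 1)
    sets = {name: spectra.subset(ids) for name, ids in
            (("cal", cal_ids), ("val", val_ids), ("test", test_ids))}
    y = {name: reference_table(references, s.sample_ids, config.target)
         for name, s in sets.items()}
    sd_cal = float(np.std(y["cal"], ddof=1))

    windowed = {name: select_range(s, *config.window) for name, s in sets.items()}

    # stage 1: pretreatment screening (LOOCV + external validation)
    pre_table = None
    best_chain = "msc"
    if config.screen_pretreatments:
        try:
            pre_table = screen_pretreatments(
                windowed["cal"], y["cal"], windowed["val"], y["val"],
                dict(config.pretreatment_chains), config.A_max)
            best_chain = pre_table.loc[pre_table["rmsep"].idxmin(), "pretreatment"]
        except Exception as exc:  # pragma: no cover - stage naming contract
            raise RuntimeError(f"pretreatment screening failed: {exc}") from exc
    steps = parse_steps(best_chain)

    # stage 2: SiPLS band selection on the pretreated working window
    sipls_best, sipls_report = None, []
    if config.run_sipls:
        intervals = pls.divide_intervals(config.window, config.n_intervals)
        try:
            sipls_best, sipls_report = pls.sipls_search(
                windowed["cal"], y["cal"], intervals, config.A_max,
                windowed["val"], y["val"], steps)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"SiPLS search failed: {exc}") from exc
        band = sipls_best.bounds
    else:
        band = config.window

    # stage 3: rank screening on the selected band
    band_sets = {name: select_range(s, *band) for name, s in windowed.items()}
    cv = pls.loocv_curve(band_sets["cal"], y["cal"], config.A_max, steps)
    treated_cal, state = apply_pretreatments(band_sets["cal"], steps)
    val_treated, _ = apply_pretreatments(band_sets["val"], steps, state)
    full_model = pls.fit_pls(treated_cal.absorbance, y["cal"], config.A_max)
    rmsep_curve = np.array([
        rmse(y["val"], pls.pls_predict(full_model, val_treated.absorbance, a))
        for a in range(1, full_model.rank + 1)])
    rank = pls.select_rank(cv.rmsecv[1:full_model.rank + 1], rmsep_curve)
    rank_curve = pd.DataFrame({
        "rank": np.arange(1, full_model.rank + 1),
        "rmsecv": cv.rmsecv[1:full_model.rank + 1],
        "rmsep": rmsep_curve,
    })

    pls_cal = calibrate(sets["cal"], y["cal"], band, steps, rank,
                        model_id="pls")

    # stage 4: BP-ANN on the PLS scores, hidden nodes screened
    scores_cal = pls_cal.scores(sets["cal"])
    scores_val = pls_cal.scores(sets["val"])
    ann_config = replace(config.ann_config, seed=config.seed + 2)
    try:
        h_star, h_reports = bpann.screen_hidden_nodes(
            scores_cal, y["cal"], scores_val, y["val"],
            config.hidden_candidates, ann_config)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"hidden-node screening failed: {exc}") from exc
    hidden_table = pd.DataFrame([r.__dict__ for r in h_reports])
    ann = bpann.fit_ann(scores_cal, y["cal"], h_star, ann_config,
                        rng_branch=(999,))
    ann_cal = CalibratedModel(band, steps, state, pls_cal.pls_model, rank,
                              ann=ann, model_id="pls-bpann")

    # stage 5: evaluation on validation and test sets
    reports = []
    for model in (pls_cal, ann_cal):
        for context, name in (("external", "val"), ("test", "test")):
            y_pred = model.predict(sets[name])
            reports.append(EvaluationReport.from_predictions(
                model.model_id, context, y[name], y_pred, sd_cal,
                rank=rank,
                hidden_nodes=None if model.ann is None else h_star))

    return PipelineResult(
        pretreatment_table=pre_table,
        sipls_best=sipls_best,
        sipls_report=sipls_report,
        rank=rank,
        rank_curve=rank_curve,
        hidden_nodes=h_star,
        hidden_table=hidden_table,
        pls_cal_model=pls_cal,
        ann_cal_model=ann_cal,
        reports=reports,
        split={"cal": cal_ids, "val": val_ids, "test": test_ids},
    )
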