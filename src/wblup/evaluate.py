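"""Train/validation evaluation harness for genomic prediction methods.

Metrics, computed on the withheld validation set for each method:

* accuracy        ``cor(TD, ghat)`` (predictive ability),
* reliability     ``REL = accuracy^2 / h2``,
* mean-square error between predicted and observed TD (raw and standardized
  by the TD variance),
* slope of the OLS regression of TD on the predictions (values below 1
  indicate inflation of the prediction scale).

The heritability in the REL denominator is taken from the training-set REML
of the standardized GBLUP baseline, so all methods of a comparison share one
denominator. ``run_comparison`` wires every method in the package to a
simulated dataset bundle: fit on training individuals only, predict the
withheld generation, evaluate identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes import BayesrConfig, BslmmConfig, bayesr_sample, bslmm_sample, predict_from_posterior
from .gblup import Prediction, gblup_predict
from .grm import (GenotypeDesign, build_design, standardized_grm, vanraden_grm,
                  weighted_grm)
from .regionscan import ScanConfig, amblup_fit, bam_blup_regions, chunk_scan, form_regions
from .simdata import DatasetBundle
from .ssgblup import SsModelSpec, ssgblup_solve
from .varcomp import reml_fit
from .weighting import brpv_weights, iw_gblup, wpip_select, wpip_weights

__all__ = ["EvalMetrics", "ComparisonConfig", "evaluate_predictions", "run_comparison",
           "METHODS"]

METHODS = ("gblup", "gblup_std", "amblup", "bamblup", "bslmm", "bayesr",
           "wpip", "iw", "brpv", "ssgblup", "ssgblup_amblup")


@dataclass
class EvalMetrics:
    accuracy: float
    reliability: float
    mse: float
    mse_std: float
    slope: float
    n_val: int
    flag: str = ""

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "reliability": self.reliability,
                "mse": self.mse, "mse_std": self.mse_std, "slope": self.slope,
                "n_val": self.n_val, "flag": self.flag}


@dataclass
class ComparisonConfig:
    """Chain lengths and scan settings used by run_comparison."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    bslmm: BslmmConfig = field(default_factory=lambda: BslmmConfig(
        n_iter=3000, burn_in=1000, thin=5))
    bayesr: BayesrConfig = field(default_factory=lambda: BayesrConfig(
        n_iter=3000, burn_in=1000, thin=5))
    iw_iterations: int = 10
    reml_max_iter: int = 100


def evaluate_predictions(td_val: np.ndarray, ghat_val: np.ndarray,
                         h2: float) -> EvalMetrics:
    """Reliability / MSE / bias metrics on the validation set."""
    td = np.asarray(td_val, dtype=float)
    g = np.asarray(ghat_val, dtype=float)
    if td.size != g.size or td.size < 3:
        raise ValueError("need >= 3 paired validation records")
    if h2 <= 0:
        raise ValueError("h2 must be positive for reliability")
    flag = ""
    if np.var(g) == 0:
        acc, slope, flag = 0.0, np.nan, "zero-variance prediction"
    else:
        acc = float(np.corrcoef(td, g)[0, 1])
        slope = float(np.cov(td, g, bias=True)[0, 1] / np.var(g))
    mse = float(np.mean((td - g) ** 2))
    return EvalMetrics(accuracy=acc, reliability=acc ** 2 / h2, mse=mse,
                       mse_std=mse / float(np.var(td)), slope=slope,
                       n_val=td.size, flag=flag)


# ---------------------------------------------------------------------------
# method wiring
# ---------------------------------------------------------------------------

def _predict_single_kernel(y_tr, G, tr, va, design, max_iter) -> Prediction:
    fit = reml_fit(y_tr, [G.values[np.ix_(tr, tr)]], max_iter=max_iter)
    return gblup_predict(y_tr, [G], fit.vc, train_idx=tr, val_idx=va,
                         samples=design.samples)


class _TraitContext:
    """Shared per-trait state (design, split, baseline fit, posterior caches)."""

    def __init__(self, bundle: DatasetBundle, trait: str, cfg: ComparisonConfig,
                 seed: int):
        self.bundle = bundle
        self.trait = trait
        self.cfg = cfg
        self.seed = seed
        g = bundle.genotypes
        self.design: GenotypeDesign = build_design(g)
        ids = list(g.samples)
        index = {s: i for i, s in enumerate(ids)}
        self.tr = np.array([index[s] for s in bundle.train_ids if s in index])
        self.va = np.array([index[s] for s in bundle.val_ids if s in index])
        y_all = bundle.phenotypes.trait(trait)
        self.y_tr = y_all.reindex([ids[i] for i in self.tr]).to_numpy()
        self.td_val = y_all.reindex([ids[i] for i in self.va]).to_numpy()
        self.G_std = standardized_grm(self.design)
        self.fit_std = reml_fit(self.y_tr,
                                [self.G_std.values[np.ix_(self.tr, self.tr)]],
                                max_iter=cfg.reml_max_iter)
        self.h2_ref = max(self.fit_std.vc.h2, 1e-6)
        self._cache: dict = {}

    def bslmm_summary(self):
        if "bslmm" not in self._cache:
            cfg = replace(self.cfg.bslmm, seed=self.seed)
            self._cache["bslmm"] = bslmm_sample(self.y_tr, self.design, cfg,
                                                train_idx=self.tr)
        return self._cache["bslmm"]

    def bayesr_summary(self):
        if "bayesr" not in self._cache:
            cfg = replace(self.cfg.bayesr, seed=self.seed)
            self._cache["bayesr"] = bayesr_sample(self.y_tr, self.design, cfg,
                                                  train_idx=self.tr)
        return self._cache["bayesr"]

    def weighted_prediction(self, weights) -> Prediction:
        Gw = weighted_grm(self.design, weights)
        return _predict_single_kernel(self.y_tr, Gw, self.tr, self.va,
                                      self.design, self.cfg.reml_max_iter)

    # -- methods -----------------------------------------------------------
    def predict(self, method: str) -> Prediction:
        cfg = self.cfg
        if method == "gblup":
            return _predict_single_kernel(self.y_tr, vanraden_grm(self.design),
                                          self.tr, self.va, self.design,
                                          cfg.reml_max_iter)
        if method == "gblup_std":
            return gblup_predict(self.y_tr, [self.G_std], self.fit_std.vc,
                                 train_idx=self.tr, val_idx=self.va,
                                 samples=self.design.samples)
        if method in ("amblup", "bamblup"):
            scan_cfg = replace(cfg.scan, seed=self.seed)
            scan = chunk_scan(self.y_tr, self.design, scan_cfg, train_idx=self.tr)
            if method == "amblup":
                regions = form_regions(scan, scan_cfg, m=self.design.m)
            else:
                regions, _ = bam_blup_regions(self.y_tr, self.design, scan_cfg,
                                              train_idx=self.tr, scan=scan)
            fit, weights = amblup_fit(self.y_tr, self.design, regions,
                                      train_idx=self.tr,
                                      max_iter=cfg.reml_max_iter)
            self._cache[f"{method}_regions"] = regions
            self._cache[f"{method}_weights"] = weights
            return self.weighted_prediction(weights)
        if method == "bslmm":
            return predict_from_posterior(self.bslmm_summary(), self.design,
                                          train_idx=self.tr, val_idx=self.va)
        if method == "bayesr":
            return predict_from_posterior(self.bayesr_summary(), self.design,
                                          train_idx=self.tr, val_idx=self.va)
        if method == "wpip":
            sel = wpip_select(self.bslmm_summary(), snps=self.design.snps)
            res = wpip_weights(self.y_tr, self.design, sel, train_idx=self.tr,
                               max_iter=cfg.reml_max_iter)
            self._cache["wpip_weights"] = res
            return self.weighted_prediction(res.weights)
        if method == "iw":
            res = iw_gblup(self.y_tr, self.design, train_idx=self.tr,
                           n_iter=cfg.iw_iterations,
                           max_reml_iter=cfg.reml_max_iter)
            return self.weighted_prediction(res.weights)
        if method == "brpv":
            res = brpv_weights(self.bayesr_summary())
            return self.weighted_prediction(res.weights)
        raise ValueError(f"unknown method: {method}")

    def predict_ssgblup(self, method: str) -> np.ndarray:
        """ssGBLUP EBVs for the validation individuals (pedigree + records
        of all non-validation phenotyped individuals, genotyped or not)."""
        bundle = self.bundle
        y_all = bundle.phenotypes.trait(self.trait)
        val_set = set(bundle.val_ids)
        rec_ids = [i for i in y_all.index if i not in val_set]
        y_rec = y_all.reindex(rec_ids).to_numpy()
        if method == "ssgblup":
            G = self.G_std
        elif method == "ssgblup_amblup":
            if "amblup_weights" not in self._cache:
                self.predict("amblup")
            G = weighted_grm(self.design, self._cache["amblup_weights"])
        else:
            raise ValueError(f"unknown single-step method: {method}")
        vc = self.fit_std.vc
        spec = SsModelSpec(sigma2_g=max(vc.sigma2_T, 1e-8),
                           sigma2_e=max(vc.sigma2_e, 1e-8))
        ebv, _ = ssgblup_solve(y_rec, rec_ids, bundle.pedigree, G, spec)
        return ebv.reindex(bundle.val_ids).to_numpy()

    def evaluate(self, method: str) -> EvalMetrics:
        if method.startswith("ssgblup"):
            ghat_val = self.predict_ssgblup(method)
        else:
            ghat_val = self.predict(method).ghat_val
        return evaluate_predictions(self.td_val, ghat_val, self.h2_ref)


def run_comparison(
    bundle: DatasetBundle,
    methods: list[str],
    traits: list[str] | None = None,
    cfg: ComparisonConfig | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Fit every requested method on the training split of every trait and
    evaluate on the withheld validation generation.

    Individual method failures are recorded (``flag`` column) and the
    comparison continues. Deterministic under ``seed``.
    """
    cfg = cfg or ComparisonConfig()
    traits = traits or [t.name for t in bundle.config.traits]
    rows = []
    for trait in traits:
        ctx = _TraitContext(bundle, trait, cfg, seed=seed)
        for method in methods:
            try:
                met = ctx.evaluate(method)
                rows.append({"method": method, "trait": trait, **met.as_dict(),
                             "h2_ref": ctx.h2_ref})
            except Exception as e:  # noqa: BLE001 - harness must keep going
                rows.append({"method": method, "trait": trait,
                             "accuracy": np.nan, "reliability": np.nan,
                             "mse": np.nan, "mse_std": np.nan, "slope": np.nan,
                             "n_val": 0, "flag": f"failed: {e}",
                             "h2_ref": np.nan})
    return pd.DataFrame(rows)
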