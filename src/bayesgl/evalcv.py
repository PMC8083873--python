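"""Cross-validation harness, prediction accuracy and bias metrics.

The default scheme is six-fold cross-validation repeated five times;
results aggregate as mean +/- standard error over the replicate means.
Accuracy is the Pearson correlation of the response with the direct
genomic value, divided -- when the response is a DRP with reliabilities
-- by the mean square-root reliability of the test animals:
``acc = cor(DRP, DGV) / rbar``.  Bias is the slope of the regression of
the response on the DGV; a slope of one means unbiased prediction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gblup as _gblup
from .chain_core import ChainConfig, ModelSpec, genomic_values, run_chain
from .genio import GenotypeMatrix, PhenotypeTable


# ---------------------------------------------------------------------------
# DRP reliability algebra
# ---------------------------------------------------------------------------

def heritability_lambda(h2: float) -> float:
    """lambda = (1 - h^2) / h^2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    return (1.0 - h2) / h2


def drp_reliability(erc, h2: float):
    """Reliability of a DRP: ERC / (ERC + lambda)."""
    erc = np.asarray(erc, dtype=float)
    if np.any(erc <= 0):
        raise ValueError("ERC must be positive")
    lam = heritability_lambda(h2)
    out = erc / (erc + lam)
    return float(out) if out.ndim == 0 else out


def erc_from_rel(rel, h2: float):
    """Effective record contribution from an EBV reliability:
    lambda * REL / (1 - REL)."""
    rel = np.asarray(rel, dtype=float)
    if np.any((rel <= 0) | (rel >= 1)):
        raise ValueError("REL must lie strictly inside (0, 1)")
    lam = heritability_lambda(h2)
    out = lam * rel / (1.0 - rel)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(y_test: np.ndarray, dgv: np.ndarray,
             reliability: np.ndarray | None = None) -> float:
    """cor(y, DGV), divided by mean sqrt reliability when DRPs are used."""
    y_test = np.asarray(y_test, dtype=float)
    dgv = np.asarray(dgv, dtype=float)
    if y_test.size != dgv.size or y_test.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(y_test) == 0 or np.std(dgv) == 0:
        raise ValueError("accuracy undefined: zero variance")
    r = float(np.corrcoef(y_test, dgv)[0, 1])
    if reliability is None:
        return r
    rbar = float(np.mean(np.sqrt(np.asarray(reliability, dtype=float))))
    return r / rbar


def bias(y_test: np.ndarray, dgv: np.ndarray) -> float:
    """Regression slope of the response on the DGV, cov(y, dgv)/var(dgv)."""
    y_test = np.asarray(y_test, dtype=float)
    dgv = np.asarray(dgv, dtype=float)
    v = float(np.var(dgv, ddof=1))
    if v <= 0:
        raise ValueError("bias undefined: DGV has zero variance")
    c = float(np.cov(y_test, dgv, ddof=1)[0, 1])
    return c / v


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_cv_folds(n: int, k: int = 6, reps: int = 5, seed: int = 0) -> list:
    """Per replicate, an independent random partition into k near-equal folds.

    Returns a list of ``reps`` lists of ``k`` index arrays.
    """
    if k < 2 or n < k:
        raise ValueError("need k >= 2 folds and n >= k individuals")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        perm = rng.permutation(n)
        out.append([np.sort(f) for f in np.array_split(perm, k)])
    return out


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Tidy per-fold metrics plus the replicate-level aggregation."""

    records: pd.DataFrame            # model, replicate, fold, accuracy, bias
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.summary is None:
            rep_means = (self.records
                         .groupby(["model", "replicate"])[["accuracy", "bias"]]
                         .mean().reset_index())
            agg = rep_means.groupby("model")[["accuracy", "bias"]].agg(["mean", "sem"])
            agg.columns = ["_".join(c) for c in agg.columns]
            self.summary = agg.rename(columns={
                "accuracy_mean": "accuracy", "accuracy_sem": "accuracy_se",
                "bias_mean": "bias", "bias_sem": "bias_se"}).reset_index()

    def write(self, records_path, summary_path=None):
        self.records.to_csv(records_path, index=False)
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False)


def _model_label(spec: ModelSpec) -> str:
    if spec.family == "bayesHE":
        return f"bayesHE(a={spec.a:g},b={spec.b:g})"
    if spec.family == "bayesB":
        return f"bayesB(pi={spec.pi:g})"
    return spec.family


def fit_predict(g: GenotypeMatrix, ph: PhenotypeTable, spec: ModelSpec,
                cfg: ChainConfig, train_idx, test_idx,
                reestimate_vc: bool = True) -> np.ndarray:
    """Fit one model on the training animals only and return test DGVs.

    Allele frequencies, genotype centering and (for GBLUP) variance
    components all come from the training data, so no information leaks
    from the test fold.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    g_train = GenotypeMatrix([g.individual_ids[i] for i in train_idx],
                             list(g.marker_ids), g.codes[train_idx])
    ph_train = ph.subset(train_idx)
    if spec.family == "gblup":
        grm_full = _gblup.build_grm(g, freqs=g_train.freqs)
        grm_train = _gblup.GRM(grm_full.matrix[np.ix_(train_idx, train_idx)],
                               grm_full.scale,
                               [g.individual_ids[i] for i in train_idx])
        if reestimate_vc:
            sg, se, _ = _gblup.estimate_vc_em(grm_train, ph_train)
        else:
            vy = float(np.var(ph_train.y, ddof=1))
            sg, se = 0.5 * vy, 0.5 * vy
        return _gblup.gblup_predict(grm_full, train_idx, test_idx, ph_train, sg, se)
    post = run_chain(g_train, ph_train, spec, cfg)
    g_test = GenotypeMatrix([g.individual_ids[i] for i in test_idx],
                            list(g.marker_ids), g.codes[test_idx])
    return genomic_values(g_test, post.beta_mean)


def cross_validate(g: GenotypeMatrix, ph: PhenotypeTable,
                   models: list[ModelSpec], cfg: ChainConfig,
                   folds: list | None = None, k: int = 6, reps: int = 5,
                   seed: int = 0, reestimate_vc: bool = True) -> CVResult:
    """Replicated k-fold cross-validation of a list of model specs."""
    if list(g.individual_ids) != list(ph.individual_ids):
        raise ValueError("genotype and phenotype ids must be aligned")
    n = g.n_individuals
    if folds is None:
        folds = make_cv_folds(n, k=k, reps=reps, seed=seed)
    rows = []
    for rep, rep_folds in enumerate(folds):
        test_sets = [np.asarray(f) for f in rep_folds]
        covered = np.concatenate(test_sets)
        if len(np.unique(covered)) != n or covered.size != n:
            raise ValueError("folds must partition the individuals exactly")
        for fold_i, test_idx in enumerate(test_sets):
            if test_idx.size < 3:
                raise ValueError("each test fold needs >= 3 individuals")
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            rel_test = (None if ph.reliability is None
                        else ph.reliability[test_idx])
            for spec in models:
                fold_cfg = ChainConfig(cfg.n_iter, cfg.burn_in, cfg.thin,
                                       seed=cfg.seed + 1009 * rep + fold_i)
                dgv = fit_predict(g, ph, spec, fold_cfg, train_idx, test_idx,
                                  reestimate_vc=reestimate_vc)
                rows.append({
                    "model": _model_label(spec), "replicate": rep, "fold": fold_i,
                    "accuracy": accuracy(ph.y[test_idx], dgv, rel_test),
                    "bias": bias(ph.y[test_idx], dgv),
                })
    return CVResult(pd.DataFrame(rows))
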