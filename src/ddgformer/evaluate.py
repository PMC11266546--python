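"""Evaluation metrics for ΔΔG predictors.

Regression metrics (Pearson, Spearman, RMSE) are complemented by the
classification metrics that matter for protein engineering: precision,
recall, AUROC and MCC for the *stabilizing* class.  A mutation is
experimentally stabilizing below -0.5 kcal/mol, neutral within
±0.5 kcal/mol and destabilizing above +0.5 kcal/mol (boundaries follow the
average experimental error; values exactly at ±0.5 are neutral).

Two classification thresholds are in common use — 0 kcal/mol and
-0.5 kcal/mol — so every report names the threshold it used.  For AUROC
the score of the stabilizing class is the *negated* prediction: more
negative predictions rank higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from ._tables import (AA_INDEX, AA_ORDER, HYDROPHOBIC_AAS, MAX_SASA,
                      POLAR_AAS, THREE_TO_ONE)

__all__ = ["MetricReport", "MutationTypeMatrix", "classify_ddg",
           "metric_suite", "threshold_sweep", "mutation_type_matrix",
           "rsa_analysis", "relative_solvent_accessibility"]

STABILIZING_CUTOFF = -0.5    # kcal/mol
NEUTRAL_BAND = 0.5
DEFAULT_RSA_BINS = (0.05, 0.25, 0.5, 1.0)


@dataclass
class MetricReport:
    pearson: float
    spearman: float
    rmse: float
    mcc: float | None
    auroc: float | None
    precision: float | None
    recall: float | None
    threshold: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MutationTypeMatrix:
    counts: np.ndarray            # (20, 20), rows = from, cols = to

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20, 20):
            raise ValueError("matrix must be 20 x 20")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be structurally zero")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def coverage(self) -> float:
        """Fraction of the 380 off-diagonal mutation types with data."""
        off = ~np.eye(20, dtype=bool)
        return float((self.counts[off] > 0).sum() / 380.0)

    def fractions(self) -> np.ndarray:
        return self.counts / self.total if self.total else self.counts


def classify_ddg(ddg: float) -> str:
    """stabilizing (< -0.5), neutral (|ΔΔG| <= 0.5) or destabilizing (> 0.5)."""
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    if ddg < -NEUTRAL_BAND:
        return "stabilizing"
    if ddg > NEUTRAL_BAND:
        return "destabilizing"
    return "neutral"


def metric_suite(predictions, experimental, threshold: float = 0.0
                 ) -> MetricReport:
    """Regression + stabilizing-class classification metrics.

    The binary label is ``experimental < threshold`` (stabilizing); the
    classifier score is the negated prediction.  With a single class in
    the labels, AUROC and MCC are reported as None (undefined), not 0.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(experimental, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predictions and experimental must be equal-length 1-D")
    if len(pred) < 2:
        raise ValueError("need at least two paired values")
    pearson = float(stats.pearsonr(pred, true).statistic)
    spearman = float(stats.spearmanr(pred, true).statistic)
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    y_true = true < threshold
    y_pred = pred < threshold
    if y_true.all() or (~y_true).all():
        auroc = mcc = None
    else:
        auroc = float(roc_auc_score(y_true, -pred))
        mcc = float(matthews_corrcoef(y_true, y_pred))
    tp = int((y_true & y_pred).sum())
    precision = tp / int(y_pred.sum()) if y_pred.any() else None
    recall = tp / int(y_true.sum()) if y_true.any() else None
    return MetricReport(pearson=pearson, spearman=spearman, rmse=rmse,
                        mcc=mcc, auroc=auroc, precision=precision,
                        recall=recall, threshold=threshold, n=len(pred))


def threshold_sweep(predictions, experimental, thresholds) -> pd.DataFrame:
    """Experimental composition of predictions below each threshold.

    For each τ the mutations with prediction < τ are selected; the report
    gives the fractions that are experimentally stabilizing / neutral /
    destabilizing (NaN when nothing is selected) and the recall of all
    experimental stabilizers.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(experimental, dtype=float)
    n_stab_total = int((true < STABILIZING_CUTOFF).sum())
    rows = []
    for tau in thresholds:
        sel = pred < tau
        n = int(sel.sum())
        if n:
            t = true[sel]
            stab = float((t < STABILIZING_CUTOFF).mean())
            neut = float((np.abs(t) <= NEUTRAL_BAND).mean())
            dest = float((t > NEUTRAL_BAND).mean())
            rec = (float((t < STABILIZING_CUTOFF).sum() / n_stab_total)
                   if n_stab_total else np.nan)
        else:
            stab = neut = dest = rec = np.nan
        rows.append((tau, n, stab, neut, dest, rec))
    return pd.DataFrame(rows, columns=["threshold", "n_selected",
                                       "frac_stabilizing", "frac_neutral",
                                       "frac_destabilizing",
                                       "recall_of_stabilizing"])


def mutation_type_matrix(records) -> MutationTypeMatrix:
    """Counts per ordered (from, to) mutation type.

    Accepts DdgRecord-like objects (``from_aa``/``to_aa``) or (from, to)
    pairs.
    """
    counts = np.zeros((20, 20))
    for r in records:
        fa, ta = (r.from_aa, r.to_aa) if hasattr(r, "from_aa") else tuple(r)
        if fa not in AA_INDEX or ta not in AA_INDEX:
            raise ValueError(f"invalid amino acid code in ({fa}, {ta})")
        if fa == ta:
            raise ValueError("self-mutations have no mutation type")
        counts[AA_INDEX[fa], AA_INDEX[ta]] += 1
    return MutationTypeMatrix(counts)


def relative_solvent_accessibility(residue_sasa: float, aa: str) -> float:
    """Residue SASA over the theoretical per-AA maximum, capped at 1."""
    if aa not in MAX_SASA:
        raise KeyError(f"unknown amino acid {aa!r}")
    return min(residue_sasa / MAX_SASA[aa], 1.0)


def rsa_analysis(predictions, experimental, wt_aas, rsa_values,
                 bins=DEFAULT_RSA_BINS, threshold: float = 0.0
                 ) -> pd.DataFrame:
    """Stabilizing precision/recall per RSA bin for polar vs hydrophobic.

    The wild-type residue's class decides membership: polar =
    {S,T,N,Q,D,E,R,K,H,Y}, hydrophobic = {L,M,I,V,F,W,A}; G, C and P belong
    to neither class and are excluded.  RSA bins are right-closed with
    edges ``bins`` (first bin starts at 0).
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(experimental, dtype=float)
    rsa = np.asarray(rsa_values, dtype=float)
    wt = np.asarray(list(wt_aas))
    edges = [0.0, *bins]
    rows = []
    for aa_class, members in (("polar", POLAR_AAS),
                              ("hydrophobic", HYDROPHOBIC_AAS)):
        in_class = np.array([a in members for a in wt])
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = in_class & (rsa > lo if lo > 0 else rsa >= 0) & (rsa <= hi)
            n = int(sel.sum())
            if n:
                y_true = true[sel] < threshold
                y_pred = pred[sel] < threshold
                tp = int((y_true & y_pred).sum())
                precision = tp / int(y_pred.sum()) if y_pred.any() else np.nan
                recall = tp / int(y_true.sum()) if y_true.any() else np.nan
            else:
                precision = recall = np.nan
            rows.append((aa_class, lo, hi, n, precision, recall))
    return pd.DataFrame(rows, columns=["aa_class", "rsa_lo", "rsa_hi", "n",
                                       "precision", "recall"])
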