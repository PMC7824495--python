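"""Evaluation metrics for normalization quality.

Six metrics score a (normalized) table: the per-feature WTR score
(within-batch over total variance of the QC replicates), pairwise QC
Spearman correlations, Spearman and R2 agreement with quantitative
concentrations for an evaluation metabolite set, and two PCA-based
prediction scores (how well a logistic model on the first PCs separates
QC from plasma samples, and how well it still predicts batch labels --
the latter should drop after good normalization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .core_io import FeatureTable

logger = logging.getLogger("metchalizer")


@dataclass
class EvaluationReport:
    """All six metric distributions plus their medians."""

    wtr: pd.Series
    qc_correlations: pd.Series
    spearman_scores: pd.Series | None
    r2_scores: pd.Series | None
    qc_prediction_score: float
    batch_prediction_score: float
    label: str = "None-Raw"

    @property
    def medians(self) -> dict:
        out = {
            "wtr": float(self.wtr.median()),
            "qc_correlation": float(self.qc_correlations.median()),
            "qc_prediction_score": self.qc_prediction_score,
            "batch_prediction_score": self.batch_prediction_score,
        }
        if self.spearman_scores is not None:
            out["spearman_score"] = float(self.spearman_scores.median())
        if self.r2_scores is not None:
            out["r2_score"] = float(self.r2_scores.median())
        return out


def wtr_score(
    table: FeatureTable,
    feature_ids: Sequence[str] | None = None,
    estimator: str = "pooled",
) -> pd.Series:
    """Within-batch over total variance ratio of the QC replicates, per feature.

    ``WTR = sigma_within^2 / sigma_tot^2`` where ``sigma_within^2`` is
    the pooled within-batch variance of the QC replicates and
    ``sigma_tot^2`` the (n-1) variance over all QC samples; a score near
    1 means batch means agree.  ``estimator='between'`` instead computes
    the equivalent ``(sigma_tot^2 - sigma_between^2) / sigma_tot^2`` with
    ``sigma_between^2`` the plain variance of the per-batch means (each
    batch weighted equally); that variant is biased low by the sampling
    noise of the batch means (by about ``1/m`` for ``m`` replicates per
    batch), which is why the pooled form is the default.  Clipped to
    [0, 1]; undefined (zero total variance) reported as NaN.
    """
    if estimator not in ("pooled", "between"):
        raise ValueError("estimator must be 'pooled' or 'between'")
    qc_ids = table.samples_of_class("qc")
    if len(qc_ids) < 4:
        raise ValueError("WTR requires QC replicates in >= 2 batches")
    feats = list(feature_ids) if feature_ids is not None else [
        f for f in table.feature_ids if f not in set(table.internal_standard_ids)
    ]
    values = table.abundance.loc[qc_ids, feats]
    batches = table.sample_meta.loc[qc_ids, "batch_id"]
    counts = batches.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("WTR requires >= 2 QC samples in >= 2 batches")

    total = values.var(axis=0, ddof=1)
    if estimator == "between":
        between = values.groupby(batches).mean().var(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            wtr = (total - between) / total
    else:
        grouped = values.groupby(batches)
        within_ss = grouped.apply(lambda g: ((g - g.mean()) ** 2).sum())
        df = sum(max(c - 1, 0) for c in counts)
        within = within_ss.sum(axis=0) / df
        with np.errstate(invalid="ignore", divide="ignore"):
            wtr = within / total
    wtr[total == 0] = np.nan
    return wtr.clip(lower=0.0, upper=1.0)


def qc_correlations(table: FeatureTable) -> pd.Series:
    """Spearman correlation over features for every unordered QC sample pair."""
    qc_ids = table.samples_of_class("qc")
    if len(qc_ids) < 2:
        raise ValueError("need >= 2 QC samples")
    feats = [f for f in table.feature_ids if f not in set(table.internal_standard_ids)]
    if len(feats) < 3:
        raise ValueError("need >= 3 features")
    sub = table.abundance.loc[qc_ids, feats]
    # rank once per sample, then Pearson on ranks == Spearman
    ranks = sub.rank(axis=1)
    out = {}
    for i in range(len(qc_ids)):
        for j in range(i + 1, len(qc_ids)):
            a, b = ranks.iloc[i], ranks.iloc[j]
            ok = a.notna() & b.notna()
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                rho = np.nan
            else:
                rho = float(np.corrcoef(a[ok], b[ok])[0, 1])
            out[(qc_ids[i], qc_ids[j])] = rho
    return pd.Series(out)


def quantitative_agreement(
    table: FeatureTable,
    concentrations: pd.DataFrame,
    mapping: Mapping[str, str],
) -> pd.DataFrame:
    """Spearman and R2 agreement with quantitative concentrations.

    ``concentrations`` is samples x metabolites in umol/L; ``mapping``
    links metabolite names to feature ids.  Per metabolite, only samples
    carrying both values are used; metabolites with fewer than 3 paired
    samples are skipped with a warning.  Returns a frame indexed by
    metabolite with columns ``spearman``, ``r2`` (clamped at 0) and
    ``r2_unclamped``.
    """
    rows = {}
    for metabolite, fid in mapping.items():
        if fid not in table.abundance.columns or metabolite not in concentrations.columns:
            logger.warning("quantitative_agreement: %s/%s not found; skipped", metabolite, fid)
            continue
        common = table.abundance.index.intersection(concentrations.index)
        y = table.abundance.loc[common, fid]
        x = concentrations.loc[common, metabolite]
        ok = y.notna() & x.notna()
        if ok.sum() < 3:
            logger.warning("quantitative_agreement: %s has < 3 paired samples; skipped", metabolite)
            continue
        xv, yv = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
        rho = float(stats.spearmanr(xv, yv).statistic)
        slope, intercept = np.polyfit(xv, yv, 1)
        resid = yv - (slope * xv + intercept)
        ss_tot = float(np.sum((yv - yv.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        rows[metabolite] = {"spearman": rho, "r2": max(r2, 0.0), "r2_unclamped": r2}
    return pd.DataFrame(rows).T


def prediction_scores(
    table: FeatureTable,
    n_pcs: int = 4,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """QC- and batch-prediction scores from a PCA + L1 logistic model.

    PCA (centred, unscaled) is fitted on all samples over all features
    excluding internal standards.  The QC score is the mean, over all
    samples, of the fitted probability of the sample's true class (QC vs
    plasma) from an L1-penalized logistic model on the first ``n_pcs``
    PCs.  The batch score fits one-vs-rest models per batch on the
    plasma samples and averages each plasma sample's fitted probability
    of its true batch; lower is better.
    """
    feats = [f for f in table.feature_ids if f not in set(table.internal_standard_ids)]
    X_df = table.abundance[feats].dropna(axis=1)
    if table.n_samples <= n_pcs:
        raise ValueError("need more samples than principal components")
    X = X_df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    classes = table.sample_meta["class"]
    is_qc = (classes == "qc").to_numpy()
    if is_qc.all() or not is_qc.any():
        raise ValueError("both QC and plasma samples are required")

    def _l1_logistic() -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=C, max_iter=10000, random_state=seed
        )

    model = _l1_logistic().fit(pcs, is_qc.astype(int))
    proba = model.predict_proba(pcs)
    qc_score = float(np.mean(proba[np.arange(len(is_qc)), is_qc.astype(int)]))

    plasma = ~is_qc
    batches = table.sample_meta["batch_id"].to_numpy()
    pcs_p = pcs[plasma]
    batch_p = batches[plasma]
    probs = np.empty(plasma.sum())
    for b in pd.unique(batch_p):
        y = (batch_p == b).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            probs[batch_p == b] = 1.0
            continue
        m = _l1_logistic().fit(pcs_p, y)
        p_b = m.predict_proba(pcs_p)[:, list(m.classes_).index(1)]
        probs[batch_p == b] = p_b[batch_p == b]
    batch_score = float(np.mean(probs))
    return qc_score, batch_score


def evaluate(
    table: FeatureTable,
    concentrations: pd.DataFrame | None = None,
    mapping: Mapping[str, str] | None = None,
    n_pcs: int = 4,
    C: float = 1.0,
    seed: int = 0,
    label: str | None = None,
) -> EvaluationReport:
    """Compute the full six-metric report for one normalized table."""
    wtr = wtr_score(table)
    qc_corr = qc_correlations(table)
    spearman = r2 = None
    if concentrations is not None and mapping is not None:
        agreement = quantitative_agreement(table, concentrations, mapping)
        if len(agreement):
            spearman = agreement["spearman"]
            r2 = agreement["r2"]
    qc_score, batch_score = prediction_scores(table, n_pcs=n_pcs, C=C, seed=seed)
    if label is None:
        label = getattr(table, "provenance", {}).get("label", "None-Raw")
    return EvaluationReport(
        wtr=wtr,
        qc_correlations=qc_corr,
        spearman_scores=spearman,
        r2_scores=r2,
        qc_prediction_score=qc_score,
        batch_prediction_score=batch_score,
        label=label,
    )
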