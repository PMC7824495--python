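"""Expected-biomarker detection curves.

For patients with a known inborn error of metabolism, an expected
biomarker counts as detected ("positive") when the magnitude of its
triplicate-mean Z-score exceeds a threshold *and* the sign matches the
expected direction (p-value mode thresholds the Welch p instead, with
the same sign requirement).  Sweeping the threshold traces a ROC-like
curve of detected expected biomarkers against the average number of
positive features per patient (a proxy for false positives); the area
under it, with the x-axis rescaled to [0, 1] by its maximum, summarizes
detection performance and is typically reported relative to a reference
strategy's AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import BiomarkerExpectation, FeatureTable
from .reference import ZScoreResult

logger = logging.getLogger("metchalizer")


@dataclass
class DetectionCurve:
    """A threshold sweep and its (normalized-x) trapezoidal AUC."""

    score: str  # "z" or "p"
    thresholds: np.ndarray
    avg_positives_per_patient: np.ndarray  # x
    detected_biomarkers: np.ndarray  # y
    auc: float
    n_evaluable: int
    auc_relative_pct: float | None = None

    def relative_to(self, reference: "DetectionCurve") -> float:
        """AUC as a percentage of a reference curve's AUC."""
        if reference.auc == 0:
            raise ValueError("reference curve has zero AUC")
        self.auc_relative_pct = 100.0 * self.auc / reference.auc
        return self.auc_relative_pct


def resolve_expectations(
    expectations: Sequence[BiomarkerExpectation],
    table: FeatureTable,
    raw_table: FeatureTable | None = None,
) -> dict[int, str | None]:
    """Map each expectation to a feature id in ``table`` (or None).

    A biomarker names either a feature id or an annotation.  When the
    annotation resolves in both ion modes, the mode with the largest
    population-average raw abundancy wins (``raw_table`` supplies the
    pre-transform abundancies; defaults to ``table``).
    """
    if raw_table is None:
        raw_table = table
    meta = table.feature_meta
    out: dict[int, str | None] = {}
    for i, exp in enumerate(expectations):
        if exp.feature in meta.index:
            out[i] = exp.feature
            continue
        hits = meta.index[meta["annotation"].astype(str) == exp.feature]
        if exp.ion_mode is not None:
            hits = hits[meta.loc[hits, "ion_mode"] == exp.ion_mode]
        if len(hits) == 0:
            out[i] = None
        elif len(hits) == 1:
            out[i] = hits[0]
        else:
            means = raw_table.abundance[hits].mean(axis=0)
            out[i] = means.idxmax()
    return out


def biomarker_status(
    z_result: ZScoreResult,
    expectations: Sequence[BiomarkerExpectation],
    table: FeatureTable,
    z_threshold: float | None = None,
    p_threshold: float | None = None,
    raw_table: FeatureTable | None = None,
) -> pd.DataFrame:
    """Positive/negative status per (patient triplicate, expected biomarker).

    A patient is evaluated only against the biomarkers of its own IEM
    (matched through the ``iem_label`` sample metadata).  Unresolvable
    biomarkers are recorded with status ``unevaluable`` and excluded
    from curve counts.
    """
    if (z_threshold is None) == (p_threshold is None):
        raise ValueError("give exactly one of z_threshold or p_threshold")
    resolved = resolve_expectations(expectations, table, raw_table)
    meta = table.sample_meta
    pat = meta[(meta["class"] == "patient") & meta["triplicate_id"].notna()]
    iem_of_tid = pat.groupby("triplicate_id")["iem_label"].first()

    rows = []
    for tid, iem in iem_of_tid.items():
        for i, exp in enumerate(expectations):
            if iem is None or exp.iem_name != iem:
                continue
            fid = resolved[i]
            if fid is None or fid not in z_result.mean_z.columns:
                rows.append((tid, exp.iem_name, exp.feature, None, "unevaluable"))
                continue
            mz = z_result.mean_z.loc[tid, fid] if tid in z_result.mean_z.index else np.nan
            if not np.isfinite(mz):
                rows.append((tid, exp.iem_name, exp.feature, fid, "unevaluable"))
                continue
            sign_ok = (mz > 0) if exp.expected_sign == "up" else (mz < 0)
            if z_threshold is not None:
                hit = abs(mz) > z_threshold and sign_ok
            else:
                pv = z_result.pvalues.loc[tid, fid]
                hit = np.isfinite(pv) and pv < p_threshold and sign_ok
            rows.append((tid, exp.iem_name, exp.feature, fid, "positive" if hit else "negative"))
    return pd.DataFrame(
        rows, columns=["triplicate_id", "iem", "biomarker", "feature_id", "status"]
    )


def default_thresholds(score: str) -> np.ndarray:
    if score == "z":
        return np.linspace(0.0, 8.0, 200)
    return np.logspace(-12, 0, 200)


def detection_curve(
    z_result: ZScoreResult,
    expectations: Sequence[BiomarkerExpectation],
    table: FeatureTable,
    thresholds: Sequence[float] | None = None,
    score: str = "z",
    raw_table: FeatureTable | None = None,
) -> DetectionCurve:
    """Sweep a Z or p threshold into a detection curve with AUC.

    Per threshold: y = total expected biomarkers detected (sign-checked),
    x = mean over patients of the number of positive features among all
    features (magnitude/p gate only).  The AUC is trapezoidal with the
    x axis rescaled by its maximum, so curves from different strategies
    are comparable; against a reference curve, report
    ``curve.relative_to(reference)`` percent.
    """
    if score not in ("z", "p"):
        raise ValueError("score must be 'z' or 'p'")
    thr = np.asarray(thresholds if thresholds is not None else default_thresholds(score), dtype=float)
    if thr.size == 0:
        raise ValueError("empty threshold grid")

    resolved = resolve_expectations(expectations, table, raw_table)
    meta = table.sample_meta
    pat = meta[(meta["class"] == "patient") & meta["triplicate_id"].notna()]
    iem_of_tid = pat.groupby("triplicate_id")["iem_label"].first()

    # (tid, fid, sign) triples evaluable for the expected-biomarker count
    triples = []
    for tid, iem in iem_of_tid.items():
        for i, exp in enumerate(expectations):
            if iem is None or exp.iem_name != iem:
                continue
            fid = resolved[i]
            if fid is None or fid not in z_result.mean_z.columns:
                continue
            if tid in z_result.mean_z.index and np.isfinite(z_result.mean_z.loc[tid, fid]):
                triples.append((tid, fid, exp.expected_sign))
    if not triples:
        raise ValueError("no evaluable (patient, expected biomarker) pairs")

    mean_z = z_result.mean_z
    pvalues = z_result.pvalues
    tids = list(mean_z.index)

    bio_z = np.array([mean_z.loc[t, f] for t, f, _ in triples])
    bio_p = np.array([pvalues.loc[t, f] for t, f, _ in triples])
    bio_sign_ok = np.array(
        [(z > 0) if s == "up" else (z < 0) for (_, _, s), z in zip(triples, bio_z)]
    )

    zmat = mean_z.to_numpy(dtype=float)
    pmat = pvalues.to_numpy(dtype=float)

    xs = np.empty(len(thr))
    ys = np.empty(len(thr))
    for t_i, t in enumerate(thr):
        if score == "z":
            detected = (np.abs(bio_z) > t) & bio_sign_ok
            pos = np.abs(zmat) > t
        else:
            detected = np.isfinite(bio_p) & (bio_p < t) & bio_sign_ok
            pos = np.isfinite(pmat) & (pmat < t)
        ys[t_i] = int(detected.sum())
        xs[t_i] = float(np.nansum(pos) / len(tids))

    order = np.argsort(xs, kind="stable")
    xs_s, ys_s = xs[order], ys[order]
    x_max = xs_s[-1]
    if x_max > 0:
        auc = float(np.trapezoid(ys_s, xs_s / x_max))
    else:
        auc = 0.0
    return DetectionCurve(
        score=score,
        thresholds=thr,
        avg_positives_per_patient=xs,
        detected_biomarkers=ys,
        auc=auc,
        n_evaluable=len(triples),
    )
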