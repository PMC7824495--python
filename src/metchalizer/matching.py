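"""Cross-batch feature matching and merging.

Features detected independently per batch are matched against a
designated reference batch with a cascade of gates: shared annotation is
sufficient on its own; otherwise retention-time and within-batch median
abundancy agreement are always required, MS/MS cosine similarity and
isotope-distribution overlap are required whenever both sides carry
them, and a ppm gate on the neutral mass (or, lacking that, the m/z)
applies when no MS/MS is available.  Any feature with two or more
passing partners is excluded as ambiguous rather than guessed at, so
the accepted pairs always form a partial bijection.  The merged table
keeps only features matched across every batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureTable

logger = logging.getLogger("metchalizer")


@dataclass(frozen=True)
class MatchCriteria:
    """Gate thresholds for cross-batch feature matching.

    Defaults: MS/MS cosine > 0.8, RT difference < 3%, isotope bin
    difference < 25 percentage points, within-batch median abundancy
    difference < 300%, ppm error < 1.
    """

    cosine_min: float = 0.8
    rt_diff_max_pct: float = 3.0
    isotope_bin_diff_max_pct: float = 25.0
    median_diff_max_pct: float = 300.0
    ppm_max: float = 1.0
    msms_mz_tolerance: float = 0.01
    rt_denominator: str = "mean"  # or "min"
    median_denominator: str = "min"  # or "mean"
    annotation_sufficient: bool = True
    prefilter_mz_window: float = 0.05  # Da
    prefilter_rt_pct: float = 10.0

    def __post_init__(self) -> None:
        for name in ("cosine_min", "rt_diff_max_pct", "isotope_bin_diff_max_pct",
                     "median_diff_max_pct", "ppm_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MatchResult:
    """Accepted pairs and exclusions from matching one batch to the reference.

    ``accepted`` holds ``(reference_id, batch_id, fired)`` triples where
    ``fired`` maps each evaluated gate to its outcome; ``excluded`` maps
    feature ids to a reason: ``ambiguous_reference_side``,
    ``ambiguous_batch_side`` or ``no_match``.
    """

    accepted: list[tuple[str, str, dict]] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def pairs(self) -> dict[str, str]:
        return {ref: bat for ref, bat, _ in self.accepted}


def cosine_similarity(
    spectrum_a,
    spectrum_b,
    mz_tolerance: float = 0.01,
) -> float:
    """Cosine similarity between two MS/MS peak lists.

    Peaks are paired greedily by nearest m/z within ``mz_tolerance`` Da;
    intensity vectors are L2-normalized, so identical spectra score 1 and
    spectra sharing no m/z bins score 0.
    """
    a = np.asarray(spectrum_a, dtype=float)
    b = np.asarray(spectrum_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty MS/MS spectrum")
    norm_a = float(np.linalg.norm(a[:, 1]))
    norm_b = float(np.linalg.norm(b[:, 1]))
    if norm_a == 0 or norm_b == 0:
        raise ValueError("spectrum with all-zero intensities")

    diffs = np.abs(a[:, 0][:, None] - b[:, 0][None, :])
    cand = np.argwhere(diffs <= mz_tolerance)
    order = np.argsort(diffs[cand[:, 0], cand[:, 1]], kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for i, j in cand[order]:
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        dot += a[i, 1] * b[j, 1]
    return dot / (norm_a * norm_b)


def _pct_diff(x: float, y: float, denominator: str) -> float:
    denom = min(x, y) if denominator == "min" else 0.5 * (x + y)
    if denom == 0:
        return np.inf
    return abs(x - y) / denom * 100.0


def _ppm_error(x: float, y: float) -> float:
    denom = 0.5 * (x + y)
    if denom == 0:
        return np.inf
    return abs(x - y) / denom * 1e6


def _has(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and np.isnan(value):
        return False
    return True


def candidate_passes(
    feature_ref: pd.Series,
    feature_batch: pd.Series,
    criteria: MatchCriteria | None = None,
) -> tuple[bool, dict]:
    """Evaluate the matching gate cascade for one candidate pair.

    Each feature is a Series/mapping with at minimum ``mz`` and ``rt``
    plus optional ``annotation``, ``msms``, ``isotope_distribution``,
    ``neutral_mass`` and ``median_abundance``.  Returns ``(passed,
    fired)`` where ``fired`` maps each evaluated gate name to a bool;
    gates whose prerequisites are absent are skipped.
    """
    if criteria is None:
        criteria = MatchCriteria()
    fired: dict[str, bool] = {}

    ann_a, ann_b = feature_ref.get("annotation"), feature_batch.get("annotation")
    if _has(ann_a) and _has(ann_b):
        same = str(ann_a) == str(ann_b)
        fired["annotation"] = same
        if same and criteria.annotation_sufficient:
            return True, fired
        if not same:
            return False, fired

    msms_a, msms_b = feature_ref.get("msms"), feature_batch.get("msms")
    both_msms = _has(msms_a) and _has(msms_b)
    if both_msms:
        cos = cosine_similarity(msms_a, msms_b, criteria.msms_mz_tolerance)
        fired["cosine"] = bool(cos > criteria.cosine_min)

    rt_diff = _pct_diff(float(feature_ref["rt"]), float(feature_batch["rt"]), criteria.rt_denominator)
    fired["rt"] = bool(rt_diff < criteria.rt_diff_max_pct)

    iso_a = feature_ref.get("isotope_distribution")
    iso_b = feature_batch.get("isotope_distribution")
    if _has(iso_a) and _has(iso_b):
        pa, pb = np.asarray(iso_a, dtype=float), np.asarray(iso_b, dtype=float)
        n = max(len(pa), len(pb))
        pa = np.pad(pa, (0, n - len(pa)))
        pb = np.pad(pb, (0, n - len(pb)))
        max_bin = float(np.max(np.abs(pa - pb))) * 100.0
        fired["isotopes"] = bool(max_bin < criteria.isotope_bin_diff_max_pct)

    med_a = feature_ref.get("median_abundance")
    med_b = feature_batch.get("median_abundance")
    if _has(med_a) and _has(med_b):
        med_diff = _pct_diff(float(med_a), float(med_b), criteria.median_denominator)
        fired["median"] = bool(med_diff < criteria.median_diff_max_pct)

    nm_a = feature_ref.get("neutral_mass")
    nm_b = feature_batch.get("neutral_mass")
    if not both_msms:
        if _has(nm_a) and _has(nm_b):
            fired["ppm_neutral_mass"] = bool(_ppm_error(float(nm_a), float(nm_b)) < criteria.ppm_max)
        else:
            fired["ppm_mz"] = bool(
                _ppm_error(float(feature_ref["mz"]), float(feature_batch["mz"])) < criteria.ppm_max
            )

    return all(fired.values()), fired


def _feature_records(table: FeatureTable) -> pd.DataFrame:
    rec = table.feature_meta.copy()
    rec["median_abundance"] = table.abundance.median(axis=0)
    return rec


def match_batches(
    reference_table: FeatureTable,
    batch_table: FeatureTable,
    criteria: MatchCriteria | None = None,
) -> MatchResult:
    """Match features of ``batch_table`` against ``reference_table``.

    A coarse prefilter (|dm/z| and RT window, both far looser than the
    accept gates) bounds the candidate search; pairs sharing an
    annotation bypass it.  Reference or batch features with two or more
    passing candidates are excluded as ambiguous.
    """
    if criteria is None:
        criteria = MatchCriteria()
    ref = _feature_records(reference_table)
    bat = _feature_records(batch_table)

    passing: list[tuple[str, str, dict]] = []
    ref_hits: dict[str, int] = {fid: 0 for fid in ref.index}
    bat_hits: dict[str, int] = {fid: 0 for fid in bat.index}

    bat_by_mode = {mode: sub for mode, sub in bat.groupby("ion_mode")}
    for rid, rrow in ref.iterrows():
        sub = bat_by_mode.get(rrow["ion_mode"])
        if sub is None:
            continue
        dmz = np.abs(sub["mz"].to_numpy(dtype=float) - float(rrow["mz"]))
        rt_ref = float(rrow["rt"])
        rt_pct = np.abs(sub["rt"].to_numpy(dtype=float) - rt_ref) / np.maximum(
            0.5 * (sub["rt"].to_numpy(dtype=float) + rt_ref), 1e-12
        ) * 100.0
        near = (dmz <= criteria.prefilter_mz_window) & (rt_pct <= criteria.prefilter_rt_pct)
        if _has(rrow.get("annotation")):
            near = near | (sub["annotation"].astype(str) == str(rrow["annotation"])).to_numpy()
        for bid in sub.index[near]:
            ok, fired = candidate_passes(rrow, sub.loc[bid], criteria)
            if ok:
                passing.append((rid, bid, fired))
                ref_hits[rid] += 1
                bat_hits[bid] += 1

    result = MatchResult()
    for rid, bid, fired in passing:
        if ref_hits[rid] > 1:
            result.excluded[rid] = "ambiguous_reference_side"
            result.excluded.setdefault(bid, "ambiguous_reference_side")
        elif bat_hits[bid] > 1:
            result.excluded[bid] = "ambiguous_batch_side"
            result.excluded.setdefault(rid, "ambiguous_batch_side")
    for rid, bid, fired in passing:
        if rid not in result.excluded and bid not in result.excluded:
            result.accepted.append((rid, bid, fired))
    matched_ref = {r for r, _, _ in result.accepted}
    matched_bat = {b for _, b, _ in result.accepted}
    for fid in ref.index:
        if fid not in matched_ref and fid not in result.excluded:
            result.excluded[fid] = "no_match"
    for fid in bat.index:
        if fid not in matched_bat and fid not in result.excluded:
            result.excluded[fid] = "no_match"
    return result


@dataclass
class MergeResult:
    """Merged multi-batch table plus feature provenance.

    ``provenance`` maps each retained reference feature id to its
    per-batch original feature id.
    """

    table: FeatureTable
    provenance: dict[str, dict[str, str]]
    per_batch: dict[str, MatchResult]


def merge_all(
    batch_tables: list[FeatureTable],
    reference_index: int = 0,
    criteria: MatchCriteria | None = None,
) -> MergeResult:
    """Merge per-batch tables, keeping features matched across every batch.

    Samples are concatenated over batches; abundancies of matched batch
    features are placed under the reference feature id.  An empty
    intersection produces a warning and an empty table, not an error.
    """
    if len(batch_tables) < 2:
        raise ValueError("merging requires at least 2 batch tables")
    if not 0 <= reference_index < len(batch_tables):
        raise ValueError("reference_index out of range")
    reference = batch_tables[reference_index]
    ref_batch = reference.sample_meta["batch_id"].iloc[0]

    per_batch: dict[str, MatchResult] = {}
    keep = set(reference.feature_ids)
    mapping: dict[str, dict[str, str]] = {fid: {ref_batch: fid} for fid in reference.feature_ids}
    for i, bt in enumerate(batch_tables):
        if i == reference_index:
            continue
        batch_id = bt.sample_meta["batch_id"].iloc[0]
        res = match_batches(reference, bt, criteria)
        per_batch[batch_id] = res
        pairs = res.pairs
        keep &= set(pairs)
        for rid, bid in pairs.items():
            mapping.setdefault(rid, {})[batch_id] = bid

    kept = [fid for fid in reference.feature_ids if fid in keep]
    if not kept:
        logger.warning("merge_all: no features matched across all batches")

    blocks = []
    metas = []
    for i, bt in enumerate(batch_tables):
        batch_id = bt.sample_meta["batch_id"].iloc[0]
        if i == reference_index:
            block = bt.abundance[kept].copy()
        else:
            cols = [mapping[fid][batch_id] for fid in kept]
            block = bt.abundance[cols].copy()
            block.columns = kept
        blocks.append(block)
        metas.append(bt.sample_meta)
    abundance = pd.concat(blocks, axis=0)
    sample_meta = pd.concat(metas, axis=0)
    feature_meta = reference.feature_meta.loc[kept].copy()
    table = FeatureTable(abundance=abundance, sample_meta=sample_meta, feature_meta=feature_meta)
    provenance = {fid: mapping[fid] for fid in kept}
    return MergeResult(table=table, provenance=provenance, per_batch=per_batch)
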