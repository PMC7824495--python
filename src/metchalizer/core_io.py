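"""Data model and tabular I/O.

A :class:`FeatureTable` is the universal currency between pipeline stages:
a samples x features abundancy matrix plus per-sample and per-feature
metadata.  On disk a table is a pair of flat CSV files -- one row per
sample, metadata columns prefixed ``meta:`` and feature columns named by
feature id, plus a sibling feature-metadata CSV keyed by feature id --
so everything stays inspectable and language neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("metchalizer")

SAMPLE_META_COLUMNS = ("batch_id", "age", "sex", "class", "triplicate_id", "iem_label")
FEATURE_META_COLUMNS = (
    "ion_mode",
    "mz",
    "rt",
    "annotation",
    "neutral_mass",
    "isotope_distribution",
    "msms",
    "is_internal_standard",
)

SAMPLE_CLASSES = ("control", "patient", "qc")
ION_MODES = ("+", "-")
META_PREFIX = "meta:"


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants."""


@dataclass
class FeatureTable:
    """Samples x features abundancy matrix with sample and feature metadata.

    Parameters
    ----------
    abundance
        DataFrame indexed by sample id with one column per feature id.
        Missing measurements are ``NaN`` (never silently zero).
    sample_meta
        DataFrame indexed by sample id with columns ``batch_id``, ``age``
        (fractional years), ``sex`` (``M``/``F``), ``class``
        (``control``/``patient``/``qc``), ``triplicate_id`` and
        ``iem_label`` (both nullable).
    feature_meta
        DataFrame indexed by feature id with columns ``ion_mode``
        (``+``/``-``), ``mz`` (Da), ``rt`` (minutes), ``annotation``,
        ``neutral_mass`` (Da), ``isotope_distribution`` (tuple of binned
        proportions summing to one), ``msms`` (tuple of ``(mz, intensity)``
        peaks) and ``is_internal_standard``.
    """

    abundance: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants, raising :class:`FeatureTableError`."""
        dup_samples = self.abundance.index[self.abundance.index.duplicated()].unique()
        if len(dup_samples):
            raise FeatureTableError(f"duplicate sample ids: {sorted(map(str, dup_samples))}")
        for mode in ION_MODES:
            ids = self.feature_meta.index[self.feature_meta["ion_mode"] == mode]
            dup = ids[ids.duplicated()].unique()
            if len(dup):
                raise FeatureTableError(f"duplicate feature ids in mode {mode}: {sorted(map(str, dup))}")
        dup_feats = self.feature_meta.index[self.feature_meta.index.duplicated()].unique()
        if len(dup_feats):
            raise FeatureTableError(f"duplicate feature ids: {sorted(map(str, dup_feats))}")
        if not self.abundance.index.equals(self.sample_meta.index):
            raise FeatureTableError("abundance and sample_meta indexed by different sample ids")
        if list(self.abundance.columns) != list(self.feature_meta.index):
            raise FeatureTableError("abundance columns and feature_meta index differ")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise FeatureTableError(f"sample_meta missing columns: {missing}")
        missing = [c for c in FEATURE_META_COLUMNS if c not in self.feature_meta.columns]
        if missing:
            raise FeatureTableError(f"feature_meta missing columns: {missing}")
        bad_class = set(self.sample_meta["class"].dropna()) - set(SAMPLE_CLASSES)
        if bad_class:
            raise FeatureTableError(f"unknown sample classes: {sorted(bad_class)}")
        bad_sex = set(self.sample_meta["sex"].dropna()) - {"M", "F"}
        if bad_sex:
            raise FeatureTableError(f"unknown sex codes: {sorted(bad_sex)}")
        ages = pd.to_numeric(self.sample_meta["age"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise FeatureTableError("negative ages present")
        bad_mode = set(self.feature_meta["ion_mode"].dropna()) - set(ION_MODES)
        if bad_mode:
            raise FeatureTableError(f"unknown ion modes: {sorted(bad_mode)}")
        values = self.abundance.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise FeatureTableError("non-finite abundancies present")
        self._validate_triplicates()

    def _validate_triplicates(self) -> None:
        trip = self.sample_meta.dropna(subset=["triplicate_id"])
        for (tid, _), grp in trip.groupby(["triplicate_id", "batch_id"], sort=False):
            if len(grp) != 3:
                raise FeatureTableError(
                    f"triplicate {tid!r} has {len(grp)} replicates in one batch, expected 3"
                )

    # -- convenience ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def feature_ids(self) -> list:
        return list(self.abundance.columns)

    @property
    def internal_standard_ids(self) -> list:
        mask = self.feature_meta["is_internal_standard"].astype(bool)
        return list(self.feature_meta.index[mask])

    @property
    def batches(self) -> list:
        return list(pd.unique(self.sample_meta["batch_id"]))

    def samples_of_class(self, cls: str) -> list:
        return list(self.sample_meta.index[self.sample_meta["class"] == cls])

    def select_samples(self, sample_ids: Sequence) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            abundance=self.abundance.loc[ids].copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
            feature_meta=self.feature_meta.copy(),
        )

    def select_features(self, feature_ids: Sequence) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            abundance=self.abundance[ids].copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.loc[ids].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            abundance=self.abundance.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
        )

    def equals(self, other: "FeatureTable", rtol: float = 1e-12) -> bool:
        if self.abundance.shape != other.abundance.shape:
            return False
        a = self.abundance.to_numpy(dtype=float)
        b = other.abundance.to_numpy(dtype=float)
        same_nan = np.array_equal(np.isnan(a), np.isnan(b))
        close = np.allclose(np.nan_to_num(a), np.nan_to_num(b), rtol=rtol, atol=0.0)
        return bool(same_nan and close)


@dataclass(frozen=True)
class TransformSpec:
    """Initial variance-stabilizing transform applied before normalization.

    ``kind`` is one of ``none``, ``log`` (natural log) or ``boxcox`` with
    the two-parameter form ``((y + lambda2)**lambda1 - 1) / lambda1``.
    Defaults for Box-Cox are ``lambda1 = 0.5`` and ``lambda2 = 1``.
    """

    kind: str = "none"
    lambda1: float = 0.5
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "log", "boxcox"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "boxcox" and self.lambda1 == 0:
            raise ValueError("boxcox requires lambda1 != 0")

    @property
    def label(self) -> str:
        return {"none": "None", "log": "Log", "boxcox": "BC"}[self.kind]


@dataclass(frozen=True)
class BiomarkerExpectation:
    """One expected biomarker for an inborn error of metabolism.

    ``feature`` names the biomarker either by annotation or by feature id;
    ``expected_sign`` is ``up`` or ``down`` (the direction of the abnormal
    Z-score in affected patients); ``ion_mode`` optionally pins the mode.
    """

    iem_name: str
    feature: str
    expected_sign: str
    ion_mode: str | None = None

    def __post_init__(self) -> None:
        if self.expected_sign not in ("up", "down"):
            raise ValueError(f"expected_sign must be 'up' or 'down', got {self.expected_sign!r}")


# ---------------------------------------------------------------------------
# serialization helpers


def _encode_isotopes(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return ";".join(f"{v:.10g}" for v in value)


def _decode_isotopes(text):
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    return tuple(float(v) for v in str(text).split(";"))


def _encode_msms(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return ";".join(f"{mz:.10g}:{inten:.10g}" for mz, inten in value)


def _decode_msms(text):
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return None
    peaks = []
    for part in str(text).split(";"):
        mz, inten = part.split(":")
        peaks.append((float(mz), float(inten)))
    return tuple(peaks)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write ``table`` as ``<path>`` (samples) plus ``<stem>.features.csv``.

    Missing abundancies are written as empty cells.  Column order is
    deterministic: metadata columns in canonical order, then features in
    table order.
    """
    path = Path(path)
    meta = table.sample_meta[list(SAMPLE_META_COLUMNS)].rename(
        columns=lambda c: META_PREFIX + c
    )
    feats = table.abundance.rename(columns=str)
    out = pd.concat([meta, feats], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)

    fmeta = table.feature_meta.copy()
    fmeta.index.name = "feature_id"
    fmeta["isotope_distribution"] = [_encode_isotopes(v) for v in fmeta["isotope_distribution"]]
    fmeta["msms"] = [_encode_msms(v) for v in fmeta["msms"]]
    fmeta["is_internal_standard"] = fmeta["is_internal_standard"].astype(bool)
    fmeta = fmeta[list(FEATURE_META_COLUMNS)]
    fmeta.to_csv(feature_meta_path(path))


def feature_meta_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".features.csv")


def read_feature_table(path: str | Path, feature_meta: str | Path | None = None) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`.

    Raises :class:`FeatureTableError` with the offending address for
    duplicate ids or non-numeric abundancy cells.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise FeatureTableError(f"{path}: missing 'sample_id' column")
    dup = raw["sample_id"][raw["sample_id"].duplicated()].unique()
    if len(dup):
        raise FeatureTableError(f"{path}: duplicate sample ids: {sorted(dup)}")
    raw = raw.set_index("sample_id")

    meta_cols = [c for c in raw.columns if c.startswith(META_PREFIX)]
    feat_cols = [c for c in raw.columns if not c.startswith(META_PREFIX)]

    sample_meta = raw[meta_cols].rename(columns=lambda c: c[len(META_PREFIX):])
    for col in SAMPLE_META_COLUMNS:
        if col not in sample_meta.columns:
            sample_meta[col] = ""
    sample_meta = sample_meta[list(SAMPLE_META_COLUMNS)].replace("", None)
    sample_meta["age"] = pd.to_numeric(sample_meta["age"], errors="coerce")

    values = np.full((raw.shape[0], len(feat_cols)), np.nan)
    for j, col in enumerate(feat_cols):
        for i, cell in enumerate(raw[col]):
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise FeatureTableError(
                    f"{path}: non-numeric abundancy {cell!r} at sample "
                    f"{raw.index[i]!r}, feature {col!r}"
                ) from None
    abundance = pd.DataFrame(values, index=raw.index, columns=feat_cols)

    meta_path = Path(feature_meta) if feature_meta is not None else feature_meta_path(path)
    fmeta = pd.read_csv(meta_path, index_col="feature_id")
    fmeta.index = fmeta.index.astype(str)
    dup = fmeta.index[fmeta.index.duplicated()].unique()
    if len(dup):
        raise FeatureTableError(f"{meta_path}: duplicate feature ids: {sorted(dup)}")
    fmeta["isotope_distribution"] = [_decode_isotopes(v) for v in fmeta["isotope_distribution"]]
    fmeta["msms"] = [_decode_msms(v) for v in fmeta["msms"]]
    fmeta["is_internal_standard"] = fmeta["is_internal_standard"].astype(bool)
    unknown = set(feat_cols) - set(fmeta.index)
    if unknown:
        raise FeatureTableError(f"{meta_path}: no metadata for features: {sorted(unknown)}")
    fmeta = fmeta.reindex(feat_cols)

    return FeatureTable(abundance=abundance, sample_meta=sample_meta, feature_meta=fmeta)


def make_feature_meta(
    feature_ids: Sequence[str],
    ion_mode: str = "+",
    mz: Sequence[float] | None = None,
    rt: Sequence[float] | None = None,
    is_internal_standard: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build a minimal feature-metadata frame with sensible defaults."""
    n = len(feature_ids)
    return pd.DataFrame(
        {
            "ion_mode": [ion_mode] * n,
            "mz": list(mz) if mz is not None else np.linspace(100.0, 600.0, n),
            "rt": list(rt) if rt is not None else np.linspace(1.0, 10.0, n),
            "annotation": [None] * n,
            "neutral_mass": [None] * n,
            "isotope_distribution": [None] * n,
            "msms": [None] * n,
            "is_internal_standard": list(is_internal_standard)
            if is_internal_standard is not None
            else [False] * n,
        },
        index=pd.Index([str(f) for f in feature_ids], name="feature_id"),
    )


def read_biomarker_expectations(path: str | Path) -> list[BiomarkerExpectation]:
    """Read an expected-biomarker CSV with columns iem, biomarker, sign[, ion_mode]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        mode = row.get("ion_mode")
        if isinstance(mode, float) and np.isnan(mode):
            mode = None
        out.append(
            BiomarkerExpectation(
                iem_name=str(row["iem"]),
                feature=str(row["biomarker"]),
                expected_sign=str(row["sign"]),
                ion_mode=mode,
            )
        )
    return out
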