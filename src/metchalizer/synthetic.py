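"""Synthetic multi-batch LC-MS datasets with known ground truth.

The generator emulates the structure of a multi-batch untargeted
metabolomics study of human plasma: nine independently measured batches,
each containing random controls, technical QC replicates of one fixed
commercial sample, and patient samples measured in technical triplicate,
with ten stable-isotope-labelled internal standards spiked into every
sample.

The abundance model is multiplicative (log-additive):

    abundance = concentration(age, sex) * sample_technical * batch_factor * noise

where ``sample_technical`` is a per-sample scalar shared by all features
and internal standards (the injection-volume analogue), and
``batch_factor`` is a log-normal per-batch factor shared within feature
groups.  Internal standards experience the same technical terms scaled
by a coupling fraction, which is exactly the structure an
internal-standard based correction is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureTable, make_feature_meta

PROTON_MASS = 1.007276


def _cv_to_sigma(cv: float) -> float:
    """Log-normal sigma producing a given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the multi-batch plasma design the package targets:
    nine batches, 18-40 controls per batch, 5-9 QC technical replicates
    per batch, patient technical triplicates and ten internal standards
    per ion mode.  Between-batch variation defaults to a 27% CV and
    within-batch technical variation to a 14% CV (split between the
    per-sample scalar and measurement noise).
    """

    n_batches: int = 9
    controls_per_batch: tuple[int, int] = (18, 40)
    qc_replicates_per_batch: tuple[int, int] = (5, 9)
    n_patients: int = 12
    n_features: int = 100
    n_internal_standards: int = 10
    ion_modes: tuple[str, ...] = ("+",)
    n_feature_groups: int = 3
    batch_cv: float = 0.27
    batch_additive: float = 0.0
    sample_technical_cv: float = 0.10
    noise_cv: float = 0.10
    is_coupling: float = 0.9
    is_noise_cv: float = 0.02
    age_fraction: float = 0.25
    age_effect_scale: float = 0.35
    max_age_degree: int = 3
    sex_fraction: float = 0.05
    sex_effect_scale: float = 0.3
    age_noise_slope: float = 0.0
    qc_profile_sd: float = 0.5
    n_biomarkers: int = 10
    spike_multiplier: float = 8.0
    frac_annotated: float = 0.2
    frac_msms: float = 0.3
    frac_isotopes: float = 0.5
    age_range: tuple[float, float] = (0.1, 80.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1 or self.n_features < 1 or self.n_internal_standards < 1:
            raise ValueError("counts must be positive")
        for name in ("batch_cv", "sample_technical_cv", "noise_cv", "is_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("is_coupling", "age_fraction", "sex_fraction", "frac_annotated",
                     "frac_msms", "frac_isotopes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.controls_per_batch
        if lo < 0 or hi < lo:
            raise ValueError("invalid controls_per_batch range")
        lo, hi = self.qc_replicates_per_batch
        if lo < 1 or hi < lo:
            raise ValueError("invalid qc_replicates_per_batch range")
        if not 1 <= self.max_age_degree <= 3:
            raise ValueError("max_age_degree must be 1..3")


@dataclass
class GroundTruth:
    """Everything injected into a simulated dataset, for downstream scoring."""

    config: SimulationConfig
    feature_base: pd.Series
    age_coefficients: pd.DataFrame  # features x [age1, age2, age3], raw-age scale, log space
    sex_coefficients: pd.Series  # log-space additive effect for sex == F
    qc_offsets: pd.Series  # log-space offset of the QC concentration profile
    feature_group: pd.Series  # feature -> group index (internal standards included)
    log_batch_factors: pd.DataFrame  # batches x groups, log space
    log_sample_technical: pd.Series  # per sample
    spikes: list[tuple[str, str, float, str]]  # (triplicate_id, feature_id, multiplier, sign)
    biomarker_features: list[str]
    correspondences: dict | None = None  # set by simulate_split_batches

    def expected_qc_ratio(self, feature_id: str, batch_a: str, batch_b: str) -> float:
        """Ratio of QC means between two batches implied by the batch factors."""
        g = self.feature_group.loc[feature_id]
        return float(
            np.exp(self.log_batch_factors.loc[batch_a, g] - self.log_batch_factors.loc[batch_b, g])
        )


def _feature_ids(mode: str, n: int, is_n: int) -> tuple[list[str], list[str]]:
    tag = "P" if mode == "+" else "N"
    feats = [f"F{tag}{j:04d}" for j in range(n)]
    standards = [f"IS{tag}{m:02d}" for m in range(is_n)]
    return feats, standards


def simulate_dataset(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Simulate one merged multi-batch dataset and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    batches = [f"b{b + 1}" for b in range(config.n_batches)]

    # --- samples -----------------------------------------------------
    rows = []
    lo, hi = config.controls_per_batch
    qlo, qhi = config.qc_replicates_per_batch
    for b, batch in enumerate(batches):
        n_ctrl = int(rng.integers(lo, hi + 1))
        for i in range(n_ctrl):
            rows.append((f"{batch}_c{i:03d}", batch, "control", None))
        n_qc = int(rng.integers(qlo, qhi + 1))
        for i in range(n_qc):
            rows.append((f"{batch}_qc{i:02d}", batch, "qc", None))
    for p in range(config.n_patients):
        batch = batches[p % len(batches)]
        tid = f"T{p:03d}"
        for r in range(3):
            rows.append((f"{batch}_p{p:03d}r{r}", batch, "patient", tid))

    sample_ids = [r[0] for r in rows]
    n_samples = len(rows)
    a_lo, a_hi = config.age_range
    ages = np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), size=n_samples))
    sexes = rng.choice(["M", "F"], size=n_samples)
    # triplicate replicates share one age/sex
    by_tid: dict[str, int] = {}
    for i, (_, _, _, tid) in enumerate(rows):
        if tid is not None:
            if tid in by_tid:
                ages[i] = ages[by_tid[tid]]
                sexes[i] = sexes[by_tid[tid]]
            else:
                by_tid[tid] = i

    sample_meta = pd.DataFrame(
        {
            "batch_id": [r[1] for r in rows],
            "age": ages,
            "sex": sexes,
            "class": [r[2] for r in rows],
            "triplicate_id": [r[3] for r in rows],
            "iem_label": [f"IEM_{r[3]}" if r[3] is not None else None for r in rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- features ----------------------------------------------------
    all_fids: list[str] = []
    all_is: list[str] = []
    meta_frames = []
    for mode in config.ion_modes:
        feats, standards = _feature_ids(mode, config.n_features, config.n_internal_standards)
        fids = feats + standards
        mz = rng.uniform(80.0, 800.0, size=len(fids))
        rt = rng.uniform(0.5, 12.0, size=len(fids))
        fm = make_feature_meta(
            fids,
            ion_mode=mode,
            mz=mz,
            rt=rt,
            is_internal_standard=[False] * len(feats) + [True] * len(standards),
        )
        sign = -1.0 if mode == "+" else 1.0
        fm["neutral_mass"] = fm["mz"] + sign * PROTON_MASS
        annotated = rng.random(len(fids)) < config.frac_annotated
        fm.loc[annotated, "annotation"] = [f"cmpd_{fid}" for fid in fm.index[annotated]]
        has_msms = rng.random(len(fids)) < config.frac_msms
        msms = []
        for fid, flag, m in zip(fm.index, has_msms, fm["mz"]):
            if not flag:
                msms.append(None)
                continue
            n_peaks = int(rng.integers(4, 9))
            pk_mz = np.sort(rng.uniform(50.0, max(60.0, m), size=n_peaks))
            pk_int = rng.uniform(10.0, 1000.0, size=n_peaks)
            msms.append(tuple(zip(pk_mz.round(4), pk_int.round(1))))
        fm["msms"] = msms
        has_iso = rng.random(len(fids)) < config.frac_isotopes
        iso = []
        for flag in has_iso:
            if not flag:
                iso.append(None)
                continue
            raw = rng.dirichlet([8.0, 2.0, 1.0])
            iso.append(tuple(np.round(raw / raw.sum(), 6)))
        fm["isotope_distribution"] = iso
        meta_frames.append(fm)
        all_fids.extend(fids)
        all_is.extend(standards)
    feature_meta = pd.concat(meta_frames)

    n_all = len(all_fids)
    fid_index = pd.Index(all_fids)

    # --- ground-truth surfaces --------------------------------------
    base = pd.Series(rng.normal(np.log(1e5), 1.0, size=n_all), index=fid_index)
    base[all_is] = rng.normal(np.log(5e5), 0.3, size=len(all_is))

    age_coef = pd.DataFrame(0.0, index=fid_index, columns=["age1", "age2", "age3"])
    sex_coef = pd.Series(0.0, index=fid_index)
    is_mask = feature_meta["is_internal_standard"].astype(bool).reindex(fid_index)
    plain = fid_index[~is_mask]
    aff_age = plain[rng.random(len(plain)) < config.age_fraction]
    amax = config.age_range[1]
    for fid in aff_age:
        degree = int(rng.integers(1, config.max_age_degree + 1))
        # coefficients on scaled age (age / amax), re-expressed on raw age so a
        # cubic never dwarfs the baseline over the simulated age range
        scaled = rng.normal(0.0, config.age_effect_scale, size=degree)
        for p, c in enumerate(scaled, start=1):
            age_coef.loc[fid, f"age{p}"] = c / amax**p
    aff_sex = plain[rng.random(len(plain)) < config.sex_fraction]
    sex_coef[aff_sex] = rng.normal(0.0, config.sex_effect_scale, size=len(aff_sex))

    qc_off = pd.Series(rng.normal(0.0, config.qc_profile_sd, size=n_all), index=fid_index)
    qc_off[all_is] = 0.0

    groups = pd.Series(rng.integers(0, config.n_feature_groups, size=n_all), index=fid_index)
    sigma_b = _cv_to_sigma(config.batch_cv)
    log_bf = pd.DataFrame(
        rng.normal(0.0, sigma_b, size=(len(batches), config.n_feature_groups)),
        index=pd.Index(batches, name="batch_id"),
        columns=range(config.n_feature_groups),
    )
    sigma_t = _cv_to_sigma(config.sample_technical_cv)
    log_tech = pd.Series(rng.normal(0.0, sigma_t, size=n_samples), index=sample_ids)

    # --- spiked biomarkers -------------------------------------------
    biomarkers = list(rng.choice(plain, size=min(config.n_biomarkers, len(plain)), replace=False))
    spikes: list[tuple[str, str, float, str]] = []
    tids = sorted(by_tid)
    for k, tid in enumerate(tids):
        if not biomarkers:
            break
        fid = biomarkers[k % len(biomarkers)]
        sign = "up" if rng.random() < 0.75 else "down"
        mult = config.spike_multiplier if sign == "up" else 1.0 / config.spike_multiplier
        spikes.append((tid, fid, mult, sign))

    spike_by_tid: dict[str, list[tuple[str, float]]] = {}
    for tid, fid, mult, _ in spikes:
        spike_by_tid.setdefault(tid, []).append((fid, mult))

    # --- assemble abundancies ----------------------------------------
    sigma_n = _cv_to_sigma(config.noise_cv)
    sigma_is = _cv_to_sigma(config.is_noise_cv)
    age_pows = np.stack([ages**p for p in (1, 2, 3)], axis=1)  # n_samples x 3
    is_f = (sexes == "F").astype(float)

    log_conc = np.tile(base.to_numpy(), (n_samples, 1))
    bio = age_pows @ age_coef.to_numpy().T + np.outer(is_f, sex_coef.to_numpy())
    qc_rows = sample_meta["class"].to_numpy() == "qc"
    log_conc[~qc_rows] += bio[~qc_rows]
    log_conc[qc_rows] += qc_off.to_numpy()[None, :]

    col_of = {fid: j for j, fid in enumerate(fid_index)}
    for i, (_, _, _, tid) in enumerate(rows):
        if tid in spike_by_tid:
            for fid, mult in spike_by_tid[tid]:
                log_conc[i, col_of[fid]] += np.log(mult)

    batch_of = sample_meta["batch_id"].to_numpy()
    bf_per_sample = log_bf.loc[batch_of, :].to_numpy()  # n_samples x groups
    log_bf_full = bf_per_sample[:, groups.to_numpy()]  # n_samples x n_all
    tech = log_tech.to_numpy()[:, None]

    is_cols = np.array([col_of[f] for f in all_is])
    coupling = np.ones(n_all)
    coupling[is_cols] = config.is_coupling
    noise_sd = np.full(n_all, sigma_n)
    noise_sd[is_cols] = sigma_is
    eps = rng.normal(0.0, 1.0, size=(n_samples, n_all)) * noise_sd[None, :]
    if config.age_noise_slope:
        # heteroskedastic measurement noise: SD grows linearly with age
        age_scale = 1.0 + config.age_noise_slope * ages / config.age_range[1]
        non_is = np.setdiff1d(np.arange(n_all), is_cols)
        eps[:, non_is] *= age_scale[:, None]

    log_y = log_conc + coupling[None, :] * (tech + log_bf_full) + eps
    values = np.exp(log_y)
    if config.batch_additive:
        values = values + config.batch_additive

    abundance = pd.DataFrame(values, index=sample_meta.index, columns=fid_index)
    table = FeatureTable(abundance=abundance, sample_meta=sample_meta, feature_meta=feature_meta)
    truth = GroundTruth(
        config=config,
        feature_base=base,
        age_coefficients=age_coef,
        sex_coefficients=sex_coef,
        qc_offsets=qc_off,
        feature_group=groups,
        log_batch_factors=log_bf,
        log_sample_technical=log_tech,
        spikes=spikes,
        biomarker_features=biomarkers,
    )
    return table, truth


def simulate_split_batches(
    table: FeatureTable,
    ground_truth: GroundTruth,
    rt_drift_pct: float = 0.0,
    ppm_jitter: float = 0.0,
    reference_index: int = 0,
    seed: int = 0,
    strip_optional: bool = False,
) -> list[FeatureTable]:
    """Split a merged table into per-batch tables with perturbed feature identities.

    Every non-reference batch gets renamed feature ids, retention times
    drifted by exactly ``rt_drift_pct`` percent and m/z plus neutral mass
    jittered by exactly ``ppm_jitter`` ppm (random sign each), so matcher
    thresholds can be exercised right at their gates.  True cross-batch
    correspondences are recorded in ``ground_truth.correspondences`` as
    ``{batch_id: {perturbed_id: original_id}}``.

    ``strip_optional`` drops annotation, MS/MS and isotope metadata so only
    the numeric gates (RT, median abundancy, ppm) can fire.
    """
    rng = np.random.default_rng(seed)
    batches = table.batches
    if not 0 <= reference_index < len(batches):
        raise ValueError("reference_index out of range")
    reference_batch = batches[reference_index]
    correspondences: dict[str, dict[str, str]] = {}
    out = []
    for batch in batches:
        sids = table.sample_meta.index[table.sample_meta["batch_id"] == batch]
        sub = table.select_samples(sids)
        fmeta = sub.feature_meta.copy()
        if strip_optional:
            fmeta["annotation"] = None
            fmeta["msms"] = None
            fmeta["isotope_distribution"] = None
        if batch == reference_batch:
            correspondences[batch] = {fid: fid for fid in fmeta.index}
            out.append(FeatureTable(sub.abundance.copy(), sub.sample_meta.copy(), fmeta))
            continue
        n = len(fmeta)
        sign_rt = rng.choice([-1.0, 1.0], size=n)
        sign_mz = rng.choice([-1.0, 1.0], size=n)
        fmeta["rt"] = fmeta["rt"] * (1.0 + sign_rt * rt_drift_pct / 100.0)
        scale = 1.0 + sign_mz * ppm_jitter * 1e-6
        fmeta["mz"] = fmeta["mz"] * scale
        nm = fmeta["neutral_mass"].astype(float)
        fmeta["neutral_mass"] = nm * scale
        new_ids = [f"{fid}@{batch}" for fid in fmeta.index]
        correspondences[batch] = dict(zip(new_ids, fmeta.index))
        fmeta.index = pd.Index(new_ids, name="feature_id")
        ab = sub.abundance.copy()
        ab.columns = new_ids
        out.append(FeatureTable(ab, sub.sample_meta.copy(), fmeta))
    ground_truth.correspondences = correspondences
    return out
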