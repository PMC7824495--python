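"""Reference populations and Z-scores for metabolic-aberration screening.

Four strategies turn a patient's (normalized) abundancy into a Z-score:

``15in``
    15 age/sex-matched control samples from the patient's own batch.
``15out``
    15 age/sex-matched controls from the *other* batches.
``all``
    every control sample from every batch, ignoring age and sex.
``regression``
    an age/sex regression fitted on all controls: abundancy modelled as
    sex + sex*age + a cubic age polynomial, OLS coefficients with a
    heteroskedasticity-robust sandwich covariance whose residual
    variances are kernel-weighted means over age, so both the predicted
    mean and the prediction variance depend on the patient's age.

Before any reference set is formed, outliers are removed with five
iterations of a |Z| > 3 filter.  Patients are measured in technical
triplicate; the final Z-score is the triplicate mean, and a Welch t-test
(or its adjusted form for the regression strategy, where the reference
mean Z is 0 with negligible variance) yields a per-feature p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureTable

logger = logging.getLogger("metchalizer")

STRATEGIES = ("15in", "15out", "all", "regression")
COEFFICIENT_NAMES = ("Intercept", "Sex", "Sex.Age", "Age1", "Age2", "Age3")


# ---------------------------------------------------------------------------
# outlier removal and matched reference sets


def iterative_outlier_filter(
    values: pd.Series | np.ndarray,
    z_cut: float = 3.0,
    n_iter: int = 5,
) -> pd.Index:
    """Retained index set after iterated |Z| > ``z_cut`` removal.

    Each of the ``n_iter`` iterations recomputes mean and SD on the
    currently retained values and drops exceedances, so masked outliers
    can emerge in later rounds; the procedure is idempotent once stable.
    """
    s = pd.Series(values).dropna()
    if len(s) < 4:
        raise ValueError("need >= 4 values for outlier filtering")
    retained = s
    for _ in range(n_iter):
        sd = retained.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            break
        z = (retained - retained.mean()) / sd
        keep = z.abs() <= z_cut
        if keep.all():
            break
        retained = retained[keep]
    if len(retained) == 0:
        raise ValueError("all values removed as outliers (degenerate spread)")
    return retained.index


def matched_reference(
    patient_age: float,
    patient_sex: str,
    candidates: pd.DataFrame,
    n: int = 15,
) -> list:
    """Select ``n`` reference samples matched on age and sex.

    ``candidates`` is indexed by sample id with columns ``age`` and
    ``sex``.  Same-sex candidates are taken first in order of |age
    difference|, relaxing to the opposite sex only when too few same-sex
    candidates exist; ties break deterministically on sample id.
    """
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} candidates available, need {n}")
    cand = candidates.copy()
    dage = (cand["age"] - patient_age).abs()
    same_sex = (cand["sex"] == patient_sex).astype(int)
    # np.lexsort: last key is primary -> same sex first, then age distance, then id
    order = np.lexsort((cand.index.astype(str), dage.to_numpy(), -same_sex.to_numpy()))
    return list(cand.index[order][:n])


def zscores_from_reference(
    patient_values: pd.Series | np.ndarray,
    reference_values: pd.Series | np.ndarray,
) -> np.ndarray:
    """Standard Z-scores against a reference set: (y - mean) / SD."""
    ref = pd.Series(reference_values).dropna().to_numpy(dtype=float)
    sd = ref.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        logger.warning("zero reference SD; Z-scores undefined")
        return np.full(len(np.atleast_1d(patient_values)), np.nan)
    return (np.asarray(patient_values, dtype=float) - ref.mean()) / sd


# ---------------------------------------------------------------------------
# age/sex regression with heteroskedastic sandwich covariance


@dataclass
class RegressionFit:
    """Per-feature OLS fit of abundancy on sex and an age polynomial.

    The design row is ``[1, sex, sex*age, age, age^2, age^3]`` with sex
    coded 1 for female.  ``covariance`` is the sandwich estimator with a
    diagonal error covariance of kernel-weighted residual variances, so
    prediction variance is age dependent.  ``a`` and ``b`` (years)
    control the exponential kernel ``exp(-|age_i - age_k| / (a + b*age_i))``.
    """

    beta: pd.Series  # indexed by COEFFICIENT_NAMES (possibly reduced)
    covariance: pd.DataFrame
    train_ages: np.ndarray
    train_sex_female: np.ndarray
    train_y: np.ndarray
    residuals: np.ndarray
    a: float = 1.0
    b: float = 1.0
    degenerate: bool = False
    feature_id: str | None = None

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.train_ages.min()), float(self.train_ages.max())

    def design_row(self, age: float, sex_female: float) -> np.ndarray:
        terms = {
            "Intercept": 1.0,
            "Sex": sex_female,
            "Sex.Age": sex_female * age,
            "Age1": age,
            "Age2": age**2,
            "Age3": age**3,
        }
        return np.array([terms[c] for c in self.beta.index])

    def residual_variance(self, age: float) -> float:
        w = np.exp(-np.abs(age - self.train_ages) / (self.a + self.b * age))
        return float(np.sum(w * self.residuals**2) / np.sum(w))

    def predict(self, age: float, sex_female: float) -> float:
        return float(self.design_row(age, sex_female) @ self.beta.to_numpy())

    def prediction_variance(self, age: float, sex_female: float) -> float:
        x = self.design_row(age, sex_female)
        return float(x @ self.covariance.to_numpy() @ x) + self.residual_variance(age)


def _design_matrix(ages: np.ndarray, sex_female: np.ndarray, names: Sequence[str]) -> np.ndarray:
    cols = {
        "Intercept": np.ones_like(ages),
        "Sex": sex_female,
        "Sex.Age": sex_female * ages,
        "Age1": ages,
        "Age2": ages**2,
        "Age3": ages**3,
    }
    return np.column_stack([cols[c] for c in names])


def _kernel_weights(eval_ages: np.ndarray, train_ages: np.ndarray, a: float, b: float) -> np.ndarray:
    """Weight matrix W[i, k] = exp(-|age_i - age_k| / (a + b * age_i))."""
    d = np.abs(eval_ages[:, None] - train_ages[None, :])
    return np.exp(-d / (a + b * eval_ages)[:, None])


def fit_reference_regression(
    ages: Sequence[float],
    sex_female: Sequence[float],
    y: Sequence[float],
    a: float = 1.0,
    b: float = 1.0,
    min_samples: int = 30,
    feature_id: str | None = None,
) -> RegressionFit:
    """Fit the age/sex reference regression for one feature.

    OLS coefficients, kernel-weighted residual variances per training
    sample, and the sandwich covariance
    ``(X'X)^-1 X' diag(sigma_k^2) X (X'X)^-1``.  A single-sex cohort is
    flagged degenerate and fitted without the sex terms.
    """
    ages = np.asarray(ages, dtype=float)
    sexf = np.asarray(sex_female, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(sexf) & np.isfinite(yv)
    ages, sexf, yv = ages[ok], sexf[ok], yv[ok]
    if len(yv) < min_samples:
        raise ValueError(f"need >= {min_samples} reference samples, got {len(yv)}")

    names = list(COEFFICIENT_NAMES)
    degenerate = False
    if len(np.unique(sexf)) < 2:
        names = [c for c in names if not c.startswith("Sex")]
        degenerate = True

    X = _design_matrix(ages, sexf, names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for feature {feature_id!r}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ yv
    resid = yv - X @ beta

    W = _kernel_weights(ages, ages, a, b)
    sigma2 = (W @ resid**2) / W.sum(axis=1)
    cov = xtx_inv @ (X.T * sigma2) @ X @ xtx_inv

    return RegressionFit(
        beta=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        train_ages=ages,
        train_sex_female=sexf,
        train_y=yv,
        residuals=resid,
        a=a,
        b=b,
        degenerate=degenerate,
        feature_id=feature_id,
    )


def regression_zscore(
    fit: RegressionFit,
    y: float,
    age: float,
    sex_female: float,
    scale: str = "sd",
) -> tuple[float, bool]:
    """Z-score of one observation under the regression reference.

    ``z = (y - yhat) / sqrt(Var[yhat])`` with the prediction variance
    evaluated at the patient's covariates (``scale='variance'`` divides
    by the variance itself, the strict-literal reading).  Returns
    ``(z, extrapolated)`` where the flag marks ages outside the training
    range.
    """
    pred = fit.predict(age, sex_female)
    var = fit.prediction_variance(age, sex_female)
    denom = np.sqrt(var) if scale == "sd" else var
    lo, hi = fit.age_range
    return (y - pred) / denom, bool(age < lo or age > hi)


def coefficient_inference(
    fit: RegressionFit,
    n_bootstrap: int = 50,
    subsample: float = 0.9,
    seed: int = 0,
) -> pd.Series:
    """Robust per-coefficient p-values from subsample-median bootstrapping.

    Each of ``n_bootstrap`` replicates refits on a ``subsample`` fraction
    of the data drawn without replacement and computes the two-tailed
    normal p-value of ``beta_i / sqrt(Var[beta_i])``; the robust p-value
    is the median over replicates.  Failed refits are skipped and
    counted in the log.
    """
    rng = np.random.default_rng(seed)
    n = len(fit.train_y)
    m = max(int(round(subsample * n)), len(fit.beta) + 1)
    pvals = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.choice(n, size=m, replace=False)
        try:
            sub = fit_reference_regression(
                fit.train_ages[idx], fit.train_sex_female[idx], fit.train_y[idx],
                a=fit.a, b=fit.b, min_samples=len(fit.beta) + 1,
            )
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        se = np.sqrt(np.diag(sub.covariance.to_numpy()))
        z = sub.beta.to_numpy() / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        pvals.append(pd.Series(p, index=sub.beta.index))
    if failures:
        logger.warning("coefficient_inference: %d bootstrap refits failed", failures)
    if not pvals:
        raise ValueError("all bootstrap refits failed")
    return pd.concat(pvals, axis=1).median(axis=1).reindex(fit.beta.index)


def significance_table(
    pvalues: pd.DataFrame,
    ion_modes: pd.Series,
    alpha: float = 0.05,
    age1_effect_pct: pd.Series | None = None,
    effect_threshold_pct_per_year: float | None = None,
) -> pd.DataFrame:
    """Percent of features with significant coefficients per ion mode.

    Benjamini-Hochberg correction is applied separately per (coefficient,
    ion mode).  Optionally, significance of the linear age coefficient is
    additionally gated on an effect size (percent change per year at the
    cohort median age) exceeding ``effect_threshold_pct_per_year``.
    Returns a frame indexed by coefficient with one column per ion mode.
    """
    modes = list(pd.unique(ion_modes.dropna()))
    out = pd.DataFrame(index=pvalues.columns, columns=modes, dtype=float)
    for coeff in pvalues.columns:
        for mode in modes:
            feats = ion_modes.index[ion_modes == mode]
            p = pvalues.loc[pvalues.index.intersection(feats), coeff].dropna()
            if len(p) == 0:
                out.loc[coeff, mode] = np.nan
                continue
            reject = multipletests(p.to_numpy(), alpha=alpha, method="fdr_bh")[0]
            sig = pd.Series(reject, index=p.index)
            if (
                coeff == "Age1"
                and age1_effect_pct is not None
                and effect_threshold_pct_per_year is not None
            ):
                eff = age1_effect_pct.reindex(p.index).abs() > effect_threshold_pct_per_year
                sig = sig & eff.fillna(False)
            out.loc[coeff, mode] = 100.0 * sig.mean()
    return out


def welch_pvalue(
    triplicate_z: Sequence[float],
    reference_z: Sequence[float] | None = None,
    method: str = "welch",
    df_adjusted: float | None = 2.0,
) -> float:
    """p-value for a triplicate's mean Z against the reference population.

    ``method='welch'`` runs the standard Welch t-test of the three
    triplicate Z-scores against the reference Z-scores.
    ``method='adjusted'`` assumes the reference mean Z is exactly 0 with
    negligible variance: ``t = mean(Z) / sqrt(s^2 / 3)``, referred to a
    t distribution with ``df_adjusted`` degrees of freedom (the
    triplicate's n - 1; pass ``None`` for a normal reference).
    """
    trip = np.asarray(triplicate_z, dtype=float)
    trip = trip[np.isfinite(trip)]
    if len(trip) < 2:
        return np.nan
    s = trip.std(ddof=1)
    if s == 0:
        logger.warning("zero triplicate spread; Welch p undefined")
        return np.nan
    if method == "adjusted":
        t = trip.mean() / np.sqrt(s**2 / len(trip))
        if df_adjusted is None:
            return float(2.0 * stats.norm.sf(abs(t)))
        return float(2.0 * stats.t.sf(abs(t), df=df_adjusted))
    if reference_z is None:
        raise ValueError("standard Welch test requires reference Z-scores")
    ref = np.asarray(reference_z, dtype=float)
    ref = ref[np.isfinite(ref)]
    res = stats.ttest_ind(trip, ref, equal_var=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# strategy orchestration


@dataclass
class ZScoreResult:
    """Z-scores of all patient replicates under one reference strategy.

    ``z`` is replicate-level (patient samples x features), ``mean_z`` and
    ``pvalues`` are triplicate-level (triplicate id x features).
    ``reference_sets`` records the sample ids used, keyed by
    ``(triplicate_id, feature_id)`` for the matched strategies and by
    ``feature_id`` for ``all``/``regression``.
    """

    strategy: str
    z: pd.DataFrame
    mean_z: pd.DataFrame
    pvalues: pd.DataFrame
    reference_sets: dict = field(default_factory=dict)
    extrapolated: pd.DataFrame | None = None
    fits: dict | None = None


def compute_zscores(
    table: FeatureTable,
    strategy: str,
    n_ref: int = 15,
    outlier_z: float = 3.0,
    n_outlier_iter: int = 5,
    a: float = 1.0,
    b: float = 1.0,
    min_regression_samples: int = 30,
    z_scale: str = "sd",
    keep_fits: bool = False,
) -> ZScoreResult:
    """Compute per-replicate and triplicate-mean Z-scores plus Welch p-values.

    Reference candidates are the control samples; a patient's own
    replicates are never part of its reference set.  See the module
    docstring for the four strategies.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    meta = table.sample_meta
    controls = meta.index[meta["class"] == "control"]
    patients = meta.index[(meta["class"] == "patient") & meta["triplicate_id"].notna()]
    if len(patients) == 0:
        raise ValueError("no patient triplicates present")
    trip_ids = list(pd.unique(meta.loc[patients, "triplicate_id"]))
    feats = [f for f in table.feature_ids if f not in set(table.internal_standard_ids)]

    z = pd.DataFrame(np.nan, index=patients, columns=feats)
    mean_z = pd.DataFrame(np.nan, index=trip_ids, columns=feats)
    pvals = pd.DataFrame(np.nan, index=trip_ids, columns=feats)
    extrap = pd.DataFrame(False, index=trip_ids, columns=feats) if strategy == "regression" else None
    ref_sets: dict = {}
    fits: dict = {}

    trip_samples = {
        tid: list(meta.index[(meta["triplicate_id"] == tid) & (meta["class"] == "patient")])
        for tid in trip_ids
    }

    for fid in feats:
        col = table.abundance[fid]
        if strategy == "regression":
            kept = _within_batch_filter(col.loc[controls], meta.loc[controls, "batch_id"],
                                        outlier_z, n_outlier_iter)
            sub = meta.loc[kept]
            try:
                fit = fit_reference_regression(
                    sub["age"].to_numpy(dtype=float),
                    (sub["sex"] == "F").to_numpy(dtype=float),
                    col.loc[kept].to_numpy(dtype=float),
                    a=a, b=b, min_samples=min_regression_samples, feature_id=fid,
                )
            except ValueError as exc:
                logger.warning("regression fit failed for %s: %s", fid, exc)
                continue
            ref_sets[fid] = list(kept)
            if keep_fits:
                fits[fid] = fit
            for tid in trip_ids:
                sids = trip_samples[tid]
                age = float(meta.loc[sids[0], "age"])
                sexf = 1.0 if meta.loc[sids[0], "sex"] == "F" else 0.0
                zs = []
                for sid in sids:
                    yv = col.loc[sid]
                    if pd.isna(yv):
                        zs.append(np.nan)
                        continue
                    zz, ex = regression_zscore(fit, float(yv), age, sexf, scale=z_scale)
                    zs.append(zz)
                    if ex:
                        extrap.loc[tid, fid] = True
                z.loc[sids, fid] = zs
                finite = [v for v in zs if np.isfinite(v)]
                if finite:
                    mean_z.loc[tid, fid] = float(np.mean(finite))
                    pvals.loc[tid, fid] = welch_pvalue(finite, method="adjusted")
            continue

        if strategy == "all":
            vals = col.loc[controls].dropna()
            if len(vals) < 4:
                continue
            kept = iterative_outlier_filter(vals, z_cut=outlier_z, n_iter=n_outlier_iter)
            ref_vals = vals.loc[kept]
            ref_sets[fid] = list(kept)
            ref_z = zscores_from_reference(ref_vals, ref_vals)
            for tid in trip_ids:
                sids = trip_samples[tid]
                zs = zscores_from_reference(col.loc[sids], ref_vals)
                z.loc[sids, fid] = zs
                finite = zs[np.isfinite(zs)]
                if len(finite):
                    mean_z.loc[tid, fid] = float(np.mean(finite))
                    pvals.loc[tid, fid] = welch_pvalue(finite, ref_z, method="welch")
            continue

        # 15in / 15out
        for tid in trip_ids:
            sids = trip_samples[tid]
            batch = meta.loc[sids[0], "batch_id"]
            if strategy == "15in":
                scope = controls[meta.loc[controls, "batch_id"] == batch]
            else:
                scope = controls[meta.loc[controls, "batch_id"] != batch]
            vals = col.loc[scope].dropna()
            if len(vals) < 4:
                continue
            kept = iterative_outlier_filter(vals, z_cut=outlier_z, n_iter=n_outlier_iter)
            cand = meta.loc[kept, ["age", "sex"]]
            if len(cand) < n_ref:
                logger.warning(
                    "%s/%s: only %d candidates for strategy %s; skipped",
                    tid, fid, len(cand), strategy,
                )
                continue
            age = float(meta.loc[sids[0], "age"])
            sex = meta.loc[sids[0], "sex"]
            chosen = matched_reference(age, sex, cand, n=n_ref)
            ref_sets[(tid, fid)] = chosen
            ref_vals = col.loc[chosen]
            ref_z = zscores_from_reference(ref_vals, ref_vals)
            zs = zscores_from_reference(col.loc[sids], ref_vals)
            z.loc[sids, fid] = zs
            finite = zs[np.isfinite(zs)]
            if len(finite):
                mean_z.loc[tid, fid] = float(np.mean(finite))
                pvals.loc[tid, fid] = welch_pvalue(finite, ref_z, method="welch")

    return ZScoreResult(
        strategy=strategy,
        z=z,
        mean_z=mean_z,
        pvalues=pvals,
        reference_sets=ref_sets,
        extrapolated=extrap,
        fits=fits if keep_fits else None,
    )


def _within_batch_filter(
    values: pd.Series,
    batches: pd.Series,
    z_cut: float,
    n_iter: int,
) -> pd.Index:
    """Iterative outlier filter applied within each batch; returns kept ids."""
    kept: list = []
    for _, grp in values.groupby(batches):
        vals = grp.dropna()
        if len(vals) < 4:
            kept.extend(list(vals.index))
            continue
        kept.extend(list(iterative_outlier_filter(vals, z_cut=z_cut, n_iter=n_iter)))
    return pd.Index(kept)


def regression_report(
    table: FeatureTable,
    n_bootstrap: int = 50,
    subsample: float = 0.9,
    seed: int = 0,
    alpha: float = 0.05,
    effect_threshold_pct_per_year: float | None = None,
    min_regression_samples: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the age/sex regression per feature and tabulate significance.

    Returns ``(pvalues, percent_significant)``: robust bootstrap-median
    p-values per feature and coefficient, and the BH-corrected percent of
    significant coefficients per ion mode.  Per-feature bootstrap seeds
    derive deterministically from ``seed``.
    """
    meta = table.sample_meta
    controls = meta.index[meta["class"] == "control"]
    feats = [f for f in table.feature_ids if f not in set(table.internal_standard_ids)]
    pvalues = pd.DataFrame(np.nan, index=feats, columns=list(COEFFICIENT_NAMES))
    effects = pd.Series(np.nan, index=feats)
    rng = np.random.default_rng(seed)
    feat_seeds = {fid: int(rng.integers(0, 2**31 - 1)) for fid in feats}
    for fid in feats:
        col = table.abundance[fid]
        kept = _within_batch_filter(col.loc[controls], meta.loc[controls, "batch_id"], 3.0, 5)
        sub = meta.loc[kept]
        try:
            fit = fit_reference_regression(
                sub["age"].to_numpy(dtype=float),
                (sub["sex"] == "F").to_numpy(dtype=float),
                col.loc[kept].to_numpy(dtype=float),
                min_samples=min_regression_samples, feature_id=fid,
            )
            p = coefficient_inference(fit, n_bootstrap=n_bootstrap, subsample=subsample,
                                      seed=feat_seeds[fid])
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("regression_report: feature %s skipped (%s)", fid, exc)
            continue
        for c in p.index:
            pvalues.loc[fid, c] = p[c]
        med_age = float(np.median(fit.train_ages))
        pred = fit.predict(med_age, 0.5)
        if pred != 0 and "Age1" in fit.beta.index:
            effects[fid] = 100.0 * abs(fit.beta["Age1"] / pred)
    modes = table.feature_meta.loc[feats, "ion_mode"]
    table1 = significance_table(
        pvalues, modes, alpha=alpha,
        age1_effect_pct=effects,
        effect_threshold_pct_per_year=effect_threshold_pct_per_year,
    )
    return pvalues, table1
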