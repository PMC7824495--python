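"""Initial transforms and batch-effect normalization methods.

Four normalizers are implemented:

``Metchalizer``
    Represents the (correlated) internal standards by an orthogonal set
    of latent variables (LVs) from a PLS regression of the IS abundancies
    against batch membership, then fits, per feature, a linear mixed model
    with the LV scores as fixed effects and a random batch intercept.
    Everything the model explains -- IS-tracked technical variation plus
    the residual batch offsets -- is subtracted from the abundancies.

``Best correlated IS``
    Divides each feature by the internal standard it correlates best
    with (within-batch Spearman, averaged over batches), rescaled by the
    global median of that standard.

``Anchor``
    Divides each feature by the per-batch mean of designated anchor
    samples (by default the QC replicates).

``PQN``
    Probabilistic quotient normalization: each sample is divided by the
    median ratio of its spectrum to the median reference spectrum.

Method labels follow the ``{None,Log,BC}-{Method}`` convention, naming
the initial transform and the normalizer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .core_io import FeatureTable, TransformSpec

logger = logging.getLogger("metchalizer")


@dataclass
class NormalizedTable(FeatureTable):
    """A :class:`FeatureTable` carrying normalization provenance.

    ``provenance`` records the initial transform, the method name and the
    composed ``{transform}-{method}`` label.
    """

    provenance: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.provenance.get("label", "None-Raw")


def _transform_label(spec: TransformSpec | None) -> str:
    return spec.label if spec is not None else "None"


def _as_normalized(table: FeatureTable, abundance: pd.DataFrame, method: str,
                   transform: TransformSpec | None, extra: dict | None = None) -> NormalizedTable:
    prov = {
        "transform": transform,
        "method": method,
        "label": f"{_transform_label(transform)}-{method}",
    }
    if extra:
        prov.update(extra)
    return NormalizedTable(
        abundance=abundance,
        sample_meta=table.sample_meta.copy(),
        feature_meta=table.feature_meta.copy(),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# initial transforms


def apply_transform(table: FeatureTable, spec: TransformSpec) -> NormalizedTable:
    """Apply the initial variance-stabilizing transform elementwise.

    ``log`` requires strictly positive abundancies; ``boxcox`` requires
    ``y + lambda2 > 0``.  Violations raise with the offending cells named.
    """
    values = table.abundance.to_numpy(dtype=float).copy()
    if spec.kind == "none":
        out = values
    elif spec.kind == "log":
        bad = np.argwhere((values <= 0) & ~np.isnan(values))
        if len(bad):
            cells = _describe_cells(table, bad)
            raise ValueError(f"log transform requires positive abundancies; offending cells: {cells}")
        out = np.log(values)
    else:  # boxcox
        shifted = values + spec.lambda2
        bad = np.argwhere((shifted <= 0) & ~np.isnan(values))
        if len(bad):
            cells = _describe_cells(table, bad)
            raise ValueError(
                f"boxcox transform requires y + lambda2 > 0; offending cells: {cells}"
            )
        out = (np.power(shifted, spec.lambda1) - 1.0) / spec.lambda1
    abundance = pd.DataFrame(out, index=table.abundance.index, columns=table.abundance.columns)
    return _as_normalized(table, abundance, "Raw", spec)


def invert_transform(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Inverse of :func:`apply_transform` on plain arrays."""
    if spec.kind == "none":
        return values
    if spec.kind == "log":
        return np.exp(values)
    return np.power(values * spec.lambda1 + 1.0, 1.0 / spec.lambda1) - spec.lambda2


def _describe_cells(table: FeatureTable, bad: np.ndarray, limit: int = 5) -> str:
    cells = [
        f"({table.abundance.index[i]}, {table.abundance.columns[j]})" for i, j in bad[:limit]
    ]
    more = "" if len(bad) <= limit else f" and {len(bad) - limit} more"
    return ", ".join(cells) + more


# ---------------------------------------------------------------------------
# latent variables from internal standards


@dataclass
class LatentVariables:
    """PLS latent variables of the internal-standard space.

    Scores for new samples are ``((X - means) / scales) @ rotations``;
    only the first ``selected_k`` columns are used as fixed effects.
    """

    is_feature_ids: list[str]
    means: np.ndarray
    scales: np.ndarray
    rotations: np.ndarray  # n_is x k_max
    selected_k: int
    i_curve: np.ndarray  # I(K) for K = 1..k_max
    scores: pd.DataFrame  # training-sample scores, samples x k_max

    def transform(self, is_matrix: pd.DataFrame) -> np.ndarray:
        x = (is_matrix[self.is_feature_ids].to_numpy(dtype=float) - self.means) / self.scales
        return x @ self.rotations


def select_latent_variables(
    is_matrix: pd.DataFrame,
    batch_labels: Sequence,
    i_fraction: float = 0.75,
    max_components: int | None = None,
) -> LatentVariables:
    """Choose PLS latent variables of the IS matrix against batch membership.

    The IS columns are centred and unit-scaled, then regressed (PLS2)
    on the one-hot batch matrix.  The selection metric

        I(K) = sum_{k<=K} sum_{b,i} (x_ib^LVk - xbar_b^LVk)^2

    accumulates, per latent variable, the squared deviation of sample
    scores from their batch centre; the smallest ``K`` reaching
    ``i_fraction`` of ``I(K_max)`` is selected.
    """
    if is_matrix.isna().any().any():
        raise ValueError("internal-standard matrix must be complete (no missing values)")
    batches = pd.Series(list(batch_labels), index=is_matrix.index)
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("latent-variable selection requires >= 2 batches")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    X = is_matrix.to_numpy(dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales

    Y = pd.get_dummies(batches).to_numpy(dtype=float)
    k_max = min(Xs.shape[1], Xs.shape[0] - 1)
    if max_components is not None:
        k_max = min(k_max, max_components)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=k_max, scale=False)
        pls.fit(Xs, Y)
    scores = pls.x_scores_  # n x k_max

    codes = batches.to_numpy()
    i_terms = np.empty(k_max)
    for k in range(k_max):
        col = scores[:, k]
        within = 0.0
        for b in counts.index:
            sub = col[codes == b]
            within += float(np.sum((sub - sub.mean()) ** 2))
        i_terms[k] = within
    i_curve = np.cumsum(i_terms)
    target = i_fraction * i_curve[-1]
    selected_k = int(np.argmax(i_curve >= target) + 1)

    return LatentVariables(
        is_feature_ids=list(is_matrix.columns),
        means=means,
        scales=scales,
        rotations=np.asarray(pls.x_rotations_),
        selected_k=selected_k,
        i_curve=i_curve,
        scores=pd.DataFrame(scores, index=is_matrix.index,
                            columns=[f"LV{k + 1}" for k in range(k_max)]),
    )


# ---------------------------------------------------------------------------
# Metchalizer


@dataclass
class MetchalizerFit:
    """Fitted Metchalizer model.

    Per feature ``j``: fixed-effect coefficients ``beta_j0, beta_jk`` on
    the selected LV scores, one random intercept ``gamma_jb`` per batch,
    and the recentering constants (global and per-batch medians of the
    fitted values).
    """

    transform: TransformSpec
    latent: LatentVariables
    coefficients: pd.DataFrame  # features x [beta0, beta1..betaK]
    random_intercepts: pd.DataFrame  # features x batches
    recenter_global: pd.Series  # per feature
    recenter_per_batch: pd.DataFrame  # features x batches
    outliers: dict  # feature -> list of sample ids removed pre-fit
    fallback_features: list  # features fitted by OLS (gamma = 0)

    @property
    def selected_k(self) -> int:
        return self.latent.selected_k

    def predict(self, scores: np.ndarray, batch_ids: Sequence, feature_id: str) -> np.ndarray:
        beta = self.coefficients.loc[feature_id].to_numpy()
        gamma = self.random_intercepts.loc[feature_id]
        k = self.selected_k
        fixed = beta[0] + scores[:, :k] @ beta[1 : k + 1]
        return fixed + np.asarray([gamma.get(b, 0.0) for b in batch_ids])


def _within_batch_outliers(y: pd.Series, batches: pd.Series, z_cut: float = 2.0) -> pd.Index:
    """Sample ids whose within-batch Z-score exceeds ``z_cut`` in magnitude."""
    out = []
    for b, grp in y.groupby(batches):
        vals = grp.dropna()
        if len(vals) < 3:
            continue
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        z = (vals - vals.mean()) / sd
        out.extend(list(z.index[z.abs() > z_cut]))
    return pd.Index(out)


def _fit_single_feature(
    y: pd.Series,
    scores: np.ndarray,
    batches: pd.Series,
    k: int,
    feature_id: str,
) -> tuple[np.ndarray, pd.Series, bool]:
    """Random-intercept fit of one feature on the first ``k`` LV scores.

    Returns ``(beta, gamma, used_fallback)``.  Estimation is REML via
    :class:`statsmodels` MixedLM.  Two degenerate regimes are handled
    explicitly: an (almost) exact fit, where the BLUP shrinkage vanishes
    and the fixed-effect solution with sum-to-zero batch contrasts is the
    limit, and a zero random-intercept variance, where the model reduces
    to OLS with all ``gamma`` at zero.
    """
    mask = y.notna()
    yv = y[mask].to_numpy(dtype=float)
    Xl = scores[mask.to_numpy(), :k]
    bv = batches[mask]
    batch_names = list(pd.unique(bv))
    n_b = len(batch_names)

    X_fixed = np.column_stack([np.ones(len(yv)), Xl])
    if np.linalg.matrix_rank(X_fixed) < X_fixed.shape[1]:
        raise ValueError(f"singular fixed-effect design for feature {feature_id!r}")

    if n_b == 1:
        beta, *_ = np.linalg.lstsq(X_fixed, yv, rcond=None)
        return beta, pd.Series(0.0, index=batch_names), False

    # sum-to-zero batch contrasts: exact-fit limit of the BLUPs
    codes = pd.Categorical(bv, categories=batch_names).codes
    D = np.zeros((len(yv), n_b - 1))
    for c in range(n_b - 1):
        D[codes == c, c] = 1.0
    D[codes == n_b - 1, :] = -1.0
    X_full = np.column_stack([X_fixed, D])
    coef, *_ = np.linalg.lstsq(X_full, yv, rcond=None)
    resid = yv - X_full @ coef
    scale = max(np.var(yv), 1e-300)
    if np.var(resid) < 1e-16 * scale:
        gamma_vals = np.append(coef[k + 1 :], -np.sum(coef[k + 1 :]))
        return coef[: k + 1], pd.Series(gamma_vals, index=batch_names), False

    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # bfgs occasionally stops on the variance boundary; powell is the
        # robust (if slower) retry before declaring the variance truly zero
        for method in ("bfgs", "powell"):
            try:
                model = MixedLM(endog=yv, exog=X_fixed, groups=np.asarray(bv))
                res = model.fit(reml=True, method=method, maxiter=500)
                var_re = float(np.asarray(res.cov_re).ravel()[0])
                if not np.isfinite(var_re) or var_re <= 1e-10 * scale:
                    continue
                beta = np.asarray(res.fe_params)
                gamma = pd.Series(
                    {g: float(np.asarray(v).ravel()[0]) for g, v in res.random_effects.items()}
                ).reindex(batch_names)
                return beta, gamma, False
            except Exception:
                continue
    # zero (or inestimable) random-intercept variance: OLS with gamma = 0
    beta, *_ = np.linalg.lstsq(X_fixed, yv, rcond=None)
    return beta, pd.Series(0.0, index=batch_names), True


def fit_metchalizer(
    table: FeatureTable,
    is_feature_ids: Sequence[str] | None = None,
    transform_spec: TransformSpec | None = None,
    outlier_z: float = 2.0,
    min_batch_samples: int = 3,
) -> MetchalizerFit:
    """Fit the Metchalizer model on a merged multi-batch table.

    The initial transform (default log) is applied to features and
    internal standards alike; the IS matrix must be complete.  Per
    feature, samples with within-batch ``|Z| > outlier_z`` are removed
    before fitting, and batches retaining fewer than ``min_batch_samples``
    samples keep a zero intercept (with a warning).
    """
    if transform_spec is None:
        transform_spec = TransformSpec(kind="log")
    is_ids = list(is_feature_ids) if is_feature_ids is not None else table.internal_standard_ids
    if not is_ids:
        raise ValueError("no internal standards designated")
    missing = [f for f in is_ids if f not in table.abundance.columns]
    if missing:
        raise ValueError(f"internal standards absent from table: {missing}")

    transformed = apply_transform(table, transform_spec)
    ab = transformed.abundance
    if ab[is_ids].isna().any().any():
        raise ValueError("internal standards must be complete in all batches")

    batches = table.sample_meta["batch_id"]
    latent = select_latent_variables(ab[is_ids], batches)
    k = latent.selected_k
    scores = latent.scores.to_numpy()[:, :]

    features = [f for f in ab.columns if f not in set(is_ids)]
    batch_names = list(pd.unique(batches))

    coefs = pd.DataFrame(
        0.0, index=features, columns=["beta0"] + [f"beta{i + 1}" for i in range(k)]
    )
    gammas = pd.DataFrame(0.0, index=features, columns=batch_names)
    rec_glob = pd.Series(0.0, index=features)
    rec_batch = pd.DataFrame(0.0, index=features, columns=batch_names)
    outliers: dict = {}
    fallback: list = []

    for fid in features:
        y = ab[fid]
        out_idx = _within_batch_outliers(y, batches, z_cut=outlier_z)
        outliers[fid] = list(out_idx)
        y_fit = y.copy()
        y_fit[out_idx] = np.nan

        keep_counts = y_fit.notna().groupby(batches).sum()
        thin = keep_counts.index[keep_counts < min_batch_samples]
        if len(thin):
            logger.warning(
                "feature %s: batches %s have < %d samples after outlier removal; "
                "their intercepts fall back to 0",
                fid, list(thin), min_batch_samples,
            )
            y_fit[batches.isin(thin)] = np.nan

        beta, gamma, used_fb = _fit_single_feature(y_fit, scores, batches, k, fid)
        coefs.loc[fid] = beta
        for b in batch_names:
            gammas.loc[fid, b] = gamma.get(b, 0.0)
        if used_fb:
            fallback.append(fid)

        # fitted values for every sample (outliers included)
        pred = beta[0] + scores[:, :k] @ beta[1:] + gammas.loc[fid, batches].to_numpy()
        present = y.notna().to_numpy()
        rec_glob[fid] = float(np.median(pred[present])) if present.any() else np.nan
        for b in batch_names:
            m = present & (batches == b).to_numpy()
            rec_batch.loc[fid, b] = float(np.median(pred[m])) if m.any() else np.nan

    return MetchalizerFit(
        transform=transform_spec,
        latent=latent,
        coefficients=coefs,
        random_intercepts=gammas,
        recenter_global=rec_glob,
        recenter_per_batch=rec_batch,
        outliers=outliers,
        fallback_features=fallback,
    )


def apply_metchalizer(
    table: FeatureTable,
    fit: MetchalizerFit,
    recenter: str = "global",
) -> NormalizedTable:
    """Batch-correct a table with a fitted Metchalizer model.

    The corrected abundancy is ``y - yhat + median(yhat)`` where the
    recentering median is over all samples (``recenter='global'``,
    default) or per batch (``recenter='per_batch'``).  Internal standards
    pass through transformed but uncorrected.  Samples excluded as
    outliers during fitting are still normalized.
    """
    if recenter not in ("global", "per_batch"):
        raise ValueError("recenter must be 'global' or 'per_batch'")
    transformed = apply_transform(table, fit.transform)
    ab = transformed.abundance.copy()
    batches = table.sample_meta["batch_id"]
    unknown = set(pd.unique(batches)) - set(fit.random_intercepts.columns)
    if unknown:
        raise ValueError(f"batches absent from fit: {sorted(unknown)}")

    scores = fit.latent.transform(ab)
    k = fit.selected_k
    batch_arr = batches.to_numpy()
    for fid in fit.coefficients.index:
        if fid not in ab.columns:
            raise ValueError(f"feature {fid!r} absent from table")
        pred = fit.predict(scores, batch_arr, fid)
        if recenter == "global":
            center = np.full(len(ab), fit.recenter_global[fid])
        else:
            center = fit.recenter_per_batch.loc[fid, batch_arr].to_numpy(dtype=float)
        ab[fid] = ab[fid].to_numpy() - pred + center

    return _as_normalized(table, ab, "Metchalizer", fit.transform, {"fit": fit, "recenter": recenter})


# ---------------------------------------------------------------------------
# baseline normalizers


def normalize_best_correlated_is(
    table: FeatureTable,
    is_feature_ids: Sequence[str] | None = None,
    transform_spec: TransformSpec | None = None,
) -> NormalizedTable:
    """Normalize each feature by its best (positively) correlated internal standard.

    The Spearman correlation between a feature and each internal standard
    is computed within every batch and averaged across batches; the
    standard with the highest positive average wins, and the feature is
    divided by it and rescaled by the standard's global median.  Features
    whose average correlations are all non-positive are left unnormalized
    with a warning.
    """
    is_ids = list(is_feature_ids) if is_feature_ids is not None else table.internal_standard_ids
    if not is_ids:
        raise ValueError("no internal standards designated")
    ab = table.abundance
    if (ab[is_ids] <= 0).any().any():
        raise ValueError("internal-standard abundancies must be strictly positive")

    batches = table.sample_meta["batch_id"]
    features = [f for f in ab.columns if f not in set(is_ids)]
    out = ab.copy()
    chosen: dict = {}
    for fid in features:
        avg = _mean_batch_spearman(ab[fid], ab[is_ids], batches)
        best = avg.idxmax()
        if not np.isfinite(avg[best]) or avg[best] <= 0:
            logger.warning("feature %s: no positively correlated internal standard; left unnormalized", fid)
            chosen[fid] = None
            continue
        chosen[fid] = best
        ref = ab[best]
        out[fid] = ab[fid] / ref * float(ref.median())
    return _as_normalized(table, out, "Best correlated IS", transform_spec, {"selected_is": chosen})


def _mean_batch_spearman(y: pd.Series, is_matrix: pd.DataFrame, batches: pd.Series) -> pd.Series:
    per_batch = []
    for _, idx in batches.groupby(batches).groups.items():
        sub_y = y.loc[idx]
        ok = sub_y.notna()
        if ok.sum() < 3:
            continue
        sub = is_matrix.loc[idx][ok]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = [stats.spearmanr(sub_y[ok], sub[c]).statistic for c in sub.columns]
        per_batch.append(pd.Series(rho, index=is_matrix.columns))
    if not per_batch:
        return pd.Series(np.nan, index=is_matrix.columns)
    return pd.concat(per_batch, axis=1).mean(axis=1)


def normalize_anchor(
    table: FeatureTable,
    anchor_class: str = "qc",
    transform_spec: TransformSpec | None = None,
) -> NormalizedTable:
    """Divide every feature by the per-batch mean of the anchor samples."""
    meta = table.sample_meta
    ab = table.abundance
    out = ab.copy()
    for b in table.batches:
        in_batch = meta["batch_id"] == b
        anchors = meta.index[in_batch & (meta["class"] == anchor_class)]
        if len(anchors) == 0:
            raise ValueError(f"batch {b!r} has no anchor samples of class {anchor_class!r}")
        means = ab.loc[anchors].mean(axis=0)
        if (means == 0).any():
            zero = list(means.index[means == 0])
            raise ValueError(f"batch {b!r}: zero anchor mean for features {zero[:5]}")
        out.loc[in_batch] = ab.loc[in_batch] / means
    return _as_normalized(table, out, "Anchor", transform_spec)


def normalize_pqn(
    table: FeatureTable,
    transform_spec: TransformSpec | None = None,
) -> NormalizedTable:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median over all samples;
    each sample is divided by the median of its feature-wise quotients
    against that reference.
    """
    ab = table.abundance
    if (ab <= 0).any().any():
        raise ValueError("PQN requires strictly positive abundancies")
    reference = ab.median(axis=0)
    quotients = ab / reference
    dilution = quotients.median(axis=1)
    if dilution.isna().any():
        bad = list(dilution.index[dilution.isna()])
        raise ValueError(f"samples with no quantifiable features: {bad}")
    out = ab.div(dilution, axis=0)
    return _as_normalized(table, out, "PQN", transform_spec, {"dilution_factors": dilution})
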