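"""Expression / CAGE-TSS cis-QTL stage.

Feature filtering (TPM and CTSS rules, age cutoff, missingness and
low-variance options), per-feature rank inverse-normal transformation,
UMAP sample-embedding covariates, and a +/-1 Mb cis window scan with
Benjamini-Hochberg FDR across all tested variant-feature pairs.

The scan itself is a plain per-pair OLS of the transformed feature on the
variant dosage plus covariates, computed via Frisch-Waugh residualization
so one covariate projection is shared across all variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class QtlFilterConfig:
    tpm_threshold: float = 1.0
    tpm_fraction: float = 1 / 3  # drop if TPM < threshold in more than this fraction
    ctss_min_samples: int = 10  # keep if > min_reads in more than this many samples
    ctss_min_reads: int = 5
    ctss_presence_fraction: float = 0.90
    min_age: float = 15.0  # samples must be strictly older
    missingness_threshold: float | None = None  # drop features detected in < this fraction
    low_variance_quantile: float | None = None  # drop the bottom q variance features

    def __post_init__(self):
        for frac in (self.tpm_fraction, self.ctss_presence_fraction):
            if not 0 < frac <= 1:
                raise ValueError("filter fractions must lie in (0, 1]")


def filter_features(
    matrix: pd.DataFrame,
    kind: str,
    cfg: QtlFilterConfig | None = None,
    ages: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the kind-appropriate feature filters; return (filtered, audit).

    Samples with age <= ``min_age`` are dropped first (when ages are given).
    TPM mode drops features with TPM < threshold in more than ``tpm_fraction``
    of subjects, then the optional missingness and low-variance filters.
    CTSS mode keeps features with > ``ctss_min_reads`` reads in >
    ``ctss_min_samples`` samples AND detected in >= ``ctss_presence_fraction``
    of samples. The audit lists every dropped feature/sample with its reason.
    """
    if kind not in ("TPM", "CTSS-count"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    cfg = cfg or QtlFilterConfig()
    audit_rows = []
    mat = matrix
    if ages is not None:
        ages = ages.reindex(mat.columns)
        young = ages[ages <= cfg.min_age].index
        for s in young:
            audit_rows.append({"item": s, "type": "sample", "kept": False,
                               "reason": f"age <= {cfg.min_age}"})
        mat = mat.drop(columns=young)

    vals = mat.to_numpy(dtype=float)
    n = mat.shape[1]
    if kind == "TPM":
        low_frac = (vals < cfg.tpm_threshold).mean(axis=1)
        keep = low_frac <= cfg.tpm_fraction
        reason = np.where(keep, "", f"TPM < {cfg.tpm_threshold} in more than {cfg.tpm_fraction:.3g} of subjects")
        if cfg.missingness_threshold is not None:
            detected = (vals > 0).mean(axis=1)
            miss = detected < cfg.missingness_threshold
            reason = np.where(keep & miss, f"detected in < {cfg.missingness_threshold:.3g} of samples", reason)
            keep &= ~miss
        if cfg.low_variance_quantile is not None:
            var = vals.var(axis=1)
            cut = np.quantile(var[keep], cfg.low_variance_quantile) if keep.any() else 0.0
            lowvar = var < cut
            reason = np.where(keep & lowvar, f"variance below the {cfg.low_variance_quantile:.3g} quantile", reason)
            keep &= ~lowvar
    else:
        deep = (vals > cfg.ctss_min_reads).sum(axis=1) > cfg.ctss_min_samples
        present = (vals > 0).mean(axis=1) >= cfg.ctss_presence_fraction
        keep = deep & present
        reason = np.where(
            keep,
            "",
            np.where(
                ~deep,
                f"not > {cfg.ctss_min_reads} reads in > {cfg.ctss_min_samples} samples",
                f"detected in < {cfg.ctss_presence_fraction:.0%} of samples",
            ),
        )

    for feat, k, r in zip(mat.index, keep, reason):
        audit_rows.append({"item": feat, "type": "feature", "kept": bool(k), "reason": r})
    filtered = mat.loc[keep]
    audit = pd.DataFrame(audit_rows)
    if filtered.empty:
        raise ValueError("all features removed by filtering")
    return filtered, audit


def quantile_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-feature rank inverse-normal transform: value -> Phi^-1((rank-0.5)/n).

    Ties get average ranks. Constant features map to all zeros and are
    returned in the flag list. Output rows have mean ~0 and a standard-normal
    marginal shape.
    """
    if matrix.shape[1] < 3:
        raise ValueError("rank inverse-normal transform needs >=3 samples")
    vals = matrix.to_numpy(dtype=float)
    n = vals.shape[1]
    out = np.zeros_like(vals)
    constant = []
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.ptp(row) == 0:
            constant.append(matrix.index[i])
            continue
        ranks = sps.rankdata(row, method="average")
        out[i] = sps.norm.ppf((ranks - 0.5) / n)
    if constant:
        warnings.warn(f"{len(constant)} constant features transformed to zeros", stacklevel=2)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), constant


def umap_covariates(
    matrix: pd.DataFrame, n_components: int = 2, seed: int = 0, **umap_kwargs
) -> pd.DataFrame:
    """Per-sample UMAP embedding of the (features x samples) matrix.

    Deterministic for a fixed seed. Returns an empty frame when
    ``n_components`` is 0 (no-op) or when there are fewer than 10 samples
    (skipped with a warning).
    """
    if n_components == 0:
        return pd.DataFrame(index=matrix.columns)
    if matrix.shape[1] < 10:
        warnings.warn("fewer than 10 samples; skipping UMAP covariates", stacklevel=2)
        return pd.DataFrame(index=matrix.columns)
    import umap  # deferred: numba compilation is expensive at import time

    reducer = umap.UMAP(n_components=n_components, random_state=seed, **umap_kwargs)
    emb = reducer.fit_transform(matrix.to_numpy(dtype=float).T)
    return pd.DataFrame(
        emb, index=matrix.columns, columns=[f"UMAP{i+1}" for i in range(n_components)]
    )


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) after OLS projection on Z (with intercept included in Z)."""
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ coef


def cis_scan(
    variants: pd.DataFrame,
    variant_positions: pd.DataFrame,
    features: pd.DataFrame,
    feature_coords: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-pair linear cis scan within ``window`` bp of each feature.

    ``variants``: samples x variants dosage frame; ``variant_positions``:
    variant -> (chrom, pos); ``features``: features x samples transformed
    matrix; ``feature_coords``: BED-like (chrom, start, end, feature). A pair
    is tested when the variant position lies within [start - window,
    end + window). Covariates are projected out once (Frisch-Waugh), making
    each test numerically identical to a full OLS with covariates. FDR is
    Benjamini-Hochberg across all emitted pairs.
    """
    samples = features.columns.intersection(variants.index)
    p_cov = 0 if covariates is None else covariates.shape[1]
    if len(samples) < p_cov + 3:
        raise ValueError("too few shared samples for the cis scan")
    V = variants.loc[samples]
    F = features[samples]
    n = len(samples)
    Z = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        Z = np.column_stack([Z, covariates.loc[samples].to_numpy(dtype=float)])

    pos = variant_positions.set_index("variant") if "variant" in variant_positions.columns else variant_positions
    coords = feature_coords.set_index("feature")

    y_res = _residualize(F.to_numpy(dtype=float).T, Z)  # samples x features
    x_res = _residualize(V.to_numpy(dtype=float), Z)  # samples x variants
    dof = n - Z.shape[1] - 1

    rows = []
    feat_index = {f: i for i, f in enumerate(F.index)}
    for vi, variant in enumerate(V.columns):
        chrom, vpos = pos.loc[variant, "chrom"], int(pos.loc[variant, "pos"])
        x = x_res[:, vi]
        sxx = float(x @ x)
        if sxx == 0:
            continue  # monomorphic after residualization
        af = float(V[variant].mean() / 2)
        in_cis = coords[
            (coords["chrom"] == chrom)
            & (vpos >= coords["start"] - window)
            & (vpos < coords["end"] + window)
        ].index
        for feature in in_cis:
            if feature not in feat_index:
                continue
            y = y_res[:, feat_index[feature]]
            beta = float(x @ y) / sxx
            resid = y - beta * x
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(sigma2 / sxx)
            tstat = beta / se if se > 0 else np.inf
            p = 2 * sps.t.sf(abs(tstat), dof)
            rows.append(
                {"variant": variant, "feature": feature, "AF": af, "beta": beta,
                 "SE": se, "t": tstat, "p_nominal": p, "n": n}
            )
    if not rows:
        warnings.warn("no variant-feature pairs inside the cis window", stacklevel=2)
        return pd.DataFrame(
            columns=["variant", "feature", "AF", "beta", "SE", "t", "p_nominal", "n", "FDR"]
        )
    result = pd.DataFrame(rows)
    result["FDR"] = multipletests(result["p_nominal"], method="fdr_bh")[1]
    return result
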