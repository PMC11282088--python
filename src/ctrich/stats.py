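"""Cohort association statistics: OLS haplotype~SNV tests, case-control GLM,
EM-based D' linkage disequilibrium, and homozygote-carrier tabulation.

Per-haplotype tests treat the haplotype as a biallelic locus (that haplotype
vs. all others, coded 0/1/2), matching the dosage coding used throughout.
Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import HAPLOTYPE_NAMES

DEFAULT_COVARIATES = ("sex", "age", "PC1", "PC2", "PC3", "PC4", "PC5")


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    outcome: str
    beta: float
    t: float
    P: float
    SE: float
    Rsq: float
    n: int


@dataclass(frozen=True)
class GlmResult:
    predictor: str
    beta: float
    t: float  # Wald z
    P: float
    SE: float
    OR: float
    ci_low: float  # 95% CI on the log-odds scale
    ci_high: float
    or_ci_low: float  # same interval exponentiated
    or_ci_high: float
    n: int


@dataclass(frozen=True)
class LDResult:
    haplotype: str
    snv: str
    dprime: float
    frequencies: np.ndarray  # (AB, Ab, aB, ab)
    iterations: int
    n: int


def _design(predictor: np.ndarray, covariates: pd.DataFrame | None, n: int) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(n), "predictor": predictor})
    if covariates is not None and covariates.shape[1] > 0:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    return X


def _check_rank(X: pd.DataFrame):
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        offenders = []
        cols = list(X.columns)
        for j in range(1, len(cols)):
            if np.linalg.matrix_rank(mat[:, : j + 1]) == np.linalg.matrix_rank(mat[:, :j]):
                offenders.append(cols[j])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {offenders}")


def _complete_cases(*arrays: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= ~np.asarray(a.isna()).reshape(len(a), -1).any(axis=1)
    return mask


def ols_assoc(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    outcome_id: str = "outcome",
    predictor_id: str = "predictor",
) -> AssociationResult:
    """OLS of ``outcome`` on ``predictor`` plus covariates, with intercept.

    Reports t, two-sided P and SE for the predictor and the model R^2 over
    complete cases.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    x = pd.Series(np.asarray(predictor, dtype=float))
    frames = [y.to_frame(), x.to_frame()] + ([covariates.reset_index(drop=True)] if covariates is not None else [])
    mask = _complete_cases(*frames)
    y, x = y[mask].to_numpy(), x[mask].to_numpy()
    cov = covariates.reset_index(drop=True)[mask].reset_index(drop=True) if covariates is not None else None
    p = 1 + (0 if cov is None else cov.shape[1])
    if len(y) < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {len(y)}")
    X = _design(x, cov, len(y))
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        predictor=predictor_id,
        outcome=outcome_id,
        beta=float(fit.params["predictor"]),
        t=float(fit.tvalues["predictor"]),
        P=float(fit.pvalues["predictor"]),
        SE=float(fit.bse["predictor"]),
        Rsq=float(fit.rsquared),
        n=int(fit.nobs),
    )


def logistic_assoc(
    phenotype,
    predictor,
    covariates: pd.DataFrame | None = None,
    predictor_id: str = "predictor",
) -> GlmResult:
    """Binomial GLM (logit link) of a 0/1 phenotype on a dosage predictor.

    OR = exp(beta); the 95% interval is reported on both the log-odds and OR
    scales. Raises on a single-class phenotype or on separation.
    """
    y = pd.Series(np.asarray(phenotype, dtype=float))
    x = pd.Series(np.asarray(predictor, dtype=float))
    frames = [y.to_frame(), x.to_frame()] + ([covariates.reset_index(drop=True)] if covariates is not None else [])
    mask = _complete_cases(*frames)
    y, x = y[mask].to_numpy(), x[mask].to_numpy()
    cov = covariates.reset_index(drop=True)[mask].reset_index(drop=True) if covariates is not None else None
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    X = _design(x, cov, len(y))
    _check_rank(X)
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge; possible separation in the data")
    beta = float(fit.params["predictor"])
    se = float(fit.bse["predictor"])
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return GlmResult(
        predictor=predictor_id,
        beta=beta,
        t=float(fit.tvalues["predictor"]),
        P=float(fit.pvalues["predictor"]),
        SE=se,
        OR=float(np.exp(beta)),
        ci_low=lo,
        ci_high=hi,
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def _dprime(p_ab: float, p_a: float, p_b: float) -> float:
    d = p_ab - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    return 0.0 if dmax == 0 else abs(d) / dmax


def dprime_em(
    geno_a,
    geno_b,
    haplotype_id: str = "A",
    snv_id: str = "B",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Estimate D' between two biallelic loci from unphased 0/1/2 genotypes.

    The four two-locus haplotype frequencies are estimated by EM: every
    genotype pair contributes known gametes except the double heterozygote,
    which is split between AB/ab and Ab/aB by the current phase expectation.
    Converges when the max frequency change drops below ``tol``.
    """
    ga = np.asarray(geno_a, dtype=int)
    gb = np.asarray(geno_b, dtype=int)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must have equal length")
    mask = (ga >= 0) & (gb >= 0)
    ga, gb = ga[mask], gb[mask]
    n = len(ga)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
        raise ValueError("both loci must be polymorphic for LD estimation")

    # 3x3 genotype table
    table = np.zeros((3, 3))
    np.add.at(table, (ga, gb), 1.0)

    p_a = ga.mean() / 2.0
    p_b = gb.mean() / 2.0
    # init at linkage equilibrium
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    total_gametes = 2.0 * n
    n_dh = table[1, 1]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # unambiguous gamete counts per cell (rows=geno_a, cols=geno_b)
        c_ab = 2 * table[2, 2] + table[2, 1] + table[1, 2]
        c_a_b = 2 * table[2, 0] + table[2, 1] + table[1, 0]
        c_b_a = 2 * table[0, 2] + table[0, 1] + table[1, 2]
        c_ab0 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
        denom = f[0] * f[3] + f[1] * f[2]
        w = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = np.array(
            [
                c_ab + w * n_dh,
                c_a_b + (1 - w) * n_dh,
                c_b_a + (1 - w) * n_dh,
                c_ab0 + w * n_dh,
            ]
        ) / total_gametes
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return LDResult(
        haplotype=haplotype_id,
        snv=snv_id,
        dprime=_dprime(f[0], f[0] + f[1], f[0] + f[2]),
        frequencies=f,
        iterations=iterations,
        n=n,
    )


def dprime_phased(gametes_a, gametes_b, haplotype_id: str = "A", snv_id: str = "B") -> LDResult:
    """D' by direct counting on phased gametes (0/1 vectors, one entry per gamete)."""
    a = np.asarray(gametes_a, dtype=int).ravel()
    b = np.asarray(gametes_b, dtype=int).ravel()
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("both loci must be polymorphic")
    n = len(a)
    f = np.array(
        [
            np.mean((a == 1) & (b == 1)),
            np.mean((a == 1) & (b == 0)),
            np.mean((a == 0) & (b == 1)),
            np.mean((a == 0) & (b == 0)),
        ]
    )
    return LDResult(haplotype_id, snv_id, _dprime(f[0], f[0] + f[1], f[0] + f[2]), f, 0, n // 2)


def bootstrap_dprime_se(
    geno_a, geno_b, n_boot: int = 200, rng: np.random.Generator | None = None
) -> float:
    """Bootstrap standard error of the EM D' estimate (resampling samples)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    ga = np.asarray(geno_a, dtype=int)
    gb = np.asarray(geno_b, dtype=int)
    n = len(ga)
    estimates = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(dprime_em(ga[idx], gb[idx]).dprime)
        except ValueError:  # monomorphic resample
            continue
    return float(np.std(estimates, ddof=1))


# ---------------------------------------------------------------------------
# Homozygote carrier tabulation


def homozygote_carrier_table(assignments: pd.DataFrame, snv_dosages: pd.DataFrame) -> pd.DataFrame:
    """Per (haplotype, SNV): % of haplotype homozygotes carrying >=1 risk allele.

    ``assignments`` is the classifier output (dosage_H1..H4 columns, indexed
    by sample via the sample_id column); ``snv_dosages`` holds 0/1/2 columns
    per SNV with a matching sample_id column. Zero homozygotes yields a
    not-estimable row (NaN percentage).
    """
    merged = assignments.merge(snv_dosages, on="sample_id", how="inner")
    rows = []
    snv_cols = [c for c in snv_dosages.columns if c != "sample_id"]
    for hap in HAPLOTYPE_NAMES:
        hom = merged[merged[f"dosage_{hap}"] == 2]
        for snv in snv_cols:
            n_hom = len(hom)
            if n_hom == 0:
                rows.append({"haplotype": hap, "snv": snv, "n_homozygotes": 0,
                             "n_carriers": 0, "percent": np.nan, "estimable": False})
                continue
            n_carriers = int((hom[snv] >= 1).sum())
            rows.append(
                {
                    "haplotype": hap,
                    "snv": snv,
                    "n_homozygotes": n_hom,
                    "n_carriers": n_carriers,
                    "percent": 100.0 * n_carriers / n_hom,
                    "estimable": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table builders


def haplotype_snv_table(
    cohort: pd.DataFrame,
    snv_ids: list[str],
    covariate_cols=DEFAULT_COVARIATES,
    direction: str = "hap_on_snv",
) -> pd.DataFrame:
    """Association + LD summary: one row per haplotype x SNV pair.

    ``direction='hap_on_snv'`` regresses haplotype dosage on SNV dosage
    (the default reporting direction); ``'snv_on_hap'`` mirrors it.
    """
    covs = cohort[list(covariate_cols)]
    rows = []
    for hap in HAPLOTYPE_NAMES:
        hap_dos = cohort[f"dosage_{hap}"]
        for snv in snv_ids:
            snv_dos = cohort[snv]
            if direction == "hap_on_snv":
                res = ols_assoc(hap_dos, snv_dos, covs, outcome_id=hap, predictor_id=snv)
            else:
                res = ols_assoc(snv_dos, hap_dos, covs, outcome_id=snv, predictor_id=hap)
            ld = dprime_em(hap_dos, snv_dos, haplotype_id=hap, snv_id=snv)
            rows.append(
                {
                    "haplotype": hap,
                    "allele_frequency": float(hap_dos.mean() / 2),
                    "risk_snv": snv,
                    "t": res.t,
                    "P": res.P,
                    "SE": res.SE,
                    "Rsq": res.Rsq,
                    "Dprime": ld.dprime,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def phenotype_table(
    cohort: pd.DataFrame,
    snv_ids: list[str],
    covariate_cols=DEFAULT_COVARIATES,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Case-control GLM summary: one row per haplotype and per SNV."""
    covs = cohort[list(covariate_cols)]
    pheno = cohort[phenotype_col]
    rows = []
    predictors = [(f"Haplotype {i+1}", cohort[f"dosage_{h}"]) for i, h in enumerate(HAPLOTYPE_NAMES)]
    predictors += [(snv, cohort[snv]) for snv in snv_ids]
    for name, dosage in predictors:
        res = logistic_assoc(pheno, dosage, covs, predictor_id=name)
        rows.append(
            {
                "predictor": name,
                "t": res.t,
                "P": res.P,
                "SE": res.SE,
                "OR": res.OR,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "or_ci_low": res.or_ci_low,
                "or_ci_high": res.or_ci_high,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
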