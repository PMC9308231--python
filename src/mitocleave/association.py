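"""Association and mediation statistics for cleavage ratios.

Cleavage ratios at a site are treated as a quantitative molecular phenotype:
OLS association against a predictor (a gene's expression, or an additive
genotype dosage 0/1/2) with an arbitrary covariate matrix (e.g. PEER factors),
Bonferroni correction, cross-cohort intersection requiring a consistent
direction of effect, percentile-bootstrap mediation for exposure -> mediator ->
outcome chains (ACME = product of the two path coefficients), and the
one-tailed knock-down-vs-control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    """Rank-deficient design matrix."""


@dataclass(frozen=True)
class AssociationResult:
    site: int | str
    predictor: str
    beta: float
    se: float
    p: float
    p_adjusted: float
    n: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta))


@dataclass(frozen=True)
class MediationResult:
    acme: float
    proportion_mediated: float
    ci_low: float
    ci_high: float
    p_mediation: float
    n_boot: int
    a: float
    b: float
    total_effect: float


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise alpha / number of tests."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def _clean(*arrays: np.ndarray) -> list[np.ndarray]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        if a.ndim == 1:
            mask &= ~np.isnan(a)
        else:
            mask &= ~np.isnan(a).any(axis=1)
    return [a[mask] for a in arrays]


def linear_association(
    response: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    site: int | str = "",
    predictor_id: str = "",
    m_tests: int = 1,
) -> AssociationResult:
    """OLS fit of ``response ~ predictor + covariates + intercept``.

    Returns the slope, two-sided p-value and Bonferroni-adjusted p for the
    predictor term.  Rows with missing values in any input are dropped.
    """
    response = np.asarray(response, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if covariates is None:
        covariates = np.empty((response.shape[0], 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    response, predictor, covariates = _clean(response, predictor, covariates)
    n, k = response.shape[0], covariates.shape[1]
    if n < k + 2:
        raise ValueError(f"n={n} too small for {k} covariates")
    if np.ptp(predictor) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(n), predictor, covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient design matrix")
    fit = sm.OLS(response, X).fit()
    beta, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    return AssociationResult(
        site, predictor_id, beta, se, p, adjust_bonferroni(p, m_tests), n
    )


def intersect_associations(
    discovery: Sequence[AssociationResult],
    replication: Sequence[AssociationResult],
    alpha: float = 0.05,
    require_significance_in_both: bool = True,
    require_same_sign: bool = True,
) -> list[tuple[AssociationResult, AssociationResult]]:
    """Pairs (keyed by site x predictor) surviving both cohorts.

    Significance means Bonferroni-adjusted p below ``alpha`` in each cohort;
    direction of effect must agree when ``require_same_sign``.
    """
    rep = {(r.site, r.predictor): r for r in replication}
    out = []
    for d in discovery:
        r = rep.get((d.site, d.predictor))
        if r is None:
            continue
        if require_significance_in_both and not (
            d.p_adjusted < alpha and r.p_adjusted < alpha
        ):
            continue
        if require_same_sign and d.direction != r.direction:
            continue
        out.append((d, r))
    return out


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients by normal equations (fast path for bootstrap loops)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def bootstrap_mediation(
    X: np.ndarray,
    M: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    rng_seed: int | np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Percentile-bootstrap mediation of X -> M -> Y.

    Fits ``M ~ X (+ covariates)`` for the a-path and ``Y ~ X + M (+ covariates)``
    for the b-path; ACME = a*b.  Individuals are resampled with replacement
    ``n_boot`` times; the CI is the percentile interval of the bootstrap ACME
    distribution and ``p_mediation`` the two-sided bootstrap tail probability
    of the ACME crossing zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (X.shape == M.shape == Y.shape):
        raise ValueError("X, M, Y must have equal length")
    if covariates is None:
        covariates = np.empty((X.shape[0], 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    X, M, Y, covariates = _clean(X, M, Y, covariates)
    n = X.shape[0]
    if np.ptp(X) == 0 or np.ptp(M) == 0:
        raise ValueError("degenerate (constant) exposure or mediator")

    ones = np.ones(n)

    def paths(idx: np.ndarray) -> tuple[float, float]:
        Xa = np.column_stack([ones[idx], X[idx], covariates[idx]])
        a = _ols_coef(Xa, M[idx])[1]
        Xb = np.column_stack([ones[idx], X[idx], M[idx], covariates[idx]])
        b = _ols_coef(Xb, Y[idx])[2]
        return float(a), float(b)

    full = np.arange(n)
    a, b = paths(full)
    acme = a * b
    Xt = np.column_stack([ones, X, covariates])
    total = float(_ols_coef(Xt, Y)[1])
    prop = acme / total if total != 0 else np.nan

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    boot = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            # guard: resample must keep X and M non-constant
            if np.ptp(X[idx]) > 0 and np.ptp(M[idx]) > 0:
                break
        ab, bb = paths(idx)
        boot[i] = ab * bb
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [tail, 1.0 - tail])
    p = 2.0 * min(np.mean(boot <= 0), np.mean(boot >= 0))
    return MediationResult(
        acme, float(prop), float(lo), float(hi), float(min(1.0, p)), n_boot, a, b, total
    )


def kd_comparison(
    control_ratios: np.ndarray,
    kd_ratios: np.ndarray,
    alternative: str = "kd_less",
) -> tuple[float, float, float, float]:
    """One-tailed Welch t-test of knock-down vs control cleavage ratios.

    ``alternative="kd_less"`` tests H1: mean(KD) < mean(control) (the
    expectation when the knocked-down gene promotes cleavage); ``"kd_greater"``
    the reverse.  Returns ``(t, one_tailed_p, mean_control, mean_kd)``.
    """
    control = np.asarray(control_ratios, dtype=float)
    kd = np.asarray(kd_ratios, dtype=float)
    if control.size < 2 or kd.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if alternative not in {"kd_less", "kd_greater"}:
        raise ValueError("alternative must be 'kd_less' or 'kd_greater'")
    alt = "less" if alternative == "kd_less" else "greater"
    t, p = stats.ttest_ind(kd, control, equal_var=False, alternative=alt)
    return float(t), float(p), float(control.mean()), float(kd.mean())


# ---------------------------------------------------------------------------
# Matrix readers (samples x features TSV with a sample-id column, plus VCF)


def read_matrix_tsv(path: str | Path, sample_col: str = "sample_id") -> pd.DataFrame:
    """Read a samples x features TSV (header row, sample-id column -> index)."""
    df = pd.read_csv(path, sep="\t")
    if sample_col not in df.columns:
        raise ValueError(f"{path}: missing {sample_col!r} column")
    return df.set_index(sample_col)


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Extract additive ALT-allele dosages (0/1/2) from VCF genotypes.

    Returns a samples x variants DataFrame; missing genotypes become NaN.
    """
    import pysam

    out: dict[str, list[float]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch():
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(1 for a in gt if a != 0)))
            out[vid] = dosages
    return pd.DataFrame(out, index=pd.Index(samples, name="sample_id"))


def association_scan(
    ratios: pd.DataFrame,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All site x predictor OLS associations with Bonferroni over the grid.

    ``ratios`` (samples x sites) and ``predictors`` (samples x features) are
    aligned on their sample index; ``m = n_sites * n_predictors``.
    """
    common = ratios.index.intersection(predictors.index)
    if covariates is not None:
        common = common.intersection(covariates.index)
        cov = covariates.loc[common].to_numpy()
    else:
        cov = None
    m = ratios.shape[1] * predictors.shape[1]
    rows = []
    for site in ratios.columns:
        y = ratios.loc[common, site].to_numpy()
        for pred in predictors.columns:
            x = predictors.loc[common, pred].to_numpy()
            try:
                res = linear_association(y, x, cov, site, str(pred), m)
            except (ValueError, CollinearityError):
                continue
            rows.append(
                {
                    "site": res.site,
                    "predictor": res.predictor,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p,
                    "p_adjusted": res.p_adjusted,
                    "n": res.n,
                    "significant": res.p_adjusted < alpha,
                }
            )
    return pd.DataFrame(rows)
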