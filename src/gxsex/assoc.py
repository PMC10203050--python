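"""Sex-stratified per-SNP association and phenotypic variance statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["run_stratified_gwas", "phenotype_variance_stats", "PhenotypeVarianceStats"]


def _stratum_ols(dosages: np.ndarray, y: np.ndarray, chunk: int = 512):
    """Per-SNP simple-regression slope and residual-based SE of y on dosage.

    Phenotypes are mean-centered within the stratum so intercepts never
    leak into slopes; the SE uses the unbiased residual variance (n - 2
    denominator).  Returns (slope, se, sxx) with NaN where the dosage is
    constant in the stratum.
    """
    n, m = dosages.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    slope = np.empty(m)
    se = np.empty(m)
    sxx_all = np.empty(m)
    for j0 in range(0, m, chunk):
        x = dosages[:, j0:j0 + chunk].astype(np.float64)
        s1 = x.sum(axis=0)
        s2 = (x * x).sum(axis=0)
        sxx = s2 - s1 * s1 / n
        sxy = x.T @ yc  # sum x*(y - ybar) = sum (x - xbar)(y - ybar)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx
            rss = np.maximum(syy - b * sxy, 0.0)
            s = np.sqrt(rss / (n - 2) / sxx)
        bad = sxx <= 0
        b[bad] = np.nan
        s[bad] = np.nan
        slope[j0:j0 + chunk] = b
        se[j0:j0 + chunk] = s
        sxx_all[j0:j0 + chunk] = sxx
    return slope, se, sxx_all


def run_stratified_gwas(cohort) -> pd.DataFrame:
    """Per-SNP, per-sex least-squares association on a simulated cohort.

    Within each sex, the effect estimate is the simple-regression slope of
    the phenotype on allele dosage and its standard error comes from the
    residual variance.  SNPs monomorphic in either sex are dropped with a
    logged count; ``p`` is the pooled sample frequency.

    Returns a summary-statistics table in the canonical column layout of
    :mod:`gxsex.io`.
    """
    males = cohort.is_male
    n_m, n_f = int(males.sum()), int((~males).sum())
    if n_m < 3 or n_f < 3:
        raise ValueError("need at least 3 individuals per sex")
    bm, sm, sxx_m = _stratum_ols(cohort.dosages[males], cohort.y[males])
    bf, sf, sxx_f = _stratum_ols(cohort.dosages[~males], cohort.y[~males])
    # a constant phenotype yields slope 0 with SE 0 (finite), so the filter
    # is on dosage variance, not on the SE
    ok = np.isfinite(bm) & np.isfinite(sm) & np.isfinite(bf) & np.isfinite(sf) \
        & (sxx_m > 0) & (sxx_f > 0)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("run_stratified_gwas: dropped %d monomorphic/degenerate SNP(s)",
                       n_drop)
    df = pd.DataFrame({
        "snp_id": cohort.snp_id,
        "chrom": cohort.chrom,
        "pos": cohort.pos,
        "effect_allele": "A",
        "other_allele": "G",
        "p": cohort.freq,
        "beta_m": bm, "se_m": sm, "n_m": n_m,
        "beta_f": bf, "se_f": sf, "n_f": n_f,
    })
    return df.loc[ok].reset_index(drop=True)


@dataclass
class PhenotypeVarianceStats:
    """Per-sex phenotypic variance with bootstrap standard errors."""

    var_m: float
    se_var_m: float
    var_f: float
    se_var_f: float
    mean_m: float
    mean_f: float
    n_m: int
    n_f: int
    n_boot: int


def phenotype_variance_stats(cohort, n_boot: int = 100, seed=None) -> PhenotypeVarianceStats:
    """Sample variance of the phenotype per sex, with the bootstrap SE

        SE = sqrt( sum_i (V_i - Vbar)^2 / (n_boot - 1) )

    over ``n_boot`` resamples of individuals with replacement.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    out = {}
    for label, mask in (("m", cohort.is_male), ("f", ~cohort.is_male)):
        y = cohort.y[mask]
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 individuals per sex")
        v = float(np.var(y, ddof=1))
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.var(y[idx], axis=1, ddof=1)
        se = float(np.sqrt(np.sum((boots - boots.mean()) ** 2) / (n_boot - 1)))
        out[label] = (v, se, float(y.mean()), n)
    return PhenotypeVarianceStats(
        var_m=out["m"][0], se_var_m=out["m"][1],
        var_f=out["f"][0], se_var_f=out["f"][1],
        mean_m=out["m"][2], mean_f=out["f"][2],
        n_m=out["m"][3], n_f=out["f"][3], n_boot=n_boot,
    )
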