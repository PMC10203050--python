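"""Polygenic scores and the three amplification-oriented PGS analyses:
per-sex slope ratio, modulator-bin amplification, and covariance-informed
prediction compared with an additive model under cross-validation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import _stratum_ols, run_stratified_gwas
from .mixture import EffectCovarianceMixture

logger = logging.getLogger(__name__)

__all__ = [
    "PgsModel",
    "compute_pgs",
    "SlopeRatio",
    "slope_ratio",
    "BinAmplification",
    "bin_amplification",
    "PredictionComparison",
    "cv_prediction_comparison",
]


@dataclass
class PgsModel:
    """Per-SNP weights defining a polygenic score."""

    snp_id: np.ndarray
    weight: np.ndarray
    source: str = "marginal-combined"

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id)
        self.weight = np.asarray(self.weight, dtype=float)
        if len(self.snp_id) != len(self.weight):
            raise ValueError("snp_id and weight must align")
        if not np.isfinite(self.weight).all():
            raise ValueError("PGS weights must be finite")


def compute_pgs(dosages: np.ndarray, snp_ids, model: PgsModel) -> np.ndarray:
    """Score = sum of weight x dosage over overlapping SNPs, standardized
    to unit SD across the scored individuals (effects downstream are per
    PGS standard deviation)."""
    snp_ids = np.asarray(snp_ids)
    pos = {s: i for i, s in enumerate(snp_ids)}
    cols, w = [], []
    for s, wt in zip(model.snp_id, model.weight):
        j = pos.get(s)
        if j is not None:
            cols.append(j)
            w.append(wt)
    if not cols:
        raise ValueError("no SNP overlap between model and dosages")
    raw = dosages[:, cols].astype(np.float64) @ np.asarray(w)
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero-variance raw score; cannot standardize")
    return raw / sd


def _ols(x, y):
    """Simple-regression slope and SE (n-2 residual denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("constant regressor")
    slope = (xc @ yc) / sxx
    rss = max(yc @ yc - slope * (xc @ yc), 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    return float(slope), float(se)


@dataclass
class SlopeRatio:
    slope_m: float
    se_m: float
    slope_f: float
    se_f: float
    ratio: float | None
    ratio_se: float | None
    t_diff: float
    p_diff: float


def slope_ratio(trait, pgs, is_male) -> SlopeRatio:
    """Per-sex OLS slope of the trait on a PGS and their male:female ratio
    (Taylor-approximation SE), with a t test of the slope difference."""
    is_male = np.asarray(is_male, dtype=bool)
    if is_male.all() or not is_male.any():
        raise ValueError("both sexes must be represented")
    trait = np.asarray(trait, dtype=float)
    pgs = np.asarray(pgs, dtype=float)
    bm, sm = _ols(pgs[is_male], trait[is_male])
    bf, sf = _ols(pgs[~is_male], trait[~is_male])
    if bf == 0:
        warnings.warn("zero female slope; ratio undefined", stacklevel=2)
        ratio = ratio_se_ = None
    else:
        ratio = bm / bf
        ratio_se_ = abs(ratio) * np.sqrt((sm / bm) ** 2 + (sf / bf) ** 2) if bm != 0 \
            else abs(sm / bf)
    t = (bm - bf) / np.sqrt(sm**2 + sf**2)
    return SlopeRatio(bm, sm, bf, sf, ratio,
                      None if ratio_se_ is None else float(ratio_se_),
                      float(t), float(2 * stats.norm.sf(abs(t))))


@dataclass
class BinAmplification:
    """Per-bin PGS slopes against a modulator, per sex."""

    bins: pd.DataFrame            # sex, bin, mean_modulator, slope, se, n
    r_m: float
    r_m_ci90: tuple
    r_f: float
    r_f_ci90: tuple
    residualized: bool = False


def _pearson_ci90(x, y):
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if n < 4 or abs(r) >= 1:
        return r, (np.nan, np.nan)
    zr = np.arctanh(r)
    half = stats.norm.ppf(0.95) / np.sqrt(n - 3)
    return r, (float(np.tanh(zr - half)), float(np.tanh(zr + half)))


def bin_amplification(trait, pgs, modulator, is_male, n_bins: int = 10,
                      covariates=None) -> BinAmplification:
    """Within-sex modulator bins vs magnitude of total polygenic effect.

    Individuals of each sex are split into ``n_bins`` modulator quantile
    bins; within each bin the trait (optionally residualized on the given
    covariates, per bin) is regressed on the PGS, and the per-sex Pearson
    correlation of slope with bin-mean modulator summarizes whether the
    modulator scales polygenic effects.  The modulator may itself be a
    PGS of the modulator trait, giving the reverse-causation-robust
    variant.
    """
    trait = np.asarray(trait, dtype=float)
    pgs = np.asarray(pgs, dtype=float)
    modulator = np.asarray(modulator, dtype=float)
    is_male = np.asarray(is_male, dtype=bool)
    if not np.isfinite(modulator).all():
        raise ValueError("modulator must be defined for all individuals")
    rows = []
    rs = {}
    for sex, mask in (("m", is_male), ("f", ~is_male)):
        mod = modulator[mask]
        edges = np.unique(np.quantile(mod, np.linspace(0, 1, n_bins + 1)))
        k = len(edges) - 1
        if k < n_bins:
            warnings.warn(f"ties reduce {n_bins} bins to {k} for sex {sex}",
                          stacklevel=2)
        labels = np.clip(np.searchsorted(edges, mod, side="right") - 1, 0, k - 1)
        slopes, means = [], []
        for b in range(k):
            sel = labels == b
            n_sel = int(sel.sum())
            if n_sel < 30:
                warnings.warn(f"bin {b} for sex {sex} has n={n_sel} < 30",
                              stacklevel=2)
            yb = trait[mask][sel]
            xb = pgs[mask][sel]
            if covariates is not None:
                C = np.column_stack([np.ones(n_sel),
                                     np.asarray(covariates, dtype=float)[mask][sel]])
                yb = yb - C @ np.linalg.lstsq(C, yb, rcond=None)[0]
            slope, se = _ols(xb, yb)
            slopes.append(slope)
            means.append(float(mod[sel].mean()))
            rows.append({"sex": sex, "bin": b, "mean_modulator": means[-1],
                         "slope": slope, "se": se, "n": n_sel})
        rs[sex] = _pearson_ci90(np.array(means), np.array(slopes))
    return BinAmplification(
        bins=pd.DataFrame(rows),
        r_m=rs["m"][0], r_m_ci90=rs["m"][1],
        r_f=rs["f"][0], r_f_ci90=rs["f"][1],
        residualized=covariates is not None,
    )


@dataclass
class PredictionComparison:
    """Per-fold incremental R2 of additive vs covariance-informed PGS."""

    folds: pd.DataFrame           # fold, r2_additive, r2_covariance, ratio, used
    n_folds: int

    @property
    def mean_ratio(self) -> float:
        used = self.folds.loc[self.folds["used"], "ratio"]
        return float(used.mean())


def cv_prediction_comparison(cohort, n_folds: int = 20, seed=None,
                             grid=None, tol: float = 1e-6) -> PredictionComparison:
    """Cross-validated comparison of an additive PGS with a GxSex PGS
    informed by the fitted polygenic covariance structure.

    Per fold: a combined-sample GWAS on the training split gives additive
    weights; a sex-stratified GWAS plus a covariance-mixture fit gives
    posterior sex-specific weights.  On held-out individuals each model's
    R2 (trait regressed on the score, after removing per-sex means) is
    computed; the relative prediction accuracy is the ratio
    covariance-informed / additive.  Folds with non-positive additive R2
    are flagged and excluded from the ratio average with a logged count.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[order] = np.arange(n) % n_folds

    def _r2(y, score, is_male):
        yc = y.copy()
        for mask in (is_male, ~is_male):
            yc[mask] = y[mask] - y[mask].mean()
        if score.std() == 0:
            return 0.0
        return float(np.corrcoef(yc, score)[0, 1] ** 2)

    rows = []
    for fold in range(n_folds):
        test = fold_of == fold
        train = ~test
        sub = _CohortView(cohort, train)
        # additive: combined-sample GWAS on per-sex-centered phenotype
        yc = sub.y.copy()
        for mask in (sub.is_male, ~sub.is_male):
            yc[mask] -= yc[mask].mean()
        b_add, _, _ = _stratum_ols(sub.dosages, yc)
        b_add = np.nan_to_num(b_add)
        # covariance-informed: stratified GWAS -> mixture -> posterior
        ss = run_stratified_gwas(sub)
        model = EffectCovarianceMixture(ss, grid=grid)
        post = model.fit(tol=tol).posterior_effects()
        post = post.set_index("snp_id").reindex(cohort.snp_id).fillna(0.0)
        Xt = cohort.dosages[test].astype(np.float64)
        score_add = Xt @ b_add
        male_t = cohort.is_male[test]
        score_cov = np.empty(Xt.shape[0])
        score_cov[male_t] = Xt[male_t] @ post["post_beta_m"].to_numpy()
        score_cov[~male_t] = Xt[~male_t] @ post["post_beta_f"].to_numpy()
        r2_add = _r2(cohort.y[test], score_add, cohort.is_male[test])
        r2_cov = _r2(cohort.y[test], score_cov, cohort.is_male[test])
        used = r2_add > 0
        if not used:
            logger.warning("fold %d: non-positive additive R2, excluded", fold)
        rows.append({"fold": fold, "r2_additive": r2_add, "r2_covariance": r2_cov,
                     "ratio": r2_cov / r2_add if used else np.nan, "used": used})
    return PredictionComparison(folds=pd.DataFrame(rows), n_folds=n_folds)


class _CohortView:
    """Row-subset view of a cohort (ducks the Cohort interface)."""

    def __init__(self, cohort, mask):
        self.dosages = cohort.dosages[mask]
        self.is_male = cohort.is_male[mask]
        self.y = cohort.y[mask]
        self.snp_id = cohort.snp_id
        self.chrom = cohort.chrom
        self.pos = cohort.pos
        self.freq = self.dosages.mean(axis=0, dtype=np.float64) / 2.0
        self.block = cohort.block

    @property
    def n_individuals(self):
        return len(self.y)

    @property
    def n_snps(self):
        return self.dosages.shape[1]
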