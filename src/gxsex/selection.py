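"""Test for sexually antagonistic viability selection.

Under the model, contemporary viability selection whose strength is linear
in each sex's additive effect on a focal trait, balanced between the sexes
(``s_f = -s_m``), produces adult male-female allele-frequency divergence
proportional to the per-site gene-by-sex genetic variance:

    FST_i ~ A * V_i,      V_i = 2 p_i (1 - p_i) (beta_m,i - beta_f,i)^2,

with a single constant A shared across sites.  A is estimated by
variance-weighted least squares of a bias-corrected between-sex FST
estimator on the estimated V, with weights inversely proportional to the
sampling variance of V-hat; sampling uncertainty is propagated by
resampling LD blocks and bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "v_gxsex",
    "var_v_gxsex",
    "fst_hat",
    "weighted_ols",
    "site_selection_stats",
    "AntagonisticSelectionModel",
    "SelectionResults",
    "estimate_A",
]


def weighted_ols(x, y, w, intercept: bool = True):
    """Weighted least-squares slope and its conventional standard error.

    Accepts 1-D arrays (one regression) or 2-D stacks (one regression per
    row).  The SE uses the weighted residual variance with ``n - 2``
    (``n - 1`` through the origin) degrees of freedom, matching standard
    WLS output.  Degenerate rows (zero weighted regressor variance) come
    back NaN.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    squeeze = x.shape[0] == 1
    n = x.shape[1]
    sw = w.sum(axis=1)
    if intercept:
        xc = x - ((w * x).sum(axis=1) / sw)[:, None]
        yc = y - ((w * y).sum(axis=1) / sw)[:, None]
        dof = n - 2
    else:
        xc, yc = x, y
        dof = n - 1
    sxx = (w * xc * xc).sum(axis=1)
    sxy = (w * xc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        resid = yc - slope[:, None] * xc
        rss = (w * resid * resid).sum(axis=1)
        se = np.where(sxx > 0, np.sqrt(rss / dof / sxx), np.nan)
    if squeeze:
        return float(slope[0]), float(se[0])
    return slope, se


def v_gxsex(p, beta_m, beta_f):
    """Per-site GxSex genetic variance ``2 p (1-p) (beta_m - beta_f)^2``."""
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p) * (np.asarray(beta_m) - np.asarray(beta_f)) ** 2


def var_v_gxsex(p, beta_m_hat, se_m, beta_f_hat, se_f):
    """Sampling variance of the estimated per-site GxSex variance.

    Treats the allele frequency as known; with normal effect estimates the
    exact moments of ``(b_m - b_f)^2`` give

        Var[V-hat] = [2p(1-p)]^2 * [ 2(s_m^4 + s_f^4) + 4 s_m^2 s_f^2
            + 4(b_m^2 s_m^2 + b_f^2 s_f^2) + 4(s_m^2 b_f^2 + s_f^2 b_m^2)
            - 8 b_m b_f (s_m^2 + s_f^2) ],

    with point estimates plugged in for the means and SEs for the SDs.
    """
    p = np.asarray(p, dtype=float)
    bm = np.asarray(beta_m_hat, dtype=float)
    bf = np.asarray(beta_f_hat, dtype=float)
    vm = np.asarray(se_m, dtype=float) ** 2
    vf = np.asarray(se_f, dtype=float) ** 2
    core = (2.0 * (vm**2 + vf**2) + 4.0 * vm * vf
            + 4.0 * (bm**2 * vm + bf**2 * vf)
            + 4.0 * (vm * bf**2 + vf * bm**2)
            - 8.0 * bm * bf * (vm + vf))
    return (2.0 * p * (1.0 - p)) ** 2 * core


def fst_hat(p_m_hat, p_f_hat, an_m, an_f):
    """Approximately unbiased between-sex FST from sample frequencies.

    ``n / d`` with ``n = (pm - pf)^2 - SE(pm)^2 - SE(pf)^2`` and
    ``d = 4 pbar (1 - pbar) - SE(pm)^2 - SE(pf)^2``, where
    ``SE(pz)^2 = pz (1 - pz) / an_z`` is the binomial sampling variance and
    ``pbar = (pm + pf) / 2``.  Negative values are retained (the
    correction requires them for unbiasedness); sites with ``d <= 0``
    come back NaN and should be excluded by the caller.
    """
    pm = np.asarray(p_m_hat, dtype=float)
    pf = np.asarray(p_f_hat, dtype=float)
    se2_m = pm * (1.0 - pm) / np.asarray(an_m, dtype=float)
    se2_f = pf * (1.0 - pf) / np.asarray(an_f, dtype=float)
    pbar = 0.5 * (pm + pf)
    num = (pm - pf) ** 2 - se2_m - se2_f
    den = 4.0 * pbar * (1.0 - pbar) - se2_m - se2_f
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def site_selection_stats(harmonized: pd.DataFrame,
                         block_ids=None) -> pd.DataFrame:
    """Per-site table feeding the weighted regression.

    Parameters
    ----------
    harmonized : DataFrame
        Output of :func:`gxsex.io.harmonize_freqs` (summary statistics
        joined with effect-allele-oriented frequency records).  ``p`` (the
        GWAS-sample frequency) enters V-hat; the frequency-table columns
        enter FST-hat, mirroring the two-dataset design.
    block_ids : array-like, optional
        Per-site LD block assignment; defaults to a ``block`` column.

    Sites with non-positive FST denominator or non-positive weight are
    excluded with a logged count.
    """
    df = harmonized
    V = v_gxsex(df["p"], df["beta_m"], df["beta_f"])
    varV = var_v_gxsex(df["p"], df["beta_m"], df["se_m"], df["beta_f"], df["se_f"])
    F = fst_hat(df["p_m_hat"], df["p_f_hat"], df["an_m"], df["an_f"])
    if block_ids is None:
        if "block" not in df.columns:
            raise ValueError("block_ids not given and no 'block' column present")
        block_ids = df["block"].to_numpy()
    block_ids = np.asarray(block_ids, dtype=np.int64)
    with np.errstate(divide="ignore"):
        w = np.where(varV > 0, 1.0 / varV, np.nan)
    out = pd.DataFrame({
        "snp_id": df["snp_id"].to_numpy(),
        "v_gxsex": V, "var_v_gxsex": varV, "fst": F, "weight": w,
        "block": block_ids,
    })
    ok = np.isfinite(out[["v_gxsex", "fst", "weight"]].to_numpy()).all(axis=1) \
        & (out["weight"] > 0) & (block_ids >= 0)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("site_selection_stats: excluded %d site(s)", n_drop)
    return out.loc[ok].reset_index(drop=True)


@dataclass
class SelectionResults:
    """Resampled weighted-regression estimates of the selection constant A."""

    slopes: np.ndarray            # per-iteration WLS slope
    slope_ses: np.ndarray
    zs: np.ndarray                # per-iteration slope / SE
    mean_z: float
    z_ci90: tuple
    mean_slope: float
    slope_ci90: tuple
    n_iterations: int
    n_bootstrap: int
    n_blocks: int
    n_sites: int
    intercept: bool
    n_skipped: int = 0
    true_A: float | None = None

    def summary(self) -> str:
        lines = [
            "Sexually antagonistic selection test (FST ~ A * V_GxSex)",
            "=" * 60,
            f"sites: {self.n_sites}   LD blocks: {self.n_blocks}   "
            f"iterations: {self.n_iterations} (skipped {self.n_skipped})   "
            f"intercept: {self.intercept}",
            f"mean slope (A-hat): {self.mean_slope:.4g}  "
            f"90% CI [{self.slope_ci90[0]:.4g}, {self.slope_ci90[1]:.4g}]",
            f"mean Z: {self.mean_z:.3f}  "
            f"90% CI [{self.z_ci90[0]:.3f}, {self.z_ci90[1]:.3f}]",
        ]
        if self.true_A is not None:
            lines.append(f"generative A: {self.true_A:.4g}")
        return "\n".join(lines)


class AntagonisticSelectionModel:
    """Weighted regression of between-sex FST on GxSex genetic variance.

    Each fit iteration resamples ``m`` LD blocks with replacement from the
    ``m`` blocks containing at least one site, draws one site per
    resampled block, and runs weighted least squares of FST-hat on V-hat
    with weights ``1 / Var[V-hat]``; the per-iteration Z score is the
    slope over its conventional SE.  The reported estimate is the mean Z
    (and mean slope) over iterations, with percentile bootstrap CIs over
    re-samplings of the iteration values.
    """

    def __init__(self, sites: pd.DataFrame, intercept: bool = True):
        need = {"v_gxsex", "fst", "weight", "block"}
        if not need.issubset(sites.columns):
            raise ValueError(f"site table needs columns {sorted(need)}")
        self.sites = sites.reset_index(drop=True)
        self.intercept = intercept
        blocks = self.sites["block"].to_numpy()
        order = np.argsort(blocks, kind="stable")
        self._sorted_idx = order
        ub, counts = np.unique(blocks, return_counts=True)
        self.n_blocks = len(ub)
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        self._sizes = counts
        if self.n_blocks < 2:
            raise ValueError("all sites fall in a single block; regression degenerate")
        if self.n_blocks < 10:
            warnings.warn("fewer than 10 LD blocks contain sites; block "
                          "resampling will be unstable", stacklevel=2)

    def fit(self, n_iter: int = 1000, n_boot: int = 10000, seed=None,
            true_A: float | None = None) -> SelectionResults:
        rng = np.random.default_rng(seed)
        m = self.n_blocks
        x_all = self.sites["v_gxsex"].to_numpy()[self._sorted_idx]
        y_all = self.sites["fst"].to_numpy()[self._sorted_idx]
        w_all = self.sites["weight"].to_numpy()[self._sorted_idx]

        draw = rng.integers(0, m, size=(n_iter, m))
        u = rng.random((n_iter, m))
        pos = np.floor(u * self._sizes[draw]).astype(np.int64)
        idx = self._offsets[draw] + pos
        x, y, w = x_all[idx], y_all[idx], w_all[idx]

        slope, se = weighted_ols(x, y, w, intercept=self.intercept)
        with np.errstate(invalid="ignore"):
            z = slope / se
        ok = np.isfinite(z)
        n_skip = int((~ok).sum())
        if n_skip:
            logger.warning("selection fit: skipped %d degenerate iteration(s)", n_skip)
        slope, se, z = slope[ok], se[ok], z[ok]
        if len(z) == 0:
            raise ValueError("all resampling iterations degenerate")

        def boot_ci(vals):
            means = np.empty(n_boot)
            chunk = max(1, int(2e6 // max(len(vals), 1)))
            for i0 in range(0, n_boot, chunk):
                k = min(chunk, n_boot - i0)
                sel = rng.integers(0, len(vals), size=(k, len(vals)))
                means[i0:i0 + k] = vals[sel].mean(axis=1)
            return tuple(np.percentile(means, [5.0, 95.0]))

        return SelectionResults(
            slopes=slope, slope_ses=se, zs=z,
            mean_z=float(z.mean()), z_ci90=boot_ci(z),
            mean_slope=float(slope.mean()), slope_ci90=boot_ci(slope),
            n_iterations=n_iter, n_bootstrap=n_boot,
            n_blocks=m, n_sites=len(self.sites),
            intercept=self.intercept, n_skipped=n_skip, true_A=true_A,
        )


def estimate_A(sumstats: pd.DataFrame, freqs: pd.DataFrame, block_ids=None,
               n_iter: int = 1000, n_boot: int = 10000, seed=None,
               intercept: bool = True, true_A: float | None = None) -> SelectionResults:
    """End-to-end convenience wrapper: harmonize, build the site table,
    fit the block-resampled weighted regression."""
    from .io import harmonize_freqs

    ss = sumstats.copy()
    if block_ids is not None:
        ss["block"] = np.asarray(block_ids, dtype=np.int64)
    merged = harmonize_freqs(ss, freqs)
    sites = site_selection_stats(merged)
    model = AntagonisticSelectionModel(sites, intercept=intercept)
    return model.fit(n_iter=n_iter, n_boot=n_boot, seed=seed, true_A=true_A)
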