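"""Variance-decomposition tests for gene-by-sex interaction.

Two results from the additive model ``Var[Y|Z] = Var[G|Z] + Var[E|Z]``:

* the no-GxSex heritability bound: if genetic effects are equal in both
  sexes, the combined-sample heritability cannot be smaller than both
  sex-specific heritabilities, ``h2 >= min(h2_m, h2_f)``;
* the joint-amplification test: under a shared scalar amplifier acting on
  genetic and environmental effects alike, the male:female ratio of
  genetic variances equals the ratio of environmental variances.  With
  ``Var[G_z] = h_z^2 Var[Y_z]`` and ``Var[E_z] = (1 - h_z^2) Var[Y_z]``,
  the statistic is ``Z = (Z_tilde - 1) / SE[Z_tilde]`` where ``Z_tilde``
  is the environmental ratio over the genetic ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ratio_se",
    "product_se",
    "HeritabilityEstimates",
    "BoundDiagnostic",
    "heritability_bound_check",
    "JointAmplificationResult",
    "joint_amplification_test",
]


def ratio_se(x, se_x, y, se_y):
    """Second-order Taylor SE of ``x / y`` for independent estimators:
    ``(x/y) sqrt(se_x^2/x^2 + se_y^2/y^2)``."""
    if y == 0:
        raise ZeroDivisionError("undefined ratio: denominator estimate is 0")
    return abs(x / y) * np.sqrt((se_x / x) ** 2 + (se_y / y) ** 2)


def product_se(a, se_a, b, se_b):
    """Exact SE of a product of independent estimators (law of total
    variance): ``sqrt(se_a^2 se_b^2 + a^2 se_b^2 + b^2 se_a^2)``."""
    return np.sqrt(se_a**2 * se_b**2 + a**2 * se_b**2 + b**2 * se_a**2)


@dataclass
class HeritabilityEstimates:
    """Sex-specific (and optionally combined-sample) narrow-sense
    heritabilities with standard errors, e.g. from LD score regression."""

    h2_m: float
    se_m: float
    h2_f: float
    se_f: float
    h2_comb: float | None = None
    se_comb: float | None = None

    def __post_init__(self):
        for se in (self.se_m, self.se_f):
            if se <= 0:
                raise ValueError("heritability SEs must be positive")


@dataclass
class BoundDiagnostic:
    violated: bool
    z: float
    p_one_sided: float


def heritability_bound_check(h: HeritabilityEstimates) -> BoundDiagnostic:
    """Check the no-GxSex bound ``h2_comb >= min(h2_m, h2_f)``.

    A combined-sample heritability below both sex-specific ones implies
    sex differences in genetic variance, i.e. GxSex.  The z statistic is
    ``(min(h2_m, h2_f) - h2_comb) / sqrt(se_min^2 + se_comb^2)``.
    """
    if h.h2_comb is None or h.se_comb is None:
        raise ValueError("combined-sample heritability and SE are required")
    if h.h2_m <= h.h2_f:
        h2_min, se_min = h.h2_m, h.se_m
    else:
        h2_min, se_min = h.h2_f, h.se_f
    z = (h2_min - h.h2_comb) / np.sqrt(se_min**2 + h.se_comb**2)
    return BoundDiagnostic(violated=h.h2_comb < h2_min, z=float(z),
                           p_one_sided=float(stats.norm.sf(z)))


@dataclass
class JointAmplificationResult:
    """Genetic/environmental variances per sex, their male:female ratios,
    the ratio of ratios and the resulting Z test."""

    var_g_m: float
    se_var_g_m: float
    var_g_f: float
    se_var_g_f: float
    var_e_m: float
    se_var_e_m: float
    var_e_f: float
    se_var_e_f: float
    genetic_ratio: float
    se_genetic_ratio: float
    environmental_ratio: float
    se_environmental_ratio: float
    z_tilde: float
    se_z_tilde: float
    z: float
    p: float
    scale: str = "ratio"

    def summary(self) -> str:
        return "\n".join([
            "Joint amplification test (genetic vs environmental variance ratios)",
            "=" * 68,
            f"Var[G] m/f: {self.var_g_m:.4g} (+-{self.se_var_g_m:.3g}) / "
            f"{self.var_g_f:.4g} (+-{self.se_var_g_f:.3g})",
            f"Var[E] m/f: {self.var_e_m:.4g} (+-{self.se_var_e_m:.3g}) / "
            f"{self.var_e_f:.4g} (+-{self.se_var_e_f:.3g})",
            f"genetic ratio      : {self.genetic_ratio:.4g} (+-{self.se_genetic_ratio:.3g})",
            f"environmental ratio: {self.environmental_ratio:.4g} "
            f"(+-{self.se_environmental_ratio:.3g})",
            f"ratio of ratios    : {self.z_tilde:.4g} (+-{self.se_z_tilde:.3g}) "
            f"[{self.scale} scale]",
            f"Z = {self.z:.3f}, two-sided p = {self.p:.3g}",
        ])


def joint_amplification_test(h: HeritabilityEstimates, v,
                             log_scale: bool = False) -> JointAmplificationResult:
    """Test equality of male:female genetic and environmental variance ratios.

    Parameters
    ----------
    h : HeritabilityEstimates
        Sex-specific heritabilities with SEs (the combined estimate is not
        used here).
    v : PhenotypeVarianceStats
        Per-sex phenotypic variances with (bootstrap) SEs.
    log_scale : bool
        If True, compute the test on ``log Z_tilde`` (delta-method SE);
        the plain ratio-scale normal approximation is asymmetric, and the
        log variant makes the sex-swap antisymmetry exact.
    """
    out = {}
    for z, h2, se_h2, var_y, se_var_y in (
        ("m", h.h2_m, h.se_m, v.var_m, v.se_var_m),
        ("f", h.h2_f, h.se_f, v.var_f, v.se_var_f),
    ):
        if var_y == 0:
            raise ZeroDivisionError("zero phenotypic variance")
        vg = h2 * var_y
        ve = (1.0 - h2) * var_y
        # SE of (1 - h2) equals SE of h2 (exact under linearity)
        out[z] = (vg, product_se(var_y, se_var_y, h2, se_h2),
                  ve, product_se(var_y, se_var_y, 1.0 - h2, se_h2))
    vg_m, se_vg_m, ve_m, se_ve_m = out["m"]
    vg_f, se_vg_f, ve_f, se_ve_f = out["f"]
    if vg_f == 0 or ve_f == 0 or vg_m == 0 or ve_m == 0:
        raise ZeroDivisionError("zero variance component; ratios undefined")
    gr = vg_m / vg_f
    se_gr = ratio_se(vg_m, se_vg_m, vg_f, se_vg_f)
    er = ve_m / ve_f
    se_er = ratio_se(ve_m, se_ve_m, ve_f, se_ve_f)
    zt = er / gr
    se_zt = ratio_se(er, se_er, gr, se_gr)
    if log_scale:
        # delta method: SE[log zt] = SE[zt] / zt; null value log(1) = 0
        z_stat = np.log(zt) / (se_zt / zt)
        scale = "log"
    else:
        z_stat = (zt - 1.0) / se_zt
        scale = "ratio"
    return JointAmplificationResult(
        var_g_m=vg_m, se_var_g_m=se_vg_m, var_g_f=vg_f, se_var_g_f=se_vg_f,
        var_e_m=ve_m, se_var_e_m=se_ve_m, var_e_f=ve_f, se_var_e_f=se_ve_f,
        genetic_ratio=gr, se_genetic_ratio=se_gr,
        environmental_ratio=er, se_environmental_ratio=se_er,
        z_tilde=zt, se_z_tilde=se_zt, z=float(z_stat),
        p=float(2.0 * stats.norm.sf(abs(z_stat))), scale=scale,
    )
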