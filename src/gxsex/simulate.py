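"""Synthetic data under sex-specific polygenic architectures.

Two generators:

* :func:`simulate_cohort` -- a sex-stratified polygenic cohort.  Genotypes
  are drawn in Hardy-Weinberg proportions at linkage equilibrium; true
  per-SNP effect pairs ``(beta_m, beta_f)`` come from a mixture of 2x2
  covariance components; the male environmental variance is set so the male
  heritability hits its target,

      Var[E | Z=m] = Var[G | Z=m] * (1 - h2_m) / h2_m,
      Var[G | Z=m] = sum_i beta_{m,i}^2 * 2 p_i (1 - p_i),

  and the female environmental variance is a fixed multiple of the male
  one.  Phenotypes are ``y = c + sum_i beta_i x_i + E``.

* :func:`simulate_sex_divergence` -- adult male/female allele frequencies
  perturbed by sexually antagonistic viability selection.  With additive
  selection coefficient ``s_z`` in sex ``z``, the adult frequency is
  ``p_z = p + p(1-p) s_z`` to first order; the generator enforces the
  equilibrium constraint ``s_f = -s_m`` with ``s_m = a_m * beta_m``, and
  draws observed frequencies binomially given sampled allele numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EQUAL_EFFECTS",
    "SimConfig",
    "Cohort",
    "TruthEffects",
    "SelectionSimConfig",
    "ConfigError",
    "simulate_cohort",
    "simulate_sex_divergence",
    "equilibrium_female_effects",
    "true_selection_constant",
    "amplification_component",
    "sex_specific_component",
]

#: equal effects in both sexes, perfectly correlated (unit pattern)
EQUAL_EFFECTS = np.array([[1.0, 1.0], [1.0, 1.0]])


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def amplification_component(q: float, r: float = 1.0) -> np.ndarray:
    """Covariance pattern with female:male magnitude ratio ``q`` and
    between-sex correlation ``r``: ``[[1, r q], [r q, q^2]]``."""
    return np.array([[1.0, r * q], [r * q, q * q]])


def sex_specific_component(sex: str) -> np.ndarray:
    """Effect in one sex only ('m' or 'f')."""
    if sex == "m":
        return np.array([[1.0, 0.0], [0.0, 0.0]])
    if sex == "f":
        return np.array([[0.0, 0.0], [0.0, 1.0]])
    raise ConfigError(f"sex must be 'm' or 'f', got {sex!r}")


@dataclass
class SimConfig:
    """Configuration of a sex-stratified polygenic cohort.

    Parameters
    ----------
    n_individuals, n_snps, n_causal : int
        Cohort and panel sizes; causal SNPs are a random subset.
    h2_m : float or None
        Target male narrow-sense heritability in [0, 1).  Ignored when
        ``env_var_m`` is given directly.
    env_var_ratio_f_to_m : float
        Var[E|f] / Var[E|m]; assigned, not sampled.
    effect_mixture : sequence of (weight, 2x2 array)
        Mixture of covariance components the causal effect pairs are drawn
        from.  Weights must sum to 1; components must be symmetric PSD.
    allele_freq_law : callable or ("uniform", lo, hi)
        Distribution of zygote allele frequencies.
    env_var_m : float, optional
        Directly assigned male environmental variance (overrides ``h2_m``).
    n_blocks : int
        Number of contiguous equal-size pseudo LD blocks the SNPs are
        partitioned into, so block-resampling code paths can be exercised
        on linkage-equilibrium data.
    """

    n_individuals: int
    n_snps: int
    n_causal: int
    h2_m: float | None = 0.5
    env_var_ratio_f_to_m: float = 1.0
    sex_ratio: float = 0.5
    effect_mixture: Sequence[tuple[float, np.ndarray]] = ((1.0, EQUAL_EFFECTS),)
    allele_freq_law: Callable | tuple = ("uniform", 0.01, 0.5)
    intercept: float = 0.0
    env_var_m: float | None = None
    n_blocks: int = 100

    def validate(self) -> None:
        if not 0 <= self.n_causal <= self.n_snps:
            raise ConfigError("need 0 <= n_causal <= n_snps")
        w = np.array([wk for wk, _ in self.effect_mixture], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ConfigError("mixture weights must be >= 0 and sum to 1")
        for _, U in self.effect_mixture:
            U = np.asarray(U, dtype=float)
            if U.shape != (2, 2) or abs(U[0, 1] - U[1, 0]) > 1e-12:
                raise ConfigError("components must be symmetric 2x2 matrices")
            if np.linalg.eigvalsh(U).min() < -1e-9:
                raise ConfigError("components must be positive semidefinite")
        if self.env_var_m is None:
            if self.h2_m is None or not 0 < self.h2_m < 1:
                if self.n_causal > 0:
                    raise ConfigError(
                        "h2_m must lie in (0, 1) when causal effects are simulated "
                        "and env_var_m is not given"
                    )
        if not 0 < self.sex_ratio < 1:
            raise ConfigError("sex_ratio must lie in (0, 1)")


@dataclass
class Cohort:
    """Simulated individuals: dosages (0/1/2), sex labels, phenotypes."""

    dosages: np.ndarray          # (n_individuals, n_snps) int8
    is_male: np.ndarray          # (n_individuals,) bool
    y: np.ndarray                # (n_individuals,) float
    snp_id: np.ndarray           # (n_snps,) str
    chrom: np.ndarray            # (n_snps,) str
    pos: np.ndarray              # (n_snps,) int, 1-based
    freq: np.ndarray             # realized pooled effect-allele frequency
    block: np.ndarray            # (n_snps,) pseudo LD-block id

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TruthEffects:
    """Generative truth for a simulated cohort."""

    beta_m: np.ndarray
    beta_f: np.ndarray
    causal: np.ndarray           # bool
    var_g_m: float               # sum beta_m^2 2p(1-p), realized frequencies
    var_g_f: float
    var_e_m: float               # assigned environmental variances
    var_e_f: float
    component: np.ndarray = field(default=None)  # mixture component per SNP (-1 noncausal)

    def genetic_values(self, cohort: Cohort) -> np.ndarray:
        """Per-individual additive genetic value under the individual's sex."""
        gm = _dosage_dot(cohort.dosages, self.beta_m)
        gf = _dosage_dot(cohort.dosages, self.beta_f)
        return np.where(cohort.is_male, gm, gf)


def _dosage_dot(dosages: np.ndarray, beta: np.ndarray, chunk: int = 512) -> np.ndarray:
    """``dosages @ beta`` without materializing a float copy of the whole
    dosage matrix."""
    out = np.zeros(dosages.shape[0])
    for j0 in range(0, dosages.shape[1], chunk):
        out += dosages[:, j0:j0 + chunk].astype(np.float64) @ beta[j0:j0 + chunk]
    return out


def _draw_effects(rng, config, n_causal):
    weights = np.array([w for w, _ in config.effect_mixture], dtype=float)
    mats = [np.asarray(U, dtype=float) for _, U in config.effect_mixture]
    comp = rng.choice(len(weights), size=n_causal, p=weights / weights.sum())
    z = rng.standard_normal((n_causal, 2))
    betas = np.empty((n_causal, 2))
    for k, U in enumerate(mats):
        idx = comp == k
        if not idx.any():
            continue
        vals, vecs = np.linalg.eigh(U)
        root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
        betas[idx] = z[idx] @ root
    return betas, comp


def simulate_cohort(config: SimConfig, seed=None) -> tuple[Cohort, TruthEffects]:
    """Simulate a cohort and its generative truth; reproducible from ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    n, m = config.n_individuals, config.n_snps

    if callable(config.allele_freq_law):
        p = np.asarray(config.allele_freq_law(rng, m), dtype=float)
    else:
        name, lo, hi = config.allele_freq_law
        if name != "uniform":
            raise ConfigError(f"unknown allele_freq_law {name!r}")
        p = rng.uniform(lo, hi, size=m)
    if ((p <= 0) | (p >= 1)).any():
        raise ConfigError("allele frequencies must lie strictly in (0, 1)")

    # two Bernoulli draws per genotype (Hardy-Weinberg), much faster than
    # the generic binomial path at this scale
    dosages = (
        (rng.random((n, m), dtype=np.float32) < p.astype(np.float32)).astype(np.int8)
        + (rng.random((n, m), dtype=np.float32) < p.astype(np.float32)).astype(np.int8)
    )

    n_m = int(round(n * config.sex_ratio))
    is_male = np.zeros(n, dtype=bool)
    is_male[:n_m] = True
    rng.shuffle(is_male)

    beta_m = np.zeros(m)
    beta_f = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    component = np.full(m, -1, dtype=np.int64)
    if config.n_causal > 0:
        idx = rng.choice(m, size=config.n_causal, replace=False)
        causal[idx] = True
        betas, comp = _draw_effects(rng, config, config.n_causal)
        beta_m[idx] = betas[:, 0]
        beta_f[idx] = betas[:, 1]
        component[idx] = comp

    freq = dosages.mean(axis=0, dtype=np.float64) / 2.0
    het = 2.0 * freq * (1.0 - freq)
    var_g_m = float(np.sum(beta_m**2 * het))
    var_g_f = float(np.sum(beta_f**2 * het))

    if config.env_var_m is not None:
        var_e_m = float(config.env_var_m)
    else:
        var_e_m = var_g_m * (1.0 - config.h2_m) / config.h2_m
    var_e_f = config.env_var_ratio_f_to_m * var_e_m

    sd_e = np.where(is_male, np.sqrt(var_e_m), np.sqrt(var_e_f))
    e = rng.standard_normal(n) * sd_e
    g = np.where(is_male, _dosage_dot(dosages, beta_m), _dosage_dot(dosages, beta_f))
    y = config.intercept + g + e

    width = len(str(m))
    snp_id = np.array([f"snp{i:0{width}d}" for i in range(m)])
    pos = np.arange(1, m + 1, dtype=np.int64)
    chrom = np.full(m, "1", dtype=object)
    block = np.minimum(
        (np.arange(m) * config.n_blocks) // m, config.n_blocks - 1
    ).astype(np.int64)

    cohort = Cohort(dosages, is_male, y, snp_id, chrom, pos, freq, block)
    truth = TruthEffects(beta_m, beta_f, causal, var_g_m, var_g_f,
                         var_e_m, var_e_f, component)
    return cohort, truth


# ---------------------------------------------------------------------------
# sexually antagonistic viability selection on allele frequencies
# ---------------------------------------------------------------------------

def true_selection_constant(a_m: float, a_f: float) -> float:
    """Proportionality constant A linking between-sex FST to the per-site
    GxSex genetic variance under the antagonistic viability-selection model.

    With selection gradients ``a_m, a_f >= 0`` and the equilibrium
    constraint ``s_f = -s_m``, first-order allele-frequency perturbation
    gives ``FST = (1/4) p (1-p) (s_m - s_f)^2`` with
    ``s_m - s_f = 2 k (beta_m - beta_f)``, ``k = a_m a_f / (a_m + a_f)``;
    dividing by ``V_GxSex = 2 p (1-p) (beta_m - beta_f)^2`` yields

        A = k^2 / 2.

    For ``a_m = a_f = a`` this is ``a^2 / 8``.
    """
    if a_m < 0 or a_f < 0:
        raise ConfigError("selection gradients must be non-negative")
    if a_m + a_f == 0:
        return 0.0
    k = a_m * a_f / (a_m + a_f)
    return 0.5 * k * k


def equilibrium_female_effects(beta_m: np.ndarray, a_m: float, a_f: float) -> np.ndarray:
    """Female effects implied by the equilibrium constraint
    ``a_f beta_f = -a_m beta_m``."""
    if a_f <= 0:
        raise ConfigError("a_f must be positive to solve for female effects")
    return -(a_m / a_f) * np.asarray(beta_m, dtype=float)


@dataclass
class SelectionSimConfig:
    """Per-site inputs for the allele-frequency divergence generator.

    ``p`` are zygote frequencies; ``beta_m``/``beta_f`` per-site effects;
    ``a_m``/``a_f`` non-negative selection gradients (per trait unit);
    ``an_m``/``an_f`` sampled allele numbers (2 x individuals).  The
    generator simulates exactly ``s_f = -s_m`` (the equilibrium assumption,
    not a free parameter); ``a_f`` enters only through the implied true A.
    """

    p: np.ndarray
    beta_m: np.ndarray
    beta_f: np.ndarray
    a_m: float
    a_f: float
    an_m: np.ndarray | int
    an_f: np.ndarray | int

    def validate(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if ((p <= 0) | (p >= 1)).any():
            raise ConfigError("zygote frequencies must lie strictly in (0, 1)")
        if self.a_m < 0 or self.a_f < 0:
            raise ConfigError("selection gradients must be non-negative")
        s = np.abs(self.a_m * np.asarray(self.beta_m, dtype=float))
        if (s >= 0.1).any():
            warnings.warn(
                "some |s| >= 0.1: the first-order frequency perturbation "
                "degrades at strong selection", stacklevel=2)

    @property
    def true_A(self) -> float:
        return true_selection_constant(self.a_m, self.a_f)


def simulate_sex_divergence(config: SelectionSimConfig, seed=None) -> pd.DataFrame:
    """Observed adult male/female allele frequencies under antagonistic
    viability selection plus binomial sampling noise.

    Returns a frequency table (canonical columns of :mod:`gxsex.io` plus
    ``p_m_true``/``p_f_true``).  Sites whose deterministic adult frequency
    leaves [0, 1] are excluded with a logged count.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    p = np.asarray(config.p, dtype=float)
    n_sites = len(p)
    s_m = config.a_m * np.asarray(config.beta_m, dtype=float)
    s_f = -s_m  # equilibrium: selection balanced between the sexes
    p_m = p + p * (1.0 - p) * s_m
    p_f = p + p * (1.0 - p) * s_f
    ok = (p_m >= 0) & (p_m <= 1) & (p_f >= 0) & (p_f <= 1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("simulate_sex_divergence: excluded %d site(s) with "
                       "out-of-range adult frequency", n_bad)
    an_m = np.broadcast_to(np.asarray(config.an_m, dtype=np.int64), (n_sites,))
    an_f = np.broadcast_to(np.asarray(config.an_f, dtype=np.int64), (n_sites,))
    p_m, p_f = p_m[ok], p_f[ok]
    an_m, an_f = an_m[ok], an_f[ok]
    p_m_hat = rng.binomial(an_m, p_m) / an_m
    p_f_hat = rng.binomial(an_f, p_f) / an_f
    width = len(str(n_sites))
    snp_id = np.array([f"snp{i:0{width}d}" for i in np.flatnonzero(ok)])
    return pd.DataFrame({
        "snp_id": snp_id,
        "counted_allele": "A",
        "p_m_hat": p_m_hat,
        "p_f_hat": p_f_hat,
        "an_m": an_m,
        "an_f": an_f,
        "p_m_true": p_m,
        "p_f_true": p_f,
    })
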