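"""Empirical-Bayes mixture of male/female effect-covariance relationships.

The model: a SNP's true effect pair ``b = (beta_m, beta_f)`` is drawn from
a mixture of zero-centered bivariate normals with pre-specified covariance
patterns (the "hypothesis matrices"), each expanded over a grid of overall
scales; the observed estimates are ``b_hat = b + noise`` with known,
SNP-specific diagonal noise covariance ``S_j = diag(se_m^2, se_f^2)``
(male and female GWAS samples do not overlap, so the error correlation is
zero).  Marginally

    b_hat_j ~ sum_k pi_k N2(0, omega_k U_k + S_j),

and the mixture proportions ``pi`` are estimated by maximum likelihood via
EM (with SQUAREM-style acceleration; every recorded step is monotone in
the log-likelihood).  Mixture weights, collapsed over scales and summed
within qualitative categories of the matrices (relative magnitude x
correlation), summarize the modes of gene-by-sex interaction; the
"sex-biased amplification" statistic is the summed non-null weight on
male-larger matrices minus the summed weight on female-larger ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Component",
    "HypothesisMatrixSet",
    "hypothesis_grid",
    "default_scale_grid",
    "EffectCovarianceMixture",
    "MixtureResults",
    "WeightSummary",
    "DEFAULT_CORRELATIONS",
    "DEFAULT_RATIOS",
]

DEFAULT_CORRELATIONS = (-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_RATIOS = (0.25, 0.5, 2.0 / 3.0, 1.0, 1.5, 2.0, 4.0)

MAGNITUDE_CLASSES = ("M>F", "equal", "M<F", "M-only", "F-only", "null")


@dataclass(frozen=True)
class Component:
    """One labeled 2x2 covariance pattern."""

    label: str
    matrix: np.ndarray
    magnitude_class: str          # one of MAGNITUDE_CLASSES
    correlation: float | None = None
    ratio: float | None = None    # female:male magnitude ratio q

    def __post_init__(self):
        U = np.asarray(self.matrix, dtype=float)
        if U.shape != (2, 2) or abs(U[0, 1] - U[1, 0]) > 1e-12:
            raise ValueError(f"component {self.label}: not a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(U).min() < -1e-9:
            raise ValueError(f"component {self.label}: not positive semidefinite")
        if self.magnitude_class not in MAGNITUDE_CLASSES:
            raise ValueError(f"unknown magnitude class {self.magnitude_class!r}")
        object.__setattr__(self, "matrix", U)


class HypothesisMatrixSet:
    """An ordered set of hypothesis components; the null comes first."""

    def __init__(self, components: list[Component]):
        nulls = [c for c in components if c.magnitude_class == "null"]
        if len(nulls) != 1:
            raise ValueError("exactly one null component is required")
        seen = set()
        for c in components:
            key = (c.correlation, c.ratio, c.magnitude_class)
            if c.correlation is not None and key in seen:
                raise ValueError(f"duplicate (correlation, ratio) pair in {c.label}")
            seen.add(key)
        self.components = [nulls[0]] + [c for c in components if c.magnitude_class != "null"]

    def __len__(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    @property
    def nonnull(self) -> list[Component]:
        return self.components[1:]

    def index(self, label: str) -> int:
        return self.labels.index(label)


def hypothesis_grid(correlations=DEFAULT_CORRELATIONS, ratios=DEFAULT_RATIOS,
                    include_specials: bool = True) -> HypothesisMatrixSet:
    """The default hypothesis set: a null matrix, single-sex matrices and a
    correlation x magnitude-ratio grid (9 x 7 by default, 66 components).

    Component pattern for correlation ``r`` and female:male magnitude
    ratio ``q`` is ``U(r, q) = [[1, r q], [r q, q^2]]``; the magnitude
    category is ``M>F`` for ``q < 1``, ``equal`` for ``q = 1`` and ``M<F``
    for ``q > 1``.
    """
    comps = [Component("null", np.zeros((2, 2)), "null")]
    if include_specials:
        comps.append(Component("M-only", np.array([[1.0, 0.0], [0.0, 0.0]]), "M-only"))
        comps.append(Component("F-only", np.array([[0.0, 0.0], [0.0, 1.0]]), "F-only"))
    seen = set()
    for r in correlations:
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        for q in ratios:
            if q <= 0:
                raise ValueError("magnitude ratios must be positive")
            if (r, q) in seen:
                raise ValueError(f"duplicate (r, q) pair ({r}, {q})")
            seen.add((r, q))
            U = np.array([[1.0, r * q], [r * q, q * q]])
            mag = "equal" if q == 1 else ("M<F" if q > 1 else "M>F")
            comps.append(Component(f"r={r:g},q={q:g}", U, mag, correlation=r, ratio=q))
    return HypothesisMatrixSet(comps)


def default_scale_grid(beta_m, beta_f, se_m, se_f) -> np.ndarray:
    """Geometric (ratio 2) grid of overall scales spanning
    ``[0.25 * min(se^2), 4 * max(beta_m^2 + beta_f^2)]``.

    The hypothesis matrices fix only relative (co)variances; a dense scale
    grid is the usual adaptive-shrinkage resolution of the unknown
    absolute scale.
    """
    lo = 0.25 * float(min(np.min(np.square(se_m)), np.min(np.square(se_f))))
    hi = 4.0 * float(np.max(np.square(beta_m) + np.square(beta_f)))
    if not np.isfinite(lo) or not np.isfinite(hi) or lo <= 0:
        raise ValueError("cannot build scale grid from degenerate inputs")
    hi = max(hi, lo)
    n = int(np.ceil(np.log2(hi / lo))) + 1
    return lo * 2.0 ** np.arange(n)


@dataclass
class WeightSummary:
    """Mixture weights collapsed over scales, plus derived summaries.

    ``sex_biased_amplification`` is the non-null-normalized summed weight
    on male-larger matrices (including male-specific) minus the sum on
    female-larger matrices (including female-specific), in [-1, 1].
    """

    raw: pd.Series                   # per component, scales collapsed
    nonnull: pd.Series | None        # raw / (1 - null weight)
    category: pd.Series              # raw weight summed per magnitude class
    category_nonnull: pd.Series | None
    sex_biased_amplification: float | None
    null_weight: float

    def __repr__(self):
        amp = (f"{self.sex_biased_amplification:+.3f}"
               if self.sex_biased_amplification is not None else "undefined")
        return (f"<WeightSummary null={self.null_weight:.3f} "
                f"sex_biased_amplification={amp}>")


class EffectCovarianceMixture:
    """Mixture-of-covariances model for sex-stratified effect estimates.

    Parameters
    ----------
    sumstats : pandas.DataFrame
        Canonical summary-statistics table (``beta_m``, ``se_m``,
        ``beta_f``, ``se_f`` are used).  Records with non-finite entries
        or non-positive SEs are excluded.
    grid : HypothesisMatrixSet, optional
        Hypothesis components; defaults to :func:`hypothesis_grid`.
    scales : array-like, optional
        Overall scale grid; defaults to :func:`default_scale_grid`
        evaluated on the data.

    ``fit`` maximizes the mixture likelihood over the proportions by EM;
    ``fit_resampled`` repeats the fit on one-SNP-per-block subsamples and
    averages the proportions, the procedure used to obtain approximately
    independent SNPs.
    """

    def __init__(self, sumstats: pd.DataFrame, grid: HypothesisMatrixSet | None = None,
                 scales=None):
        if len(sumstats) == 0:
            raise ValueError("empty summary-statistics table")
        arr = sumstats[["beta_m", "se_m", "beta_f", "se_f"]].to_numpy(dtype=float)
        ok = np.isfinite(arr).all(axis=1) & (arr[:, 1] > 0) & (arr[:, 3] > 0)
        self.n_excluded = int((~ok).sum())
        if not ok.any():
            raise ValueError("no usable records (non-finite estimates or SEs)")
        self.sumstats = sumstats.loc[ok].reset_index(drop=True)
        self.beta = arr[ok][:, [0, 2]]
        self.s2 = arr[ok][:, [1, 3]] ** 2
        self.grid = grid if grid is not None else hypothesis_grid()
        if scales is None:
            scales = default_scale_grid(self.beta[:, 0], self.beta[:, 1],
                                        np.sqrt(self.s2[:, 0]), np.sqrt(self.s2[:, 1]))
        self.scales = np.asarray(scales, dtype=float)
        # expanded component table: entry 0 is the null, then
        # (component, scale) pairs in component-major order
        self.comp_of_entry = np.concatenate([
            [0], np.repeat(np.arange(1, len(self.grid)), len(self.scales))])
        self.scale_of_entry = np.concatenate([
            [np.nan], np.tile(self.scales, len(self.grid) - 1)])
        self.n_entries = len(self.comp_of_entry)
        self._logL = None

    # -- likelihood machinery ------------------------------------------------

    def loglik_matrix(self) -> np.ndarray:
        """(n_snps, n_entries) log densities ``log N2(b_hat; 0, w U + S)``."""
        if self._logL is not None:
            return self._logL
        n = len(self.beta)
        x, y = self.beta[:, 0][:, None], self.beta[:, 1][:, None]
        sm2, sf2 = self.s2[:, 0][:, None], self.s2[:, 1][:, None]
        u00 = np.array([c.matrix[0, 0] for c in self.grid.components])
        u01 = np.array([c.matrix[0, 1] for c in self.grid.components])
        u11 = np.array([c.matrix[1, 1] for c in self.grid.components])
        w = np.where(np.isnan(self.scale_of_entry), 0.0, self.scale_of_entry)
        a = w * u00[self.comp_of_entry]  # (K,)
        b = w * u01[self.comp_of_entry]
        d = w * u11[self.comp_of_entry]
        A = a[None, :] + sm2          # (n, K)
        D = d[None, :] + sf2
        B = np.broadcast_to(b[None, :], A.shape)
        det = A * D - B * B
        quad = (D * x * x - 2.0 * B * x * y + A * y * y) / det
        self._logL = -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
        if not np.isfinite(self._logL).all():
            raise FloatingPointError("non-finite mixture likelihood")
        return self._logL

    @staticmethod
    def _prepare(logL):
        mx = logL.max(axis=1)
        return np.exp(logL - mx[:, None]), float(mx.sum())

    @staticmethod
    def _em_step(pi, L):
        w = L * pi
        s = w.sum(axis=1)
        return (w / s[:, None]).mean(axis=0)

    @staticmethod
    def _loglik(pi, L, shift):
        return float(np.log(L @ pi).sum()) + shift

    def _fit_pi(self, L, shift, tol, maxiter, accelerate=True):
        """Maximize the proportion likelihood; returns (pi, trace, converged).

        Plain EM is safeguarded SQUAREM-accelerated: whenever the
        extrapolated step would not improve the log-likelihood, the plain
        (monotone) double EM step is taken instead, so the recorded trace
        never decreases.  Mixture entries whose proportion has decayed to
        numerical zero are pruned from the working set (guarded so the
        pruning itself never lowers the log-likelihood; the likelihood is
        concave in the proportions, so decayed entries do not return).
        """
        K = L.shape[1]
        pi = np.full(K, 1.0 / K)
        ll = self._loglik(pi, L, shift)
        trace = [ll]
        converged = False
        active = np.arange(K)
        La = L
        for it in range(maxiter):
            p1 = self._em_step(pi, La)
            p2 = self._em_step(p1, La)
            new = p2
            if accelerate:
                r = p1 - pi
                v = p2 - p1 - r
                nv = np.linalg.norm(v)
                if nv > 0:
                    alpha = min(-np.linalg.norm(r) / nv, -1.0)
                    cand = pi - 2.0 * alpha * r + alpha * alpha * v
                    cand = np.clip(cand, 0.0, None)
                    s = cand.sum()
                    if s > 0:
                        cand /= s
                        cand = self._em_step(cand, La)  # stabilizing EM step
                        if self._loglik(cand, La, shift) >= self._loglik(p2, La, shift):
                            new = cand
            new_ll = self._loglik(new, La, shift)
            if new_ll < ll:   # numerical safeguard; EM step itself is monotone
                new, new_ll = p2, self._loglik(p2, La, shift)
            trace.append(new_ll)
            done = abs(new_ll - ll) <= tol * (abs(ll) + 1e-12)
            pi, ll = new, new_ll
            if done:
                converged = True
                break
            if it >= 4 and it % 5 == 4 and len(active) > 1:
                keep = pi > 1e-12
                if keep.sum() and not keep.all():
                    cand = pi[keep] / pi[keep].sum()
                    cand_ll = self._loglik(cand, La[:, keep], shift)
                    if cand_ll >= ll:
                        active = active[keep]
                        La = La[:, keep]
                        pi, ll = cand, cand_ll
                        trace[-1] = ll
        full = np.zeros(K)
        full[active] = np.clip(pi, 0.0, None)
        full /= full.sum()
        return full, np.asarray(trace), converged

    # -- public fitting API --------------------------------------------------

    def fit(self, tol: float = 1e-8, maxiter: int = 5000,
            accelerate: bool = True) -> "MixtureResults":
        """Maximum-likelihood mixture proportions on the full table."""
        L, shift = self._prepare(self.loglik_matrix())
        pi, trace, converged = self._fit_pi(L, shift, tol, maxiter, accelerate)
        return MixtureResults(self, pi, trace=trace, converged=converged,
                              n_snps=[len(self.beta)])

    def fit_resampled(self, block_ids, n_repeats: int = 100, seed=None,
                      tol: float = 1e-8, maxiter: int = 5000,
                      accelerate: bool = True) -> "MixtureResults":
        """Repeat the fit on one-SNP-per-block subsamples; average proportions.

        Each repeat draws one SNP per block.  Within a block, SNPs are
        consumed without replacement across repeats until the block's pool
        is exhausted, at which point the pool resets (a fresh permutation).
        The averaged proportions treat repeats as i.i.d. draws.
        """
        block_ids = np.asarray(block_ids)
        if len(block_ids) != len(self.beta):
            raise ValueError("block_ids must align with the model's records")
        if (block_ids < 0).any():
            raise ValueError("every SNP must be assigned to a block")
        rng = np.random.default_rng(seed)
        blocks = [np.flatnonzero(block_ids == b) for b in np.unique(block_ids)]
        blocks = [b for b in blocks if len(b)]
        if not blocks:
            raise ValueError("no non-empty blocks")
        logL = self.loglik_matrix()
        queues = [rng.permutation(b) for b in blocks]
        cursor = [0] * len(blocks)
        per_repeat = np.empty((n_repeats, self.n_entries))
        logliks = np.empty(n_repeats)
        n_snps = []
        for rep in range(n_repeats):
            idx = np.empty(len(blocks), dtype=np.int64)
            for i, q in enumerate(queues):
                if cursor[i] >= len(q):
                    queues[i] = q = rng.permutation(blocks[i])
                    cursor[i] = 0
                idx[i] = q[cursor[i]]
                cursor[i] += 1
            L, shift = self._prepare(logL[idx])
            pi, trace, _ = self._fit_pi(L, shift, tol, maxiter, accelerate)
            per_repeat[rep] = pi
            logliks[rep] = trace[-1]
            n_snps.append(len(idx))
        pi_bar = per_repeat.mean(axis=0)
        return MixtureResults(self, pi_bar, per_repeat=per_repeat,
                              repeat_logliks=logliks, n_snps=n_snps, seed=seed)


@dataclass
class MixtureResults:
    """Fitted mixture proportions and derived summaries."""

    model: EffectCovarianceMixture
    pi: np.ndarray                       # per (component, scale) entry
    trace: np.ndarray | None = None      # log-likelihood trace (single fits)
    per_repeat: np.ndarray | None = None
    repeat_logliks: np.ndarray | None = None
    n_snps: list = field(default_factory=list)
    seed: object = None
    converged: bool = True

    @property
    def n_repeats(self) -> int:
        return 0 if self.per_repeat is None else len(self.per_repeat)

    def component_weights(self, pi: np.ndarray | None = None) -> pd.Series:
        """Weights collapsed over the scale grid, indexed by component label."""
        pi = self.pi if pi is None else pi
        w = np.bincount(self.model.comp_of_entry, weights=pi,
                        minlength=len(self.model.grid))
        return pd.Series(w, index=self.model.grid.labels, name="weight")

    def weight_summary(self) -> WeightSummary:
        """Collapse scales, normalize by the non-null total, sum categories
        and compute the sex-biased amplification statistic."""
        raw = self.component_weights()
        null_w = float(raw.iloc[0])
        mag = pd.Series([c.magnitude_class for c in self.model.grid.components],
                        index=raw.index)
        category = raw.groupby(mag).sum().reindex(MAGNITUDE_CLASSES, fill_value=0.0)
        if 1.0 - null_w <= 1e-12:
            return WeightSummary(raw, None, category, None, None, null_w)
        nonnull = raw / (1.0 - null_w)
        nonnull.iloc[0] = 0.0
        cat_nn = category / (1.0 - null_w)
        cat_nn["null"] = 0.0
        amp = float(cat_nn["M>F"] + cat_nn["M-only"] - cat_nn["M<F"] - cat_nn["F-only"])
        return WeightSummary(raw, nonnull, category, cat_nn, amp, null_w)

    def posterior_effects(self) -> pd.DataFrame:
        """Posterior mean and SD of the true effect pair for every record.

        Per SNP j and mixture entry k, responsibilities are proportional
        to ``pi_k N2(b_hat_j; 0, Sigma_k + S_j)``; each entry's posterior
        is the normal-normal conjugate update
        ``mu_k = Sigma_k (Sigma_k + S_j)^{-1} b_hat_j`` with covariance
        ``Sigma_k (Sigma_k + S_j)^{-1} S_j``, combined over the mixture.
        """
        m = self.model
        logL = m.loglik_matrix()
        R = np.exp(logL - logL.max(axis=1)[:, None]) * self.pi
        R /= R.sum(axis=1)[:, None]
        x, y = m.beta[:, 0], m.beta[:, 1]
        sm2, sf2 = m.s2[:, 0], m.s2[:, 1]
        mean = np.zeros((len(x), 2))
        m2 = np.zeros((len(x), 2))
        comps = m.grid.components
        for k in range(1, m.n_entries):
            r = R[:, k]
            if not r.any():
                continue
            U = comps[m.comp_of_entry[k]].matrix * m.scale_of_entry[k]
            a, b, d = U[0, 0], U[0, 1], U[1, 1]
            A, B, D = a + sm2, b, d + sf2
            det = A * D - B * B
            # Sigma (Sigma + S)^-1, 2x2 closed form
            g00 = (a * D - b * B) / det
            g01 = (b * A - a * B) / det
            g10 = (b * D - d * B) / det
            g11 = (d * A - b * B) / det
            mu_m = g00 * x + g01 * y
            mu_f = g10 * x + g11 * y
            c_mm = g00 * sm2
            c_ff = g11 * sf2
            mean[:, 0] += r * mu_m
            mean[:, 1] += r * mu_f
            m2[:, 0] += r * (c_mm + mu_m**2)
            m2[:, 1] += r * (c_ff + mu_f**2)
        sd = np.sqrt(np.maximum(m2 - mean**2, 0.0))
        return pd.DataFrame({
            "snp_id": m.sumstats["snp_id"].to_numpy(),
            "post_beta_m": mean[:, 0], "post_beta_f": mean[:, 1],
            "post_sd_m": sd[:, 0], "post_sd_f": sd[:, 1],
        })

    def summary(self) -> str:
        ws = self.weight_summary()
        lines = ["Effect-covariance mixture fit",
                 "=" * 45,
                 f"records: {len(self.model.beta)}   entries: {self.model.n_entries} "
                 f"({len(self.model.grid)} components x {len(self.model.scales)} scales)",
                 f"repeats: {self.n_repeats or 1}",
                 f"null weight: {ws.null_weight:.4f}"]
        if ws.category_nonnull is not None:
            lines.append("non-null category weights (%):")
            for cls in ("M>F", "equal", "M<F", "M-only", "F-only"):
                lines.append(f"  {cls:8s} {100 * ws.category_nonnull[cls]:6.2f}")
            lines.append(
                f"sex-biased amplification: {100 * ws.sex_biased_amplification:+.2f} pp")
        top = self.component_weights().sort_values(ascending=False).head(5)
        lines.append("top components: " + ", ".join(
            f"{k}={v:.3f}" for k, v in top.items()))
        return "\n".join(lines)
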