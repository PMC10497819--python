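"""Univariable two-sample MR estimators and diagnostics.

All estimators consume harmonized per-SNP pairs (gamma_j, se_gamma_j) for the
instrument-exposure association and (Gamma_j, se_Gamma_j) for the
instrument-outcome association.  P-values are normal-based throughout (GWAS
large-sample convention); 95% CIs use z = 1.959964.  The random-effects IVW
uses a multiplicative overdispersion scale phi = max(1, Q / (J - 1)), so the
SE is inflated under heterogeneity and never deflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .instruments import HarmonizedRecord
from .summstats import Z975


@dataclass
class MrEstimate:
    """One method's causal estimate with its diagnostics."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=float("nan"))
    ci_high: float = field(default=float("nan"))
    q_stat: float | None = None
    q_pval: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z975 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z975 * self.se

    def to_or_ci(self) -> tuple[float, float, float]:
        return (float(np.exp(self.beta)), float(np.exp(self.ci_low)),
                float(np.exp(self.ci_high)))


def _normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def _arrays(records: list[HarmonizedRecord]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([r.gamma for r in records], dtype=float)
    sg = np.array([r.se_gamma for r in records], dtype=float)
    G = np.array([r.Gamma for r in records], dtype=float)
    sG = np.array([r.se_Gamma for r in records], dtype=float)
    return g, sg, G, sG


def wald_ratio(rec: HarmonizedRecord, second_order: bool = False) -> MrEstimate:
    """Per-SNP ratio estimate Gamma/gamma with first-order delta-method SE.

    ``second_order=True`` adds the exposure-side term
    Gamma^2 * se_gamma^2 / gamma^4 to the variance.
    """
    if rec.gamma == 0:
        raise ValueError(f"{rec.snp_id}: gamma = 0, Wald ratio undefined")
    beta = rec.Gamma / rec.gamma
    var = (rec.se_Gamma / rec.gamma) ** 2
    if second_order:
        var += rec.Gamma ** 2 * rec.se_gamma ** 2 / rec.gamma ** 4
    se = float(np.sqrt(var))
    return MrEstimate(method="wald", beta=float(beta), se=se,
                      pval=_normal_p(beta / se), n_snp=1)


def ivw(records: list[HarmonizedRecord], mode: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate: WLS of Gamma on gamma through the
    origin with weights 1/se_Gamma^2.

    ``mode='fixed'`` reports the fixed-effect SE; ``mode='random'`` applies
    the multiplicative heterogeneity scale phi = max(1, Q/(J-1)).  Cochran's
    Q and its chi-square p-value (J-1 df) are reported either way.
    """
    if mode not in {"fixed", "random"}:
        raise ValueError(f"unknown IVW mode {mode!r}")
    if len(records) == 0:
        raise ValueError("no records")
    if len(records) == 1:
        est = wald_ratio(records[0])
        est.method = f"ivw_{mode}"
        return est
    g, _, G, sG = _arrays(records)
    if np.all(g == 0):
        raise ValueError("all gamma are zero; IVW undefined")
    w = 1.0 / sG ** 2
    denom = float(np.sum(w * g * g))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (G - beta * g) ** 2))
    dof = len(records) - 1
    q_pval = float(sps.chi2.sf(q, dof))
    phi = max(1.0, q / dof)
    se = se_fixed * np.sqrt(phi) if mode == "random" else se_fixed
    return MrEstimate(method=f"ivw_{mode}", beta=beta, se=float(se),
                      pval=_normal_p(beta / se), n_snp=len(records),
                      q_stat=q, q_pval=q_pval, phi=float(phi))


def cochran_q(records: list[HarmonizedRecord], beta_ref: float
              ) -> tuple[float, float]:
    """Cochran's Q of the per-SNP Wald ratios around ``beta_ref``.

    Q = sum_j (gamma_j/se_Gamma_j)^2 (beta_j - beta_ref)^2, chi-square J-1 df.
    """
    if len(records) < 2:
        raise ValueError("Cochran's Q needs >= 2 records")
    g, _, G, sG = _arrays(records)
    ratios = G / g
    w = (g / sG) ** 2
    q = float(np.sum(w * (ratios - beta_ref) ** 2))
    return q, float(sps.chi2.sf(q, len(records) - 1))


def mr_egger(records: list[HarmonizedRecord]
             ) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger: weighted regression of Gamma on gamma WITH intercept.

    Records are first oriented so every gamma_j >= 0 (the estimator is not
    orientation-invariant).  The slope is the pleiotropy-adjusted causal
    estimate; the intercept estimates average directional pleiotropy.  Both
    SEs carry the multiplicative scale phi = max(1, Q_egger/(J-2)).
    """
    if len(records) < 3:
        raise ValueError("MR-Egger needs >= 3 records")
    g, _, G, sG = _arrays(records)
    flip = np.where(g < 0, -1.0, 1.0)
    g, G = g * flip, G * flip
    w = 1.0 / sG ** 2
    X = np.column_stack([np.ones_like(g), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    dof = len(records) - 2
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, q / dof)
    cov = np.linalg.inv(xtwx) * phi
    ses = np.sqrt(np.diag(cov))
    q_pval = float(sps.chi2.sf(q, dof))
    slope = MrEstimate(method="egger_slope", beta=float(coef[1]), se=float(ses[1]),
                       pval=_normal_p(coef[1] / ses[1]), n_snp=len(records),
                       q_stat=q, q_pval=q_pval, phi=float(phi))
    intercept = MrEstimate(method="egger_intercept", beta=float(coef[0]),
                           se=float(ses[0]), pval=_normal_p(coef[0] / ses[0]),
                           n_snp=len(records), q_stat=q, q_pval=q_pval,
                           phi=float(phi))
    return slope, intercept


def _wm_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b, w = ratios[order], weights[order]
    csum = np.cumsum(w)
    p = (csum - w / 2.0) / csum[-1]
    return float(np.interp(0.5, p, b))


def weighted_median(records: list[HarmonizedRecord], n_boot: int = 1000,
                    seed: int = 0) -> MrEstimate:
    """Weighted median of the per-SNP ratios, weights (gamma_j/se_Gamma_j)^2.

    Consistent when >= 50% of the weight comes from valid instruments.  The
    SE is a parametric bootstrap (resampling gamma and Gamma from normals
    with their reported SEs); ``n_boot=0`` skips it (SE reported as NaN).
    """
    if len(records) < 3:
        raise ValueError("weighted median needs >= 3 records")
    g, sg, G, sG = _arrays(records)
    est = _wm_point(G / g, (g / sG) ** 2)
    se, pval = float("nan"), float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            gb = rng.normal(g, sg)
            Gb = rng.normal(G, sG)
            gb[gb == 0] = np.finfo(float).tiny
            boots[b] = _wm_point(Gb / gb, (gb / sG) ** 2)
        se = float(np.std(boots, ddof=1))
        pval = _normal_p(est / se)
    return MrEstimate(method="weighted_median", beta=est, se=se, pval=pval,
                      n_snp=len(records))


def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                bandwidth_factor: float) -> float:
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = sps.median_abs_deviation(ratios, scale="normal")
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    h = bandwidth_factor * 0.9 * s * n ** (-1 / 5)
    if h == 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.sum(weights[None, :]
                  * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
                  axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(records: list[HarmonizedRecord], bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    """Weighted mode of the per-SNP ratios via a weighted Gaussian KDE.

    Bandwidth is ``bandwidth_factor`` times a modified-Silverman scale,
    0.9 * min(SD, normalized MAD) * J^(-1/5); the estimate is the argmax of
    the weighted density on a 512-point grid.  Robust when the largest group
    of similar ratios comes from valid instruments.  Parametric-bootstrap SE
    as in :func:`weighted_median`.
    """
    if len(records) < 3:
        raise ValueError("weighted mode needs >= 3 records")
    g, sg, G, sG = _arrays(records)
    w = (g / sG) ** 2
    est = _mode_point(G / g, w, bandwidth_factor)
    se, pval = float("nan"), float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            gb = rng.normal(g, sg)
            Gb = rng.normal(G, sG)
            gb[gb == 0] = np.finfo(float).tiny
            boots[b] = _mode_point(Gb / gb, (gb / sG) ** 2, bandwidth_factor)
        se = float(np.std(boots, ddof=1))
        pval = _normal_p(est / se)
    return MrEstimate(method="weighted_mode", beta=est, se=se, pval=pval,
                      n_snp=len(records))


@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO global / outlier / distortion procedure."""

    global_rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray
    outlier_indices: list[int]
    distortion_pval: float | None
    estimate_raw: MrEstimate
    estimate_corrected: MrEstimate | None
    n_sim: int
    seed: int


def _loo_ivw_beta(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW betas, vectorized; rows may be 2-D (sims x SNPs)."""
    num = np.sum(w * g * G, axis=-1, keepdims=True) - w * g * G
    den = np.sum(w * g * g, axis=-1, keepdims=True) - w * g * g
    return num / den


def mr_presso(records: list[HarmonizedRecord], n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed: int = 0) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    Global test: observed RSS = sum_j w_j (Gamma_j - beta_loo_j * gamma_j)^2
    with beta_loo_j the leave-one-out IVW estimate and w_j = 1/se_Gamma_j^2;
    the null distribution is built by parametric simulation (Gamma*_j ~
    N(beta_loo_j * gamma_j, se_Gamma_j^2), gamma*_j ~ N(gamma_j,
    se_gamma_j^2)) and the p-value is the exceedance fraction.  Outlier test:
    each SNP's observed weighted squared residual against its simulated
    distribution, Bonferroni-corrected by J.  Distortion test: shift of the
    outlier-corrected IVW beta against random removals of the same count.
    """
    J = len(records)
    if J < 4:
        raise ValueError("MR-PRESSO needs >= 4 records")
    g, sg, G, sG = _arrays(records)
    w = 1.0 / sG ** 2
    rng = np.random.default_rng(seed)

    beta_loo = _loo_ivw_beta(g, G, w)
    resid_obs = w * (G - beta_loo * g) ** 2
    rss_obs = float(np.sum(resid_obs))

    g_sim = rng.normal(g, sg, size=(n_sim, J))
    G_sim = rng.normal(beta_loo * g, sG, size=(n_sim, J))
    beta_loo_sim = _loo_ivw_beta(g_sim, G_sim, w)
    resid_sim = w * (G_sim - beta_loo_sim * g_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_pval = float(np.mean(rss_sim >= rss_obs))

    # per-SNP outlier p-values (empirical exceedance, Bonferroni by J)
    exceed = np.mean(resid_sim >= resid_obs[None, :], axis=0)
    outlier_pvals = np.minimum(exceed * J, 1.0)
    outlier_idx = [int(i) for i in np.flatnonzero(outlier_pvals < outlier_alpha)]

    raw = ivw(records, mode="random")
    corrected = None
    distortion_pval = None
    if outlier_idx:
        keep = [r for i, r in enumerate(records) if i not in set(outlier_idx)]
        if not keep:
            raise ValueError("all SNPs flagged as outliers; no corrected model")
        corrected = ivw(keep, mode="random")
        corrected.method = "presso_corrected"
        d_obs = abs(corrected.beta - raw.beta)
        n_rm = len(outlier_idx)
        wgG, wgg = w * g * G, w * g * g
        rm_idx = np.stack([rng.choice(J, size=n_rm, replace=False)
                           for _ in range(n_sim)])
        num = wgG.sum() - wgG[rm_idx].sum(axis=1)
        den = wgg.sum() - wgg[rm_idx].sum(axis=1)
        d_null = np.abs(num / den - raw.beta)
        distortion_pval = float(np.mean(d_null >= d_obs))
    raw.method = "presso_raw"
    return PressoResult(global_rss_obs=rss_obs, global_pval=global_pval,
                        outlier_pvals=outlier_pvals, outlier_indices=outlier_idx,
                        distortion_pval=distortion_pval, estimate_raw=raw,
                        estimate_corrected=corrected, n_sim=n_sim, seed=seed)


def run_all_uvmr(records: list[HarmonizedRecord], n_boot: int = 1000,
                 n_sim: int = 1000, seed: int = 0) -> dict[str, MrEstimate]:
    """Convenience: IVW (random) plus the full sensitivity suite."""
    out: dict[str, MrEstimate] = {"ivw_random": ivw(records, mode="random"),
                                  "ivw_fixed": ivw(records, mode="fixed")}
    if len(records) >= 3:
        slope, intercept = mr_egger(records)
        out["egger_slope"] = slope
        out["egger_intercept"] = intercept
        out["weighted_median"] = weighted_median(records, n_boot=n_boot, seed=seed)
        out["weighted_mode"] = weighted_mode(records, n_boot=n_boot, seed=seed)
    if len(records) >= 4:
        presso = mr_presso(records, n_sim=n_sim, seed=seed)
        out["presso_raw"] = presso.estimate_raw
        if presso.estimate_corrected is not None:
            out["presso_corrected"] = presso.estimate_corrected
    return out


__all__ = [
    "MrEstimate", "PressoResult", "wald_ratio", "ivw", "cochran_q",
    "mr_egger", "weighted_median", "weighted_mode", "mr_presso", "run_all_uvmr",
]
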