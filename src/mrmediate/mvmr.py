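"""Multivariable MR: direct effects of K exposures estimated jointly.

MV-IVW is weighted least squares of the per-SNP outcome effects on the K
columns of exposure effects with no intercept and weights 1/se_Gamma^2;
MVMR-Egger adds an intercept after orienting records on a chosen exposure.
SEs carry a multiplicative overdispersion scale with residual degrees of
freedom J-K (J-K-1 for Egger).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .instruments import InstrumentSet, _align_outcome, find_proxy
from .mr import MrEstimate, _normal_p
from .summstats import LdPanel, SummaryStats, pairwise_r2

logger = logging.getLogger(__name__)


@dataclass
class MultiHarmonizedRecord:
    """One SNP's effects on K exposures and the outcome, allele-aligned."""

    snp_id: str
    gammas: np.ndarray
    se_gammas: np.ndarray
    Gamma: float
    se_Gamma: float

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, dtype=float)
        self.se_gammas = np.asarray(self.se_gammas, dtype=float)
        if self.gammas.shape != self.se_gammas.shape:
            raise ValueError(f"{self.snp_id}: gammas/se_gammas shape mismatch")
        if np.any(self.se_gammas <= 0) or self.se_Gamma <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


def mv_harmonize(instrument_sets: list[InstrumentSet],
                 exposures: list[SummaryStats], outcome: SummaryStats,
                 panel: LdPanel, r2_threshold: float = 0.001,
                 window_kb: int = 10_000,
                 eaf_window: tuple[float, float] = (0.42, 0.58),
                 proxy_r2: float = 0.8) -> list[MultiHarmonizedRecord]:
    """Union the per-exposure instruments, re-clump jointly, harmonize all.

    The union is re-clumped greedily at ``r2_threshold`` keeping the smallest
    min-p across exposures; every retained SNP must be found (or proxied) in
    every exposure and the outcome, with alleles aligned to the first
    exposure's effect allele.
    """
    if len(instrument_sets) < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    if len(instrument_sets) != len(exposures):
        raise ValueError("one instrument set per exposure required")

    # min-p per union SNP across the exposure GWASs
    union: dict[str, float] = {}
    anchor: dict[str, object] = {}  # snp -> anchor exposure record (alleles)
    for inst in instrument_sets:
        for snp in inst.snps:
            p_min = min(ss.records[snp.snp_id].pval
                        for ss in exposures if snp.snp_id in ss)
            if snp.snp_id not in union or p_min < union[snp.snp_id]:
                union[snp.snp_id] = p_min
    order = sorted((p, s) for s, p in union.items() if s in panel)
    if len(order) < len(union):
        logger.info("mv_harmonize: %d union SNPs not in panel, dropped",
                    len(union) - len(order))

    window = window_kb * 1000
    accepted: list[str] = []
    for _, snp in order:
        c_chrom, c_pos = panel.positions[snp]
        ok = True
        for kept in accepted:
            k_chrom, k_pos = panel.positions[kept]
            if k_chrom != c_chrom or abs(k_pos - c_pos) > window:
                continue
            try:
                r2 = pairwise_r2(panel, snp, kept)
            except ValueError:
                r2 = 0.0
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(snp)

    k = len(exposures)
    records: list[MultiHarmonizedRecord] = []
    dropped = 0
    for snp in accepted:
        first = exposures[0].records.get(snp)
        out = outcome.records.get(snp)
        if out is None and snp in panel:
            match = find_proxy(snp, outcome, panel, r2_min=proxy_r2)
            if match is not None and first is not None:
                out = outcome.records[match.snp_id]
        if first is None or out is None:
            dropped += 1
            continue
        gammas = np.empty(k)
        ses = np.empty(k)
        gammas[0], ses[0] = first.beta, first.se
        complete = True
        for i, ss in enumerate(exposures[1:], start=1):
            rec = ss.records.get(snp)
            if rec is None:
                complete = False
                break
            aligned = _align_outcome(first, rec, eaf_window)
            if aligned is None:
                complete = False
                break
            gammas[i], ses[i] = aligned[0] * rec.beta, rec.se
        if not complete:
            dropped += 1
            continue
        if out.snp_id == snp:
            aligned = _align_outcome(first, out, eaf_window)
            if aligned is None:
                dropped += 1
                continue
            Gamma = aligned[0] * out.beta
        else:  # proxy: sign from the dosage correlation
            Gamma = match.sign * out.beta
        records.append(MultiHarmonizedRecord(
            snp_id=snp, gammas=gammas, se_gammas=ses,
            Gamma=float(Gamma), se_Gamma=out.se))
    if dropped:
        logger.info("mv_harmonize: dropped %d SNPs missing in a source or "
                    "unalignable", dropped)
    if len(records) < k + 1:
        raise ValueError(f"only {len(records)} SNPs retained for {k} exposures; "
                         "model unidentifiable")
    return records


def _design(records: list[MultiHarmonizedRecord]
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([r.gammas for r in records])
    y = np.array([r.Gamma for r in records])
    w = np.array([1.0 / r.se_Gamma ** 2 for r in records])
    return X, y, w


def _check_rank(X: np.ndarray) -> None:
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        # name a collinear pair for the error message
        corr = np.corrcoef(X, rowvar=False)
        for i in range(k):
            for jj in range(i + 1, k):
                if abs(corr[i, jj]) > 1 - 1e-10:
                    raise ValueError(
                        f"rank-deficient design: exposures {i} and {jj} collinear")
        raise ValueError("rank-deficient design matrix")


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, dof: int
         ) -> tuple[np.ndarray, np.ndarray, float, float]:
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, q / dof) if dof > 0 else 1.0
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx)) * phi)
    return coef, ses, q, phi


def mvmr_ivw(records: list[MultiHarmonizedRecord]) -> list[MrEstimate]:
    """MV-IVW direct effects: no-intercept WLS with weights 1/se_Gamma^2.

    An exposure whose gamma column is identically zero carries no
    information; it is excluded from the fit and reported as NaN, so the
    remaining exposures' estimates reduce to the lower-dimensional model.
    """
    X, y, w = _design(records)
    J, K = X.shape
    live = [i for i in range(K) if np.any(X[:, i] != 0)]
    if not live:
        raise ValueError("all exposure columns are zero")
    Xl = X[:, live]
    kl = len(live)
    if J <= kl:
        raise ValueError(f"need more SNPs ({J}) than exposures ({kl})")
    _check_rank(Xl)
    coef, ses, q, phi = _wls(Xl, y, w, J - kl)
    q_pval = float(sps.chi2.sf(q, J - kl))
    out = [MrEstimate(method="mvmr_ivw", beta=float("nan"), se=float("nan"),
                      pval=float("nan"), n_snp=J, q_stat=q, q_pval=q_pval,
                      phi=phi)
           for _ in range(K)]
    for pos, i in enumerate(live):
        out[i] = MrEstimate(method="mvmr_ivw", beta=float(coef[pos]),
                            se=float(ses[pos]),
                            pval=_normal_p(coef[pos] / ses[pos]), n_snp=J,
                            q_stat=q, q_pval=q_pval, phi=phi)
    return out


def mvmr_egger(records: list[MultiHarmonizedRecord], orient_on: int = 0
               ) -> tuple[list[MrEstimate], MrEstimate]:
    """MVMR-Egger: intercept-augmented WLS after orienting on one exposure.

    Each record's signs are flipped jointly so the ``orient_on`` exposure's
    gamma is non-negative; the intercept is the directional-pleiotropy
    diagnostic.
    """
    X, y, w = _design(records)
    J, K = X.shape
    if J <= K + 1:
        raise ValueError(f"need more SNPs ({J}) than exposures + 1 ({K + 1})")
    if not 0 <= orient_on < K:
        raise ValueError(f"orient_on index {orient_on} out of range for K={K}")
    flip = np.where(X[:, orient_on] < 0, -1.0, 1.0)
    Xf = X * flip[:, None]
    yf = y * flip
    _check_rank(Xf)
    Xd = np.column_stack([np.ones(J), Xf])
    coef, ses, q, phi = _wls(Xd, yf, w, J - K - 1)
    q_pval = float(sps.chi2.sf(q, J - K - 1))
    slopes = [MrEstimate(method="mvmr_egger", beta=float(coef[i + 1]),
                         se=float(ses[i + 1]),
                         pval=_normal_p(coef[i + 1] / ses[i + 1]), n_snp=J,
                         q_stat=q, q_pval=q_pval, phi=phi)
              for i in range(K)]
    intercept = MrEstimate(method="mvmr_egger_intercept", beta=float(coef[0]),
                           se=float(ses[0]), pval=_normal_p(coef[0] / ses[0]),
                           n_snp=J, q_stat=q, q_pval=q_pval, phi=phi)
    return slopes, intercept


__all__ = ["MultiHarmonizedRecord", "mv_harmonize", "mvmr_ivw", "mvmr_egger"]
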