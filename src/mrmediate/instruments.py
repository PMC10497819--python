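"""Instrument construction: significance filtering, LD clumping, proxy lookup,
allele harmonization, composite-phenotype weighting and instrument strength.

Conventions follow standard two-sample MR practice: genome-wide significance
p < 5e-8, greedy p-ordered clumping at r2 < 0.001 within a 10,000 kb window,
proxies at r2 > 0.8, and a palindromic-SNP ambiguity window of (0.42, 0.58)
on the effect-allele frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .summstats import (EffectWithCi, LdPanel, SnpAssociation, SummaryStats,
                        pairwise_r2)

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

P_THRESHOLD_DEFAULT = 5e-8
R2_CLUMP_DEFAULT = 0.001
WINDOW_KB_DEFAULT = 10_000
PROXY_R2_DEFAULT = 0.8
EAF_WINDOW_DEFAULT = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """Clumped, significant instruments for one exposure with F statistics."""

    exposure_trait: str
    snps: list[SnpAssociation]
    per_snp_f: list[float]
    mean_f: float

    def __len__(self) -> int:
        return len(self.snps)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass
class HarmonizedRecord:
    """One SNP's aligned instrument-exposure / instrument-outcome pair.

    ``gamma`` (SE ``se_gamma``) is the SNP-exposure effect and ``Gamma``
    (SE ``se_Gamma``) the SNP-outcome effect, both expressed per copy of
    ``aligned_effect_allele``.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    aligned_effect_allele: str
    palindromic_flag: bool = False
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if not (self.se_gamma > 0 and self.se_Gamma > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


def _is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT[a] == b


def select_instruments(stats: SummaryStats, panel: LdPanel,
                       p_threshold: float = P_THRESHOLD_DEFAULT,
                       r2_threshold: float = R2_CLUMP_DEFAULT,
                       window_kb: int = WINDOW_KB_DEFAULT) -> InstrumentSet:
    """Greedy p-ordered LD clumping of genome-wide-significant SNPs.

    SNPs passing ``p_threshold`` are sorted by ascending p (snp_id breaks
    ties); a SNP is accepted iff its panel r2 with every already-accepted SNP
    on the same chromosome within ``window_kb`` is below ``r2_threshold``.
    Significant SNPs absent from the panel are dropped with a logged count.
    """
    passing = [r for r in stats.records.values() if r.pval < p_threshold]
    covered = [r for r in passing if r.snp_id in panel]
    if len(covered) < len(passing):
        logger.info("select_instruments(%s): %d significant SNPs not in panel, dropped",
                    stats.trait, len(passing) - len(covered))
    covered.sort(key=lambda r: (r.pval, r.snp_id))

    accepted: list[SnpAssociation] = []
    window = window_kb * 1000
    for cand in covered:
        c_chrom, c_pos = panel.positions[cand.snp_id]
        ok = True
        for kept in accepted:
            k_chrom, k_pos = panel.positions[kept.snp_id]
            if k_chrom != c_chrom or abs(k_pos - c_pos) > window:
                continue
            try:
                r2 = pairwise_r2(panel, cand.snp_id, kept.snp_id)
            except ValueError:
                # monomorphic panel variant: LD unassessable, treat as independent
                r2 = 0.0
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(cand)
    if not accepted:
        raise ValueError(f"no valid instruments for {stats.trait!r} "
                         f"at p < {p_threshold} after clumping")
    per_f = [(s.beta / s.se) ** 2 for s in accepted]
    return InstrumentSet(exposure_trait=stats.trait, snps=accepted,
                         per_snp_f=per_f, mean_f=float(np.mean(per_f)))


@dataclass
class ProxyMatch:
    snp_id: str
    r2: float
    sign: int  # sign of the dosage correlation with the index SNP


def find_proxy(missing: str, candidates: SummaryStats, panel: LdPanel,
               r2_min: float = PROXY_R2_DEFAULT) -> ProxyMatch | None:
    """Best LD proxy for a missing SNP among variants present in ``candidates``.

    Returns the candidate with maximal panel r2 >= ``r2_min``; ties broken by
    smaller genomic distance, then lexicographic snp_id.  ``sign`` records the
    direction of the dosage correlation for effect-allele transfer.
    """
    if missing not in panel:
        raise KeyError(f"index SNP {missing} not in panel")
    m_chrom, m_pos = panel.positions[missing]
    best: tuple[float, int, str] | None = None  # (-r2, distance, snp_id)
    best_match: ProxyMatch | None = None
    for snp_id in candidates.records:
        if snp_id == missing or snp_id not in panel:
            continue
        try:
            r = np.corrcoef(panel.genotypes[missing], panel.genotypes[snp_id])[0, 1]
        except Exception:
            continue
        if not np.isfinite(r):
            continue
        r2 = min(float(r * r), 1.0)
        if r2 < r2_min:
            continue
        c_chrom, c_pos = panel.positions[snp_id]
        dist = abs(c_pos - m_pos) if c_chrom == m_chrom else np.inf
        key = (-round(r2, 12), dist, snp_id)
        if best is None or key < best:
            best = key
            best_match = ProxyMatch(snp_id=snp_id, r2=r2, sign=1 if r >= 0 else -1)
    if best_match is None:
        logger.info("find_proxy: no proxy with r2 >= %.2f for %s", r2_min, missing)
    return best_match


def _align_outcome(exp: SnpAssociation, out: SnpAssociation,
                   eaf_window: tuple[float, float]
                   ) -> tuple[float, bool] | None:
    """Return (sign for the outcome beta, palindromic_flag) or None to drop."""
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if _is_palindromic(e_ea, e_oa):
        # strand is unknowable from the alleles; orient by allele frequency
        lo, hi = eaf_window
        if np.isnan(exp.eaf) or np.isnan(out.eaf):
            return None
        if lo < exp.eaf < hi or lo < out.eaf < hi:
            return None
        same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
        return (1.0 if same_side else -1.0), True

    if (o_ea, o_oa) == (e_ea, e_oa):
        return 1.0, False
    if (o_ea, o_oa) == (e_oa, e_ea):
        return -1.0, False
    # try the strand complement of the outcome record
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return 1.0, False
    if (c_ea, c_oa) == (e_oa, e_ea):
        return -1.0, False
    return None


def harmonize(exposure: InstrumentSet, outcome: SummaryStats,
              eaf_window: tuple[float, float] = EAF_WINDOW_DEFAULT,
              panel: LdPanel | None = None,
              proxy_r2: float = PROXY_R2_DEFAULT) -> list[HarmonizedRecord]:
    """Align instrument and outcome effects to a shared effect allele.

    Swapped alleles negate the outcome beta; strand flips are resolved by
    complementing; palindromic (A/T, C/G) SNPs are oriented by allele
    frequency and dropped when either frequency is missing or inside
    ``eaf_window``.  Instruments missing from the outcome are replaced by the
    best panel proxy (r2 >= ``proxy_r2``) when a panel is supplied; the proxy
    SNP's own effects are used, sign-aligned via the dosage correlation.
    """
    records: list[HarmonizedRecord] = []
    n_dropped_palindromic = 0
    n_dropped_mismatch = 0
    n_missing = 0
    for exp in exposure.snps:
        proxy_of = None
        proxy_sign = 1.0
        out = outcome.records.get(exp.snp_id)
        if out is None and panel is not None and exp.snp_id in panel:
            match = find_proxy(exp.snp_id, outcome, panel, r2_min=proxy_r2)
            if match is not None:
                out = outcome.records[match.snp_id]
                proxy_of = exp.snp_id
                proxy_sign = float(match.sign)
        if out is None:
            n_missing += 1
            continue
        if proxy_of is None:
            aligned = _align_outcome(exp, out, eaf_window)
            if aligned is None:
                if _is_palindromic(exp.effect_allele, exp.other_allele):
                    n_dropped_palindromic += 1
                else:
                    n_dropped_mismatch += 1
                continue
            sign, palindromic = aligned
        else:
            # proxy transfer: orientation carried by the dosage correlation,
            # assuming panel alt alleles match the reported effect alleles
            sign, palindromic = proxy_sign, False
        records.append(HarmonizedRecord(
            snp_id=out.snp_id if proxy_of else exp.snp_id,
            gamma=exp.beta, se_gamma=exp.se,
            Gamma=sign * out.beta, se_Gamma=out.se,
            aligned_effect_allele=exp.effect_allele,
            palindromic_flag=palindromic, proxy_of=proxy_of))
    if n_dropped_palindromic or n_dropped_mismatch or n_missing:
        logger.info("harmonize(%s -> %s): %d palindromic dropped, %d allele "
                    "mismatches dropped, %d missing (no proxy)",
                    exposure.exposure_trait, outcome.trait,
                    n_dropped_palindromic, n_dropped_mismatch, n_missing)
    if not records:
        raise ValueError("harmonization produced an empty instrument set")
    return records


def composite_instrument_weights(component_betas: np.ndarray,
                                 component_ses: np.ndarray,
                                 signs: np.ndarray,
                                 snp_ids: list[str] | None = None
                                 ) -> list[EffectWithCi]:
    """Fixed-effect IVW pooling of component-trait effects per SNP.

    Used to weight instruments of a composite phenotype (e.g., an insulin
    resistance score built from fasting insulin, triglycerides and HDL-C):
    per SNP, each component's standardized beta is orientation-aligned by
    ``signs`` (components that lower the composite enter with inverted sign),
    its absolute value taken, and the components pooled with weights 1/se^2.
    """
    b = np.atleast_2d(np.asarray(component_betas, dtype=float))
    s = np.atleast_2d(np.asarray(component_ses, dtype=float))
    signs = np.asarray(signs, dtype=float)
    if b.shape != s.shape or b.shape[1] != signs.shape[0]:
        raise ValueError("component betas/ses/signs shapes disagree")
    out: list[EffectWithCi] = []
    for i in range(b.shape[0]):
        usable = np.isfinite(b[i]) & np.isfinite(s[i]) & (s[i] > 0)
        if usable.sum() < 2:
            snp = snp_ids[i] if snp_ids else f"row {i}"
            raise ValueError(f"fewer than 2 usable components for SNP {snp}")
        aligned = np.abs(signs[usable] * b[i, usable])
        w = 1.0 / s[i, usable] ** 2
        pooled = float(np.sum(w * aligned) / np.sum(w))
        pooled_se = float(np.sqrt(1.0 / np.sum(w)))
        out.append(EffectWithCi.from_beta_se(pooled, pooled_se))
    return out


def mean_f_statistic(instruments: InstrumentSet) -> float:
    """Mean per-SNP F statistic, F_j = (gamma_j / se_j)^2; warns below 10."""
    if not instruments.snps:
        raise ValueError("empty instrument set")
    mean_f = float(np.mean(instruments.per_snp_f))
    if mean_f < 10:
        warnings.warn(f"weak instruments: mean F = {mean_f:.2f} < 10",
                      UserWarning, stacklevel=2)
    return mean_f


__all__ = [
    "InstrumentSet", "HarmonizedRecord", "ProxyMatch",
    "select_instruments", "find_proxy", "harmonize",
    "composite_instrument_weights", "mean_f_statistic",
]
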