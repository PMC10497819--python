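"""Summary-level GWAS simulator with known causal ground truth.

The generator emulates the two-sample design used throughout the package:
an exposure GWAS in one large cohort, a mediator GWAS and a binary-outcome
GWAS in non-overlapping cohorts, all reported as per-SNP summary statistics.
Everything is simulated directly at the summary level — true per-SNP effects
plus normal sampling noise with the usual GWAS standard error
``se = sqrt(1 / (2 * MAF * (1 - MAF) * n))`` — rather than via
individual-level genotypes; binary-outcome effects are drawn directly on the
log-odds scale with ``n`` interpreted as an effective sample size.

Causal diagram (effects per SD of exposure / mediator, log-odds for the
binary outcome)::

    G_x --gamma*--> exposure --beta1--> mediator --beta2--> outcome
                        \\__________ theta (total) _________/
    G_m --delta--> mediator

``theta`` is the TOTAL exposure->outcome effect, so the implied mediated
fraction is ``pm_true = beta1 * beta2 / theta``.  Mediator-specific
instruments (``n_snps_mediator`` SNPs with effects ``delta`` on the mediator
only, reaching the outcome only through ``beta2``) are generated alongside
the exposure instruments; without them the multivariable regression that
estimates the mediator's direct effect would be collinear in truth, exactly
as a real two-step analysis needs the mediator's own GWAS instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .summstats import LdPanel, SnpAssociation, SummaryStats

# true-effect |z| floor guaranteeing that simulated instruments are recovered
# at genome-wide significance (p < 5e-8 needs |z_obs| > 5.45; with a true z of
# 7.5 the observed z clears that in ~98% of draws)
_Z_FLOOR = 7.5

# non-palindromic allele pairs used by default so harmonization keeps all SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated two-sample dataset.

    Defaults mirror a UK-Biobank-scale exposure (n ~ 450k), a MAGIC-scale
    mediator (n ~ 150k) and a case-control outcome with effective n ~ 200k,
    with a moderate causal chain theta = 0.2, beta1 = 0.4, beta2 = 0.15
    (implied mediated fraction 0.30).
    """

    n_snps: int = 100
    n_snps_mediator: int = 50
    n_exposure: int = 450_000
    n_mediator: int = 150_000
    n_outcome: int = 200_000
    theta: float = 0.2
    beta1_true: float = 0.4
    beta2_true: float = 0.15
    reverse_effect: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float | None = None
    pleiotropy_frac: float = 1.0
    outlier_frac: float = 0.0
    outlier_multiplier: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.25
    h2_mediator: float = 0.25
    swap_allele_frac: float = 0.0
    panel_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if self.n_snps_mediator < 0:
            raise ValueError("n_snps_mediator must be >= 0")
        for name in ("n_exposure", "n_mediator", "n_outcome", "panel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "inside_violating"}:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not (0 <= self.outlier_frac < 1):
            raise ValueError("outlier_frac must be in [0, 1)")

    @property
    def pm_true(self) -> float:
        """Implied mediated fraction beta1*beta2/theta (NaN when theta = 0)."""
        if self.theta == 0:
            return float("nan")
        return self.beta1_true * self.beta2_true / self.theta


@dataclass
class TruthRecord:
    """Ground truth emitted next to every simulated dataset."""

    snp_ids: list[str]
    is_mediator_snp: np.ndarray
    gamma_true: np.ndarray        # true per-SNP effect on the exposure
    mediator_true: np.ndarray     # true per-SNP effect on the mediator
    outcome_true: np.ndarray      # true per-SNP effect on the outcome (log-odds)
    alpha: np.ndarray             # per-SNP direct (pleiotropic) outcome effect
    theta: float
    beta1_true: float
    beta2_true: float
    pm_true: float


@dataclass
class SimulatedArrays:
    """Raw array view of one simulated dataset (fast path for estimator work).

    Index convention: the first ``n_snps`` entries are exposure instruments,
    the remaining ``n_snps_mediator`` are mediator-specific instruments.
    """

    snp_ids: list[str]
    maf: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_med: np.ndarray
    se_med: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    truth: TruthRecord
    n_exposure_snps: int = 0

    @property
    def exposure_slice(self) -> slice:
        return slice(0, self.n_exposure_snps)


def _gwas_se(maf: np.ndarray, n: float) -> np.ndarray:
    return np.sqrt(1.0 / (2.0 * maf * (1.0 - maf) * n))


def _significant_effects(rng: np.random.Generator, k: int, h2: float,
                         se: np.ndarray) -> np.ndarray:
    """Draw true effects N(0, h2/k) then floor |effect| at _Z_FLOOR * se."""
    raw = rng.normal(0.0, math.sqrt(h2 / max(k, 1)), size=k)
    sign = np.where(raw == 0, 1.0, np.sign(raw))
    return sign * np.maximum(np.abs(raw), _Z_FLOOR * se)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.nextafter(0, 1))


def simulate_arrays(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedArrays:
    """Simulate the per-SNP summary statistics of all three samples as arrays."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    j, m = config.n_snps, config.n_snps_mediator
    total = j + m
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=total)

    se_exp = _gwas_se(maf, config.n_exposure)
    se_med = _gwas_se(maf, config.n_mediator)
    se_out = _gwas_se(maf, config.n_outcome)

    # true instrument effects
    gamma_star = _significant_effects(rng, j, config.h2_exposure, se_exp[:j])
    delta = (_significant_effects(rng, m, config.h2_mediator, se_med[j:])
             if m else np.empty(0))

    # direct (pleiotropic) outcome effects on exposure instruments
    alpha = np.zeros(total)
    mode, psd = config.pleiotropy_mode, config.pleiotropy_sd
    if mode == "balanced" and psd > 0:
        alpha[:j] = rng.normal(0.0, psd, size=j)
    elif mode == "directional" and psd > 0:
        # directional relative to the exposure-increasing allele: the shift
        # follows each instrument's orientation, as in oriented GWAS catalogs
        mu = config.pleiotropy_mean if config.pleiotropy_mean is not None else psd
        alpha[:j] = np.sign(gamma_star) * rng.normal(mu, psd, size=j)
    elif mode == "inside_violating" and psd > 0:
        scale = psd / max(np.std(gamma_star), 1e-12)
        alpha[:j] = scale * gamma_star + rng.normal(0.0, psd / 2.0, size=j)
    if config.pleiotropy_frac < 1.0 and mode != "none":
        # pleiotropy confined to a random subset of instruments (the rest valid)
        n_pl = int(round(config.pleiotropy_frac * j))
        valid = rng.choice(j, size=j - n_pl, replace=False)
        alpha[valid] = 0.0
    if config.outlier_frac > 0:
        n_out = int(round(config.outlier_frac * j))
        idx = rng.choice(j, size=n_out, replace=False)
        alpha[idx] *= config.outlier_multiplier

    gamma_true = np.concatenate([gamma_star, config.reverse_effect * delta])
    mediator_true = np.concatenate([config.beta1_true * gamma_star, delta])
    outcome_true = np.concatenate([config.theta * gamma_star,
                                   config.beta2_true * delta]) + alpha

    beta_exp = gamma_true + rng.normal(0.0, se_exp)
    beta_med = mediator_true + rng.normal(0.0, se_med)
    beta_out = outcome_true + rng.normal(0.0, se_out)

    snp_ids = [f"rs{100000 + i}" for i in range(total)]
    truth = TruthRecord(
        snp_ids=snp_ids,
        is_mediator_snp=np.arange(total) >= j,
        gamma_true=gamma_true, mediator_true=mediator_true,
        outcome_true=outcome_true, alpha=alpha,
        theta=config.theta, beta1_true=config.beta1_true,
        beta2_true=config.beta2_true, pm_true=config.pm_true,
    )
    return SimulatedArrays(snp_ids=snp_ids, maf=maf,
                           beta_exp=beta_exp, se_exp=se_exp,
                           beta_med=beta_med, se_med=se_med,
                           beta_out=beta_out, se_out=se_out,
                           truth=truth, n_exposure_snps=j)


def _positions(total: int) -> list[tuple[str, int]]:
    # one SNP per 11 Mb so no two instruments share a clumping window
    out = []
    for i in range(total):
        chrom = str(1 + (i % 22))
        pos = 1_000_000 + (i // 22) * 11_000_000
        out.append((chrom, pos))
    return out


def _stats_from_arrays(trait: str, unit: str, sim: SimulatedArrays,
                       beta: np.ndarray, se: np.ndarray, n: float,
                       alleles: list[tuple[str, str]],
                       swapped: np.ndarray) -> SummaryStats:
    pvals = _pvals(beta, se)
    pos = _positions(len(sim.snp_ids))
    ss = SummaryStats(trait=trait, unit=unit, population="simulated-European")
    for i, snp in enumerate(sim.snp_ids):
        ea, oa = alleles[i]
        b, eaf = beta[i], sim.maf[i]
        if swapped[i]:
            ea, oa, b, eaf = oa, ea, -b, 1 - eaf
        ss.add(SnpAssociation(snp_id=snp, chrom=pos[i][0], pos=pos[i][1],
                              effect_allele=ea, other_allele=oa, eaf=float(eaf),
                              beta=float(b), se=float(se[i]),
                              pval=float(pvals[i]), n=float(n)))
    return ss


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[SummaryStats, SummaryStats, SummaryStats,
                                   LdPanel, TruthRecord]:
    """Simulate (exposure, mediator, outcome) summary stats, LD panel, truth.

    The three samples use independent noise draws (no sample overlap).  The
    panel contains every instrument as an independent variant with dosages
    Binomial(2, MAF).  A configurable fraction of outcome records is emitted
    with swapped alleles and sign-flipped betas to exercise harmonization;
    allele pairs are non-palindromic by construction.
    """
    rng = np.random.default_rng(config.seed)
    sim = simulate_arrays(config, rng)
    total = len(sim.snp_ids)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    no_swap = np.zeros(total, dtype=bool)
    swapped = rng.random(total) < config.swap_allele_frac

    exposure = _stats_from_arrays("exposure", "1-SD", sim, sim.beta_exp,
                                  sim.se_exp, config.n_exposure, alleles, no_swap)
    mediator = _stats_from_arrays("mediator", "1-SD", sim, sim.beta_med,
                                  sim.se_med, config.n_mediator, alleles, no_swap)
    outcome = _stats_from_arrays("outcome", "log-odds", sim, sim.beta_out,
                                 sim.se_out, config.n_outcome, alleles, swapped)

    pos = _positions(total)
    panel = LdPanel(samples=[f"S{i}" for i in range(config.panel_size)])
    for i, snp in enumerate(sim.snp_ids):
        dos = rng.binomial(2, sim.maf[i], size=config.panel_size).astype(float)
        oa, ea = alleles[i][1], alleles[i][0]
        # panel alt allele = the effect allele of the unswapped records
        panel.add_variant(snp, dos, ref=oa, alt=ea, chrom=pos[i][0], pos=pos[i][1])
    return exposure, mediator, outcome, panel, sim.truth


def simulate_ld_block(panel_size: int, n_variants: int, target_r2: float,
                      seed: int = 0, maf: float = 0.3,
                      start_pos: int = 1_000_000, chrom: str = "1") -> LdPanel:
    """Generate a block of variants with controlled LD between neighbours.

    Uses a haplotype copy-with-mutation scheme: each haplotype allele of
    variant i+1 copies variant i's allele with probability sqrt(target_r2)
    and is redrawn Bernoulli(maf) otherwise, giving consecutive-pair r2 near
    the target (within about +-0.1 at panel_size >= 500).  Variants are
    placed 1 kb apart.
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    if not (0 <= target_r2 <= 1):
        raise ValueError("target_r2 must be in [0, 1]")
    if panel_size < 30 and 0 < target_r2 < 1:
        raise ValueError("panel too small to realize intermediate LD targets; "
                         "use panel_size >= 30")
    rng = np.random.default_rng(seed)
    q = math.sqrt(target_r2)
    haps = rng.random((panel_size, 2)) < maf
    panel = LdPanel(samples=[f"S{i}" for i in range(panel_size)])
    for i in range(n_variants):
        if i > 0:
            keep = rng.random((panel_size, 2)) < q
            fresh = rng.random((panel_size, 2)) < maf
            haps = np.where(keep, haps, fresh)
        panel.add_variant(f"blk{i}", haps.sum(axis=1).astype(float),
                          ref="A", alt="G", chrom=chrom, pos=start_pos + 1000 * i)
    return panel


def harmonized_view(sim: SimulatedArrays, target: str = "outcome",
                    subset: str = "exposure"):
    """Pre-harmonized instrument-target records straight from the arrays.

    Because the simulator emits every effect on the same effect allele, the
    harmonization step is the identity here; this is the fast path for
    estimator-calibration work.  ``subset`` picks exposure instruments,
    mediator instruments, or all SNPs; ``target`` picks the outcome or the
    mediator as the second sample.
    """
    from .instruments import HarmonizedRecord

    j = sim.n_exposure_snps
    idx = {"exposure": range(0, j),
           "mediator": range(j, len(sim.snp_ids)),
           "all": range(len(sim.snp_ids))}[subset]
    if target == "outcome":
        tb, ts = sim.beta_out, sim.se_out
    elif target == "mediator":
        tb, ts = sim.beta_med, sim.se_med
    elif target == "exposure":
        tb, ts = sim.beta_exp, sim.se_exp
    else:
        raise ValueError(f"unknown target {target!r}")
    gb = sim.beta_med if subset == "mediator" else sim.beta_exp
    gs = sim.se_med if subset == "mediator" else sim.se_exp
    return [HarmonizedRecord(snp_id=sim.snp_ids[i], gamma=float(gb[i]),
                             se_gamma=float(gs[i]), Gamma=float(tb[i]),
                             se_Gamma=float(ts[i]), aligned_effect_allele="A")
            for i in idx]


def multi_view(sim: SimulatedArrays):
    """All SNPs as two-exposure (exposure, mediator) multivariable records."""
    from .mvmr import MultiHarmonizedRecord

    return [MultiHarmonizedRecord(
        snp_id=sim.snp_ids[i],
        gammas=np.array([sim.beta_exp[i], sim.beta_med[i]]),
        se_gammas=np.array([sim.se_exp[i], sim.se_med[i]]),
        Gamma=float(sim.beta_out[i]), se_Gamma=float(sim.se_out[i]))
        for i in range(len(sim.snp_ids))]


def write_truth(truth: TruthRecord, path) -> None:
    """Write the per-SNP truth as a sidecar TSV (plus global values in header)."""
    import pandas as pd

    df = pd.DataFrame({
        "SNP": truth.snp_ids,
        "IS_MEDIATOR_SNP": truth.is_mediator_snp.astype(int),
        "GAMMA_TRUE": truth.gamma_true,
        "MEDIATOR_TRUE": truth.mediator_true,
        "OUTCOME_TRUE": truth.outcome_true,
        "ALPHA": truth.alpha,
    })
    with open(path, "w") as fh:
        fh.write(f"# theta={truth.theta} beta1={truth.beta1_true} "
                 f"beta2={truth.beta2_true} pm_true={truth.pm_true}\n")
        df.to_csv(fh, sep="\t", index=False)


__all__ = [
    "SimulationConfig", "TruthRecord", "SimulatedArrays",
    "simulate_arrays", "simulate_two_sample", "simulate_ld_block",
    "harmonized_view", "multi_view", "write_truth",
]
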