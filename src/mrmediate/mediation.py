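"""Two-step MR mediation: eligibility screen, mediation proportion with
delta-method CI, reverse-causation check, and Benjamini-Hochberg FDR.

The mediated (indirect) effect of an exposure on an outcome through a
mediator is the product beta1 * beta2, where beta1 is the exposure->mediator
effect (univariable MR) and beta2 the mediator->outcome effect adjusted for
the exposure (multivariable MR).  The mediation proportion is

    PM = beta1 * beta2 / beta0

with beta0 the total exposure->outcome effect (univariable MR).  Its
delta-method variance treats the three estimates as independent (they come
from separate regressions on partly different samples):

    Var(PM) = (b2/b0)^2 Var(b1) + (b1/b0)^2 Var(b2) + (b1 b2 / b0^2)^2 Var(b0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .instruments import harmonize, select_instruments
from .mr import MrEstimate, ivw
from .summstats import EffectWithCi, LdPanel, SummaryStats, Z975


@dataclass
class MediationResult:
    """Mediation proportion and its components for one pathway."""

    exposure: str
    mediator: str
    outcome: str
    beta0: EffectWithCi
    beta1: EffectWithCi
    beta2: EffectWithCi
    indirect: float
    indirect_se: float
    pm: float
    pm_se: float
    pm_ci_low: float
    pm_ci_high: float
    out_of_range: bool = False
    checks: tuple[bool, bool, bool, bool] | None = None
    eligible: bool | None = None


def two_step_mediation(beta0: EffectWithCi, beta1: EffectWithCi,
                       beta2: EffectWithCi, exposure: str = "exposure",
                       mediator: str = "mediator", outcome: str = "outcome"
                       ) -> MediationResult:
    """Mediation proportion PM = beta1*beta2/beta0 with delta-method 95% CI.

    PM values outside [0, 1] are reported as computed with ``out_of_range``
    set, never truncated.
    """
    b0, b1, b2 = beta0.point, beta1.point, beta2.point
    if b0 == 0:
        raise ValueError("total effect beta0 is zero; mediation proportion undefined")
    v0, v1, v2 = beta0.se ** 2, beta1.se ** 2, beta2.se ** 2
    pm = b1 * b2 / b0
    var_pm = ((b2 / b0) ** 2 * v1
              + (b1 / b0) ** 2 * v2
              + (b1 * b2 / b0 ** 2) ** 2 * v0)
    pm_se = math.sqrt(var_pm)
    ind_se = math.sqrt(b2 ** 2 * v1 + b1 ** 2 * v2)
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        beta0=beta0, beta1=beta1, beta2=beta2,
        indirect=b1 * b2, indirect_se=ind_se,
        pm=pm, pm_se=pm_se,
        pm_ci_low=pm - Z975 * pm_se, pm_ci_high=pm + Z975 * pm_se,
        out_of_range=not (0 <= pm <= 1))


def eligibility_screen(beta0: EffectWithCi, beta2_adjusted: EffectWithCi,
                       beta1: EffectWithCi, reverse_beta: EffectWithCi,
                       alpha: float = 0.05
                       ) -> tuple[bool, bool, bool, bool, bool]:
    """Four-step screen a pathway must pass before a mediation proportion
    is reported.

    (1) the exposure is causally associated with the outcome;
    (2) the mediator is associated with the outcome independent of the
        exposure (exposure-adjusted multivariable estimate significant);
    (3) the direct effect (beta0 - beta1*beta2) and the indirect effect
        (beta1*beta2) point the same way;
    (4) the exposure is associated with the mediator but not vice versa
        (reverse estimate non-significant).
    Returns (check1, check2, check3, check4, eligible).
    """
    check1 = beta0.pval < alpha
    check2 = beta2_adjusted.pval < alpha
    indirect = beta1.point * beta2_adjusted.point
    direct = beta0.point - indirect
    check3 = math.copysign(1.0, direct) == math.copysign(1.0, indirect)
    check4 = (beta1.pval < alpha) and (reverse_beta.pval >= alpha)
    eligible = check1 and check2 and check3 and check4
    return check1, check2, check3, check4, eligible


def reverse_mr(mediator_stats: SummaryStats, exposure_stats: SummaryStats,
               panel: LdPanel, p_threshold: float = 5e-8,
               r2_threshold: float = 0.001, window_kb: int = 10_000,
               exclude_shared_instruments: bool = True) -> MrEstimate:
    """Reverse-causation check: full UVMR with the mediator as the exposure.

    Selects the mediator's own instruments, harmonizes them against the
    original exposure's summary statistics, and returns the random-effects
    IVW estimate of the mediator->exposure effect.

    By default, variants that are themselves genome-wide significant for the
    original exposure are excluded from the mediator instrument set: such
    shared instruments act on the exposure directly (a forward path), and
    their reverse Wald ratios would mimic reverse causation even when no
    mediator->exposure path exists.
    """
    if exclude_shared_instruments:
        shared = {snp for snp, rec in exposure_stats.records.items()
                  if rec.pval < p_threshold}
        filtered = SummaryStats(trait=mediator_stats.trait,
                                unit=mediator_stats.unit,
                                population=mediator_stats.population)
        for snp, rec in mediator_stats.records.items():
            if snp not in shared:
                filtered.add(rec)
        mediator_stats = filtered
    inst = select_instruments(mediator_stats, panel, p_threshold=p_threshold,
                              r2_threshold=r2_threshold, window_kb=window_kb)
    records = harmonize(inst, exposure_stats, panel=panel)
    return ivw(records, mode="random")


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values, q_(i) = min_{j>=i} m p_(j) / j."""
    if len(pvals) == 0:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def _format_estimate_row(trait: str, outcome: str, est: MrEstimate) -> dict:
    or_point, lo, hi = est.to_or_ci()
    return {"exposure": trait, "outcome": outcome, "method": est.method,
            "nsnp": est.n_snp, "beta": est.beta, "se": est.se,
            "or": or_point, "or_ci_low": lo, "or_ci_high": hi,
            "pval": est.pval, "q_stat": est.q_stat, "q_pval": est.q_pval}


def assemble_report(uvmr_results: dict[tuple[str, str], dict[str, MrEstimate]],
                    mediation_results: list[MediationResult] | None = None,
                    fdr_families: list[list[tuple[str, str]]] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the forest-style estimate table and the mediation table.

    ``uvmr_results`` maps (exposure, outcome) to a method->estimate dict as
    returned by :func:`mrmediate.mr.run_all_uvmr`.  ``fdr_families`` groups
    (exposure, outcome) pairs whose IVW p-values share one BH correction; a
    ``q`` column is added to the IVW rows of each family.  A pair is marked
    ``significant`` when the IVW estimate and at least one sensitivity
    analysis (weighted median, weighted mode, Egger slope or PRESSO) are both
    significant at 0.05.
    """
    rows = []
    for (exposure, outcome), methods in uvmr_results.items():
        ivw_est = methods.get("ivw_random") or methods.get("ivw_fixed")
        sens_sig = any(
            methods[m].pval < 0.05
            for m in ("weighted_median", "weighted_mode", "egger_slope",
                      "presso_corrected", "presso_raw")
            if m in methods and np.isfinite(methods[m].pval))
        for name, est in methods.items():
            row = _format_estimate_row(exposure, outcome, est)
            row["significant"] = bool(
                ivw_est is not None and ivw_est.pval < 0.05 and sens_sig
            ) if name.startswith("ivw") else None
            rows.append(row)
    forest = pd.DataFrame(rows)

    if not forest.empty and fdr_families:
        forest["q"] = np.nan
        for family in fdr_families:
            mask = (forest["method"] == "ivw_random") & forest.apply(
                lambda r: (r["exposure"], r["outcome"]) in set(family), axis=1)
            if mask.any():
                forest.loc[mask, "q"] = bh_fdr(forest.loc[mask, "pval"].tolist())

    med_cols = ["exposure", "mediator", "outcome", "beta0", "beta1", "beta2",
                "indirect", "pm", "pm_se", "pm_ci_low", "pm_ci_high",
                "out_of_range", "check1", "check2", "check3", "check4",
                "eligible"]
    med_rows = []
    for m in (mediation_results or []):
        checks = m.checks or (None, None, None, None)
        med_rows.append({
            "exposure": m.exposure, "mediator": m.mediator, "outcome": m.outcome,
            "beta0": m.beta0.point, "beta1": m.beta1.point, "beta2": m.beta2.point,
            "indirect": m.indirect, "pm": m.pm, "pm_se": m.pm_se,
            "pm_ci_low": m.pm_ci_low, "pm_ci_high": m.pm_ci_high,
            "out_of_range": m.out_of_range,
            "check1": checks[0], "check2": checks[1],
            "check3": checks[2], "check4": checks[3],
            "eligible": m.eligible})
    mediation_table = pd.DataFrame(med_rows, columns=med_cols)
    return forest, mediation_table


__all__ = [
    "MediationResult", "two_step_mediation", "eligibility_screen",
    "reverse_mr", "bh_fdr", "assemble_report",
]
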