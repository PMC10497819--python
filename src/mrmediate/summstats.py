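"""GWAS summary-statistic containers, readers/writers, and effect-size utilities.

The canonical on-disk format is a UTF-8 tab-separated table with header
columns ``SNP CHR BP EA OA EAF BETA SE P N``.  ``column_map`` lets callers
ingest tables with arbitrary source headers.  Betas for continuous traits are
in SD units; betas for binary traits are log-odds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: two-sided 97.5% normal quantile used for every 95% CI in the package
Z975 = 1.959964

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]


@dataclass
class SnpAssociation:
    """One SNP's summary association with one phenotype.

    ``beta`` is the per-effect-allele estimate on the trait's analysis scale
    (SD units for continuous traits, log-odds for binary ones).  ``eaf`` is
    the effect-allele frequency and may be missing (NaN).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]")
        if not math.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position")


@dataclass
class SummaryStats:
    """A full set of per-SNP associations for one trait (one GWAS)."""

    trait: str
    unit: str = ""
    population: str = ""
    records: dict[str, SnpAssociation] = field(default_factory=dict)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: SnpAssociation) -> None:
        if rec.snp_id in self.records:
            raise ValueError(f"duplicate snp_id {rec.snp_id} in {self.trait}")
        self.records[rec.snp_id] = rec

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
             r.eaf, r.beta, r.se, r.pval, r.n)
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


@dataclass
class LdPanel:
    """Reference genotypes used for LD computations (clumping, proxies).

    Dosages are alt-allele counts in {0, 1, 2}, one vector per variant, all
    of identical length (the number of panel samples).
    """

    samples: list[str]
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.genotypes

    def __len__(self) -> int:
        return len(self.genotypes)

    def add_variant(self, snp_id: str, dosages: np.ndarray,
                    ref: str = "A", alt: str = "G",
                    chrom: str = "1", pos: int = 0) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(self.samples),):
            raise ValueError(
                f"{snp_id}: dosage vector length {dosages.shape} != {len(self.samples)} samples")
        self.genotypes[snp_id] = dosages
        self.alleles[snp_id] = (ref, alt)
        self.positions[snp_id] = (str(chrom), int(pos))


@dataclass
class EffectWithCi:
    """Point estimate with SE, 95% CI and two-sided normal p-value."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @classmethod
    def from_beta_se(cls, beta: float, se: float) -> "EffectWithCi":
        if not se > 0:
            raise ValueError("se must be positive")
        z = beta / se
        return cls(point=beta, se=se,
                   ci_low=beta - Z975 * se, ci_high=beta + Z975 * se,
                   pval=float(2 * sps.norm.sf(abs(z))) or np.nextafter(0, 1))

    def to_or_ci(self) -> tuple[float, float, float]:
        """Exponentiate a log-odds effect into (OR, ci_low, ci_high)."""
        return math.exp(self.point), math.exp(self.ci_low), math.exp(self.ci_high)


def or_ci_to_beta_se(or_point: float, ci_low: float, ci_high: float) -> EffectWithCi:
    """Invert the reporting transform: OR (95% CI) back to log-odds beta/SE.

    The SE is recovered from the CI width on the log scale,
    ``se = (ln hi - ln lo) / (2 * 1.959964)``, and the p-value is the
    two-sided normal tail of beta/se.
    """
    if not (0 < ci_low < or_point < ci_high):
        raise ValueError("require 0 < ci_low < or_point < ci_high")
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z975)
    return EffectWithCi(point=beta, se=se,
                        ci_low=math.log(ci_low), ci_high=math.log(ci_high),
                        pval=float(2 * sps.norm.sf(abs(beta / se))))


# ---------------------------------------------------------------------------
# readers / writers

def _coerce_row(row: pd.Series) -> SnpAssociation:
    eaf = row.get("EAF", np.nan)
    rec = SnpAssociation(
        snp_id=str(row["SNP"]),
        chrom=str(row.get("CHR", "0")),
        pos=int(row.get("BP", 0) or 0),
        effect_allele=str(row["EA"]).upper(),
        other_allele=str(row["OA"]).upper(),
        eaf=float(eaf) if pd.notna(eaf) else float("nan"),
        beta=float(row["BETA"]),
        se=float(row["SE"]),
        pval=float(row["P"]),
        n=float(row.get("N", np.nan)),
    )
    rec.validate()
    return rec


def read_summary_stats(path, column_map: dict[str, str] | None = None,
                       trait: str = "", unit: str = "", population: str = "",
                       sep: str = "\t") -> SummaryStats:
    """Read a delimited summary-statistics table into a validated SummaryStats.

    ``column_map`` maps source header names to canonical field names
    (SNP, CHR, BP, EA, OA, EAF, BETA, SE, P, N).  Rows failing the per-record
    invariants (non-positive SE, p outside (0,1], bad alleles, ...) are
    dropped with a logged count; a missing mandatory column is a hard error.
    """
    df = pd.read_csv(path, sep=sep, dtype={"SNP": str},
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    ss = SummaryStats(trait=trait or str(path), unit=unit, population=population)
    dropped = 0
    for _, row in df.iterrows():
        try:
            ss.add(_coerce_row(row))
        except (ValueError, TypeError):
            dropped += 1
    if dropped:
        logger.info("read_summary_stats(%s): dropped %d invalid rows", path, dropped)
    return ss


def write_summary_stats(ss: SummaryStats, path) -> None:
    """Write the canonical TSV (schema SNP CHR BP EA OA EAF BETA SE P N).

    Floats are written with repr so that a read-back is bit-exact.
    """
    ss.to_dataframe().to_csv(path, sep="\t", index=False,
                             float_format=lambda v: repr(float(v)))


def read_ld_panel(path) -> LdPanel:
    """Load a VCF into an LdPanel of alt-allele dosages.

    Only biallelic SNVs are kept; multiallelic or indel records are skipped
    with a logged count.  Missing genotypes count as zero alt alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    panel = LdPanel(samples=list(vcf.samples))
    skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if v.REF not in VALID_ALLELES or alts[0] not in VALID_ALLELES:
            skipped += 1
            continue
        gts = np.asarray(v.genotypes, dtype=int)[:, :2]
        dosages = (gts == 1).sum(axis=1).astype(float)
        snp_id = v.ID or f"{v.CHROM}:{v.POS}"
        panel.add_variant(snp_id, dosages, ref=v.REF, alt=alts[0],
                          chrom=v.CHROM, pos=v.POS)
    if skipped:
        logger.info("read_ld_panel(%s): skipped %d non-biallelic/non-SNV records",
                    path, skipped)
    return panel


def write_ld_panel(panel: LdPanel, path) -> None:
    """Write the panel as a minimal VCF 4.2 with GT-only genotype fields."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    order = sorted(panel.genotypes,
                   key=lambda s: (panel.positions[s][0], panel.positions[s][1], s))
    contigs = sorted({panel.positions[s][0] for s in order})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for snp_id in order:
            chrom, pos = panel.positions[snp_id]
            ref, alt = panel.alleles[snp_id]
            gts = "\t".join(gt_codes[int(d)] for d in panel.genotypes[snp_id])
            fh.write(f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def pairwise_r2(panel: LdPanel, a: str, b: str) -> float:
    """Squared Pearson correlation of two variants' dosage vectors."""
    for snp in (a, b):
        if snp not in panel:
            raise KeyError(f"variant {snp} not in panel")
    # canonical argument order so the result is bit-identical under swaps
    first, second = (a, b) if a <= b else (b, a)
    x, y = panel.genotypes[first], panel.genotypes[second]
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("monomorphic variant: r2 undefined for zero-variance dosages")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


__all__ = [
    "SnpAssociation", "SummaryStats", "LdPanel", "EffectWithCi",
    "read_summary_stats", "write_summary_stats", "read_ld_panel",
    "write_ld_panel", "pairwise_r2", "or_ci_to_beta_se", "Z975",
]
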