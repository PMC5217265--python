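"""Individual-genotyping validation of candidate SNPs.

Candidates that survive the pooled scan are re-tested on individual
genotypes with an allelic 2x2 Fisher exact test (each individual contributes
two alleles), odds ratios with Woolf (normal-approximation) 95% confidence
intervals, and a two-tier significance classification:

* ``corrected``  -- Fisher p below the Bonferroni-corrected family threshold
  0.05 / n_tests;
* ``suggestive`` -- nominal p < 0.05 together with an effect size of
  OR >= 1.2 or OR <= 0.83;
* ``not_validated`` otherwise.

A candidate counts as *validated* only if, in addition, its direction of
effect agrees with the pooled-scan frequency shift after allele-orientation
harmonisation.  Cross-disease bookkeeping (unique / shared loci, shared
direction) operates on the validated records of two diseases.

Conventions: the minor allele is defined in controls and the reported OR and
MAF refer to it.  The OR boundary of the suggestive tier is inclusive
because printed validated effect sizes sit exactly on 0.83; ``strict_or``
restores strict inequalities.  Zero cells receive the Haldane-Anscombe +0.5
correction for the OR/CI only -- never for the exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allelotyping import ScanResult
from .simulate import GenotypeTable

__all__ = [
    "ContingencyTable",
    "ValidationRecord",
    "SharedLociSummary",
    "allele_table",
    "fisher_exact_test",
    "odds_ratio_ci",
    "bonferroni_threshold",
    "expected_false_positives",
    "classify_validation",
    "direction_concordance",
    "validate_candidates",
    "shared_loci",
    "summarize_known_panel",
]

TIERS = ("corrected", "suggestive", "not_validated")


@dataclass(frozen=True)
class ContingencyTable:
    """Allele-count 2x2 table: rows cases/controls, columns minor/major."""

    a: int  # minor alleles, cases
    b: int  # major alleles, cases
    c: int  # minor alleles, controls
    d: int  # major alleles, controls

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def is_monomorphic(self) -> bool:
        return (self.a + self.c == 0) or (self.b + self.d == 0)

    def swapped_groups(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)

    def swapped_alleles(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclass
class ValidationRecord:
    snp_id: str
    disease: str
    table: ContingencyTable
    fisher_p: float
    or_point: float
    ci_low: float
    ci_high: float
    maf_controls: float
    tier: str
    direction_concordant_with_gwas: bool | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def validated(self) -> bool:
        """Associated tier plus (when known) GWAS direction concordance."""
        if self.tier == "not_validated":
            return False
        if self.direction_concordant_with_gwas is False:
            return False
        return True


@dataclass
class SharedLociSummary:
    unique_disease1: set[str]
    unique_disease2: set[str]
    shared: set[str]
    shared_same_direction: set[str]


def allele_table(
    genotypes: GenotypeTable,
    snp_id: str,
    case_group: str,
    control_group: str,
) -> ContingencyTable:
    """Allele counts for one SNP; missing genotypes (-1) are excluded from
    both margins.  Counts refer to allele_a (the dosage allele)."""
    try:
        j = genotypes.snp_ids.index(snp_id)
    except ValueError:
        raise KeyError(f"SNP {snp_id!r} not in the genotype table") from None
    col = genotypes.genotypes[:, j]
    counts = {}
    for group in (case_group, control_group):
        rows = genotypes.group_indices(group)
        if len(rows) == 0:
            raise ValueError(f"no individuals in group {group!r}")
        dos = col[rows]
        dos = dos[dos >= 0]
        if len(dos) == 0:
            raise ValueError(f"all genotypes missing in group {group!r}")
        minor = int(dos.sum())
        counts[group] = (minor, 2 * len(dos) - minor)
    a, b = counts[case_group]
    c, d = counts[control_group]
    return ContingencyTable(a, b, c, d)


def fisher_exact_test(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    Computed in exact integer arithmetic (probabilities compared via their
    integer numerators over the common denominator), so there is no floating
    tie-breaking.  Degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = comb(r1, a) * comb(r2, c)
    total = comb(n, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            acc += w
    return min(1.0, acc / total)


def odds_ratio_ci(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, float, float]:
    """Allelic odds ratio with Woolf (normal-approximation) CI.

    OR = (a*d)/(b*c); CI = exp(log OR +- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell triggers the Haldane-Anscombe +0.5 correction (all four
    cells) for the OR and CI.  A table with an all-zero row or column has no
    defined OR and returns NaNs.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or table.is_monomorphic:
        return (math.nan, math.nan, math.nan)
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log(or_point)
    return (or_point, math.exp(log_or - z * se), math.exp(log_or + z * se))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling family-wise error."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def expected_false_positives(n_tests: int, alpha: float = 0.05) -> float:
    """Expected false positives among n independent null tests: n * alpha."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    return n_tests * alpha


def classify_validation(
    fisher_p: float,
    or_point: float,
    n_tests: int,
    *,
    strict_or: bool = False,
    alpha: float = 0.05,
    or_risk: float = 1.2,
    or_protective: float = 0.83,
) -> str:
    """Two-tier significance classification of a validation record."""
    if fisher_p < bonferroni_threshold(n_tests, alpha):
        return "corrected"
    if fisher_p < alpha and not math.isnan(or_point):
        if strict_or:
            big = or_point > or_risk or or_point < or_protective
        else:
            big = or_point >= or_risk or or_point <= or_protective
        if big:
            return "suggestive"
    return "not_validated"


def direction_concordance(
    scan: ScanResult,
    record: ValidationRecord,
    *,
    same_allele: bool | None = None,
) -> bool | None:
    """Whether the pooled-scan frequency shift and the validation OR point
    the same way.

    ``same_allele`` states whether the RAS-measured allele and the OR's
    minor allele are the same physical allele; None (unknown orientation)
    yields None, never a silent assumption.  A zero effect on either side
    also yields None.
    """
    if same_allele is None:
        return None
    if scan.direction == 0:
        return None
    if math.isnan(record.or_point) or record.or_point == 1.0:
        return None
    agree = (scan.direction > 0) == (record.or_point > 1.0)
    return agree if same_allele else not agree


def validate_candidates(
    genotypes: GenotypeTable,
    snp_ids: Iterable[str],
    disease: str,
    case_group: str,
    control_group: str,
    n_tests: int,
    *,
    scans: dict[str, ScanResult] | None = None,
    same_allele: bool = True,
    strict_or: bool = False,
) -> list[ValidationRecord]:
    """Run the full validation stage for a list of candidate SNPs.

    ``n_tests`` is the per-disease Bonferroni denominator and is always
    passed explicitly.  The reported OR/MAF follow the control-defined minor
    allele: when the dosage allele exceeds 0.5 in controls the table is
    allele-flipped first (and the scan orientation flipped accordingly).
    """
    records: list[ValidationRecord] = []
    for sid in snp_ids:
        tab = allele_table(genotypes, sid, case_group, control_group)
        flipped = False
        n_ctrl_alleles = tab.c + tab.d
        if n_ctrl_alleles > 0 and tab.c / n_ctrl_alleles > 0.5:
            tab = tab.swapped_alleles()
            flipped = True
        p = fisher_exact_test(tab)
        or_point, lo, hi = odds_ratio_ci(tab)
        maf = tab.c / (tab.c + tab.d)
        tier = classify_validation(p, or_point, n_tests, strict_or=strict_or)
        rec = ValidationRecord(
            snp_id=sid,
            disease=disease,
            table=tab,
            fisher_p=p,
            or_point=or_point,
            ci_low=lo,
            ci_high=hi,
            maf_controls=maf,
            tier=tier,
        )
        if scans is not None and sid in scans:
            rec.direction_concordant_with_gwas = direction_concordance(
                scans[sid], rec, same_allele=(same_allele != flipped)
            )
        records.append(rec)
    return records


def shared_loci(
    recs1: Sequence[ValidationRecord], recs2: Sequence[ValidationRecord]
) -> SharedLociSummary:
    """Unique / shared validated SNPs of two diseases.

    A SNP counts for a disease when its tier is corrected or suggestive;
    shared SNPs additionally split by whether both ORs sit on the same side
    of 1.
    """
    def hits(recs: Sequence[ValidationRecord]) -> dict[str, ValidationRecord]:
        return {r.snp_id: r for r in recs if r.tier in ("corrected", "suggestive")}

    h1, h2 = hits(recs1), hits(recs2)
    shared = set(h1) & set(h2)
    same_dir = {
        sid
        for sid in shared
        if not math.isnan(h1[sid].or_point)
        and not math.isnan(h2[sid].or_point)
        and (h1[sid].or_point > 1.0) == (h2[sid].or_point > 1.0)
        and h1[sid].or_point != 1.0
        and h2[sid].or_point != 1.0
    }
    return SharedLociSummary(
        unique_disease1=set(h1) - shared,
        unique_disease2=set(h2) - shared,
        shared=shared,
        shared_same_direction=same_dir,
    )


def summarize_known_panel(
    recs: Sequence[ValidationRecord], panel: Sequence[str]
) -> pd.DataFrame:
    """Replication status of a panel of previously reported SNPs.

    One row per panel SNP, one status column per disease present in the
    records ('not_tested' when the SNP was not genotyped for that disease).
    """
    diseases: list[str] = []
    for r in recs:
        if r.disease not in diseases:
            diseases.append(r.disease)
    by_key = {(r.disease, r.snp_id): r for r in recs}
    rows = []
    for sid in panel:
        row: dict[str, object] = {"snp_id": sid}
        for dis in diseases:
            rec = by_key.get((dis, sid))
            row[f"status_{dis}"] = rec.tier if rec is not None else "not_tested"
        rows.append(row)
    cols = ["snp_id"] + [f"status_{d}" for d in diseases]
    return pd.DataFrame(rows, columns=cols)
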