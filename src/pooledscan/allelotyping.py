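"""Pooled-array allelotyping: RAS computation, PCA pool QC, Welch t-scan.

The relative allele signal RAS = A/(A+B) of the two allele channels
approximates the pool's allele frequency.  Per SNP, case pools are compared
with control pools by a two-sided Welch t-test (Welch-Satterthwaite degrees
of freedom) and p-values are Bonferroni-corrected over the tested SNPs.

Pool quality control replaces the by-eye inspection of principal components
used with real arrays by a reproducible surrogate: pools whose Euclidean
distance from the coordinate-wise median in the first ``n_components`` PC
coordinates is a robust-z outlier (distance scaled by the median absolute
deviation, default threshold 3.5) are removed.  QC runs separately per pool
set because the sets are separate hybridisations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import IntensityTable, SnpDef

__all__ = [
    "RasMatrix",
    "QcReport",
    "ScanResult",
    "compute_ras",
    "qc_pools",
    "welch_scan",
    "bonferroni_adjust",
    "export_manhattan",
]

MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality


@dataclass
class RasMatrix:
    """Pools x SNPs matrix of relative allele signals in [0, 1].

    Entries where both channels were zero are missing: NaN in ``values`` and
    True in ``missing``; they are excluded from downstream tests.
    """

    pools: list[tuple[str, str, str]]  # (pool_id, group, set_id)
    values: np.ndarray
    missing: np.ndarray
    snp_index: list[SnpDef]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.pools), len(self.snp_index))
        if self.values.shape != shape or self.missing.shape != shape:
            raise ValueError("RAS matrix shape does not match labels")
        ids = [p[0] for p in self.pools]
        if len(set(ids)) != len(ids):
            raise ValueError("pool_id values must be unique")

    @property
    def pool_ids(self) -> list[str]:
        return [p[0] for p in self.pools]

    def set_ids(self) -> list[str]:
        seen: list[str] = []
        for _, _, s in self.pools:
            if s not in seen:
                seen.append(s)
        return seen

    def subset_set(self, set_id: str) -> "RasMatrix":
        rows = [i for i, (_, _, s) in enumerate(self.pools) if s == set_id]
        if not rows:
            raise ValueError(f"no pools with set_id {set_id!r}")
        return RasMatrix(
            pools=[self.pools[i] for i in rows],
            values=self.values[rows],
            missing=self.missing[rows],
            snp_index=self.snp_index,
        )

    def drop_pools(self, pool_ids: Iterable[str]) -> "RasMatrix":
        drop = set(pool_ids)
        rows = [i for i, (pid, _, _) in enumerate(self.pools) if pid not in drop]
        return RasMatrix(
            pools=[self.pools[i] for i in rows],
            values=self.values[rows],
            missing=self.missing[rows],
            snp_index=self.snp_index,
        )

    def missing_per_snp(self) -> np.ndarray:
        return self.missing.sum(axis=0)


@dataclass
class QcReport:
    retained_pools: list[str]
    removed_pools: list[tuple[str, str, float]]  # (pool_id, reason, robust z)
    pc_coordinates: dict[str, np.ndarray]  # set_id -> (n_pools_in_set, k)
    threshold_used: float
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ScanResult:
    """Per-SNP pooled association record.

    ``direction`` is the sign of (mean case RAS - mean control RAS); skipped
    SNPs (untestable or zero variance in both groups with equal means) carry
    p_value = 1 and remain in the output -- no probe filtering.
    """

    snp_id: str
    set_id: str
    mean_ras_case: float
    mean_ras_control: float
    t_stat: float
    df: float
    p_value: float
    p_bonferroni: float
    direction: int
    n_case_pools: int
    n_control_pools: int
    skipped: bool = False


def compute_ras(intensities: IntensityTable) -> RasMatrix:
    """RAS = A / (A + B) entrywise; zero-total entries are flagged missing."""
    a = np.asarray(intensities.channel_a, dtype=float)
    b = np.asarray(intensities.channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel matrices must have the same shape")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("channel intensities must be non-negative")
    total = a + b
    missing = total == 0
    values = np.divide(a, np.where(missing, 1.0, total))
    values[missing] = np.nan
    return RasMatrix(
        pools=list(intensities.pools),
        values=values,
        missing=missing,
        snp_index=list(intensities.snp_panel),
    )


def _robust_distance_z(scores: np.ndarray) -> np.ndarray:
    """Robust z of each row's distance from the coordinate-wise median."""
    med = np.median(scores, axis=0)
    d = np.sqrt(((scores - med) ** 2).sum(axis=1))
    center = np.median(d)
    mad = np.median(np.abs(d - center))
    scale = MAD_SCALE * mad
    if scale == 0:
        return np.zeros_like(d)
    return (d - center) / scale


def qc_pools(
    ras: RasMatrix,
    n_components: int = 4,
    *,
    threshold: float = 3.5,
    restrict_groups: Sequence[str] | None = None,
) -> QcReport:
    """PCA-based outlier QC, run separately per pool set.

    A pool is removed when its robust distance z-score in the first
    ``n_components`` PC coordinates exceeds ``threshold``.  When
    ``restrict_groups`` is given only pools of those groups may be removed
    (e.g. a controls-only removal policy).
    """
    if len(ras.pools) < 3:
        raise ValueError("QC requires at least 3 pools")
    retained: list[str] = []
    removed: list[tuple[str, str, float]] = []
    coords: dict[str, np.ndarray] = {}
    warnings: list[str] = []
    for set_id in ras.set_ids():
        sub = ras.subset_set(set_id)
        ids = sub.pool_ids
        if len(ids) < n_components + 1:
            warnings.append(
                f"set {set_id!r}: only {len(ids)} pools, fewer than "
                f"n_components + 1 = {n_components + 1}; QC skipped"
            )
            retained.extend(ids)
            continue
        x = sub.values.copy()
        # impute missing entries at the SNP mean so they are QC-neutral
        col_mean = np.nanmean(np.where(sub.missing, np.nan, x), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
        x = np.where(sub.missing, col_mean[None, :], x)
        x = x - x.mean(axis=0, keepdims=True)
        k = min(n_components, len(ids) - 1, x.shape[1])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        scores = u[:, :k] * s[:k]
        coords[set_id] = scores
        z = _robust_distance_z(scores)
        for i, pid in enumerate(ids):
            group = sub.pools[i][1]
            removable = restrict_groups is None or group in restrict_groups
            if removable and z[i] > threshold:
                removed.append((pid, f"robust PC distance z > {threshold}", float(z[i])))
            else:
                retained.append(pid)
    return QcReport(
        retained_pools=retained,
        removed_pools=removed,
        pc_coordinates=coords,
        threshold_used=threshold,
        warnings=warnings,
    )


def welch_scan(
    ras: RasMatrix, case_group: str, control_group: str
) -> list[ScanResult]:
    """Two-sided Welch t-test on RAS, case pools vs control pools, per SNP.

    The matrix must contain a single pool set (subset first); every SNP
    appears in the output, with untestable SNPs skip-flagged at p = 1.
    """
    sets = ras.set_ids()
    if len(sets) != 1:
        raise ValueError(
            "welch_scan expects a single pool set; use RasMatrix.subset_set"
        )
    set_id = sets[0]
    groups = {g for _, g, _ in ras.pools}
    for g in (case_group, control_group):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}")
    rows1 = [i for i, (_, g, _) in enumerate(ras.pools) if g == case_group]
    rows2 = [i for i, (_, g, _) in enumerate(ras.pools) if g == control_group]
    x1 = np.where(ras.missing[rows1], np.nan, ras.values[rows1])
    x2 = np.where(ras.missing[rows2], np.nan, ras.values[rows2])

    n1 = (~np.isnan(x1)).sum(axis=0)
    n2 = (~np.isnan(x2)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=0)
        m2 = np.nanmean(x2, axis=0)
        v1 = _nanvar(x1, n1)
        v2 = _nanvar(x2, n2)
        se2 = v1 / n1 + v2 / n2
        diff = m1 - m2
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
            + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)

    testable = (n1 >= 2) & (n2 >= 2)
    zero_se = testable & (se2 == 0)
    flat = zero_se & (diff == 0)
    skip = ~testable | flat
    # zero pooled variance with unequal means: an exact separation
    sep = zero_se & (diff != 0)

    results: list[ScanResult] = []
    for j, snp in enumerate(ras.snp_index):
        if skip[j]:
            t_j, df_j, p_j = 0.0, 0.0, 1.0
        elif sep[j]:
            t_j = math.inf if diff[j] > 0 else -math.inf
            df_j, p_j = float(n1[j] + n2[j] - 2), 0.0
        else:
            t_j, df_j, p_j = float(t[j]), float(df[j]), float(p[j])
        d = 0
        if not skip[j] and not math.isnan(diff[j]) and diff[j] != 0:
            d = 1 if diff[j] > 0 else -1
        results.append(
            ScanResult(
                snp_id=snp.snp_id,
                set_id=set_id,
                mean_ras_case=float(m1[j]) if n1[j] else math.nan,
                mean_ras_control=float(m2[j]) if n2[j] else math.nan,
                t_stat=t_j,
                df=df_j,
                p_value=p_j,
                p_bonferroni=math.nan,
                direction=d,
                n_case_pools=int(n1[j]),
                n_control_pools=int(n2[j]),
                skipped=bool(skip[j]),
            )
        )
    return results


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Column sample variance (ddof=1) ignoring NaN; 0 where n < 2."""
    out = np.zeros(x.shape[1], dtype=float)
    ok = n >= 2
    if ok.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.nanvar(x[:, ok], axis=0, ddof=1)
        out[ok] = v
    return out


def bonferroni_adjust(results: Sequence[ScanResult]) -> list[ScanResult]:
    """p_bonferroni = min(1, m*p) with m = number of non-skipped SNPs."""
    m = sum(1 for r in results if not r.skipped)
    return [
        replace(r, p_bonferroni=1.0 if r.skipped else min(1.0, m * r.p_value))
        for r in results
    ]


def _chrom_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def export_manhattan(
    results: Sequence[ScanResult], snp_index: Sequence[SnpDef]
) -> pd.DataFrame:
    """Manhattan-plot table: chrom, pos, snp_id, p, -log10(p), sorted by
    genomic position."""
    pos = {s.snp_id: (s.chrom, s.pos) for s in snp_index}
    rows = []
    for r in results:
        chrom, bp = pos[r.snp_id]
        rows.append(
            {
                "chrom": chrom,
                "pos": bp,
                "snp_id": r.snp_id,
                "p_value": r.p_value,
                "neg_log10_p": -math.log10(r.p_value) if r.p_value > 0 else math.inf,
            }
        )
    df = pd.DataFrame(rows)
    df["_ck"] = df["chrom"].map(_chrom_key)
    df = df.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    return df.reset_index(drop=True)
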