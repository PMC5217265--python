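"""Synthetic case/control cohorts for pooled-DNA association scans.

This module is the data stand-in for a two-stage pooled-DNA GWAS: it draws
individual genotypes with haplotype-block linkage disequilibrium (LD) and
seeded risk loci, assembles equimolar DNA pools per diagnosis group in one or
more pool sets of configurable size, and emits noisy two-channel array
intensities from which the relative allele signal (RAS) is recovered
downstream.

Model summary
-------------
Genotypes are sums of two independent haplotypes.  The panel is partitioned
into consecutive blocks of ``ld_block_length`` SNPs (blocks never span
chromosomes).  Within a block each haplotype draws one shared uniform ``u``;
a SNP with minor-allele frequency ``p`` copies the block tag ``1{u < p}``
with probability ``ld_r`` and otherwise draws an independent Bernoulli(p).
Marginal allele frequencies are therefore exact while SNPs within a block are
positively correlated (allelic correlation ~ ``ld_r**2`` for equal MAFs).

A risk locus with per-allele odds ratio ``OR`` shifts the case minor-allele
frequency to ``p' = OR*p / (1 - p + OR*p)`` (multiplicative allelic model).
Case haplotypes draw the risk allele at ``p'`` and the block tag uniform is
drawn *conditionally* on it, so SNPs in LD with the locus inherit the
frequency shift attenuated by the copy probability -- the behaviour the
block-based candidate-selection algorithm relies on.

Pooled intensities: for each pool the true pooled minor-allele fraction
``f = sum(dosages) / (2 * pool_size)`` is perturbed by additive Gaussian
noise truncated to [0, 1] and split into two channels ``A = f_noisy * S``
and ``B = (1 - f_noisy) * S``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SnpDef",
    "EffectLocus",
    "PoolSetSpec",
    "SimulationSpec",
    "GenotypeTable",
    "Pool",
    "PoolAssignment",
    "IntensityTable",
    "shifted_maf",
    "make_snp_panel",
    "two_set_design",
    "simulate_cohort",
    "assign_pools",
    "simulate_intensities",
]


@dataclass(frozen=True)
class SnpDef:
    """A SNP on the panel: position and the measured (minor) allele.

    ``allele_a`` is the allele tracked by both the dosage matrix and the
    array A channel; ``maf`` is its frequency in the control population.
    Positions are 1-based base pairs.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class EffectLocus:
    """A seeded risk locus: per-minor-allele odds ratio under the
    multiplicative allelic model."""

    snp_id: str
    odds_ratio: float
    disease: str = "CASE"

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError(f"{self.snp_id}: odds_ratio must be > 0")


@dataclass(frozen=True)
class PoolSetSpec:
    """One pool set: how many pools of how many individuals per group.

    ``pool_sizes`` optionally overrides ``pool_size`` per group (real designs
    sometimes vary pool size between diagnosis groups within a set).
    """

    set_id: str
    pool_size: int
    pools_per_group: Mapping[str, int]
    pool_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.pool_sizes is not None:
            for g, s in self.pool_sizes.items():
                if s < 2:
                    raise ValueError(f"pool size for group {g!r} must be >= 2")

    def size_for(self, group: str) -> int:
        if self.pool_sizes and group in self.pool_sizes:
            return self.pool_sizes[group]
        return self.pool_size


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic pooled-GWAS study.

    The seed fully determines every output (genotypes, pool membership,
    intensity noise).
    """

    n_cases: int
    n_controls: int
    snp_panel: tuple[SnpDef, ...]
    ld_block_length: int
    ld_r: float
    effect_loci: tuple[EffectLocus, ...] = ()
    pool_sets: tuple[PoolSetSpec, ...] = ()
    noise_sd: float = 0.02
    seed: int = 0
    case_group: str = "CASE"
    control_group: str = "CTRL"
    #: if False, individuals used by an earlier pool set are excluded from
    #: later sets (disjoint sub-cohorts); if True the same cohort is re-pooled.
    reuse_across_sets: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ld_block_length < 1:
            raise ValueError("ld_block_length must be >= 1")
        if not 0.0 <= self.ld_r < 1.0:
            raise ValueError("ld_r must be in [0, 1)")
        object.__setattr__(self, "snp_panel", tuple(self.snp_panel))
        object.__setattr__(self, "effect_loci", tuple(self.effect_loci))
        object.__setattr__(self, "pool_sets", tuple(self.pool_sets))
        ids = [s.snp_id for s in self.snp_panel]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique within the panel")


@dataclass
class GenotypeTable:
    """Individuals x SNPs minor-allele dosage matrix.

    Dosages are in {0, 1, 2}; a value of -1 marks a missing genotype (never
    produced by the simulator, but representable for tables read from disk).
    """

    individuals: list[tuple[str, str]]  # (individual_id, group)
    genotypes: np.ndarray  # int8, shape (n_individuals, n_snps)
    snp_panel: list[SnpDef]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.snp_panel)):
            raise ValueError("genotype matrix shape does not match labels")

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, (_, g) in enumerate(self.individuals) if g == group], dtype=int
        )

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snp_panel]


@dataclass(frozen=True)
class Pool:
    pool_id: str
    group: str
    set_id: str
    member_indices: tuple[int, ...]


@dataclass
class PoolAssignment:
    pools: list[Pool]
    #: (set_id, group) -> number of group members not fitting a complete pool
    leftovers: dict[tuple[str, str], int]

    def for_set(self, set_id: str) -> list[Pool]:
        return [p for p in self.pools if p.set_id == set_id]


@dataclass
class IntensityTable:
    """Two-channel pooled array intensities (A = measured allele channel)."""

    pools: list[tuple[str, str, str]]  # (pool_id, group, set_id)
    channel_a: np.ndarray
    channel_b: np.ndarray
    snp_panel: list[SnpDef]

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channel matrices must have the same shape")
        if self.channel_a.shape != (len(self.pools), len(self.snp_panel)):
            raise ValueError("channel matrix shape does not match labels")


def shifted_maf(p: float, odds_ratio: float) -> float:
    """Case minor-allele frequency implied by a per-allele odds ratio.

    p' = OR*p / (1 - p + OR*p)
    """
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def two_set_design(
    case_group: str = "CASE",
    control_group: str = "CTRL",
    *,
    case_pools: tuple[int, int] = (21, 11),
    control_pools: tuple[int, int] = (30, 10),
    set1_case_size: int = 20,
    set1_control_size: int = 24,
    set2_size: int = 37,
) -> tuple[PoolSetSpec, PoolSetSpec]:
    """The default two-set pooling design: a first set of many small pools
    (20-24 individuals each) and a second set of fewer large pools (37 each),
    built from the same case cohort."""
    set1 = PoolSetSpec(
        set_id="I",
        pool_size=set1_case_size,
        pools_per_group={case_group: case_pools[0], control_group: control_pools[0]},
        pool_sizes={case_group: set1_case_size, control_group: set1_control_size},
    )
    set2 = PoolSetSpec(
        set_id="II",
        pool_size=set2_size,
        pools_per_group={case_group: case_pools[1], control_group: control_pools[1]},
    )
    return set1, set2


def make_snp_panel(
    n_snps: int,
    *,
    block_length: int = 15,
    spacing_bp: int = 5_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom: str = "1",
    start_pos: int = 1_000_000,
    shared_block_maf: bool = True,
    rng: np.random.Generator | int | None = None,
) -> tuple[SnpDef, ...]:
    """Generate an evenly spaced synthetic SNP panel.

    With ``shared_block_maf`` (default) all SNPs of an LD block share one MAF
    drawn uniformly from ``maf_range``: SNPs in strong LD necessarily have
    near-equal allele frequencies, so a per-block draw is the realistic
    default.  Set it to False for fully independent per-SNP MAFs.
    """
    rng = np.random.default_rng(rng)
    lo, hi = maf_range
    if shared_block_maf:
        n_blocks = -(-n_snps // block_length)
        block_mafs = rng.uniform(lo, hi, size=n_blocks)
        mafs = np.repeat(block_mafs, block_length)[:n_snps]
    else:
        mafs = rng.uniform(lo, hi, size=n_snps)
    return tuple(
        SnpDef(
            snp_id=f"snp{i:06d}",
            chrom=chrom,
            pos=start_pos + i * spacing_bp,
            allele_a="A",
            allele_b="G",
            maf=float(mafs[i]),
        )
        for i in range(n_snps)
    )


def _panel_blocks(panel: Sequence[SnpDef], block_length: int) -> list[slice]:
    """Consecutive LD blocks of at most ``block_length`` SNPs, restarting at
    every chromosome boundary."""
    blocks: list[slice] = []
    i = 0
    n = len(panel)
    while i < n:
        chrom = panel[i].chrom
        j = i
        while j < n and j - i < block_length and panel[j].chrom == chrom:
            j += 1
        blocks.append(slice(i, j))
        i = j
    return blocks


def _haplotypes(
    n_hap: int,
    mafs: np.ndarray,
    blocks: list[slice],
    ld_r: float,
    rng: np.random.Generator,
    effects: Mapping[int, tuple[int, float]],
) -> np.ndarray:
    """Draw ``n_hap`` haplotypes over the panel.

    ``effects`` maps block index -> (local SNP offset, shifted frequency p');
    pass an empty mapping for the control population.
    """
    if ld_r == 0.0:
        # no LD: one vectorised Bernoulli draw over the whole panel
        ind_p = mafs.copy()
        for bi, (j, p_prime) in effects.items():
            ind_p[blocks[bi].start + j] = p_prime
        return rng.random((n_hap, len(mafs))) < ind_p[None, :]
    out = np.empty((n_hap, len(mafs)), dtype=bool)
    for bi, sl in enumerate(blocks):
        pb = mafs[sl]
        blen = sl.stop - sl.start
        eff = effects.get(bi)
        if eff is None:
            u = rng.random(n_hap)
            ind_p = pb
        else:
            j, p_prime = eff
            pe = pb[j]
            carrier = rng.random(n_hap) < p_prime
            # tag uniform conditional on the risk allele: 1{u < pe} == carrier
            u = np.where(
                carrier,
                rng.random(n_hap) * pe,
                pe + rng.random(n_hap) * (1.0 - pe),
            )
            ind_p = pb.copy()
            ind_p[j] = p_prime
        copy = rng.random((n_hap, blen)) < ld_r
        tag = u[:, None] < pb[None, :]
        indep = rng.random((n_hap, blen)) < ind_p[None, :]
        out[:, sl] = np.where(copy, tag, indep)
    return out


def simulate_cohort(spec: SimulationSpec) -> GenotypeTable:
    """Draw the full case/control genotype table for a simulation spec.

    Cases are generated first, then controls, each as 2n haplotypes from the
    block-copy LD model; the spec seed fully determines the output.
    """
    panel = list(spec.snp_panel)
    index = {s.snp_id: i for i, s in enumerate(panel)}
    blocks = _panel_blocks(panel, spec.ld_block_length)
    block_of = np.empty(len(panel), dtype=int)
    for bi, sl in enumerate(blocks):
        block_of[sl] = bi

    effects: dict[int, tuple[int, float]] = {}
    for locus in spec.effect_loci:
        if locus.snp_id not in index:
            raise KeyError(
                f"effect locus references unknown SNP id {locus.snp_id!r}"
            )
        gi = index[locus.snp_id]
        bi = int(block_of[gi])
        if bi in effects:
            raise ValueError(
                f"two effect loci fall in the same LD block (near {locus.snp_id!r}); "
                "the haplotype model supports at most one per block"
            )
        p_prime = shifted_maf(panel[gi].maf, locus.odds_ratio)
        effects[bi] = (gi - blocks[bi].start, p_prime)

    mafs = np.array([s.maf for s in panel], dtype=float)
    rng = np.random.default_rng([0, spec.seed])

    hap_cases = _haplotypes(2 * spec.n_cases, mafs, blocks, spec.ld_r, rng, effects)
    hap_ctrls = _haplotypes(2 * spec.n_controls, mafs, blocks, spec.ld_r, rng, {})
    geno_cases = hap_cases[0::2].astype(np.int8) + hap_cases[1::2].astype(np.int8)
    geno_ctrls = hap_ctrls[0::2].astype(np.int8) + hap_ctrls[1::2].astype(np.int8)

    individuals = [
        (f"{spec.case_group}_{i:05d}", spec.case_group) for i in range(spec.n_cases)
    ] + [
        (f"{spec.control_group}_{i:05d}", spec.control_group)
        for i in range(spec.n_controls)
    ]
    return GenotypeTable(
        individuals=individuals,
        genotypes=np.vstack([geno_cases, geno_ctrls]),
        snp_panel=panel,
    )


def assign_pools(table: GenotypeTable, spec: SimulationSpec) -> PoolAssignment:
    """Partition individuals into equimolar pools per diagnosis group.

    Within each set individuals of a group are shuffled (seeded) and pools
    filled in that order; individuals not filling a complete pool are left
    out of the set.  With ``reuse_across_sets`` (default) the same cohort is
    re-pooled in every set, otherwise later sets draw from individuals unused
    so far.
    """
    rng = np.random.default_rng([1, spec.seed])
    pools: list[Pool] = []
    leftovers: dict[tuple[str, str], int] = {}
    used: dict[str, set[int]] = {}
    for pool_set in spec.pool_sets:
        for group, n_pools in pool_set.pools_per_group.items():
            size = pool_set.size_for(group)
            avail = table.group_indices(group)
            if len(avail) == 0:
                raise ValueError(
                    f"no individuals in group {group!r} for set {pool_set.set_id!r}"
                )
            if not spec.reuse_across_sets:
                taken = used.setdefault(group, set())
                avail = np.array([i for i in avail if i not in taken], dtype=int)
            need = n_pools * size
            if len(avail) < need:
                raise ValueError(
                    f"group {group!r}: set {pool_set.set_id!r} needs {need} "
                    f"individuals but only {len(avail)} are available"
                )
            perm = rng.permutation(avail)
            for k in range(n_pools):
                members = tuple(int(i) for i in perm[k * size : (k + 1) * size])
                pools.append(
                    Pool(
                        pool_id=f"{pool_set.set_id}:{group}:{k + 1:02d}",
                        group=group,
                        set_id=pool_set.set_id,
                        member_indices=members,
                    )
                )
                if not spec.reuse_across_sets:
                    used.setdefault(group, set()).update(members)
            leftovers[(pool_set.set_id, group)] = len(avail) - need
    return PoolAssignment(pools=pools, leftovers=leftovers)


def simulate_intensities(
    table: GenotypeTable,
    assignment: PoolAssignment,
    spec: SimulationSpec,
    *,
    total_signal: float = 1.0,
    batch_shift: Mapping[str, np.ndarray] | None = None,
) -> IntensityTable:
    """Emit two-channel intensities for every pool.

    ``batch_shift`` maps pool_id -> per-SNP additive shift on the pooled
    allele fraction (applied before noise, clipped to [0, 1]); it exists to
    plant systematic outlier pools for QC testing.
    """
    if total_signal <= 0:
        raise ValueError("total_signal must be > 0")
    rng = np.random.default_rng([2, spec.seed])
    n_snps = len(table.snp_panel)
    n_pools = len(assignment.pools)
    freqs = np.empty((n_pools, n_snps), dtype=float)
    for i, pool in enumerate(assignment.pools):
        dosages = table.genotypes[list(pool.member_indices)]
        if (dosages < 0).any():
            raise ValueError(f"pool {pool.pool_id!r} contains missing genotypes")
        freqs[i] = dosages.sum(axis=0) / (2.0 * len(pool.member_indices))
    if batch_shift:
        for i, pool in enumerate(assignment.pools):
            shift = batch_shift.get(pool.pool_id)
            if shift is not None:
                freqs[i] = np.clip(freqs[i] + np.asarray(shift, dtype=float), 0.0, 1.0)
    if spec.noise_sd > 0:
        sd = spec.noise_sd
        a = (0.0 - freqs) / sd
        b = (1.0 - freqs) / sd
        noisy = stats.truncnorm.rvs(
            a, b, loc=freqs, scale=sd, size=freqs.shape, random_state=rng
        )
    else:
        noisy = freqs
    return IntensityTable(
        pools=[(p.pool_id, p.group, p.set_id) for p in assignment.pools],
        channel_a=noisy * total_signal,
        channel_b=(1.0 - noisy) * total_signal,
        snp_panel=table.snp_panel,
    )
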