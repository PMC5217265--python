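"""Synthetic cohort generator: allele-frequency model, LD, pooling, noise."""

import math

import numpy as np
import pytest

from pooledscan.allelotyping import compute_ras
from pooledscan.simulate import (
    EffectLocus,
    GenotypeTable,
    Pool,
    PoolAssignment,
    PoolSetSpec,
    SimulationSpec,
    SnpDef,
    assign_pools,
    make_snp_panel,
    shifted_maf,
    simulate_cohort,
    simulate_intensities,
)

from conftest import flat_panel


def _spec(panel, *, n=2000, or_=1.0, eff_idx=7, ld_r=0.9, block=15,
          noise=0.0, seed=1, pools=()):
    loci = () if or_ == 1.0 else (EffectLocus(panel[eff_idx].snp_id, or_),)
    return SimulationSpec(
        n_cases=n, n_controls=n, snp_panel=panel, ld_block_length=block,
        ld_r=ld_r, effect_loci=loci, pool_sets=tuple(pools),
        noise_sd=noise, seed=seed,
    )


class TestAlleleFrequencyModel:
    def test_shifted_maf_closed_form(self):
        # p' = OR*p / (1 - p + OR*p): 0.4 / (0.8 + 0.4) = 1/3
        assert shifted_maf(0.2, 2.0) == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert shifted_maf(0.2, 1.0) == pytest.approx(0.2)

    def test_case_maf_matches_odds_model(self):
        panel = flat_panel(15)
        spec = _spec(panel, n=5000, or_=2.0)
        table = simulate_cohort(spec)
        cases = table.group_indices("CASE")
        freq = table.genotypes[cases, 7].sum() / (2.0 * len(cases))
        expected = 1.0 / 3.0
        se = math.sqrt(expected * (1 - expected) / (2 * 5000))
        assert abs(freq - expected) < 3 * se

    def test_null_model_no_frequency_difference(self):
        panel = flat_panel(15)
        spec = _spec(panel, n=2000, or_=1.0)
        table = simulate_cohort(spec)
        cases = table.group_indices("CASE")
        ctrls = table.group_indices("CTRL")
        diff = (
            table.genotypes[cases].mean(axis=0)
            - table.genotypes[ctrls].mean(axis=0)
        ) / 2.0
        # per-SNP sampling SE of the frequency difference at p=0.2, n=2000
        se = math.sqrt(2 * 0.2 * 0.8 / (2 * 2000))
        assert abs(diff.mean()) < 3 * se
        assert np.max(np.abs(diff)) < 5 * se

    def test_effect_size_recovered_in_allelic_or(self):
        panel = flat_panel(15)
        spec = _spec(panel, n=5000, or_=2.0)
        table = simulate_cohort(spec)
        cases = table.group_indices("CASE")
        ctrls = table.group_indices("CTRL")
        a = int(table.genotypes[cases, 7].sum())
        b = 2 * len(cases) - a
        c = int(table.genotypes[ctrls, 7].sum())
        d = 2 * len(ctrls) - c
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(log_or - math.log(2.0)) < 3 * se

    def test_unknown_effect_locus_errors_with_id(self):
        panel = flat_panel(5)
        spec = _spec(panel, n=10, or_=1.0, block=5)
        bad = SimulationSpec(
            n_cases=10, n_controls=10, snp_panel=panel, ld_block_length=5,
            ld_r=0.5, effect_loci=(EffectLocus("rs_nowhere", 2.0),),
            noise_sd=0.0, seed=1,
        )
        with pytest.raises(KeyError, match="rs_nowhere"):
            simulate_cohort(bad)

    def test_two_effect_loci_one_block_rejected(self):
        panel = flat_panel(15)
        spec = SimulationSpec(
            n_cases=10, n_controls=10, snp_panel=panel, ld_block_length=15,
            ld_r=0.5,
            effect_loci=(
                EffectLocus(panel[2].snp_id, 2.0),
                EffectLocus(panel[9].snp_id, 1.5),
            ),
            noise_sd=0.0, seed=1,
        )
        with pytest.raises(ValueError, match="same LD block"):
            simulate_cohort(spec)


class TestDeterminismAndLd:
    def test_same_seed_bitwise_identical(self):
        panel = flat_panel(30)
        spec = _spec(panel, n=200, or_=1.5, block=15,
                     pools=[PoolSetSpec("I", 20, {"CASE": 5, "CTRL": 5})],
                     noise=0.02)
        t1, t2 = simulate_cohort(spec), simulate_cohort(spec)
        assert np.array_equal(t1.genotypes, t2.genotypes)
        assert t1.individuals == t2.individuals
        a1, a2 = assign_pools(t1, spec), assign_pools(t2, spec)
        assert a1.pools == a2.pools
        i1 = simulate_intensities(t1, a1, spec)
        i2 = simulate_intensities(t2, a2, spec)
        assert np.array_equal(i1.channel_a, i2.channel_a)
        assert np.array_equal(i1.channel_b, i2.channel_b)

    def test_within_block_correlation_exceeds_cross_block(self):
        panel = flat_panel(30)  # two blocks of 15
        spec = _spec(panel, n=2000, or_=1.0, ld_r=0.9, block=15)
        g = simulate_cohort(spec).genotypes.astype(float)
        within = np.corrcoef(g[:, 3], g[:, 4])[0, 1]
        cross = np.corrcoef(g[:, 14], g[:, 15])[0, 1]
        assert within > 0.5
        assert within > cross + 0.3

    def test_ld_free_panel_uncorrelated(self):
        panel = flat_panel(10)
        spec = _spec(panel, n=2000, or_=1.0, ld_r=0.0, block=1)
        g = simulate_cohort(spec).genotypes.astype(float)
        corr = np.corrcoef(g.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1


class TestPoolAssignment:
    def test_exact_partition(self):
        panel = flat_panel(5)
        spec = _spec(panel, n=120, block=5,
                     pools=[PoolSetSpec("I", 20, {"CASE": 6})])
        table = simulate_cohort(spec)
        assignment = assign_pools(table, spec)
        pools = assignment.for_set("I")
        assert len(pools) == 6
        members = [i for p in pools for i in p.member_indices]
        assert len(members) == 120
        assert len(set(members)) == 120  # disjoint, covering all cases
        assert assignment.leftovers[("I", "CASE")] == 0
        assert all(p.group == "CASE" for p in pools)

    def test_leftovers_excluded_from_set(self):
        # 443 cases in 11 pools of 37 -> 407 pooled, 36 left out
        panel = flat_panel(5)
        spec = SimulationSpec(
            n_cases=443, n_controls=120, snp_panel=panel, ld_block_length=5,
            ld_r=0.0, pool_sets=(
                PoolSetSpec("II", 37, {"CASE": 11, "CTRL": 3}),
            ), noise_sd=0.0, seed=3,
        )
        table = simulate_cohort(spec)
        assignment = assign_pools(table, spec)
        case_pools = [p for p in assignment.for_set("II") if p.group == "CASE"]
        assert sum(len(p.member_indices) for p in case_pools) == 407
        assert assignment.leftovers[("II", "CASE")] == 36
        # 120 controls in 3 pools of 37 -> 111 pooled, 9 left out
        assert assignment.leftovers[("II", "CTRL")] == 9

    def test_insufficient_individuals_names_group_and_set(self):
        panel = flat_panel(5)
        spec = _spec(panel, n=50, block=5,
                     pools=[PoolSetSpec("I", 20, {"CASE": 6})])
        table = simulate_cohort(spec)
        with pytest.raises(ValueError, match="'CASE'.*'I'"):
            assign_pools(table, spec)

    def test_same_individuals_repooled_across_sets(self):
        panel = flat_panel(5)
        spec = _spec(panel, n=100, block=5,
                     pools=[PoolSetSpec("I", 20, {"CASE": 5}),
                            PoolSetSpec("II", 25, {"CASE": 4})])
        table = simulate_cohort(spec)
        assignment = assign_pools(table, spec)
        s1 = {i for p in assignment.for_set("I") for i in p.member_indices}
        s2 = {i for p in assignment.for_set("II") for i in p.member_indices}
        assert s1 == s2  # full cohort reused in both sets

    def test_disjoint_sets_option(self):
        panel = flat_panel(5)
        spec = SimulationSpec(
            n_cases=100, n_controls=10, snp_panel=panel, ld_block_length=5,
            ld_r=0.0, pool_sets=(
                PoolSetSpec("I", 20, {"CASE": 2}),
                PoolSetSpec("II", 20, {"CASE": 2}),
            ), noise_sd=0.0, seed=3, reuse_across_sets=False,
        )
        table = simulate_cohort(spec)
        assignment = assign_pools(table, spec)
        s1 = {i for p in assignment.for_set("I") for i in p.member_indices}
        s2 = {i for p in assignment.for_set("II") for i in p.member_indices}
        assert not (s1 & s2)


class TestIntensities:
    def _manual_table(self, dosage_rows, panel):
        individuals = [(f"i{k}", "CASE") for k in range(len(dosage_rows))]
        return GenotypeTable(individuals, np.array(dosage_rows, np.int8), list(panel))

    def test_noiseless_ras_equals_pooled_fraction(self):
        panel = flat_panel(1)
        table = self._manual_table([[2]] * 20, panel)
        spec = _spec(panel, n=2, block=1, noise=0.0)
        assignment = PoolAssignment(
            pools=[Pool("p1", "CASE", "I", tuple(range(20)))], leftovers={}
        )
        intens = simulate_intensities(table, assignment, spec)
        ras = compute_ras(intens)
        assert ras.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_ras_fraction_example(self):
        # dosage sum 12 over a 20-individual pool -> f = 12/40 = 0.3
        panel = flat_panel(1)
        rows = [[1]] * 12 + [[0]] * 8
        table = self._manual_table(rows, panel)
        spec = _spec(panel, n=2, block=1, noise=0.0)
        assignment = PoolAssignment(
            pools=[Pool("p1", "CASE", "I", tuple(range(20)))], leftovers={}
        )
        ras = compute_ras(simulate_intensities(table, assignment, spec))
        assert ras.values[0, 0] == pytest.approx(0.3, abs=1e-12)

    def test_noise_sd_in_truncated_normal_band(self):
        # 30 replicate pools of identical composition, noise_sd = 0.02:
        # the sample SD of reconstructed RAS should sit near 0.02
        panel = flat_panel(50, maf=0.3)
        rows = [[1] * 50] * 20  # every pool fraction is exactly 0.5... use mixed
        rows = [[1] * 50 for _ in range(12)] + [[0] * 50 for _ in range(8)]
        table = self._manual_table(rows, panel)
        spec = _spec(panel, n=2, block=1, noise=0.02, seed=9)
        pools = [Pool(f"p{k}", "CASE", "I", tuple(range(20))) for k in range(30)]
        assignment = PoolAssignment(pools=pools, leftovers={})
        ras = compute_ras(simulate_intensities(table, assignment, spec))
        sds = ras.values.std(axis=0, ddof=1)
        assert 0.014 < np.median(sds) < 0.026

    def test_channels_sum_to_total_signal(self):
        panel = flat_panel(3)
        table = self._manual_table([[0, 1, 2]] * 4, panel)
        spec = _spec(panel, n=2, block=1, noise=0.02)
        assignment = PoolAssignment(
            pools=[Pool("p1", "CASE", "I", (0, 1, 2, 3))], leftovers={}
        )
        intens = simulate_intensities(table, assignment, spec, total_signal=2.5)
        assert np.allclose(intens.channel_a + intens.channel_b, 2.5)

    def test_batch_shift_moves_ras(self):
        panel = flat_panel(4)
        table = self._manual_table([[1, 1, 1, 1]] * 10, panel)
        spec = _spec(panel, n=2, block=1, noise=0.0)
        pools = [Pool("p1", "CASE", "I", tuple(range(10))),
                 Pool("p2", "CASE", "I", tuple(range(10)))]
        assignment = PoolAssignment(pools=pools, leftovers={})
        shift = np.array([0.05, 0.05, 0.0, 0.0])
        ras = compute_ras(
            simulate_intensities(table, assignment, spec,
                                 batch_shift={"p2": shift})
        )
        assert np.allclose(ras.values[1] - ras.values[0], shift, atol=1e-12)


class TestPanelHelpers:
    def test_make_snp_panel_shared_block_maf(self):
        panel = make_snp_panel(30, block_length=10, rng=0)
        mafs = [s.maf for s in panel]
        assert len({round(m, 12) for m in mafs[:10]}) == 1
        assert mafs[0] != mafs[10]
        pos = [s.pos for s in panel]
        assert all(b - a == 5_000 for a, b in zip(pos, pos[1:]))

    def test_invalid_snp_rejected(self):
        with pytest.raises(ValueError):
            SnpDef("x", "1", 0, "A", "G", 0.2)
        with pytest.raises(ValueError):
            SnpDef("x", "1", 10, "A", "A", 0.2)
        with pytest.raises(ValueError):
            SnpDef("x", "1", 10, "A", "G", 0.7)
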