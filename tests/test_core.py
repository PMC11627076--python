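"""Unit and property tests for the potential algebra."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genodyn import core
from genodyn.frequency_io import HaploblockRecord

from conftest import random_block, simple_freq_table

# frozen oracle: -(0.9*log2(0.9) + 0.1*log2(0.1)) evaluated independently
ENTROPY_09_01 = 0.4689955935892812


class TestShannonEntropy:
    def test_uniform_binary(self):
        assert core.shannon_entropy([0.5, 0.5]) == pytest.approx(1.0, abs=1e-15)

    def test_fixed(self):
        assert core.shannon_entropy([1.0, 0.0]) == 0.0

    def test_skewed(self):
        assert core.shannon_entropy([0.9, 0.1]) == pytest.approx(
            ENTROPY_09_01, abs=1e-12
        )

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            core.shannon_entropy([1.1, -0.1])

    def test_bad_normalization_rejected(self):
        with pytest.raises(ValueError):
            core.shannon_entropy([0.5, 0.4])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6).map(
            lambda xs: (np.array(xs) / np.sum(xs)).tolist()
        )
    )
    def test_bounds(self, p):
        s = core.shannon_entropy(p)
        assert 0.0 <= s <= math.log2(len(p)) + 1e-12


class TestNicAndTenv:
    def test_fully_ordered(self):
        assert core.nic(0.0, 100.0) == 1.0

    def test_maximal_variation(self):
        assert core.nic(100.0, 100.0) == 0.0

    def test_arithmetic(self):
        assert core.nic(9.75, 100.0) == pytest.approx(0.9025, abs=1e-12)

    def test_s_genome_above_s_max_rejected(self):
        with pytest.raises(ValueError):
            core.nic(101.0, 100.0)

    def test_tenv_identity(self):
        assert core.environmental_potential(1.0) == 1.0

    def test_tenv_pel_roundtrip(self):
        # PEL environmental potential 1.108 GEU round-trips its NIC
        assert core.environmental_potential(1.0 / 1.108) == pytest.approx(
            1.108, abs=1e-12
        )

    def test_tenv_half(self):
        assert core.environmental_potential(0.5) == 2.0

    def test_tenv_zero_nic_rejected(self):
        with pytest.raises(ValueError):
            core.environmental_potential(0.0)

    @given(st.floats(0.0, 100.0), st.floats(1.0, 1e4))
    def test_nic_tenv_roundtrip(self, s, smax):
        n = core.nic(min(s, smax), smax)
        if n > 0:
            assert core.environmental_potential(n) * n == pytest.approx(
                core.MU_CHECK, abs=1e-12
            )


class TestAllelicPotential:
    @pytest.mark.parametrize("t_env", np.linspace(1.0, 3.0, 9))
    def test_max_variation_unit(self, t_env):
        assert core.allelic_potential(0.5, t_env) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_fixing_potential(self):
        assert core.allelic_potential(1.0, 1.108) == pytest.approx(
            -0.108, abs=1e-12
        )

    def test_quarter(self):
        assert core.allelic_potential(0.25, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_absent_allele_sentinel(self):
        assert core.allelic_potential(0.0, 1.2) == math.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            core.allelic_potential(-0.1, 1.1)
        with pytest.raises(ValueError):
            core.allelic_potential(1.5, 1.1)


class TestSnpPotential:
    def test_max_variation(self):
        assert core.snp_potential([0.5, 0.5], 1.108) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_fixed(self):
        assert core.snp_potential([1.0, 0.0], 1.108) == pytest.approx(
            -0.108, abs=1e-12
        )

    def test_entropy_identity(self):
        # mu_S = mu_check - T + T*s
        assert core.snp_potential([0.9, 0.1], 1.0) == pytest.approx(
            ENTROPY_09_01, abs=1e-12
        )

    @given(st.floats(0.001, 0.999), st.floats(1.0, 3.0))
    def test_at_most_one_geu(self, p, t_env):
        mu = core.snp_potential([p, 1 - p], t_env)
        assert mu <= 1.0 + 1e-12
        if abs(p - 0.5) > 1e-6:
            assert mu < 1.0

    @given(st.floats(0.001, 0.999), st.floats(1.0, 3.0))
    def test_weighted_mean_of_allelic(self, p, t_env):
        mu = p * core.allelic_potential(p, t_env) + (1 - p) * core.allelic_potential(
            1 - p, t_env
        )
        assert core.snp_potential([p, 1 - p], t_env) == pytest.approx(
            mu, abs=1e-12
        )


class TestHaplotypePotential:
    def test_fixed_block(self):
        assert core.haplotype_potential(1.0, 2, 1.108) == pytest.approx(
            -0.216, abs=1e-12
        )

    def test_half(self):
        assert core.haplotype_potential(0.5, 2, 1.0) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_arithmetic(self):
        assert core.haplotype_potential(0.25, 3, 1.108) == pytest.approx(
            3 * (-0.108) + 1.108 * 2, abs=1e-12
        )

    def test_absent_sentinel(self):
        assert core.haplotype_potential(0.0, 2, 1.1) == math.inf


def _block(freqs, population="POPX", block_id="b1"):
    n = len(next(iter(freqs)))
    return HaploblockRecord(
        block_id=block_id,
        population_code=population,
        snp_ids=tuple(f"s{i}" for i in range(n)),
        haplotype_freq=freqs,
    )


class TestHaploblockPotential:
    def test_independent_pair_equals_sum_of_snps(self):
        blk = _block({"AA": 0.25, "AG": 0.25, "GA": 0.25, "GG": 0.25})
        hb = core.haploblock_potential(blk, 1.0)
        assert hb.mu_block == pytest.approx(2.0, abs=1e-12)
        assert hb.mu_block == pytest.approx(
            2 * core.snp_potential([0.5, 0.5], 1.0), abs=1e-12
        )

    def test_perfect_ld_pair(self):
        hb = core.haploblock_potential(_block({"AA": 0.5, "GG": 0.5}), 1.0)
        assert hb.mu_block == pytest.approx(1.0, abs=1e-12)

    def test_fully_fixed_block(self):
        hb = core.haploblock_potential(_block({"AAA": 1.0}), 1.108)
        assert hb.mu_block == pytest.approx(3 * (-0.108), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_entropy_identity(self, seed):
        rng = np.random.default_rng(seed)
        blk = random_block(rng)
        t_env = float(rng.uniform(1.0, 1.3))
        hb = core.haploblock_potential(blk, t_env)
        s_h = core.shannon_entropy(list(blk.haplotype_freq.values()))
        assert hb.mu_block == pytest.approx(
            blk.n_snps * (1 - t_env) + t_env * s_h, abs=1e-9
        )


class TestDistributeBlockPotential:
    def test_single_snp_block(self):
        blk = _block({"A": 0.7, "G": 0.3})
        hb = core.haploblock_potential(blk, 1.1)
        s = core.shannon_entropy([0.7, 0.3])
        dist = core.distribute_block_potential(hb, {"s0": s})
        assert dist["s0"] == pytest.approx(
            core.snp_potential([0.7, 0.3], 1.1), abs=1e-12
        )

    def test_perfect_ld_equal_weights(self):
        hb = core.haploblock_potential(_block({"AA": 0.5, "GG": 0.5}), 1.0)
        dist = core.distribute_block_potential(hb, {"s0": 1.0, "s1": 1.0})
        assert dist["s0"] == pytest.approx(0.5, abs=1e-12)
        assert dist["s1"] == pytest.approx(0.5, abs=1e-12)

    def test_fixed_member_gets_fixing_potential(self):
        # SNP s0 fixed (A in every haplotype), s1 at 0.5
        blk = _block({"AA": 0.5, "AG": 0.5})
        hb = core.haploblock_potential(blk, 1.0)
        dist = core.distribute_block_potential(hb, {"s0": 0.0, "s1": 1.0})
        assert dist["s0"] == pytest.approx(hb.mu_fixed, abs=1e-15)
        assert dist["s1"] == pytest.approx(
            hb.mu_block - hb.mu_fixed, abs=1e-12
        )

    def test_fully_fixed_fallback(self):
        hb = core.haploblock_potential(_block({"AAA": 1.0}), 1.2)
        dist = core.distribute_block_potential(
            hb, {"s0": 0.0, "s1": 0.0, "s2": 0.0}
        )
        assert all(v == hb.mu_fixed for v in dist.values())

    @given(st.integers(0, 10_000), st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_rule2_conservation_and_binding_sign(self, seed, fix):
        rng = np.random.default_rng(seed)
        blk = random_block(rng, fix_snps=fix)
        t_env = float(rng.uniform(1.0, 1.3))
        hb = core.haploblock_potential(blk, t_env)
        marg = blk.marginals()
        weights = {
            s: core.shannon_entropy(list(marg[s].values())) for s in blk.snp_ids
        }
        dist = core.distribute_block_potential(hb, weights)
        if sum(weights.values()) > 0:
            assert abs(sum(dist.values()) - hb.mu_block) < 1e-9
        for s in blk.snp_ids:
            mu_s = core.snp_potential(
                list(marg[s].values()) + ([] if len(marg[s]) == 2 else [0.0]),
                t_env,
            )
            eps = core.binding_potential(dist[s], mu_s)
            if sum(weights.values()) > 0:
                assert eps <= 1e-9


class TestBindingAndDistributedAllelic:
    def test_independent_block_zero_binding(self):
        blk = _block({"AA": 0.25, "AG": 0.25, "GA": 0.25, "GG": 0.25})
        hb = core.haploblock_potential(blk, 1.0)
        dist = core.distribute_block_potential(hb, {"s0": 1.0, "s1": 1.0})
        for s in ("s0", "s1"):
            eps = core.binding_potential(dist[s], core.snp_potential([0.5, 0.5], 1.0))
            assert eps == pytest.approx(0.0, abs=1e-12)

    def test_perfect_ld_binding(self):
        assert core.binding_potential(0.5, 1.0) == pytest.approx(-0.5)

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError):
            core.binding_potential(math.inf, 1.0)

    def test_unlinked_shift(self):
        assert core.distributed_allelic_potential(1.0, 0.0) == 1.0

    def test_additive_shift(self):
        assert core.distributed_allelic_potential(1.0, -0.5) == 0.5

    def test_sentinel_preserved(self):
        assert core.distributed_allelic_potential(math.inf, -0.5) == math.inf

    def test_allele_difference_preserved(self):
        # both alleles of a linked SNP shift by the same eps
        mu_maj = core.allelic_potential(0.7, 1.0)
        mu_min = core.allelic_potential(0.3, 1.0)
        eps = -0.4
        assert core.distributed_allelic_potential(
            mu_maj, eps
        ) - core.distributed_allelic_potential(mu_min, eps) == pytest.approx(
            mu_maj - mu_min, abs=1e-12
        )


# ---------------------------------------------------------------------------
# genome entropy
# ---------------------------------------------------------------------------


def joint_entropy_oracle(marginal_vectors, block_freqs=None):
    """Exhaustive joint entropy of independent SNPs x one block (bits)."""
    dists = [list(v) for v in marginal_vectors]
    if block_freqs is not None:
        dists.append(list(block_freqs.values()))
    total = 0.0
    for combo in product(*dists):
        p = math.prod(combo)
        if p > 0:
            total -= p * math.log2(p)
    return total


class TestGenomeEntropy:
    def test_three_unlinked_half(self):
        table = simple_freq_table({"P1": [0.5, 0.5, 0.5]})
        assert core.genome_entropy(table, population="P1") == pytest.approx(
            3.0, abs=1e-12
        )

    def test_perfect_ld_pair_counts_once(self):
        table = simple_freq_table({"P1": [0.5, 0.5]})
        blk = HaploblockRecord(
            "b1", "P1", ("snp0", "snp1"), {"AA": 0.5, "GG": 0.5}
        )
        assert core.genome_entropy(table, [blk], population="P1") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_snp_in_two_blocks_rejected(self):
        table = simple_freq_table({"P1": [0.5, 0.5]})
        b1 = HaploblockRecord("b1", "P1", ("snp0",), {"A": 0.5, "G": 0.5})
        b2 = HaploblockRecord("b2", "P1", ("snp0",), {"A": 0.5, "G": 0.5})
        with pytest.raises(ValueError, match="two blocks"):
            core.genome_entropy(table, [b1, b2], population="P1")

    @given(st.integers(0, 2_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_unlinked = 17
        p = rng.uniform(0.0, 1.0, size=n_unlinked + 3)
        table = simple_freq_table({"P1": list(p)})
        blk_snps = ("snp17", "snp18", "snp19")
        raw = rng.dirichlet(np.ones(8))
        haps = [f"{a}{b}{c}" for a in "AG" for b in "AG" for c in "AG"]
        blk = HaploblockRecord("b1", "P1", blk_snps, dict(zip(haps, raw)))
        got = core.genome_entropy(table, [blk], population="P1")
        expected = joint_entropy_oracle(
            [[pi, 1 - pi] for pi in p[:n_unlinked]], blk.haplotype_freq
        )
        assert got == pytest.approx(expected, abs=1e-9)


class TestProfilesAndPotentialTable:
    def test_profiles_roundtrip(self):
        table = simple_freq_table({"P1": [0.5, 0.9, 1.0], "P2": [0.6, 0.6, 0.6]})
        profs = core.population_profiles(table)
        for prof in profs.values():
            assert prof.s_max == 3.0
            assert prof.nic == pytest.approx(
                (prof.s_max - prof.s_genome) / prof.s_max, abs=1e-12
            )
            assert prof.t_env * prof.nic == pytest.approx(1.0, abs=1e-12)

    def test_potential_table_unlinked(self):
        table = simple_freq_table({"P1": [0.5], "P2": [0.25]})
        pot = core.compute_potentials(table, t_env={"P1": 1.0, "P2": 1.0})
        row = pot[(pot.population == "P1") & (pot.allele == "A")].iloc[0]
        assert row.mu_allele == pytest.approx(1.0)
        assert not row.linked and row.eps_binding == 0.0
        row = pot[(pot.population == "P2") & (pot.role == "minor")].iloc[0]
        # minor allele at 0.75... wait: major freq 0.25 means table major col
        assert row.p == pytest.approx(0.75)

    def test_potential_table_marginal_mismatch_rejected(self):
        table = simple_freq_table({"P1": [0.5, 0.5]})
        blk = HaploblockRecord(
            "b1", "P1", ("snp0", "snp1"), {"AA": 0.8, "GG": 0.2}
        )
        with pytest.raises(ValueError, match="marginal"):
            core.compute_potentials(table, [blk], {"P1": 1.1})

    def test_potential_table_linked_columns(self):
        table = simple_freq_table({"P1": [0.5, 0.5]})
        blk = HaploblockRecord(
            "b1", "P1", ("snp0", "snp1"), {"AA": 0.5, "GG": 0.5}
        )
        pot = core.compute_potentials(table, [blk], {"P1": 1.0})
        sub = pot[pot.snp_id == "snp0"].iloc[0]
        assert sub.linked
        assert sub.mu_snp_distributed == pytest.approx(0.5, abs=1e-12)
        assert sub.eps_binding == pytest.approx(-0.5, abs=1e-12)
        assert sub.mu_allele_distributed == pytest.approx(0.5, abs=1e-12)
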