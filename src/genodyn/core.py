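"""Potential algebra for population genomic information content.

Implements the entropy-based quantities used throughout the pipeline:

* Shannon entropy of allele / haplotype frequency vectors (bits).
* Normalized information content (NIC) of a population genome and the
  derived environmental potential ``T_E = mu_check / NIC`` (GEU).
* Allelic and SNP potentials for bi-allelic sites.
* Haplotype / haploblock potentials for linked sites, the rules for
  distributing a block potential back onto its member SNPs, and the
  resulting binding potentials.

All potentials are expressed in genomic energy units (GEU), defined so
that a non-linked bi-allelic SNP at maximum variation (p = 0.5) has
potential ``MU_CHECK = 1`` GEU.  Entropies are in bits (log base 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum potential of a non-linked bi-allelic SNP, in GEU.  This is the
#: unit of the whole framework and is deliberately not configurable.
MU_CHECK = 1.0

#: Tolerance for probability-vector normalization checks.
NORM_TOL = 1e-9

#: Tolerance for conservation identities (block-sum rules).
CONS_TOL = 1e-9

__all__ = [
    "MU_CHECK",
    "shannon_entropy",
    "nic",
    "environmental_potential",
    "allelic_potential",
    "fixing_potential",
    "snp_potential",
    "haplotype_potential",
    "haploblock_potential",
    "distribute_block_potential",
    "binding_potential",
    "distributed_allelic_potential",
    "genome_entropy",
    "population_profiles",
    "compute_potentials",
    "PopulationEntropyProfile",
    "HaploblockPotential",
]


def _validate_probability_vector(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D probability vector")
    if np.any(p < 0) or np.any(p > 1 + 1e-12):
        raise ValueError(f"probabilities outside [0, 1]: {p!r}")
    total = float(p.sum())
    if abs(total - 1.0) > NORM_TOL:
        raise ValueError(f"probability vector sums to {total!r}, not 1")
    return p


def shannon_entropy(freqs: Sequence[float]) -> float:
    """Shannon entropy of a probability vector, in bits.

    ``0 * log2(0)`` is treated as 0.  Raises ``ValueError`` on negative
    entries or a vector that does not sum to 1 within ``NORM_TOL``.
    """
    p = _validate_probability_vector(freqs)
    nz = p[p > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def nic(s_genome: float, s_max: float) -> float:
    """Normalized information content ``(s_max - s_genome) / s_max``."""
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    if s_genome < -NORM_TOL or s_genome > s_max + NORM_TOL:
        raise ValueError(
            f"s_genome={s_genome!r} outside [0, s_max={s_max!r}]"
        )
    return (s_max - s_genome) / s_max


def environmental_potential(nic_value: float) -> float:
    """Environmental potential ``T_E = MU_CHECK / NIC`` in GEU."""
    if nic_value <= 0:
        raise ValueError("NIC must be positive (zero means infinite disorder)")
    if nic_value > 1 + 1e-12:
        raise ValueError("NIC cannot exceed 1")
    return MU_CHECK / nic_value


def fixing_potential(t_env: float) -> float:
    """Potential of an allele fixed in the population: ``MU_CHECK - T_E``."""
    return MU_CHECK - t_env


def allelic_potential(p: float, t_env: float) -> float:
    """Allelic potential ``MU_CHECK - T_E - T_E * log2(p)`` in GEU.

    Returns ``math.inf`` for an absent allele (p = 0); callers must treat
    that sentinel with weight zero in any average.
    """
    if p < 0 or p > 1 + 1e-12:
        raise ValueError(f"allele frequency {p!r} outside [0, 1]")
    if p == 0:
        return math.inf
    return MU_CHECK - t_env - t_env * math.log2(min(p, 1.0))


def snp_potential(freqs: Sequence[float], t_env: float) -> float:
    """Frequency-weighted mean of a SNP's allelic potentials (GEU).

    Equal to ``MU_CHECK - T_E + T_E * s`` with ``s`` the allele entropy;
    absent alleles contribute zero.  The maximum, 1 GEU, is attained only
    at p = 0.5 for a bi-allelic SNP.
    """
    p = _validate_probability_vector(freqs)
    total = 0.0
    for pa in p:
        if pa > 0:
            total += pa * allelic_potential(float(pa), t_env)
    return total


def haplotype_potential(p_h: float, n_snps: int, t_env: float) -> float:
    """Potential of a haplotype at frequency ``p_h`` spanning ``n_snps`` sites.

    ``mu_h = n_snps * (MU_CHECK - T_E) - T_E * log2(p_h)``.  The baseline is
    ``n_snps`` fixing potentials so that a fully fixed block carries exactly
    ``n_snps`` times the fixing potential (making the distribution rules
    self-consistent in the fixed limit).  p_h = 0 returns ``math.inf``.
    """
    if n_snps < 1:
        raise ValueError("a haplotype spans at least one SNP")
    if p_h < 0 or p_h > 1 + 1e-12:
        raise ValueError(f"haplotype frequency {p_h!r} outside [0, 1]")
    if p_h == 0:
        return math.inf
    return n_snps * fixing_potential(t_env) - t_env * math.log2(min(p_h, 1.0))


@dataclass(frozen=True)
class PopulationEntropyProfile:
    """Whole-genome entropy summary for one population."""

    population_code: str
    s_genome: float  # bits
    s_max: float  # bits (= number of bi-allelic SNPs)
    nic: float
    t_env: float  # GEU

    def __post_init__(self) -> None:
        if not (0 <= self.nic <= 1):
            raise ValueError(f"NIC {self.nic!r} outside [0, 1]")


@dataclass
class HaploblockPotential:
    """Haploblock potential and its per-haplotype decomposition."""

    block_id: str
    population_code: str
    mu_haplotype: dict  # haplotype string -> GEU (inf for absent)
    mu_block: float  # population mean of haplotype potentials, GEU
    n_snps: int
    mu_fixed: float  # fixing potential MU_CHECK - T_E, GEU
    t_env: float = field(repr=False, default=float("nan"))


def haploblock_potential(block, t_env: float) -> HaploblockPotential:
    """Population-averaged haploblock potential.

    ``block`` is any object with ``block_id``, ``population_code``,
    ``n_snps`` and a ``haplotype_freq`` mapping (see
    :class:`genodyn.frequency_io.HaploblockRecord`).  The mean equals
    ``n_snps * mu_fixed + T_E * s_H`` with ``s_H`` the haplotype entropy.
    """
    freqs = dict(block.haplotype_freq)
    _validate_probability_vector(list(freqs.values()))
    mu_h = {
        h: haplotype_potential(p, block.n_snps, t_env) for h, p in freqs.items()
    }
    mu_block = 0.0
    for h, p in freqs.items():
        if p > 0:
            mu_block += p * mu_h[h]
    return HaploblockPotential(
        block_id=block.block_id,
        population_code=block.population_code,
        mu_haplotype=mu_h,
        mu_block=mu_block,
        n_snps=block.n_snps,
        mu_fixed=fixing_potential(t_env),
        t_env=t_env,
    )


def distribute_block_potential(
    block_potential: HaploblockPotential,
    marginal_entropies: Mapping[str, float],
) -> dict:
    """Distribute a haploblock potential onto its member SNPs.

    Three rules:

    1. a SNP fixed in the population (zero marginal entropy) receives
       exactly the fixing potential;
    2. the distributed potentials sum to the block potential;
    3. the remainder above ``n * mu_fixed`` is apportioned proportional to
       the marginal Shannon entropy of each SNP.

    A fully fixed multi-SNP block (all weights zero) degenerates to
    treating every member as an unlinked fixed SNP; this is logged.
    Returns ``{snp_id: mu_distributed}``.
    """
    if len(marginal_entropies) != block_potential.n_snps:
        raise ValueError("one marginal entropy required per member SNP")
    weights = {s: float(w) for s, w in marginal_entropies.items()}
    if any(w < -NORM_TOL for w in weights.values()):
        raise ValueError("marginal entropies must be non-negative")
    total_w = sum(max(w, 0.0) for w in weights.values())
    mu_fixed = block_potential.mu_fixed
    if total_w <= 0.0:
        if block_potential.n_snps > 1:
            logger.info(
                "block %s/%s fully fixed; members fall back to unlinked "
                "fixed SNPs",
                block_potential.block_id,
                block_potential.population_code,
            )
        return {s: mu_fixed for s in weights}
    remainder = block_potential.mu_block - block_potential.n_snps * mu_fixed
    return {
        s: mu_fixed + remainder * max(w, 0.0) / total_w
        for s, w in weights.items()
    }


def binding_potential(mu_distributed: float, mu_marginal_snp: float) -> float:
    """Binding potential ``eps = mu_distributed - mu_marginal_snp`` (GEU).

    Non-positive on valid blocks: linkage can only lower a member SNP's
    potential relative to its unlinked value.
    """
    if not (math.isfinite(mu_distributed) and math.isfinite(mu_marginal_snp)):
        raise ValueError("binding potential requires finite inputs")
    return mu_distributed - mu_marginal_snp


def distributed_allelic_potential(mu_allele: float, eps_binding: float) -> float:
    """Shift an allelic potential by the SNP's binding potential.

    Both alleles of a linked SNP share the same shift.  An absent allele
    (``inf`` sentinel) stays absent.
    """
    if math.isinf(mu_allele):
        return mu_allele
    return mu_allele + eps_binding


# ---------------------------------------------------------------------------
# genome-level entropy and per-population profiles
# ---------------------------------------------------------------------------


def _blocks_for_population(blocks: Iterable, population: str) -> list:
    out = []
    seen: dict = {}
    for blk in blocks:
        if blk.population_code != population:
            continue
        for sid in blk.snp_ids:
            if sid in seen:
                raise ValueError(
                    f"SNP {sid} belongs to two blocks in population "
                    f"{population}: {seen[sid]} and {blk.block_id}"
                )
            seen[sid] = blk.block_id
        out.append(blk)
    return out


def genome_entropy(freq_table, blocks: Iterable = (), *, population: str) -> float:
    """Total maintained entropy of one population's SNP set, in bits.

    Unlinked SNPs contribute their marginal allele entropy; SNPs inside a
    haploblock contribute through the joint entropy of the block's
    haplotype distribution (never double-counted).  Raises if a SNP is
    assigned to two blocks in the same population.
    """
    pop_blocks = _blocks_for_population(blocks, population)
    blocked = {sid for blk in pop_blocks for sid in blk.snp_ids}
    s = 0.0
    for snp_id in freq_table.snp_ids:
        if snp_id in blocked:
            continue
        s += shannon_entropy(list(freq_table.freq(snp_id, population).values()))
    for blk in pop_blocks:
        s += shannon_entropy(list(blk.haplotype_freq.values()))
    return s


def population_profiles(
    freq_table, blocks: Iterable = ()
) -> dict:
    """Entropy profile (s_genome, s_max, NIC, T_E) for every population.

    ``s_max`` counts every ingested bi-allelic SNP (monomorphic sites
    included) at one bit each.
    """
    s_max = float(len(freq_table.snp_ids))
    profiles = {}
    for pop in freq_table.populations:
        s_genome = genome_entropy(freq_table, blocks, population=pop)
        n = nic(s_genome, s_max)
        profiles[pop] = PopulationEntropyProfile(
            population_code=pop,
            s_genome=s_genome,
            s_max=s_max,
            nic=n,
            t_env=environmental_potential(n),
        )
    return profiles


# ---------------------------------------------------------------------------
# PotentialTable assembly
# ---------------------------------------------------------------------------

POTENTIAL_COLUMNS = [
    "snp_id",
    "population",
    "allele",
    "role",
    "p",
    "mu_allele",
    "mu_snp",
    "block_id",
    "mu_snp_distributed",
    "mu_allele_distributed",
    "eps_binding",
    "linked",
]


def compute_potentials(
    freq_table,
    blocks: Iterable = (),
    t_env: Mapping[str, float] | None = None,
    *,
    marginal_tol: float = 1e-6,
) -> pd.DataFrame:
    """Build the full potential table: one row per SNP x population x allele.

    ``t_env`` maps population code to its environmental potential; if
    ``None`` it is computed from the supplied SNP set via
    :func:`population_profiles`.  For SNPs inside a haploblock the block
    potential is distributed (rules 1-3) and the binding potential applied
    to both alleles.  Block haplotype marginals are checked against the
    frequency table within ``marginal_tol``.
    """
    if t_env is None:
        t_env = {p: prof.t_env for p, prof in population_profiles(freq_table, blocks).items()}
    missing = [p for p in freq_table.populations if p not in t_env]
    if missing:
        raise ValueError(f"no environmental potential supplied for: {missing}")

    block_of: dict = {}
    for pop in freq_table.populations:
        for blk in _blocks_for_population(blocks, pop):
            for sid in blk.snp_ids:
                block_of[(sid, pop)] = blk

    rows = []
    dist_cache: dict = {}
    for pop in freq_table.populations:
        te = float(t_env[pop])
        for snp_id in freq_table.snp_ids:
            info = freq_table.snp(snp_id)
            freqs = freq_table.freq(snp_id, pop)
            mu_a = {a: allelic_potential(p, te) for a, p in freqs.items()}
            mu_s = snp_potential(list(freqs.values()), te)
            blk = block_of.get((snp_id, pop))
            if blk is None:
                mu_dist, eps, block_id, linked = mu_s, 0.0, "", False
            else:
                key = (blk.block_id, pop)
                if key not in dist_cache:
                    dist_cache[key] = _distribute_for_block(
                        blk, te, freq_table, marginal_tol
                    )
                dist, degenerate = dist_cache[key]
                mu_dist = dist[snp_id]
                eps = binding_potential(mu_dist, mu_s) if not degenerate else 0.0
                block_id, linked = blk.block_id, not degenerate
            for allele, p in freqs.items():
                role = "major" if allele == info.allele_major else "minor"
                rows.append(
                    {
                        "snp_id": snp_id,
                        "population": pop,
                        "allele": allele,
                        "role": role,
                        "p": p,
                        "mu_allele": mu_a[allele],
                        "mu_snp": mu_s,
                        "block_id": block_id,
                        "mu_snp_distributed": mu_dist,
                        "mu_allele_distributed": distributed_allelic_potential(
                            mu_a[allele], eps
                        ),
                        "eps_binding": eps,
                        "linked": linked,
                    }
                )
    return pd.DataFrame(rows, columns=POTENTIAL_COLUMNS)


def _distribute_for_block(blk, te: float, freq_table, marginal_tol: float):
    """Distribute one block's potential; returns (dict, degenerate_flag)."""
    marginals = blk.marginals()
    for sid in blk.snp_ids:
        table_freqs = freq_table.freq(sid, blk.population_code)
        for allele, p in marginals[sid].items():
            ref = table_freqs.get(allele, 0.0)
            if abs(p - ref) > marginal_tol:
                raise ValueError(
                    f"haplotype marginal for {sid}:{allele} in block "
                    f"{blk.block_id}/{blk.population_code} is {p:.6g}, "
                    f"frequency table says {ref:.6g}"
                )
    hb = haploblock_potential(blk, te)
    weights = {
        sid: shannon_entropy(list(marginals[sid].values()))
        for sid in blk.snp_ids
    }
    degenerate = sum(weights.values()) <= 0.0 and blk.n_snps > 1
    return distribute_block_potential(hb, weights), degenerate
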