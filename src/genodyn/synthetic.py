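"""Synthetic populations with implanted potential-environment relationships.

Generates everything the pipeline consumes — allele frequency tables,
haploblocks with controlled linkage, per-population environmental
potentials and environmental scalars — entirely from a seed, so the full
analysis is testable with no external data.  Implanted SNPs follow a
chosen potential curve mu(lambda) (plus Gaussian noise on the potential
scale) that is inverted to allele frequencies through the defining
potential formula; the generator records the ground truth for recovery
tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import MU_CHECK, fixing_potential
from .envscan import CandidateForm
from .frequency_io import (
    AlleleFrequencyTable,
    EnvironmentTable,
    HaploblockRecord,
    PopulationPanel,
    SnpInfo,
    write_blocks,
    write_environment,
    write_frequency_table,
    write_panel,
    write_tenv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Implant",
    "BlockSpec",
    "ScenarioConfig",
    "Scenario",
    "invert_potential_to_frequency",
    "gen_null_snps",
    "gen_implanted_snp",
    "gen_haploblock_fixture",
    "generate_scenario",
]

#: Environmental-potential range spanned by the study populations (GEU).
TENV_RANGE = (1.10, 1.25)

DEFAULT_PARAMETER = "zoonotic_virus_richness"


def invert_potential_to_frequency(mu_target: float, t_env: float) -> float:
    """Allele frequency whose potential equals ``mu_target`` at ``t_env``.

    Inverse of the allelic potential formula:
    ``p = 2 ** ((MU_CHECK - T_E - mu) / T_E)``.  A target below the fixing
    potential is unreachable for an unlinked allele (only distributed
    potentials can lie below it).
    """
    mu_fix = fixing_potential(t_env)
    if mu_target < mu_fix - 1e-12:
        raise ValueError(
            f"potential {mu_target!r} below the fixing potential {mu_fix!r}: "
            "unreachable without linkage"
        )
    return min(2.0 ** ((MU_CHECK - t_env - mu_target) / t_env), 1.0)


@dataclass(frozen=True)
class Implant:
    """A SNP whose target-allele potential follows mu(lambda) + noise."""

    snp_id: str
    target_role: str  # "major" or "minor": which allele carries the curve
    form_id: str
    parameters: tuple
    residual_sd: float = 0.0  # GEU, noise on the potential scale

    def curve(self) -> CandidateForm:
        return CandidateForm(self.form_id, np.asarray(self.parameters, float))


@dataclass(frozen=True)
class BlockSpec:
    """A haploblock implanted in a subset of populations."""

    block_id: str
    populations: tuple  # population codes carrying the block
    n_snps: int
    ld_strength: float  # 0 = independent, 1 = two-haplotype support
    maf: float = 0.5  # common marginal minor-allele frequency


@dataclass
class ScenarioConfig:
    n_populations: int = 10
    n_null_snps: int = 100
    t_env_values: Sequence[float] | None = None  # drawn in TENV_RANGE if None
    env_values: Sequence[float] | None = None  # default: linspace, 5x span
    parameter_name: str = DEFAULT_PARAMETER
    implants: Sequence[Implant] = field(default_factory=list)
    block_specs: Sequence[BlockSpec] = field(default_factory=list)
    samples_per_population: int = 50  # diploids, for the VCF fixture
    seed: int = 0


@dataclass
class Scenario:
    """A fully generated scenario plus its ground truth."""

    config: ScenarioConfig
    populations: list
    freq_table: AlleleFrequencyTable
    blocks: list
    t_env: dict
    env: EnvironmentTable
    truth: dict

    def write_fixtures(self, outdir) -> dict:
        """Write all interchange files plus a phased VCF/panel; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "freqs": outdir / "freqs.tsv",
            "blocks": outdir / "blocks.tsv",
            "tenv": outdir / "tenv.tsv",
            "env": outdir / "env.tsv",
            "truth": outdir / "truth.json",
            "vcf": outdir / "sim.vcf",
            "panel": outdir / "panel.tsv",
        }
        write_frequency_table(self.freq_table, paths["freqs"])
        write_blocks(self.blocks, paths["blocks"])
        write_tenv(self.t_env, paths["tenv"])
        write_environment(self.env, paths["env"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        panel = self._write_vcf(paths["vcf"])
        write_panel(panel, paths["panel"])
        return paths

    def _write_vcf(self, path) -> PopulationPanel:
        rng = np.random.default_rng(self.config.seed + 104729)
        n_dip = self.config.samples_per_population
        samples = []
        sample_pop = {}
        for pop in self.populations:
            for i in range(n_dip):
                s = f"{pop}_s{i:03d}"
                samples.append(s)
                sample_pop[s] = pop
        # draw chromosomes: blocks jointly per population, the rest per site
        blocked = {
            (sid, blk.population_code): blk
            for blk in self.blocks
            for sid in blk.snp_ids
        }
        hap = {}  # (snp_id, pop) -> array of 2*n_dip alleles (0 ref/major)
        for blk in self.blocks:
            haps = list(blk.haplotype_freq)
            probs = np.array([blk.haplotype_freq[h] for h in haps])
            draws = rng.choice(len(haps), size=2 * n_dip, p=probs / probs.sum())
            for i, sid in enumerate(blk.snp_ids):
                minor = self.freq_table.snp(sid).allele_minor
                hap[(sid, blk.population_code)] = np.array(
                    [1 if haps[d][i] == minor else 0 for d in draws], dtype=int
                )
        for sid in self.freq_table.snp_ids:
            info = self.freq_table.snp(sid)
            for pop in self.populations:
                if (sid, pop) in hap:
                    continue
                p_minor = self.freq_table.freq(sid, pop)[info.allele_minor]
                hap[(sid, pop)] = (
                    rng.random(2 * n_dip) < p_minor
                ).astype(int)
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        chroms = sorted({self.freq_table.snp(s).chrom for s in self.freq_table.snp_ids})
        for c in chroms:
            lines.append(f"##contig=<ID={c}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
        for sid in self.freq_table.snp_ids:
            info = self.freq_table.snp(sid)
            gts = []
            for pop in self.populations:
                h = hap[(sid, pop)]
                for j in range(n_dip):
                    gts.append(f"{h[2 * j]}|{h[2 * j + 1]}")
            lines.append(
                f"{info.chrom}\t{info.pos}\t{sid}\t{info.allele_major}\t"
                f"{info.allele_minor}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
        Path(path).write_text("\n".join(lines) + "\n")
        return PopulationPanel(sample_pop)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _population_codes(n: int) -> list:
    return [f"POP{i + 1:02d}" for i in range(n)]


def gen_null_snps(
    populations: Sequence[str],
    n_snps: int,
    rng: np.random.Generator,
    *,
    start_index: int = 0,
    chrom: str = "1",
) -> tuple:
    """Environment-independent SNPs: per-population uniform MAF in [0.02, 0.5].

    Returns (list of SnpInfo, freq dict) ready for AlleleFrequencyTable.
    """
    snps = []
    freqs = {}
    bases = ("A", "C", "G", "T")
    for k in range(n_snps):
        snp_id = f"null{start_index + k:05d}"
        major, minor = bases[k % 4], bases[(k + 1) % 4]
        info = SnpInfo(snp_id, chrom, 1000 * (start_index + k + 1), major, minor)
        snps.append(info)
        for pop in populations:
            maf = float(rng.uniform(0.02, 0.5))
            freqs[(snp_id, pop)] = {major: 1.0 - maf, minor: maf}
    return snps, freqs


def gen_implanted_snp(
    implant: Implant,
    t_env: Mapping[str, float],
    env_values: Mapping[str, float],
    rng: np.random.Generator,
    *,
    max_retries: int = 100,
    chrom: str = "1",
    pos: int = 1,
) -> tuple:
    """Per-population frequencies realizing an implanted potential curve.

    The curve value at each population's lambda, plus Gaussian noise of the
    implant's residual SD, is inverted to the target-allele frequency with
    that population's T_E.  Draws leaving the reachable range are resampled
    (bounded retries).  Returns (SnpInfo, freq dict, truth dict).
    """
    curve = implant.curve()
    major, minor = "T", "C"
    target_allele = major if implant.target_role == "major" else minor
    other_allele = minor if implant.target_role == "major" else major
    info = SnpInfo(implant.snp_id, chrom, pos, major, minor)
    freqs = {}
    truth_mu = {}
    for pop, lam in env_values.items():
        te = float(t_env[pop])
        mu_fix = fixing_potential(te)
        mu_clean = float(curve(lam))
        if mu_clean < mu_fix:
            raise ValueError(
                f"implant {implant.snp_id}: curve value {mu_clean!r} at "
                f"lambda={lam!r} below the fixing potential for {pop}"
            )
        mu = mu_clean
        for attempt in range(max_retries + 1):
            mu = mu_clean + float(rng.normal(0.0, implant.residual_sd))
            if mu >= mu_fix:
                break
            logger.info(
                "implant %s: resampling noise for %s (draw %d unreachable)",
                implant.snp_id,
                pop,
                attempt,
            )
        else:
            raise RuntimeError(
                f"implant {implant.snp_id}: could not reach target for {pop}"
            )
        p = invert_potential_to_frequency(mu, te)
        freqs[(implant.snp_id, pop)] = {target_allele: p, other_allele: 1.0 - p}
        truth_mu[pop] = {"lambda": float(lam), "mu_clean": mu_clean, "mu": mu}
    truth = {
        "snp_id": implant.snp_id,
        "target_role": implant.target_role,
        "target_allele": target_allele,
        "form_id": implant.form_id,
        "parameters": list(implant.parameters),
        "residual_sd": implant.residual_sd,
        "per_population": truth_mu,
    }
    return info, freqs, truth


def _mixture_haplotypes(
    alleles_per_snp: Sequence[tuple], maf: float, ld_strength: float
) -> dict:
    """Haplotype distribution interpolating independence and perfect LD.

    All member SNPs share the marginal minor-allele frequency ``maf``; the
    distribution is ``(1 - w) * product-of-marginals + w * two-haplotype``
    (all-major with probability 1 - maf, all-minor with maf), which
    preserves the marginals for every ``w``.
    """
    if not 0.0 <= ld_strength <= 1.0:
        raise ValueError("ld_strength must lie in [0, 1]")
    n = len(alleles_per_snp)
    probs: dict = {}
    for combo in product((0, 1), repeat=n):
        h = "".join(alleles_per_snp[i][c] for i, c in enumerate(combo))
        p_ind = math.prod(maf if c else 1.0 - maf for c in combo)
        p_ld = 0.0
        if all(c == 1 for c in combo):
            p_ld = maf
        elif all(c == 0 for c in combo):
            p_ld = 1.0 - maf
        probs[h] = (1.0 - ld_strength) * p_ind + ld_strength * p_ld
    return {h: p for h, p in probs.items() if p > 0.0}


def gen_haploblock_fixture(
    n_snps: int,
    ld_strength: float,
    population: str,
    seed: int,
    *,
    n_chromosomes: int = 500,
    maf: float = 0.5,
    block_id: str = "blk1",
    snp_prefix: str = "bsnp",
    chrom: str = "1",
    start_pos: int = 1_000_000,
) -> dict:
    """A counted haploblock plus the phased VCF lines realizing it.

    Returns a dict with the ``record`` (counted frequencies — exactly
    consistent with the emitted genotypes), ``truth`` multinomial
    probabilities, ``snps`` (SnpInfo list), ``vcf_lines`` and
    ``sample_names`` for round-trip tests.  ``n_chromosomes`` must be even
    (chromosomes are paired into diploids).
    """
    if n_chromosomes % 2:
        raise ValueError("n_chromosomes must be even")
    rng = np.random.default_rng(seed)
    snps = [
        SnpInfo(f"{snp_prefix}{i + 1}", chrom, start_pos + 100 * i, "A", "G")
        for i in range(n_snps)
    ]
    alleles = [(s.allele_major, s.allele_minor) for s in snps]
    probs = _mixture_haplotypes(alleles, maf, ld_strength)
    haps = sorted(probs)
    pvec = np.array([probs[h] for h in haps])
    counts = rng.multinomial(n_chromosomes, pvec / pvec.sum())
    chrom_list = [h for h, c in zip(haps, counts) for _ in range(c)]
    rng.shuffle(chrom_list)
    record = HaploblockRecord(
        block_id=block_id,
        population_code=population,
        snp_ids=tuple(s.snp_id for s in snps),
        haplotype_freq={
            h: c / n_chromosomes for h, c in zip(haps, counts) if c > 0
        },
    )
    n_dip = n_chromosomes // 2
    sample_names = [f"{population}_s{i:03d}" for i in range(n_dip)]
    vcf_lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names),
    ]
    for i, s in enumerate(snps):
        gts = []
        for j in range(n_dip):
            a = int(chrom_list[2 * j][i] == s.allele_minor)
            b = int(chrom_list[2 * j + 1][i] == s.allele_minor)
            gts.append(f"{a}|{b}")
        vcf_lines.append(
            f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.allele_major}\t"
            f"{s.allele_minor}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    return {
        "record": record,
        "truth": probs,
        "snps": snps,
        "vcf_lines": vcf_lines,
        "sample_names": sample_names,
    }


def default_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Default scenario: 10 populations, 100 nulls, one implanted SNP.

    The implant carries a linear target-allele potential of slope +0.1 per
    lambda unit with residual SD 0.03 GEU; lambda spans a factor of five;
    one 3-SNP block at high LD sits in the lowest-lambda population.
    """
    cfg = ScenarioConfig(
        implants=[
            Implant(
                snp_id="implant001",
                target_role="major",
                form_id="linear",
                parameters=(0.0, 0.1),
                residual_sd=0.03,
            )
        ],
        block_specs=[BlockSpec("blk1", ("POP01",), 3, 0.9)],
        seed=seed,
        **overrides,
    )
    return cfg


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full scenario (frequencies, blocks, T_E, environment, truth)."""
    rng = np.random.default_rng(config.seed)
    populations = _population_codes(config.n_populations)
    if config.t_env_values is not None:
        tvals = list(config.t_env_values)
        if len(tvals) != config.n_populations:
            raise ValueError("t_env_values length mismatch")
    else:
        tvals = list(rng.uniform(*TENV_RANGE, size=config.n_populations))
    t_env = {pop: float(t) for pop, t in zip(populations, tvals)}
    if config.env_values is not None:
        evals = list(config.env_values)
        if len(evals) != config.n_populations:
            raise ValueError("env_values length mismatch")
    else:
        evals = list(np.linspace(2.0, 10.0, config.n_populations))
    env_series = {pop: float(v) for pop, v in zip(populations, evals)}
    env = EnvironmentTable({config.parameter_name: env_series})

    snps: list = []
    freqs: dict = {}
    null_snps, null_freqs = gen_null_snps(populations, config.n_null_snps, rng)
    snps.extend(null_snps)
    freqs.update(null_freqs)

    truth: dict = {
        "seed": config.seed,
        "parameter_name": config.parameter_name,
        "t_env": t_env,
        "env": env_series,
        "implants": [],
        "blocks": [],
        "null_snp_ids": [s.snp_id for s in null_snps],
    }
    pos = 10_000_000
    for implant in config.implants:
        info, f, tr = gen_implanted_snp(
            implant, t_env, env_series, rng, pos=pos
        )
        pos += 1000
        snps.append(info)
        for pop in populations:
            if (info.snp_id, pop) not in f:
                raise ValueError(f"implant missing population {pop}")
        freqs.update(f)
        truth["implants"].append(tr)

    blocks: list = []
    for spec in config.block_specs:
        for pop in spec.populations:
            if pop not in populations:
                raise ValueError(f"block population {pop!r} not in scenario")
        fx = gen_haploblock_fixture(
            spec.n_snps,
            spec.ld_strength,
            spec.populations[0],
            int(rng.integers(0, 2**31)),
            maf=spec.maf,
            block_id=spec.block_id,
            snp_prefix=f"{spec.block_id}_snp",
            start_pos=pos,
        )
        pos += 1000 * spec.n_snps
        snps.extend(fx["snps"])
        marg = fx["record"].marginals()
        for s in fx["snps"]:
            for pop in populations:
                if pop in spec.populations:
                    m = dict(marg[s.snp_id])
                    m.setdefault(s.allele_major, 0.0)
                    m.setdefault(s.allele_minor, 0.0)
                    freqs[(s.snp_id, pop)] = m
                else:
                    maf = float(rng.uniform(0.02, 0.5))
                    freqs[(s.snp_id, pop)] = {
                        s.allele_major: 1.0 - maf,
                        s.allele_minor: maf,
                    }
        for pop in spec.populations:
            rec = fx["record"]
            blocks.append(
                HaploblockRecord(
                    block_id=rec.block_id,
                    population_code=pop,
                    snp_ids=rec.snp_ids,
                    haplotype_freq=dict(rec.haplotype_freq),
                )
            )
        truth["blocks"].append(
            {
                "block_id": spec.block_id,
                "populations": list(spec.populations),
                "snp_ids": list(fx["record"].snp_ids),
                "ld_strength": spec.ld_strength,
                "haplotype_probs": fx["truth"],
            }
        )

    table = AlleleFrequencyTable(snps, populations, freqs)
    return Scenario(
        config=config,
        populations=populations,
        freq_table=table,
        blocks=blocks,
        t_env=t_env,
        env=env,
        truth=truth,
    )
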