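"""Ingestion and validation of genotype, frequency, block and environment data.

Reads phased VCF genotypes with a sample-to-population panel and produces
per-population allele frequency tables and haploblock records by direct
counting; also round-trips the plain-TSV interchange formats used by the
CLI (frequency table, block file, environmental scalars, environmental
potentials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NORM_TOL, shannon_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "SnpInfo",
    "AlleleFrequencyTable",
    "HaploblockRecord",
    "EnvironmentTable",
    "read_panel",
    "frequencies_from_vcf",
    "haplotype_frequencies",
    "detect_blocks",
    "read_frequency_table",
    "write_frequency_table",
    "read_blocks",
    "write_blocks",
    "read_environment",
    "write_environment",
    "read_tenv",
    "write_tenv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationPanel:
    """Mapping of sample identifiers to population codes."""

    sample_to_population: dict

    def __post_init__(self) -> None:
        if not self.sample_to_population:
            raise ValueError("panel is empty")
        for sample, pop in self.sample_to_population.items():
            if not pop:
                raise ValueError(f"sample {sample!r} has an empty population")

    @property
    def populations(self) -> list:
        seen: dict = {}
        for pop in self.sample_to_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples(self, population: str) -> list:
        return [
            s for s, p in self.sample_to_population.items() if p == population
        ]

    def population_of(self, sample: str) -> str:
        try:
            return self.sample_to_population[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} absent from panel") from None


@dataclass(frozen=True)
class SnpInfo:
    snp_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    allele_major: str
    allele_minor: str


class AlleleFrequencyTable:
    """Per-SNP, per-population bi-allelic frequencies.

    ``freqs`` maps ``(snp_id, population)`` to ``{allele: frequency}``;
    every entry is validated to be a two-allele probability vector.
    """

    def __init__(
        self,
        snps: Sequence[SnpInfo],
        populations: Sequence[str],
        freqs: Mapping,
    ) -> None:
        self._snps = {s.snp_id: s for s in snps}
        if len(self._snps) != len(snps):
            raise ValueError("duplicate snp_id in table")
        self._populations = list(populations)
        self._freqs = {}
        for snp in snps:
            for pop in self._populations:
                key = (snp.snp_id, pop)
                if key not in freqs:
                    raise ValueError(f"missing frequencies for {key}")
                f = dict(freqs[key])
                self._validate_entry(snp, f)
                self._freqs[key] = f
        self.n_multiallelic_skipped = 0

    @staticmethod
    def _validate_entry(snp: SnpInfo, f: dict) -> None:
        expected = {snp.allele_major, snp.allele_minor}
        if set(f) != expected:
            raise ValueError(
                f"{snp.snp_id}: alleles {sorted(f)} do not match "
                f"{sorted(expected)}"
            )
        vals = np.array(list(f.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1 + 1e-12):
            raise ValueError(f"{snp.snp_id}: frequency outside [0, 1]")
        if abs(vals.sum() - 1.0) > NORM_TOL:
            raise ValueError(
                f"{snp.snp_id}: frequencies sum to {vals.sum()!r}, not 1"
            )

    @property
    def snp_ids(self) -> list:
        return list(self._snps)

    @property
    def populations(self) -> list:
        return list(self._populations)

    def snp(self, snp_id: str) -> SnpInfo:
        return self._snps[snp_id]

    def freq(self, snp_id: str, population: str) -> dict:
        return dict(self._freqs[(snp_id, population)])

    def marginal_entropy(self, snp_id: str, population: str) -> float:
        return shannon_entropy(list(self._freqs[(snp_id, population)].values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for snp in self._snps.values():
            for pop in self._populations:
                for allele, p in self._freqs[(snp.snp_id, pop)].items():
                    rows.append(
                        {
                            "snp_id": snp.snp_id,
                            "chrom": snp.chrom,
                            "pos": snp.pos,
                            "allele": allele,
                            "population": pop,
                            "freq": p,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class HaploblockRecord:
    """Member SNPs and counted haplotype frequencies of one block."""

    block_id: str
    population_code: str
    snp_ids: tuple
    haplotype_freq: dict  # haplotype string -> frequency

    def __post_init__(self) -> None:
        self.snp_ids = tuple(self.snp_ids)
        if not self.snp_ids:
            raise ValueError("block has no member SNPs")
        vals = np.array(list(self.haplotype_freq.values()), dtype=float)
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > NORM_TOL:
            raise ValueError(
                f"block {self.block_id}: haplotype frequencies not normalized"
            )
        for h in self.haplotype_freq:
            if len(h) != self.n_snps:
                raise ValueError(
                    f"block {self.block_id}: haplotype {h!r} has wrong length"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def marginals(self) -> dict:
        """Per-SNP allele frequencies implied by the haplotype distribution."""
        out: dict = {sid: {} for sid in self.snp_ids}
        for h, p in self.haplotype_freq.items():
            for i, sid in enumerate(self.snp_ids):
                out[sid][h[i]] = out[sid].get(h[i], 0.0) + p
        return out


@dataclass(frozen=True)
class EnvironmentTable:
    """Per-population environmental scalars, one value per parameter."""

    values: dict  # parameter_name -> {population: value}

    @property
    def parameters(self) -> list:
        return list(self.values)

    def series(self, parameter: str) -> dict:
        return dict(self.values[parameter])


# ---------------------------------------------------------------------------
# panel / environment TSV
# ---------------------------------------------------------------------------


def read_panel(path) -> PopulationPanel:
    """Read a sample/population TSV panel; duplicate samples are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "population"):
        if col not in df.columns:
            raise ValueError(f"panel {path}: missing column {col!r}")
    mapping: dict = {}
    for _, row in df.iterrows():
        sample = row["sample"]
        if sample in mapping:
            raise ValueError(f"duplicate sample {sample!r} in panel {path}")
        pop = row["population"]
        if pd.isna(pop) or not str(pop).strip():
            raise ValueError(f"sample {sample!r} has an empty population")
        mapping[sample] = str(pop)
    return PopulationPanel(mapping)


def write_panel(panel: PopulationPanel, path) -> None:
    pd.DataFrame(
        {
            "sample": list(panel.sample_to_population),
            "population": list(panel.sample_to_population.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def read_environment(path) -> EnvironmentTable:
    df = pd.read_csv(path, sep="\t", dtype={"parameter": str, "population": str})
    for col in ("parameter", "population", "value"):
        if col not in df.columns:
            raise ValueError(f"environment file {path}: missing column {col!r}")
    values: dict = {}
    for _, row in df.iterrows():
        param = values.setdefault(row["parameter"], {})
        if row["population"] in param:
            raise ValueError(
                f"duplicate value for {row['parameter']}/{row['population']}"
            )
        param[row["population"]] = float(row["value"])
    return EnvironmentTable(values)


def write_environment(env: EnvironmentTable, path) -> None:
    rows = [
        {"parameter": param, "population": pop, "value": v}
        for param, series in env.values.items()
        for pop, v in series.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_tenv(path) -> dict:
    """Read per-population environmental potentials (columns population, t_env)."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    for col in ("population", "t_env"):
        if col not in df.columns:
            raise ValueError(f"t_env file {path}: missing column {col!r}")
    out = {}
    for _, row in df.iterrows():
        if row["population"] in out:
            raise ValueError(f"duplicate population {row['population']!r}")
        out[row["population"]] = float(row["t_env"])
    return out


def write_tenv(t_env: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"population": list(t_env), "t_env": list(t_env.values())}
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# frequency table TSV
# ---------------------------------------------------------------------------


def write_frequency_table(table: AlleleFrequencyTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_frequency_table(path) -> AlleleFrequencyTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "chrom": str, "allele": str, "population": str}
    )
    required = {"snp_id", "chrom", "pos", "allele", "population", "freq"}
    if not required.issubset(df.columns):
        raise ValueError(f"frequency table {path}: needs columns {sorted(required)}")
    populations = list(dict.fromkeys(df["population"]))
    snps = []
    freqs: dict = {}
    for snp_id, grp in df.groupby("snp_id", sort=False):
        alleles = list(dict.fromkeys(grp["allele"]))
        if len(alleles) != 2:
            raise ValueError(f"{snp_id}: expected 2 alleles, found {alleles}")
        # major = allele with the larger mean frequency across populations
        means = grp.groupby("allele")["freq"].mean()
        major = max(alleles, key=lambda a: (means[a], a == alleles[0]))
        minor = next(a for a in alleles if a != major)
        snps.append(
            SnpInfo(
                snp_id=str(snp_id),
                chrom=str(grp["chrom"].iloc[0]),
                pos=int(grp["pos"].iloc[0]),
                allele_major=major,
                allele_minor=minor,
            )
        )
        for _, row in grp.iterrows():
            freqs.setdefault((snp_id, row["population"]), {})[row["allele"]] = float(
                row["freq"]
            )
    return AlleleFrequencyTable(snps, populations, freqs)


# ---------------------------------------------------------------------------
# block TSV
# ---------------------------------------------------------------------------


def write_blocks(blocks: Iterable[HaploblockRecord], path) -> None:
    """Write blocks with their haplotype distributions (one row per haplotype)."""
    rows = []
    for blk in blocks:
        for h, p in blk.haplotype_freq.items():
            rows.append(
                {
                    "block_id": blk.block_id,
                    "population": blk.population_code,
                    "snp_ids": ",".join(blk.snp_ids),
                    "haplotype": h,
                    "freq": p,
                }
            )
    pd.DataFrame(
        rows, columns=["block_id", "population", "snp_ids", "haplotype", "freq"]
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_blocks(path) -> list:
    """Read a block TSV.

    With ``haplotype``/``freq`` columns the haplotype distribution is taken
    verbatim; a membership-only file (just block_id, population, snp_ids)
    raises, since the potentials need haplotype frequencies — recompute them
    from the phased VCF in that case.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("block_id", "population", "snp_ids"):
        if col not in df.columns:
            raise ValueError(f"block file {path}: missing column {col!r}")
    if "haplotype" not in df.columns or "freq" not in df.columns:
        raise ValueError(
            f"block file {path} lists membership only; haplotype frequencies "
            "are required (columns haplotype, freq) or must be recomputed "
            "from a phased VCF"
        )
    blocks = []
    for (block_id, pop), grp in df.groupby(["block_id", "population"], sort=False):
        snp_lists = set(grp["snp_ids"])
        if len(snp_lists) != 1:
            raise ValueError(f"block {block_id}/{pop}: inconsistent snp_ids")
        snp_ids = tuple(next(iter(snp_lists)).split(","))
        hfreq = {
            row["haplotype"]: float(row["freq"]) for _, row in grp.iterrows()
        }
        blocks.append(
            HaploblockRecord(
                block_id=str(block_id),
                population_code=str(pop),
                snp_ids=snp_ids,
                haplotype_freq=hfreq,
            )
        )
    return blocks


def read_block_membership(path) -> list:
    """Read (block_id, population, snp_ids) triples from a block TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("block_id", "population", "snp_ids"):
        if col not in df.columns:
            raise ValueError(f"block file {path}: missing column {col!r}")
    out = []
    for (block_id, pop), grp in df.groupby(["block_id", "population"], sort=False):
        snp_ids = tuple(next(iter(set(grp["snp_ids"]))).split(","))
        out.append((str(block_id), str(pop), snp_ids))
    return out


# ---------------------------------------------------------------------------
# VCF ingestion (cyvcf2)
# ---------------------------------------------------------------------------


def _open_vcf(path):
    from cyvcf2 import VCF

    return VCF(str(path))


def _panel_indices(vcf_samples, panel: PopulationPanel) -> dict:
    """Column indices per population; errors on samples absent from the panel."""
    unknown = [s for s in vcf_samples if s not in panel.sample_to_population]
    if unknown:
        raise ValueError(f"VCF samples absent from panel: {unknown}")
    idx: dict = {pop: [] for pop in panel.populations}
    for i, s in enumerate(vcf_samples):
        idx[panel.population_of(s)].append(i)
    return {pop: cols for pop, cols in idx.items() if cols}


def frequencies_from_vcf(vcf_path, panel: PopulationPanel) -> AlleleFrequencyTable:
    """Per-population allele frequencies by counting diploid genotypes.

    Missing genotypes are excluded from numerator and denominator.
    Multi-allelic records are skipped, counted and logged; monomorphic
    records are retained.  Counting is integer arithmetic before division.
    """
    vcf = _open_vcf(vcf_path)
    idx = _panel_indices(vcf.samples, panel)
    populations = list(idx)
    snps = []
    freqs: dict = {}
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) > 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s at %s:%d",
                var.ID or ".",
                var.CHROM,
                var.POS,
            )
            continue
        ref = var.REF
        alt = var.ALT[0] if var.ALT else "."
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        pop_counts = {}
        total_alt = 0
        total_called = 0
        for pop, cols in idx.items():
            alt_count = 0
            called = 0
            for c in cols:
                for a in gts[c][:2]:
                    if a >= 0:
                        called += 1
                        if a == 1:
                            alt_count += 1
            pop_counts[pop] = (alt_count, called)
            total_alt += alt_count
            total_called += called
        if total_called == 0:
            logger.warning("no called genotypes at %s; skipped", snp_id)
            continue
        # pooled majority decides the major/minor labels; ties go to REF
        if 2 * total_alt > total_called:
            major, minor = alt, ref
        else:
            major, minor = ref, alt
        snps.append(
            SnpInfo(snp_id, str(var.CHROM), int(var.POS), major, minor)
        )
        for pop, (alt_count, called) in pop_counts.items():
            p_alt = alt_count / called if called else 0.0
            freqs[(snp_id, pop)] = {ref: 1.0 - p_alt, alt: p_alt}
            if ref == alt:  # degenerate, should not happen in practice
                freqs[(snp_id, pop)] = {ref: 1.0}
    table = AlleleFrequencyTable(snps, populations, freqs)
    table.n_multiallelic_skipped = n_skipped
    return table


def _phased_haplotypes(vcf_path, panel: PopulationPanel, snp_ids):
    """Phased allele matrix per population for the requested SNPs.

    Returns (ordered snp ids, alleles per snp as (ref, alt),
    {population: int8 array of shape (n_chromosomes, n_snps)}); chromosomes
    with a missing genotype at any requested SNP are dropped.
    """
    wanted = set(snp_ids)
    vcf = _open_vcf(vcf_path)
    idx = _panel_indices(vcf.samples, panel)
    found: dict = {}
    alleles: dict = {}
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id not in wanted or len(var.ALT) > 1:
            continue
        gts = var.genotypes
        per_pop = {}
        for pop, cols in idx.items():
            hap = np.full((2 * len(cols),), -1, dtype=np.int8)
            for j, c in enumerate(cols):
                a0, a1, phased = gts[c][0], gts[c][1], gts[c][2]
                het = a0 >= 0 and a1 >= 0 and a0 != a1
                if het and not phased:
                    raise ValueError(
                        f"unphased heterozygote at {snp_id} for a block "
                        "member; phased genotypes are required"
                    )
                hap[2 * j] = a0
                hap[2 * j + 1] = a1
            per_pop[pop] = hap
        found[snp_id] = per_pop
        alleles[snp_id] = (var.REF, var.ALT[0] if var.ALT else ".")
    missing = [s for s in snp_ids if s not in found]
    if missing:
        raise ValueError(f"SNPs absent from VCF: {missing}")
    ordered = [s for s in snp_ids]
    mats = {}
    for pop in idx:
        cols = [found[s][pop] for s in ordered]
        mat = np.stack(cols, axis=1)
        keep = (mat >= 0).all(axis=1)
        mats[pop] = mat[keep]
    return ordered, alleles, mats


def haplotype_frequencies(
    vcf_path,
    panel: PopulationPanel,
    snp_ids: Sequence[str],
    *,
    block_id: str | None = None,
    populations: Sequence[str] | None = None,
) -> list:
    """Count phased haplotype frequencies for one SNP set, per population."""
    ordered, alleles, mats = _phased_haplotypes(vcf_path, panel, snp_ids)
    if populations is None:
        populations = list(mats)
    records = []
    for pop in populations:
        mat = mats[pop]
        if mat.shape[0] == 0:
            raise ValueError(f"no complete phased chromosomes for {pop}")
        counts: dict = {}
        for row in mat:
            h = "".join(
                alleles[s][int(a)] for s, a in zip(ordered, row)
            )
            counts[h] = counts.get(h, 0) + 1
        total = mat.shape[0]
        records.append(
            HaploblockRecord(
                block_id=block_id or "-".join([ordered[0], ordered[-1]]),
                population_code=pop,
                snp_ids=tuple(ordered),
                haplotype_freq={h: c / total for h, c in counts.items()},
            )
        )
    return records


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """LD r^2 between two 0/1 haplotype vectors; 0 if either is monomorphic."""
    px, py = x.mean(), y.mean()
    vx, vy = px * (1 - px), py * (1 - py)
    if vx <= 0 or vy <= 0:
        return 0.0
    d = (x * y).mean() - px * py
    return float(d * d / (vx * vy))


def detect_blocks(
    vcf_path,
    panel: PopulationPanel,
    *,
    r2_threshold: float = 0.8,
) -> list:
    """Greedy left-to-right adjacency merge of consecutive high-LD SNPs.

    Within each chromosome and population, a SNP joins the current block
    while its r^2 with the previous SNP meets the threshold; blocks of at
    least two SNPs are emitted with counted haplotype frequencies.  Supplied
    block files always take precedence over this simple detector.
    """
    vcf = _open_vcf(vcf_path)
    idx = _panel_indices(vcf.samples, panel)
    order: list = []  # (chrom, snp_id)
    for var in vcf:
        if len(var.ALT) > 1:
            continue
        order.append((str(var.CHROM), var.ID or f"{var.CHROM}:{var.POS}"))
    if not order:
        return []
    all_ids = [sid for _, sid in order]
    _, alleles, mats = _phased_haplotypes(vcf_path, panel, all_ids)
    col = {sid: i for i, sid in enumerate(all_ids)}
    blocks = []
    for pop, mat in mats.items():
        if mat.shape[0] == 0:
            continue
        counter = 0
        run: list = []
        prev_chrom = None
        for chrom, sid in order:
            extend = (
                run
                and chrom == prev_chrom
                and _r_squared(
                    mat[:, col[run[-1]]].astype(float),
                    mat[:, col[sid]].astype(float),
                )
                >= r2_threshold
            )
            if extend:
                run.append(sid)
            else:
                if len(run) >= 2:
                    counter += 1
                    blocks.extend(
                        haplotype_frequencies(
                            vcf_path,
                            panel,
                            run,
                            block_id=f"{pop}_blk{counter}",
                            populations=[pop],
                        )
                    )
                run = [sid]
            prev_chrom = chrom
        if len(run) >= 2:
            counter += 1
            blocks.extend(
                haplotype_frequencies(
                    vcf_path, panel, run, block_id=f"{pop}_blk{counter}",
                    populations=[pop],
                )
            )
    return blocks
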