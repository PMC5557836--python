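"""Synthetic multi-population diploid genotype data with known ground truth.

The generator produces everything the analysis stages consume — genotypes,
read depths, gene models, a genome sequence, a genetic map — from a single
seed, together with a :class:`TruthTrack` recording the latent state
(ancestry blocks, sweep intervals, ancestral allele frequencies) so that
recovery can be scored exactly.

Generative model
----------------
* SNP positions: Poisson along each chromosome at the configured density.
* Ancestral allele frequency per site ``q ~ Beta(0.8, 0.8)`` — a U-shaped
  spectrum resembling a neutral site-frequency spectrum.
* Population frequencies follow the Balding–Nichols model:
  ``p_i ~ Beta(q(1-F)/F, (1-q)(1-F)/F)`` with per-population drift ``F``.
* An optional admixed population is a block mosaic: each chromosome is tiled
  with blocks of fixed length, each block's source drawn from the configured
  source fractions; block frequencies are copied from the source population
  and perturbed by residual drift.  A ``None`` source stands for ancestry
  from an unsampled contributor (frequencies drawn fresh with their own
  drift), which downstream ancestry calls should label uncertain.
* Sweeps: inside each sweep interval the target population's frequencies are
  rounded to 0/1, collapsing diversity — a frequency-fixation implant, not a
  hitchhiking simulation, but sufficient to create the diversity contrast a
  sweep filter must detect.
* Genotypes ``~ Binomial(2, p)``; missingness masked uniformly at random;
  read depths ``~ Poisson(lambda)`` with alt reads ``~ Binomial(depth, f)``
  where ``f`` is the allelic fraction perturbed by the error rate.

Sites are simulated independently, so the default output has no linkage
disequilibrium beyond what drift induces; LD-specific tests build correlated
blocks explicitly via :func:`simulate_ld_blocks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    DepthTable,
    GeneModel,
    GeneModelSet,
    GeneticMap,
    GenotypeDataset,
    PopulationGrouping,
)

_BASES = np.array(list("ACGT"))


@dataclass
class PopulationSpec:
    """One sampled population.

    ``F`` is the Balding-Nichols drift from the common ancestor.  For a
    population representing a distinct species, ``F_within`` adds a second
    drift level: the species' site frequencies are first drawn with ``F``
    (deep divergence, pushing many sites toward alternate fixation between
    species) and the sampled population's frequencies are then drawn around
    them with ``F_within`` (within-species diversity).
    """

    label: str
    n: int
    F: float  # Balding-Nichols drift, in (0, 1)
    F_within: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.F < 1):
            raise ValueError(f"population {self.label}: F must be in (0,1), got {self.F}")
        if self.F_within is not None and not (0 < self.F_within < 1):
            raise ValueError(f"population {self.label}: F_within must be in (0,1)")
        if self.n < 1:
            raise ValueError(f"population {self.label}: n must be >=1")


@dataclass
class AdmixedSpec:
    """Block-mosaic population drawing ancestry from named sources.

    ``source_fractions`` maps source population label -> genome fraction;
    a ``None`` key denotes an unsampled contributor whose block frequencies
    are drawn fresh from the ancestral spectrum with ``novel_F`` drift.
    """

    label: str
    n: int
    block_length: int
    source_fractions: dict[str | None, float]
    residual_F: float = 0.02
    novel_F: float = 0.3

    def __post_init__(self) -> None:
        total = sum(self.source_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"source fractions sum to {total}, not 1")
        for frac in self.source_fractions.values():
            if not (0 <= frac <= 1):
                raise ValueError("source fractions must lie in [0,1]")
        if self.block_length < 1:
            raise ValueError("block length must be positive")


@dataclass
class SweepSpec:
    chrom: str
    start: int
    end: int
    target: str


@dataclass
class SimulationConfig:
    """All knobs of the generator; one seed drives every stage."""

    seed: int
    chromosomes: list[tuple[str, int]]
    populations: list[PopulationSpec]
    admixed: AdmixedSpec | None = None
    sweeps: list[SweepSpec] = field(default_factory=list)
    snp_density: float = 0.002  # expected SNPs per bp
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    missing_rate: float = 0.02
    depth_mean: float = 12.0  # mean mapped-read depth per accession-site
    depth_error: float = 0.01  # per-read miscall rate
    gene_spacing: int = 5000
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.admixed is not None:
            max_len = max(length for _, length in self.chromosomes)
            if self.admixed.block_length > max_len:
                raise ValueError("admixed block length exceeds every chromosome length")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing rate must be in [0,1)")


@dataclass
class TruthTrack:
    """Latent simulation state for scoring recovery.

    blocks: (chrom, start, end, source label or None) tiling each chromosome
    of the admixed population; sweeps: implanted intervals; ancestral_freq:
    per-site ancestral allele frequency aligned with the dataset's sites.
    """

    blocks: list[tuple[str, int, int, str | None]]
    sweeps: list[SweepSpec]
    ancestral_freq: np.ndarray
    seed: int = 0


@dataclass
class SimulationResult:
    dataset: GenotypeDataset
    depths: DepthTable
    truth: TruthTrack
    genes: GeneModelSet
    grouping: PopulationGrouping
    genome: dict[str, str]
    genetic_map: GeneticMap


def _balding_nichols(rng: np.random.Generator, q: np.ndarray, F: float) -> np.ndarray:
    q = np.clip(q, 1e-9, 1 - 1e-9)
    scale = (1 - F) / F
    return rng.beta(q * scale, (1 - q) * scale)


def _toy_genes(chromosomes: list[tuple[str, int]], spacing: int) -> GeneModelSet:
    """Tile simple 3-exon genes over the genome, alternating strands."""
    genes = []
    k = 0
    for chrom, length in chromosomes:
        start = 1001
        while start + 1300 <= length:
            strand = "+" if k % 2 == 0 else "-"
            cds = [(start, start + 299, 0), (start + 500, start + 799, 0), (start + 1000, start + 1299, 0)]
            if strand == "+":
                phases = [0, (3 - 300 % 3) % 3, (3 - 600 % 3) % 3]
            else:
                phases = [(3 - 600 % 3) % 3, (3 - 300 % 3) % 3, 0]
            cds = [(s, e, p) for (s, e, _), p in zip(cds, phases)]
            genes.append(GeneModel(f"gene{k:05d}", chrom, strand, cds))
            k += 1
            start += spacing
    return GeneModelSet(genes)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the generative model; see the module docstring for its definition."""
    root = np.random.SeedSequence(config.seed)
    (ss_pos, ss_freq, ss_geno, ss_miss, ss_depth, ss_seq, ss_adm) = root.spawn(7)
    rng_pos = np.random.default_rng(ss_pos)
    rng_freq = np.random.default_rng(ss_freq)
    rng_geno = np.random.default_rng(ss_geno)
    rng_miss = np.random.default_rng(ss_miss)
    rng_depth = np.random.default_rng(ss_depth)
    rng_seq = np.random.default_rng(ss_seq)
    rng_adm = np.random.default_rng(ss_adm)

    pop_labels = [p.label for p in config.populations]
    pops = {p.label: p for p in config.populations}

    genome: dict[str, str] = {}
    gmap_anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    site_frames: list[pd.DataFrame] = []
    freq_by_pop: dict[str, list[np.ndarray]] = {p.label: [] for p in config.populations}
    adm_freqs: list[np.ndarray] = []
    q_all: list[np.ndarray] = []
    blocks: list[tuple[str, int, int, str | None]] = []

    for chrom, length in config.chromosomes:
        seq = rng_seq.choice(_BASES, size=length)
        n_snps = rng_pos.poisson(config.snp_density * length)
        pos = np.unique(rng_pos.integers(1, length + 1, size=n_snps))
        a, b = config.ancestral_beta
        q = rng_freq.beta(a, b, size=len(pos))
        q_all.append(q)
        ref = seq[pos - 1]
        # alt drawn uniformly from the three non-ref bases
        offsets = rng_freq.integers(1, 4, size=len(pos))
        base_idx = np.searchsorted(_BASES, ref)
        alt = _BASES[(base_idx + offsets) % 4]
        genome[chrom] = "".join(seq)
        gmap_anchors[chrom] = (
            np.array([0, length]),
            np.array([0.0, length / 1e6 * config.cm_per_mb]),
        )
        site_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}))

        chrom_pop_freq: dict[str, np.ndarray] = {}
        for p in config.populations:
            pf = _balding_nichols(rng_freq, q, p.F)
            if p.F_within is not None:
                pf = _balding_nichols(rng_freq, pf, p.F_within)
            chrom_pop_freq[p.label] = pf

        if config.admixed is not None:
            adm = config.admixed
            p_adm = np.empty(len(pos))
            edges = list(range(1, length + 1, adm.block_length)) + [length + 1]
            labels = list(adm.source_fractions.keys())
            weights = np.array([adm.source_fractions[l] for l in labels])
            for lo, hi in zip(edges[:-1], edges[1:]):
                src = labels[rng_adm.choice(len(labels), p=weights)]
                mask = (pos >= lo) & (pos < hi)
                if src is None:
                    p_blk = _balding_nichols(rng_adm, q[mask], adm.novel_F)
                else:
                    p_blk = _balding_nichols(rng_adm, chrom_pop_freq[src][mask], adm.residual_F)
                p_adm[mask] = p_blk
                blocks.append((chrom, lo, hi - 1, src))
            # sweeps targeting the admixed population
            for sw in config.sweeps:
                if sw.target == adm.label and sw.chrom == chrom:
                    m = (pos >= sw.start) & (pos <= sw.end)
                    p_adm[m] = np.round(p_adm[m])
            adm_freqs.append(p_adm)

        for p in config.populations:
            pf = chrom_pop_freq[p.label]
            for sw in config.sweeps:
                if sw.target == p.label and sw.chrom == chrom:
                    m = (pos >= sw.start) & (pos <= sw.end)
                    pf[m] = np.round(pf[m])
            freq_by_pop[p.label].append(pf)

    sites = pd.concat(site_frames, ignore_index=True)
    n_sites = len(sites)

    accessions: list[str] = []
    group_map: dict[str, list[str]] = {}
    dosage_rows: list[np.ndarray] = []
    for p in config.populations:
        freqs = np.concatenate(freq_by_pop[p.label])
        for i in range(p.n):
            acc = f"{p.label}_{i + 1:03d}"
            accessions.append(acc)
            group_map.setdefault(p.label, []).append(acc)
            dosage_rows.append(rng_geno.binomial(2, freqs).astype(np.int8))
    if config.admixed is not None:
        freqs = np.concatenate(adm_freqs)
        for i in range(config.admixed.n):
            acc = f"{config.admixed.label}_{i + 1:03d}"
            accessions.append(acc)
            group_map.setdefault(config.admixed.label, []).append(acc)
            dosage_rows.append(rng_geno.binomial(2, freqs).astype(np.int8))

    dosages = np.stack(dosage_rows) if dosage_rows else np.zeros((0, n_sites), dtype=np.int8)

    # read depths from the true (pre-masking) dosages
    total = rng_depth.poisson(config.depth_mean, size=dosages.shape).astype(np.int32)
    e = config.depth_error
    f_alt = dosages / 2.0 * (1 - e) + (1 - dosages / 2.0) * e
    alt_reads = rng_depth.binomial(total, np.clip(f_alt, 0, 1)).astype(np.int32)

    if config.missing_rate > 0:
        mask = rng_miss.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    dataset = GenotypeDataset(accessions, sites, dosages)
    depths = DepthTable(accessions, sites.copy(), total, alt_reads)
    truth = TruthTrack(
        blocks=blocks,
        sweeps=list(config.sweeps),
        ancestral_freq=np.concatenate(q_all) if q_all else np.empty(0),
        seed=config.seed,
    )
    genes = _toy_genes(config.chromosomes, config.gene_spacing)
    grouping = PopulationGrouping.from_dict(group_map)
    return SimulationResult(
        dataset, depths, truth, genes, grouping, genome, GeneticMap(gmap_anchors)
    )


def truth_ancestry_fractions(truth: TruthTrack) -> dict[str | None, float]:
    """Genome fraction per ancestry source, by bp of truth blocks; sums to 1."""
    if not truth.blocks:
        raise ValueError("truth track has no ancestry blocks")
    total = 0
    per_source: dict[str | None, int] = {}
    for _, start, end, src in truth.blocks:
        span = end - start + 1
        total += span
        per_source[src] = per_source.get(src, 0) + span
    return {src: bp / total for src, bp in per_source.items()}


def simulate_ld_blocks(
    seed: int,
    n_accessions: int = 50,
    n_blocks: int = 40,
    snps_per_block: int = 10,
    block_span: int = 5000,
    block_gap: int = 50000,
    rho: float = 0.9,
    chrom: str = "chr1",
) -> GenotypeDataset:
    """Correlated-block genotypes for LD-decay tests.

    The default site-independent simulator carries no linkage, so this helper
    builds haplotype blocks explicitly: within a block, each haplotype copies
    a block founder allele with probability ``rho`` per site (else an
    independent Bernoulli draw), producing high r-squared within blocks and
    none between blocks.
    """
    rng = np.random.default_rng(seed)
    pos_list: list[int] = []
    hap1 = np.zeros((n_accessions, n_blocks * snps_per_block), dtype=np.int8)
    hap2 = np.zeros_like(hap1)
    col = 0
    start = 1
    for _ in range(n_blocks):
        p = rng.uniform(0.2, 0.8, size=snps_per_block)
        offsets = np.sort(rng.choice(np.arange(block_span), size=snps_per_block, replace=False))
        for hap in (hap1, hap2):
            founder = rng.random(n_accessions) < 0.5
            for j in range(snps_per_block):
                copy = rng.random(n_accessions) < rho
                independent = rng.random(n_accessions) < p[j]
                hap[:, col + j] = np.where(copy, founder, independent)
        pos_list.extend(int(start + o) for o in offsets)
        col += snps_per_block
        start += block_gap
    dosages = (hap1 + hap2).astype(np.int8)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos_list, "ref": "A", "alt": "C"}
    )
    labels = [f"acc_{i + 1:03d}" for i in range(n_accessions)]
    return GenotypeDataset(labels, sites, dosages)
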