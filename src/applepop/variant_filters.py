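"""Genotype-calling filters, SNP-set selections, and codon-degeneracy logic.

The calling rule assigns an allele as *present* in an accession when it is
supported by at least ``min_reads`` reads and makes up at least ``min_af`` of
that accession's reads at the site (the read-fraction reading of the allele
frequency threshold; it sits inside per-accession genotype assignment).
Site-level filters then drop close SNP pairs, heterozygous-only sites, and
sites with too much missing data.

Threshold boundaries follow their wording exactly: "more than 50% missing"
is strict, "MAF >= 5%" and "missing rate <= 10%" are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, DepthTable, GeneModel, GeneModelSet, GenotypeDataset

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# third-position fourfold codon families of the standard code, by first two
# bases in transcription orientation
_FOURFOLD_PREFIXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

_CODON_TABLE: dict[str, str] = {}


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon, "X")


@dataclass
class FilterReport:
    """Per-rule removal counts for one :func:`filter_sites` run.

    A site violating several rules is counted once, under the first rule in
    the order: proximity, heterozygous-only, missingness.
    """

    input_sites: int = 0
    removed_proximity: int = 0
    removed_het_only: int = 0
    removed_missingness: int = 0
    removed_min_reads: int = 0
    removed_allele_freq: int = 0
    retained: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_proximity
            + self.removed_het_only
            + self.removed_missingness
            + self.removed_min_reads
            + self.removed_allele_freq
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_sites", self.input_sites),
            ("removed_proximity", self.removed_proximity),
            ("removed_het_only", self.removed_het_only),
            ("removed_missingness", self.removed_missingness),
            ("retained", self.retained),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def call_genotypes(
    depths: DepthTable, min_reads: int = 2, min_af: float = 0.3
) -> GenotypeDataset:
    """Call dosages from read support.

    An allele is present iff its read count is ``>= min_reads`` and its read
    fraction is ``>= min_af``; ref and alt are judged symmetrically.  Both
    present -> 1, alt only -> 2, ref only -> 0, neither (or zero depth) ->
    missing.
    """
    if not (0 <= min_af <= 1):
        raise ValueError(f"min_af must be in [0,1], got {min_af}")
    total = depths.total.astype(np.float64)
    alt = depths.alt.astype(np.float64)
    ref = total - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_frac = np.where(total > 0, alt / total, 0.0)
        ref_frac = np.where(total > 0, ref / total, 0.0)
    alt_present = (depths.alt >= min_reads) & (alt_frac >= min_af)
    ref_present = ((depths.total - depths.alt) >= min_reads) & (ref_frac >= min_af)
    dosages = np.full(depths.total.shape, MISSING, dtype=np.int8)
    dosages[ref_present & ~alt_present] = 0
    dosages[ref_present & alt_present] = 1
    dosages[~ref_present & alt_present] = 2
    return GenotypeDataset(list(depths.accession_ids), depths.sites.copy(), dosages)


def filter_sites(
    dataset: GenotypeDataset, min_spacing: int = 5, max_missing: float = 0.5
) -> tuple[GenotypeDataset, FilterReport]:
    """Drop close SNP pairs, heterozygous-only sites, and high-missingness sites.

    Proximity is symmetric: both members of a pair closer than ``min_spacing``
    bp are removed (distances measured on the input coordinates, so the
    operation is idempotent).  ``max_missing`` is a strict bound: a site is
    removed only when its missing fraction exceeds it.
    """
    report = FilterReport(input_sites=dataset.n_sites)
    n = dataset.n_sites
    keep = np.ones(n, dtype=bool)
    reason = np.zeros(n, dtype=np.int8)  # 0 keep, 1 proximity, 2 het-only, 3 missing

    pos = dataset.sites["pos"].to_numpy()
    chroms = dataset.sites["chrom"].to_numpy()
    same_chrom = chroms[1:] == chroms[:-1]
    close = same_chrom & (np.diff(pos) < min_spacing)
    prox = np.zeros(n, dtype=bool)
    prox[:-1] |= close
    prox[1:] |= close
    reason[prox] = 1

    dos = dataset.dosages
    missing = dos == MISSING
    n_nonmissing = (~missing).sum(axis=0)
    n_het = (dos == 1).sum(axis=0)
    het_only = (n_nonmissing > 0) & (n_het == n_nonmissing)
    reason[(reason == 0) & het_only] = 2

    frac_missing = missing.sum(axis=0) / max(dataset.n_accessions, 1)
    too_missing = frac_missing > max_missing
    reason[(reason == 0) & too_missing] = 3

    keep = reason == 0
    report.removed_proximity = int((reason == 1).sum())
    report.removed_het_only = int((reason == 2).sum())
    report.removed_missingness = int((reason == 3).sum())
    report.retained = int(keep.sum())
    return dataset.take_sites(np.flatnonzero(keep)), report


def site_maf(dataset: GenotypeDataset) -> np.ndarray:
    """Minor allele frequency per site over non-missing calls (0 where no calls)."""
    dos = dataset.dosages
    missing = dos == MISSING
    alt_count = np.where(missing, 0, dos).sum(axis=0)
    allele_n = 2 * (~missing).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(allele_n > 0, alt_count / np.maximum(allele_n, 1), 0.0)
    return np.minimum(p, 1 - p)


def maf_missing_filter(
    dataset: GenotypeDataset, min_maf: float = 0.05, max_missing: float = 0.10
) -> GenotypeDataset:
    """Keep sites with MAF >= ``min_maf`` and missing rate <= ``max_missing``
    (both boundaries inclusive)."""
    maf = site_maf(dataset)
    miss = (dataset.dosages == MISSING).sum(axis=0) / max(dataset.n_accessions, 1)
    keep = (maf >= min_maf) & (miss <= max_missing)
    return dataset.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Codon logic
# ---------------------------------------------------------------------------

def _coding_positions(gene: GeneModel) -> np.ndarray:
    """Genomic positions of coding bases in transcription order, after
    trimming the initial phase."""
    if gene.strand == "+":
        pos = np.concatenate([np.arange(s, e + 1) for s, e, _ in gene.cds])
        phase = gene.cds[0][2]
        return pos[phase:]
    pos = np.concatenate([np.arange(e, s - 1, -1) for s, e, _ in reversed(gene.cds)])
    phase = gene.cds[-1][2]
    return pos[phase:]


def _gene_codon_context(
    gene: GeneModel, genome: dict[str, str]
) -> tuple[np.ndarray, np.ndarray] | None:
    """(coding genomic positions, codon index array) or None if malformed."""
    pos = _coding_positions(gene)
    if len(pos) % 3 != 0:
        warnings.warn(f"gene {gene.gene_id}: CDS length not divisible by 3; skipped")
        return None
    return pos, np.arange(len(pos))


def _codon_for(
    gene: GeneModel, genome: dict[str, str], coding_pos: np.ndarray, idx: int
) -> tuple[str, int]:
    """Codon string (transcription orientation) containing coding index
    ``idx`` and the within-codon offset of that index."""
    seq = genome[gene.chrom]
    codon_start = (idx // 3) * 3
    bases = []
    for k in range(3):
        gpos = int(coding_pos[codon_start + k])
        b = seq[gpos - 1]
        if gene.strand == "-":
            b = b.translate(_COMPLEMENT)
        bases.append(b)
    return "".join(bases), idx % 3


def _site_frames(
    dataset: GenotypeDataset, genes: GeneModelSet, genome: dict[str, str]
):
    """For each dataset site, the list of (gene, coding_pos array, coding idx)
    frames covering it.  Malformed genes are skipped with a warning."""
    frames: list[list] = [[] for _ in range(dataset.n_sites)]
    site_pos = {
        chrom: (sub["pos"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in dataset.sites.groupby("chrom", sort=False)
    }
    for gene in genes.genes:
        if gene.chrom not in site_pos:
            continue
        ctx = _gene_codon_context(gene, genome)
        if ctx is None:
            continue
        coding_pos, _ = ctx
        pos_arr, global_idx = site_pos[gene.chrom]
        lo, hi = gene.span
        sel = np.flatnonzero((pos_arr >= lo) & (pos_arr <= hi))
        if len(sel) == 0:
            continue
        lookup = {int(p): i for i, p in enumerate(coding_pos)}
        for s in sel:
            idx = lookup.get(int(pos_arr[s]))
            if idx is not None:
                frames[int(global_idx[s])].append((gene, coding_pos, idx))
    return frames


def _is_fourfold(gene: GeneModel, genome: dict[str, str], coding_pos: np.ndarray, idx: int) -> bool:
    codon, offset = _codon_for(gene, genome, coding_pos, idx)
    return offset == 2 and codon[:2] in _FOURFOLD_PREFIXES


def fourfold_degenerate_sites(
    dataset: GenotypeDataset, genes: GeneModelSet, genome: dict[str, str]
) -> GenotypeDataset:
    """Subset to SNPs at fourfold degenerate third codon positions.

    Strand and CDS phase are honored.  A SNP covered by several coding frames
    is kept only if it is fourfold degenerate in every one of them.
    """
    frames = _site_frames(dataset, genes, genome)
    keep = [
        j
        for j, fr in enumerate(frames)
        if fr and all(_is_fourfold(g, genome, cp, idx) for g, cp, idx in fr)
    ]
    return dataset.take_sites(np.array(keep, dtype=int))


def classify_coding_effect(
    snp: tuple[str, int, str, str], genes: GeneModelSet, genome: dict[str, str]
) -> str:
    """Classify one SNP (chrom, pos, ref, alt) as synonymous / nonsynonymous /
    noncoding by translating the codon before and after substitution.

    With several overlapping frames, any nonsynonymous frame wins.
    """
    chrom, pos, ref, alt = snp
    effects = []
    for gene in genes.genes:
        if gene.chrom != chrom:
            continue
        lo, hi = gene.span
        if not (lo <= pos <= hi):
            continue
        ctx = _gene_codon_context(gene, genome)
        if ctx is None:
            continue
        coding_pos, _ = ctx
        hits = np.flatnonzero(coding_pos == pos)
        if len(hits) == 0:
            continue
        idx = int(hits[0])
        codon, offset = _codon_for(gene, genome, coding_pos, idx)
        ref_b, alt_b = ref, alt
        if gene.strand == "-":
            ref_b = ref_b.translate(_COMPLEMENT)
            alt_b = alt_b.translate(_COMPLEMENT)
        ref_codon = codon[:offset] + ref_b + codon[offset + 1 :]
        alt_codon = codon[:offset] + alt_b + codon[offset + 1 :]
        effects.append(
            "synonymous" if _translate(ref_codon) == _translate(alt_codon) else "nonsynonymous"
        )
    if not effects:
        return "noncoding"
    return "nonsynonymous" if "nonsynonymous" in effects else "synonymous"
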