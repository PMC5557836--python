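"""Major-allele ancestry assignment for an admixed (domesticated) population.

The procedure asks, site by site, whether the domesticated group shares its
major allele (frequency strictly > 0.6 among non-missing calls) with the
progenitor group or with the secondary (introgressor) group, then classifies
non-overlapping 100-kb windows: a window derives from the progenitor when
progenitor-matching sites outnumber introgressor-matching sites more than
two-fold AND the window holds more than five SNPs (both strict); the
mirrored rule assigns the introgressor; everything else is uncertain.

Sites whose major allele matches both wild groups count toward both tallies
— they dilute the ratio naturally, since the procedure defines no exclusion
rule for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, PopulationGrouping, Region

PROGENITOR = "progenitor"
INTROGRESSOR = "introgressor"
UNCERTAIN = "uncertain"
BOTH = "both"
NONE = "none"


@dataclass
class AncestryCall:
    """One window's ancestry label with its site tallies."""

    chrom: str
    start: int  # 1-based
    width: int
    label: str
    n_progenitor: int
    n_introgressor: int
    n_total: int


def major_allele(dosages: np.ndarray, threshold: float = 0.6) -> int | None:
    """The allele (0 = ref, 1 = alt) with frequency strictly above
    ``threshold`` among non-missing calls, else None."""
    dosages = np.asarray(dosages)
    called = dosages != MISSING
    if not called.any():
        return None
    alt = dosages[called].sum()
    n = 2 * called.sum()
    p_alt = alt / n
    if p_alt > threshold:
        return 1
    if 1 - p_alt > threshold:
        return 0
    return None


def assign_site(dom_major, siek_major, syl_major) -> str:
    """Per-site ancestry: progenitor / introgressor / both / none."""
    if dom_major is None:
        return NONE
    matches_p = siek_major is not None and dom_major == siek_major
    matches_i = syl_major is not None and dom_major == syl_major
    if matches_p and matches_i:
        return BOTH
    if matches_p:
        return PROGENITOR
    if matches_i:
        return INTROGRESSOR
    return NONE


def ancestry_snp_set(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    groups: list[str],
    min_maf: float = 0.05,
    max_missing: float = 0.10,
) -> GenotypeDataset:
    """The SNP set scanned for ancestry: MAF and missing-rate gates computed
    over the pooled accessions of the groups under comparison.

    Sites near-monomorphic across the whole trio carry no ancestry signal
    (every group shares the same major allele) and fall below the MAF gate;
    computing MAF on the analyzed accessions rather than a wider panel is
    what removes them.
    """
    from .variant_filters import maf_missing_filter

    members = [a for g in groups for a in grouping.members(g)]
    sub = dataset.take_accessions([a for a in members if a in dataset.accession_ids])
    kept = maf_missing_filter(sub, min_maf=min_maf, max_missing=max_missing)
    key = set(zip(kept.sites["chrom"], kept.sites["pos"]))
    mask = [
        (c, p) in key
        for c, p in zip(dataset.sites["chrom"], dataset.sites["pos"])
    ]
    return dataset.take_sites(np.flatnonzero(mask))


def site_assignments(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    dom_group: str,
    progenitor_group: str,
    introgressor_group: str,
    threshold: float = 0.6,
) -> np.ndarray:
    """Vectorized per-site assignment over the whole dataset."""

    def group_major(group: str) -> np.ndarray:
        dos = dataset.dosages[grouping.indices(dataset, group)]
        called = dos != MISSING
        alt = np.where(called, dos, 0).sum(axis=0).astype(float)
        n = 2.0 * called.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        major = np.full(dataset.n_sites, -9, dtype=np.int8)  # -9 = none
        major[p > threshold] = 1
        major[(1 - p) > threshold] = 0
        return major

    dom = group_major(dom_group)
    pro = group_major(progenitor_group)
    intro = group_major(introgressor_group)
    out = np.full(dataset.n_sites, NONE, dtype=object)
    has_dom = dom != -9
    m_p = has_dom & (pro != -9) & (dom == pro)
    m_i = has_dom & (intro != -9) & (dom == intro)
    out[m_p & ~m_i] = PROGENITOR
    out[m_i & ~m_p] = INTROGRESSOR
    out[m_p & m_i] = BOTH
    return out


def classify_windows(
    assignments: np.ndarray,
    dataset: GenotypeDataset,
    width: int = 100000,
    ratio: float = 2.0,
    min_snps: int = 5,
    chrom_lengths: dict[str, int] | None = None,
    total_mode: str = "all",
) -> list[AncestryCall]:
    """Tile each chromosome with fixed windows and label their ancestry.

    ``assignments`` aligns with ``dataset.sites``.  "Both"-assigned sites
    increment both tallies; ``n_total`` counts every scanned SNP in the
    window (``total_mode='assigned'`` counts only source-assigned sites
    instead — the alternative reading of "total SNP count").  The label rule
    is strict on both inequalities.  With ``chrom_lengths`` the windows tile
    whole chromosomes (so SNP-free terminal windows exist and are
    uncertain); otherwise they extend to the last SNP.
    """
    if total_mode not in ("all", "assigned"):
        raise ValueError(f"unknown total_mode {total_mode!r}")
    calls: list[AncestryCall] = []
    chrom_of = dataset.sites["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_of):
        sub = dataset.sites[chrom_of == chrom]
        pos = sub["pos"].to_numpy()
        asn = assignments[sub.index.to_numpy()]
        if chrom_lengths and chrom in chrom_lengths:
            n_windows = int(np.ceil(chrom_lengths[chrom] / width))
        else:
            n_windows = int((pos.max() - 1) // width) + 1 if len(pos) else 0
        win = (pos - 1) // width
        for w in range(n_windows):
            in_w = win == w
            if total_mode == "all":
                total = int(in_w.sum())
            else:
                total = int((asn != NONE)[in_w].sum())
            c_p = int(((asn == PROGENITOR) | (asn == BOTH))[in_w].sum())
            c_i = int(((asn == INTROGRESSOR) | (asn == BOTH))[in_w].sum())
            if total > min_snps and c_p > ratio * c_i:
                label = PROGENITOR
            elif total > min_snps and c_i > ratio * c_p:
                label = INTROGRESSOR
            else:
                label = UNCERTAIN
            calls.append(AncestryCall(chrom, w * width + 1, width, label, c_p, c_i, total))
    return calls


def genome_fractions(
    calls: list[AncestryCall], chrom_lengths: dict[str, int] | None = None
) -> dict[str, float]:
    """Percentage of the genome per ancestry label, weighted by bp.

    Terminal windows are weighted by their actual span when
    ``chrom_lengths`` is given.  Percentages sum to 100 within rounding.
    """
    if not calls:
        raise ValueError("no ancestry calls")
    weights = {PROGENITOR: 0.0, INTROGRESSOR: 0.0, UNCERTAIN: 0.0}
    total = 0.0
    for c in calls:
        span = c.width
        if chrom_lengths and c.chrom in chrom_lengths:
            span = min(c.start + c.width - 1, chrom_lengths[c.chrom]) - c.start + 1
            if span <= 0:
                continue
        weights[c.label] += span
        total += span
    return {label: 100.0 * bp / total for label, bp in weights.items()}


def calls_to_frame(calls: list[AncestryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.width, c.label, c.n_progenitor, c.n_introgressor, c.n_total)
            for c in calls
        ],
        columns=["chrom", "start", "width", "label", "n_progenitor", "n_introgressor", "n_total"],
    )


def calls_to_regions(calls: list[AncestryCall]) -> dict[str, list[Region]]:
    """Per-label region lists, e.g. for colored BED output."""
    out: dict[str, list[Region]] = {PROGENITOR: [], INTROGRESSOR: [], UNCERTAIN: []}
    for c in calls:
        out[c.label].append(Region(c.chrom, c.start, c.start + c.width - 1))
    return out
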