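"""Windowed diversity, differentiation, LD decay, and HWE testing.

Estimator choices
-----------------
* Nucleotide diversity: per-site unbiased heterozygosity
  ``pi_site = n/(n-1) * (1 - sum_a p_a^2)`` over the ``n`` non-missing
  alleles of the group (equals the mean pairwise difference among allele
  copies), summed per fixed-width window and divided by the window width in
  bp.  The callable-bp denominator is available via ``denominator``.
* F_ST: Weir & Cockerham (1984) variance components ``a`` (among
  populations), ``b`` (among individuals within populations), ``c`` (within
  individuals); the multi-locus estimate is the ratio of averages
  ``sum(a) / sum(a+b+c)``.  Loci with a zero denominator are skipped.
* LD: composite (genotype-dosage) r-squared over accessions non-missing at
  both sites, after MAF and Hardy-Weinberg gating of sites.
* HWE: exact conditional test — enumerate every heterozygote count
  compatible with the observed allele counts and sum the probabilities no
  larger than that of the observed configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import spearmanr

from .io_formats import MISSING, GenotypeDataset, PopulationGrouping, Region


@dataclass
class WindowTrack:
    """Fixed-width, non-overlapping per-window values along chromosomes.

    ``table`` columns: chrom, start (1-based), width, value, n_sites.
    ``value`` is NaN for windows flagged missing.
    """

    table: pd.DataFrame
    width: int

    def values_for(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def to_regions(self) -> list[Region]:
        return [
            Region(r.chrom, int(r.start), int(r.start) + self.width - 1,
                   None if np.isnan(r.value) else float(r.value))
            for r in self.table.itertuples(index=False)
        ]

    def write_tsv(self, path: str, header_comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for comment in header_comments or []:
                fh.write(f"#{comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def per_site_pi(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site diversity and the non-missing allele count.

    Sites with fewer than two called alleles get pi = 0 and are reported with
    their allele count so callers can exclude them from site tallies.
    """
    missing = dosages == MISSING
    alt = np.where(missing, 0, dosages).sum(axis=0).astype(float)
    n = 2.0 * (~missing).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        h = 2 * p * (1 - p)
        pi = np.where(n >= 2, n / np.maximum(n - 1, 1) * h, 0.0)
    return pi, n


def pi_windows(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    group: str,
    width: int = 10000,
    denominator: str = "window",
) -> WindowTrack:
    """Windowed nucleotide diversity for one group.

    ``denominator='window'`` divides the summed per-site diversity by the
    window width in bp (the default); ``'sites'`` divides by the number of
    polymorphic-capable (>=2 alleles called) sites instead.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    idx = grouping.indices(dataset, group)
    if len(idx) < 2:
        raise ValueError(f"group {group!r} needs >=2 accessions in the dataset")
    pi, n_alleles = per_site_pi(dataset.dosages[idx])
    rows = []
    for chrom, sub in dataset.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        site_idx = sub.index.to_numpy()
        win = (pos - 1) // width
        for w in range(int(win.max()) + 1 if len(win) else 0):
            in_w = site_idx[win == w]
            usable = in_w[n_alleles[in_w] >= 2]
            total = float(pi[usable].sum())
            if denominator == "window":
                value = total / width
            elif denominator == "sites":
                value = total / len(usable) if len(usable) else 0.0
            else:
                raise ValueError(f"unknown denominator {denominator!r}")
            rows.append((chrom, w * width + 1, width, value, len(usable)))
    table = pd.DataFrame(rows, columns=["chrom", "start", "width", "value", "n_sites"])
    return WindowTrack(table, width)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_components(group_dosages: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for r populations.

    Each array in ``group_dosages`` is (n_individuals, n_loci) with MISSING
    sentinels.  Loci where any population has no non-missing call, or where
    the mean sample size is <= 1, get NaN components.
    """
    r = len(group_dosages)
    if r < 2:
        raise ValueError("need >=2 populations")
    n_i, p_i, h_i = [], [], []
    for dos in group_dosages:
        miss = dos == MISSING
        n = (~miss).sum(axis=0).astype(float)
        alt = np.where(miss, 0, dos).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h = np.where(n > 0, (dos == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)  # (r, L)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)

    nbar = n_i.mean(axis=0)
    valid = (n_i > 0).all(axis=0) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = ~valid | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _group_dosages(
    dataset: GenotypeDataset, grouping: PopulationGrouping, groups: list[str]
) -> list[np.ndarray]:
    out = []
    for g in groups:
        idx = grouping.indices(dataset, g)
        dos = dataset.dosages[idx]
        if ((dos != MISSING).sum(axis=0) >= 2).sum() == 0:
            raise ValueError(f"group {g!r} has <2 non-missing calls at every locus")
        out.append(dos)
    return out


def multilocus_fst(
    dataset: GenotypeDataset, grouping: PopulationGrouping, groups: list[str]
) -> float:
    """Ratio-of-averages WC84 F_ST over all usable loci."""
    a, b, c = wc_components(_group_dosages(dataset, grouping, groups))
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def pairwise_fst(dataset: GenotypeDataset, grouping: PopulationGrouping) -> FstMatrix:
    """Pairwise multi-locus WC84 F_ST among all groups of the grouping."""
    labels = grouping.group_labels
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = multilocus_fst(dataset, grouping, [labels[i], labels[j]])
    return FstMatrix(labels, mat)


def per_snp_fst(
    dataset: GenotypeDataset, grouping: PopulationGrouping, group_a: str, group_b: str
) -> np.ndarray:
    """Single-locus WC84 F_ST (a/(a+b+c)) per site; NaN where undefined.

    Negative values are kept — they carry rank information."""
    a, b, c = wc_components(_group_dosages(dataset, grouping, [group_a, group_b]))
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(np.isfinite(denom) & (denom != 0), a / denom, np.nan)
    return fst


def per_snp_fst_top(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    group_a: str,
    group_b: str,
    top_frac: float = 0.01,
) -> pd.DataFrame:
    """The most divergent SNPs between two groups, by single-locus F_ST.

    Retains ``ceil(top_frac * n_sites)`` SNPs; ties at the cutoff are all
    retained.  Returns the site table with an ``fst`` column, ranked
    descending.
    """
    n = dataset.n_sites
    if n == 0:
        return dataset.sites.assign(fst=pd.Series(dtype=float)).iloc[0:0]
    fst = per_snp_fst(dataset, grouping, group_a, group_b)
    k = int(np.ceil(top_frac * n))
    order = np.argsort(-np.where(np.isfinite(fst), fst, -np.inf), kind="stable")
    cutoff = fst[order[k - 1]] if k >= 1 else np.inf
    keep = np.flatnonzero(np.isfinite(fst) & (fst >= cutoff))
    keep = keep[np.argsort(-fst[keep], kind="stable")]
    out = dataset.sites.iloc[keep].copy()
    out["fst"] = fst[keep]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

def mds_embed(fst: FstMatrix, dims: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) scaling of a distance-like matrix.

    Returns the ``(n, dims)`` embedding and the Spearman rank correlation
    between embedded Euclidean distances and the input values over all pairs.
    Negative eigenvalues are truncated to zero; if the matrix's Euclidean
    rank is below ``dims`` the extra coordinates are zero-padded (with a
    warning).
    """
    D = np.asarray(fst.matrix, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    rank = int((eigval > 1e-12 * max(eigval.max(), 1e-300)).sum())
    if dims > rank:
        warnings.warn(f"requested {dims} dimensions but Euclidean rank is {rank}; zero-padding")
    lam = np.clip(eigval[:dims], 0, None)
    coords = eigvec[:, :dims] * np.sqrt(lam)
    iu = np.triu_indices(n, k=1)
    embedded = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if len(iu[0]) < 2 or np.allclose(D[iu], D[iu][0]):
        rho = 1.0
    else:
        rho = float(spearmanr(embedded[iu], D[iu]).statistic)
    return coords, rho


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _log_hwe_prob(n_het: np.ndarray, n: int, n_a: int) -> np.ndarray:
    """log P(n_het | n individuals, n_a copies of allele A) under HWE."""
    n_het = np.asarray(n_het)
    n_aa = (n_a - n_het) // 2
    n_bb = n - n_aa - n_het
    n_b = 2 * n - n_a
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_het + 1)
        - gammaln(n_bb + 1)
        + n_het * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact(genotype_counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa).  All configurations with the
    observed allele counts are enumerated; the p-value is the summed
    probability of configurations no more probable than the observed one.
    """
    n_aa_hom, n_het, n_bb_hom = (int(x) for x in genotype_counts)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        return 1.0
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    max_het = min(n_a, n_b)
    hets = np.arange(n_a % 2, max_het + 1, 2)
    logp = _log_hwe_prob(hets, n, n_a)
    logp -= np.logaddexp.reduce(logp)  # exact renormalization
    obs = logp[np.flatnonzero(hets == n_het)[0]]
    p = float(np.exp(logp[logp <= obs + 1e-12]).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    group: str,
    min_maf: float = 0.10,
    hwe_cutoff: float = 0.001,
    window_bp: int = 500000,
    bins: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """Mean genotype r-squared by physical distance within one group.

    Sites failing MAF >= ``min_maf`` or with HWE exact p <= ``hwe_cutoff``
    are excluded.  Every remaining pair within ``window_bp`` on the same
    chromosome contributes its squared Pearson correlation of dosages over
    accessions non-missing at both sites; pairs where either site has zero
    variance are skipped.  Returns a frame with columns
    ``bin_lo, bin_hi, mean_r2, n_pairs`` — empty bins are absent.
    """
    idx = grouping.indices(dataset, group)
    if len(idx) < 4:
        raise ValueError(f"group {group!r} needs >=4 accessions")
    if bins is None:
        bins = np.linspace(0, window_bp, 11)
    bins = np.asarray(bins, dtype=float)

    dos = dataset.dosages[idx].astype(float)
    dos[dataset.dosages[idx] == MISSING] = np.nan

    # site gating within the group
    keep = np.zeros(dataset.n_sites, dtype=bool)
    for j in range(dataset.n_sites):
        col = dos[:, j]
        called = col[~np.isnan(col)]
        if len(called) == 0:
            continue
        p = called.sum() / (2 * len(called))
        if min(p, 1 - p) < min_maf:
            continue
        counts = (int((called == 0).sum()), int((called == 1).sum()), int((called == 2).sum()))
        if hwe_exact(counts) <= hwe_cutoff:
            continue
        keep[j] = True

    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1, dtype=int)
    for chrom, sub in dataset.sites.groupby("chrom", sort=False):
        site_idx = sub.index.to_numpy()[keep[sub.index.to_numpy()]]
        pos = dataset.sites["pos"].to_numpy()[site_idx]
        X = dos[:, site_idx]
        for a in range(len(site_idx)):
            hi = np.searchsorted(pos, pos[a] + window_bp, side="right")
            for b in range(a + 1, hi):
                both = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
                if both.sum() < 2:
                    continue
                xa, xb = X[both, a], X[both, b]
                if xa.std() == 0 or xb.std() == 0:
                    continue
                r = np.corrcoef(xa, xb)[0, 1]
                d = pos[b] - pos[a]
                k = int(np.searchsorted(bins, d, side="right")) - 1
                if 0 <= k < len(sums):
                    sums[k] += r * r
                    counts[k] += 1
    rows = [
        (bins[k], bins[k + 1], sums[k] / counts[k], int(counts[k]))
        for k in range(len(sums))
        if counts[k] > 0
    ]
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])
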