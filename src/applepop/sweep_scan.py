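"""Cross-population composite-likelihood sweep scan (XP-CLR-style).

Model
-----
For a putative sweep location x in the object population, each SNP j within
a window of +/- 0.025 cM around x contributes a likelihood ratio between a
neutral and a sweep model of the object allele count ``k_j`` out of ``n_j``:

* Neutral: the object frequency p is the reference frequency ``p_ref``
  perturbed by drift — a Normal(p_ref, omega * p_ref(1-p_ref)) truncated to
  (0,1), with the truncated tail mass placed as point masses at 0 and 1.
  ``L0_j = Integral Binom(k_j | n_j, p) dPhi(p)`` (midpoint quadrature plus
  the boundary masses).
* Sweep: with effective selection parameter ``s`` and genetic distance
  ``d_j`` (Morgans) from x, a lineage escapes the sweep with probability
  ``c_j = 1 - exp(-d_j / s)``; with probability ``1 - c_j`` the site is
  dragged to fixation of whichever allele was swept, giving
  ``L1_j(s) = c_j L0_j + (1 - c_j) (p_ref 1{k=n} + (1-p_ref) 1{k=0})``.

SNPs are down-weighted for linkage: ``w_j = 1/m_j`` with ``m_j`` the number
of window SNPs whose reference-population dosage r-squared with j is at or
above the correlation level (0.7), including j itself.  The score at x is
``max(0, 2 * max_s sum_j w_j (log L1_j(s) - log L0_j))``.  Because
``L1 <= L0`` whenever the window has no object-fixed site, the score is
exactly zero there.

SNPs fixed in the reference (p_ref of 0 or 1) carry no frequency contrast
and are excluded from windows.  The drift scale omega defaults to the
method-of-moments value ``F_ST / (1 - F_ST)`` from the genome-wide WC84
F_ST of the two groups.

Downstream, the paper-style region calling applies: 10-kb window averaging
of the 100-bp grid, joining windows at >= 80% of the genome-wide mean,
single-gap merging, top-10% region selection by the maximal member-window
score, and a diversity-ratio filter keeping the top half by
pi(reference)/pi(object).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import MISSING, GeneModelSet, GeneticMap, GenotypeDataset, PopulationGrouping
from .popgen_stats import WindowTrack, multilocus_fst, per_site_pi


@dataclass
class ScanParams:
    """Scan parameters; defaults mirror '-w1 0.0005 100 100 -p0 0.7'."""

    grid_spacing: int = 100  # bp between scored points
    window_half_cm: float = 0.025  # half of the 0.05 cM window
    max_snps: int = 100  # per window, nearest kept
    corr_level: float = 0.7  # r^2 at/above which SNPs share weight
    sel_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-5, -1, 12)
    )  # effective selection parameters, Morgans
    omega: float | None = None  # None -> estimate from genome-wide F_ST
    n_quad: int = 1000  # interior quadrature points

    def __post_init__(self) -> None:
        self.sel_grid = np.asarray(self.sel_grid, dtype=float)
        if self.sel_grid.size == 0 or np.any(self.sel_grid <= 0):
            raise ValueError("selection grid must be non-empty and positive")
        if self.grid_spacing <= 0 or self.window_half_cm <= 0 or self.n_quad < 2:
            raise ValueError("scan parameters must be positive")


@dataclass
class SweepRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    score: float
    n_windows: int
    pi_ratio: float | None = None
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end < start")


def interpolate_cM(gmap: GeneticMap, chrom: str, positions) -> np.ndarray:
    """Piecewise-linear bp -> cM; positions beyond the anchors extrapolate at
    the chromosome's mean cM/bp rate."""
    if chrom not in gmap.anchors:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    bp, cm = gmap.anchors[chrom]
    positions = np.asarray(positions, dtype=float)
    out = np.interp(positions, bp, cm)
    rate = (cm[-1] - cm[0]) / (bp[-1] - bp[0])
    left = positions < bp[0]
    right = positions > bp[-1]
    out[left] = cm[0] - (bp[0] - positions[left]) * rate
    out[right] = cm[-1] + (positions[right] - bp[-1]) * rate
    return out


# ---------------------------------------------------------------------------
# Per-SNP ingredients
# ---------------------------------------------------------------------------

def _ref_freq(ref_dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference allele frequency and allele count per site."""
    called = ref_dos != MISSING
    n = 2.0 * called.sum(axis=0)
    alt = np.where(called, ref_dos, 0).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def _obj_counts(obj_dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = obj_dos != MISSING
    n = (2 * called.sum(axis=0)).astype(float)
    k = np.where(called, obj_dos, 0).sum(axis=0).astype(float)
    return n, k


def neutral_loglik(
    p_ref: np.ndarray, n: np.ndarray, k: np.ndarray, omega: float, n_quad: int = 1000
) -> np.ndarray:
    """log L0 per SNP: binomial marginal under truncated-Normal drift.

    Vectorized midpoint quadrature with boundary point masses; chunked to
    bound memory.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    p_ref = np.asarray(p_ref, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    T = n_quad
    t = (np.arange(T) + 0.5) / T  # interior points
    out = np.empty(len(p_ref))
    from scipy.special import gammaln

    log_binom = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    for lo in range(0, len(p_ref), 2048):
        hi = min(lo + 2048, len(p_ref))
        p = p_ref[lo:hi, None]
        sigma = np.sqrt(omega * p * (1 - p))
        sigma = np.maximum(sigma, 1e-12)
        dens = norm.pdf(t[None, :], loc=p, scale=sigma) / T
        mass0 = norm.cdf(0.0, loc=p[:, 0], scale=sigma[:, 0])
        mass1 = norm.sf(1.0, loc=p[:, 0], scale=sigma[:, 0])
        total = dens.sum(axis=1) + mass0 + mass1
        total = np.maximum(total, 1e-300)
        nn = n[lo:hi, None]
        kk = k[lo:hi, None]
        with np.errstate(divide="ignore"):
            log_pmf = (
                log_binom[lo:hi, None]
                + kk * np.log(t[None, :])
                + (nn - kk) * np.log1p(-t[None, :])
            )
        interior = (dens * np.exp(log_pmf)).sum(axis=1)
        L0 = interior + mass0 * (k[lo:hi] == 0) + mass1 * (k[lo:hi] == n[lo:hi])
        L0 /= total
        out[lo:hi] = np.log(np.maximum(L0, 1e-300))
    return out


def _fixation_mass(p_ref: np.ndarray, n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """A_j = p_ref 1{k=n} + (1-p_ref) 1{k=0} — the sweep fixation term."""
    return p_ref * (k == n) + (1 - p_ref) * (k == 0)


def composite_score(
    ref_dos: np.ndarray,
    obj_dos: np.ndarray,
    site_cm: np.ndarray,
    grid_cm: float,
    params: ScanParams,
    omega: float,
) -> float | None:
    """Composite likelihood-ratio score at one grid point.

    ``ref_dos``/``obj_dos`` are (individuals, window SNPs) dosage slices for
    SNPs already inside the window; ``site_cm`` their map positions.
    Returns None when no SNP is usable.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    site_cm = np.asarray(site_cm, dtype=float)
    p_ref, n_ref = _ref_freq(ref_dos)
    n_obj, k_obj = _obj_counts(obj_dos)
    usable = (n_ref >= 2) & (p_ref > 0) & (p_ref < 1) & (n_obj >= 1)
    if not usable.any():
        return None
    order = np.flatnonzero(usable)
    if len(order) > params.max_snps:  # keep the nearest
        d = np.abs(site_cm[order] - grid_cm)
        order = order[np.argsort(d, kind="stable")[: params.max_snps]]
        order.sort()
    p_ref, n_obj, k_obj = p_ref[order], n_obj[order], k_obj[order]
    cm = site_cm[order]
    logL0 = neutral_loglik(p_ref, n_obj, k_obj, omega, params.n_quad)
    A = _fixation_mass(p_ref, n_obj, k_obj)
    R = A / np.exp(logL0)

    # linkage weights from reference-dosage r^2 among the window SNPs
    X = ref_dos[:, order].astype(float)
    X[ref_dos[:, order] == MISSING] = np.nan
    m = np.ones(len(order))
    for j in range(len(order)):
        for l in range(len(order)):
            if l == j:
                continue
            both = ~np.isnan(X[:, j]) & ~np.isnan(X[:, l])
            if both.sum() < 2:
                continue
            xa, xb = X[both, j], X[both, l]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            if r * r >= params.corr_level:
                m[j] += 1
    w = 1.0 / m

    d = np.abs(cm - grid_cm) / 100.0  # Morgans
    best = -np.inf
    with np.errstate(divide="ignore"):
        for s in params.sel_grid:
            c = -np.expm1(-d / s)
            term = np.log(c + (1 - c) * R)
            best = max(best, float((w * term).sum()))
    return max(0.0, 2.0 * best)


# ---------------------------------------------------------------------------
# Chromosome scan (vectorized)
# ---------------------------------------------------------------------------

def _band_weight_cumsum(ref_dos: np.ndarray, cm: np.ndarray, params: ScanParams):
    """Banded r^2 >= corr_level adjacency, cumulative along offsets.

    Returns (C, b): C has shape (S, 2b+2); the count of correlated partners
    of SNP j with index in [j+o1, j+o2] is C[j, o2+b+1] - C[j, o1+b].
    """
    S = ref_dos.shape[1]
    span = 2 * params.window_half_cm
    # widest index distance over which two SNPs can share a window
    b = 1
    for j in range(S):
        hi = np.searchsorted(cm, cm[j] + span, side="right")
        b = max(b, hi - j - 1)
    b = min(b, max(params.max_snps, 1))
    X = ref_dos.astype(float)
    X[ref_dos == MISSING] = np.nan
    valid = ~np.isnan(X)
    Xz = np.where(valid, X, 0.0)
    adj = np.zeros((S, 2 * b + 1), dtype=bool)
    adj[:, b] = True  # self
    for o in range(1, b + 1):
        a_cols = slice(0, S - o)
        b_cols = slice(o, S)
        both = valid[:, a_cols] & valid[:, b_cols]
        nb = both.sum(axis=0)
        xa = np.where(both, Xz[:, a_cols], 0.0)
        xb = np.where(both, Xz[:, b_cols], 0.0)
        sa, sb = xa.sum(axis=0), xb.sum(axis=0)
        saa, sbb = (xa**2).sum(axis=0), (xb**2).sum(axis=0)
        sab = (xa * xb).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sab - sa * sb / np.maximum(nb, 1)
            va = saa - sa**2 / np.maximum(nb, 1)
            vb = sbb - sb**2 / np.maximum(nb, 1)
            r2 = np.where((va > 0) & (vb > 0) & (nb >= 2), cov**2 / (va * vb), 0.0)
        hit = r2 >= params.corr_level
        adj[:S - o, b + o] = hit
        adj[o:, b - o] = hit
    C = np.zeros((S, 2 * b + 2))
    C[:, 1:] = np.cumsum(adj, axis=1)
    return C, b


def scan_chromosome(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    ref_group: str,
    obj_group: str,
    gmap: GeneticMap,
    chrom: str,
    params: ScanParams | None = None,
    omega: float | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Composite scores on the 100-bp grid of one chromosome.

    Returns columns ``chrom, pos, score`` with NaN at grid points whose
    window holds no usable SNP.  ``omega`` must be supplied (estimate it
    once genome-wide with :func:`estimate_omega`) unless set in ``params``.
    """
    params = params or ScanParams()
    if omega is None:
        omega = params.omega
    if omega is None:
        omega = estimate_omega(dataset, grouping, ref_group, obj_group)
    if omega <= 0:
        raise ValueError("omega must be positive")

    mask = dataset.sites["chrom"].to_numpy() == chrom
    sub_idx = np.flatnonzero(mask)
    pos = dataset.sites["pos"].to_numpy()[sub_idx]
    length = chrom_length or (int(pos.max()) if len(pos) else 0)
    grid = np.arange(params.grid_spacing, length + 1, params.grid_spacing)
    if len(grid) == 0:
        return pd.DataFrame({"chrom": [], "pos": [], "score": []})
    scores = np.full(len(grid), np.nan)
    if len(pos) == 0:
        return pd.DataFrame({"chrom": chrom, "pos": grid, "score": scores})

    ref_dos = dataset.dosages[grouping.indices(dataset, ref_group)][:, sub_idx]
    obj_dos = dataset.dosages[grouping.indices(dataset, obj_group)][:, sub_idx]
    p_ref, n_ref = _ref_freq(ref_dos)
    n_obj, k_obj = _obj_counts(obj_dos)
    usable = (n_ref >= 2) & (p_ref > 0) & (p_ref < 1) & (n_obj >= 1)
    if not usable.any():
        return pd.DataFrame({"chrom": chrom, "pos": grid, "score": scores})

    keep = np.flatnonzero(usable)
    pos_u = pos[keep]
    cm = interpolate_cM(gmap, chrom, pos_u)
    p_ref, n_obj, k_obj = p_ref[keep], n_obj[keep], k_obj[keep]
    ref_u = ref_dos[:, keep]
    logL0 = neutral_loglik(p_ref, n_obj, k_obj, omega, params.n_quad)
    R = _fixation_mass(p_ref, n_obj, k_obj) / np.exp(logL0)
    C, band = _band_weight_cumsum(ref_u, cm, params)

    grid_cm = interpolate_cM(gmap, chrom, grid)
    lo = np.searchsorted(cm, grid_cm - params.window_half_cm, side="left")
    hi = np.searchsorted(cm, grid_cm + params.window_half_cm, side="right")
    # trim windows to the nearest max_snps (kept set stays contiguous)
    over = np.flatnonzero(hi - lo > params.max_snps)
    for g in over:
        a, bnd = int(lo[g]), int(hi[g])
        while bnd - a > params.max_snps:
            if grid_cm[g] - cm[a] >= cm[bnd - 1] - grid_cm[g]:
                a += 1
            else:
                bnd -= 1
        lo[g], hi[g] = a, bnd

    counts = hi - lo
    nonempty = np.flatnonzero(counts > 0)
    if len(nonempty) == 0:
        return pd.DataFrame({"chrom": chrom, "pos": grid, "score": scores})

    chunk = 20000
    for c0 in range(0, len(nonempty), chunk):
        gsel = nonempty[c0 : c0 + chunk]
        cnt = counts[gsel]
        starts = np.zeros(len(gsel) + 1, dtype=np.int64)
        np.cumsum(cnt, out=starts[1:])
        total = int(starts[-1])
        rep = np.repeat(np.arange(len(gsel)), cnt)
        j_flat = np.arange(total) - np.repeat(starts[:-1], cnt) + np.repeat(lo[gsel], cnt)
        lo_rep = np.repeat(lo[gsel], cnt)
        hi_rep = np.repeat(hi[gsel], cnt)
        o1 = np.maximum(lo_rep - j_flat, -band)
        o2 = np.minimum(hi_rep - 1 - j_flat, band)
        m = C[j_flat, o2 + band + 1] - C[j_flat, o1 + band]
        w = 1.0 / np.maximum(m, 1.0)
        d = np.abs(cm[j_flat] - np.repeat(grid_cm[gsel], cnt)) / 100.0
        Rf = R[j_flat]
        best = np.full(len(gsel), -np.inf)
        seg = starts[:-1]
        with np.errstate(divide="ignore"):
            for s in params.sel_grid:
                cc = -np.expm1(-d / s)
                term = w * np.log(cc + (1 - cc) * Rf)
                sums = np.add.reduceat(term, seg)
                sums[cnt == 0] = -np.inf
                np.maximum(best, sums, out=best)
        scores[gsel] = np.maximum(0.0, 2.0 * best)
    return pd.DataFrame({"chrom": chrom, "pos": grid, "score": scores})


def estimate_omega(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    ref_group: str,
    obj_group: str,
) -> float:
    """Method-of-moments drift scale: omega = F_ST / (1 - F_ST)."""
    fst = multilocus_fst(dataset, grouping, [ref_group, obj_group])
    fst = min(max(fst, 1e-4), 0.99)
    return fst / (1 - fst)


# ---------------------------------------------------------------------------
# Window averaging, region calling, filters
# ---------------------------------------------------------------------------

def window_average(grid_scores: pd.DataFrame, width: int = 10000) -> WindowTrack:
    """Mean of non-missing grid scores per fixed window; empty windows NaN."""
    rows = []
    for chrom, sub in grid_scores.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        val = sub["score"].to_numpy(dtype=float)
        win = (pos - 1) // width
        n_windows = int(win.max()) + 1 if len(win) else 0
        for wdx in range(n_windows):
            v = val[win == wdx]
            v = v[~np.isnan(v)]
            rows.append(
                (chrom, wdx * width + 1, width, v.mean() if len(v) else np.nan, len(v))
            )
    return WindowTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "width", "value", "n_sites"]), width
    )


def merge_regions(
    track: WindowTrack,
    join_frac: float = 0.8,
    top_frac: float = 0.10,
    threshold: float | None = None,
) -> list[SweepRegion]:
    """Join high-score windows into regions and keep the top fraction.

    The join threshold is ``join_frac`` times the genome-wide mean of
    non-missing window scores (pass ``threshold`` to override it, e.g. with
    a per-chromosome mean).  Maximal runs of windows at/above threshold
    become regions; two regions separated by exactly one scored window below
    threshold are merged (the gap window joins the span).  The region score
    is the maximum member-window mean.  ``ceil(top_frac * n_regions)``
    regions are kept, with ties at the cutoff retained.
    """
    values = track.table["value"].to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if len(finite) == 0:
        return []
    if threshold is None:
        threshold = join_frac * finite.mean()
    regions: list[SweepRegion] = []
    width = track.width
    for chrom, sub in track.table.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        qual = ~np.isnan(vals) & (vals >= threshold)
        runs: list[list[int]] = []
        i = 0
        while i < len(vals):
            if qual[i]:
                j = i
                while j + 1 < len(vals) and qual[j + 1]:
                    j += 1
                runs.append([i, j])
                i = j + 1
            else:
                i += 1
        # merge runs separated by exactly one scored, below-threshold window
        merged: list[list[int]] = []
        for run in runs:
            if (
                merged
                and run[0] - merged[-1][1] == 2
                and not np.isnan(vals[run[0] - 1])
            ):
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for i0, i1 in merged:
            member_vals = vals[i0 : i1 + 1]
            member_vals = member_vals[~np.isnan(member_vals)]
            regions.append(
                SweepRegion(
                    chrom,
                    int(starts[i0]),
                    int(starts[i1]) + width - 1,
                    float(member_vals.max()),
                    i1 - i0 + 1,
                )
            )
    if not regions:
        return []
    k = int(np.ceil(top_frac * len(regions)))
    ordered = sorted(regions, key=lambda r: -r.score)
    cutoff = ordered[k - 1].score
    return [r for r in ordered if r.score >= cutoff]


def pi_ratio_filter(
    regions: list[SweepRegion],
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    ref_group: str,
    obj_group: str,
    keep_frac: float = 0.5,
) -> list[SweepRegion]:
    """Keep the top ``keep_frac`` of regions by pi(ref)/pi(obj).

    Regions where the object group has zero diversity rank first (infinite
    ratio); ties at the cutoff are retained.
    """
    if not regions:
        return []
    ref_pi, _ = per_site_pi(dataset.dosages[grouping.indices(dataset, ref_group)])
    obj_pi, _ = per_site_pi(dataset.dosages[grouping.indices(dataset, obj_group)])
    chroms = dataset.sites["chrom"].to_numpy()
    pos = dataset.sites["pos"].to_numpy()
    for r in regions:
        m = (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end)
        num, den = float(ref_pi[m].sum()), float(obj_pi[m].sum())
        r.pi_ratio = np.inf if den == 0 else num / den
    k = int(np.ceil(keep_frac * len(regions)))
    ordered = sorted(regions, key=lambda r: -r.pi_ratio)
    cutoff = ordered[k - 1].pi_ratio
    return [r for r in ordered if r.pi_ratio >= cutoff]


def annotate_genes(regions: list[SweepRegion], genes: GeneModelSet) -> list[SweepRegion]:
    """Attach IDs of genes whose span intersects each region by >= 1 bp."""
    by_chrom = genes.by_chrom()
    for r in regions:
        hits = []
        for g in by_chrom.get(r.chrom, []):
            lo, hi = g.span
            if lo <= r.end and hi >= r.start:
                hits.append(g.gene_id)
        r.genes = sorted(hits)
    return regions


def scan_genome(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    ref_group: str,
    obj_group: str,
    gmap: GeneticMap,
    params: ScanParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Grid scores for every chromosome, with a single genome-wide omega."""
    params = params or ScanParams()
    omega = params.omega or estimate_omega(dataset, grouping, ref_group, obj_group)
    frames = []
    for chrom in dict.fromkeys(dataset.sites["chrom"]):
        frames.append(
            scan_chromosome(
                dataset, grouping, ref_group, obj_group, gmap, chrom,
                params=params, omega=omega,
                chrom_length=(chrom_lengths or {}).get(chrom),
            )
        )
    return pd.concat(frames, ignore_index=True)


def sweep_pipeline(
    dataset: GenotypeDataset,
    grouping: PopulationGrouping,
    ref_group: str,
    obj_group: str,
    gmap: GeneticMap,
    genes: GeneModelSet | None = None,
    params: ScanParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
    window_width: int = 10000,
    join_frac: float = 0.8,
    top_frac: float = 0.10,
    keep_frac: float = 0.5,
) -> tuple[pd.DataFrame, WindowTrack, list[SweepRegion]]:
    """Full scan -> average -> merge -> diversity-ratio filter -> annotate."""
    grid = scan_genome(
        dataset, grouping, ref_group, obj_group, gmap,
        params=params, chrom_lengths=chrom_lengths,
    )
    track = window_average(grid, window_width)
    regions = merge_regions(track, join_frac=join_frac, top_frac=top_frac)
    regions = pi_ratio_filter(
        regions, dataset, grouping, ref_group, obj_group, keep_frac=keep_frac
    )
    regions.sort(key=lambda r: (r.chrom, r.start))
    if genes is not None:
        regions = annotate_genes(regions, genes)
    return grid, track, regions
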