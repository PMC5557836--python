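"""Independent brute-force oracles used by the test suite.

Everything here is deliberately coded from first principles — explicit
loops, exact integer/Fraction arithmetic, pair enumeration — and kept
independent of the implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Nucleotide diversity: explicit allele-pair enumeration
# ---------------------------------------------------------------------------

def site_pi_pair_enumeration(dosages) -> float:
    """Mean pairwise difference among allele copies at one site."""
    alleles = []
    for d in dosages:
        if d == MISSING:
            continue
        alleles.extend([1] * int(d) + [0] * (2 - int(d)))
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            diff += alleles[i] != alleles[j]
    return diff / total


# ---------------------------------------------------------------------------
# Weir-Cockerham 1984, coded from the genotype-count formulation
# ---------------------------------------------------------------------------

def wc_fst_single_locus(groups: list[list[int]]):
    """(a, b, c) for one biallelic locus; ``groups`` holds dosage lists.

    Returns None when undefined (a population without data or nbar <= 1).
    """
    r = len(groups)
    stats = []
    for dosages in groups:
        called = [d for d in dosages if d != MISSING]
        if not called:
            return None
        n = len(called)
        p = sum(called) / (2 * n)
        h = sum(1 for d in called if d == 1) / n
        stats.append((n, p, h))
    nbar = sum(s[0] for s in stats) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(s[0] ** 2 for s in stats) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = sum(s[0] * s[1] for s in stats) / (r * nbar)
    s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
    hbar = sum(s[0] * s[2] for s in stats) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_fst_multilocus(group_matrices: list) -> float:
    """Ratio-of-averages F_ST over loci, looping site by site."""
    num = 0.0
    den = 0.0
    n_loci = len(group_matrices[0][0])
    for locus in range(n_loci):
        groups = [[row[locus] for row in g] for g in group_matrices]
        comps = wc_fst_single_locus(groups)
        if comps is None:
            continue
        a, b, c = comps
        if a + b + c == 0:
            continue
        num += a
        den += a + b + c
    return num / den


# ---------------------------------------------------------------------------
# HWE exact: integer-weight enumeration
# ---------------------------------------------------------------------------

def hwe_exact_fraction(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact p-value via integer configuration weights.

    Conditional on allele counts, P(n_het) is proportional to
    ``n! / (nAA! nAb! nbb!) * 2^nAb``; the common denominator cancels.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return Fraction(1)
    na = 2 * n_aa + n_ab
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return Fraction(1)

    def weight(het: int) -> int:
        aa = (na - het) // 2
        bb = n - aa - het
        return (factorial(n) // (factorial(aa) * factorial(het) * factorial(bb))) * 2**het

    hets = range(na % 2, min(na, nb) + 1, 2)
    weights = {h: weight(h) for h in hets}
    w_obs = weights[n_ab]
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(tail, total)


# ---------------------------------------------------------------------------
# Random additive trees for NJ recovery
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree; returns (edges, leaf labels, distances).

    edges: list of (node_u, node_v, length); leaves are labeled 'T0'..;
    distances: dict[(label_a, label_b)] of path lengths.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # start from a 3-leaf star; insert remaining leaves on random edges
    next_internal = [n_taxa]

    def new_internal():
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    def length():
        return float(rng.uniform(0.05, 1.0))

    center = new_internal()
    edges = [(labels[i], center, length()) for i in range(3)]
    for leaf in labels[3:]:
        k = int(rng.integers(0, len(edges)))
        u, v, l = edges.pop(k)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        edges.append((u, mid, l * split))
        edges.append((mid, v, l * (1 - split)))
        edges.append((leaf, mid, length()))
    # path distances by BFS
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, l in edges:
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    dist = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nbr, l in adj[cur]:
                if nbr not in seen:
                    seen[nbr] = seen[cur] + l
                    stack.append(nbr)
        for dst in labels:
            dist[(src, dst)] = seen[dst]
    return edges, labels, dist


def tree_edge_set(edges, labels):
    """Canonical {(bipartition frozenset, length)} for an unrooted tree,
    including pendant edges keyed by their leaf."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, l in edges:
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    label_set = frozenset(labels)
    anchor = min(labels)
    out = {}
    for u, v, l in edges:
        # leaves reachable from v without crossing u
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            cur = stack.pop()
            if cur in labels:
                side.add(cur)
            for nbr, _ in adj[cur]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if v in labels:
            side.add(v)
        side = frozenset(side)
        if anchor in side:
            side = label_set - side
        out[side] = l
    return out


# ---------------------------------------------------------------------------
# Classical scaling: independent eigendecomposition
# ---------------------------------------------------------------------------

def cmdscale_oracle(D: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson scaling via explicit double-centering loops and scipy."""
    from scipy.linalg import eigh

    n = D.shape[0]
    D2 = D * D
    B = np.zeros((n, n))
    row = D2.mean(axis=1)
    grand = D2.mean()
    for i in range(n):
        for j in range(n):
            B[i, j] = -0.5 * (D2[i, j] - row[i] - row[j] + grand)
    vals, vecs = eigh(B)
    idx = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


# ---------------------------------------------------------------------------
# Neutral marginal likelihood for the sweep model, via adaptive quadrature
# ---------------------------------------------------------------------------

def neutral_likelihood_quad(p_ref: float, n: int, k: int, omega: float) -> float:
    """High-resolution independent evaluation of the drift marginal
    Integral Binom(k|n,p) dPhi_omega(p) with boundary point masses."""
    from scipy.integrate import quad
    from scipy.stats import norm as snorm

    sigma = np.sqrt(omega * p_ref * (1 - p_ref))
    mass0 = snorm.cdf(0.0, loc=p_ref, scale=sigma)
    mass1 = snorm.sf(1.0, loc=p_ref, scale=sigma)

    def integrand(p):
        return comb(n, k) * p**k * (1 - p) ** (n - k) * snorm.pdf(p, loc=p_ref, scale=sigma)

    interior, _ = quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-13, epsrel=1e-12)
    interior_mass, _ = quad(
        lambda p: snorm.pdf(p, loc=p_ref, scale=sigma), 0.0, 1.0, limit=200,
        epsabs=1e-13, epsrel=1e-12,
    )
    total = interior_mass + mass0 + mass1
    L = interior + mass0 * (k == 0) + mass1 * (k == n)
    return L / total
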