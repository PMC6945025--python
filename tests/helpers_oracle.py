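"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity by a different route than
the package (interval enumeration, exact combinatorics, path sums on
explicit trees) so agreement is informative.
"""

from __future__ import annotations

import math
import random


# ---------------------------------------------------------- WC84 components
def wc84_oracle(groups: list[tuple[int, float, float]]) -> tuple[float, float, float, float]:
    """Evaluate the two-population variance-component algebra step by
    step from (n_i, p_i, h_i) tuples; returns (a, b, c, theta)."""
    r = len(groups)
    ns = [g[0] for g in groups]
    ps = [g[1] for g in groups]
    hs = [g[2] for g in groups]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else math.nan
    return a, b, c, theta


def counts_from_genotypes(genotypes: list[int]) -> tuple[int, float, float]:
    """(n, p, h) tallies from genotype codes with -1 = missing."""
    called = [g for g in genotypes if g >= 0]
    n = len(called)
    p = sum(called) / (2 * n)
    h = sum(1 for g in called if g == 1) / n
    return n, p, h


# ------------------------------------------------------------- DSR scanning
def dsr_oracle(
    flags: str, gap_max: int = 2, run_min: int = 6
) -> set[tuple[int, int, str]]:
    """Enumerate regions directly from the interval predicates.

    ``flags`` is a string over {'N', 'S', 'C'} (NONE / SIG-only /
    CORE).  Returns {(start_index, end_index, rule)} with 0-based
    inclusive indices, after merging overlapping/adjacent regions.
    """
    n = len(flags)
    flagged = [i for i, f in enumerate(flags) if f in "SC"]

    def valid(i: int, j: int) -> bool:
        """Endpoints flagged and no internal NONE-run longer than gap_max."""
        if flags[i] not in "SC" or flags[j] not in "SC":
            return False
        run = 0
        for k in range(i, j + 1):
            if flags[k] == "N":
                run += 1
                if run > gap_max:
                    return False
            else:
                run = 0
        return True

    # Rule 1: maximal valid intervals containing a CORE.  An interval is
    # maximal iff no flagged SNP lies within gap_max+1 positions outside
    # either end (extension would stay valid).
    core_regions = []
    for i in flagged:
        for j in flagged:
            if j < i or not valid(i, j):
                continue
            if "C" not in flags[i : j + 1]:
                continue
            left_ext = any(
                k in set(flagged) for k in range(max(0, i - gap_max - 1), i)
            )
            right_ext = any(
                k in set(flagged) for k in range(j + 1, min(n, j + gap_max + 2))
            )
            if not left_ext and not right_ext:
                core_regions.append((i, j, "CORE_SEEDED"))

    # Rule 2: maximal zero-gap runs of SIG-only flags of length >= run_min.
    run_regions = []
    i = 0
    while i < n:
        if flags[i] == "S":
            j = i
            while j + 1 < n and flags[j + 1] == "S":
                j += 1
            if j - i + 1 >= run_min:
                run_regions.append((i, j, "SIG_RUN"))
            i = j + 1
        else:
            i += 1

    # unconditional merge of overlapping or index-adjacent regions
    merged: list[list] = []
    for lo, hi, rule in sorted(core_regions + run_regions):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
            if rule == "CORE_SEEDED":
                merged[-1][2] = "CORE_SEEDED"
        else:
            merged.append([lo, hi, rule])
    return {tuple(m) for m in merged}


def random_flag_string(rng: random.Random, max_len: int = 50) -> str:
    length = rng.randint(1, max_len)
    return "".join(
        rng.choices("NSC", weights=[0.6, 0.25, 0.15], k=length)
    )


# ----------------------------------------------------------- hypergeometric
def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact summation."""
    total = 0
    denom = math.comb(N, n)
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


# ------------------------------------------------------------- random trees
def random_additive_tree(
    rng: random.Random, n_taxa: int
) -> tuple[list[str], list[list[float]]]:
    """A random unrooted binary tree with positive branch lengths,
    returned as its exact leaf-to-leaf path-length matrix.

    Built by repeatedly attaching a new leaf to a uniformly chosen
    existing edge; distances are maintained directly, so the matrix is
    additive by construction.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # start with two taxa
    d = {(0, 1): rng.uniform(0.5, 2.0)}

    def get(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return d[(min(i, j), max(i, j))]

    # attachment bookkeeping: track, for each present leaf pair, their
    # distance; attach new leaf v by picking an existing leaf u and a
    # fraction along u's pendant edge is complex — instead regrow from
    # an explicit node structure.
    # Simpler: build an explicit adjacency tree.
    # nodes: 0..n_taxa-1 leaves; internal nodes numbered from n_taxa
    edges: dict[tuple[int, int], float] = {}
    next_node = n_taxa

    def add_edge(u, v, w):
        edges[(min(u, v), max(u, v))] = w

    add_edge(0, 1, rng.uniform(0.5, 2.0))
    for leaf in range(2, n_taxa):
        # split a uniformly chosen edge with a new internal node
        (u, v), w = rng.choice(sorted(edges.items()))
        del edges[(u, v)]
        mid = next_node
        next_node += 1
        t = rng.uniform(0.2, 0.8)
        add_edge(u, mid, w * t)
        add_edge(mid, v, w * (1 - t))
        add_edge(mid, leaf, rng.uniform(0.5, 2.0))
    # all-pairs leaf distances by BFS path sums
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    mat = [[0.0] * n_taxa for _ in range(n_taxa)]
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n_taxa):
            mat[src][dst] = dist[dst]
    return labels, mat


# ------------------------------------------------------------------- Venn
def venn_oracle(a: set, b: set, c: set) -> dict[str, int]:
    """Cell counts by classifying every element of the union."""
    cells = {"100": 0, "010": 0, "001": 0, "110": 0, "101": 0, "011": 0, "111": 0}
    for x in a | b | c:
        key = f"{int(x in a)}{int(x in b)}{int(x in c)}"
        cells[key] += 1
    return cells
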