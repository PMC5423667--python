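"""Between-population structure: chord distances, neighbor-joining trees with
locus-bootstrap supports, principal coordinates, and permutation-tested
Weir-Cockerham theta.

The genetic distance is the Cavalli-Sforza & Edwards chord distance, computed
per locus from square-root allele-frequency geometry and averaged over loci;
differentiation is the Weir-Cockerham (1984) variance-components estimator
theta with two demes, combined across alleles and loci as a ratio of sums.
Both are deliberately small, explicit implementations: they are the
scientific core of this package, and each is cross-checked in the test suite
against an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeTable, allele_frequencies

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "FstResult",
    "OrdinationResult",
    "chord_distance",
    "chord_matrix",
    "nj_tree",
    "bootstrap_nj",
    "pcoa",
    "pairwise_fst",
    "fst_permutation_test",
    "fst_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix over population labels."""

    labels: list[str]
    values: np.ndarray
    metric: str = "D_CE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# -- Cavalli-Sforza & Edwards chord distance ------------------------------


def chord_distance(
    freqs_x: Mapping[str, Mapping[int, float]],
    freqs_y: Mapping[str, Mapping[int, float]],
    combine: str = "mean",
) -> float:
    """Multi-locus chord distance between two populations.

    For each locus, with allele frequency vectors x and y over the union of
    allele labels (absent alleles have frequency 0)::

        f_l = sum_a sqrt(x_a * y_a)          # cosine of the angular distance
        d_l = (2 / pi) * sqrt(2 * (1 - f_l))

    so identical profiles give 0 and disjoint allele sets give the per-locus
    maximum ``(2/pi) * sqrt(2)``. Loci undefined (no typed copies) in either
    population are dropped with a warning. The multi-locus value combines
    per-locus distances by arithmetic mean (``combine="mean"``, the default)
    or by the quadratic mean ``sqrt(mean(d_l^2))`` (``combine="rms"``).
    """
    if combine not in ("mean", "rms"):
        raise ValueError("combine must be 'mean' or 'rms'")
    d_locus: list[float] = []
    dropped = 0
    for locus in freqs_x:
        fx, fy = freqs_x[locus], freqs_y.get(locus, {})
        if not fx or not fy:
            dropped += 1
            continue
        alleles = set(fx) | set(fy)
        f = sum(np.sqrt(fx.get(a, 0.0) * fy.get(a, 0.0)) for a in alleles)
        f = min(1.0, float(f))  # guard rounding above 1
        d_locus.append((2.0 / np.pi) * np.sqrt(2.0 * (1.0 - f)))
    if dropped:
        warnings.warn(f"{dropped} locus/loci undefined in one population, dropped")
    if not d_locus:
        return float("nan")
    arr = np.asarray(d_locus)
    return float(arr.mean()) if combine == "mean" else float(np.sqrt((arr**2).mean()))


def chord_matrix(
    freq_table: AlleleFrequencyTable, combine: str = "mean"
) -> DistanceMatrix:
    """Pairwise chord distances among all populations."""
    pops = freq_table.populations
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = chord_distance(
                freq_table.freqs[pops[i]], freq_table.freqs[pops[j]], combine=combine
            )
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(pops), vals, metric="D_CE")


# -- neighbor joining -----------------------------------------------------


@dataclass
class SupportTree:
    """Unrooted tree over population labels with optional split supports.

    Stored as a node list and an undirected edge list with branch lengths.
    Leaves carry labels; internal nodes are anonymous. ``supports`` maps a
    split (frozenset of leaf labels on the far side of an internal edge,
    canonicalized to the side *not* containing the first leaf label) to a
    bootstrap support in [0, 1].
    """

    leaf_labels: list[str]
    edges: list[tuple[int, int, float]]
    node_labels: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    support_threshold: float = 0.70

    def _adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in self.edges:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))
        return adj

    def splits(self) -> dict[frozenset, tuple[int, int]]:
        """Nontrivial bipartitions (internal edges), canonicalized.

        Each split is the frozenset of leaf labels on the side not containing
        the first label of ``leaf_labels``; maps to the defining edge.
        """
        adj = self._adjacency()
        leaves = set(self.node_labels)
        anchor = self.leaf_labels[0]
        out: dict[frozenset, tuple[int, int]] = {}
        for u, v, _w in self.edges:
            side = self._leafset_beyond(u, v, adj)
            labels = {self.node_labels[n] for n in side if n in leaves}
            if len(labels) < 2 or len(labels) > len(self.leaf_labels) - 2:
                continue  # trivial split
            if anchor in labels:
                labels = set(self.leaf_labels) - labels
            out[frozenset(labels)] = (u, v)
        return out

    def _leafset_beyond(
        self, u: int, v: int, adj: dict[int, list[tuple[int, float]]]
    ) -> set[int]:
        """Nodes on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        while stack:
            x = stack.pop()
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        seen.discard(u)
        return seen

    def significant_splits(self) -> dict[frozenset, float]:
        """Splits whose support exceeds the threshold (default 0.70, the
        conventional cutoff above which bootstrap proportions are read as
        statistically significant)."""
        return {s: v for s, v in self.supports.items() if v > self.support_threshold}

    def distance(self, a: str, b: str) -> float:
        """Path length between two leaves."""
        inv = {lbl: n for n, lbl in self.node_labels.items()}
        adj = self._adjacency()
        dist = {inv[a]: 0.0}
        stack = [inv[a]]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist[inv[b]]

    def neighbor_pairs(self) -> set[frozenset]:
        """Cherries: pairs of leaves attached to a common internal node."""
        adj = self._adjacency()
        inv = {n: lbl for n, lbl in self.node_labels.items()}
        out: set[frozenset] = set()
        internal = [n for n in adj if n not in inv]
        for n in internal:
            here = [inv[y] for y, _ in adj[n] if y in inv]
            for i in range(len(here)):
                for j in range(i + 1, len(here)):
                    out.add(frozenset({here[i], here[j]}))
        return out

    def newick(self, decimals: int = 6) -> str:
        """Newick string; split supports are written as internal node labels."""
        adj = self._adjacency()
        inv = self.node_labels
        # root at an internal node if any, else first node
        internal = [n for n in adj if n not in inv]
        root = internal[0] if internal else self.edges[0][0]
        sup_by_edge: dict[frozenset, float] = {}
        for split, (u, v) in self.splits().items():
            if split in self.supports:
                sup_by_edge[frozenset({u, v})] = self.supports[split]

        def rec(node: int, parent: int | None) -> str:
            children = [(y, w) for y, w in adj[node] if y != parent]
            if not children and node in inv:
                return inv[node]
            parts = []
            for y, w in children:
                lbl = ""
                key = frozenset({node, y})
                if key in sup_by_edge and y not in inv:
                    lbl = f"{sup_by_edge[key]:.2f}"
                parts.append(f"{rec(y, node)}{lbl}:{w:.{decimals}f}")
            body = "(" + ",".join(parts) + ")"
            if node in inv:  # leaf acting as root (degenerate)
                body += inv[node]
            return body

        return rec(root, None) + ";"


def nj_tree(D: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Deterministic: ties in Q are broken by the lexicographically smallest
    (label_i, label_j) pair among the current nodes. Negative branch lengths
    are clamped to zero and the deficit moved to the sibling branch of the
    same join, preserving the pair's summed length.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # active nodes: id -> label used for tie-breaking
    ids = list(range(n))
    labels = {i: D.labels[i] for i in range(n)}
    dist = {(i, j): float(D.values[i, j]) for i in range(n) for j in range(n) if i != j}
    edges: list[tuple[int, int, float]] = []
    next_id = n

    def d(a: int, b: int) -> float:
        return dist[(a, b)] if a != b else 0.0

    while len(ids) > 3:
        m = len(ids)
        r = {a: sum(d(a, b) for b in ids if b != a) for a in ids}
        best: tuple[float, str, str, int, int] | None = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = ids[ii], ids[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                la, lb = sorted((labels[a], labels[b]))
                cand = (q, la, lb, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        _q, _la, _lb, a, b = best
        m2 = len(ids)
        va = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m2 - 2))
        vb = d(a, b) - va
        # clamp negatives, transfer to sibling so va + vb is preserved
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        u = next_id
        next_id += 1
        edges.append((u, a, max(va, 0.0)))
        edges.append((u, b, max(vb, 0.0)))
        labels[u] = min(labels[a], labels[b])  # representative for tie-breaks
        for c in ids:
            if c in (a, b):
                continue
            duc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(u, c)] = dist[(c, u)] = duc
        ids = [c for c in ids if c not in (a, b)] + [u]

    # final three nodes joined at one internal node
    a, b, c = ids
    u = next_id
    va = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    vb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    vc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for node, v in ((a, va), (b, vb), (c, vc)):
        edges.append((u, node, max(v, 0.0)))

    node_labels = {i: D.labels[i] for i in range(n)}
    return SupportTree(list(D.labels), edges, node_labels)


def bootstrap_nj(
    table: GenotypeTable,
    reps: int = 2000,
    seed: int | np.random.Generator | None = None,
    combine: str = "mean",
) -> SupportTree:
    """Chord-distance NJ tree with locus-bootstrap split supports.

    Loci are resampled with replacement ``reps`` times; the chord-distance
    matrix and NJ tree are rebuilt for each pseudo-replicate, and the
    support of each internal split of the point-estimate tree is the
    fraction of replicate trees containing that bipartition. Splits with
    support > 0.70 are flagged significant by
    :meth:`SupportTree.significant_splits`.
    """
    if table.n_loci < 2:
        raise ValueError("locus bootstrap needs at least 2 loci")
    if len(table.population_order) < 3:
        raise ValueError("need at least 3 populations")
    rng = np.random.default_rng(seed)
    ft = allele_frequencies(table)
    point = nj_tree(chord_matrix(ft, combine=combine))
    target_splits = set(point.splits())
    if not target_splits:
        return point
    hits = {s: 0 for s in target_splits}
    loci = ft.loci
    L = len(loci)
    for _ in range(reps):
        pick = rng.integers(0, L, size=L)
        # frequency table restricted to the resampled loci (renamed uniquely)
        freqs = {
            p: {f"b{k}": ft.freqs[p][loci[i]] for k, i in enumerate(pick)}
            for p in ft.populations
        }
        sub = AlleleFrequencyTable(
            list(ft.populations),
            [f"b{k}" for k in range(L)],
            freqs,
            {
                p: {f"b{k}": ft.n_copies[p][loci[i]] for k, i in enumerate(pick)}
                for p in ft.populations
            },
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj_tree(chord_matrix(sub, combine=combine))
        rep_splits = set(rep_tree.splits())
        for s in target_splits & rep_splits:
            hits[s] += 1
    point.supports = {s: hits[s] / reps for s in target_splits}
    return point


# -- principal coordinates ------------------------------------------------


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of populations.

    ``coordinates``: populations x axes, axes ordered by decreasing
    eigenvalue; ``percent_variance``: share of the positive-eigenvalue total
    explained by each axis (sums to 100 over the retained axes).
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(D: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Classical metric scaling (Torgerson) of a distance matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues. Axes with eigenvalues
    <= ``eps`` x largest are dropped; percent variance is taken over the
    positive eigenvalues only.
    """
    k = len(D.labels)
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ (D.values**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > eps * max(w.max(initial=0.0), 1e-300)
    if not pos.any():
        return OrdinationResult(list(D.labels), np.zeros((k, 0)), np.zeros(0), np.zeros(0))
    wp, Vp = w[pos], V[:, pos]
    coords = Vp * np.sqrt(wp)
    total = w[w > 0].sum()
    pct = 100.0 * wp / total
    return OrdinationResult(list(D.labels), coords, wp, pct)


# -- Weir-Cockerham theta -------------------------------------------------


def _pair_components(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, float]:
    """Summed (a, a+b+c) Weir-Cockerham variance components for two demes.

    ``calls_*``: (n, L, 2) allele arrays, 0 = missing. Loci untyped in either
    deme, or with a single allele overall, contribute nothing.
    """
    num, den = _theta_sums_batch(calls_a[None, ...], calls_b[None, ...])
    return float(num[0]), float(den[0])


def _theta_sums_batch(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized numerator/denominator sums for batches of deme pairs.

    Shapes: (R, n_a, L, 2) and (R, n_b, L, 2). Returns (R,) arrays of
    sum(a) and sum(a+b+c) over loci and alleles.
    """
    R, _, L, _ = calls_a.shape
    nums = np.zeros(R)
    dens = np.zeros(R)
    for l in range(L):
        ga = calls_a[:, :, l, :]
        gb = calls_b[:, :, l, :]
        alleles = np.unique(np.concatenate([ga.ravel(), gb.ravel()]))
        alleles = alleles[alleles != MISSING]
        if alleles.size < 2:
            continue
        na, ha, ca = _locus_profile(ga, alleles)  # (R,), (R,K), (R,K)
        nb, hb, cb = _locus_profile(gb, alleles)
        ok = (na >= 1) & (nb >= 1) & (na + nb >= 3)
        if not ok.any():
            continue
        n1 = na.astype(float)
        n2 = nb.astype(float)
        nbar = (n1 + n2) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
            p1 = ca / (2.0 * n1)[:, None]
            p2 = cb / (2.0 * n2)[:, None]
            h1 = ha / n1[:, None]
            h2 = hb / n2[:, None]
            pbar = (n1[:, None] * p1 + n2[:, None] * p2) / (2.0 * nbar)[:, None]
            s2 = (
                n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2
            ) / nbar[:, None]
            hbar = (n1[:, None] * h1 + n2[:, None] * h2) / (2.0 * nbar)[:, None]
            inner = pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0
            a = (nbar / nc)[:, None] * (
                s2 - (1.0 / (nbar - 1.0))[:, None] * inner
            )
            b = (nbar / (nbar - 1.0))[:, None] * (
                pbar * (1 - pbar)
                - s2 / 2.0
                - ((2.0 * nbar - 1.0) / (4.0 * nbar))[:, None] * hbar
            )
            c = hbar / 2.0
        contrib_num = np.where(ok[:, None], a, 0.0)
        contrib_den = np.where(ok[:, None], a + b + c, 0.0)
        nums += np.nansum(contrib_num, axis=1)
        dens += np.nansum(contrib_den, axis=1)
    return nums, dens


def _locus_profile(
    g: np.ndarray, alleles: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-batch typed count, het-carrier counts and allele-copy counts.

    ``g``: (R, n, 2) calls at one locus. Returns ``n_typed`` (R,),
    ``het_counts`` (R, K) — typed heterozygotes carrying each allele — and
    ``copy_counts`` (R, K).
    """
    typed = g[:, :, 0] != MISSING  # (R, n)
    n_typed = typed.sum(axis=1)
    K = alleles.size
    het = (g[:, :, 0] != g[:, :, 1]) & typed  # (R, n)
    copy_counts = np.zeros((g.shape[0], K))
    het_counts = np.zeros((g.shape[0], K))
    for k, al in enumerate(alleles):
        carries = (g[:, :, 0] == al).astype(np.int64) + (g[:, :, 1] == al)
        copy_counts[:, k] = (carries * typed).sum(axis=1)
        het_counts[:, k] = ((carries > 0) & het).sum(axis=1)
    return n_typed, het_counts, copy_counts


def pairwise_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Weir-Cockerham theta between two populations (ratio of sums).

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed per locus and
    allele from sample sizes, allele frequencies and observed heterozygote
    frequencies with r = 2 demes; theta = sum(a) / sum(a + b + c) over all
    alleles and loci. Missing genotypes shrink the per-locus sample sizes;
    loci untyped in a population are excluded for the pair. The estimate may
    be negative and is reported as computed.
    """
    ca = table.calls[table.pop_mask(pop_a)]
    cb = table.calls[table.pop_mask(pop_b)]
    num, den = _pair_components(ca, cb)
    return num / den if den != 0 else float("nan")


def fst_permutation_test(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
    batch: int = 200,
) -> tuple[float, float]:
    """Permutation test of differentiation between two populations.

    Pools the two samples' individuals, reassigns population labels at
    random preserving the sample sizes, and recomputes theta for each of
    ``reps`` permutations; ``p = (1 + #{theta_perm >= theta_obs}) /
    (reps + 1)``. Returns ``(theta_obs, p)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ca = table.calls[table.pop_mask(pop_a)]
    cb = table.calls[table.pop_mask(pop_b)]
    na = ca.shape[0]
    pooled = np.concatenate([ca, cb], axis=0)
    n = pooled.shape[0]
    num, den = _pair_components(ca, cb)
    theta_obs = num / den if den != 0 else float("nan")
    if np.isnan(theta_obs):
        return theta_obs, float("nan")
    count = 0
    done = 0
    while done < reps:
        r = min(batch, reps - done)
        keys = rng.random((r, n))
        perm = np.argsort(keys, axis=1)
        shuffled = pooled[perm]  # (r, n, L, 2)
        nums, dens = _theta_sums_batch(shuffled[:, :na], shuffled[:, na:])
        with np.errstate(divide="ignore", invalid="ignore"):
            th = np.where(dens != 0, nums / dens, -np.inf)
        count += int((th >= theta_obs - 1e-12).sum())
        done += r
    return theta_obs, (1 + count) / (reps + 1)


@dataclass
class FstResult:
    """Pairwise theta matrix with permutation p-values (theta below the
    diagonal, p above, in the conventional report layout)."""

    labels: list[str]
    theta: np.ndarray
    p_values: np.ndarray
    permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        k = len(self.labels)
        out = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.theta[i, j]
                elif i < j:
                    out[i, j] = self.p_values[i, j]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def fst_matrix(
    table: GenotypeTable,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> FstResult:
    """All pairwise theta values with permutation p-values.

    Each pair is tested independently at the stated permutation count; no
    across-pair FDR is applied here (report layers decide significance
    thresholds)."""
    rng = np.random.default_rng(seed)
    pops = table.population_order
    k = len(pops)
    theta = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            th, p = fst_permutation_test(table, pops[i], pops[j], reps=reps, seed=rng)
            theta[i, j] = theta[j, i] = th
            pvals[i, j] = pvals[j, i] = p
    return FstResult(list(pops), theta, pvals, reps)
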