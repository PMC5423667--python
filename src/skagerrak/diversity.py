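"""Per-locus, per-population diversity statistics and equilibrium tests.

Covers the classical microsatellite summary panel: observed and expected
heterozygosity, allele counts, hypergeometric-rarefaction allelic richness,
private alleles, a Monte-Carlo exact Hardy-Weinberg test, a G-statistic
permutation test for two-locus association (linkage disequilibrium at the
genotypic level), and the Benjamini-Yekutieli FDR-adjusted significance
threshold used to correct whole families of such tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeTable, allele_frequencies

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allelic_richness",
    "private_alleles",
    "private_allele_table",
    "hwe_exact_test",
    "ld_permutation_test",
    "by_fdr_alpha",
    "TestFamilyResult",
    "diversity_table",
    "locus_summary",
]


def observed_heterozygosity(
    table: GenotypeTable, population: str, locus: str
) -> float:
    """Fraction of non-missing individuals whose two alleles differ.

    Returns NaN when every individual is missing at the locus.
    """
    j = table.locus_index(locus)
    sub = table.calls[table.pop_mask(population), j, :]
    typed = sub[:, 0] != MISSING
    if not typed.any():
        return float("nan")
    het = sub[typed, 0] != sub[typed, 1]
    return float(het.mean())


def expected_heterozygosity(
    freqs: Mapping[int, float], n_copies: int | None = None, unbiased: bool = False
) -> float:
    """Gene diversity ``1 - sum(p_i^2)``, optionally with Nei's small-sample
    correction ``2n/(2n - 1)`` where ``2n`` is the gene-copy count.

    The uncorrected form is the pooled-sample convention; the unbiased form
    is the per-population convention. Returns NaN for an empty frequency map
    or, in unbiased mode, fewer than two gene copies.
    """
    if not freqs:
        return float("nan")
    p = np.asarray(list(freqs.values()), dtype=float)
    h = 1.0 - float(p @ p)
    if not unbiased:
        return h
    if n_copies is None or n_copies < 2:
        return float("nan")
    return h * n_copies / (n_copies - 1)


def allelic_richness(counts: Sequence[int] | np.ndarray, g: int) -> float:
    """Rarefied allelic richness: expected number of distinct alleles in a
    random subsample of ``g`` gene copies.

    For allele copy counts ``N_i`` summing to ``N``::

        A_R(g) = sum_i [ 1 - C(N - N_i, g) / C(N, g) ]

    the hypergeometric probability that allele ``i`` appears at least once
    among ``g`` draws without replacement. ``A_R(N)`` equals the observed
    allele count; a monomorphic locus has richness 1 for any ``g``.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    if c.size == 0:
        return float("nan")
    N = int(c.sum())
    if not 1 <= g <= N:
        raise ValueError(f"subsample size g={g} must be in [1, N={N}]")
    # log C(N - N_i, g) - log C(N, g), with C(m, g) = 0 when m < g
    out = 0.0
    logCNg = _log_comb(N, g)
    for Ni in c:
        m = N - int(Ni)
        if m < g:
            out += 1.0
        else:
            out += 1.0 - float(np.exp(_log_comb(m, g) - logCNg))
    return out


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def private_alleles(
    freq_table: AlleleFrequencyTable,
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, int]:
    """Count (locus, allele) pairs present in exactly one group and absent
    from every other group.

    ``grouping`` maps group name -> populations; it must partition the
    populations (disjoint cover). By default each population is its own
    group, which yields the per-location private-allele counts; pooled
    groupings (e.g. all Norwegian samples vs the compiled Swedish+Danish
    sample) quantify how much of the allele pool is exclusive to each side.
    Counts are raw presence/absence, not rarefied.
    """
    if grouping is None:
        grouping = {p: [p] for p in freq_table.populations}
    _check_partition(grouping, freq_table.populations)
    group_alleles: dict[str, set[tuple[str, int]]] = {}
    for gname, pops in grouping.items():
        seen: set[tuple[str, int]] = set()
        for pop in pops:
            for locus in freq_table.loci:
                seen.update(
                    (locus, a)
                    for a, f in freq_table.freq(pop, locus).items()
                    if f > 0
                )
        group_alleles[gname] = seen
    out: dict[str, int] = {}
    for gname, seen in group_alleles.items():
        others: set[tuple[str, int]] = set()
        for other, s in group_alleles.items():
            if other != gname:
                others |= s
        out[gname] = len(seen - others)
    return out


def private_allele_table(freq_table: AlleleFrequencyTable) -> pd.DataFrame:
    """Per (population, locus) private-allele counts (population-level groups)."""
    pops, loci = freq_table.populations, freq_table.loci
    mat = np.zeros((len(pops), len(loci)), dtype=int)
    for j, locus in enumerate(loci):
        present = {
            p: {a for a, f in freq_table.freq(p, locus).items() if f > 0}
            for p in pops
        }
        for i, p in enumerate(pops):
            others: set[int] = set()
            for q in pops:
                if q != p:
                    others |= present[q]
            mat[i, j] = len(present[p] - others)
    return pd.DataFrame(mat, index=pops, columns=loci)


def _check_partition(
    grouping: Mapping[str, Sequence[str]], populations: Sequence[str]
) -> None:
    seen: list[str] = []
    for pops in grouping.values():
        seen.extend(pops)
    if len(seen) != len(set(seen)):
        raise ValueError("grouping is not disjoint")
    if set(seen) != set(populations):
        raise ValueError("grouping does not cover all populations")


# -- Hardy-Weinberg Monte-Carlo exact test --------------------------------


def _genotype_log_weight(pair_codes: np.ndarray, n_alleles: int) -> np.ndarray:
    """Per-arrangement log conditional weight, up to arrangement-independent
    constants: ``h * log 2 - sum_{i<=j} log(n_ij!)`` where ``h`` is the
    heterozygote count.

    ``pair_codes``: integer genotype codes ``min * K + max``, shape
    (n_arrangements, n_individuals).
    """
    R, n = pair_codes.shape
    K2 = n_alleles * n_alleles
    offset = (np.arange(R, dtype=np.int64) * K2)[:, None]
    flat = (pair_codes + offset).ravel()
    tab = np.bincount(flat, minlength=R * K2).reshape(R, K2)
    a = np.arange(n_alleles)
    het_cols = (a[:, None] != a[None, :]).ravel()  # code grid min*K+max
    h = tab[:, het_cols].sum(axis=1)
    return h * np.log(2.0) - gammaln(tab + 1).sum(axis=1)


def hwe_exact_test(
    genotypes: np.ndarray,
    steps: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    ``genotypes``: (n, 2) array of allele labels for the typed individuals of
    one population (missing calls must be excluded beforehand). The observed
    2n gene copies are repeatedly shuffled into n random diploid pairings;
    each arrangement's conditional probability given the allele counts is
    compared with the observed table's, and

        p = (1 + #{arrangements with probability <= observed}) / (steps + 1)

    (the exact-test ordering: tables as improbable as, or more improbable
    than, the data count against it; +1 smoothing avoids p = 0). Returns NaN
    for a monomorphic locus or fewer than two typed individuals, matching
    the "test not applicable" convention of diversity reports.
    """
    geno = np.asarray(genotypes, dtype=np.int64)
    if geno.ndim != 2 or geno.shape[1] != 2:
        raise ValueError("genotypes must be (n, 2)")
    geno = geno[geno[:, 0] != MISSING]
    n = geno.shape[0]
    copies = geno.ravel()
    alleles = np.unique(copies)
    if n < 2 or alleles.size < 2:
        return float("nan")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    K = alleles.size
    recode = {int(a): k for k, a in enumerate(alleles)}
    copies01 = np.asarray([recode[int(a)] for a in copies], dtype=np.int64)

    obs_pairs = np.sort(np.asarray([[recode[int(a)], recode[int(b)]] for a, b in geno]), axis=1)
    obs_codes = (obs_pairs[:, 0] * K + obs_pairs[:, 1])[None, :]
    log_w_obs = _genotype_log_weight(obs_codes, K)[0]

    # shuffle the 2n copies into n pairings, `steps` times (batched)
    batch = max(1, min(steps, int(2e7) // max(1, 2 * n)))
    count = 0
    done = 0
    while done < steps:
        b = min(batch, steps - done)
        keys = rng.random((b, 2 * n))
        perm = np.argsort(keys, axis=1)
        shuffled = copies01[perm].reshape(b, n, 2)
        shuffled.sort(axis=2)
        codes = shuffled[:, :, 0] * K + shuffled[:, :, 1]
        log_w = _genotype_log_weight(codes, K)
        count += int((log_w <= log_w_obs + 1e-9).sum())
        done += b
    return (1 + count) / (steps + 1)


# -- genotypic linkage-disequilibrium permutation test --------------------


def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, Ka: int, Kb: int) -> np.ndarray:
    """G statistic of the genotype x genotype contingency table.

    ``codes_a``: (n,) observed genotype codes at locus A; ``codes_b``:
    (R, n) genotype codes at locus B for R permutations.
    """
    R, n = codes_b.shape
    cell = codes_a[None, :] * Kb + codes_b
    offset = (np.arange(R, dtype=np.int64) * (Ka * Kb))[:, None]
    tab = np.bincount((cell + offset).ravel(), minlength=R * Ka * Kb).reshape(R, Ka, Kb)
    rows = tab.sum(axis=2, keepdims=True)
    cols = tab.sum(axis=1, keepdims=True)
    expect = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(tab > 0, tab * np.log(tab / expect), 0.0)
    return 2.0 * term.sum(axis=(1, 2))


def ld_permutation_test(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation test of genotypic association between two loci.

    Individuals typed at both loci contribute a (genotype A, genotype B)
    pair; the association statistic is the G statistic of the genotype
    contingency table. The null is built by permuting locus B's single-locus
    genotypes across individuals ``reps`` times, which preserves both
    single-locus genotype distributions while breaking their association.

        p = (1 + #{G_perm >= G_obs}) / (reps + 1)

    Returns NaN if either locus is monomorphic among the jointly typed
    individuals.
    """
    a = np.sort(np.asarray(genotypes_a, dtype=np.int64), axis=1)
    b = np.sort(np.asarray(genotypes_b, dtype=np.int64), axis=1)
    typed = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    a, b = a[typed], b[typed]
    n = a.shape[0]
    if n < 2:
        return float("nan")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    def codes(geno: np.ndarray) -> tuple[np.ndarray, int]:
        pairs = [tuple(row) for row in geno]
        uniq = sorted(set(pairs))
        lut = {g: i for i, g in enumerate(uniq)}
        return np.asarray([lut[g] for g in pairs], dtype=np.int64), len(uniq)

    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    ca, Ka = codes(a)
    cb, Kb = codes(b)
    g_obs = _g_statistic(ca, cb[None, :], Ka, Kb)[0]

    rng = np.random.default_rng(seed)
    batch = max(1, min(reps, int(2e7) // max(1, n)))
    count = 0
    done = 0
    while done < reps:
        r = min(batch, reps - done)
        keys = rng.random((r, n))
        perm = np.argsort(keys, axis=1)
        g_perm = _g_statistic(ca, cb[perm], Ka, Kb)
        count += int((g_perm >= g_obs - 1e-9).sum())
        done += r
    return (1 + count) / (reps + 1)


# -- Benjamini-Yekutieli family threshold ---------------------------------


def by_fdr_alpha(alpha: float, k: int) -> float:
    """Benjamini-Yekutieli FDR-adjusted significance threshold.

    ``alpha / sum_{i=1..k} 1/i`` — the single-threshold form of the B-Y
    correction, valid under arbitrary dependence among the ``k`` tests.
    Reports round it to 5 decimals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    harmonic = float(np.sum(1.0 / np.arange(1, k + 1)))
    return alpha / harmonic


@dataclass
class TestFamilyResult:
    """A family of tests corrected with a single B-Y threshold."""

    labels: list[str]
    p_values: list[float]
    alpha: float

    @property
    def k(self) -> int:
        return sum(1 for p in self.p_values if not np.isnan(p))

    @property
    def adjusted_alpha(self) -> float:
        return by_fdr_alpha(self.alpha, max(1, self.k))

    @property
    def significant(self) -> list[bool]:
        thr = self.adjusted_alpha
        return [(not np.isnan(p)) and p <= thr for p in self.p_values]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "test": self.labels,
                "p": self.p_values,
                "significant": self.significant,
            }
        ).assign(adjusted_alpha=round(self.adjusted_alpha, 5))


def _stars(p: float, thr: float) -> str:
    if np.isnan(p) or p > thr:
        return "NS"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    return "*"


def diversity_table(
    table: GenotypeTable,
    g: int | None = None,
    hwe_steps: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-population x per-locus summary panel with a ``Mean`` column.

    Rows (per population): ``N_A`` observed alleles, ``A_R`` rarefied
    allelic richness at ``g`` gene copies (default: per-locus minimum across
    populations, so the smallest sample sets the standard), ``P_A`` private
    alleles, ``H_O``, ``H_E`` (unbiased), ``p`` the HWE Monte-Carlo p-value,
    and significance stars against the B-Y-adjusted threshold for the whole
    HWE family. Means are arithmetic over defined per-locus values.
    """
    rng = np.random.default_rng(seed)
    ft = allele_frequencies(table)
    pops, loci = ft.populations, ft.loci
    priv = private_allele_table(ft)

    hwe_p = pd.DataFrame(np.nan, index=pops, columns=loci)
    rows: list[dict[str, object]] = []
    for pop in pops:
        mask = table.pop_mask(pop)
        stats: dict[str, dict[str, float]] = {s: {} for s in ("N_A", "A_R", "P_A", "H_O", "H_E", "p")}
        for j, locus in enumerate(loci):
            f = ft.freq(pop, locus)
            n = ft.copies(pop, locus)
            stats["N_A"][locus] = float(len(f)) if n else np.nan
            if n:
                counts = list(ft.counts(pop, locus).values())
                g_loc = g if g is not None else min(
                    ft.copies(q, locus) for q in pops if ft.copies(q, locus) > 0
                )
                g_loc = min(g_loc, n)
                stats["A_R"][locus] = allelic_richness(counts, g_loc)
            else:
                stats["A_R"][locus] = np.nan
            stats["P_A"][locus] = float(priv.loc[pop, locus])
            stats["H_O"][locus] = observed_heterozygosity(table, pop, locus)
            stats["H_E"][locus] = expected_heterozygosity(f, n, unbiased=True)
            p = hwe_exact_test(table.calls[mask, j, :], steps=hwe_steps, seed=rng)
            stats["p"][locus] = p
            hwe_p.loc[pop, locus] = p
        for sname, vals in stats.items():
            arr = np.asarray([vals[l] for l in loci], dtype=float)
            mean = float(np.nanmean(arr)) if not np.all(np.isnan(arr)) else np.nan
            rows.append(
                {"population": pop, "statistic": sname, **vals, "Mean": mean}
            )

    df = pd.DataFrame(rows).set_index(["population", "statistic"])
    k = int(hwe_p.notna().sum().sum())
    thr = by_fdr_alpha(alpha, max(1, k))
    star_rows = []
    for pop in pops:
        star_rows.append(
            {
                "population": pop,
                "statistic": "HWE",
                **{l: _stars(hwe_p.loc[pop, l], thr) for l in loci},
                "Mean": "",
            }
        )
    stars = pd.DataFrame(star_rows).set_index(["population", "statistic"])
    out = pd.concat([df, stars]).sort_index(
        level=0, key=lambda idx: idx.map({p: i for i, p in enumerate(pops)}), sort_remaining=False
    )
    out.attrs["hwe_family_k"] = k
    out.attrs["hwe_adjusted_alpha"] = round(thr, 5)
    return out


def locus_summary(table: GenotypeTable) -> pd.DataFrame:
    """Pooled per-locus panel: alleles, typed individuals, H_O, H_E.

    Pools all populations (the marker-panel view of the data set); H_E here
    is the uncorrected gene diversity of the pooled sample.
    """
    rows = []
    for j, locus in enumerate(table.loci):
        calls = table.calls[:, j, :]
        typed = calls[:, 0] != MISSING
        flat = calls[typed].ravel()
        vals, counts = np.unique(flat, return_counts=True)
        freqs = {int(a): c / flat.size for a, c in zip(vals, counts)}
        het = calls[typed, 0] != calls[typed, 1]
        rows.append(
            {
                "locus": locus,
                "N_A": len(vals),
                "N": int(typed.sum()),
                "H_O": float(het.mean()) if typed.any() else np.nan,
                "H_E": expected_heterozygosity(freqs),
            }
        )
    return pd.DataFrame(rows).set_index("locus")
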