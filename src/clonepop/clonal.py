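"""Clone discrimination and clonal-structure indices.

Ramets (physically distinct sampled colonies) sharing the same alleles at
every locus form one multilocus genotype (MLG).  Because scoring errors and
somatic mutation can split a true clone into near-identical MLGs, MLGs whose
genotypes differ by at most ``threshold`` alleles (default 1) are merged into
multilocus lineages (MLLs) by single-linkage over the pairwise allele
distance; MLLs are the working estimate of genets.

For each MLG observed more than once, ``P_sex`` gives the probability that
its repeats arose from independent sexual reproduction events rather than
cloning; small values (< 0.001 by convention) support clonality.

Clonal structure of a population is summarised by clonal richness
``R = (G-1)/(N-1)`` and Simpson's-complement evenness
``V = (D - D_min)/(D_max - D_min)``, where ``D`` is the unbiased probability
that two distinct sampled ramets belong to different genets, and
``D_min``/``D_max`` are the values of ``D`` for the most uneven (one
dominant clone) and perfectly even clone-size configurations with the same
``N`` and ``G``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from clonepop.genotype_io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClonalPartition",
    "ClonalIndices",
    "assign_mlg",
    "allele_distance",
    "pairwise_allele_distances",
    "collapse_mll",
    "clonal_partition",
    "estimate_allele_freqs",
    "p_gen",
    "p_sex",
    "clonal_richness",
    "simpson_complement",
    "evenness_v",
    "fit_pareto_beta",
    "clonal_indices",
]


# ---------------------------------------------------------------------------
# MLG assignment


def assign_mlg(table: GenotypeTable) -> np.ndarray:
    """Assign a multilocus-genotype id to every individual.

    Two individuals share an MLG iff their unordered allele pairs are
    identical at every locus.  A missing call matches nothing — not even
    another missing call — so any individual with missing data is a
    singleton MLG (missing values are treated as different alleles).
    MLG ids are consecutive integers in first-appearance order.
    """
    ids = np.empty(table.n_individuals, dtype=np.int64)
    seen: dict[tuple, int] = {}
    next_id = 0
    missing_any = table.missing_mask.any(axis=1)
    for i in range(table.n_individuals):
        if missing_any[i]:
            ids[i] = next_id  # missing matches nothing: always a new MLG
            next_id += 1
            continue
        key = tuple(map(tuple, table.alleles[i]))
        if key in seen:
            ids[i] = seen[key]
        else:
            seen[key] = ids[i] = next_id
            next_id += 1
    return ids


# ---------------------------------------------------------------------------
# allele distance


def _pair_intersection(a1, a2, b1, b2):
    """Multiset intersection size of two sorted diploid pairs (vectorised)."""
    equal = (a1 == b1) & (a2 == b2)
    common = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
    return np.where(equal, 2, np.where(common, 1, 0))


def allele_distance(
    calls_a: np.ndarray, calls_b: np.ndarray, missing_vs_missing: int = 0
) -> int:
    """Number of allele differences between two multilocus genotypes.

    Per locus the contribution is ``2 - |multiset intersection|`` of the two
    unordered pairs.  A missing call against a non-missing call contributes
    2 (nothing shared); missing against missing contributes
    ``missing_vs_missing`` (default 0, so two genotypes identical except for
    a shared failed locus still look identical for lineage collapsing).
    """
    a = np.sort(np.asarray(calls_a, dtype=np.int64), axis=-1)
    b = np.sort(np.asarray(calls_b, dtype=np.int64), axis=-1)
    if a.shape != b.shape:
        raise ValueError("genotypes are defined on different locus sets")
    miss_a = a[..., 0] == MISSING
    miss_b = b[..., 0] == MISSING
    inter = _pair_intersection(a[..., 0], a[..., 1], b[..., 0], b[..., 1])
    per_locus = 2 - inter
    per_locus = np.where(miss_a & miss_b, missing_vs_missing, per_locus)
    per_locus = np.where(miss_a ^ miss_b, 2, per_locus)
    return int(per_locus.sum())


def pairwise_allele_distances(genotypes: np.ndarray) -> np.ndarray:
    """Symmetric matrix of allele distances among genotypes ``(m, L, 2)``."""
    g = np.sort(np.asarray(genotypes, dtype=np.int64), axis=-1)
    m = g.shape[0]
    miss = g[:, :, 0] == MISSING
    a1 = g[:, None, :, 0]
    a2 = g[:, None, :, 1]
    b1 = g[None, :, :, 0]
    b2 = g[None, :, :, 1]
    per_locus = 2 - _pair_intersection(a1, a2, b1, b2)
    mm = miss[:, None, :] & miss[None, :, :]
    xm = miss[:, None, :] ^ miss[None, :, :]
    per_locus = np.where(mm, 0, per_locus)
    per_locus = np.where(xm, 2, per_locus)
    d = per_locus.sum(axis=2)
    np.fill_diagonal(d, 0)
    return d


# ---------------------------------------------------------------------------
# MLL collapsing


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def collapse_mll(
    table: GenotypeTable, mlg_of: np.ndarray, threshold: int = 1
) -> dict[int, int]:
    """Merge MLGs differing by at most ``threshold`` alleles into MLLs.

    MLLs are the connected components (single linkage) of the graph joining
    MLG representatives at allele distance <= threshold; transitive chains
    merge and are logged.  Returns ``{mlg_id: mll_id}`` with MLL ids
    relabelled consecutively by smallest member MLG id.
    """
    mlg_ids = np.unique(mlg_of)
    # representative = first individual carrying the MLG
    rep = {g: int(np.nonzero(mlg_of == g)[0][0]) for g in mlg_ids}
    genotypes = table.alleles[[rep[g] for g in mlg_ids]]
    d = pairwise_allele_distances(genotypes)
    uf = _UnionFind(len(mlg_ids))
    for i in range(len(mlg_ids)):
        for j in range(i + 1, len(mlg_ids)):
            if d[i, j] <= threshold:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(len(mlg_ids))]
    # relabel components by smallest member MLG id, consecutively
    comp_min: dict[int, int] = {}
    for i, r in enumerate(roots):
        comp_min[r] = min(comp_min.get(r, int(mlg_ids[i])), int(mlg_ids[i]))
    order = sorted(set(comp_min.values()))
    new_label = {m: k for k, m in enumerate(order)}
    mll_of = {int(mlg_ids[i]): new_label[comp_min[roots[i]]] for i in range(len(mlg_ids))}
    n_chained = sum(1 for r in set(roots) if roots.count(r) > 2)
    if n_chained:
        logger.info("collapse_mll: %d component(s) merged by transitive chaining", n_chained)
    return mll_of


# ---------------------------------------------------------------------------
# allele frequencies and P_sex


def estimate_allele_freqs(
    table: GenotypeTable,
    scheme: str = "per_genet",
    mlg_of: np.ndarray | None = None,
) -> dict[str, dict[int, float]]:
    """Per-locus allele frequencies under a clone-aware counting scheme.

    ``per_genet`` counts one genotype copy per MLG (avoids clones inflating
    their alleles); ``round_robin`` estimates frequencies at locus *l* from
    the genotypes unique over all loci except *l*; ``per_ramet`` counts every
    individual.  Frequencies at each locus sum to 1 over observed alleles;
    missing calls are skipped.
    """
    if scheme not in ("per_genet", "round_robin", "per_ramet"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme in ("per_genet", "round_robin") and mlg_of is None:
        mlg_of = assign_mlg(table)

    def _freqs_from_rows(rows: np.ndarray, j: int) -> dict[int, float]:
        pairs = table.alleles[rows, j, :]
        alleles = pairs[pairs[:, 0] != MISSING].ravel()
        if alleles.size == 0:
            return {}
        values, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        return {int(v): float(c) / float(total) for v, c in zip(values, counts)}

    out: dict[str, dict[int, float]] = {}
    n = table.n_individuals
    if scheme == "per_ramet":
        rows = np.arange(n)
        for j, locus in enumerate(table.loci):
            out[locus] = _freqs_from_rows(rows, j)
    elif scheme == "per_genet":
        _, first = np.unique(mlg_of, return_index=True)
        rows = np.sort(first)
        for j, locus in enumerate(table.loci):
            out[locus] = _freqs_from_rows(rows, j)
    else:  # round_robin
        for j, locus in enumerate(table.loci):
            others = [l for l in table.loci if l != locus]
            sub = table.select_loci(others)
            sub_mlg = assign_mlg(sub)
            _, first = np.unique(sub_mlg, return_index=True)
            out[locus] = _freqs_from_rows(np.sort(first), j)
    return out


def p_gen(
    genotype: np.ndarray,
    frequencies: dict[str, dict[int, float]],
    loci: tuple[str, ...],
    f_is: float = 0.0,
) -> float:
    """Probability of drawing a multilocus genotype under random mating.

    Per locus: homozygote (a,a) has probability ``f_a^2 + f_a(1-f_a)F_IS``;
    heterozygote (a,b) has ``2 f_a f_b (1-F_IS)``.  ``F_IS = 0`` reduces to
    Hardy-Weinberg; negative per-locus terms are clamped to 0 with a
    warning.  Missing loci are skipped.
    """
    if not -1.0 <= f_is <= 1.0:
        raise ValueError("F_IS must be in [-1, 1]")
    g = np.sort(np.asarray(genotype, dtype=np.int64), axis=-1)
    prob = 1.0
    for j, locus in enumerate(loci):
        a, b = int(g[j, 0]), int(g[j, 1])
        if a == MISSING:
            continue
        freqs = frequencies[locus]
        if a not in freqs or b not in freqs:
            raise KeyError(f"allele absent from frequency table at locus {locus}")
        fa = freqs[a]
        if a == b:
            term = fa * fa + fa * (1.0 - fa) * f_is
        else:
            term = 2.0 * fa * freqs[b] * (1.0 - f_is)
        if term < 0.0:
            warnings.warn(
                f"negative genotype probability clamped to 0 at locus {locus} "
                f"(F_IS={f_is:.3f})",
                stacklevel=2,
            )
            term = 0.0
        prob *= term
    return prob


def p_sex(
    p_gen_value: float,
    n_repeats: int,
    n_sample: int,
    convention: str = "parks-werth",
) -> float:
    """Probability that an MLG's repeats arose by independent sexual events.

    Under the default Parks-Werth convention, with the focal sample fixed,
    ``P_sex`` is the binomial probability that at least ``n_repeats - 1`` of
    the remaining ``n_sample - 1`` samples independently draw the same
    genotype (probability ``p_gen`` each).  The alternative ``"binomial-n"``
    convention counts at least ``n_repeats`` successes among all
    ``n_sample`` draws.
    """
    if not 0.0 <= p_gen_value <= 1.0:
        raise ValueError("p_gen must be in [0, 1]")
    if n_repeats < 2:
        raise ValueError("P_sex is defined for MLGs observed at least twice")
    if n_sample < n_repeats:
        raise ValueError("n_sample must be >= n_repeats")
    if convention == "parks-werth":
        return float(stats.binom.sf(n_repeats - 2, n_sample - 1, p_gen_value))
    if convention == "binomial-n":
        return float(stats.binom.sf(n_repeats - 1, n_sample, p_gen_value))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# clonal indices


def clonal_richness(n_genets: int, n_individuals: int) -> float:
    """Clonal richness ``R = (G-1)/(N-1)``; 0 = all clones, 1 = all distinct."""
    if n_individuals < 2:
        raise ValueError("clonal richness requires N >= 2")
    if not 1 <= n_genets <= n_individuals:
        raise ValueError("need 1 <= G <= N")
    return (n_genets - 1) / (n_individuals - 1)


def simpson_complement(ramet_counts) -> tuple[float, float, float]:
    """Unbiased Simpson's complement D with its configuration bounds.

    ``D = 1 - sum n_i(n_i-1) / (N(N-1))`` is the probability that two
    distinct sampled ramets belong to different genets.  ``D_max`` is D when
    all G genets have equal ramet counts; ``D_min`` when all but one genet
    are singletons.  Returns ``(D, D_min, D_max)``.
    """
    counts = np.asarray(list(ramet_counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("ramet_counts is empty")
    if (counts < 1).any():
        raise ValueError("every genet must have at least one ramet")
    n = int(counts.sum())
    g = counts.size
    if n < 2:
        raise ValueError("Simpson's complement requires N >= 2")
    d = 1.0 - float((counts * (counts - 1)).sum()) / (n * (n - 1))
    d_max = n * (g - 1) / (g * (n - 1))
    d_min = 1.0 - (n - g + 1) * (n - g) / (n * (n - 1))
    return d, d_min, d_max


def evenness_v(ramet_counts) -> float:
    """Simpson's-complement evenness ``V = (D - D_min)/(D_max - D_min)``.

    0 when a single genet dominates, 1 when all genets have equal ramet
    counts.  Undefined (NaN) for G = 1, where the bounds coincide.  Values
    within 1e-12 of the bounds are clamped so the float-noise negatives a
    degenerate configuration produces are reported as exact 0 (or 1).
    """
    counts = np.asarray(list(ramet_counts), dtype=np.int64)
    if counts.size < 2:
        return float("nan")
    d, d_min, d_max = simpson_complement(counts)
    span = d_max - d_min
    if span <= 1e-12:
        return float("nan")
    v = (d - d_min) / span
    if abs(d - d_min) < 1e-12:
        return 0.0
    if abs(d - d_max) < 1e-12:
        return 1.0
    return min(max(v, 0.0), 1.0)


def fit_pareto_beta(ramet_counts) -> float:
    """Power-law (Pareto) slope of the clone-size distribution.

    Fits ordinary least squares of ``log N_{>=x}`` (number of lineages with
    at least x ramets) against ``log x``, evaluated at every observed clone
    size (tied sizes contribute one point each, so the body of the
    distribution is weighted by its multiplicity — the sparse extreme tail
    cannot flatten the slope).  Returns ``beta = -slope``; requires at
    least 3 distinct clone sizes, otherwise NaN.
    """
    counts = np.asarray(list(ramet_counts), dtype=np.int64)
    if np.unique(counts).size < 3:
        return float("nan")
    s = np.sort(counts)
    n_geq = len(s) - np.searchsorted(s, s, side="left")
    slope, _ = np.polyfit(np.log(s), np.log(n_geq), 1)
    return float(-slope)


# ---------------------------------------------------------------------------
# assembled partition


@dataclass
class ClonalPartition:
    """Individuals partitioned into MLGs and MLLs, with P_sex per repeated MLG."""

    individuals: tuple[str, ...]
    mlg_of: np.ndarray              # MLG id per individual
    mll_of: dict[int, int]          # MLG id -> MLL id
    psex_of: dict[int, float] = field(default_factory=dict)  # MLG id -> P_sex

    @property
    def mll_per_individual(self) -> np.ndarray:
        return np.array([self.mll_of[int(g)] for g in self.mlg_of], dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_mlg(self) -> int:
        return len(np.unique(self.mlg_of))

    @property
    def n_mll(self) -> int:
        return len(set(self.mll_of.values()))

    @property
    def ramet_counts(self) -> np.ndarray:
        """Ramets per MLL, ordered by MLL id."""
        mll = self.mll_per_individual
        ids, counts = np.unique(mll, return_counts=True)
        return counts

    def representatives(self, missing_mask: np.ndarray | None = None) -> list[int]:
        """One individual index per MLL: fewest missing loci, ties by input order."""
        mll = self.mll_per_individual
        reps: list[int] = []
        for m in np.unique(mll):
            members = np.nonzero(mll == m)[0]
            if missing_mask is not None:
                n_miss = missing_mask[members].sum(axis=1)
                members = members[np.argsort(n_miss, kind="stable")]
            reps.append(int(members[0]))
        return sorted(reps)


@dataclass
class ClonalIndices:
    """Summary indices of a population's clonal structure."""

    n_individuals: int
    n_mlg: int
    n_mll: int
    richness: float
    simpson_d: float
    d_min: float
    d_max: float
    evenness: float
    pareto_beta: float


def _multilocus_fis(table: GenotypeTable, rows: np.ndarray) -> float:
    """Multilocus 1 - Ho/Hs over representative rows (plug-in gene diversity)."""
    ho_vals, hs_vals = [], []
    for j in range(table.n_loci):
        pairs = table.alleles[rows, j, :]
        pairs = pairs[pairs[:, 0] != MISSING]
        if len(pairs) == 0:
            continue
        alleles = pairs.ravel()
        _, counts = np.unique(alleles, return_counts=True)
        freqs = counts / counts.sum()
        hs = 1.0 - float((freqs**2).sum())
        if hs <= 0:
            continue
        ho_vals.append(float((pairs[:, 0] != pairs[:, 1]).mean()))
        hs_vals.append(hs)
    if not hs_vals:
        return 0.0
    return 1.0 - float(np.mean(ho_vals)) / float(np.mean(hs_vals))


def clonal_partition(
    table: GenotypeTable,
    threshold: int = 1,
    freq_scheme: str = "per_genet",
    f_is: float | None = None,
    psex_convention: str = "parks-werth",
) -> ClonalPartition:
    """Full clone discrimination for one population's genotype table.

    Assigns MLGs, collapses MLLs at the allele-distance threshold, and
    computes ``P_sex`` for every MLG observed at least twice.  ``f_is``
    defaults to the multilocus per-population estimate over unique MLGs,
    floored at 0 (a negative inbreeding correction would deflate homozygote
    genotype probabilities below their Hardy-Weinberg value).
    """
    mlg_of = assign_mlg(table)
    mll_of = collapse_mll(table, mlg_of, threshold=threshold)
    freqs = estimate_allele_freqs(table, scheme=freq_scheme, mlg_of=mlg_of)
    if f_is is None:
        _, first = np.unique(mlg_of, return_index=True)
        f_is = max(0.0, _multilocus_fis(table, np.sort(first)))
    psex_of: dict[int, float] = {}
    ids, counts = np.unique(mlg_of, return_counts=True)
    for g, c in zip(ids, counts):
        if c < 2:
            continue
        rep = int(np.nonzero(mlg_of == g)[0][0])
        pg = p_gen(table.alleles[rep], freqs, table.loci, f_is=f_is)
        psex_of[int(g)] = p_sex(pg, int(c), table.n_individuals, convention=psex_convention)
    return ClonalPartition(table.individuals, mlg_of, mll_of, psex_of)


def clonal_indices(partition: ClonalPartition) -> ClonalIndices:
    """Richness, Simpson's complement, evenness and Pareto slope for a partition."""
    counts = partition.ramet_counts
    n = partition.n_individuals
    g = partition.n_mll
    d, d_min, d_max = simpson_complement(counts)
    return ClonalIndices(
        n_individuals=n,
        n_mlg=partition.n_mlg,
        n_mll=g,
        richness=clonal_richness(g, n),
        simpson_d=d,
        d_min=d_min,
        d_max=d_max,
        evenness=evenness_v(counts),
        pareto_beta=fit_pareto_beta(counts),
    )
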