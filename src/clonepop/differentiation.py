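"""Pairwise population differentiation on clone-corrected genotype tables.

Two families of estimators:

* Weir & Cockerham's (1984) theta — the variance-components estimator of
  Wright's F_ST: per locus and allele the among-population (a), among-
  individual (b) and within-individual (c) components are accumulated and
  ``theta = sum(a) / sum(a + b + c)``.
* The Nei G_ST family with Nei & Chesser (1983) small-sample corrections:
  ``G_ST = (H_T - H_S)/H_T``, Hedrick's (2005) ``G'_ST`` and Meirmans &
  Hedrick's (2011) ``G''_ST = k(H_T - H_S)/((k H_T - H_S)(1 - H_S))``,
  which reaches 1 when populations share no alleles regardless of
  within-population diversity (the reason it is preferred for highly
  polymorphic microsatellites).

Significance is assessed by permuting genets between populations (sample
sizes preserved) and recomputing the statistic; permutation never operates
on ramets — differentiation inputs are one representative per lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from clonepop.genotype_io import MISSING, GenotypeTable

__all__ = [
    "DiffResult",
    "wc_theta",
    "gst_family",
    "gst_from_frequencies",
    "diff_permutation_test",
    "pairwise_differentiation",
]


@dataclass
class DiffResult:
    """Pairwise differentiation indices with permutation p-values."""

    pair: tuple[str, str]
    f_st: float
    g_st: float
    g_prime_st: float
    g_dprime_st: float
    h_s: float
    h_t: float
    k: int
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# array-level cores (alleles: (n, L, 2); pop_codes: (n,) ints 0..r-1)


def _theta_components(alleles: np.ndarray, pop_codes: np.ndarray, r: int):
    """Summed Weir-Cockerham a and a+b+c over loci and alleles."""
    sum_a = 0.0
    sum_abc = 0.0
    n_loci = alleles.shape[1]
    for j in range(n_loci):
        pairs = alleles[:, j, :]
        scored = pairs[:, 0] != MISSING
        if not scored.any():
            continue
        pj = pairs[scored]
        cj = pop_codes[scored]
        n_i = np.bincount(cj, minlength=r).astype(float)
        if (n_i < 2).any():
            continue  # a deme with <2 scored genets gives no variance info
        values = np.unique(pj.ravel())
        if values.size < 2:
            continue
        n_bar = n_i.mean()
        n_total = n_i.sum()
        n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)
        for v in values:
            is_v = pj == v
            # allele frequency and heterozygote frequency per deme
            count_v = np.bincount(cj, weights=is_v.sum(axis=1), minlength=r)
            p_i = count_v / (2 * n_i)
            het_v = np.bincount(
                cj, weights=(is_v[:, 0] ^ is_v[:, 1]).astype(float), minlength=r
            )
            h_i = het_v / n_i
            p_bar = (n_i * p_i).sum() / n_total
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / n_total
            a = (n_bar / n_c) * (
                s2
                - (1.0 / (n_bar - 1))
                * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - ((r - 1) / r) * s2
                - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            c = h_bar / 2.0
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def _theta_from_arrays(alleles: np.ndarray, pop_codes: np.ndarray, r: int) -> float:
    sum_a, sum_abc = _theta_components(alleles, pop_codes, r)
    if sum_abc == 0.0:
        return float("nan")
    return sum_a / sum_abc


def _gst_from_arrays(alleles: np.ndarray, pop_codes: np.ndarray, r: int):
    """Multilocus (H_S, H_T) with Nei & Chesser corrections, then G-family."""
    hs_list: list[float] = []
    ht_list: list[float] = []
    n_loci = alleles.shape[1]
    for j in range(n_loci):
        pairs = alleles[:, j, :]
        scored = pairs[:, 0] != MISSING
        pj = pairs[scored]
        cj = pop_codes[scored]
        n_i = np.bincount(cj, minlength=r).astype(float)
        if (n_i < 2).any():
            continue
        values = np.unique(pj.ravel())
        # per-deme frequencies
        freq = np.empty((r, values.size))
        for t, v in enumerate(values):
            count_v = np.bincount(cj, weights=(pj == v).sum(axis=1), minlength=r)
            freq[:, t] = count_v / (2 * n_i)
        het = np.bincount(
            cj, weights=(pj[:, 0] != pj[:, 1]).astype(float), minlength=r
        )
        ho = (het / n_i).mean()
        hs_plug = (1.0 - (freq**2).sum(axis=1)).mean()
        n_harm = r / (1.0 / n_i).sum()
        hs = (n_harm / (n_harm - 1.0)) * (hs_plug - ho / (2.0 * n_harm))
        p_bar = freq.mean(axis=0)
        ht_plug = 1.0 - (p_bar**2).sum()
        ht = ht_plug + hs / (n_harm * r) - ho / (2.0 * n_harm * r)
        hs_list.append(hs)
        ht_list.append(ht)
    if not ht_list:
        return float("nan"), float("nan"), float("nan"), float("nan"), float("nan")
    h_s = float(np.mean(hs_list))
    h_t = float(np.mean(ht_list))
    if h_t <= 0:
        return float("nan"), float("nan"), float("nan"), h_s, h_t
    g_st = (h_t - h_s) / h_t
    g_prime = (
        float("nan")
        if h_s >= 1.0
        else g_st * (r - 1 + h_s) / ((r - 1) * (1.0 - h_s))
    )
    denom = (r * h_t - h_s) * (1.0 - h_s)
    g_dprime = float("nan") if denom <= 0 else r * (h_t - h_s) / denom
    return g_st, g_prime, g_dprime, h_s, h_t


def gst_from_frequencies(freqs: np.ndarray) -> dict[str, float]:
    """Parametric G_ST family from a (k populations x alleles) frequency matrix.

    Evaluates the index definitions on population allele frequencies
    directly, with no sample-size corrections: ``H_S = mean_i(1 - sum_a
    p_ia^2)``, ``H_T = 1 - sum_a p_bar_a^2``.  For any valid frequency
    configuration ``H_T >= H_S`` and ``G''_ST >= G'_ST >= G_ST >= 0``.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need a (k >= 2) x alleles frequency matrix")
    if not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("rows must each sum to 1")
    k = p.shape[0]
    h_s = float((1.0 - (p**2).sum(axis=1)).mean())
    p_bar = p.mean(axis=0)
    h_t = float(1.0 - (p_bar**2).sum())
    if h_t == 0:
        return {"G_ST": float("nan"), "G_prime_ST": float("nan"),
                "G_dprime_ST": float("nan"), "H_S": h_s, "H_T": h_t, "k": k}
    g_st = (h_t - h_s) / h_t
    g_prime = g_st * (k - 1 + h_s) / ((k - 1) * (1.0 - h_s)) if h_s < 1 else float("nan")
    denom = (k * h_t - h_s) * (1.0 - h_s)
    g_dprime = k * (h_t - h_s) / denom if denom > 0 else float("nan")
    return {"G_ST": g_st, "G_prime_ST": g_prime, "G_dprime_ST": g_dprime,
            "H_S": h_s, "H_T": h_t, "k": k}


def _encode(table: GenotypeTable, pair: tuple[str, str] | None):
    if pair is None:
        pops = table.population_names
    else:
        pops = tuple(pair)
    rows = [i for i, q in enumerate(table.populations) if q in set(pops)]
    if not rows:
        raise KeyError(f"no individuals in populations {pops}")
    code_of = {p: c for c, p in enumerate(pops)}
    pop_codes = np.array([code_of[table.populations[i]] for i in rows])
    counts = np.bincount(pop_codes, minlength=len(pops))
    if (counts < 2).any():
        small = [p for p, c in zip(pops, counts) if c < 2]
        raise ValueError(f"population(s) {small} have fewer than 2 genets")
    return table.alleles[rows], pop_codes, len(pops)


# ---------------------------------------------------------------------------
# public surface


def wc_theta(table: GenotypeTable, pair: tuple[str, str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta over a population pair (or all pops)."""
    alleles, pop_codes, r = _encode(table, pair)
    return float(_theta_from_arrays(alleles, pop_codes, r))


def gst_family(
    table: GenotypeTable, pair: tuple[str, str] | None = None
) -> dict[str, float]:
    """Multilocus G_ST, G'_ST, G''_ST with the underlying H_S and H_T."""
    alleles, pop_codes, r = _encode(table, pair)
    g_st, g_prime, g_dprime, h_s, h_t = _gst_from_arrays(alleles, pop_codes, r)
    return {
        "G_ST": g_st,
        "G_prime_ST": g_prime,
        "G_dprime_ST": g_dprime,
        "H_S": h_s,
        "H_T": h_t,
        "k": r,
    }


_STATISTICS = {
    "theta": lambda a, c, r: _theta_from_arrays(a, c, r),
    "g_st": lambda a, c, r: _gst_from_arrays(a, c, r)[0],
    "g_dprime_st": lambda a, c, r: _gst_from_arrays(a, c, r)[2],
}


def diff_permutation_test(
    table: GenotypeTable,
    pair: tuple[str, str],
    statistic: str = "theta",
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """One-sided permutation p-value for a differentiation statistic.

    Genets are shuffled between the two populations with sample sizes
    preserved; p is the smoothed proportion of permuted statistics at least
    as large as the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    alleles, pop_codes, r = _encode(table, pair)
    observed = stat(alleles, pop_codes, r)
    if np.isnan(observed):
        return float("nan")
    rng = np.random.default_rng(seed)
    perm = pop_codes.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        value = stat(alleles, perm, r)
        if not np.isnan(value) and value >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def pairwise_differentiation(
    table: GenotypeTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[DiffResult]:
    """All pairwise DiffResults for the populations in a clone-corrected table."""
    results = []
    for idx, pair in enumerate(combinations(table.population_names, 2)):
        theta = wc_theta(table, pair)
        g = gst_family(table, pair)
        pair_seed = None if seed is None else seed + idx
        p_theta = diff_permutation_test(
            table, pair, "theta", n_perm=n_perm, seed=pair_seed
        )
        p_gpp = diff_permutation_test(
            table, pair, "g_dprime_st", n_perm=n_perm,
            seed=None if pair_seed is None else pair_seed + 10_000,
        )
        results.append(
            DiffResult(
                pair=pair,
                f_st=theta,
                g_st=g["G_ST"],
                g_prime_st=g["G_prime_ST"],
                g_dprime_st=g["G_dprime_ST"],
                h_s=g["H_S"],
                h_t=g["H_T"],
                k=2,
                p_values={"F_ST": p_theta, "G_dprime_ST": p_gpp},
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results
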