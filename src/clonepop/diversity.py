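"""Per-locus genetic diversity on unique lineages, and locus-QC tests.

All statistics here are meant to be computed on a table holding one
representative per multilocus lineage (clone-corrected data): clonal
replication otherwise pseudo-replicates genotypes and biases every
frequency-based quantity.

Estimators
----------
* ``He`` — unbiased expected heterozygosity (Nei 1978),
  ``(2n/(2n-1)) (1 - sum f_i^2)`` with *n* genets scored.
* ``F_IS`` — primary definition ``1 - Ho/Hs`` with the plug-in gene
  diversity ``Hs = 1 - sum f_i^2`` (an all-heterozygote two-allele locus
  gives exactly -1); the Weir-Cockerham small-sample *f* is reported
  alongside.
* ``AR`` — allelic richness rarefied to a common number of gene copies by
  the hypergeometric expectation ``sum_i [1 - C(2n-c_i, m)/C(2n, m)]``.
* Null alleles — Brookfield estimator 1, ``r = (He - Ho)/(1 + He)``,
  flagged when *r* exceeds a threshold and a one-sided binomial test finds
  significant homozygote excess.

The Hardy-Weinberg and linkage-disequilibrium tests are permutation tests
in the FSTAT style: alleles (HWE) or single-locus genotypes (LD) are
shuffled among individuals within a population, and the p-value is the
smoothed proportion of permutations at least as extreme as the observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from clonepop.genotype_io import MISSING, GenotypeTable

__all__ = [
    "LocusSummary",
    "diversity_summary",
    "multilocus_summary",
    "hwe_permutation_test",
    "linkage_permutation_test",
    "null_allele_test",
]


@dataclass
class LocusSummary:
    """Diversity summary for one locus in one population."""

    locus: str
    population: str
    n: int                      # genets with a scored call
    na: int                     # allele count
    ar: float                   # rarefied allelic richness
    ap: int                     # private alleles (absent from all other pops)
    ho: float
    he: float                   # unbiased expected heterozygosity
    fis: float                  # 1 - Ho/Hs (NaN when Hs = 0)
    fis_wc: float               # Weir-Cockerham small-sample f
    hwe_p: float = float("nan")
    null_r: float = float("nan")
    null_flag: bool = False


# ---------------------------------------------------------------------------
# building blocks


def _locus_counts(table: GenotypeTable, j: int, rows: np.ndarray):
    """Non-missing pairs and allele counts for locus column j over rows."""
    pairs = table.alleles[rows, j, :]
    pairs = pairs[pairs[:, 0] != MISSING]
    if len(pairs) == 0:
        return pairs, np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    values, counts = np.unique(pairs.ravel(), return_counts=True)
    return pairs, values, counts


def _unbiased_he(counts: np.ndarray) -> float:
    m = counts.sum()
    if m < 2:
        return 0.0
    freqs = counts / m
    return float((m / (m - 1)) * (1.0 - (freqs**2).sum()))


def _plugin_hs(counts: np.ndarray) -> float:
    m = counts.sum()
    if m == 0:
        return 0.0
    freqs = counts / m
    return float(1.0 - (freqs**2).sum())


def _wc_f_single_pop(pairs: np.ndarray) -> float:
    """Weir-Cockerham within-population f for one sample at one locus."""
    n = len(pairs)
    if n < 2:
        return float("nan")
    values = np.unique(pairs.ravel())
    if values.size < 2:
        return float("nan")
    sum_b = 0.0
    sum_c = 0.0
    for a in values:
        p = float((pairs == a).sum()) / (2 * n)
        h = float(((pairs[:, 0] == a) ^ (pairs[:, 1] == a)).mean())
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        sum_b += b
        sum_c += h / 2
    denom = sum_b + sum_c
    if denom == 0:
        return float("nan")
    return float(1.0 - sum_c / denom)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts: np.ndarray, m: int) -> float:
    """Expected allele count in a random subsample of ``m`` gene copies."""
    total = int(counts.sum())
    if m > total:
        raise ValueError(f"rarefaction size {m} exceeds {total} gene copies")
    ar = 0.0
    for c in counts:
        if total - c < m:
            ar += 1.0
        else:
            ar += 1.0 - math.exp(_log_comb(total - c, m) - _log_comb(total, m))
    return float(ar)


# ---------------------------------------------------------------------------
# the summary


def diversity_summary(
    table: GenotypeTable, rarefaction_size: int | None = None
) -> list[LocusSummary]:
    """Per-locus, per-population diversity on a clone-corrected table.

    ``rarefaction_size`` is the number of gene copies AR is rarefied to;
    the default is the smallest number of scored gene copies over all
    (population, locus) cells, so every cell can be rarefied.
    """
    pops = table.population_names
    pop_rows = {p: np.array([i for i, q in enumerate(table.populations) if q == p]) for p in pops}

    copies = []
    cell: dict[tuple[str, int], tuple] = {}
    for p in pops:
        for j in range(table.n_loci):
            pairs, values, counts = _locus_counts(table, j, pop_rows[p])
            cell[(p, j)] = (pairs, values, counts)
            if counts.sum() > 0:
                copies.append(int(counts.sum()))
    if not copies:
        raise ValueError("no scored calls anywhere in the table")
    if rarefaction_size is None:
        rarefaction_size = min(copies)
    if rarefaction_size > min(copies):
        raise ValueError(
            f"rarefaction size {rarefaction_size} exceeds the smallest "
            f"population sample of {min(copies)} gene copies"
        )

    out: list[LocusSummary] = []
    for p in pops:
        for j, locus in enumerate(table.loci):
            pairs, values, counts = cell[(p, j)]
            n = len(pairs)
            if n == 0:
                out.append(
                    LocusSummary(locus, p, 0, 0, float("nan"), 0,
                                 float("nan"), float("nan"), float("nan"), float("nan"))
                )
                continue
            ho = float((pairs[:, 0] != pairs[:, 1]).mean())
            he = _unbiased_he(counts)
            hs = _plugin_hs(counts)
            fis = float("nan") if hs == 0 else 1.0 - ho / hs
            others = set()
            for q in pops:
                if q != p:
                    others.update(cell[(q, j)][1].tolist())
            ap = int(sum(1 for v in values if int(v) not in others))
            out.append(
                LocusSummary(
                    locus=locus,
                    population=p,
                    n=n,
                    na=int(values.size),
                    ar=rarefied_richness(counts, rarefaction_size),
                    ap=ap,
                    ho=ho,
                    he=he,
                    fis=fis,
                    fis_wc=_wc_f_single_pop(pairs),
                )
            )
    return out


def multilocus_summary(summaries: list[LocusSummary]) -> dict[str, dict[str, float]]:
    """Unweighted per-population means over loci (plus allele totals).

    Returns ``{population: {"A": total alleles, "AR": mean, "Ap": total,
    "Ho": mean, "He": mean, "F_IS": 1 - mean(Ho)/mean(He)}}``; loci with no
    scored calls in a population are skipped.
    """
    pops: dict[str, list[LocusSummary]] = {}
    for s in summaries:
        if s.n > 0:
            pops.setdefault(s.population, []).append(s)
    out: dict[str, dict[str, float]] = {}
    for p, rows in pops.items():
        ho = float(np.mean([s.ho for s in rows]))
        he = float(np.mean([s.he for s in rows]))
        fis_rows = [s.fis for s in rows if not math.isnan(s.fis)]
        out[p] = {
            "A": float(sum(s.na for s in rows)),
            "AR": float(np.mean([s.ar for s in rows])),
            "Ap": float(sum(s.ap for s in rows)),
            "Ho": ho,
            "He": he,
            "F_IS": float("nan") if he == 0 else 1.0 - ho / he,
            "F_IS_locus_mean": float(np.mean(fis_rows)) if fis_rows else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# permutation tests


def _abs_fis_from_pairs(pairs: np.ndarray, hs: float) -> float:
    ho = float((pairs[:, 0] != pairs[:, 1]).mean())
    return abs(1.0 - ho / hs)


def hwe_permutation_test(
    table: GenotypeTable,
    locus: str,
    population: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided permutation test of Hardy-Weinberg within a population.

    Alleles at the locus are pooled over the population's scored
    individuals and randomly re-paired; the p-value is the smoothed
    proportion of permutations with ``|F_IS|`` at least the observed value.
    Returns NaN for a monomorphic locus.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    j = table.loci.index(locus)
    rows = np.array([i for i, q in enumerate(table.populations) if q == population])
    if rows.size == 0:
        raise KeyError(f"unknown population {population!r}")
    pairs, values, counts = _locus_counts(table, j, rows)
    if values.size < 2:
        return float("nan")
    hs = _plugin_hs(counts)
    observed = _abs_fis_from_pairs(pairs, hs)
    pool = pairs.ravel().copy()
    rng = np.random.default_rng(seed)
    n = len(pairs)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        perm = pool.reshape(n, 2)
        # allele counts are invariant under shuffling, so hs is fixed
        if _abs_fis_from_pairs(perm, hs) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, ka: int, kb: int) -> float:
    """G log-likelihood statistic of the two-way contingency table."""
    flat = codes_a * kb + codes_b
    obs = np.bincount(flat, minlength=ka * kb).astype(float).reshape(ka, kb)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    return float(2.0 * terms.sum())


def linkage_permutation_test(
    table: GenotypeTable,
    locus_pair: tuple[str, str],
    population: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation test of genotypic linkage disequilibrium between two loci.

    The statistic is the G log-likelihood of the two-locus genotype
    contingency table; the null is built by permuting one locus's genotypes
    among the population's individuals scored at both loci.  Returns NaN if
    either locus is genotypically monomorphic in the population.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    la, lb = locus_pair
    ja, jb = table.loci.index(la), table.loci.index(lb)
    rows = np.array([i for i, q in enumerate(table.populations) if q == population])
    if rows.size == 0:
        raise KeyError(f"unknown population {population!r}")
    a = table.alleles[rows, ja, :]
    b = table.alleles[rows, jb, :]
    keep = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    a, b = a[keep], b[keep]
    codes_a = np.unique(a, axis=0, return_inverse=True)[1].ravel()
    codes_b = np.unique(b, axis=0, return_inverse=True)[1].ravel()
    ka, kb = codes_a.max() + 1, codes_b.max() + 1
    if ka < 2 or kb < 2:
        return float("nan")
    observed = _g_statistic(codes_a, codes_b, ka, kb)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes_b.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _g_statistic(codes_a, perm, ka, kb) >= observed - 1e-9:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# null alleles


def null_allele_test(
    table: GenotypeTable,
    locus: str,
    population: str,
    r_threshold: float = 0.1,
    alpha: float = 0.05,
) -> dict:
    """Brookfield estimator-1 null-allele screen for one locus/population.

    ``r = (He - Ho)/(1 + He)``.  The locus is flagged when ``r`` exceeds
    ``r_threshold`` *and* a one-sided binomial test of the observed
    homozygote count against the Hardy-Weinberg expectation finds a
    significant excess.  Returns ``{"testable", "r", "p", "flag"}``.
    """
    j = table.loci.index(locus)
    rows = np.array([i for i, q in enumerate(table.populations) if q == population])
    if rows.size == 0:
        raise KeyError(f"unknown population {population!r}")
    pairs, values, counts = _locus_counts(table, j, rows)
    n = len(pairs)
    if values.size < 2 or n < 5:
        return {"testable": False, "r": float("nan"), "p": float("nan"), "flag": False}
    ho = float((pairs[:, 0] != pairs[:, 1]).mean())
    he = _unbiased_he(counts)
    r = (he - ho) / (1.0 + he)
    hs = _plugin_hs(counts)
    n_hom = int((pairs[:, 0] == pairs[:, 1]).sum())
    p = float(stats.binomtest(n_hom, n, 1.0 - hs, alternative="greater").pvalue)
    return {
        "testable": True,
        "r": float(r),
        "p": p,
        "flag": bool(r > r_threshold and p < alpha),
    }
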