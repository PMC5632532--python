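"""Synthetic clonal microsatellite datasets with a full truth record.

The generator emulates small invasive-coral microsatellite surveys: a few
populations of ~24 sampled colonies, 8-10 loci with 1-5 alleles each, heavy
clonal replication with one dominant genet per site, occasional one-allele
scoring slips, and sparse missing data.

Model
-----
* Ancestral allele frequencies per locus are drawn from a symmetric
  Dirichlet (or supplied); population frequencies diverge from them under
  the Balding-Nichols model, ``Dirichlet(ancestral * (1-F)/F)``.
* Genet genotypes are drawn per locus with inbreeding: with probability
  ``f_is_sim`` the locus is autozygous (one draw duplicated), otherwise the
  two gene copies are drawn independently.
* Each genet is replicated into ramets according to a clone-size law
  (fixed counts, one dominant clone, discrete Pareto, or uniform).
* Observation noise: null-allele masking (a carrier renders as an apparent
  homozygote of its visible allele; a null homozygote as missing), a
  per-ramet one-allele scoring error of one repeat unit, and random
  missing calls.

Allele *indices* are mapped to plausible fragment sizes
(``base + spacing*locus + repeat_unit*(index+1)``) so emitted GenAlEx files
look like real fragment-analysis exports.

Everything is deterministic under the config seed, and every stochastic
event (true genotypes, injected errors, masked and missing calls) is
recorded in the :class:`TruthRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from clonepop.errors import ConfigError
from clonepop.genotype_io import MISSING, GenotypeTable, table_from_calls
from clonepop.clonal import pairwise_allele_distances

__all__ = ["SimConfig", "TruthRecord", "simulate_dataset", "make_paper_like_fixture"]


@dataclass
class SimConfig:
    """Full parameterisation of the clonal-population generator."""

    seed: int
    n_pops: int = 2
    genets_per_pop: int = 6
    ramets_per_pop: int = 24
    n_loci: int = 10
    alleles_per_locus: int = 4
    dirichlet_concentration: float = 1.0
    ancestral_freqs: Sequence[np.ndarray] | None = None
    divergence_f: float = 0.05
    f_is_sim: float = 0.0
    clone_size_law: tuple | str = ("dominant", 19)
    scoring_error_rate: float = 0.0
    missing_rate: float = 0.0
    null_allele_freq: float | Sequence[float] | None = None
    pop_names: tuple[str, ...] | None = None
    base_size: int = 100
    locus_spacing: int = 24
    repeat_unit: int = 3

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ConfigError("n_pops must be >= 1")
        if not 1 <= self.genets_per_pop <= self.ramets_per_pop:
            raise ConfigError("need 1 <= genets_per_pop <= ramets_per_pop")
        if self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ConfigError("need at least one locus and one allele")
        if not 0.0 < self.divergence_f < 1.0:
            raise ConfigError("divergence_f must be in (0, 1)")
        for name, v in [
            ("f_is_sim", self.f_is_sim),
            ("scoring_error_rate", self.scoring_error_rate),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability")
        if self.pop_names is not None and len(self.pop_names) != self.n_pops:
            raise ConfigError("pop_names length must equal n_pops")

    @property
    def null_freqs(self) -> np.ndarray:
        if self.null_allele_freq is None:
            return np.zeros(self.n_loci)
        q = np.broadcast_to(np.asarray(self.null_allele_freq, dtype=float), (self.n_loci,))
        if (q < 0).any() or (q > 1).any():
            raise ConfigError("null_allele_freq entries must be probabilities")
        return q.copy()


@dataclass
class TruthRecord:
    """Ground truth paired with a simulated :class:`GenotypeTable`."""

    genet_of: tuple[int, ...]                      # global genet id per ramet
    clone_sizes: dict[str, tuple[int, ...]]        # per population
    true_genotypes: dict[int, np.ndarray]          # genet id -> (L, 2) sizes
    pop_freqs: dict[str, np.ndarray]               # (L, k) drawn frequencies
    allele_sizes: np.ndarray                       # (L, k) index -> fragment size
    errors: list[tuple[str, str, int, int]] = field(default_factory=list)
    masked_null: list[tuple[str, str]] = field(default_factory=list)
    missing: list[tuple[str, str]] = field(default_factory=list)

    def n_genets(self, population: str | None = None) -> int:
        if population is None:
            return len(self.true_genotypes)
        return len(self.clone_sizes[population])

    def observed_allele_counts(self, table: GenotypeTable) -> dict[str, dict[int, int]]:
        """Allele counts per locus of an emitted table (consistency helper)."""
        out: dict[str, dict[int, int]] = {}
        for j, locus in enumerate(table.loci):
            pairs = table.alleles[:, j, :]
            pairs = pairs[pairs[:, 0] != MISSING]
            values, counts = np.unique(pairs.ravel(), return_counts=True)
            out[locus] = {int(v): int(c) for v, c in zip(values, counts)}
        return out


# ---------------------------------------------------------------------------
# clone-size laws


def clone_sizes(law: tuple | str, n_genets: int, n_ramets: int, rng) -> list[int]:
    """Resolve a clone-size law to per-genet ramet counts summing to N."""
    if isinstance(law, str):
        law = (law,)
    kind = law[0]
    if kind == "fixed_counts":
        counts = [int(c) for c in law[1]]
        if len(counts) != n_genets or sum(counts) != n_ramets or min(counts) < 1:
            raise ConfigError("fixed_counts must give one positive count per genet, summing to N")
        return counts
    if kind == "uniform":
        base, extra = divmod(n_ramets, n_genets)
        return [base + (1 if i < extra else 0) for i in range(n_genets)]
    if kind == "dominant":
        n_dom = int(law[1])
        rest = n_ramets - n_dom
        if n_genets == 1:
            if n_dom != n_ramets:
                raise ConfigError("dominant size must equal N when G = 1")
            return [n_dom]
        if rest < n_genets - 1:
            raise ConfigError("dominant clone too large for the remaining genets")
        base, extra = divmod(rest, n_genets - 1)
        tail = [base + (1 if i < extra else 0) for i in range(n_genets - 1)]
        if max(tail) > n_dom:
            raise ConfigError("dominant clone smaller than the evenly split remainder")
        return [n_dom] + tail
    if kind == "pareto":
        beta = float(law[1])
        if beta <= 0:
            raise ConfigError("pareto beta must be positive")
        draws = rng.zipf(beta + 1.0, size=n_genets)
        sizes = np.minimum(draws, n_ramets).astype(int)
        # nudge to the exact total while keeping every genet >= 1
        diff = n_ramets - int(sizes.sum())
        while diff != 0:
            if diff > 0:
                sizes[int(np.argmax(sizes))] += 1
                diff -= 1
            else:
                candidates = np.nonzero(sizes > 1)[0]
                if candidates.size == 0:
                    raise ConfigError("cannot fit pareto sizes to N with G genets")
                sizes[candidates[int(np.argmax(sizes[candidates]))]] -= 1
                diff += 1
        return [int(s) for s in sizes]
    raise ConfigError(f"unknown clone_size_law {law!r}")


# ---------------------------------------------------------------------------
# the generator


def simulate_dataset(config: SimConfig) -> tuple[GenotypeTable, TruthRecord]:
    """Draw a clonal multi-population genotype table plus its truth record."""
    rng = np.random.default_rng(config.seed)
    L, k = config.n_loci, config.alleles_per_locus
    pops = config.pop_names or tuple(f"pop{i + 1}" for i in range(config.n_pops))

    if config.ancestral_freqs is not None:
        ancestral = [np.asarray(f, dtype=float) for f in config.ancestral_freqs]
        if len(ancestral) != L:
            raise ConfigError("ancestral_freqs must give one vector per locus")
    else:
        ancestral = [
            rng.dirichlet(np.full(k, config.dirichlet_concentration)) for _ in range(L)
        ]

    sizes_map = np.array(
        [
            [
                config.base_size + config.locus_spacing * j + config.repeat_unit * (a + 1)
                for a in range(max(len(ancestral[j]), k))
            ]
            for j in range(L)
        ],
        dtype=np.int64,
    )
    loci = tuple(f"L{j + 1:02d}" for j in range(L))
    null_q = config.null_freqs

    individuals: list[str] = []
    populations: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    genet_of: list[int] = []
    clone_sizes_out: dict[str, tuple[int, ...]] = {}
    true_genotypes: dict[int, np.ndarray] = {}
    pop_freqs: dict[str, np.ndarray] = {}
    errors: list[tuple[str, str, int, int]] = []
    masked_null: list[tuple[str, str]] = []
    missing_log: list[tuple[str, str]] = []

    fbn = (1.0 - config.divergence_f) / config.divergence_f
    next_genet = 0
    for pop in pops:
        freqs = np.zeros((L, sizes_map.shape[1]))
        for j in range(L):
            anc = ancestral[j]
            freqs[j, : anc.size] = rng.dirichlet(anc * fbn)
        pop_freqs[pop] = freqs

        sizes = clone_sizes(
            config.clone_size_law, config.genets_per_pop, config.ramets_per_pop, rng
        )
        clone_sizes_out[pop] = tuple(sizes)

        # genet-level truth: true genotype + null-masked observable genotype
        genet_ids = list(range(next_genet, next_genet + len(sizes)))
        next_genet += len(sizes)
        observable: dict[int, list[tuple[int, int]]] = {}
        genet_null_hits: dict[int, list[int]] = {}
        for g in genet_ids:
            geno = np.zeros((L, 2), dtype=np.int64)
            obs: list[tuple[int, int]] = []
            null_hits: list[int] = []
            for j in range(L):
                f = freqs[j] / freqs[j].sum()
                if rng.random() < config.f_is_sim:
                    a = b = int(rng.choice(f.size, p=f))
                else:
                    a = int(rng.choice(f.size, p=f))
                    b = int(rng.choice(f.size, p=f))
                geno[j] = sorted((sizes_map[j, a], sizes_map[j, b]))
                if null_q[j] > 0:
                    a_null = rng.random() < null_q[j]
                    b_null = rng.random() < null_q[j]
                    if a_null and b_null:
                        obs.append((MISSING, MISSING))
                        null_hits.append(j)
                        continue
                    if a_null or b_null:
                        visible = int(sizes_map[j, b if a_null else a])
                        obs.append((visible, visible))
                        null_hits.append(j)
                        continue
                obs.append((int(geno[j, 0]), int(geno[j, 1])))
            true_genotypes[g] = geno
            observable[g] = obs
            genet_null_hits[g] = null_hits

        ramet_no = 0
        for g, size in zip(genet_ids, sizes):
            for _ in range(size):
                ramet_no += 1
                name = f"{pop}_{ramet_no:02d}"
                row = [tuple(c) for c in observable[g]]
                for j in genet_null_hits[g]:
                    masked_null.append((name, loci[j]))
                if config.scoring_error_rate > 0 and rng.random() < config.scoring_error_rate:
                    scored = [j for j in range(L) if row[j][0] != MISSING]
                    if scored:
                        j = int(rng.choice(scored))
                        which = int(rng.integers(2))
                        shift = config.repeat_unit * (1 if rng.random() < 0.5 else -1)
                        old = row[j][which]
                        new = max(old + shift, config.repeat_unit)
                        pair = list(row[j])
                        pair[which] = new
                        row[j] = (min(pair), max(pair))
                        errors.append((name, loci[j], old, new))
                if config.missing_rate > 0:
                    for j in range(L):
                        if row[j][0] != MISSING and rng.random() < config.missing_rate:
                            row[j] = (MISSING, MISSING)
                            missing_log.append((name, loci[j]))
                individuals.append(name)
                populations.append(pop)
                calls.append(row)
                genet_of.append(g)

    table = table_from_calls(individuals, populations, loci, calls)
    truth = TruthRecord(
        genet_of=tuple(genet_of),
        clone_sizes=clone_sizes_out,
        true_genotypes=true_genotypes,
        pop_freqs=pop_freqs,
        allele_sizes=sizes_map,
        errors=errors,
        masked_null=masked_null,
        missing=missing_log,
    )
    return table, truth


# ---------------------------------------------------------------------------
# paper-shaped fixture


#: name -> (n_ramets, n_genets, dominant clone size, one-allele slips to inject)
_PAPER_SHAPES = {
    "Tc-TSB": (23, 13, 4, 0),
    "Tc-IGB": (24, 6, 19, 0),
    "Tt-TSB": (24, 5, 14, 2),
    "Tt-IGB": (24, 3, 22, 3),
}


def _simulate_population_min_distance(
    config: SimConfig, min_distance: int, max_tries: int = 200
) -> tuple[GenotypeTable, TruthRecord]:
    """Redraw until all genets are pairwise >= min_distance alleles apart.

    Guarantees that a single injected one-allele slip stays closer to its
    own genet than to any other, so lineage collapsing is unambiguous.
    """
    for attempt in range(max_tries):
        cfg = replace(config, seed=config.seed + 1_000_003 * attempt)
        table, truth = simulate_dataset(cfg)
        genotypes = np.stack([truth.true_genotypes[g] for g in sorted(truth.true_genotypes)])
        d = pairwise_allele_distances(genotypes)
        m = d[np.triu_indices(len(genotypes), k=1)]
        if m.size == 0 or m.min() >= min_distance:
            return table, truth
    raise RuntimeError("could not draw sufficiently distinct genets")


def make_paper_like_fixture(seed: int) -> dict[str, tuple[GenotypeTable, TruthRecord]]:
    """Two-species, two-site bundle shaped like the study's four samples.

    Emits four single-population tables keyed ``Tc-TSB``, ``Tc-IGB``,
    ``Tt-TSB``, ``Tt-IGB`` with the published sample sizes, lineage counts
    and dominant-clone sizes (23 ramets/13 genets dominant 4;
    24/6 dominant 19; 24/5 dominant 14; 24/3 dominant 22).  The two sites of
    each species share ancestral frequencies and loci, so per-species tables
    can be concatenated for differentiation analyses.  The one-allele
    scoring slips that split some lineages into several multilocus genotypes
    (7 MLG/5 MLL and 6 MLG/3 MLL in the second species) are injected
    deterministically into ramets of the dominant clone at distinct loci.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[GenotypeTable, TruthRecord]] = {}
    for species, L, k in [("Tc", 8, 3), ("Tt", 10, 3)]:
        sub = np.random.default_rng(rng.integers(2**31 - 1))
        ancestral = [sub.dirichlet(np.full(k, 5.0)) for _ in range(L)]
        for site in ("TSB", "IGB"):
            n, g, dom, n_slips = _PAPER_SHAPES[f"{species}-{site}"]
            cfg = SimConfig(
                seed=int(sub.integers(2**31 - 1)),
                n_pops=1,
                genets_per_pop=g,
                ramets_per_pop=n,
                n_loci=L,
                alleles_per_locus=k,
                ancestral_freqs=ancestral,
                divergence_f=0.10,
                clone_size_law=("dominant", dom),
                pop_names=(site,),
            )
            table, truth = _simulate_population_min_distance(cfg, min_distance=3)
            if n_slips:
                arr = np.array(table.alleles, dtype=np.int64)
                # dominant clone = first genet; skip its first (reference) ramet
                members = [i for i, gid in enumerate(truth.genet_of)
                           if gid == min(truth.genet_of)][1:]
                for s in range(n_slips):
                    i, j = members[s], s  # distinct loci => distinct mutant MLGs
                    old = int(arr[i, j, 1])
                    new = old + cfg.repeat_unit
                    arr[i, j, 1] = new
                    truth.errors.append((table.individuals[i], table.loci[j], old, new))
                table = GenotypeTable(table.individuals, table.populations, table.loci, arr)
            out[f"{species}-{site}"] = (table, truth)
    return out
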