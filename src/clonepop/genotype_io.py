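"""Data model and I/O for diploid multilocus microsatellite genotypes.

The central container is :class:`GenotypeTable`: an individuals x loci matrix
of unordered diploid allele pairs (integer fragment sizes in base pairs),
with a population label per individual.  Missing calls are stored as the
pair ``(0, 0)``; the module-level constant :data:`MISSING` is that sentinel.

Two on-disk dialects are supported:

* ``genalex`` — a GenAlEx-style codominant CSV: a numeric header row
  (n_loci, n_individuals, n_pops, then per-population sizes), a title row
  carrying population names, a column-header row, then one row per
  individual with two columns per locus.
* ``long`` — a tidy CSV with columns
  ``individual,population,locus,allele1,allele2``.

Half-missing calls (one allele scored, the other not) are conservatively
treated as fully missing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from clonepop.errors import EmptyTableError, FormatError, PipelineAbortError

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing call.  A missing call is (0, 0).
MISSING: int = 0


class LocusStatus(str, Enum):
    """Quality-control fate of a locus."""

    RETAINED = "retained"
    DROPPED_NULL_ALLELES = "dropped_null_alleles"
    DROPPED_LINKAGE = "dropped_linkage"
    DROPPED_MONOMORPHIC_FAILURE = "dropped_monomorphic_failure"


@dataclass
class LocusMeta:
    """Per-locus metadata and QC status."""

    name: str
    repeat_motif: str = ""
    size_range: tuple[int, int] | None = None
    status: LocusStatus = LocusStatus.RETAINED


@dataclass(frozen=True)
class GenotypeTable:
    """Individuals x loci diploid allele-size matrix with population labels.

    Parameters
    ----------
    individuals:
        Ordered unique individual identifiers.
    populations:
        Population label per individual (same order).  Labels partition the
        individuals; every declared population is non-empty.
    loci:
        Ordered unique locus names.
    alleles:
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Each
        non-missing call holds two positive allele sizes sorted ascending
        (a homozygote repeats the value); a missing call is ``(0, 0)``.
    """

    individuals: tuple[str, ...]
    populations: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles, dtype=np.int64)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if arr.shape[0] != len(self.individuals) or arr.shape[1] != len(self.loci):
            raise ValueError("alleles shape does not match individuals/loci")
        if len(self.individuals) == 0:
            raise EmptyTableError("table has no individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(self.populations) != len(self.individuals):
            raise ValueError("populations must give one label per individual")
        if arr.min(initial=0) < 0:
            raise ValueError("allele values must be positive (0 = missing)")
        # half-missing (one zero) is normalised upstream; enforce here
        half = (arr == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls must be normalised to (0, 0)")
        # canonical unordered pair: sorted ascending
        object.__setattr__(self, "alleles", np.sort(arr, axis=2))
        self.alleles.setflags(write=False)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.alleles[:, :, 0] == MISSING

    @property
    def population_names(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return tuple(seen)

    # -- subsetting --------------------------------------------------------
    def take_individuals(self, index: Sequence[int]) -> "GenotypeTable":
        idx = list(index)
        if not idx:
            raise EmptyTableError("selection removes every individual")
        return GenotypeTable(
            individuals=tuple(self.individuals[i] for i in idx),
            populations=tuple(self.populations[i] for i in idx),
            loci=self.loci,
            alleles=self.alleles[idx],
        )

    def select_loci(self, names: Iterable[str]) -> "GenotypeTable":
        wanted = list(names)
        pos = {l: j for j, l in enumerate(self.loci)}
        missing = [l for l in wanted if l not in pos]
        if missing:
            raise KeyError(f"unknown loci: {missing}")
        cols = [pos[l] for l in wanted]
        return GenotypeTable(
            individuals=self.individuals,
            populations=self.populations,
            loci=tuple(wanted),
            alleles=self.alleles[:, cols],
        )

    def restrict_population(self, population: str) -> "GenotypeTable":
        idx = [i for i, p in enumerate(self.populations) if p == population]
        if not idx:
            raise KeyError(f"unknown population: {population!r}")
        return self.take_individuals(idx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.individuals, self.populations, self.loci))


# ---------------------------------------------------------------------------
# construction helpers


def table_from_calls(
    individuals: Sequence[str],
    populations: Sequence[str],
    loci: Sequence[str],
    calls: np.ndarray | Sequence,
) -> GenotypeTable:
    """Build a table from raw calls, normalising half-missing pairs to missing."""
    arr = np.array(calls, dtype=np.int64)
    half = (arr == MISSING).sum(axis=2) == 1
    if half.any():
        arr[half] = MISSING
    return GenotypeTable(tuple(individuals), tuple(populations), tuple(loci), arr)


def concat_tables(*tables: GenotypeTable) -> GenotypeTable:
    """Stack tables sharing the same loci into one multi-population table."""
    if not tables:
        raise ValueError("need at least one table")
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValueError("tables have different locus sets")
    individuals = tuple(i for t in tables for i in t.individuals)
    populations = tuple(p for t in tables for p in t.populations)
    alleles = np.concatenate([t.alleles for t in tables], axis=0)
    return GenotypeTable(individuals, populations, loci, alleles)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_allele(token: str, missing_code: int, row: int, col: int) -> int:
    token = token.strip()
    if token == "":
        return MISSING
    try:
        value = int(token)
    except ValueError as exc:
        raise FormatError(
            f"non-integer allele token {token!r} at row {row}, column {col}"
        ) from exc
    if value == missing_code:
        return MISSING
    if value <= 0:
        raise FormatError(
            f"allele value {value} at row {row}, column {col} must be positive"
        )
    return value


def read_genotype_table(
    path, dialect: str = "genalex", missing_code: int = 0
) -> GenotypeTable:
    """Read a genotype table from a GenAlEx-style or long-format CSV.

    Parameters
    ----------
    path:
        CSV file path.
    dialect:
        ``"genalex"`` (two columns per locus, numeric header) or ``"long"``
        (``individual,population,locus,allele1,allele2``).
    missing_code:
        Integer token encoding a missing allele (GenAlEx convention: 0).

    Returns
    -------
    GenotypeTable
        Validated table preserving input individual order.
    """
    if dialect == "genalex":
        return _read_genalex(path, missing_code)
    if dialect == "long":
        return _read_long(path, missing_code)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genalex(path, missing_code: int) -> GenotypeTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise FormatError("GenAlEx file needs 3 header rows plus data")
    try:
        n_loci, n_ind, n_pops = (int(x) for x in rows[0][:3])
        pop_sizes = [int(x) for x in rows[0][3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise FormatError("malformed GenAlEx numeric header row") from exc
    pop_names = [x for x in rows[1][2 : 2 + n_pops] if x.strip()]
    if len(pop_names) != n_pops:
        pop_names = [f"pop{i + 1}" for i in range(n_pops)]
    header = rows[2]
    if len(header) < 2 + 2 * n_loci:
        raise FormatError(
            f"locus columns malformed: expected {2 * n_loci} allele columns "
            f"(two per locus), found {len(header) - 2}"
        )
    loci = [header[2 + 2 * j].strip() for j in range(n_loci)]
    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_ind:
        raise FormatError(
            f"header declares {n_ind} individuals but file has {len(data)} data rows"
        )
    if sum(pop_sizes) != n_ind:
        raise FormatError("population sizes in header do not sum to n_individuals")
    individuals, populations, calls = [], [], []
    # individuals appear grouped by population, sizes from the header
    bounds = np.cumsum([0] + pop_sizes)
    for i, row in enumerate(data):
        if len(row) < 2 + 2 * n_loci:
            raise FormatError(f"row {i + 4}: expected {2 + 2 * n_loci} columns")
        individuals.append(row[0].strip())
        pop_idx = int(np.searchsorted(bounds, i, side="right")) - 1
        label = row[1].strip() or pop_names[pop_idx]
        populations.append(label)
        pair_row = []
        for j in range(n_loci):
            a = _parse_allele(row[2 + 2 * j], missing_code, i + 4, 2 + 2 * j)
            b = _parse_allele(row[3 + 2 * j], missing_code, i + 4, 3 + 2 * j)
            pair_row.append((a, b))
        calls.append(pair_row)
    return table_from_calls(individuals, populations, loci, calls)


def _read_long(path, missing_code: int) -> GenotypeTable:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"individual", "population", "locus", "allele1", "allele2"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"long format requires columns {sorted(required)}")
        records = list(reader)
    individuals: list[str] = []
    populations: dict[str, str] = {}
    loci: list[str] = []
    cell: dict[tuple[str, str], tuple[int, int]] = {}
    for i, rec in enumerate(records):
        ind, pop, locus = rec["individual"], rec["population"], rec["locus"]
        if ind not in populations:
            individuals.append(ind)
            populations[ind] = pop
        elif populations[ind] != pop:
            raise FormatError(f"individual {ind!r} listed in two populations")
        if locus not in loci:
            loci.append(locus)
        a = _parse_allele(rec["allele1"], missing_code, i + 2, 4)
        b = _parse_allele(rec["allele2"], missing_code, i + 2, 5)
        cell[(ind, locus)] = (a, b)
    calls = [[cell.get((ind, l), (MISSING, MISSING)) for l in loci] for ind in individuals]
    return table_from_calls(individuals, [populations[i] for i in individuals], loci, calls)


def write_genalex(table: GenotypeTable, path, title: str = "clonepop export") -> None:
    """Write a GenAlEx-dialect CSV; inverse of :func:`read_genotype_table`.

    Individuals are written grouped by population (first-appearance order of
    labels, input order within a population), which is also the canonical
    order ``read_genotype_table`` reproduces.
    """
    pops = table.population_names
    order = [i for p in pops for i, q in enumerate(table.populations) if q == p]
    sizes = [sum(1 for q in table.populations if q == p) for p in pops]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([table.n_loci, table.n_individuals, len(pops), *sizes])
        w.writerow([title, "", *pops])
        header = ["Individual", "Pop"]
        for locus in table.loci:
            header += [locus, ""]
        w.writerow(header)
        for i in order:
            row = [table.individuals[i], table.populations[i]]
            for j in range(table.n_loci):
                a, b = table.alleles[i, j]
                row += [int(a), int(b)]
            w.writerow(row)


def write_long(table: GenotypeTable, path) -> None:
    """Write the tidy long-format CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "population", "locus", "allele1", "allele2"])
        for i, ind in enumerate(table.individuals):
            for j, locus in enumerate(table.loci):
                a, b = table.alleles[i, j]
                w.writerow([ind, table.populations[i], locus, int(a), int(b)])


# ---------------------------------------------------------------------------
# quality-control filters


def filter_individuals_by_missing(
    table: GenotypeTable, max_missing_loci: int = 1
) -> GenotypeTable:
    """Keep individuals with at most ``max_missing_loci`` missing calls.

    Individuals with missing information at more loci than the threshold are
    removed (and logged); order of the survivors is preserved.
    """
    if max_missing_loci < 0:
        raise ValueError("max_missing_loci must be >= 0")
    n_missing = table.missing_mask.sum(axis=1)
    keep = [i for i in range(table.n_individuals) if n_missing[i] <= max_missing_loci]
    removed = [table.individuals[i] for i in range(table.n_individuals) if i not in set(keep)]
    if removed:
        logger.info(
            "filter_individuals_by_missing: removed %d individual(s): %s",
            len(removed), ", ".join(removed),
        )
    if not keep:
        raise EmptyTableError("missing-data filter removed every individual")
    if len(keep) == table.n_individuals:
        return table
    return table.take_individuals(keep)


def apply_locus_qc(
    table: GenotypeTable,
    null_allele_flags: Iterable[str] = (),
    linkage_flags: Iterable[str] = (),
    locus_meta: dict[str, LocusMeta] | None = None,
) -> tuple[GenotypeTable, list[LocusMeta]]:
    """Drop loci flagged for null alleles or linkage disequilibrium.

    Null-allele drops are applied first; linkage flags are then honoured for
    the survivors (the two passes are logged separately).  Surviving calls
    are never altered.

    Returns the filtered table and a :class:`LocusMeta` per input locus.
    """
    null_set = set(null_allele_flags)
    link_set = set(linkage_flags)
    unknown = (null_set | link_set) - set(table.loci)
    if unknown:
        raise KeyError(f"flags reference unknown loci: {sorted(unknown)}")
    meta: list[LocusMeta] = []
    retained: list[str] = []
    for locus in table.loci:
        base = (locus_meta or {}).get(locus, LocusMeta(name=locus))
        if locus in null_set:
            m = replace(base, status=LocusStatus.DROPPED_NULL_ALLELES)
        elif locus in link_set:
            m = replace(base, status=LocusStatus.DROPPED_LINKAGE)
        else:
            m = replace(base, status=LocusStatus.RETAINED)
            retained.append(locus)
        meta.append(m)
    if null_set:
        logger.info("locus QC pass 1 (null alleles): dropped %s", sorted(null_set))
    if link_set:
        logger.info("locus QC pass 2 (linkage): dropped %s", sorted(link_set - null_set))
    if len(retained) < 2:
        raise PipelineAbortError(
            f"only {len(retained)} locus/loci survive QC; clone discrimination "
            "requires at least 2"
        )
    return table.select_loci(retained), meta
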