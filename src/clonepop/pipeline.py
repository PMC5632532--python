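"""End-to-end clonal population-genetics pipeline.

Fixed stage order: import -> locus QC (null alleles, then linkage) ->
missing-data filter -> clone discrimination per population (MLG, P_sex,
MLL, R, V) -> clone correction to one representative per lineage ->
per-locus diversity -> pairwise differentiation.  Diversity and
differentiation never see ramet duplicates.

``run_pipeline`` returns a report dictionary and optionally writes TSV
tables (per-individual clone membership, per-locus diversity, per-population
summary, pairwise differentiation), a machine-readable JSON summary, and a
run log recording every decision, seed and dropped locus/individual.
Reruns with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from clonepop import clonal, differentiation, diversity
from clonepop.errors import ConfigError
from clonepop.genotype_io import (
    GenotypeTable,
    concat_tables,
    apply_locus_qc,
    filter_individuals_by_missing,
    read_genotype_table,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run; the seed is mandatory."""

    seed: int
    input_paths: tuple[str, ...] = ()
    dialect: str = "genalex"
    missing_code: int = 0
    max_missing_loci: int = 1
    mll_threshold: int = 1
    psex_alpha: float = 0.001
    psex_convention: str = "parks-werth"
    freq_scheme: str = "per_genet"
    rarefaction_size: int | None = None
    n_perm: int = 999
    run_locus_qc: bool = True
    null_r_threshold: float = 0.1
    qc_alpha: float = 0.05
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for pipeline runs")
        if not 0 < self.psex_alpha < 1:
            raise ConfigError("psex_alpha must be in (0, 1)")
        if self.mll_threshold < 0:
            raise ConfigError("mll_threshold must be >= 0")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")


def _unique_mlg_table(pop_table: GenotypeTable) -> GenotypeTable:
    mlg = clonal.assign_mlg(pop_table)
    _, first = np.unique(mlg, return_index=True)
    return pop_table.take_individuals(sorted(int(i) for i in first))


def _locus_qc_flags(
    table: GenotypeTable, config: PipelineConfig, log: list[str]
) -> tuple[list[str], list[str]]:
    """Null-allele and linkage flags from per-population tests on unique MLGs."""
    pops = table.population_names
    qc_tables = {p: _unique_mlg_table(table.restrict_population(p)) for p in pops}

    null_flags: set[str] = set()
    for p in pops:
        for locus in table.loci:
            res = diversity.null_allele_test(
                qc_tables[p], locus, p, r_threshold=config.null_r_threshold,
                alpha=config.qc_alpha,
            )
            if res["flag"]:
                null_flags.add(locus)
                log.append(
                    f"QC: locus {locus} flagged for null alleles in {p} "
                    f"(Brookfield r={res['r']:.3f}, p={res['p']:.4f})"
                )

    survivors = [l for l in table.loci if l not in null_flags]
    pairs = list(combinations(survivors, 2))
    link_flags: set[str] = set()
    if pairs:
        bonferroni = config.qc_alpha / (len(pairs) * len(pops))
        log.append(
            f"QC: linkage tested on {len(pairs)} pair(s) x {len(pops)} pop(s), "
            f"Bonferroni alpha = {bonferroni:.2e}"
        )
        counter = 0
        for p in pops:
            for la, lb in pairs:
                counter += 1
                pval = diversity.linkage_permutation_test(
                    qc_tables[p], (la, lb), p, n_perm=config.n_perm,
                    seed=config.seed + 50_000 + counter,
                )
                if not math.isnan(pval) and pval < bonferroni:
                    link_flags.update((la, lb))
                    log.append(
                        f"QC: loci {la}/{lb} flagged for linkage in {p} (p={pval:.4f})"
                    )
    return sorted(null_flags), sorted(link_flags)


def run_pipeline(
    config: PipelineConfig, table: GenotypeTable | None = None
) -> dict:
    """Execute the full analysis; returns the report bundle as a dict."""
    log: list[str] = [f"pipeline seed = {config.seed}"]

    if table is None:
        if not config.input_paths:
            raise ConfigError("either a table or input_paths is required")
        tables = [
            read_genotype_table(p, dialect=config.dialect, missing_code=config.missing_code)
            for p in config.input_paths
        ]
        table = tables[0] if len(tables) == 1 else concat_tables(*tables)
    log.append(
        f"import: {table.n_individuals} individuals x {table.n_loci} loci, "
        f"populations: {', '.join(table.population_names)}"
    )

    # stage 1: locus QC (null-allele pass, then linkage on survivors)
    locus_meta = []
    if config.run_locus_qc:
        null_flags, link_flags = _locus_qc_flags(table, config, log)
        table, locus_meta = apply_locus_qc(table, null_flags, link_flags)
        log.append(f"locus QC: retained {table.n_loci} loci: {', '.join(table.loci)}")
    else:
        log.append("locus QC skipped by config")

    # stage 2: missing-data filter (after locus QC, before clone discrimination)
    before = table.n_individuals
    table = filter_individuals_by_missing(table, config.max_missing_loci)
    if table.n_individuals < before:
        log.append(
            f"missing filter: removed {before - table.n_individuals} individual(s) "
            f"with > {config.max_missing_loci} missing loci"
        )

    # stage 3: clone discrimination per population
    pops = table.population_names
    partitions: dict[str, clonal.ClonalPartition] = {}
    pop_rows: dict[str, dict] = {}
    clones_rows: list[dict] = []
    for p in pops:
        sub = table.restrict_population(p)
        part = clonal.clonal_partition(
            sub,
            threshold=config.mll_threshold,
            freq_scheme=config.freq_scheme,
            psex_convention=config.psex_convention,
        )
        partitions[p] = part
        idx = clonal.clonal_indices(part)
        mll = part.mll_per_individual
        mll_sizes = {int(m): int(c) for m, c in zip(*np.unique(mll, return_counts=True))}
        for i, ind in enumerate(sub.individuals):
            g = int(part.mlg_of[i])
            clones_rows.append(
                {
                    "individual": ind,
                    "population": p,
                    "mlg": g,
                    "mll": int(mll[i]),
                    "ramet_count": mll_sizes[int(mll[i])],
                    "p_sex": part.psex_of.get(g, float("nan")),
                }
            )
        n_sig = sum(1 for v in part.psex_of.values() if v < config.psex_alpha)
        log.append(
            f"clones[{p}]: N={idx.n_individuals} MLG={idx.n_mlg} MLL={idx.n_mll} "
            f"R={idx.richness:.4f} V={idx.evenness:.4f}; "
            f"{n_sig}/{len(part.psex_of)} repeated MLGs with P_sex < {config.psex_alpha}"
        )
        pop_rows[p] = {
            "N": idx.n_individuals,
            "MLG": idx.n_mlg,
            "MLL": idx.n_mll,
            "R": idx.richness,
            "V": idx.evenness,
            "pareto_beta": idx.pareto_beta,
            "simpson_d": idx.simpson_d,
        }

    # stage 4: clone correction — one representative per MLL
    reps = []
    offset = 0
    for p in pops:
        sub = table.restrict_population(p)
        local = partitions[p].representatives(sub.missing_mask)
        # map local indices back to the combined table
        local_ids = [sub.individuals[i] for i in local]
        reps.extend(table.individuals.index(i) for i in local_ids)
        offset += sub.n_individuals
    unique_table = table.take_individuals(sorted(reps))
    log.append(f"clone correction: {unique_table.n_individuals} unique MLL representatives")

    # stage 5: diversity on unique MLLs
    summaries = diversity.diversity_summary(unique_table, config.rarefaction_size)
    counter = 0
    for s in summaries:
        counter += 1
        if s.n > 0:
            s.hwe_p = diversity.hwe_permutation_test(
                unique_table, s.locus, s.population, n_perm=config.n_perm,
                seed=config.seed + 90_000 + counter,
            )
            null = diversity.null_allele_test(
                unique_table, s.locus, s.population,
                r_threshold=config.null_r_threshold, alpha=config.qc_alpha,
            )
            s.null_r, s.null_flag = null["r"], null["flag"]
    multilocus = diversity.multilocus_summary(summaries)
    for p in pops:
        pop_rows[p].update(
            {k: multilocus.get(p, {}).get(k, float("nan"))
             for k in ("A", "AR", "Ap", "Ho", "He", "F_IS")}
        )

    # stage 6: pairwise differentiation on unique MLLs
    diff_results: list[differentiation.DiffResult] = []
    if len(pops) >= 2:
        diff_results = differentiation.pairwise_differentiation(
            unique_table, n_perm=config.n_perm, seed=config.seed + 70_000
        )
        for d in diff_results:
            log.append(
                f"diff[{d.pair[0]}-{d.pair[1]}]: F_ST={d.f_st:.4f} "
                f"(p={d.p_values['F_ST']:.4f}) G''_ST={d.g_dprime_st:.4f} "
                f"(p={d.p_values['G_dprime_ST']:.4f})"
            )

    report = {
        "config": asdict(config),
        "populations": pop_rows,
        "clones": clones_rows,
        "per_locus": [vars(s) for s in summaries],
        "differentiation": [
            {
                "pair": list(d.pair),
                "F_ST": d.f_st,
                "G_ST": d.g_st,
                "G_prime_ST": d.g_prime_st,
                "G_dprime_ST": d.g_dprime_st,
                "H_S": d.h_s,
                "H_T": d.h_t,
                "p_F_ST": d.p_values["F_ST"],
                "p_G_dprime_ST": d.p_values["G_dprime_ST"],
            }
            for d in diff_results
        ],
        "locus_meta": [
            {"name": m.name, "status": m.status.value} for m in locus_meta
        ],
        "log": log,
    }
    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


# ---------------------------------------------------------------------------
# report serialisation


def _fmt(v) -> str:
    if isinstance(v, float):
        return "NA" if math.isnan(v) else f"{v:.6g}"
    return str(v)


def _write_tsv(path: Path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r[c]) for c in columns) + "\n")


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        out_dir / "clones.tsv",
        report["clones"],
        ["individual", "population", "mlg", "mll", "ramet_count", "p_sex"],
    )
    _write_tsv(
        out_dir / "per_locus.tsv",
        report["per_locus"],
        ["locus", "population", "n", "na", "ar", "ap", "ho", "he",
         "fis", "fis_wc", "hwe_p", "null_r", "null_flag"],
    )
    pop_cols = ["population", "N", "MLG", "MLL", "R", "V", "pareto_beta",
                "A", "AR", "Ap", "Ho", "He", "F_IS"]
    pop_tbl = [{"population": p, **row} for p, row in report["populations"].items()]
    _write_tsv(out_dir / "populations.tsv", pop_tbl, pop_cols)
    if report["differentiation"]:
        diff_rows = [
            {**d, "pair": f"{d['pair'][0]}-{d['pair'][1]}"}
            for d in report["differentiation"]
        ]
        _write_tsv(
            out_dir / "differentiation.tsv",
            diff_rows,
            ["pair", "F_ST", "G_ST", "G_prime_ST", "G_dprime_ST",
             "H_S", "H_T", "p_F_ST", "p_G_dprime_ST"],
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(report["log"]) + "\n")


def _json_default(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, float) and math.isnan(v):
        return None
    raise TypeError(f"not JSON serialisable: {type(v)}")
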