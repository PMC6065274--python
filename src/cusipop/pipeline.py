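"""Full study-shaped analysis: one config in, a report bundle out.

Stages: morphometrics (Welch tests + PCA; optional), locus filtering,
per-population diversity with the cross-population comparison table,
Weir-Cockerham theta with its permutation null, and the replicate
admixture scan with ΔK selection.  Every stage's parameters and seeds are
echoed into ``report.json``; stage tables are written as TSV/JSON files
next to it.  Runs are deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import AdmixtureModelConfig, align_runs, replicate_runs
from .differentiation import fst_permutation_test, wc_theta
from .diversity import METRICS, compare_populations, locus_diversity, summarize_population
from .evanno import delta_k
from .genotype_io import (
    filter_loci,
    first_snp_per_locus,
    read_genepop,
    read_popmap,
    read_structure,
    read_vcf,
)
from .morphometrics import compare_traits, pc_ranges_by_population, pca_traits, read_morph_table
from .types import GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    genotypes: str | None = None
    genotype_format: str = "structure"   # structure | genepop | vcf
    popmap: str | None = None            # required for vcf
    morphometrics: str | None = None
    min_fraction: float = 0.25
    min_populations: int = 1
    single_snp: bool = False
    n_permutations: int = 1000
    permutation_seed: int = 1
    k_min: int = 1
    k_max: int = 5
    n_replicates: int = 10
    admixture_seed: int = 1
    burn_in: int = 5000
    reps: int = 50000
    out_dir: str = "cusipop_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _load_genotypes(cfg: AnalysisConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    if cfg.genotype_format == "structure":
        return read_structure(cfg.genotypes)
    if cfg.genotype_format == "genepop":
        return read_genepop(cfg.genotypes)
    if cfg.genotype_format == "vcf":
        if not cfg.popmap:
            raise ValueError("vcf input requires a popmap path")
        return read_vcf(cfg.genotypes, cfg.popmap)
    raise ValueError(f"unknown genotype format {cfg.genotype_format!r}")


def run_full_analysis(
    cfg: AnalysisConfig,
    matrix: GenotypeMatrix | None = None,
    popmap: PopulationMap | None = None,
    morphs=None,
) -> dict:
    """Execute every configured stage and write the report bundle.

    ``matrix``/``popmap``/``morphs`` may be passed directly (e.g. from the
    synthetic generator) instead of file paths in the config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(cfg),
        "stages": {},
    }
    manifest: list[str] = []
    stage = "load"
    try:
        if matrix is None:
            if not cfg.genotypes:
                raise ValueError("no genotype input configured")
            matrix, popmap = _load_genotypes(cfg)
        if morphs is None and cfg.morphometrics:
            morphs = read_morph_table(cfg.morphometrics)

        # ---- morphometrics ------------------------------------------------
        stage = "morphometrics"
        if morphs is not None:
            t0 = time.perf_counter()
            comps = compare_traits(morphs)
            pca = pca_traits(morphs, scale=True)
            ranges = pc_ranges_by_population(pca, morphs)
            rows = [
                {"trait": c.trait, **{f"mean_{p}": m for p, m in c.means.items()},
                 "t": c.t, "df": c.df, "p_value": c.p_value,
                 "significant": c.significant}
                for c in comps
            ]
            _write_tsv(out / "morph_tests.tsv", rows)
            score_rows = [
                {"individual_id": ind, "population": pop,
                 **{f"PC{j + 1}": float(s) for j, s in enumerate(sc)}}
                for ind, pop, sc in zip(
                    morphs["individual_id"], morphs["population"], pca.scores
                )
            ]
            _write_tsv(out / "pca_scores.tsv", score_rows)
            manifest += ["morph_tests.tsv", "pca_scores.tsv"]
            report["stages"]["morphometrics"] = {
                "tests": rows,
                "pc1_proportion": float(pca.proportion_variance[0]),
                "eigenvalues": [float(e) for e in pca.eigenvalues],
                "pc1_ranges": {p: list(v) for p, v in ranges.items()},
                "seconds": time.perf_counter() - t0,
            }
        else:
            report["stages"]["morphometrics"] = {"skipped": "no morphometric table"}
            logger.info("morphometrics stage skipped: no table provided")

        # ---- filtering ----------------------------------------------------
        stage = "filter"
        t0 = time.perf_counter()
        n_before = matrix.n_loci
        if cfg.single_snp:
            matrix = first_snp_per_locus(matrix)
        matrix = filter_loci(matrix, popmap, cfg.min_fraction, cfg.min_populations)
        report["stages"]["filter"] = {
            "loci_before": n_before, "loci_after": matrix.n_loci,
            "min_fraction": cfg.min_fraction,
            "min_populations": cfg.min_populations,
            "single_snp": cfg.single_snp,
            "seconds": time.perf_counter() - t0,
        }

        # ---- diversity ----------------------------------------------------
        stage = "diversity"
        t0 = time.perf_counter()
        pops = popmap.populations()
        summaries = {}
        for pop in pops:
            summaries[pop] = summarize_population(locus_diversity(matrix, popmap, pop))
        rows = []
        div_block: dict = {"populations": {}}
        for pop, s in summaries.items():
            div_block["populations"][pop] = {
                m: {"mean": s.mean[m], "sd": s.sd[m], "n_loci": s.n_loci[m]}
                for m in METRICS
            }
        if len(pops) == 2:
            comps = compare_populations(summaries[pops[0]], summaries[pops[1]])
            for c in comps:
                rows.append(
                    {"metric": c.metric,
                     f"mean_{pops[0]}": c.mean_a, f"sd_{pops[0]}": summaries[pops[0]].sd[c.metric],
                     f"mean_{pops[1]}": c.mean_b, f"sd_{pops[1]}": summaries[pops[1]].sd[c.metric],
                     "t": c.t, "df": c.df, "p_value": c.p_value}
                )
            div_block["comparison"] = rows
            _write_tsv(out / "table1.tsv", rows)
            manifest.append("table1.tsv")
        div_block["seconds"] = time.perf_counter() - t0
        report["stages"]["diversity"] = div_block

        # ---- FST + permutation null --------------------------------------
        stage = "fst"
        t0 = time.perf_counter()
        est = wc_theta(matrix, popmap)
        perm = fst_permutation_test(
            matrix, popmap, n_perm=cfg.n_permutations, seed=cfg.permutation_seed
        )
        fst_block = {
            "theta": est.theta,
            "n_loci_used": est.n_loci_used,
            "p_value": perm.p_value,
            "cutoff_95": perm.cutoff_95,
            "group_sizes": list(perm.group_sizes),
            "n_permutations": cfg.n_permutations,
            "seed": cfg.permutation_seed,
            "seconds": time.perf_counter() - t0,
        }
        with open(out / "fst_permutation.json", "w") as fh:
            json.dump({**fst_block, "null_thetas": perm.null_thetas.tolist()}, fh, indent=1)
        manifest.append("fst_permutation.json")
        report["stages"]["fst"] = fst_block

        # ---- admixture scan + ΔK -----------------------------------------
        stage = "admixture"
        t0 = time.perf_counter()
        adm_cfg = AdmixtureModelConfig(burn_in=cfg.burn_in, reps=cfg.reps)
        evidence, runs = replicate_runs(
            matrix, range(cfg.k_min, cfg.k_max + 1), cfg.n_replicates,
            cfg.admixture_seed, adm_cfg,
        )
        dk = delta_k(evidence)
        k_hat = dk.k_hat
        q_rows = []
        if k_hat is not None:
            reps_k = align_runs([runs[(k_hat, r)] for r in range(cfg.n_replicates)])
            Q_mean = np.mean([r.Q for r in reps_k], axis=0)
            for ind, pop, q in zip(
                matrix.individual_ids, popmap.labels_for(matrix), Q_mean
            ):
                q_rows.append(
                    {"individual_id": ind, "population": pop,
                     **{f"Q{k + 1}": float(v) for k, v in enumerate(q)}}
                )
            _write_tsv(out / "q_matrix.tsv", q_rows)
            manifest.append("q_matrix.tsv")
        dk.table.to_csv(out / "deltak.tsv", sep="\t", index=False)
        manifest.append("deltak.tsv")
        report["stages"]["admixture"] = {
            "k_hat": k_hat,
            "delta_k": None if dk.delta_k_at_k_hat is None else float(dk.delta_k_at_k_hat),
            "evidence": evidence.to_dict("records"),
            "q_matrix": q_rows,
            "burn_in": cfg.burn_in, "reps": cfg.reps,
            "base_seed": cfg.admixture_seed,
            "seconds": time.perf_counter() - t0,
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _finalize(out, report, manifest)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    _finalize(out, report, manifest)
    return report


def _finalize(out: Path, report: dict, manifest: list[str]) -> None:
    report["manifest"] = sorted(manifest)
    _validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)


def _validate_report(report: dict) -> None:
    for key in ("schema_version", "config", "stages", "manifest"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")


def _write_tsv(path: Path, rows: list[dict]) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
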