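"""Genotype matrix I/O and locus filtering.

Supported formats: STRUCTURE text (one- or two-rows-per-individual),
GENEPOP text (2- or 3-digit allele encoding) and VCF 4.x (GT field only,
via pysam) with a separate two-column population map.  On ingestion every
reader recodes allele codes to a dense ``0..k-1`` per locus (rank order of
the original codes preserved, so VCF REF=0 stays 0) and coerces half-called
genotypes to fully missing, counting them in a logged warning.

Locus retention mirrors the reduced-representation conventions used to
assemble de novo SNP panels: a locus is kept when genotyped in at least a
minimum fraction of individuals in at least a minimum number of
populations, and optionally thinned to a single SNP per assembly locus to
limit linked sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .types import MISSING, GenotypeMatrix, ParseError, PopulationMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StructureDialect:
    """Layout options for STRUCTURE text files.

    ``rows_per_individual`` is 1 (two columns per locus) or 2 (one column
    per locus, two consecutive rows per individual).
    """

    rows_per_individual: int = 1
    missing_code: int = -9
    pop_column: bool = True
    locus_header: bool = True

    def __post_init__(self) -> None:
        if self.rows_per_individual not in (1, 2):
            raise ValueError("rows_per_individual must be 1 or 2")


def _coerce_half_missing(calls: np.ndarray) -> int:
    """In-place: make (-1, x) / (x, -1) genotypes fully missing; return count."""
    half = (calls == MISSING).sum(axis=2) == 1
    n_half = int(half.sum())
    if n_half:
        calls[half] = MISSING
        logger.warning("coerced %d half-missing genotype(s) to missing", n_half)
    return n_half


def read_structure(
    path: str | Path, dialect: StructureDialect = StructureDialect()
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Read a STRUCTURE-format genotype file.

    Returns a dense-recoded matrix and the population map taken from the
    population column (all individuals assigned to population "1" when the
    dialect has no such column).
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")

    locus_ids: list[str] | None = None
    if dialect.locus_header:
        locus_ids = lines[0].split()
        body = lines[1:]
    else:
        body = lines

    rows = [ln.split() for ln in body]
    meta = 1 + (1 if dialect.pop_column else 0)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        bad = next(i for i, r in enumerate(rows) if len(r) != len(rows[0]))
        raise ParseError(f"{path}: ragged row at data line {bad + 1}")
    n_fields = widths.pop() if widths else 0
    n_allele_cols = n_fields - meta
    per_locus = 2 if dialect.rows_per_individual == 1 else 1
    if n_allele_cols <= 0 or n_allele_cols % per_locus:
        raise ParseError(f"{path}: {n_allele_cols} allele columns not divisible by {per_locus}")
    n_loci = n_allele_cols // per_locus
    if locus_ids is None:
        locus_ids = [f"locus_{j}" for j in range(n_loci)]
    if len(locus_ids) != n_loci:
        raise ParseError(f"{path}: header names {len(locus_ids)} loci, data has {n_loci}")

    ids: list[str] = []
    pops: dict[str, str] = {}
    genos: list[np.ndarray] = []
    if dialect.rows_per_individual == 1:
        for r in rows:
            ind = r[0]
            ids.append(ind)
            if dialect.pop_column:
                pops[ind] = r[1]
            a = np.array(r[meta:], dtype=np.int64).reshape(n_loci, 2)
            genos.append(a)
    else:
        if len(rows) % 2:
            raise ParseError(f"{path}: odd number of data rows for two-row dialect")
        for r1, r2 in zip(rows[::2], rows[1::2]):
            if r1[0] != r2[0]:
                raise ParseError(f"{path}: row pair ids differ ({r1[0]!r} vs {r2[0]!r})")
            ind = r1[0]
            ids.append(ind)
            if dialect.pop_column:
                pops[ind] = r1[1]
            a = np.stack(
                [np.array(r1[meta:], dtype=np.int64), np.array(r2[meta:], dtype=np.int64)],
                axis=1,
            )
            genos.append(a)

    calls = np.stack(genos).astype(np.int32)
    calls[calls == dialect.missing_code] = MISSING
    if (calls < 0).any() and not (calls[calls < 0] == MISSING).all():
        raise ValidationError(f"{path}: negative allele code that is not the missing code")
    _coerce_half_missing(calls)
    if not dialect.pop_column:
        pops = {i: "1" for i in ids}
    matrix = GenotypeMatrix(ids, list(locus_ids), calls).recode_dense()
    return matrix, PopulationMap(pops)


def write_structure(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    path: str | Path,
    dialect: StructureDialect = StructureDialect(),
) -> None:
    """Write a STRUCTURE text file; inverse of :func:`read_structure`."""
    labels = popmap.labels_for(matrix) if dialect.pop_column else None
    with open(path, "w") as fh:
        if dialect.locus_header:
            fh.write(" ".join(matrix.locus_ids) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            meta = [ind] + ([labels[i]] if labels is not None else [])
            g = matrix.calls[i].astype(object).copy()
            g[g == MISSING] = dialect.missing_code
            if dialect.rows_per_individual == 1:
                fh.write(" ".join(meta + [str(v) for v in g.reshape(-1)]) + "\n")
            else:
                for c in (0, 1):
                    fh.write(" ".join(meta + [str(v) for v in g[:, c]]) + "\n")


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, PopulationMap]:
    """Read a GENEPOP text file (title, locus names, POP blocks)."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for GENEPOP layout")
    body = lines[1:]  # drop title
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        # locus names: one per line, or comma-separated on one line
        locus_ids.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if i == len(body):
        raise ParseError(f"{path}: no POP separator found")

    ids: list[str] = []
    pops: dict[str, str] = {}
    genos: list[np.ndarray] = []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        ln = body[i]
        if "," not in ln:
            raise ParseError(f"{path}: expected 'id , genotypes' line, got {ln!r}")
        ind, geno_part = ln.split(",", 1)
        ind = ind.strip()
        toks = geno_part.split()
        if len(toks) != len(locus_ids):
            raise ParseError(
                f"{path}: individual {ind!r} has {len(toks)} genotypes, expected {len(locus_ids)}"
            )
        width = len(toks[0]) // 2
        if any(len(t) != 2 * width for t in toks) or width not in (2, 3):
            raise ParseError(f"{path}: inconsistent allele encoding width for {ind!r}")
        pair = np.array(
            [[int(t[:width]), int(t[width:])] for t in toks], dtype=np.int32
        )
        pair[pair == 0] = MISSING  # "00"/"000" means missing
        ids.append(ind)
        pops[ind] = f"pop_{pop_idx}"
        genos.append(pair)
        i += 1

    calls = np.stack(genos)
    _coerce_half_missing(calls)
    matrix = GenotypeMatrix(ids, locus_ids, calls).recode_dense()
    return matrix, PopulationMap(pops)


def write_genepop(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    path: str | Path,
    digits: int = 2,
    title: str = "cusipop export",
) -> None:
    """Write GENEPOP text; allele code ``a`` is stored as ``a + 1`` so that
    code 0 is reserved for missing."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if matrix.calls.max(initial=0) + 1 >= 10**digits:
        raise ValidationError(f"allele codes exceed {digits}-digit GENEPOP encoding")
    labels = popmap.labels_for(matrix)
    order = popmap.populations()
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for lid in matrix.locus_ids:
            fh.write(lid + "\n")
        for pop in order:
            members = [i for i, lab in enumerate(labels) if lab == pop]
            if not members:
                continue
            fh.write("POP\n")
            for i in members:
                toks = []
                for j in range(matrix.n_loci):
                    a, b = matrix.calls[i, j]
                    a = 0 if a == MISSING else int(a) + 1
                    b = 0 if b == MISSING else int(b) + 1
                    toks.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{matrix.individual_ids[i]} , " + " ".join(toks) + "\n")


def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column whitespace/tab-delimited individual -> population file."""
    assignments: dict[str, str] = {}
    for k, ln in enumerate(Path(path).read_text().splitlines()):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: line {k + 1} is not two columns")
        ind, pop = parts
        if ind in assignments:
            raise ParseError(f"{path}: duplicate individual {ind!r}")
        assignments[ind] = pop
    if not assignments:
        raise ParseError(f"{path}: empty population map")
    return PopulationMap(assignments)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, pop in popmap.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


def read_vcf(
    path: str | Path,
    popmap_path: str | Path,
    multiallelic: str = "keep",
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Read GT calls from a VCF and pair them with a population map.

    ``multiallelic`` is ``"keep"`` (ingest with dense codes), ``"drop"``
    (skip records with >2 ALT+REF alleles) or ``"reject"`` (raise).
    Phasing is ignored; ``./.`` becomes missing.
    """
    if multiallelic not in ("keep", "drop", "reject"):
        raise ValueError("multiallelic must be keep/drop/reject")
    popmap = read_popmap(popmap_path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        absent = [s for s in samples if s not in popmap.assignments]
        if absent:
            raise ValidationError(f"individuals in VCF absent from popmap: {absent}")
        locus_ids: list[str] = []
        positions: dict[str, tuple[str, int]] = {}
        cols: list[np.ndarray] = []
        for rec in vf:
            n_all = len(rec.alleles)
            if n_all > 2:
                if multiallelic == "reject":
                    raise ValidationError(
                        f"multiallelic record at {rec.chrom}:{rec.pos} (policy=reject)"
                    )
                if multiallelic == "drop":
                    continue
            lid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            col = np.full((len(samples), 2), MISSING, dtype=np.int32)
            for si, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    continue  # half-calls and haploid calls -> missing
                col[si] = gt
            locus_ids.append(lid)
            positions[lid] = (rec.chrom, rec.pos)
            cols.append(col)
    if not cols:
        raise ParseError(f"{path}: no usable records")
    calls = np.stack(cols, axis=1)
    matrix = GenotypeMatrix(samples, locus_ids, calls, positions).recode_dense()
    popmap.validate_against(matrix)
    return matrix, popmap


def write_vcf(matrix: GenotypeMatrix, path: str | Path, contig: str = "1") -> None:
    """Write a minimal GT-only VCF.

    Loci without position metadata are laid out on a single synthetic
    contig at consecutive positions.  Alleles are written as symbolic
    single bases (A for code 0, then C, G, T in code order).
    """
    if (matrix.n_alleles() > 4).any():
        raise ValidationError("VCF export supports at most 4 alleles per locus")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = {c for c, _ in matrix.locus_positions.values()} or {contig}
    for c in sorted(contigs):
        header.contigs.add(c)
    for s in matrix.individual_ids:
        header.add_sample(s)
    bases = "ACGT"
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, lid in enumerate(matrix.locus_ids):
            chrom, pos = matrix.locus_positions.get(lid, (contig, j + 1))
            k = max(int(matrix.n_alleles()[j]), 2)
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos,
                alleles=tuple(bases[:k]), id=lid,
            )
            for si, s in enumerate(matrix.individual_ids):
                a, b = matrix.calls[si, j]
                rec.samples[s]["GT"] = None if a == MISSING else (int(a), int(b))
            out.write(rec)


def filter_loci(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    min_fraction: float = 0.25,
    min_populations: int = 1,
) -> GenotypeMatrix:
    """Keep loci genotyped in >= ``min_fraction`` of the individuals of at
    least ``min_populations`` populations; locus order is preserved."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if min_populations < 1:
        raise ValueError("min_populations must be >= 1")
    labels = popmap.labels_for(matrix)
    present = ~matrix.missing_mask()
    ok_pops = np.zeros(matrix.n_loci, dtype=int)
    for pop in popmap.populations():
        rows = labels == pop
        if not rows.any():
            continue
        frac = present[rows].mean(axis=0)
        ok_pops += frac >= min_fraction
    keep = np.flatnonzero(ok_pops >= min_populations)
    return matrix.subset_loci(keep)


def _rad_key(locus_id: str) -> tuple[str, int]:
    key, _, pos = locus_id.rpartition("_")
    if not key:
        raise ValidationError(f"locus id {locus_id!r} lacks '<radlocus>_<column>' metadata")
    try:
        return key, int(pos)
    except ValueError:
        raise ValidationError(
            f"locus id {locus_id!r} has non-integer intra-locus position {pos!r}"
        ) from None


def first_snp_per_locus(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Retain the lowest-position SNP of every assembly (RAD) locus.

    Locus ids must be ``<key>_<column>``.  Output order is canonical
    (sorted by key, numerically when keys are integers), so shuffled input
    yields the same matrix as sorted input.
    """
    parsed = [_rad_key(lid) for lid in matrix.locus_ids]
    best: dict[str, tuple[int, int]] = {}
    for idx, (key, pos) in enumerate(parsed):
        if key not in best or pos < best[key][0]:
            best[key] = (pos, idx)

    def sort_key(k: str):
        return (0, int(k), "") if k.isdigit() else (1, 0, k)

    keep = [best[k][1] for k in sorted(best, key=sort_key)]
    return matrix.subset_loci(keep)
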