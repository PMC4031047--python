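"""Readers/writers for the genotype and phenotype dialects, and the
reduction of genotypes + phenotypes to three-group allele counts.

Two genotype dialects are supported: VCF 4.x with hard GT calls (via
cyvcf2) and a plain TSV with one header row of individual ids and one row
per SNP of minor-allele dosages.  Phenotypes travel as a TSV with
``individual_id`` and ``migraine_status`` columns plus the ten
characteristic flags for active migraineurs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .constants import ACTIVE_VS_FORMER, CHARACTERISTICS
from .datatypes import CohortTable, GenotypeMatrix, SnpRecord, TriGroupCounts

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_phenotypes",
    "tabulate_trigroup",
]

_MISSING_TOKENS = {"", ".", "na", "nan"}


def read_genotypes(path: str | os.PathLike, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named format.

    The minor allele per SNP is the allele with sample frequency <= 0.5
    in the whole file; an exact 0.5 tie is broken by taking the
    alphabetically first allele as minor.  Counts are minor-allele
    dosages in {0,1,2}; missing hard calls become NaN.
    """
    if format == "vcf":
        return _read_vcf(os.fspath(path))
    if format == "tsv":
        return _read_genotype_tsv(os.fspath(path))
    raise ValueError(f"unknown genotype format {format!r} (expected 'vcf' or 'tsv')")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individual_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site not supported: {variant.CHROM}:{variant.POS} "
                f"({variant.ID or '.'}) with ALT={variant.ALT}"
            )
        ref, alt = variant.REF, variant.ALT[0]
        alt_dose = np.full(len(individual_ids), np.nan)
        for j, call in enumerate(variant.genotypes):
            alleles = [a for a in call[:-1] if a >= 0]
            if not alleles:
                continue
            if any(a > 1 for a in alleles):
                raise ValueError(
                    f"genotype beyond biallelic at {variant.CHROM}:{variant.POS} "
                    f"sample {individual_ids[j]}"
                )
            alt_dose[j] = float(sum(alleles))
        mask = np.isfinite(alt_dose)
        if mask.any():
            alt_freq = alt_dose[mask].sum() / (2.0 * mask.sum())
        else:
            alt_freq = 0.0
        minor, major, dose = _orient_minor(ref, alt, alt_freq, alt_dose)
        snp_id = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chromosome=str(variant.CHROM),
                position=int(variant.POS),
                allele_minor=minor,
                allele_major=major,
            )
        )
        rows.append(dose)
    counts = np.vstack(rows) if rows else np.empty((0, len(individual_ids)))
    return GenotypeMatrix(snps, individual_ids, counts)


def _orient_minor(
    ref: str, alt: str, alt_freq: float, alt_dose: np.ndarray
) -> tuple[str, str, np.ndarray]:
    """Choose minor/major orientation from the ALT sample frequency."""
    if alt_freq < 0.5:
        return alt, ref, alt_dose
    if alt_freq > 0.5:
        return ref, alt, 2.0 - alt_dose
    # exact tie: alphabetically first allele is minor
    if min(ref, alt) == alt:
        return alt, ref, alt_dose
    return ref, alt, 2.0 - alt_dose


def _read_genotype_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: genotype TSV needs a header of individual ids")
        individual_ids = header[1:]
        snps: list[SnpRecord] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            snp_id = fields[0]
            dose = np.full(len(individual_ids), np.nan)
            for j, tok in enumerate(fields[1:]):
                tok = tok.strip()
                if tok.lower() in _MISSING_TOKENS:
                    continue
                if tok not in ("0", "1", "2"):
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {tok!r} for SNP {snp_id}"
                    )
                dose[j] = float(tok)
            # TSV carries dosages only; synthesize placeholder allele labels
            snps.append(
                SnpRecord(
                    snp_id=snp_id,
                    chromosome="0",
                    position=lineno - 1,
                    allele_minor="A",
                    allele_major="B",
                )
            )
            rows.append(dose)
    counts = np.vstack(rows) if rows else np.empty((0, len(individual_ids)))
    return GenotypeMatrix(snps, individual_ids, counts)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(geno.individual_ids) + "\n")
        for i, snp in enumerate(geno.snps):
            toks = [
                "." if not np.isfinite(v) else str(int(v)) for v in geno.counts[i]
            ]
            fh.write(snp.snp_id + "\t" + "\t".join(toks) + "\n")


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 text file.

    The minor allele is written as ALT so that a round trip through
    :func:`read_genotypes` reproduces the dosage matrix (minor-allele
    frequency <= 0.5 by construction of the matrix).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: list[str] = []
        for snp in geno.snps:
            if snp.chromosome not in seen:
                seen.append(snp.chromosome)
                fh.write(f"##contig=<ID={snp.chromosome}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i, snp in enumerate(geno.snps):
            gts = [
                gt_map[v] if np.isfinite(v) else "./."
                for v in geno.counts[i]
            ]
            fh.write(
                "\t".join(
                    [
                        snp.chromosome,
                        str(snp.position),
                        snp.snp_id,
                        snp.allele_major,
                        snp.allele_minor,
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_phenotypes(path: str | os.PathLike) -> CohortTable:
    """Read and validate the phenotype TSV."""
    frame = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    for col in ("individual_id", "migraine_status"):
        if col not in frame.columns:
            raise ValueError(f"{path}: phenotype TSV requires column {col!r}")
    active = frame["migraine_status"] == "active"
    if active.any():
        missing_cols = [c for c in CHARACTERISTICS if c not in frame.columns]
        if missing_cols:
            raise ValueError(
                f"{path}: active migraineurs present but characteristic "
                f"column(s) {missing_cols} are missing"
            )
    return CohortTable(frame)


def write_phenotypes(cohort: CohortTable, path: str | os.PathLike) -> None:
    out = cohort.frame.reset_index()
    if "index" in out.columns and "individual_id" not in out.columns:
        out = out.rename(columns={"index": "individual_id"})
    out.to_csv(path, sep="\t", index=False)


def trigroup_labels(
    cohort: CohortTable,
    characteristic: str,
    case_universe: str = "active",
) -> pd.Series:
    """Assign each individual to a group: 0=with, 1=without, 2=ctrl, -1=excluded.

    For the ten attack characteristics, groups are active migraineurs with
    and without the feature versus never-migraineurs; former migraineurs
    are excluded (they were not sub-classified).  The special partition
    ``active_vs_former`` compares active vs former migraineurs against
    never-migraineurs.
    """
    status = cohort.migraine_status
    labels = pd.Series(-1, index=cohort.frame.index, dtype=int)
    if characteristic == ACTIVE_VS_FORMER:
        labels[status == "active"] = 0
        labels[status == "former"] = 1
        labels[status == "never"] = 2
        return labels
    if characteristic not in CHARACTERISTICS:
        raise KeyError(f"unknown characteristic {characteristic!r}")
    if case_universe not in ("active", "ever"):
        raise ValueError("case_universe must be 'active' or 'ever'")
    flag = cohort.characteristic(characteristic)
    active = status == "active"
    labels[active & (flag == 1)] = 0
    labels[active & (flag == 0)] = 1
    labels[status == "never"] = 2
    if case_universe == "ever":
        # former migraineurs lack sub-classification; place them with the
        # 'without' stratum only on explicit request of the ever universe
        labels[status == "former"] = 1
    return labels


def tabulate_trigroup(
    geno: GenotypeMatrix,
    cohort: CohortTable,
    snp_id: str,
    characteristic: str,
    case_universe: str = "active",
) -> TriGroupCounts:
    """Reduce one SNP x characteristic to three-group allele counts.

    Individuals with a missing genotype at the SNP are dropped from all
    three groups for that SNP only (complete-case per SNP).
    """
    dose = geno.row(snp_id)
    labels = trigroup_labels(cohort, characteristic, case_universe)
    cols = geno.column_indices(list(labels.index))
    dose = dose[cols]
    lab = labels.to_numpy()
    valid = (lab >= 0) & np.isfinite(dose)
    lab, dose = lab[valid], dose[valid]
    k = np.zeros(3, dtype=float)
    m = np.zeros(3, dtype=int)
    for g in range(3):
        sel = lab == g
        m[g] = int(sel.sum())
        k[g] = dose[sel].sum()
    names = ("with", "without", "ctrl")
    for g, name in enumerate(names):
        if m[g] == 0:
            raise ValueError(
                f"degenerate design for SNP {snp_id!r} x {characteristic!r}: "
                f"group {name!r} is empty after exclusions"
            )
    return TriGroupCounts(
        k_with=int(k[0]),
        n_with=2 * m[0],
        k_without=int(k[1]),
        n_without=2 * m[1],
        k_ctrl=int(k[2]),
        n_ctrl=2 * m[2],
        group_sizes={name: int(m[g]) for g, name in enumerate(names)},
    )
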