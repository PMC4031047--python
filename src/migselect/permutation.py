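"""Permutation-based empirical significance for the model-selection scan.

Null distributions are simulated by randomly reassigning SNP genotypes to
participants (one individual-level permutation per replicate, shared by
all SNPs and characteristics, so inter-SNP correlation and the phenotype
structure are preserved).  The whole model-selection procedure is re-run
per replicate and three quantities are estimated per SNP x
characteristic:

* the fraction of replicates selecting a non-null model (chance rate of
  a "non-null" call);
* an empirical p-value for the LLR test: the fraction of permuted
  analytic p-values <= the observed analytic p (null-selected replicates
  contribute p = 1);
* a rank-statistic correction across the 10 characteristics of each SNP:
  the observed r-th smallest p is compared with the permutation
  distribution of r-th smallest p-values.

Rank-adjusted p-values are then Sidak-corrected across SNPs (default 12
assumed independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CHARACTERISTICS, DEFAULT_SIDAK_M
from .datatypes import CohortTable, GenotypeMatrix
from .io import trigroup_labels
from .models import SelectionResult, _select_from_arrays

__all__ = [
    "PermutationConfig",
    "PermutationSummary",
    "permute_genotypes",
    "empirical_cell_significance",
    "rank_adjust",
    "sidak_correct",
    "run_permutation_analysis",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    seed: int = 0
    criterion: str = "bic"
    #: use (r+1)/(B+1) instead of r/B for empirical fractions
    add_one: bool = False
    #: condition the empirical LLR comparison on non-null selections
    #: (excluded replicates; default pools all with p=1 for null picks)
    condition_on_nonnull: bool = False
    sidak_m: int = DEFAULT_SIDAK_M

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.criterion not in ("bic", "aic"):
            raise ValueError("criterion must be 'bic' or 'aic'")


@dataclass(frozen=True)
class PermutationSummary:
    snp_id: str
    characteristic: str
    selected: str
    llr_p_analytic: float
    frac_nonnull: float
    empirical_p: float
    rank_adjusted_p: float
    sidak_p: float


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One independent, reproducible stream per replicate index."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def permute_genotypes(
    geno: GenotypeMatrix, rng: np.random.Generator
) -> GenotypeMatrix:
    """Reassign genotypes to individuals: one column permutation applied
    jointly to all SNPs, leaving per-SNP genotype multisets unchanged."""
    perm = rng.permutation(geno.n_individuals)
    return GenotypeMatrix(geno.snps, geno.individual_ids, geno.counts[:, perm])


def _fraction(count: int, total: int, add_one: bool) -> float:
    if total == 0:
        raise ValueError("cannot form an empirical fraction from 0 permutations")
    if add_one:
        return (count + 1) / (total + 1)
    return count / total


def empirical_cell_significance(
    observed: SelectionResult,
    permuted: list[SelectionResult],
    add_one: bool = False,
    condition_on_nonnull: bool = False,
) -> tuple[float, float]:
    """(frac_nonnull, empirical_p) for one SNP x characteristic cell."""
    if not permuted:
        raise ValueError("need at least one permutation replicate")
    nonnull = [r for r in permuted if r.selected != "null"]
    frac_nonnull = _fraction(len(nonnull), len(permuted), add_one)
    pool = nonnull if condition_on_nonnull else permuted
    if not pool:
        return frac_nonnull, 1.0
    hits = sum(r.llr_p_analytic <= observed.llr_p_analytic for r in pool)
    return frac_nonnull, _fraction(hits, len(pool), add_one)


def rank_adjust(
    observed_ps: np.ndarray,
    permuted_ps: np.ndarray,
    add_one: bool = False,
) -> np.ndarray:
    """Rank-statistic multiplicity correction across one SNP's cells.

    For rank r, the observed r-th smallest analytic p is compared with
    the permutation distribution of r-th smallest p-values; adjusted
    values are forced monotone non-decreasing in rank (step-down
    enforcement) and mapped back to their characteristics.
    """
    observed_ps = np.asarray(observed_ps, dtype=float)
    permuted_ps = np.asarray(permuted_ps, dtype=float)
    if permuted_ps.ndim != 2 or permuted_ps.shape[1] != observed_ps.shape[0]:
        raise ValueError(
            f"permuted_ps shape {permuted_ps.shape} incompatible with "
            f"{observed_ps.shape[0]} observed p-values"
        )
    B = permuted_ps.shape[0]
    order = np.argsort(observed_ps, kind="stable")
    obs_sorted = observed_ps[order]
    perm_sorted = np.sort(permuted_ps, axis=1)
    hits = (perm_sorted <= obs_sorted[None, :]).sum(axis=0)
    adj_sorted = np.array([_fraction(int(h), B, add_one) for h in hits])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def sidak_correct(p: float | np.ndarray, m: int = DEFAULT_SIDAK_M) -> float | np.ndarray:
    """Family-wise Sidak correction 1 - (1 - p)^m for m independent tests."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    out = 1.0 - (1.0 - arr) ** m
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _cell_counts(
    dose: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Three-group (k, n) arrays from a dosage vector and group labels."""
    valid = (labels >= 0) & np.isfinite(dose)
    lab = labels[valid]
    d = dose[valid]
    k = np.array(
        [d[lab == 0].sum(), d[lab == 1].sum(), d[lab == 2].sum()], dtype=float
    )
    n = 2.0 * np.array(
        [(lab == 0).sum(), (lab == 1).sum(), (lab == 2).sum()], dtype=float
    )
    return k, n


def run_permutation_analysis(
    geno: GenotypeMatrix,
    cohort: CohortTable,
    config: PermutationConfig,
    characteristics: tuple[str, ...] = CHARACTERISTICS,
    case_universe: str = "active",
) -> pd.DataFrame:
    """Full empirical-significance scan over SNPs x characteristics.

    Returns one row per cell with the observed selection, the fraction of
    non-null permutation selections, the empirical LLR p, the
    rank-adjusted p across the SNP's characteristics, and the
    Sidak-corrected p across SNPs.
    """
    snp_ids = geno.snp_ids
    label_mat = np.stack(
        [
            trigroup_labels(cohort, ch, case_universe).to_numpy()
            for ch in characteristics
        ]
    )  # (C, individuals) in cohort row order
    cols = geno.column_indices(list(cohort.frame.index))
    dose_mat = geno.counts[:, cols]  # (S, individuals) aligned to cohort order
    S, C = len(snp_ids), len(characteristics)

    def scan(doses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(selected != null, analytic p) for every SNP x characteristic."""
        nonnull = np.zeros((S, C), dtype=bool)
        pvals = np.ones((S, C), dtype=float)
        for i in range(S):
            for j in range(C):
                k, n = _cell_counts(doses[i], label_mat[j])
                if (n == 0).any():
                    raise ValueError(
                        f"empty group for SNP {snp_ids[i]!r} x "
                        f"{characteristics[j]!r}"
                    )
                res = _select_from_arrays(
                    k, n, config.criterion, int(n.sum() // 2)
                )
                nonnull[i, j] = res.selected != "null"
                pvals[i, j] = res.llr_p_analytic
        return nonnull, pvals

    obs_sel = np.empty((S, C), dtype=object)
    obs_p = np.ones((S, C))
    for i in range(S):
        for j in range(C):
            k, n = _cell_counts(dose_mat[i], label_mat[j])
            res = _select_from_arrays(k, n, config.criterion, int(n.sum() // 2))
            obs_sel[i, j] = res.selected
            obs_p[i, j] = res.llr_p_analytic

    B = config.n_permutations
    perm_nonnull = np.zeros((B, S, C), dtype=bool)
    perm_p = np.ones((B, S, C))
    n_ind = dose_mat.shape[1]
    for b, rng in enumerate(_replicate_rngs(config.seed, B)):
        perm = rng.permutation(n_ind)
        perm_nonnull[b], perm_p[b] = scan(dose_mat[:, perm])

    rows = []
    for i, snp_id in enumerate(snp_ids):
        rank_adj = rank_adjust(obs_p[i], perm_p[:, i, :], add_one=config.add_one)
        for j, ch in enumerate(characteristics):
            nn_hits = int(perm_nonnull[:, i, j].sum())
            frac_nonnull = _fraction(nn_hits, B, config.add_one)
            if config.condition_on_nonnull:
                pool = perm_p[perm_nonnull[:, i, j], i, j]
                emp = (
                    _fraction(int((pool <= obs_p[i, j]).sum()), pool.size,
                              config.add_one)
                    if pool.size
                    else 1.0
                )
            else:
                emp = _fraction(
                    int((perm_p[:, i, j] <= obs_p[i, j]).sum()), B, config.add_one
                )
            rows.append(
                PermutationSummary(
                    snp_id=snp_id,
                    characteristic=ch,
                    selected=obs_sel[i, j],
                    llr_p_analytic=obs_p[i, j],
                    frac_nonnull=frac_nonnull,
                    empirical_p=emp,
                    rank_adjusted_p=float(rank_adj[j]),
                    sidak_p=float(sidak_correct(float(rank_adj[j]), config.sidak_m)),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
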