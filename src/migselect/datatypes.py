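"""Core containers: SNP records, genotype matrices, cohort tables, and the
three-group allele-count sufficient statistics.

The analysis design stratifies every SNP x characteristic combination into
three groups: (a) active migraineurs reporting the characteristic, (b)
active migraineurs not reporting it, and (c) non-migraineurs.  Under
Hardy-Weinberg equilibrium within each group, the minor-allele count and
allele total per group are sufficient for all six inheritance models, so
:class:`TriGroupCounts` is the single statistic every model fit consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CHARACTERISTICS, MIGRAINE_STATUSES


@dataclass(frozen=True)
class SnpRecord:
    """Identity of a biallelic SNP (hard-call genotypes only)."""

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    allele_major: str
    coded_allele: str = "minor"  # orientation set later by effect estimation

    def __post_init__(self) -> None:
        if self.allele_minor == self.allele_major:
            raise ValueError(
                f"{self.snp_id}: minor and major allele are identical "
                f"({self.allele_minor!r})"
            )
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive (1-based)")
        if self.coded_allele not in ("minor", "major"):
            raise ValueError(f"coded_allele must be 'minor' or 'major'")


class GenotypeMatrix:
    """Minor-allele dosage matrix, SNPs x individuals.

    ``counts`` is a float array with entries in {0, 1, 2} or NaN for a
    missing hard call.  Row order follows ``snps``; column order follows
    ``individual_ids``.
    """

    def __init__(
        self,
        snps: list[SnpRecord],
        individual_ids: list[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(snps), len(individual_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(snps)} SNPs x {len(individual_ids)} individuals"
            )
        finite = counts[np.isfinite(counts)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"genotype counts must be in {{0,1,2}}; got {bad[:5]}")
        ids = pd.Index(individual_ids)
        if ids.has_duplicates:
            raise ValueError("duplicate individual ids in genotype matrix")
        snp_ids = pd.Index([s.snp_id for s in snps])
        if snp_ids.has_duplicates:
            raise ValueError("duplicate SNP ids in genotype matrix")
        self.snps = list(snps)
        self.individual_ids = list(individual_ids)
        self.counts = counts
        self._snp_index = {s.snp_id: i for i, s in enumerate(self.snps)}
        self._ind_index = {iid: j for j, iid in enumerate(self.individual_ids)}

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def row(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP, ordered as ``individual_ids``."""
        try:
            return self.counts[self._snp_index[snp_id]]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self._snp_index[snp_id]]

    def column_indices(self, individual_ids: list[str]) -> np.ndarray:
        try:
            return np.array([self._ind_index[i] for i in individual_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.counts, other.counts, equal_nan=True)
        )


class CohortTable:
    """Phenotype table: migraine status, attack characteristics, covariates.

    Wraps a DataFrame indexed by ``individual_id`` with a ``migraine_status``
    column in {never, former, active}.  The ten characteristic columns are
    nullable integers that must be 0/1 for active migraineurs and missing
    otherwise (former migraineurs are not sub-classified).  Remaining
    columns are treated as covariates.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.copy()
        if "individual_id" in frame.columns:
            if frame["individual_id"].duplicated().any():
                dup = frame.loc[frame["individual_id"].duplicated(), "individual_id"]
                raise ValueError(f"duplicated individual_id: {dup.iloc[0]!r}")
            frame = frame.set_index("individual_id")
        if frame.index.has_duplicates:
            raise ValueError("duplicated individual_id in cohort table")
        if "migraine_status" not in frame.columns:
            raise ValueError("cohort table requires a migraine_status column")
        bad = ~frame["migraine_status"].isin(MIGRAINE_STATUSES)
        if bad.any():
            label = frame.loc[bad, "migraine_status"].iloc[0]
            raise ValueError(f"unknown migraine_status label {label!r}")

        active = frame["migraine_status"] == "active"
        for name in CHARACTERISTICS:
            if name not in frame.columns:
                frame[name] = pd.array([pd.NA] * len(frame), dtype="Int64")
                continue
            col = pd.to_numeric(frame[name], errors="coerce").astype("Int64")
            missing_active = active & col.isna()
            if missing_active.any():
                row = frame.index[missing_active][0]
                raise ValueError(
                    f"active migraineur {row!r} is missing characteristic {name!r}"
                )
            present = col.dropna()
            if not present.isin((0, 1)).all():
                raise ValueError(f"characteristic {name!r} must be binary 0/1")
            # former/never migraineurs are never sub-classified
            col[~active] = pd.NA
            frame[name] = col
        self.frame = frame

    @property
    def individual_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def migraine_status(self) -> pd.Series:
        return self.frame["migraine_status"]

    @property
    def covariate_names(self) -> list[str]:
        reserved = set(CHARACTERISTICS) | {"migraine_status"}
        return [c for c in self.frame.columns if c not in reserved]

    def characteristic(self, name: str) -> pd.Series:
        if name not in CHARACTERISTICS:
            raise KeyError(f"unknown characteristic {name!r}")
        return self.frame[name]

    def group_sizes(self) -> dict[str, int]:
        return self.migraine_status.value_counts().reindex(
            MIGRAINE_STATUSES, fill_value=0
        ).to_dict()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class TriGroupCounts:
    """Minor-allele counts (k) and allele totals (n) in the three analysis
    groups; n_g = 2 x non-missing individuals in group g."""

    k_with: int
    n_with: int
    k_without: int
    n_without: int
    k_ctrl: int
    n_ctrl: int
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, k, n in (
            ("with", self.k_with, self.n_with),
            ("without", self.k_without, self.n_without),
            ("ctrl", self.k_ctrl, self.n_ctrl),
        ):
            if not 0 <= k <= n:
                raise ValueError(f"group {label!r}: need 0 <= k={k} <= n={n}")
            if n % 2 != 0:
                raise ValueError(f"group {label!r}: allele total n={n} must be even")

    @property
    def n_individuals(self) -> int:
        """Individuals across the three groups (allele totals / 2)."""
        return (self.n_with + self.n_without + self.n_ctrl) // 2

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        k = np.array([self.k_with, self.k_without, self.k_ctrl], dtype=float)
        n = np.array([self.n_with, self.n_without, self.n_ctrl], dtype=float)
        return k, n
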