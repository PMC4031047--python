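"""Synthetic cohort generator emulating the study's statistical structure.

The generator produces (i) a phenotype table with exact group sizes for
active, former and never migraineurs, with the ten attack characteristics
drawn at their cohort prevalences among active migraineurs (optionally
with exchangeable correlation through a shared latent normal), and (ii)
genotypes drawn under Hardy-Weinberg equilibrium with group-specific
minor-allele frequencies obeying any of the six inheritance-model
constraints.  A fast count-level sampler is also provided for power and
calibration studies where only the three-group sufficient statistics are
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import (
    CHARACTERISTICS,
    DEFAULT_CHARACTERISTIC_PREVALENCES,
    DEFAULT_N_ACTIVE,
    DEFAULT_N_FORMER,
    DEFAULT_N_NEVER,
)
from .datatypes import CohortTable, GenotypeMatrix, SnpRecord, TriGroupCounts

__all__ = [
    "SnpScenario",
    "SimulationScenario",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_trigroup_counts",
    "null_snp_scenarios",
]

_MODEL_NAMES = ("null", "basic", "subset", "inverse_subset", "modifier", "general")


@dataclass(frozen=True)
class SnpScenario:
    """Generating model for one SNP, anchored to one characteristic.

    The three frequencies are minor-allele frequencies among active
    migraineurs with the anchoring characteristic, without it, and in
    never-migraineurs.  They must satisfy the named model's constraints
    exactly (for 'modifier' the control frequency must equal
    w*p_with + (1-w)*p_without with w the anchoring characteristic's
    prevalence).  Former migraineurs receive ``p_former`` (default: the
    control frequency).
    """

    snp_id: str
    model: str
    characteristic: str = "aura"
    p_with: float = 0.3
    p_without: float = 0.3
    p_ctrl: float = 0.3
    p_former: float | None = None
    chromosome: str = "1"
    position: int = 0

    def validate(self, prevalence: float, atol: float = 1e-9) -> None:
        if self.model not in _MODEL_NAMES:
            raise ValueError(f"{self.snp_id}: unknown model {self.model!r}")
        if self.characteristic not in CHARACTERISTICS:
            raise ValueError(
                f"{self.snp_id}: unknown characteristic {self.characteristic!r}"
            )
        freqs = (self.p_with, self.p_without, self.p_ctrl)
        if not all(0.0 < p < 1.0 for p in freqs):
            raise ValueError(f"{self.snp_id}: frequencies must lie in (0,1)")
        pw, po, pc = freqs
        ok = {
            "null": pw == po == pc,
            "basic": pw == po,
            "subset": po == pc,
            "inverse_subset": pw == pc,
            "general": True,
            "modifier": abs(pc - (prevalence * pw + (1 - prevalence) * po)) <= atol,
        }[self.model]
        if not ok:
            raise ValueError(
                f"{self.snp_id}: frequencies {freqs} violate the "
                f"{self.model!r} constraint"
            )


def _default_prevalences() -> dict[str, float]:
    return dict(DEFAULT_CHARACTERISTIC_PREVALENCES)


@dataclass(frozen=True)
class SimulationScenario:
    """Cohort-level generating conditions.

    Defaults reproduce the study cohort margins: 3,003 active, 2,119
    former and 18,108 never migraineurs, with the published
    characteristic prevalences among active migraineurs (aura 0.39,
    photophobia 0.66, duration 4-72h 0.78, ...).
    """

    n_active: int = DEFAULT_N_ACTIVE
    n_former: int = DEFAULT_N_FORMER
    n_never: int = DEFAULT_N_NEVER
    characteristic_prevalences: dict[str, float] = field(
        default_factory=_default_prevalences
    )
    snps: tuple[SnpScenario, ...] = ()
    rho: float = 0.0  # exchangeable latent correlation among characteristics
    covariates: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in CHARACTERISTICS:
            p = self.characteristic_prevalences.get(name)
            if p is None or not 0.0 < p < 1.0:
                raise ValueError(
                    f"characteristic prevalence for {name!r} must be in (0,1)"
                )
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for snp in self.snps:
            snp.validate(self.characteristic_prevalences[snp.characteristic])


def simulate_phenotypes(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> CohortTable:
    """Phenotype table with exact group sizes and stochastic flags."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n_total = scenario.n_active + scenario.n_former + scenario.n_never
    width = len(str(n_total))
    ids = [f"I{i:0{width}d}" for i in range(1, n_total + 1)]
    status = (
        ["active"] * scenario.n_active
        + ["former"] * scenario.n_former
        + ["never"] * scenario.n_never
    )
    frame = pd.DataFrame({"individual_id": ids, "migraine_status": status})

    na = scenario.n_active
    thresholds = norm.ppf(
        [scenario.characteristic_prevalences[c] for c in CHARACTERISTICS]
    )
    if scenario.rho > 0:
        shared = rng.standard_normal((na, 1))
        noise = rng.standard_normal((na, len(CHARACTERISTICS)))
        z = np.sqrt(scenario.rho) * shared + np.sqrt(1 - scenario.rho) * noise
    else:
        z = rng.standard_normal((na, len(CHARACTERISTICS)))
    flags = (z < thresholds[None, :]).astype(int)
    for c, name in enumerate(CHARACTERISTICS):
        col = pd.array([pd.NA] * n_total, dtype="Int64")
        col[:na] = flags[:, c]
        frame[name] = col

    for name, spec in scenario.covariates.items():
        kind = spec.get("kind", "normal")
        if kind == "normal":
            frame[name] = rng.normal(
                spec.get("mean", 0.0), spec.get("sd", 1.0), n_total
            )
        elif kind == "bernoulli":
            # group-specific success probabilities allowed via 'p_by_status'
            p_by = spec.get("p_by_status")
            if p_by:
                p_vec = frame["migraine_status"].map(p_by).to_numpy(dtype=float)
            else:
                p_vec = np.full(n_total, spec.get("p", 0.5))
            frame[name] = (rng.random(n_total) < p_vec).astype(int)
        elif kind == "categorical":
            frame[name] = rng.choice(
                spec["levels"], size=n_total, p=spec.get("probs")
            )
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")

    return CohortTable(frame)


def _group_frequencies(
    snp: SnpScenario, cohort: CohortTable
) -> np.ndarray:
    """Per-individual generating frequency for one SNP."""
    status = cohort.migraine_status
    flag = cohort.characteristic(snp.characteristic)
    p = np.empty(len(cohort), dtype=float)
    active = (status == "active").to_numpy()
    with_f = active & (flag == 1).fillna(False).to_numpy(dtype=bool)
    without_f = active & (flag == 0).fillna(False).to_numpy(dtype=bool)
    p[with_f] = snp.p_with
    p[without_f] = snp.p_without
    p[(status == "never").to_numpy()] = snp.p_ctrl
    p_former = snp.p_former if snp.p_former is not None else snp.p_ctrl
    p[(status == "former").to_numpy()] = p_former
    return p


def simulate_genotypes(
    scenario: SimulationScenario,
    cohort: CohortTable,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: dose ~ Binomial(2, p_group) per SNP, SNPs independent."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    if not scenario.snps:
        raise ValueError("scenario defines no SNPs")
    snps = []
    rows = []
    for idx, snp in enumerate(scenario.snps):
        p = _group_frequencies(snp, cohort)
        rows.append(rng.binomial(2, p).astype(float))
        snps.append(
            SnpRecord(
                snp_id=snp.snp_id,
                chromosome=snp.chromosome,
                position=snp.position if snp.position > 0 else idx + 1,
                allele_minor="A",
                allele_major="B",
            )
        )
    return GenotypeMatrix(snps, cohort.individual_ids, np.vstack(rows))


def simulate_cohort(
    scenario: SimulationScenario,
) -> tuple[GenotypeMatrix, CohortTable]:
    """Phenotypes then genotypes from one master seed; deterministic."""
    master = np.random.SeedSequence(scenario.seed)
    pheno_rng, geno_rng = (np.random.default_rng(s) for s in master.spawn(2))
    cohort = simulate_phenotypes(scenario, pheno_rng)
    geno = simulate_genotypes(scenario, cohort, geno_rng)
    return geno, cohort


def simulate_trigroup_counts(
    p_with: float,
    p_without: float,
    p_ctrl: float,
    m_with: int,
    m_without: int,
    m_ctrl: int,
    rng: np.random.Generator,
) -> TriGroupCounts:
    """Count-level sampler: k_g ~ Binomial(2*m_g, p_g) per group.

    Summing per-individual Binomial(2, p) genotypes over a group is
    exactly Binomial(2*m_g, p_g), so this matches the individual-level
    generator in distribution while being far cheaper; used for
    calibration and power studies.
    """
    n = (2 * m_with, 2 * m_without, 2 * m_ctrl)
    k = rng.binomial(n, (p_with, p_without, p_ctrl))
    return TriGroupCounts(
        k_with=int(k[0]),
        n_with=n[0],
        k_without=int(k[1]),
        n_without=n[1],
        k_ctrl=int(k[2]),
        n_ctrl=n[2],
        group_sizes={"with": m_with, "without": m_without, "ctrl": m_ctrl},
    )


def null_snp_scenarios(
    n_snps: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.2, 0.4),
    prefix: str = "null",
) -> tuple[SnpScenario, ...]:
    """A panel of no-association SNPs (used for the null covariance)."""
    mafs = rng.uniform(*maf_range, size=n_snps)
    return tuple(
        SnpScenario(
            snp_id=f"{prefix}{i:05d}",
            model="null",
            characteristic="aura",
            p_with=float(m),
            p_without=float(m),
            p_ctrl=float(m),
        )
        for i, m in enumerate(mafs)
    )
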