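"""End-to-end orchestration: cohort summaries, the model-selection scan,
permutation significance, stratified effects, and selectivity clustering,
emitting report tables shaped like the study's.

All outputs are TSV/Newick/JSON text files written atomically: stages run
into a staging directory that replaces the output directory only on
success, so a failed stage leaves no partial bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .constants import (
    ACTIVE_VS_FORMER,
    CHARACTERISTICS,
    DEFAULT_N_NULL_SNPS,
    DEFAULT_SIDAK_M,
)
from .clustering import (
    estimate_null_covariance,
    hierarchical_cluster,
    pairwise_mahalanobis,
    tstat_vectors_from_effects,
)
from .datatypes import CohortTable, GenotypeMatrix
from .effects import choose_coded_allele, effects_table
from .io import read_genotypes, read_phenotypes, tabulate_trigroup
from .models import MODEL_LABELS, select_model
from .permutation import PermutationConfig, run_permutation_analysis
from .simulate import (
    SimulationScenario,
    SnpScenario,
    null_snp_scenarios,
    simulate_cohort,
    simulate_genotypes,
)

logger = logging.getLogger("migselect")

__all__ = ["RunConfig", "summarize_cohort", "run_full_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage."""


@dataclass
class RunConfig:
    """Configuration for a full run; built from a YAML mapping."""

    scenario: SimulationScenario | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    phenotypes_path: str | None = None
    criteria: tuple[str, ...] = ("bic", "aic")
    characteristics: tuple[str, ...] = CHARACTERISTICS
    permutations: PermutationConfig = field(
        default_factory=lambda: PermutationConfig(n_permutations=200, seed=0)
    )
    include_active_vs_former: bool = True
    n_null_snps: int = DEFAULT_N_NULL_SNPS
    min_null_snps: int = 30
    linkage: str = "complete"
    alpha: float = 0.05
    sidak_m: int = DEFAULT_SIDAK_M
    seed: int = 0
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("at least one selection criterion is required")
        for ch in self.characteristics:
            if ch not in CHARACTERISTICS:
                raise ValueError(f"unknown characteristic {ch!r}")
        has_files = self.genotypes_path is not None and self.phenotypes_path is not None
        if (self.scenario is None) == (not has_files):
            raise ValueError(
                "exactly one of a simulation scenario or input paths is required"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            snps = tuple(SnpScenario(**s) for s in sc.pop("snps", []))
            kwargs["scenario"] = SimulationScenario(snps=snps, **sc)
        inputs = raw.get("inputs", {})
        kwargs["genotypes_path"] = inputs.get("genotypes")
        kwargs["genotypes_format"] = inputs.get("genotypes_format", "tsv")
        kwargs["phenotypes_path"] = inputs.get("phenotypes")
        if "criteria" in raw:
            kwargs["criteria"] = tuple(raw["criteria"])
        if "characteristics" in raw:
            kwargs["characteristics"] = tuple(raw["characteristics"])
        perm = raw.get("permutations", {})
        kwargs["permutations"] = PermutationConfig(
            n_permutations=perm.get("count", 200),
            seed=perm.get("seed", raw.get("seed", 0)),
            criterion=perm.get("criterion", "bic"),
            sidak_m=perm.get("sidak_m", raw.get("sidak_m", DEFAULT_SIDAK_M)),
        )
        clus = raw.get("clustering", {})
        kwargs["n_null_snps"] = clus.get("n_null_snps", DEFAULT_N_NULL_SNPS)
        kwargs["min_null_snps"] = clus.get("min_null_snps", 30)
        kwargs["linkage"] = clus.get("linkage", "complete")
        for key in ("alpha", "seed", "include_active_vs_former", "sidak_m"):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs["covariate_types"] = raw.get("covariate_types", {})
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(self, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def summarize_cohort(
    cohort: CohortTable,
    covariate_types: dict[str, str],
    groups: tuple[str, str] = ("active", "never"),
) -> pd.DataFrame:
    """Per-covariate group summaries with two-sided tests.

    Continuous covariates are summarized as median (IQR) and compared by
    a two-sided t-test (pooled variance); categorical covariates as
    N (%) per level with a Pearson chi-square on the r x 2 contingency
    table, without continuity correction.
    """
    status = cohort.migraine_status
    masks = {g: status == g for g in groups}
    rows = []
    for name, kind in covariate_types.items():
        if name not in cohort.frame.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        col = cohort.frame[name]
        if kind == "continuous":
            x = {g: pd.to_numeric(col[m], errors="coerce").dropna() for g, m in masks.items()}
            t, p = stats.ttest_ind(x[groups[0]], x[groups[1]], equal_var=True)
            summ = {
                g: f"{v.median():.1f} ({v.quantile(0.25):.1f}-{v.quantile(0.75):.1f})"
                for g, v in x.items()
            }
            rows.append(
                {"covariate": name, "type": kind, **summ, "statistic": float(t),
                 "p": float(p), "note": ""}
            )
        elif kind == "categorical":
            tab = pd.crosstab(col, status)[list(groups)]
            tab = tab.loc[(tab.sum(axis=1) > 0)]
            if tab.shape[0] < 2:
                rows.append(
                    {"covariate": name, "type": kind,
                     **{g: "" for g in groups},
                     "statistic": np.nan, "p": np.nan,
                     "note": "single level; chi-square skipped"}
                )
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            summ = {
                g: "; ".join(
                    f"{lvl}: {tab.loc[lvl, g]} ({100 * tab.loc[lvl, g] / tab[g].sum():.1f}%)"
                    for lvl in tab.index
                )
                for g in groups
            }
            rows.append(
                {"covariate": name, "type": kind, **summ,
                 "statistic": float(chi2), "p": float(p), "note": ""}
            )
        else:
            raise ValueError(f"covariate {name!r}: type must be continuous/categorical")
    return pd.DataFrame(rows)


def characteristic_prevalence(cohort: CohortTable) -> pd.DataFrame:
    """Counts and fractions of each characteristic among active migraineurs."""
    active = cohort.frame[cohort.migraine_status == "active"]
    rows = []
    for name in CHARACTERISTICS:
        flags = active[name].dropna()
        yes = int((flags == 1).sum())
        no = int((flags == 0).sum())
        total = yes + no
        rows.append(
            {"characteristic": name, "n_yes": yes, "n_no": no,
             "fr_yes": round(yes / total, 2) if total else np.nan,
             "fr_no": round(no / total, 2) if total else np.nan}
        )
    return pd.DataFrame(rows)


def _model_matrix(
    perm_summary: pd.DataFrame, characteristics: tuple[str, ...], alpha: float
) -> pd.DataFrame:
    """SNP x characteristic matrix of selected-model labels with '*' for
    cells significant after rank + Sidak correction."""
    rows = {}
    for snp_id, grp in perm_summary.groupby("snp_id", sort=False):
        entries = {}
        for _, rec in grp.iterrows():
            label = MODEL_LABELS[rec["selected"]]
            if rec["selected"] != "null" and rec["sidak_p"] < alpha:
                label += "*"
            entries[rec["characteristic"]] = label
        rows[snp_id] = entries
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.reindex(columns=list(characteristics))
    out.index.name = "snp_id"
    return out


def run_full_analysis(config: RunConfig, outdir: str) -> dict[str, str]:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a mapping of output names to file paths.  Any stage failure
    raises :class:`PipelineError` naming the stage; no partial bundle is
    left behind.
    """
    staging = outdir.rstrip(os.sep) + ".staging"
    if os.path.exists(staging):
        shutil.rmtree(staging)
    os.makedirs(staging)
    outputs: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, fname: str, writer) -> None:
        path = os.path.join(staging, fname)
        writer(path)
        outputs[name] = os.path.join(outdir, fname)

    try:
        t0 = time.time()
        stage = "load"
        if config.scenario is not None:
            geno, cohort = simulate_cohort(config.scenario)
        else:
            geno = read_genotypes(config.genotypes_path, config.genotypes_format)
            cohort = read_phenotypes(config.phenotypes_path)
        logger.info("stage load: %d SNPs, %d individuals (%.1fs)",
                    geno.n_snps, len(cohort), time.time() - t0)

        stage = "cohort_summary"
        t0 = time.time()
        prev = characteristic_prevalence(cohort)
        emit("characteristic_prevalence", "characteristic_prevalence.tsv",
             lambda p: prev.to_csv(p, sep="\t", index=False))
        if config.covariate_types:
            summ = summarize_cohort(cohort, config.covariate_types)
            emit("cohort_summary", "cohort_summary.tsv",
                 lambda p: summ.to_csv(p, sep="\t", index=False))
        logger.info("stage cohort_summary done (%.1fs)", time.time() - t0)

        stage = "permutation"
        t0 = time.time()
        perm_frames = {}
        for criterion in config.criteria:
            pconf = PermutationConfig(
                n_permutations=config.permutations.n_permutations,
                seed=config.permutations.seed,
                criterion=criterion,
                add_one=config.permutations.add_one,
                condition_on_nonnull=config.permutations.condition_on_nonnull,
                sidak_m=config.sidak_m,
            )
            df = run_permutation_analysis(
                geno, cohort, pconf, characteristics=config.characteristics
            )
            perm_frames[criterion] = df
            emit(f"permutation_{criterion}", f"permutation_summary_{criterion}.tsv",
                 lambda p, d=df: d.to_csv(p, sep="\t", index=False))
            matrix = _model_matrix(df, config.characteristics, config.alpha)
            emit(f"model_matrix_{criterion}", f"model_matrix_{criterion}.tsv",
                 lambda p, m=matrix: m.to_csv(p, sep="\t"))
        logger.info("stage permutation done (%.1fs)", time.time() - t0)

        stage = "active_vs_former"
        if config.include_active_vs_former:
            t0 = time.time()
            rows = []
            for snp_id in geno.snp_ids:
                counts = tabulate_trigroup(geno, cohort, snp_id, ACTIVE_VS_FORMER)
                rec: dict = {"snp_id": snp_id}
                for criterion in config.criteria:
                    res = select_model(counts, criterion)
                    rec[criterion] = MODEL_LABELS[res.selected]
                rows.append(rec)
            avf = pd.DataFrame(rows)
            emit("active_vs_former", "active_vs_former.tsv",
                 lambda p: avf.to_csv(p, sep="\t", index=False))
            logger.info("stage active_vs_former done (%.1fs)", time.time() - t0)

        stage = "effects"
        t0 = time.time()
        orientations = choose_coded_allele(geno, cohort)
        eff = effects_table(
            geno, cohort, characteristics=CHARACTERISTICS,
            orientations=orientations,
        )
        emit("effects", "stratified_effects.tsv",
             lambda p: eff.to_csv(p, sep="\t", index=False))
        logger.info("stage effects done (%.1fs)", time.time() - t0)

        stage = "clustering"
        t0 = time.time()
        null_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0]
        )
        null_scen = SimulationScenario(
            n_active=(config.scenario.n_active if config.scenario else
                      int((cohort.migraine_status == "active").sum())),
            n_former=(config.scenario.n_former if config.scenario else
                      int((cohort.migraine_status == "former").sum())),
            n_never=(config.scenario.n_never if config.scenario else
                     int((cohort.migraine_status == "never").sum())),
            snps=null_snp_scenarios(config.n_null_snps, null_rng),
            seed=config.seed + 1,
        )
        null_geno = simulate_genotypes(null_scen, cohort, null_rng)
        null_eff = effects_table(null_geno, cohort)
        null_vectors = tstat_vectors_from_effects(null_eff)
        cov = estimate_null_covariance(null_vectors, min_snps=config.min_null_snps)
        vectors = tstat_vectors_from_effects(eff)
        dist = pairwise_mahalanobis(vectors, cov)
        emit("distance_matrix", "distance_matrix.tsv",
             lambda p: dist.to_csv(p, sep="\t"))
        clus = hierarchical_cluster(dist, method=config.linkage)
        emit("dendrogram", "dendrogram.nwk",
             lambda p: open(p, "w").write(clus.newick + "\n"))
        # effect matrix in dendrogram leaf order (Figure-style data)
        wide = eff.pivot_table(
            index="snp_id", columns=["characteristic", "stratum"], values="beta"
        ).reindex(clus.leaf_order)
        wide.columns = [f"{c}_{s}" for c, s in wide.columns]
        emit("effects_clustered", "effects_clustered.tsv",
             lambda p: wide.to_csv(p, sep="\t"))
        logger.info("stage clustering done (%.1fs)", time.time() - t0)

        stage = "manifest"
        manifest = {
            "package": "migselect",
            "version": __version__,
            "seed": config.seed,
            "permutation_seed": config.permutations.seed,
            "config_hash": config.config_hash(),
            "n_snps": geno.n_snps,
            "n_individuals": len(cohort),
            "criteria": list(config.criteria),
            "outputs": sorted(os.listdir(staging)),
        }
        emit("manifest", "run_manifest.json",
             lambda p: open(p, "w").write(json.dumps(manifest, indent=2) + "\n"))

        if os.path.exists(outdir):
            shutil.rmtree(outdir)
        os.replace(staging, outdir)
        return outputs
    except Exception as exc:
        shutil.rmtree(staging, ignore_errors=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
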