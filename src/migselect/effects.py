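"""Stratified logistic effect estimates with the coded-allele convention.

For each SNP and characteristic three unadjusted logistic regressions are
fit against never-migraineurs: active migraineurs with the characteristic
("with"), active migraineurs without it ("without"), and all active
migraineurs ("overall").  Genotypes enter as additive allele dose
(0/1/2).  The coded allele is oriented per SNP so that it associates with
increased odds of any report of migraine (active or former vs never);
this fixes the sign convention of all downstream betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import CHARACTERISTICS
from .datatypes import CohortTable, GenotypeMatrix

__all__ = [
    "EffectEstimate",
    "choose_coded_allele",
    "stratum_effect",
    "effects_table",
]

STRATA = ("with", "without", "overall")


@dataclass(frozen=True)
class EffectEstimate:
    snp_id: str
    characteristic: str
    stratum: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    ok: bool = True
    message: str = ""


def _logit_fit(y: np.ndarray, dose: np.ndarray) -> tuple[float, float, float, bool, str]:
    """Unadjusted logistic fit of y on allele dose; returns (beta, se, p,
    converged, message)."""
    X = sm.add_constant(dose)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # perfect separation, singular design, ...
            return np.nan, np.nan, np.nan, False, f"logistic fit failed: {exc}"
    converged = bool(res.mle_retvals.get("converged", False))
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    msg = "" if converged else "logistic fit did not converge"
    return beta, se, p, converged, msg


def choose_coded_allele(
    geno: GenotypeMatrix, cohort: CohortTable
) -> dict[str, str]:
    """Per-SNP coded-allele orientation from the any-migraine regression.

    Fits ever-migraine (active + former) vs never on the minor-allele
    dose; the coded allele is the minor allele when beta >= 0, otherwise
    the major allele.
    """
    status = cohort.migraine_status
    keep = status.isin(("never", "former", "active"))
    y_full = status[keep].isin(("former", "active")).to_numpy(dtype=float)
    cols = geno.column_indices(list(status.index[keep]))
    orientation: dict[str, str] = {}
    for i, snp in enumerate(geno.snps):
        dose = geno.counts[i, cols]
        valid = np.isfinite(dose)
        d, y = dose[valid], y_full[valid]
        if np.all(d == d[0]):
            raise ValueError(
                f"SNP {snp.snp_id!r} is monomorphic; coded allele undefined"
            )
        beta, _, _, ok, msg = _logit_fit(y, d)
        if not ok:
            raise RuntimeError(f"orientation fit failed for {snp.snp_id!r}: {msg}")
        orientation[snp.snp_id] = "minor" if beta >= 0 else "major"
    return orientation


def _case_mask(
    cohort: CohortTable, characteristic: str, stratum: str
) -> pd.Series:
    status = cohort.migraine_status
    active = status == "active"
    if stratum == "overall":
        return active
    flag = cohort.characteristic(characteristic)
    if stratum == "with":
        return active & (flag == 1)
    if stratum == "without":
        return active & (flag == 0)
    raise ValueError(f"unknown stratum {stratum!r}")


def stratum_effect(
    geno: GenotypeMatrix,
    cohort: CohortTable,
    snp_id: str,
    characteristic: str,
    stratum: str,
    orientation: str = "minor",
    min_cases: int = 10,
    min_controls: int = 10,
) -> EffectEstimate:
    """Logistic effect of the coded allele for one stratum vs non-cases.

    Former migraineurs are excluded throughout; the control group is
    never-migraineurs.  ``orientation`` is the coded allele ('minor' or
    'major') as chosen by :func:`choose_coded_allele`.
    """
    cases = _case_mask(cohort, characteristic, stratum)
    controls = cohort.migraine_status == "never"
    universe = cases | controls
    ids = list(cohort.frame.index[universe])
    y = cases[universe].to_numpy(dtype=float)
    dose = geno.row(snp_id)[geno.column_indices(ids)]
    if orientation == "major":
        dose = 2.0 - dose
    valid = np.isfinite(dose)
    y, dose = y[valid], dose[valid]
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < min_cases or n_controls < min_controls:
        raise ValueError(
            f"stratum {stratum!r} for {snp_id} x {characteristic}: "
            f"{n_cases} cases / {n_controls} controls below the "
            f"({min_cases}, {min_controls}) guard"
        )
    beta, se, p, ok, msg = _logit_fit(y, dose)
    return EffectEstimate(
        snp_id=snp_id,
        characteristic=characteristic,
        stratum=stratum,
        beta=beta,
        se=se,
        p=p,
        n_cases=n_cases,
        n_controls=n_controls,
        ok=ok,
        message=msg,
    )


def effects_table(
    geno: GenotypeMatrix,
    cohort: CohortTable,
    characteristics: tuple[str, ...] = CHARACTERISTICS,
    orientations: dict[str, str] | None = None,
    min_cases: int = 10,
    min_controls: int = 10,
) -> pd.DataFrame:
    """Per SNP x characteristic with/without betas plus the overall
    active-migraine effect (one overall row per SNP)."""
    if orientations is None:
        orientations = choose_coded_allele(geno, cohort)
    rows: list[EffectEstimate] = []
    for snp_id in geno.snp_ids:
        orient = orientations[snp_id]
        rows.append(
            stratum_effect(
                geno, cohort, snp_id, characteristics[0], "overall",
                orientation=orient, min_cases=min_cases, min_controls=min_controls,
            )
        )
        for ch in characteristics:
            for stratum in ("with", "without"):
                rows.append(
                    stratum_effect(
                        geno, cohort, snp_id, ch, stratum,
                        orientation=orient,
                        min_cases=min_cases, min_controls=min_controls,
                    )
                )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.loc[out["stratum"] == "overall", "characteristic"] = "actmig"
    return out
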