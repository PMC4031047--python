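"""Constrained binomial likelihood models for selective association.

Every SNP x characteristic combination is summarized by minor-allele
counts in three groups: active migraineurs with the characteristic (w),
active migraineurs without it (o), and non-migraineurs (c).  Assuming
Hardy-Weinberg equilibrium within each group, the allele count k_g is
Binomial(n_g, p_g) with n_g = 2 x individuals, and the log-likelihood is

    LL(p) = sum_g [ k_g log p_g + (n_g - k_g) log(1 - p_g) ]

(constant binomial coefficients omitted).  The six inheritance models are
nested constraints on (p_w, p_o, p_c):

========  ===========================================  ==
model     constraint                                   df
========  ===========================================  ==
null      p_w = p_o = p_c                               1
basic     p_w = p_o, p_c free                           2
subset    p_w free, p_o = p_c                           2
inverse   p_o free, p_w = p_c                           2
modifier  p_w, p_o free, p_c = w*p_w + (1-w)*p_o        2
general   all three free                                3
========  ===========================================  ==

where w = n_w / (n_w + n_o) is the allele-total weight of the with-group.
The "modifier" model encodes association with the characteristic
conditional on having migraine (no case/control difference in the
margin).  Model selection minimizes AIC = -2LL + 2df or
BIC = -2LL + df log(N) with N the number of individuals, and the selected
model is tested against the null by the log-likelihood-ratio statistic
with an asymptotic chi-square reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, xlogy
from scipy.stats import chi2

from .datatypes import TriGroupCounts

__all__ = [
    "MODEL_NAMES",
    "MODEL_DF",
    "ModelFit",
    "SelectionResult",
    "fit_model",
    "fit_all_models",
    "select_model",
    "llr_pvalue",
]

#: Fixed model order; also the tie-break order in selection (already
#: sorted by increasing df within equal-df blocks).
MODEL_NAMES: tuple[str, ...] = (
    "null",
    "basic",
    "subset",
    "inverse_subset",
    "modifier",
    "general",
)

MODEL_DF: dict[str, int] = {
    "null": 1,
    "basic": 2,
    "subset": 2,
    "inverse_subset": 2,
    "modifier": 2,
    "general": 3,
}

#: Display labels used in report tables.
MODEL_LABELS: dict[str, str] = {
    "null": "-",
    "basic": "basic",
    "subset": "sub.",
    "inverse_subset": "inv. sub.",
    "modifier": "modifier",
    "general": "general",
}


@dataclass(frozen=True)
class ModelFit:
    """One fitted inheritance model on a three-group count table."""

    model: str
    freq_with: float
    freq_without: float
    freq_ctrl: float
    loglik: float
    df: int
    aic: float
    bic: float


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of information-criterion model selection for one cell."""

    criterion: str
    selected: str
    llr_stat: float
    llr_df: int
    llr_p_analytic: float
    fits: dict[str, ModelFit] | None = None


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Per-group binomial log-likelihood; 0*log 0 = 0 at boundary MLEs."""
    p = np.asarray(p, dtype=float)
    return float(np.sum(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def _freq(k: float, n: float, fallback: float) -> float:
    return k / n if n > 0 else fallback


def _modifier_mle(
    k: np.ndarray, n: np.ndarray, tol: float = 1e-10
) -> tuple[float, float, float]:
    """Numeric MLE of the modifier model on the logit scale.

    Returns (p_with, p_without, loglik).  The control frequency is tied to
    w*p_with + (1-w)*p_without with w the allele-total weight of the
    with-group among cases.
    """
    kw, ko, kc = k
    nw, no, nc = n
    w = nw / (nw + no)

    # start points stay off the boundary: at logit extremes the chain
    # factor p(1-p) annihilates the gradient and the optimizer stalls
    def clip(p: float) -> float:
        return min(max(p, 1e-2), 1.0 - 1e-2)

    pooled = clip(float(k.sum() / n.sum()))
    starts = [
        np.array([logit(clip(_freq(kw, nw, 0.5))), logit(clip(_freq(ko, no, 0.5)))]),
        np.array([logit(pooled), logit(pooled)]),
    ]

    def negll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # clamp away from exact 0/1 where expit saturates in float
        pw, po = np.clip(expit(theta), 1e-12, 1.0 - 1e-12)
        pc = w * pw + (1.0 - w) * po
        ll = (
            xlogy(kw, pw)
            + xlogy(nw - kw, 1.0 - pw)
            + xlogy(ko, po)
            + xlogy(no - ko, 1.0 - po)
            + xlogy(kc, pc)
            + xlogy(nc - kc, 1.0 - pc)
        )
        # d ll / d p, then chain through the logit: dp/dtheta = p(1-p)
        def score(kk: float, nn: float, p: float) -> float:
            s = 0.0
            if kk > 0:
                s += kk / p
            if nn - kk > 0:
                s -= (nn - kk) / (1.0 - p)
            return s

        sc = score(kc, nc, pc)
        g_pw = score(kw, nw, pw) + w * sc
        g_po = score(ko, no, po) + (1.0 - w) * sc
        grad = -np.array([g_pw * pw * (1.0 - pw), g_po * po * (1.0 - po)])
        return -float(ll), grad

    best = None
    for p0 in starts:
        res = minimize(
            negll_grad,
            p0,
            jac=True,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-9, "maxiter": 200},
        )
        if not res.success and res.status != 2:  # status 2 = precision loss
            raise RuntimeError(
                f"modifier model did not converge: {res.message} "
                f"(counts k={k.tolist()}, n={n.tolist()})"
            )
        if best is None or res.fun < best.fun:
            best = res
    pw, po = expit(best.x)
    return float(pw), float(po), -float(best.fun)


def _fit_from_arrays(
    model: str, k: np.ndarray, n: np.ndarray, n_individuals: int, bic_n: int | None
) -> ModelFit:
    kw, ko, kc = k
    nw, no, nc = n
    total_n = float(n.sum())
    if total_n == 0:
        raise ValueError("all three groups are empty")
    pooled = float(k.sum() / total_n)

    if model == "null":
        p = (pooled, pooled, pooled)
    elif model == "basic":
        p_case = _freq(kw + ko, nw + no, pooled)
        p = (p_case, p_case, _freq(kc, nc, pooled))
    elif model == "subset":
        shared = _freq(ko + kc, no + nc, pooled)
        p = (_freq(kw, nw, pooled), shared, shared)
    elif model == "inverse_subset":
        shared = _freq(kw + kc, nw + nc, pooled)
        p = (shared, _freq(ko, no, pooled), shared)
    elif model == "general":
        p = (_freq(kw, nw, pooled), _freq(ko, no, pooled), _freq(kc, nc, pooled))
    elif model == "modifier":
        pw, po, _ = _modifier_mle(k, n)
        w = nw / (nw + no)
        p = (pw, po, w * pw + (1.0 - w) * po)
    else:
        raise ValueError(f"unknown model {model!r}")

    ll = _binom_loglik(k, n, np.array(p))
    df = MODEL_DF[model]
    nn = bic_n if bic_n is not None else n_individuals
    return ModelFit(
        model=model,
        freq_with=float(p[0]),
        freq_without=float(p[1]),
        freq_ctrl=float(p[2]),
        loglik=ll,
        df=df,
        aic=-2.0 * ll + 2.0 * df,
        bic=-2.0 * ll + df * np.log(nn),
    )


def fit_model(
    counts: TriGroupCounts, model: str, bic_n: int | None = None
) -> ModelFit:
    """Fit one inheritance model by maximum likelihood.

    All models except ``modifier`` have closed-form MLEs (pooled sample
    frequencies over the groups each parameter covers); the modifier
    constraint is maximized numerically.  ``bic_n`` overrides the BIC
    sample size (default: individuals across the three groups).
    """
    k, n = counts.as_arrays()
    return _fit_from_arrays(model, k, n, counts.n_individuals, bic_n)


def fit_all_models(
    counts: TriGroupCounts, bic_n: int | None = None
) -> dict[str, ModelFit]:
    return {m: fit_model(counts, m, bic_n=bic_n) for m in MODEL_NAMES}


def llr_pvalue(llr_stat: float, llr_df: int) -> float:
    """Upper-tail chi-square probability of the LLR statistic.

    The reference distribution uses df = difference in free parameters
    between the selected model and the null.  Used analytically only to
    rank permutation replicates; empirical calibration is done by
    permutation.
    """
    if llr_df <= 0:
        raise ValueError(f"llr_df must be positive, got {llr_df}")
    if llr_stat < 0:
        raise ValueError(f"llr_stat must be non-negative, got {llr_stat}")
    if llr_stat == 0:
        return 1.0
    return float(chi2.sf(llr_stat, llr_df))


def _select_from_arrays(
    k: np.ndarray,
    n: np.ndarray,
    criterion: str,
    n_individuals: int,
    bic_n: int | None = None,
    keep_fits: bool = False,
) -> SelectionResult:
    if criterion not in ("bic", "aic"):
        raise ValueError(f"criterion must be 'bic' or 'aic', got {criterion!r}")
    nn = bic_n if bic_n is not None else n_individuals
    penalty = (np.log(nn) if criterion == "bic" else 2.0)

    fits: dict[str, ModelFit] = {}
    closed = ("null", "basic", "subset", "inverse_subset", "general")
    for m in closed:
        fits[m] = _fit_from_arrays(m, k, n, n_individuals, bic_n)

    def crit(f: ModelFit) -> float:
        return f.bic if criterion == "bic" else f.aic

    best = min(
        (m for m in closed),
        key=lambda m: (crit(fits[m]), fits[m].df, MODEL_NAMES.index(m)),
    )
    # The modifier log-likelihood is bounded above by the general model's;
    # fit it only when that bound allows it to win the criterion.
    modifier_bound = crit(fits["general"]) - penalty  # df 2 vs 3
    if keep_fits or modifier_bound <= crit(fits[best]):
        fits["modifier"] = _fit_from_arrays("modifier", k, n, n_individuals, bic_n)
        cand = (*closed, "modifier")
        best = min(
            cand,
            key=lambda m: (crit(fits[m]), fits[m].df, MODEL_NAMES.index(m)),
        )

    if best == "null":
        return SelectionResult(
            criterion=criterion,
            selected="null",
            llr_stat=0.0,
            llr_df=0,
            llr_p_analytic=1.0,
            fits=fits if keep_fits else None,
        )
    stat = max(0.0, 2.0 * (fits[best].loglik - fits["null"].loglik))
    df = fits[best].df - fits["null"].df
    return SelectionResult(
        criterion=criterion,
        selected=best,
        llr_stat=stat,
        llr_df=df,
        llr_p_analytic=llr_pvalue(stat, df) if stat > 0 else 1.0,
        fits=fits if keep_fits else None,
    )


def general_vs_null(counts: TriGroupCounts) -> SelectionResult:
    """Forced 2-df LLR test of the general model against the null.

    Unlike criterion-based selection, this statistic is continuous under
    the null, which makes it suitable for calibration checks of the
    analytic chi-square reference and of the permutation machinery.
    """
    k, n = counts.as_arrays()
    f_null = _fit_from_arrays("null", k, n, counts.n_individuals, None)
    f_gen = _fit_from_arrays("general", k, n, counts.n_individuals, None)
    stat = max(0.0, 2.0 * (f_gen.loglik - f_null.loglik))
    return SelectionResult(
        criterion="forced",
        selected="general",
        llr_stat=stat,
        llr_df=2,
        llr_p_analytic=llr_pvalue(stat, 2) if stat > 0 else 1.0,
    )


def select_model(
    counts: TriGroupCounts,
    criterion: str = "bic",
    bic_n: int | None = None,
    keep_fits: bool = False,
) -> SelectionResult:
    """Select an inheritance model by minimizing the penalized likelihood.

    Ties break toward fewer free parameters and then the fixed model
    order (null, basic, subset, inverse_subset, modifier, general).  The
    LLR statistic and analytic chi-square p compare the selected model
    with the null fit; a null selection yields stat 0 and p 1.
    """
    k, n = counts.as_arrays()
    return _select_from_arrays(
        k, n, criterion, counts.n_individuals, bic_n=bic_n, keep_fits=keep_fits
    )
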