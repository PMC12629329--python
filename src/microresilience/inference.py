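"""Statistical machinery for the two-arm longitudinal design.

The workhorse is a linear mixed model per outcome,

    value ~ arm + time + arm:time (+ covariates),  random intercept ~ subject

fitted by REML for estimates.  The single treatment-by-time interaction
p-value is a likelihood-ratio test (ML refits) of the model with versus
without all interaction terms, since time is a categorical factor with
potentially several levels.  When the interaction is significant,
per-visit between-arm contrasts are read off the fitted fixed effects.

Nonparametric companions: exact-by-default Wilcoxon signed-rank (baseline
vs post-antibiotic, within subject) and Mann-Whitney U (between arms, per
visit), with Benjamini-Hochberg correction across each per-taxon screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import CLRMatrix
from .tables import Arm, SampleRecord, Timepoint, ValidationError

logger = logging.getLogger("microresilience")

__all__ = [
    "LMMSpec",
    "LMMResult",
    "InsufficientDataError",
    "ContractError",
    "DesignError",
    "fit_lmm",
    "posthoc_contrast",
    "paired_wilcoxon",
    "mann_whitney",
    "bh_adjust",
    "correlate",
    "taxa_screen",
]


class InsufficientDataError(ValueError):
    pass


class ContractError(RuntimeError):
    pass


class DesignError(ValueError):
    pass


#: time levels eligible for supplementation-period models
_SUPP_LEVELS = ("CID2", "SUV1", "SUV2", "SUV3", "CID3")


@dataclass
class LMMSpec:
    """Specification of one treatment-by-time mixed model.

    ``covariates`` may contain ``vanco_delta_covariate`` (change of the
    outcome during the antibiotic week) and/or ``baseline_covariate``
    (baseline BMI); per-taxon and resilience models use none.
    """

    outcome_name: str
    time_levels: tuple[str, ...] = _SUPP_LEVELS
    covariates: tuple[str, ...] = ()
    alpha: float = 0.05

    def __post_init__(self) -> None:
        bad = [t for t in self.time_levels if t not in _SUPP_LEVELS]
        if bad:
            raise DesignError(
                f"time levels {bad} outside the supplementation period {_SUPP_LEVELS}"
            )
        if len(self.time_levels) < 2:
            raise DesignError("need at least two time levels for an interaction")


@dataclass
class LMMResult:
    """Fitted fixed effects and the interaction test for one outcome."""

    outcome_name: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, p
    p_interaction: float
    lr_stat: float
    df_interaction: int
    converged: bool
    method: Literal["mixedlm", "ols"]
    alpha: float
    time_levels: tuple[str, ...]
    posthoc: dict[str, tuple[float, float]] = field(default_factory=dict)
    _fit: object = field(default=None, repr=False, compare=False)

    def interaction_terms(self) -> pd.DataFrame:
        mask = [":" in t and "time" in t for t in self.fixed_effects.index]
        return self.fixed_effects[mask]


def _model_frame(data: pd.DataFrame, spec: LMMSpec) -> pd.DataFrame:
    df = data.copy()
    if "value" not in df.columns:
        raise ValidationError("long data must carry a 'value' column")
    df["arm"] = [
        (a.value if isinstance(a, Arm) else Arm.parse(a).value) for a in df["arm"]
    ]
    df["time"] = [
        (t.name if isinstance(t, Timepoint) else Timepoint.parse(t).name)
        for t in df["timepoint"]
    ]
    df = df[df["time"].isin(spec.time_levels)]
    df = df.dropna(subset=["value", *spec.covariates])
    df["arm"] = pd.Categorical(df["arm"], categories=["placebo", "2FL"])
    df["time"] = pd.Categorical(df["time"], categories=list(spec.time_levels))
    if df["arm"].nunique() < 2:
        raise DesignError("both arms are required to estimate a treatment effect")
    if df["time"].nunique() < 2:
        raise DesignError("at least two observed time levels are required")
    per_arm = df.groupby("arm", observed=True)["subject_id"].nunique()
    if (per_arm < 2).any():
        raise InsufficientDataError("need >= 2 subjects per arm")
    return df


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """Fit the treatment-by-time mixed model for one outcome.

    ``data`` is long-format with columns ``subject_id``, ``arm``,
    ``timepoint``, ``value`` and any covariate columns named in the spec.
    Estimates come from a REML fit; the interaction p-value from an ML
    likelihood-ratio test of all interaction terms jointly.  On degenerate
    data where the mixed model cannot be fitted (e.g. zero residual
    variance), the fixed effects fall back to OLS — identical on balanced
    complete designs — and the result is flagged.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = _model_frame(data, spec)
    cov = "".join(f" + {c}" for c in spec.covariates)
    f_full = "value ~ arm * time" + cov
    f_red = "value ~ arm + time" + cov
    df_int = (df["arm"].nunique() - 1) * (df["time"].nunique() - 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            reml = smf.mixedlm(f_full, df, groups=df["subject_id"]).fit(reml=True)
            full = smf.mixedlm(f_full, df, groups=df["subject_id"]).fit(reml=False)
            red = smf.mixedlm(f_red, df, groups=df["subject_id"]).fit(reml=False)
            lr = max(0.0, 2.0 * (full.llf - red.llf))
            p_int = float(stats.chi2.sf(lr, df_int))
            fe = pd.DataFrame(
                dict(
                    estimate=reml.fe_params,
                    se=reml.bse_fe,
                    p=reml.pvalues[reml.fe_params.index],
                )
            )
            converged = bool(reml.converged and full.converged and red.converged)
            method: Literal["mixedlm", "ols"] = "mixedlm"
            fit_obj = reml
            if not converged:
                logger.warning(
                    "fit_lmm(%s): mixed model did not converge", spec.outcome_name
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning(
                "fit_lmm(%s): mixed model failed (%s); falling back to OLS "
                "fixed effects",
                spec.outcome_name,
                exc,
            )
            ols_full = smf.ols(f_full, df).fit()
            ols_red = smf.ols(f_red, df).fit()
            lr = float(ols_red.ssr - ols_full.ssr)
            if ols_full.ssr <= 1e-12 and ols_red.ssr > 1e-12:
                p_int = 0.0  # saturated noiseless fit
            else:
                lr_stat = df.shape[0] * np.log(
                    max(ols_red.ssr, 1e-300) / max(ols_full.ssr, 1e-300)
                )
                p_int = float(stats.chi2.sf(lr_stat, df_int))
            fe = pd.DataFrame(
                dict(
                    estimate=ols_full.params,
                    se=ols_full.bse,
                    p=ols_full.pvalues,
                )
            )
            converged = False
            method = "ols"
            fit_obj = ols_full

    result = LMMResult(
        outcome_name=spec.outcome_name,
        fixed_effects=fe,
        p_interaction=p_int,
        lr_stat=float(lr),
        df_interaction=df_int,
        converged=converged,
        method=method,
        alpha=spec.alpha,
        time_levels=tuple(spec.time_levels),
        _fit=fit_obj,
    )
    if result.p_interaction < spec.alpha:
        observed_levels = [
            t for t in spec.time_levels if t in set(df["time"].astype(str))
        ]
        for tp in observed_levels:
            try:
                result.posthoc[tp] = _arm_contrast_at(result, tp)
            except Exception as exc:  # noqa: BLE001 - keep other contrasts
                logger.warning("posthoc contrast at %s failed: %s", tp, exc)
    return result


def _arm_contrast_at(result: LMMResult, timepoint: str) -> tuple[float, float]:
    """Between-arm (2FL − placebo) difference at one visit from the fit."""
    fit = result._fit
    names = list(result.fixed_effects.index)
    vec = np.zeros(len(names))
    arm_term = next((n for n in names if n.startswith("arm[") and ":" not in n), None)
    if arm_term is None:
        raise ContractError("no arm main-effect term in the fitted model")
    vec[names.index(arm_term)] = 1.0
    inter = f"{arm_term}:time[T.{timepoint}]"
    if inter in names:
        vec[names.index(inter)] = 1.0
    if result.method == "mixedlm":
        # Wald z-contrast on the fixed-effect block (t_test on MixedLM
        # results mishandles the appended variance parameters)
        beta = fit.fe_params.to_numpy()
        cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
        est = float(vec @ beta)
        se = float(np.sqrt(vec @ cov @ vec))
        z = est / se if se > 0 else np.inf
        return est, float(2.0 * stats.norm.sf(abs(z)))
    tt = fit.t_test(vec)
    return float(np.squeeze(tt.effect)), float(np.squeeze(tt.pvalue))


def posthoc_contrast(result: LMMResult, timepoint: str | Timepoint) -> tuple[float, float]:
    """Between-arm difference (estimate, p) at one visit.

    Only meaningful after a significant treatment-by-time interaction;
    calling it otherwise is a contract violation.
    """
    if result.p_interaction >= result.alpha:
        raise ContractError(
            f"posthoc_contrast requires p_interaction < {result.alpha} "
            f"(got {result.p_interaction:.3f})"
        )
    tp = timepoint.name if isinstance(timepoint, Timepoint) else str(timepoint).upper()
    if tp in result.posthoc:
        return result.posthoc[tp]
    return _arm_contrast_at(result, tp)


# ---------------------------------------------------------------------------
# nonparametric tests


def paired_wilcoxon(
    before: Sequence[float], after: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Pairs with missing values are dropped listwise, zero differences are
    discarded before ranking.  Exact p for n ≤ 25 informative pairs
    without tied absolute differences; otherwise normal approximation
    with continuity correction.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValidationError("before/after must be paired (same length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 5:
        raise InsufficientDataError(f"need >= 5 complete pairs, got {len(a)}")
    diff = a - b
    diff = diff[diff != 0]
    if len(diff) < 5:
        raise InsufficientDataError(
            f"only {len(diff)} informative (nonzero) pairs remain"
        )
    ties = len(np.unique(np.abs(diff))) < len(diff)
    method = "exact" if (len(diff) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        diff, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two independent groups.

    Exact p for small samples without ties; otherwise normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p.

    Pairs with a missing value in either variable are dropped listwise;
    at least 4 complete pairs are required.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("x and y must be paired")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# per-taxon screens


def taxa_screen(
    clr_filtered: CLRMatrix,
    meta: dict[str, SampleRecord],
    design: Literal["paired_vanco", "per_timepoint_arms", "lmm_8week", "lmm_2week"],
    timepoint: Timepoint | str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen every (prevalence-filtered, CLR-transformed) taxon.

    Designs
    -------
    paired_vanco
        Wilcoxon signed-rank, baseline (CID1) vs post-antibiotic (CID2),
        paired within subject.
    per_timepoint_arms
        Mann-Whitney U between arms at the given ``timepoint``.
    lmm_8week / lmm_2week
        Treatment-by-time mixed model over the full supplementation
        period (CID2..CID3) or its first two weeks (CID2, SUV1); the
        p-value is the interaction LRT.

    Returns a DataFrame (taxon_id, statistic, p, q, direction) with BH
    adjustment across all taxa of the screen.
    """
    long = _clr_long(clr_filtered, meta)
    rows = []
    for taxon, sub in long.groupby("taxon_id", sort=False):
        if design == "paired_vanco":
            wide = sub.pivot_table(
                index="subject_id", columns="time", values="value", aggfunc="first"
            )
            if "CID1" not in wide or "CID2" not in wide:
                raise DesignError("paired_vanco needs CID1 and CID2 samples")
            pairs = wide[["CID1", "CID2"]].dropna()
            statistic, p = paired_wilcoxon(pairs["CID1"], pairs["CID2"])
            direction = float(np.sign((pairs["CID2"] - pairs["CID1"]).median()))
        elif design == "per_timepoint_arms":
            if timepoint is None:
                raise DesignError("per_timepoint_arms requires a timepoint")
            tp = (
                timepoint.name
                if isinstance(timepoint, Timepoint)
                else Timepoint.parse(timepoint).name
            )
            at = sub[sub["time"] == tp]
            a = at.loc[at["arm"] == Arm.FL2.value, "value"]
            b = at.loc[at["arm"] == Arm.PLACEBO.value, "value"]
            statistic, p = mann_whitney(a, b)
            direction = float(np.sign(a.median() - b.median()))
        elif design in ("lmm_8week", "lmm_2week"):
            levels = ("CID2", "SUV1") if design == "lmm_2week" else _SUPP_LEVELS
            spec = LMMSpec(outcome_name=taxon, time_levels=levels, alpha=alpha)
            res = fit_lmm(
                sub.rename(columns={"time": "timepoint"}), spec
            )
            statistic, p = res.lr_stat, res.p_interaction
            direction = float("nan")
        else:
            raise DesignError(f"unknown design {design!r}")
        rows.append(dict(taxon_id=taxon, statistic=statistic, p=p, direction=direction))
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["taxon_id", "statistic", "p", "q", "direction"]]


def _clr_long(clr: CLRMatrix, meta: dict[str, SampleRecord]) -> pd.DataFrame:
    records = []
    for sid in clr.sample_ids:
        rec = meta.get(sid)
        if rec is None:
            continue
        records.append((sid, rec.subject_id, rec.arm.value, rec.timepoint.name))
    info = pd.DataFrame(
        records, columns=["sample_id", "subject_id", "arm", "time"]
    ).set_index("sample_id")
    stacked = (
        clr.values.loc[info.index]
        .stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_0": "sample_id", "level_1": "taxon_id"})
    )
    stacked.columns = ["sample_id", "taxon_id", "value"]
    return stacked.join(info, on="sample_id")
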