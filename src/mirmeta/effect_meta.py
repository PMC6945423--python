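"""Standardized-mean-difference meta-analysis.

Per-study effects are Hedges' g (Cohen's d behind a flag): the two-arm mean
difference divided by the pooled SD, with the small-sample bias factor
J = 1 - 3/(4m - 1), m = n1 + n2 - 2, and sampling variance
J^2 * [(1/n1 + 1/n2) + d^2 / (2(n1 + n2))].

Pooling is inverse-variance, either with common-effect weights 1/v_i
(``fixed``) or with DerSimonian-Laird moment weights 1/(v_i + tau^2)
(``random_dl``), where

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),   w = 1/v.

Heterogeneity is summarized by Cochran's Q (chi-square with k-1 df) and
Higgins' I^2 = max(0, 100 (Q - df)/Q). Supporting diagnostics: subgroup
pooling, leave-one-out re-pooling, and Egger's precision-form regression
for small-study (publication-bias) asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .study_io import StudySummary

Z975 = 1.959963984540054  # two-sided 95% normal quantile


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSize:
    """A standardized mean difference with its sampling variance."""

    study_id: str
    g: float
    var_g: float
    subgroup: str = ""

    @property
    def se_g(self) -> float:
        return math.sqrt(self.var_g)


@dataclass
class MetaResult:
    pooled: float
    ci_low: float
    ci_high: float
    se: float
    q: float
    df: int
    p_q: float
    tau2: float
    i2: float
    model: str
    study_ids: list[str] = field(default_factory=list)
    effects: list[float] = field(default_factory=list)
    variances: list[float] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)  # normalized, sum to 1

    @property
    def k(self) -> int:
        return len(self.study_ids)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "k": self.k, "pooled": self.pooled,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "se": self.se,
            "q": self.q, "df": self.df, "p_q": self.p_q,
            "tau2": self.tau2, "i2": self.i2,
            "study_ids": self.study_ids, "effects": self.effects,
            "variances": self.variances, "weights": self.weights,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"row": sid, "effect": g, "variance": v, "weight": w,
             "ci_low": g - Z975 * math.sqrt(v), "ci_high": g + Z975 * math.sqrt(v)}
            for sid, g, v, w in zip(self.study_ids, self.effects,
                                    self.variances, self.weights)
        ]
        rows.append({"row": f"pooled[{self.model}]", "effect": self.pooled,
                     "variance": self.se**2, "weight": 1.0,
                     "ci_low": self.ci_low, "ci_high": self.ci_high})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BiasResult:
    intercept: float
    se_intercept: float
    p_value: float
    slope: float
    funnel_points: tuple[tuple[float, float], ...]  # (effect, se) pairs


def _standardized_difference(s: StudySummary) -> tuple[float, float]:
    if s.n_case < 2 or s.n_control < 2:
        raise InsufficientDataError(
            f"{s.key}: effect size needs n >= 2 in both arms")
    m = s.n_case + s.n_control - 2
    sp2 = ((s.n_case - 1) * s.sd_case**2 + (s.n_control - 1) * s.sd_control**2) / m
    if sp2 <= 0:
        raise ValueError(f"{s.key}: degenerate study, pooled SD is zero")
    d = (s.mean_case - s.mean_control) / math.sqrt(sp2)
    return d, m


def hedges_g(s: StudySummary, *, correction: bool = True) -> EffectSize:
    """Standardized mean difference for one study; case minus control.

    With ``correction`` (default) applies Hedges' J small-sample factor;
    without it this is Cohen's d with variance (1/n1 + 1/n2) + d^2/(2N).
    """
    d, m = _standardized_difference(s)
    n1, n2 = s.n_case, s.n_control
    base_var = (1 / n1 + 1 / n2) + d**2 / (2 * (n1 + n2))
    if correction:
        j = 1 - 3 / (4 * m - 1)
        return EffectSize(study_id=s.key, g=j * d, var_g=j * j * base_var,
                          subgroup=s.specimen)
    return EffectSize(study_id=s.key, g=d, var_g=base_var, subgroup=s.specimen)


def cohen_d(s: StudySummary) -> EffectSize:
    return hedges_g(s, correction=False)


def effects_from_studies(studies: Iterable[StudySummary], *,
                         correction: bool = True) -> list[EffectSize]:
    return [hedges_g(s, correction=correction) for s in studies]


def pool(effects: Sequence[EffectSize], model: str = "random_dl") -> MetaResult:
    """Inverse-variance pooling of effect sizes.

    ``fixed`` uses weights 1/v_i; ``random_dl`` estimates tau^2 by the
    DerSimonian-Laird moment formula and uses weights 1/(v_i + tau^2).
    The 95% CI is the normal approximation pooled +- 1.96 SE. Q, tau^2 and
    I^2 are always computed from the fixed-effect weights, so they agree
    between the two models on the same data.
    """
    if model not in {"fixed", "random_dl"}:
        raise ValueError(f"unknown model {model!r}")
    if len(effects) == 0:
        raise InsufficientDataError("cannot pool an empty collection")
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("effect variances must be strictly positive")

    w = 1.0 / v
    mu_fixed = float(np.sum(w * g) / np.sum(w))
    df = len(g) - 1
    q = float(np.sum(w * (g - mu_fixed) ** 2))
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    if df > 0:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / denom)
    else:
        tau2 = 0.0

    if model == "fixed":
        wm = w
        mu = mu_fixed
    else:
        wm = 1.0 / (v + tau2)
        mu = float(np.sum(wm * g) / np.sum(wm))
    se = float(math.sqrt(1.0 / np.sum(wm)))
    return MetaResult(
        pooled=mu, ci_low=mu - Z975 * se, ci_high=mu + Z975 * se, se=se,
        q=q, df=df, p_q=p_q, tau2=tau2, i2=i2, model=model,
        study_ids=[e.study_id for e in effects],
        effects=g.tolist(), variances=v.tolist(),
        weights=(wm / np.sum(wm)).tolist(),
    )


def subgroup_pool(effects: Sequence[EffectSize], *,
                  model: str = "random_dl") -> dict[str, MetaResult]:
    """Pool independently within each effect's subgroup label.

    Labels with a single study come back as the degenerate k = 1 result.
    """
    labels = [e.subgroup for e in effects]
    if any(lab == "" for lab in labels):
        raise ValueError("every effect must carry a subgroup label")
    out: dict[str, MetaResult] = {}
    for lab in dict.fromkeys(labels):  # first-seen order
        out[lab] = pool([e for e in effects if e.subgroup == lab], model=model)
    return out


def leave_one_out(effects: Sequence[EffectSize], *,
                  model: str = "random_dl") -> list[tuple[str, MetaResult]]:
    """Re-pool k times, omitting one study each time (tau^2 refitted)."""
    if len(effects) < 2:
        raise InsufficientDataError("leave-one-out needs k >= 2")
    out = []
    for i, e in enumerate(effects):
        rest = [x for j, x in enumerate(effects) if j != i]
        out.append((e.study_id, pool(rest, model=model)))
    return out


def egger_test(effects: Sequence[EffectSize]) -> BiasResult:
    """Egger's precision-form regression test for funnel asymmetry.

    Regresses the standardized effect g_i/se_i on the precision 1/se_i;
    the intercept estimates small-study asymmetry and is tested two-sided
    against t with k - 2 df.
    """
    if len(effects) < 3:
        raise InsufficientDataError("Egger regression needs k >= 3")
    se = np.array([e.se_g for e in effects])
    g = np.array([e.g for e in effects])
    if np.ptp(se) < 1e-12:
        raise ValueError("degenerate design: all studies have identical SEs")
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(g / se, x).fit()
    return BiasResult(
        intercept=float(fit.params[0]), se_intercept=float(fit.bse[0]),
        p_value=float(fit.pvalues[0]), slope=float(fit.params[1]),
        funnel_points=tuple(zip(g.tolist(), se.tolist())),
    )
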