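"""Diagnostic-test-accuracy synthesis: 2x2 metrics, SROC curves, AUC.

Each study contributes a 2x2 table (TP/FP/FN/TN) obtained by dichotomizing
continuous expression at some study-specific threshold (higher expression
calls cancer). Because thresholds differ across studies, paired
(sensitivity, specificity) points are summarized with a summary ROC curve
rather than a single pooled point alone. Two models are provided:

* ``bivariate`` (default): joint random-effects model on
  (logit sensitivity, logit specificity) with an unstructured between-study
  covariance, fitted by (restricted) maximum likelihood with the usual
  within-study normal approximation. The SROC is the conditional-mean line
  E[logit Se | logit Sp] traced over the false-positive-rate axis.
* ``moses``: Moses-Littenberg least squares of D = logit TPR - logit FPR on
  S = logit TPR + logit FPR, optionally weighted (inverse-variance or total
  sample size), with the curve back-transformed from the fitted line.

AUC is the trapezoid integral of the curve over FPR in (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .study_io import DiagnosticCounts

Z975 = 1.959963984540054
_FPR_GRID = np.linspace(1e-6, 1 - 1e-6, 1000)


class InsufficientDataError(ValueError):
    pass


class FitError(RuntimeError):
    """Likelihood maximization failed; diagnostics carried in the message."""


@dataclass(frozen=True)
class AccuracyMetrics:
    study_id: str
    sens: float
    spec: float
    lr_pos: float
    lr_neg: float
    dor: float
    corrected: bool


@dataclass
class SrocResult:
    pooled_sens: float
    pooled_sens_ci: tuple[float, float]
    pooled_spec: float
    pooled_spec_ci: tuple[float, float]
    auc: float
    model: str
    curve: np.ndarray  # (n, 2) array of (fpr, sensitivity)
    study_ids: list[str] = field(default_factory=list)
    per_study: list[AccuracyMetrics] = field(default_factory=list)
    bivariate_params: dict | None = None  # mu, sigma, rho on the logit scale

    @property
    def k(self) -> int:
        return len(self.study_ids)

    def to_dict(self) -> dict:
        d = {
            "model": self.model, "k": self.k, "auc": self.auc,
            "pooled_sens": self.pooled_sens,
            "pooled_sens_ci": list(self.pooled_sens_ci),
            "pooled_spec": self.pooled_spec,
            "pooled_spec_ci": list(self.pooled_spec_ci),
            "study_ids": self.study_ids,
            "per_study": [vars(m) | {} for m in self.per_study],
        }
        if self.bivariate_params is not None:
            d["bivariate_params"] = self.bivariate_params
        return d

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"row": m.study_id, "sens": m.sens, "spec": m.spec,
             "lr_pos": m.lr_pos, "lr_neg": m.lr_neg, "dor": m.dor}
            for m in self.per_study
        ]
        rows.append({"row": f"summary[{self.model}]",
                     "sens": self.pooled_sens, "spec": self.pooled_spec,
                     "lr_pos": self.pooled_sens / (1 - self.pooled_spec),
                     "lr_neg": (1 - self.pooled_sens) / self.pooled_spec,
                     "dor": (self.pooled_sens / (1 - self.pooled_sens))
                            * (self.pooled_spec / (1 - self.pooled_spec))})
        return pd.DataFrame(rows)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["fpr", "sensitivity"])


def _corrected_cells(c: DiagnosticCounts, correction: str
                     ) -> tuple[float, float, float, float, bool]:
    tp, fp, fn, tn = float(c.tp), float(c.fp), float(c.fn), float(c.tn)
    has_zero = 0.0 in (tp, fp, fn, tn)
    apply = (correction == "always") or (correction == "zero" and has_zero)
    if apply:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    return tp, fp, fn, tn, apply


def accuracy_from_counts(c: DiagnosticCounts, *,
                         correction: str = "zero") -> AccuracyMetrics:
    """Sensitivity, specificity, likelihood ratios and DOR for one 2x2 table.

    ``correction``: ``"zero"`` adds 0.5 to all four cells only when the
    table has a zero cell (default), ``"always"`` adds it unconditionally,
    ``"none"`` never does (zero cells then give infinite ratios).
    """
    if correction not in {"zero", "always", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    if c.tp + c.fp + c.fn + c.tn == 0:
        raise ValueError("all-zero 2x2 table")
    tp, fp, fn, tn, applied = _corrected_cells(c, correction)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = sens / (1 - spec) if spec < 1 else math.inf
    lr_neg = (1 - sens) / spec
    dor = lr_pos / lr_neg if lr_neg > 0 else math.inf
    return AccuracyMetrics(study_id=c.study_id, sens=sens, spec=spec,
                           lr_pos=lr_pos, lr_neg=lr_neg, dor=dor,
                           corrected=applied)


def _logit_data(counts: Sequence[DiagnosticCounts], correction: str):
    """Per-study (logit Se, logit Sp) with within-study variances."""
    y, c2 = [], []
    for c in counts:
        tp, fp, fn, tn, _ = _corrected_cells(c, correction)
        if min(tp, fp, fn, tn) <= 0:
            raise ValueError(
                f"{c.study_id}: zero cell without continuity correction")
        y.append((math.log(tp / fn), math.log(tn / fp)))
        c2.append((1 / tp + 1 / fn, 1 / tn + 1 / fp))
    return np.asarray(y), np.asarray(c2)


def _fit_bivariate(y: np.ndarray, cvar: np.ndarray, reml: bool):
    """Maximize the (RE)ML of y_i ~ N(mu, Sigma + C_i), C_i diagonal known."""
    k = len(y)

    def unpack(p):
        mu = p[:2]
        s1, s2 = np.exp(p[2]), np.exp(p[3])
        rho = np.tanh(p[4])
        sigma = np.array([[s1 * s1, rho * s1 * s2],
                          [rho * s1 * s2, s2 * s2]])
        return mu, sigma

    def nll(p):
        mu, sigma = unpack(p)
        tot = 0.0
        wsum = np.zeros((2, 2))
        for i in range(k):
            v = sigma + np.diag(cvar[i])
            vinv = np.linalg.inv(v)
            r = y[i] - mu
            tot += 0.5 * (math.log(np.linalg.det(v)) + r @ vinv @ r)
            wsum += vinv
        if reml:
            tot += 0.5 * math.log(np.linalg.det(wsum))
        return tot

    starts = [
        [y[:, 0].mean(), y[:, 1].mean(), 0.0, 0.0, 0.0],
        [y[:, 0].mean(), y[:, 1].mean(), math.log(max(y[:, 0].std(), .1)),
         math.log(max(y[:, 1].std(), .1)), -0.3],
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 20000, "maxfev": 20000,
                                         "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        raise FitError(f"bivariate likelihood maximization failed: {best.message}")
    mu, sigma = unpack(best.x)
    # conditional-on-Sigma GLS covariance of mu
    wsum = np.zeros((2, 2))
    for i in range(k):
        wsum += np.linalg.inv(sigma + np.diag(cvar[i]))
    return mu, sigma, np.linalg.inv(wsum)


def _auc_from_curve(fpr: np.ndarray, se: np.ndarray) -> float:
    se = np.clip(se, 0.0, 1.0)
    return float(np.trapezoid(se, fpr))


def pool_accuracy(counts: Sequence[DiagnosticCounts], *,
                  model: str = "bivariate",
                  correction: str = "zero",
                  reml: bool = True,
                  moses_weighting: str = "none") -> SrocResult:
    """Fit a summary ROC model to a collection of 2x2 tables.

    ``moses_weighting`` applies to the ``moses`` model only: ``"none"``
    (ordinary least squares), ``"invvar"`` (weights 1/var(D_i)), or
    ``"size"`` (weights = total study size).
    """
    if model not in {"bivariate", "moses"}:
        raise ValueError(f"unknown model {model!r}")
    kmin = 3 if model == "bivariate" else 2
    if len(counts) < kmin:
        raise InsufficientDataError(f"{model} model needs k >= {kmin}")
    per_study = [accuracy_from_counts(c, correction=correction) for c in counts]
    y, cvar = _logit_data(counts, correction)
    fpr = _FPR_GRID
    lf = logit(fpr)

    if model == "bivariate":
        mu, sigma, mu_cov = _fit_bivariate(y, cvar, reml)
        # E[logit Se | logit Sp = v] traced along the FPR axis (v = -logit fpr)
        slope = sigma[0, 1] / sigma[1, 1]
        se_curve = expit(mu[0] + slope * (-lf - mu[1]))
        auc = _auc_from_curve(fpr, se_curve)
        sens_ci = expit(mu[0] + Z975 * math.sqrt(mu_cov[0, 0]) * np.array([-1, 1]))
        spec_ci = expit(mu[1] + Z975 * math.sqrt(mu_cov[1, 1]) * np.array([-1, 1]))
        params = {
            "mu_logit_sens": float(mu[0]), "mu_logit_spec": float(mu[1]),
            "sigma_logit_sens": float(math.sqrt(sigma[0, 0])),
            "sigma_logit_spec": float(math.sqrt(sigma[1, 1])),
            "rho": float(sigma[0, 1] / math.sqrt(sigma[0, 0] * sigma[1, 1])),
            "reml": reml,
        }
        return SrocResult(
            pooled_sens=float(expit(mu[0])), pooled_sens_ci=tuple(sens_ci),
            pooled_spec=float(expit(mu[1])), pooled_spec_ci=tuple(spec_ci),
            auc=auc, model="bivariate",
            curve=np.column_stack([fpr, se_curve]),
            study_ids=[c.study_id for c in counts], per_study=per_study,
            bivariate_params=params)

    # Moses-Littenberg: D = a + b S on the (S, D) plane
    if moses_weighting not in {"none", "invvar", "size"}:
        raise ValueError(f"unknown moses_weighting {moses_weighting!r}")
    u, v = y[:, 0], y[:, 1]
    d_stat = u + v          # logit TPR - logit FPR = ln DOR
    s_stat = u - v          # logit TPR + logit FPR (threshold proxy)
    if moses_weighting == "invvar":
        w = 1.0 / (cvar[:, 0] + cvar[:, 1])
    elif moses_weighting == "size":
        w = np.array([c.tp + c.fp + c.fn + c.tn for c in counts], dtype=float)
    else:
        w = np.ones_like(d_stat)
    x = np.column_stack([np.ones_like(s_stat), s_stat])
    wsq = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * wsq[:, None], d_stat * wsq, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    if abs(1 - b) < 1e-9:
        raise FitError("Moses fit degenerate: slope b -> 1")
    se_curve = expit((a + (1 + b) * lf) / (1 - b))
    auc = _auc_from_curve(fpr, se_curve)
    # summary operating point: simple inverse-variance pooled logits
    wu, wv = 1 / cvar[:, 0], 1 / cvar[:, 1]
    mu_u = float(np.sum(wu * u) / np.sum(wu))
    mu_v = float(np.sum(wv * v) / np.sum(wv))
    se_u = math.sqrt(1 / np.sum(wu))
    se_v = math.sqrt(1 / np.sum(wv))
    return SrocResult(
        pooled_sens=float(expit(mu_u)),
        pooled_sens_ci=tuple(expit(mu_u + Z975 * se_u * np.array([-1, 1]))),
        pooled_spec=float(expit(mu_v)),
        pooled_spec_ci=tuple(expit(mu_v + Z975 * se_v * np.array([-1, 1]))),
        auc=auc, model="moses", curve=np.column_stack([fpr, se_curve]),
        study_ids=[c.study_id for c in counts], per_study=per_study,
        bivariate_params=None)


def dichotomize_youden(case_values: Sequence[float],
                       control_values: Sequence[float], *,
                       study_id: str = "", specimen: str = "tissue"
                       ) -> DiagnosticCounts:
    """Dichotomize continuous values at the cutoff maximizing Youden's J.

    Higher values call cancer. Every midpoint between adjacent distinct
    sorted observations is evaluated (plus sentinels beyond the extremes);
    ties in J = sens + spec - 1 break toward higher specificity, then
    toward the higher cutoff.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both arms must be non-empty")
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2 if pooled.size > 1 else np.array([])
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    best = None
    for cut in candidates:
        tp = int(np.sum(cases > cut))
        fn = cases.size - tp
        fp = int(np.sum(controls > cut))
        tn = controls.size - fp
        j = tp / cases.size + tn / controls.size - 1.0
        spec = tn / controls.size
        key = (j, spec, cut)
        if best is None or key > best[0]:
            best = (key, (tp, fp, fn, tn, cut))
    tp, fp, fn, tn, cut = best[1]
    return DiagnosticCounts(study_id=study_id, specimen=specimen,
                            tp=tp, fp=fp, fn=fn, tn=tn, cutoff=float(cut))


def empirical_auc(case_values: Sequence[float],
                  control_values: Sequence[float]) -> float:
    """Empirical ROC AUC: P(case > control) + 0.5 P(tie) (Mann-Whitney)."""
    cases = np.asarray(case_values, float)[:, None]
    controls = np.asarray(control_values, float)[None, :]
    wins = np.sum(cases > controls) + 0.5 * np.sum(cases == controls)
    return float(wins / (cases.size * controls.size))
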