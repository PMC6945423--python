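"""Synthetic study-set generator with the meta-analytic structure assumed
by the pooling model.

Data-generating model per study i:

    theta_i ~ Normal(delta + shift_i, tau^2)        true standardized effect
    control values ~ Normal(loc_p, scale_p^2)        platform p baseline
    case values    ~ Normal(loc_p + theta_i * scale_p, scale_p^2)

``shift_i`` is an additive modification of the effect for serum studies
(tissue markers typically separate more strongly than circulating ones).
Platform profiles emulate the disparate reporting scales of qPCR
(2^-dCq), sequencing (log2 expression) and chips (intensity): the location
and scale change, the standardized effect does not. Summaries emitted are
the exact sample moments of the emitted values, so summary-statistic
methods can be validated against full-data methods bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .study_io import StudySet, StudySummary
from .targets_filter import PLATFORMS, PredictionMatrix

DEFAULT_PLATFORM_PROFILES = {
    "qpcr": (28.0, 5.0),      # 2^-dCq-scale relative expression
    "seq": (14.0, 1.0),       # log2 expression
    "chip": (8.0, 1.2),       # chip intensity
}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Conditions of the simulated multi-study comparison.

    Defaults mirror the structure of the real corpus this package
    analyses: a strong tissue effect around delta = 0.8 standardized
    units, moderate between-study heterogeneity, arm sizes from a handful
    to ~100, 40% serum studies whose effect is attenuated.
    """

    k_studies: int = 25
    delta: float = 0.8
    tau: float = 0.2
    n_case_range: tuple[int, int] = (5, 100)
    n_control_range: tuple[int, int] = (5, 100)
    platform_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORM_PROFILES))
    specimen_mix: float = 0.4
    specimen_effect_shift: float = -0.6
    seed: int = 0

    def validate(self) -> None:
        if self.k_studies < 1:
            raise ConfigError("k_studies must be >= 1")
        if self.tau < 0:
            raise ConfigError("tau must be >= 0")
        if not 0 <= self.specimen_mix <= 1:
            raise ConfigError("specimen_mix must lie in [0, 1]")
        for lo, hi in (self.n_case_range, self.n_control_range):
            if lo < 2 or hi < lo:
                raise ConfigError("arm-size ranges must satisfy 2 <= lo <= hi")
        if not self.platform_profiles:
            raise ConfigError("at least one platform profile is required")
        for name, (loc, scale) in self.platform_profiles.items():
            if scale <= 0:
                raise ConfigError(f"platform {name}: scale must be > 0")


def simulate_studies(cfg: SimulationConfig
                     ) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], StudySet]:
    """Draw per-study sample-level values and their exact summaries.

    Returns ``(samples, study_set)`` where ``samples[key]`` is the
    (case_values, control_values) pair and the StudySet holds each study's
    realized n/mean/SD (ddof=1 SDs, matching the summary-table convention).
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    platforms = sorted(cfg.platform_profiles)
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    studies = []
    for i in range(cfg.k_studies):
        key = f"SIM{i:03d}"
        specimen = "serum" if rng.random() < cfg.specimen_mix else "tissue"
        shift = cfg.specimen_effect_shift if specimen == "serum" else 0.0
        theta = rng.normal(cfg.delta + shift, cfg.tau)
        platform = platforms[rng.integers(len(platforms))]
        loc, scale = cfg.platform_profiles[platform]
        n1 = int(rng.integers(cfg.n_case_range[0], cfg.n_case_range[1] + 1))
        n2 = int(rng.integers(cfg.n_control_range[0], cfg.n_control_range[1] + 1))
        case = rng.normal(loc + theta * scale, scale, size=n1)
        control = rng.normal(loc, scale, size=n2)
        samples[key] = (case, control)
        studies.append(StudySummary(
            study_id=key, subset_label="", disease_subset="NSCLC",
            specimen=specimen,
            n_case=n1, mean_case=float(case.mean()),
            sd_case=float(case.std(ddof=1)),
            n_control=n2, mean_control=float(control.mean()),
            sd_control=float(control.std(ddof=1)),
            scale_note=f"simulated {platform} scale",
        ))
    return samples, StudySet(studies=studies, provenance="simulation")


def simulate_prediction_matrix(n_genes: int,
                               vote_prob: float | list[float] = 0.5,
                               seed: int = 0) -> PredictionMatrix:
    """Independent Bernoulli platform votes for ``n_genes`` synthetic genes."""
    probs = np.broadcast_to(np.asarray(vote_prob, dtype=float), (12,))
    if np.any((probs < 0) | (probs > 1)):
        raise ConfigError("vote probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    votes = (rng.random((n_genes, 12)) < probs).astype(int)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    return PredictionMatrix(genes=genes, platforms=PLATFORMS, votes=votes)
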