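"""Seeded generator of MRMC ordinal rating panels and dose cohorts.

The real study rated 50 patients under 3 tomosynthesis protocols; that
rating deposit is access-restricted, so this module generates panels with
the same structure and *known* ground truth from a latent-variable model:

    q(case, protocol, criterion) = delta_protocol + gamma_case + eps

with ``gamma_case ~ N(0, case_sd^2)`` shared by all protocols of a case
(this induces the within-patient pairing the bootstrap exploits) and
``eps ~ N(0, noise_sd^2)`` independent per (case, protocol, criterion).
Each observer perceives ``q`` plus independent N(0, noise_sd^2) reading
noise and discretises it through observer-specific strictly increasing
thresholds — equally spaced base thresholds jittered per observer, so
observers differ only in how they use the rating scale, not in the latent
quality they perceive.

Under this model the probability that one latent draw of a shifted arm
exceeds one of the reference arm is the closed form
``Phi(delta / (sigma * sqrt(2)))`` with per-arm SD
``sigma = sqrt(case_sd^2 + 2 * noise_sd^2)``, which serves as the ground
truth for parameter-recovery and coverage checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dose import DoseRecord, effective_dose
from .ratings import RatingPanel

__all__ = ["SyntheticConfig", "generate_panel", "true_auc", "generate_dose_cohort"]

#: Latent shifts emulating the study's three protocols: the vendor-default
#: reference and two dose-reduced protocols rated slightly worse.
DEFAULT_PROTOCOL_SHIFTS = {"standard": 0.0, "reduced30": -0.05, "reduced50": -0.13}


@dataclass(frozen=True)
class SyntheticConfig:
    """Latent-model parameters for panel generation.

    Defaults reproduce the study's design: 4 observers x 50 cases x
    3 protocols x 14 criteria on a 5-category scale, with a unit case
    effect and 0.5-SD rating noise so that null bootstrap intervals at this
    size are visibly asymmetric.
    """

    n_observers: int = 4
    n_cases: int = 50
    n_criteria: int = 14
    n_categories: int = 5
    protocol_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTOCOL_SHIFTS)
    )
    case_sd: float = 1.0
    noise_sd: float = 0.5
    observer_threshold_jitter: float = 0.3
    threshold_span: float = 1.2  # outermost base thresholds at +/- span * sigma
    seed: int = 0

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("need at least 2 rating categories")
        if min(self.n_observers, self.n_cases, self.n_criteria) < 1:
            raise ValueError("panel dimensions must be positive")
        if self.case_sd < 0 or self.observer_threshold_jitter < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.protocol_shifts:
            raise ValueError("at least one protocol required")
        if 0.0 not in self.protocol_shifts.values():
            raise ValueError("one protocol must be the reference with shift 0")

    @property
    def latent_sigma(self) -> float:
        """Per-arm SD of the latent quality an observer perceives."""
        return float(np.sqrt(self.case_sd**2 + 2.0 * self.noise_sd**2))


def true_auc(delta: float, sigma: float) -> float:
    """Closed-form latent AUC: P(shifted-arm draw > reference-arm draw).

    ``sigma`` is the per-arm latent SD; the difference of two independent
    draws has SD ``sigma * sqrt(2)``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(stats.norm.cdf(delta / (sigma * np.sqrt(2.0))))


def _observer_thresholds(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing rating thresholds, one row per observer.

    Base thresholds are equally spaced, symmetric, with the outer pair at
    +/- ``threshold_span`` latent SDs.  Observer jitter is mostly a shared
    shift of the whole threshold set (differences in overall leniency) plus
    a small independent perturbation of each threshold (differences in
    category widths, SD = jitter / 4).
    """
    k = config.n_categories
    base = np.linspace(-config.threshold_span, config.threshold_span, k - 1)
    base = base * config.latent_sigma
    jit = config.observer_threshold_jitter
    shift = rng.normal(0.0, jit, size=(config.n_observers, 1))
    spacing = rng.normal(0.0, jit / 4.0, size=(config.n_observers, k - 1))
    thr = np.sort(base[None, :] + shift + spacing, axis=1)
    # enforce strict monotonicity if the jitter produced exact ties
    tiny = 1e-9 * np.arange(k - 1)
    return thr + tiny[None, :]


def generate_panel(config: SyntheticConfig) -> RatingPanel:
    """Generate a complete MRMC rating panel from the latent model.

    Deterministic given ``config.seed``; the returned panel always passes
    :class:`~vgckit.ratings.RatingPanel` validation.
    """
    rng = np.random.default_rng(config.seed)
    protocols = list(config.protocol_shifts)
    shifts = np.array([config.protocol_shifts[p] for p in protocols])
    n_o, n_c, n_p, n_q = (
        config.n_observers,
        config.n_cases,
        len(protocols),
        config.n_criteria,
    )

    gamma = rng.normal(0.0, config.case_sd, size=n_c)
    eps = rng.normal(0.0, config.noise_sd, size=(n_c, n_p, n_q))
    q = shifts[None, :, None] + gamma[:, None, None] + eps

    thresholds = _observer_thresholds(config, rng)
    reading = rng.normal(0.0, config.noise_sd, size=(n_o, n_c, n_p, n_q))
    perceived = q[None, :, :, :] + reading
    # rating = 1 + number of thresholds at or below the perceived quality
    ratings = (
        perceived[..., None] >= thresholds[:, None, None, None, :]
    ).sum(axis=-1) + 1

    width = len(str(max(n_o, n_c, n_q)))
    observers = [f"obs{i + 1:0{width}d}" for i in range(n_o)]
    cases = [f"case{i + 1:0{width}d}" for i in range(n_c)]
    criteria = [f"Q{i + 1}" for i in range(n_q)]

    oi, ci, pi, qi = np.meshgrid(
        np.arange(n_o), np.arange(n_c), np.arange(n_p), np.arange(n_q), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "observer": np.array(observers)[oi.ravel()],
            "case": np.array(cases)[ci.ravel()],
            "protocol": np.array(protocols)[pi.ravel()],
            "criterion": np.array(criteria)[qi.ravel()],
            "rating": ratings.ravel().astype(int),
        }
    )
    return RatingPanel(df, n_categories=config.n_categories)


#: Group-mean reference-ratio DAP (Gy·cm²) emulating the study cohort.
DEFAULT_GROUP_MEAN_DAP = {"under25": 2.53, "b25to30": 4.11, "over30": 4.78}

#: Nominal exposure fractions of the three dose-ratio protocols.
DEFAULT_RATIO_FACTORS = {10: 1.0, 7: 0.7, 5: 0.5}

_BMI_RANGES = {"under25": (20.0, 24.9), "b25to30": (25.0, 30.0), "over30": (30.1, 36.0)}


def generate_dose_cohort(
    n_per_group: int,
    group_mean_dap: dict[str, float] | None = None,
    ratio_factors: dict | None = None,
    seed: int = 0,
    dap_cv: float = 0.25,
) -> list[DoseRecord]:
    """Generate a dose cohort: one record per (patient, dose ratio).

    Per-patient reference DAP is drawn log-normally around its BMI group's
    mean (coefficient of variation ``dap_cv``); reduced-ratio DAPs scale the
    patient's reference DAP by ``ratio_factors``.  A factor may be a single
    number applied to every group or a per-group mapping
    ``{bmi_group: factor}``.  Deterministic given ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be positive")
    group_mean_dap = group_mean_dap or dict(DEFAULT_GROUP_MEAN_DAP)
    ratio_factors = ratio_factors or dict(DEFAULT_RATIO_FACTORS)
    if min(group_mean_dap.values()) <= 0:
        raise ValueError("group mean DAPs must be positive")

    def factor_for(ratio, group) -> float:
        f = ratio_factors[ratio]
        f = f[group] if isinstance(f, dict) else f
        if f <= 0:
            raise ValueError("ratio factors must be positive")
        return float(f)

    rng = np.random.default_rng(seed)
    records: list[DoseRecord] = []
    pid = 0
    for group, mean_dap in group_mean_dap.items():
        lo, hi = _BMI_RANGES[group]
        sigma = np.sqrt(np.log(1.0 + dap_cv**2))
        mu = np.log(mean_dap) - 0.5 * sigma**2
        base_dap = rng.lognormal(mu, sigma, size=n_per_group)
        bmis = rng.uniform(lo, hi, size=n_per_group)
        for i in range(n_per_group):
            pid += 1
            for ratio in sorted(ratio_factors, reverse=True):
                dap = float(base_dap[i] * factor_for(ratio, group))
                records.append(
                    DoseRecord(
                        patient_id=f"p{pid:04d}",
                        dap=dap,
                        dose_ratio=int(ratio),
                        bmi=float(bmis[i]),
                    )
                )
    return records
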