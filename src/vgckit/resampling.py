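"""Fixed-reader, paired-case bootstrap inference for AUC_VGC.

Observers are a fixed panel; the patient (case) is the sampling unit.  Each
bootstrap replicate redraws cases with replacement, and a drawn case carries
along all of its ratings — every observer, every criterion, and both
protocols — which preserves the pairing of the protocols within a patient.
Per replicate the per-observer AUCs are recomputed and averaged; the
percentile interval of the replicate distribution gives an asymmetric
confidence interval, and the two-sided p-value against the null
AUC_VGC = 0.5 is the doubled smaller tail fraction (replicates exactly at
0.5 count in both tails), capped at 1.

Internally each observer's ratings are reduced to per-case category counts,
so one replicate's AUC is a pair of (n_boot x n_cases) @ (n_cases x K)
matrix products followed by an O(K) cumulation — the whole replicate set is
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .ratings import RatingPanel
from .vgc import VGCResult, auc_from_counts, effect_size

__all__ = ["BootstrapConfig", "bootstrap_vgc", "compare_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for case-resampling inference.

    ``n_boot`` bootstrap replicates (default 10000), percentile interval at
    ``ci_level`` (default 0.95), seeded reproducibly; only the two-sided
    alternative is implemented.
    """

    n_boot: int = 10000
    ci_level: float = 0.95
    seed: int = 0
    alternative: str = "two_sided"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly between 0 and 1")
        if self.alternative != "two_sided":
            raise ValueError("only the two-sided alternative is implemented")


def _case_counts(panel: RatingPanel, protocol: str, criteria: list[str]) -> np.ndarray:
    """Array C[obs, case, category] of rating counts within ``criteria``."""
    df = panel.data
    sub = df[(df["protocol"] == protocol) & (df["criterion"].isin(criteria))]
    observers, cases = panel.observers, panel.cases
    obs_idx = {o: i for i, o in enumerate(observers)}
    case_idx = {c: i for i, c in enumerate(cases)}
    k = panel.n_categories
    counts = np.zeros((len(observers), len(cases), k), dtype=np.int64)
    oi = sub["observer"].map(obs_idx).to_numpy()
    ci = sub["case"].map(case_idx).to_numpy()
    ri = sub["rating"].to_numpy() - 1
    np.add.at(counts, (oi, ci, ri), 1)
    return counts


def _replicate_aucs(
    ct: np.ndarray, cr: np.ndarray, mult: np.ndarray
) -> np.ndarray:
    """Averaged-over-observers AUC for each bootstrap replicate.

    ``ct``/``cr``: per-observer per-case category counts, shape (O, C, K);
    ``mult``: case multiplicities per replicate, shape (B, C).
    """
    n_obs = ct.shape[0]
    aucs = np.zeros((mult.shape[0], n_obs))
    for o in range(n_obs):
        t = mult @ ct[o]  # (B, K)
        r = mult @ cr[o]
        below = np.concatenate(
            (np.zeros((r.shape[0], 1)), np.cumsum(r, axis=1)[:, :-1]), axis=1
        )
        n_t = t.sum(axis=1, dtype=float)
        n_r = r.sum(axis=1, dtype=float)
        aucs[:, o] = (t * (below + 0.5 * r)).sum(axis=1) / (n_t * n_r)
    return aucs.mean(axis=1)


def bootstrap_vgc(
    panel: RatingPanel,
    test: str,
    ref: str,
    criteria=None,
    config: BootstrapConfig | None = None,
    criterion_class: str = "all",
) -> VGCResult:
    """Bootstrap a test-vs-reference AUC_VGC for one criterion class.

    Cases are resampled with replacement; observers are fixed; the pairing
    of protocols within each drawn case is preserved.  Deterministic given
    ``config.seed``.
    """
    config = config or BootstrapConfig()
    if criteria is None:
        criteria = panel.criteria
    criteria = list(criteria)
    unknown = set(criteria) - set(panel.criteria)
    if unknown:
        raise KeyError(f"unknown criteria: {sorted(unknown)}")
    for p in (test, ref):
        if p not in panel.protocols:
            raise KeyError(f"unknown protocol {p!r}")
    n_cases = len(panel.cases)
    if n_cases < 2:
        raise ValueError("bootstrap needs at least 2 cases")

    ct = _case_counts(panel, test, criteria)
    cr = _case_counts(panel, ref, criteria)

    # point estimate: per-observer pooled AUC, averaged
    per_obs = {
        obs: auc_from_counts(ct[i].sum(axis=0), cr[i].sum(axis=0))
        for i, obs in enumerate(panel.observers)
    }
    point = float(np.mean(list(per_obs.values())))

    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n_cases, size=(config.n_boot, n_cases))
    offsets = np.arange(config.n_boot)[:, None] * n_cases
    mult = np.bincount(
        (idx + offsets).ravel(), minlength=config.n_boot * n_cases
    ).reshape(config.n_boot, n_cases)

    boot = _replicate_aucs(ct, cr, mult)

    alpha = 1.0 - config.ci_level
    ci_low, ci_high = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    p_low = float(np.mean(boot <= 0.5))
    p_high = float(np.mean(boot >= 0.5))
    p_value = min(1.0, 2.0 * min(p_low, p_high))

    ties = int(sum((ct[i].sum(axis=0) * cr[i].sum(axis=0)).sum() for i in range(ct.shape[0])))
    logger.info(
        "bootstrap %s vs %s [%s]: auc=%.4f ci=(%.4f, %.4f) p=%.4f "
        "n_boot=%d seed=%d tied_pairs=%d per_observer=%s",
        test, ref, criterion_class, point, ci_low, ci_high, p_value,
        config.n_boot, config.seed, ties,
        {o: round(a, 4) for o, a in per_obs.items()},
    )
    return VGCResult(
        reference_protocol=ref,
        test_protocol=test,
        criterion_class=criterion_class,
        auc=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        effect_size=effect_size(point),
        per_observer_auc=per_obs,
        n_boot=config.n_boot,
    )


def compare_all(
    panel: RatingPanel,
    ref: str,
    class_map: dict[str, str],
    config: BootstrapConfig | None = None,
) -> list[VGCResult]:
    """All (non-reference protocol x criterion class) comparisons.

    One :class:`~vgckit.vgc.VGCResult` per combination, ordered by test
    protocol then by the class order of first appearance in ``class_map``.
    No multiple-testing correction is applied.
    """
    config = config or BootstrapConfig()
    if ref not in panel.protocols:
        raise KeyError(f"unknown reference protocol {ref!r}")
    tests = [p for p in panel.protocols if p != ref]
    if not tests:
        raise ValueError("panel has no protocol other than the reference")
    unknown = set(class_map) - set(panel.criteria)
    if unknown:
        raise KeyError(f"class map names unknown criteria: {sorted(unknown)}")
    unmapped = set(panel.criteria) - set(class_map)
    if unmapped:
        raise KeyError(f"criteria missing from class map: {sorted(unmapped)}")

    classes: list[str] = []
    for cls in class_map.values():
        if cls not in classes:
            classes.append(cls)

    # one independent child seed per comparison, derived reproducibly
    ss = np.random.SeedSequence(config.seed)
    children = iter(ss.spawn(len(tests) * len(classes)))

    results = []
    for test in tests:
        for cls in classes:
            criteria = [c for c, v in class_map.items() if v == cls]
            child_seed = int(next(children).generate_state(1)[0] % (2**31))
            cfg = BootstrapConfig(
                n_boot=config.n_boot,
                ci_level=config.ci_level,
                seed=child_seed,
                alternative=config.alternative,
            )
            results.append(
                bootstrap_vgc(panel, test, ref, criteria, cfg, criterion_class=cls)
            )
    return results
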