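"""Monte-Carlo harnesses: type-I error control and planted-effect recovery.

These drive the full pipeline over replicated synthetic logs and are
used both by the test suite and by the reproduction script.  Replicate
seeds are spawned deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .synthetic_logs import PlantedEffect, default_seed_urls, lexicon_for, null_config

logger = logging.getLogger("stepscreen")

#: min_users for simulated logs (small cohorts; the production default of 50
#: reflects population-scale logs)
SIM_MIN_USERS = 10


def spawn_seeds(seed: int, n: int) -> list[int]:
    """``n`` deterministic child seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def _run(cfg, alpha: float = 0.05, baseline: str = "pre_leadup"):
    pipe = PipelineConfig(
        simulate=cfg,
        lexicon=lexicon_for(cfg),
        seed_urls=default_seed_urls(),
        alpha=alpha,
        min_users=SIM_MIN_USERS,
        baseline=baseline,
    )
    return run_pipeline(pipe)


def null_replicate(
    seed: int,
    n_symptoms: int = 20,
    n_target: int = 500,
    n_comparison: int = 5000,
    alpha: float = 0.05,
    baseline: str = "pre_leadup",
) -> bool:
    """True iff a no-effect simulation yields any significant pair."""
    cfg = null_config(
        n_symptoms, seed, n_target_users=n_target, n_comparison_users=n_comparison
    )
    report = _run(cfg, alpha=alpha, baseline=baseline)
    return bool(report.windows["significant"].any())


def type1_error_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_symptoms: int = 20,
    n_target: int = 500,
    n_comparison: int = 5000,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the screen under the null."""
    flags = []
    for i, s in enumerate(spawn_seeds(seed, n_replicates)):
        flags.append(
            null_replicate(
                s,
                n_symptoms=n_symptoms,
                n_target=n_target,
                n_comparison=n_comparison,
                alpha=alpha,
            )
        )
        if (i + 1) % 25 == 0:
            logger.info("type-I study: %d/%d replicates", i + 1, n_replicates)
    return {
        "n_replicates": n_replicates,
        "n_with_false_positive": int(sum(flags)),
        "family_wise_rate": float(sum(flags)) / n_replicates,
        "alpha": alpha,
    }


def planted_replicate(
    seed: int,
    windows: tuple[str, ...] = ("proximal",),
    multiplier: float = 8.0,
    n_symptoms: int = 20,
    n_target: int = 2000,
    n_comparison: int = 500,
    symptom_base_prob: float = 0.01,
    alpha: float = 0.05,
) -> dict:
    """Run one planted-effect replicate; report the planted symptom's fate."""
    cfg = null_config(
        n_symptoms,
        seed,
        n_target_users=n_target,
        n_comparison_users=n_comparison,
        symptom_base_prob=symptom_base_prob,
    )
    planted = cfg.symptoms[0]
    cfg = dataclasses.replace(
        cfg,
        planted_effects=tuple(PlantedEffect(planted, w, multiplier) for w in windows),
    )
    report = _run(cfg, alpha=alpha)
    row = report.persistence.loc[report.persistence["symptom"].eq(planted)]
    sig = report.windows[
        report.windows["symptom"].eq(planted) & report.windows["significant"]
    ]["window"]
    return {
        "symptom": planted,
        "category": row["category"].iloc[0],
        "significant_windows": set(sig),
    }


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    windows: tuple[str, ...] = ("proximal",),
    expected_category: str = "immediate",
    multiplier: float = 8.0,
    **kwargs,
) -> dict:
    """Fraction of replicates recovering the planted category/detection."""
    n_cat = n_det = 0
    for i, s in enumerate(spawn_seeds(seed, n_replicates)):
        rep = planted_replicate(s, windows=windows, multiplier=multiplier, **kwargs)
        n_cat += rep["category"] == expected_category
        n_det += bool(set(windows) & rep["significant_windows"])
        if (i + 1) % 10 == 0:
            logger.info("recovery study %s: %d/%d replicates", windows, i + 1, n_replicates)
    return {
        "n_replicates": n_replicates,
        "category_rate": n_cat / n_replicates,
        "detection_rate": n_det / n_replicates,
        "expected_category": expected_category,
        "windows": windows,
        "multiplier": multiplier,
    }
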