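"""End-to-end experiment pipelines built from the analysis stages.

These helpers wire simulate -> score -> performer filter -> linear model ->
multiple-testing correction into single calls, for calibration studies
(type-I error under the null), power analyses, fatigue-logic checks and
morphometry ground-truth recovery.  Analysis drivers, the test suite and
the acceptance script all run the pipeline through this module so they
exercise identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habituation_metrics import performer_filter, score_sessions
from .nmj_morphometry import MorphometryParams, quantify_nmj
from .stats_engine import LmComparison, classify_fatigue, fit_log_ttc_lm
from .synthetic_data import (
    BehaviorSimConfig,
    GenotypeParams,
    NmjSimConfig,
    generate_nmj_image,
    simulate_fatigue,
    simulate_habituation,
)
from .trial_data import HABITUATION, Protocol

__all__ = [
    "run_two_group_experiment",
    "null_rejection_rate",
    "detection_power",
    "fatigue_verdict_rate",
    "RecoverySummary",
    "nmj_recovery_study",
]


def run_two_group_experiment(
    control: GenotypeParams,
    test: GenotypeParams,
    n_flies: int,
    seed: int,
    protocol: Protocol = HABITUATION,
) -> LmComparison | None:
    """One simulated two-genotype experiment through the full pipeline.

    Simulates both cohorts, scores TTC, applies the 50% initial-jumper
    performer filter per genotype, and fits the covariate-corrected log-TTC
    model on the scored flies.  Returns None when either genotype fails the
    performer filter, in which case no comparison is made (the experiment
    is uninterpretable, as in the behavioural protocol).
    """
    cfg = BehaviorSimConfig(
        genotypes={"control": control, "test": test},
        n_flies=n_flies,
        protocol=protocol,
        seed=seed,
    )
    sessions, _ = simulate_habituation(cfg)
    scored_sessions = []
    for genotype in ("control", "test"):
        group = [s for s in sessions if s.genotype == genotype]
        performer, jumpers = performer_filter(group)
        if not performer:
            return None
        scored_sessions.extend(jumpers)
    scores = score_sessions(scored_sessions)
    return fit_log_ttc_lm(scores, "test", "control")


def null_rejection_rate(
    n_replicates: int,
    n_flies: int = 32,
    params: GenotypeParams | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the pipeline under the null.

    Both genotypes share one set of generative parameters; the rate is the
    fraction of performed comparisons rejecting at ``alpha`` (replicates
    where a genotype fails the performer filter contribute no comparison).
    """
    params = params or GenotypeParams()
    rejections = 0
    performed = 0
    for r in range(n_replicates):
        cmp = run_two_group_experiment(params, params, n_flies, seed=seed + r)
        if cmp is None:
            continue
        performed += 1
        rejections += cmp.p_raw < alpha
    if performed == 0:
        return float("nan")
    return rejections / performed


def detection_power(
    n_replicates: int,
    control: GenotypeParams,
    test: GenotypeParams,
    n_flies: int = 96,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates detecting a true genotype effect at ``alpha``."""
    detected = 0
    performed = 0
    for r in range(n_replicates):
        cmp = run_two_group_experiment(control, test, n_flies, seed=seed + r)
        if cmp is None:
            continue
        performed += 1
        detected += cmp.p_raw < alpha
    if performed == 0:
        return float("nan")
    return detected / performed


def fatigue_verdict_rate(
    n_replicates: int,
    test_decay: float,
    control_decay: float = 0.0,
    n_flies: int = 32,
    p0: float = 0.65,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of fatigue-protocol replicates concluding "fatigue".

    Control flies always follow a flat (decay ``control_decay``) response;
    the test group's decay models true motor fatigue when positive.
    """
    fatigued = 0
    performed = 0
    for r in range(n_replicates):
        cfg = BehaviorSimConfig(
            genotypes={
                "control": GenotypeParams(p0=p0, decay=control_decay),
                "test": GenotypeParams(p0=p0, decay=test_decay),
            },
            n_flies=n_flies,
            seed=seed + r,
        )
        # simulate_fatigue keeps each genotype's configured decay here by
        # passing it explicitly per group
        sessions = []
        for genotype, decay in (("control", control_decay), ("test", test_decay)):
            sub_cfg = BehaviorSimConfig(
                genotypes={genotype: GenotypeParams(p0=p0, decay=decay)},
                n_flies=n_flies,
                seed=seed + r + (0 if genotype == "control" else 1_000_000),
            )
            sessions.extend(simulate_fatigue(sub_cfg, fatigue_decay=decay))
        scored_sessions = []
        ok = True
        for genotype in ("control", "test"):
            group = [s for s in sessions if s.genotype == genotype]
            performer, jumpers = performer_filter(group)
            if not performer:
                ok = False
                break
            scored_sessions.extend(jumpers)
        if not ok:
            continue
        scores = score_sessions(scored_sessions)
        verdict = classify_fatigue(scores, "test", "control", alpha=alpha)
        performed += 1
        fatigued += verdict.verdict == "fatigue"
    if performed == 0:
        return float("nan")
    return fatigued / performed


@dataclass(frozen=True)
class RecoverySummary:
    """How well morphometry recovers the generator's ground truth."""

    n_scenes: int
    bouton_exact_rate: float
    branching_point_exact_rate: float
    branch_exact_rate: float
    max_length_error_pct: float
    max_area_error_pct: float
    frame: pd.DataFrame


def nmj_recovery_study(
    n_scenes: int,
    seed: int = 0,
    params: MorphometryParams | None = None,
    **config_overrides,
) -> RecoverySummary:
    """Measure ground-truth recovery across random synthetic NMJ scenes."""
    params = params or MorphometryParams()
    rows = []
    for i in range(n_scenes):
        cfg = NmjSimConfig(seed=seed + i, **config_overrides)
        image, truth = generate_nmj_image(cfg)
        res = quantify_nmj(image, params)
        rows.append(
            {
                "scene": i,
                "boutons_true": truth.boutons, "boutons": res.boutons,
                "bp_true": truth.branching_points, "bp": res.branching_points,
                "branches_true": truth.branches, "branches": res.branches,
                "length_true": truth.length_um, "length": res.length_um,
                "area_true": truth.area_um2, "area": res.area_um2,
            }
        )
    df = pd.DataFrame(rows)
    len_err = 100 * np.abs(df["length"] - df["length_true"]) / df["length_true"]
    area_err = 100 * np.abs(df["area"] - df["area_true"]) / df["area_true"]
    return RecoverySummary(
        n_scenes=n_scenes,
        bouton_exact_rate=float((df["boutons"] == df["boutons_true"]).mean()),
        branching_point_exact_rate=float((df["bp"] == df["bp_true"]).mean()),
        branch_exact_rate=float((df["branches"] == df["branches_true"]).mean()),
        max_length_error_pct=float(len_err.max()),
        max_area_error_pct=float(area_err.max()),
        frame=df,
    )
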