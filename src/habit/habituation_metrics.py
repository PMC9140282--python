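"""Habituation scoring: trials-to-criterion and genotype-level summaries.

A fly is considered habituated once it fails to jump in five consecutive
trials (the no-jump criterion).  Habituation speed is quantified as Trials
To Criterion (TTC).  Genotypes whose fraction of initial jumpers (flies that
jump to the very first pulse) falls below 50% are "non-performers" and are
excluded from habituation comparisons, because a poor startle response
precludes measuring its suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .trial_data import FlySession

__all__ = [
    "HabituationScore",
    "GenotypeCurve",
    "GenotypeSummary",
    "compute_ttc",
    "classify_initial_jumper",
    "performer_filter",
    "habituation_curve",
    "summarize_genotype",
    "score_sessions",
]

NO_JUMP_CRITERION = 5  # consecutive no-jump trials defining habituation
PERFORMER_THRESHOLD_PCT = 50.0


@dataclass(frozen=True)
class HabituationScore:
    fly_id: str
    ttc: int
    censored: bool  # criterion never met within the protocol
    initial_jumper: bool


@dataclass(frozen=True)
class GenotypeCurve:
    """Fraction of flies jumping at each trial, the group habituation curve."""

    genotype: str
    n_flies: int
    fraction_jumping: tuple[float, ...]


@dataclass(frozen=True)
class GenotypeSummary:
    genotype: str
    n_flies: int
    pct_initial_jumpers: float
    performer: bool
    n_scored: int
    mean_ttc: float
    sd_ttc: float
    sem_ttc: float


def compute_ttc(
    session: FlySession,
    k: int = NO_JUMP_CRITERION,
    convention: str = "last_jump",
) -> HabituationScore:
    """Trials To Criterion for one fly.

    Scans for the first run of ``k`` consecutive no-jump trials.  Under the
    default ``last_jump`` convention TTC is the 1-based index of the last
    jump trial preceding that run (0 if the fly never jumps); under
    ``criterion_end`` it is the index of the trial completing the run.  If
    no qualifying run exists the fly never habituates: TTC equals the trial
    count and the score is flagged censored.
    """
    n = session.protocol.n_trials
    if not 1 <= k <= n:
        raise InvalidInputError(f"criterion length k={k} outside 1..{n}")
    if convention not in ("last_jump", "criterion_end"):
        raise InvalidInputError(f"unknown TTC convention {convention!r}")

    jumps = np.asarray(session.jumps, dtype=bool)
    initial = bool(jumps[0])

    # first index (0-based) where a run of k no-jumps starts
    run_start = None
    run = 0
    for i, j in enumerate(jumps):
        run = 0 if j else run + 1
        if run == k:
            run_start = i - k + 1
            break

    if run_start is None:
        return HabituationScore(session.fly_id, ttc=n, censored=True, initial_jumper=initial)

    if convention == "criterion_end":
        ttc = run_start + k  # 1-based index of the run's last trial
    else:
        prior = np.flatnonzero(jumps[:run_start])
        ttc = int(prior[-1]) + 1 if prior.size else 0
    return HabituationScore(session.fly_id, ttc=int(ttc), censored=False, initial_jumper=initial)


def classify_initial_jumper(session: FlySession) -> bool:
    """True iff the fly jumps to the first light-off pulse."""
    return bool(session.jumps[0])


def performer_filter(
    sessions: Sequence[FlySession],
    threshold_pct: float = PERFORMER_THRESHOLD_PCT,
) -> tuple[bool, list[FlySession]]:
    """Performer status of a genotype and the scored (initial-jumper) subset.

    A genotype is a performer when at least ``threshold_pct`` percent of its
    tested flies jump on trial 1; only those initial jumpers contribute TTC
    values to downstream statistics.
    """
    if not sessions:
        raise InvalidInputError("performer_filter needs a non-empty group")
    jumpers = [s for s in sessions if classify_initial_jumper(s)]
    pct = 100.0 * len(jumpers) / len(sessions)
    return pct >= threshold_pct, jumpers


def habituation_curve(sessions: Sequence[FlySession]) -> GenotypeCurve:
    """Per-trial fraction of flies jumping (the group habituation curve)."""
    if not sessions:
        raise InvalidInputError("habituation_curve needs a non-empty group")
    protocols = {s.protocol.name for s in sessions}
    if len(protocols) > 1:
        raise InvalidInputError(f"mixed protocols in one curve: {sorted(protocols)}")
    genotypes = {s.genotype for s in sessions}
    genotype = sessions[0].genotype if len(genotypes) == 1 else "+".join(sorted(genotypes))
    mat = np.array([s.jumps for s in sessions], dtype=float)
    return GenotypeCurve(
        genotype=genotype,
        n_flies=len(sessions),
        fraction_jumping=tuple(mat.mean(axis=0)),
    )


def summarize_genotype(
    scores: Sequence[HabituationScore],
    sessions: Sequence[FlySession],
    threshold_pct: float = PERFORMER_THRESHOLD_PCT,
) -> GenotypeSummary:
    """Mean/SD/SEM of TTC over the scored subset plus performer status.

    ``sessions`` is the full tested group (used for the % initial jumpers);
    ``scores`` are the TTC scores of the scored subset.  SD uses the n-1
    denominator and SEM = SD/sqrt(n_scored).
    """
    if not sessions:
        raise InvalidInputError("summarize_genotype needs tested sessions")
    if len(scores) < 2:
        raise InvalidInputError("need at least 2 scored flies for SD/SEM")
    genotype = sessions[0].genotype
    n_init = sum(classify_initial_jumper(s) for s in sessions)
    pct = 100.0 * n_init / len(sessions)
    ttcs = np.array([sc.ttc for sc in scores], dtype=float)
    sd = float(np.std(ttcs, ddof=1))
    return GenotypeSummary(
        genotype=genotype,
        n_flies=len(sessions),
        pct_initial_jumpers=pct,
        performer=pct >= threshold_pct,
        n_scored=len(scores),
        mean_ttc=float(np.mean(ttcs)),
        sd_ttc=sd,
        sem_ttc=sd / np.sqrt(len(ttcs)),
    )


def score_sessions(
    sessions: Sequence[FlySession],
    k: int = NO_JUMP_CRITERION,
    convention: str = "last_jump",
) -> pd.DataFrame:
    """Score every session and return the long-format scores table.

    Columns: fly_id, genotype, day, system, ttc, censored, initial_jumper —
    the input expected by the statistical engine.
    """
    rows = []
    for s in sessions:
        sc = compute_ttc(s, k=k, convention=convention)
        rows.append(
            {
                "fly_id": s.fly_id,
                "genotype": s.genotype,
                "day": s.day,
                "system": s.system,
                "ttc": sc.ttc,
                "censored": sc.censored,
                "initial_jumper": sc.initial_jumper,
            }
        )
    return pd.DataFrame(rows)
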