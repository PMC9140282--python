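"""Generate the behavioural cohorts every later stage consumes.

Simulates a control genotype (fast habituation), a slow-habituating mutant
(half the control decay rate) and a rescue genotype restored to control-like
decay, each with 96 flies spread over 3 testing days and 2 recording
systems, plus matching fatigue-protocol cohorts.  Writes long-format trial
tables under results/.
"""

from pathlib import Path

from habit.synthetic_data import BehaviorSimConfig, GenotypeParams, simulate_fatigue, simulate_habituation
from habit.trial_data import sessions_to_frame

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240901

GENOTYPES = {
    "control": GenotypeParams(p0=0.65, decay=0.3),
    "mutant": GenotypeParams(p0=0.65, decay=0.15),
    "rescue": GenotypeParams(p0=0.65, decay=0.28),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = BehaviorSimConfig(genotypes=GENOTYPES, n_flies=96, seed=SEED)
    sessions, _ = simulate_habituation(cfg)
    sessions_to_frame(sessions).to_csv(OUT / "trials_habituation.csv", index=False)
    print(f"habituation cohort: {len(sessions)} flies x 100 trials")

    fatigue_sessions = simulate_fatigue(cfg, fatigue_decay=0.0)
    sessions_to_frame(fatigue_sessions).to_csv(OUT / "trials_fatigue.csv", index=False)
    print(f"fatigue cohort: {len(fatigue_sessions)} flies x 50 trials (flat response)")


if __name__ == "__main__":
    main()
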