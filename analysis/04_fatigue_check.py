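"""Rule out fatigue as the explanation for low rescue TTCs.

Scores the fatigue-protocol cohort (50 pulses, 5 s spacing — too slow for
habituation) and applies the sign-gated decision rule: fatigue is concluded
only when a test genotype's log-TTC is significantly *smaller* than the
control's.  Under the flat-response simulation no genotype should be called
fatigued.
"""

from pathlib import Path

import pandas as pd

from habit.habituation_metrics import score_sessions
from habit.stats_engine import classify_fatigue, holm_bonferroni
from habit.trial_data import FATIGUE, assemble_sessions, parse_events_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_events_table(OUT / "trials_fatigue.csv")
    sessions = assemble_sessions(records, FATIGUE)
    scores = score_sessions(sessions)
    scored = scores[scores["initial_jumper"]]

    tests = [g for g in sorted(scored["genotype"].unique()) if g != "control"]
    verdicts = [classify_fatigue(scored, t, "control") for t in tests]
    adj = holm_bonferroni([v.p_adj for v in verdicts])
    rows = []
    for v, pa in zip(verdicts, adj):
        final = "fatigue" if (v.direction < 0 and pa < 0.05) else "no_fatigue"
        rows.append({"comparison": v.comparison, "verdict": final,
                     "estimate": v.estimate, "p_adj": float(pa)})
        print(f"{v.comparison}: {final} (effect {v.estimate:+.2f}, p_adj={pa:.3f})")
    pd.DataFrame(rows).to_csv(OUT / "fatigue_verdicts.csv", index=False)


if __name__ == "__main__":
    main()
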