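"""Score trials-to-criterion and summarise each genotype.

Reads the simulated habituation trial table, applies the 5-consecutive-
no-jump criterion per fly, the 50% initial-jumper performer filter per
genotype, and writes per-fly scores, group habituation curves and the
genotype summary table (N, % initial jumpers, mean TTC +/- SD/SEM).
"""

from pathlib import Path

import pandas as pd

from habit.habituation_metrics import (
    compute_ttc,
    habituation_curve,
    performer_filter,
    score_sessions,
    summarize_genotype,
)
from habit.trial_data import HABITUATION, assemble_sessions, parse_events_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_events_table(OUT / "trials_habituation.csv")
    sessions = assemble_sessions(records, HABITUATION)

    score_sessions(sessions).to_csv(OUT / "scores_habituation.csv", index=False)

    curve_rows, summary_rows = [], []
    for genotype in sorted({s.genotype for s in sessions}):
        group = [s for s in sessions if s.genotype == genotype]
        curve = habituation_curve(group)
        curve_rows += [
            {"genotype": genotype, "trial": t, "fraction_jumping": f}
            for t, f in enumerate(curve.fraction_jumping, start=1)
        ]
        performer, jumpers = performer_filter(group)
        summ = summarize_genotype([compute_ttc(s) for s in jumpers], group)
        summary_rows.append(vars(summ))
        print(
            f"{genotype}: N={summ.n_flies}, {summ.pct_initial_jumpers:.0f}% initial "
            f"jumpers ({'performer' if performer else 'non-performer'}), "
            f"mean TTC {summ.mean_ttc:.1f} +/- {summ.sd_ttc:.1f} SD "
            f"({summ.sem_ttc:.2f} SEM, n={summ.n_scored} scored)"
        )
    pd.DataFrame(curve_rows).to_csv(OUT / "habituation_curves.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(OUT / "genotype_summaries.csv", index=False)


if __name__ == "__main__":
    main()
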