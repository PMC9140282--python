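"""Test genotype effects on log-TTC with day/system correction.

Fits one mutant-vs-control ordinary-least-squares model per test genotype
on the scored (initial-jumper) flies, corrects the family with the
step-down Bonferroni-Holm procedure, and writes the comparison table.
"""

from pathlib import Path

import pandas as pd

from habit.stats_engine import fit_log_ttc_family

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(OUT / "scores_habituation.csv")
    scored = scores[scores["initial_jumper"]]
    comparisons = fit_log_ttc_family(scored, reference="control")
    rows = []
    for c in comparisons:
        rows.append({
            "test": c.genotype_pair[0], "control": c.genotype_pair[1],
            "estimate": c.estimate, "se": c.se, "t": c.t_stat,
            "p": c.p_raw, "p_adj": c.p_adj, "n": c.n,
        })
        verdict = "slower habituation" if c.estimate > 0 else "faster habituation"
        sig = "significant" if c.p_adj < 0.05 else "not significant"
        print(f"{c.genotype_pair[0]} vs control: effect {c.estimate:+.2f} log-TTC "
              f"({verdict}), p_adj = {c.p_adj:.2e} ({sig})")
    pd.DataFrame(rows).to_csv(OUT / "genotype_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
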