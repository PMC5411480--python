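#!/usr/bin/env python
"""Behavioural statistics on the simulated cohorts.

For each experiment: per-condition bias proportions with Bonferroni-
corrected bootstrap confidence intervals against the 0.5 chance level,
and a Kruskal-Wallis test of the condition effect with a permutation-
estimated P value (labels shuffled within listener).
"""

from pathlib import Path

import pandas as pd

import tonebind as tb
from tonebind.synthetic import expand_conditions

RESPONSES = Path("results/responses")
OUT = Path("results/stats")
SEED = 606
GROUP_VARS = {"exp2": "n_context", "exp4": "context_duration_ms",
              "exp5": "gap_s", "exp6": "n_components"}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    kw_rows = []
    for i, (exp, var) in enumerate(GROUP_VARS.items()):
        responses = tb.responses_from_csv(RESPONSES / f"responses_{exp}.csv")
        summary = tb.summarize_bias(responses, var, n_boot=2000,
                                    seed=SEED + i)
        summary.to_csv(OUT / f"bias_{exp}.csv", index=False)
        n_sig = int(summary.significant_vs_chance.sum())
        print(f"{exp}: {n_sig}/{len(summary)} {var} levels significantly "
              f"different from chance after Bonferroni correction")

        # per-listener bias proportions per level feed the KW test,
        # excluding levels without a bias direction
        df = expand_conditions(responses)
        df = df[df.bias_direction != "none"]
        per = df.groupby(["listener_id", var])[
            "response_consistent_with_bias"].mean().reset_index()
        res = tb.kruskal_wallis_perm(
            per["response_consistent_with_bias"].astype(float),
            per[var], listeners=per["listener_id"],
            n_permutations=10_000, seed=SEED + 50 + i)
        kw_rows.append({"experiment": exp, "variable": var, "H": res.H,
                        "df": res.df, "p_perm": res.p_perm,
                        "n_permutations": res.n_permutations})
        print(f"      Kruskal-Wallis H({res.df}) = {res.H:.2f}, "
              f"permutation P = {res.p_perm:.4f}")
    pd.DataFrame(kw_rows).to_csv(OUT / "kruskal_wallis.csv", index=False)


if __name__ == "__main__":
    main()
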