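"""Temporal-order analyses and the scale-invariance test.

Computes per-participant robust similarity→RT slopes (correct trials only)
for the three cue conditions, then the group inference: accuracy ANOVAs,
the 3 x 3 mixed ANOVA on slopes, the pooled one-sample t against zero, and
the JZS Bayes factor for the null of no between-protocol slope difference.
A Bayes factor well below 1 is evidence that the similarity→RT coupling is
the same from the minutes-scale laboratory protocol to the weeks-scale
real-world protocol — temporal scale invariance.

Run after 01/02:  ``python analysis/04_temporal_order.py``
"""

from pathlib import Path

from epimem import io, order

DATA = Path("results/data")
OUT = Path("results/order")


def main() -> None:
    io.setup_logging(OUT / "run.log")
    trials = {p: io.read_trials(DATA / p / "order_trials.csv", "order") for p in ("VR", "RW", "SL")}
    res = order.run_order_stage(trials)
    OUT.mkdir(parents=True, exist_ok=True)

    res["slopes"].to_csv(OUT / "slopes.csv", index=False)
    res["accuracy"].to_csv(OUT / "accuracy.csv", index=False)
    res["anova_toobj"].table.to_csv(OUT / "anova_toobj_accuracy.csv", index=False)
    res["anova_toloc"].table.to_csv(OUT / "anova_toloc_accuracy.csv", index=False)
    res["anova_slopes"].table.to_csv(OUT / "anova_slopes.csv", index=False)
    res["tukey_toloc_experiment"].to_csv(OUT / "tukey_toloc.csv", index=False)
    res["condition_means"].to_csv(OUT / "condition_means.csv", index=False)

    a = res["anova_toobj"].table.iloc[0]
    print(f"TOobj accuracy, experiment effect: F({a.df_num},{a.df_den}) = {a.F:.2f}, p = {a.p:.3f}")
    cond = res["anova_slopes"].effect("condition")
    exp = res["anova_slopes"].effect("experiment")
    print(
        f"slopes: condition F({cond['df_num']},{cond['df_den']}) = {cond['F']:.2f} (p = {cond['p']:.4f}); "
        f"experiment F({exp['df_num']},{exp['df_den']}) = {exp['F']:.2f} (p = {exp['p']:.3f})"
    )
    t = res["pooled_t"]
    bf = res["bf_experiment"]
    print(f"pooled slope t({t.df}) = {t.t:.2f}, p = {t.p:.2e}; mean slope = {t.mean:.0f} ms/unit")
    print(f"JZS BF10 (experiment effect on mean slopes) = {bf.bf10:.4f}  (BF01 = {bf.bf01:.1f})")
    print(res["condition_means"].pivot(index="condition", columns="experiment", values="beta").round(0))
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
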