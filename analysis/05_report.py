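"""Assemble the analysis outputs into one human-readable report.

Collects the tables written by 03/04 into ``results/report.md`` with the
run metadata.  Missing tables are listed rather than silently skipped.

Run last:  ``python analysis/05_report.py``
"""

from pathlib import Path

import pandas as pd

RESULTS = Path("results")

SECTIONS = [
    ("Source retrieval — logistic coefficients", "source/coefficients.csv"),
    ("Source retrieval — interaction model", "source/interaction_coefficients.csv"),
    ("Source retrieval — ANOVAs", "source/anova_recognition.csv"),
    ("Source retrieval — Rem ratio ANOVA", "source/anova_rem_ratio.csv"),
    ("Source retrieval — source x confidence x experiment", "source/anova_source_cells.csv"),
    ("Source retrieval — above-chance tests", "source/above_chance.csv"),
    ("Temporal order — slope ANOVA", "order/anova_slopes.csv"),
    ("Temporal order — accuracy ANOVAs", "order/anova_toobj_accuracy.csv"),
    ("Temporal order — condition means", "order/condition_means.csv"),
]


def main() -> None:
    lines = ["# Synthetic study report", ""]
    missing = []
    for title, rel in SECTIONS:
        path = RESULTS / rel
        if not path.exists():
            missing.append(rel)
            continue
        df = pd.read_csv(path, comment="#")
        lines += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
    if missing:
        lines.insert(2, "**Missing tables:** " + ", ".join(missing) + "\n")
    (RESULTS / "report.md").write_text("\n".join(lines))
    print(f"report -> {RESULTS / 'report.md'}" + (f" (missing: {missing})" if missing else ""))


if __name__ == "__main__":
    main()
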