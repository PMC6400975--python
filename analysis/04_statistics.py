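"""Factorial statistics on the CA count table.

Repeated-measures ANOVAs over the trained instances (regime x word type x
area groupings, Greenhouse-Geisser corrected, partial eta squared with the
conventional size bands) plus the Bonferroni planned comparisons per area
(corrected criterion p < 0.05/6 = 0.0083).

Usage: python analysis/04_statistics.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from lexigrow.connectivity import EXTRASYLVIAN, PERISYLVIAN
from lexigrow.pipeline import standard_anovas
from lexigrow.stats import effect_size_label, planned_comparisons


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    counts = pd.read_csv(args.out / "ca_counts.csv")
    anovas = standard_anovas(counts)
    for name, df in anovas.items():
        df = df.copy()
        df["label"] = [effect_size_label(min(max(x, 0.0), 1.0))
                       for x in df["partial_eta_sq"]]
        df.to_csv(args.out / f"anova_{name}.csv", index=False)
        print(f"\n== {name} ==")
        cols = ["effect", "F", "df1", "df2", "epsilon", "p_corrected",
                "partial_eta_sq", "label"]
        print(df[cols].to_string(index=False,
                                 float_format=lambda x: f"{x:.4g}"))

    for word_type in ("action", "object"):
        comp = planned_comparisons(
            counts[counts.word_type == word_type], "regime",
            areas=list(EXTRASYLVIAN), correction_m=6)
        comp.to_csv(args.out / f"planned_{word_type}_extrasylvian.csv",
                    index=False)
        print(f"\n== planned comparisons, {word_type} words, "
              "blind vs sighted, extrasylvian areas ==")
        print(comp.to_string(index=False, float_format=lambda x: f"{x:.4g}"))


if __name__ == "__main__":
    main()
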