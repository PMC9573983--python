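#!/usr/bin/env python
"""Reliability of the subjective colour-scoring charts.

Recomputes Pearson repeatability from the published confusion matrices
of repeated scoring (188 doubly scored images per replicate pair) for
both the population-specific 3-point cooked chart and the commercial
12-point chart.  The study chart is clearly more repeatable — the same
conclusion that motivated regrading all cooked images on the 3-point
scale.  Output: results/repeatability_table3.txt
"""

from pathlib import Path

from shrimpqg import study_params as sp_
from shrimpqg.colorimetry import ConfusionMatrix, format_confusion_matrix, repeatability

OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    blocks = []
    for title, confusions, cats in (
        ("Study-specific 3-point cooked chart", sp_.STUDY_CHART_CONFUSIONS, [1, 2, 3]),
        ("Commercial 12-point chart (categories 9-11 tabulated)",
         sp_.COMMERCIAL_CHART_CONFUSIONS, sp_.COMMERCIAL_CHART_CATEGORIES),
    ):
        blocks.append(title)
        for (ra, rb), counts in confusions.items():
            cm = ConfusionMatrix(cats, counts)
            r = repeatability(cm)
            blocks.append(f"\n{ra} (rows) vs {rb} (columns), n = {cm.total}")
            blocks.append(format_confusion_matrix(cm, r))
            print(f"{title.split()[0]:>10} chart {ra} vs {rb}: r = {r:.2f}")
        blocks.append("")
    (OUT / "repeatability_table3.txt").write_text("\n".join(blocks) + "\n")
    print(f"written to {OUT}/repeatability_table3.txt")


if __name__ == "__main__":
    main()
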