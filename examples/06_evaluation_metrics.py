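"""The technical-evaluation statistics.

Rebuilds the published evaluation numbers from their raw inputs: multiclass
precision/recall/F1 from per-class confusion counts, the Wilson 95% interval
for a 59/60 task-success rate, and the SUS usability summary for three
evaluator scores.
"""

from nutrikiosk.evaluation import (
    ConfusionCounts,
    metrics,
    round_half_up,
    summarize_sus,
    wilson_interval,
)

counts = ConfusionCounts(
    classes=("adequate", "minor_adjustment", "requires_consultation"),
    tp={"adequate": 152, "minor_adjustment": 74, "requires_consultation": 36},
    fp={"adequate": 16, "minor_adjustment": 13, "requires_consultation": 9},
    fn={"adequate": 13, "minor_adjustment": 16, "requires_consultation": 9},
    support={"adequate": 165, "minor_adjustment": 90, "requires_consultation": 45},
)
rep = metrics(counts)
print("class                   precision  recall     F1")
for cls, vals in rep.per_class.items():
    print(f"  {cls:<22} {vals['precision']:>6.1f} %  {vals['recall']:>6.1f} %  {vals['f1']:>6.1f} %")
print(f"  macro average          {rep.macro['precision']:>6.1f} %  "
      f"{rep.macro['recall']:>6.1f} %  {rep.macro['f1']:>6.1f} %")
print(f"  overall accuracy       {rep.micro_accuracy:>6.1f} %")

lo, hi = wilson_interval(59, 60, 0.95)
print(f"\ntask success 59/60 -> {round_half_up(100 * 59 / 60, 1)} % "
      f"(Wilson 95% CI {round_half_up(100 * lo, 1)} - {round_half_up(100 * hi, 1)} %)")

sus = summarize_sus([87.5, 92.5, 87.5])
print(f"SUS: mean {sus['mean']} (SD {sus['sd']}), grade {sus['grade']}")
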