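"""The seven triage scores on a small hand-checkable prediction set."""

from lexcnn import evaluate

gold = ["green", "green", "green", "amber", "amber", "red", "crisis", "crisis"]
pred = ["green", "green", "amber", "amber", "red", "red", "crisis", "green"]

report = evaluate(gold, pred)
print(report.pretty())
# 5 of 8 posts are labeled correctly (all_acc = 0.625).  flagged_f1 = 0.8
# scores the binary "needs any attention" collapse ({amber, red, crisis} vs
# green); urgent_f1 = 0.667 the {red, crisis} collapse.  non_green_f1
# averages the per-class F1 of the three at-risk categories only.
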