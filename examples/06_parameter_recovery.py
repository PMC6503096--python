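"""Check how accurately the pipeline recovers known generator parameters.

Generates the directional scenario at reduced scale and compares recovered
familiar-phrase TPs and row entropies against the planted ground truth.
"""

from meloinfo.evaluation import recovery_report

report = recovery_report(seed=11, notes_per_movement=1000, order=2)

print("period   target TP   recovered TP   |error|")
for label in ("early", "middle", "late"):
    print(
        f"{label:8s} {report.target_tp_by_period[label]:9.2f}"
        f" {report.recovered_tp_by_period[label]:13.4f}"
        f" {report.tp_errors_by_period[label]:9.4f}"
    )
print(f"max row-entropy error across 32 pieces: {report.max_entropy_error:.4f} bits")
# Errors shrink with movement length: TP estimates are binomial proportions
# over context visits, entropy errors reflect plug-in estimation of each row.
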