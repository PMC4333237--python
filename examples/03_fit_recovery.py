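"""Simulate-and-refit on a small rich-BAL design.

Generates a 12-subject study (BAL pairs spread over 1/4/8 h post-dose so
both extent ratios are well informed), then re-estimates the freed
parameters from deliberately neutral starting values and prints the
estimates next to the generating truth.
"""

from pulmopk.recovery import (
    neutral_start,
    recovery_design,
    reference_parameters,
    run_recovery_replicate,
)

truth = reference_parameters()
result, _ = run_recovery_replicate(seed=42, n_subjects=12, compute_se=True)

print(f"OFV: {result.ofv:.2f}   converged: {result.converged}")
print(f"{'parameter':>14s} {'estimate':>9s} {'truth':>8s} {'RSE%':>6s}")
for name in result.free:
    est = getattr(result.estimates, name)
    rse = (result.rse_percent or {}).get(name)
    rse_s = f"{rse:6.1f}" if rse is not None else "   n/a"
    print(f"{name:>14s} {est:9.3f} {getattr(truth, name):8.3f} {rse_s}")
print()
print("A single 12-subject replicate scatters roughly as the RSEs predict;")
print("the full experiment (scripts/acceptance.py) uses 50 subjects and")
print("reports medians across 10 seeded replicates, which recover the")
print("generating values to within a few percent.")
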