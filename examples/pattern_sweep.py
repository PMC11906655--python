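"""Trap-count patterns from distance-dependent behavioural responses.

Runs a small sweep of published response-function combinations in the
square field (side 50, trap radius 5) at desk scale (2000 walkers, 500
steps, 10 replicates) and classifies each ensemble-mean daily-count
series.  The headline result: several combinations produce counts that
RISE for tens of steps (P3) or dip and then rise (P4) although the
population is strictly decreasing the whole time — rising trap counts do
not imply a growing population.
"""

from trapwalk import (
    ResponseProfile,
    classify_pattern,
    ensemble_mean,
    get_preset,
    reference_setup,
    run_ensemble,
)

combos = [
    ("r1/row2", "s1"),          # randomness > 1 everywhere: unbaited-like decay
    ("r1/row1", "s1"),          # directed near trap: counts rise to a peak
    ("r2/row2", "s2"),          # concave attraction + fast near trap
    ("r3/row1", "s2"),          # dazzling: disoriented close in -> dip first
    ("r3/row2-dazzle", "s3"),   # dazzling + inverse-square speed decay
]

print(f"{'r preset':16s} {'s preset':8s} {'pattern':26s} peak step")
for r_name, s_name in combos:
    profile = ResponseProfile(get_preset(r_name), get_preset(s_name))
    cfg = reference_setup(
        "results_square", profile=profile,
        N0=2000, n_steps=500, n_replicates=10, seed=7,
    )
    label = classify_pattern(ensemble_mean(run_ensemble(cfg)))
    peak = "-" if label.peak_step is None else str(label.peak_step + 1)
    print(f"{r_name:16s} {s_name:8s} {label.label:26s} {peak}")

print("\nP1 = monotone decay, P3 = rise to interior peak then decay,")
print("P4 = initial dip, rise to peak, decay. P3/P4 arise purely from the")
print("attractant reshaping movement behaviour; the population never grows.")
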