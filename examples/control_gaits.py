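"""Baseline walking in both coordination modes.

Runs the calibrated three-leg model for 20 s in tetrapod and in tripod
mode, detects lift-off/touch-down events from the coxa-trochanter angle β,
and prints the stepping period, the inter-leg phase lags and the pattern
label.  Expect a period near 1180 ms with ≈1/3-period lags (tetrapod) and
near 600 ms with the front and hind leg in phase (tripod).
"""

from stickwalk import build_model

for mode in ("tetrapod", "tripod"):
    model = build_model(mode=mode)
    traj = model.run(20000.0)
    s = traj.summarize()
    print(f"{mode}:")
    print(f"  classified pattern : {s.pattern}")
    for leg in ("FL", "ML", "HL"):
        print(f"  {leg} period        : {s.period_mean[leg]:7.1f} ms "
              f"(CV {100 * s.period_cv[leg]:.2f}%)")
    for pair, ph in s.phase.items():
        print(f"  phase {pair:6s}     : {ph:.3f} of a cycle")
    print()
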