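"""Run the four measurement-level detectors and score them.

Contaminates the 393-child weight-for-length cohort with all error types
at intensity 3 and compares sBIV, mBIV, SMOM and MMOM against the
injection gold standard.
"""

from growthguard import (
    InjectionSpec,
    evaluate_detection,
    generate,
    inject,
    mbiv,
    mmom,
    preset,
    sbiv,
    smom,
    trajectory_gold,
)

cohort = generate(preset("targetkids_zwfl"), seed=1)
res = inject(cohort, InjectionSpec(intensity=3.0, seed=2))
gold_cells, gold_subjects = res.flag_cells(), trajectory_gold(res)

print(f"{'method':<6} {'flags':>6} {'sens':>6} {'spec':>6} {'prec':>6} {'kappa':>7}")
for name, det in [("sbiv", sbiv(res.cohort)), ("mbiv", mbiv(res.cohort)),
                  ("smom", smom(res.cohort)),
                  ("mmom", mmom(res.cohort, k=2, seed=0))]:
    m = evaluate_detection(det, res.cohort, gold_cells, gold_subjects)
    print(f"{name:<6} {len(det.flags):>6} {m.sensitivity:>6.3f} "
          f"{m.specificity:>6.3f} {m.precision:>6.3f} {m.kappa:>7.3f}")
# The model-based screens (SMOM/MMOM) catch roughly half the injected
# errors at this intensity with near-perfect specificity; the fixed WHO
# cut-offs (sBIV/mBIV) only fire on perturbations pushed past +/-5 z.
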