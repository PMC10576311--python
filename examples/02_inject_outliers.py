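"""Inject flagged synthetic outliers of all three error types.

Perturbs 5% of measurements per type (15% total) at intensity 3 SD and
prints the gold-standard bookkeeping: flags per type, affected subjects,
and outliers per affected subject.
"""

from growthguard import InjectionSpec, generate, inject, preset, trajectory_gold

cohort = generate(preset("ctx_zwa"), seed=7)
result = inject(cohort, InjectionSpec(error_types=("a", "b", "c"),
                                      intensity=3.0, rate=0.05, seed=11))

print("flags per type:")
print(result.flags["error_type"].value_counts().to_string())
print(f"total flags: {len(result.flags)} "
      f"({len(result.flags) / cohort.n_measurements:.1%} of measurements)")
subjects = trajectory_gold(result)
print(f"affected subjects: {len(subjects)} "
      f"({len(result.flags) / len(subjects):.2f} outliers each on average)")
# ~1146 flags spread over ~650 of 849 children, ~1.76 outliers per
# affected child - the contamination level the detectors are scored on.
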