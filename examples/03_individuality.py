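"""How much individual identity does a single-note call carry?

Simulates a 26-male population with the calibrated between/within variance
structure, applies the inclusion filters (drop brooding recordings, short
recordings, the first 5 calls and first-of-sequence calls, then keep 3
recordings per male), and computes CV ratios, Beecher's information capacity
and LDA assignment accuracy.
"""

import warnings

from peepkit import (PopulationSpec, apply_inclusion_filters,
                     individuality_report, simulate_call_table)

spec = PopulationSpec(n_males=26, seed=5)
raw = simulate_call_table(spec, n_recordings=5, calls_per_recording=35)
calls = apply_inclusion_filters(raw, seed=5)
print(f"{len(raw)} simulated calls -> {len(calls)} after inclusion filters "
      f"({calls['recording_id'].nunique()} recordings, "
      f"{calls['male_id'].nunique()} males)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = individuality_report(calls, cv_scheme="loo_recording")

print("\nCV table (within-recording CVw vs pooled CVb, %):")
print(report.cv.round(2).to_string(index=False))
print("\nPCA eigenvalues:", report.pca.eigenvalues.round(2))
print(f"Beecher's Hs (all 8 PCs):        {report.hs_all.total:.2f} bits "
      f"-> group size {report.group_size_all:.1f}")
print(f"Beecher's Hs (eigenvalue > 1):   {report.hs_conservative.total:.2f} "
      f"bits -> group size {report.group_size_conservative:.1f}")
print(f"LDA ({report.lda.scheme}): {report.lda.mean_accuracy:.1f} "
      f"+/- {report.lda.sd_accuracy:.1f}% correct "
      f"(chance {report.lda.chance:.1f}%)")
print("\nAll CVb/CVw ratios above 1 mean every parameter varies more between "
      "males than within; Hs summarizes that in bits (2^Hs = largest group "
      "in which a male stays identifiable). Clean synthetic calls carry far "
      "more bits than noisy field recordings would.")
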