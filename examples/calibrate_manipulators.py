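"""Co-register two micromanipulators with an affine software correction.

Simulates a calibration session: 15 points on a 5 mm lattice observed by
both the reference manipulator and the tilted one (48.2 degree approach),
with a hidden mechanical misalignment and 3 um readout noise. Fitting the
affine map between the frames should collapse the position error from tens
of micrometres to a few.
"""

from pairedval.coreg import distance_errors, fit_affine_correction
from pairedval.synth import generate_calibration_scene, random_misalignment

# hidden truth: a small rotation/scale/offset error scaled so the raw
# (uncorrected) positioning error averages ~75 um over the lattice
true_misalignment = random_misalignment(seed=0, raw_error_target_um=75.6)

pairs = generate_calibration_scene(
    true_misalignment, n_points=15, noise_sd_um=3.0, seed=0
)

before = distance_errors(pairs)
correction = fit_affine_correction(pairs)
after = distance_errors(pairs, correction)

print(f"distance error before correction: {before.mean_um:.1f} +/- {before.sd_um:.1f} um")
print(f"distance error after correction:  {after.mean_um:.1f} +/- {after.sd_um:.1f} um")
print(f"fitted offset (um): {correction.offset.round(1)}")

# Before: the mechanical misalignment alone leaves errors far too large to
# blindly bring a pipette within ~100 um of a probe site. After: the fitted
# affine map absorbs it down to the readout noise floor, the accuracy regime
# in which paired recordings become practical.
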