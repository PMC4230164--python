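"""The headline comparison: searchlight decoding vs mass-univariate group tests.

Simulates a cohort whose CP group has *reduced face-object pattern
separability at matched mean amplitude*, then runs the controls-minus-CPs
comparison along both routes. The decoding route sees the effect (accuracy
drops wherever the pattern information shrinks); the univariate route is
blind to it by construction (every category evokes the same mean response in
both groups).
"""

from roamlight import PipelineConfig, sensitivity_experiment

config = PipelineConfig(seed=3, grid_dims=(16, 18, 10), n_controls=6, n_cps=5,
                        cp_separability_factor=0.3)
report = sensitivity_experiment(config.cohort_spec(), n_permutations=500)
print(report.summary())

# Expected: the MVPA route detects a cluster at corrected p < 0.05 while the
# univariate route does not — the pattern effect is invisible to mean
# amplitudes.
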