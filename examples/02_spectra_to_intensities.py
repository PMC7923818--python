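"""From toy 1D spectra back to metabolite intensities.

Renders a few samples to Lorentzian-peak spectra with random chemical-shift
offsets, re-aligns them on the lactate doublet at 1.310 ppm, and recovers
intensities by non-negative template least squares.
"""

import menmetab as mm

cfg = mm.SimulationConfig(seed=2)
matrix, _, _ = mm.simulate_cohort(cfg)
named = [m for m in matrix.metabolite_names if not m.startswith("metabolite_")]
sub = matrix.with_values(matrix.values[named].iloc[:3], matrix.state)

spectra = mm.simulate_spectra(sub, cfg)
lib = mm.TemplateLibrary.builtin()

for spec in spectra.spectra:
    aligned, shift = mm.align_to_lactate(spec)
    result = mm.quantify(aligned, lib, metabolites=named)
    true_shift = spectra.shifts[spec.sample_id]
    glycine_true = sub.values.loc[spec.sample_id, "glycine"]
    glycine_est = result.intensities["glycine"]
    print(f"{spec.sample_id}: applied shift {true_shift:+.4f} ppm, "
          f"alignment correction {shift:+.4f} ppm; "
          f"glycine {glycine_est:.3f} (true {glycine_true:.3f}), "
          f"fit residual {result.residual_norm:.2e}")

# The correction should cancel the applied offset to within one grid step
# (~0.001 ppm), and quantified intensities should track the generating
# values to ~1%.
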