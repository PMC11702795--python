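"""Detection model basics: Poisson test, PPM quantification, and LOD.

A bespoke MRD panel pools variant-supporting molecules across ~1,800
tumor-specific sites. Detection asks whether the pooled count k is
significantly above the background expectation lambda0 (one-tailed
Poisson, p <= 0.001); quantification converts the excess into parts per
million of tumor DNA.
"""

from ctdna_mrd import PanelDesign, PlasmaSample, call_sample, compute_lod, poisson_detect

panel = PanelDesign(
    patient_id="PT01",
    n_variants=1800,
    mean_molecules_per_site=4000,
    per_site_error_rate=5e-7,
)

# a draw with 45 variant molecules among 7.2M informative molecules
sample = PlasmaSample(
    patient_id="PT01",
    timepoint_label="C2D1",
    day=28,
    variant_molecules=45,
    total_molecules=7_200_000,
    expected_noise=3.6,
)

p, detected = poisson_detect(sample.variant_molecules, sample.expected_noise)
call = call_sample(sample, panel)
lod = compute_lod(panel)

print(f"one-tailed Poisson p-value : {p:.3e}  (detected: {detected})")
print(f"tumor fraction             : {call.ppm:.2f} PPM")
print(f"panel limit of detection   : {lod:.2f} PPM")
print()
print("45 molecules against an expected background of 3.6 is decisive")
print("(p ~ 1e-30): this sample carries about 5.8 PPM of ctDNA, i.e. a")
print("0.00058% tumor fraction - far below what imaging could ever see,")
print("but ~3x above this panel's ~2 PPM limit of detection.")
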