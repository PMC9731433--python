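"""Quantify allelic regulatory activity from simulated qPCR plates.

One construct carries a true 0.5x archaic-allele effect; the analysis fits
amplification efficiencies from dilution series, computes pDNA-normalised
delta-Ct expression per transfection replicate, and tests each construct's
archaic/non-archaic ratio against 1.
"""

from introcre import reporter
from introcre.synthdata import ReporterConfig, simulate_reporter_plate

plate = simulate_reporter_plate(
    ReporterConfig(seed=2, noise_sd=0.1, fold_changes={"oligo1": 0.5})
)

eff = reporter.estimate_efficiency(plate.dilutions)
print("Amplification efficiencies from the 1:10 dilution series:")
print(eff.round(4).to_string(index=False))

res = reporter.run_reporter_analysis(plate.ct_table, plate.dilutions)
print("\nAllelic expression ratios (archaic / non-archaic):")
print(res.round(4).to_string(index=False))
print("\nTrue fold changes:")
print(plate.truth.to_string(index=False))
# oligo1 recovers a ratio near 0.5 with q < 0.05; the null constructs sit
# near 1 and stay non-significant.
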