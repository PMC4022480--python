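# IRMA network kinetic parameters (model units: concentration, min).
# Edit freely; names mirror the symbols used in cyberloop.gene_models.
# basal transcription rates (conc/min)
alpha1 = 0.002
alpha2 = 0.002
alpha3 = 0.002
alpha4 = 0.002
alpha5 = 0.002
# maximal promoter-driven production rates (conc/min)
v1 = 0.10
v2 = 0.20
v3 = 0.30
v4 = 0.08
v5 = 0.08
# activation/repression thresholds (conc)
k1 = 1.0
k2 = 2.0
k3 = 1.0
k4 = 0.1
k5 = 1.0
k6 = 1.0
# Hill coefficients
h1 = 2.0
h2 = 2.0
h3 = 2.0
h4 = 2.0
# degradation + dilution rates (1/min)
d1 = 0.04
d2 = 0.05
d3 = 0.05
d4 = 0.04
d5 = 0.04
# Gal80p-Gal4p protein-protein inhibition constant (conc)
gamma = 1.0
# transcriptional delay on HO-driven CBF1 production (min)
tau = 100.0
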