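"""Score dimer subunit exchange from SEC-MALLS chromatograms.

Simulates a mixing experiment in which a fraction f of all dimers are
heterodimers after incubation, computes the residual chromatogram and the
fraction sum residual theta_res, and classifies the published exchange
panel against its mismatched-pair background.
"""

import numpy as np

from dimerswap import exchange, synthetic
from dimerswap.reference import exchange_panel_records

# --- a single simulated exchange experiment ------------------------------
scenario = synthetic.resolved_exchange_scenario(hetero_fraction=0.25)
grid = synthetic.default_time_grid()
mix, comp_a, comp_b = synthetic.simulate_exchange_pair(scenario, grid)

mix, comp_a, comp_b = exchange.resample_to_common_grid(mix, comp_a, comp_b)
residual = exchange.residual_chromatogram(mix, comp_a, comp_b)
total = exchange.sum_chromatogram(comp_a, comp_b)
theta = exchange.theta_res(residual, total)
print(f"heterodimer fraction 0.25 -> theta_res = {theta:.2f} %")
# theta_res equals 100*f for resolved peaks: 25 % here, and 50 % would mean
# complete statistical exchange of an equimolar mixture.

# --- the published restriction-factor / CA panel --------------------------
results, bg_mean, bg_sd = exchange.score_records(exchange_panel_records())
print(f"\nnon-exchanging background: {bg_mean:.2f} +/- {bg_sd:.2f} %")
print(f"{'restriction factor':22s} {'CA':22s} {'theta':>6s}  score")
for r in results:
    rf, ca = r.pair
    print(f"{rf:22s} {ca:22s} {r.theta_res:6.1f}  {r.score}")
# Scores: 3 = largely exchanged (>5x background), 2 = appreciable (>2x),
# 1 = weak (>1.3x), 0 = non-observable.  Matched Dimer-1 motifs (AVL/AVL or
# VTF/VTF) exchange; mismatched pairs sit at background.
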