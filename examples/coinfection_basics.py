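"""Mean coinfections and the lysogeny probability for a single phage-host pair.

Evaluates COI = P * alpha * tau at the lambda laboratory reference point and
shows how the Poisson coinfection model turns COI into a probability of
lysogenization (at least two infections within the commitment time).
"""

import numpy as np

from phagecoi import (CoinfectionParams, coi_from_ratio, coi_grid_table,
                      lysogeny_probability, mean_coinfections,
                      percent_lysogeny_curve)

# lambda reference: alpha0 = 5.6e-7 ml/h, tau0 = 0.1 h, B0 = 5e8 cells/ml
ALPHA0, TAU0, B0 = 5.6e-7, 0.1, 5e8

coi_at_unit_ratio = coi_from_ratio(1.0, B0, ALPHA0, TAU0)
print(f"COI at phage-to-bacterium ratio 1 (lambda reference): {coi_at_unit_ratio:.1f}")
# 28 mean infections: under lab conditions even modest ratios coinfect heavily

for coi in [0.1, 1.0, 2.0, 5.0]:
    print(f"  COI = {coi:>4}: p_lys = {lysogeny_probability(coi):.4f}")
# p_lys is P(Poisson(COI) >= 2): negligible below COI ~ 0.5, ~59% at COI = 2

ratio_where_two = 2.0 / coi_at_unit_ratio
print(f"ratio giving COI = 2: {ratio_where_two:.4f}")

curve = percent_lysogeny_curve([ratio_where_two], B0, ALPHA0, TAU0)
print(f"percent lysogeny at that ratio: {curve[0]:.1f}%")

# a small COI scan over bacterial densities at environmental ratios
fixed = CoinfectionParams(phage_conc=B0, bacteria_conc=B0,
                          adsorption_rate=ALPHA0, commitment_time=TAU0)
table = coi_grid_table("bacteria_conc", np.logspace(5, 10, 6),
                       np.logspace(-2, 2, 5), fixed)
print("\nCOI across bacterial densities (rows) and ratios (columns):")
print(table.pivot(index="bacteria_conc", columns="ratio", values="coi")
      .to_string(float_format=lambda v: f"{v:.3g}"))
# COI >= 2 needs ~1e6 cells/ml even at ratios above 10 for lambda-like traits
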