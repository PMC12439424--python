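"""Red List assessment: EOO/AOO geometry, criterion B and A3(c).

Assesses a species from published-style range statistics (EOO from the
convex hull, AOO on the 2-km grid), then re-assesses it under projected
range loss with the criterion A3(c) bands.
"""

import numpy as np

import sdmrisk as s

# 36 subpopulations, one per 2-km cell, in a mountain block
pts = np.array([[4 * i + 1.0, 4 * j + 1.0]
                for i in range(6) for j in range(6)], dtype=float)

rm = s.RangeMetrics(eoo_km2=s.eoo(pts), aoo_km2=s.aoo(pts),
                    n_locations=2, occupied_cells=36)
flags = s.ConditionFlags(severely_fragmented=True,
                         continuing_decline=("i", "iii", "iv", "v"))
a = s.assess(rm, flags, population=(1000, 50, True),
             projected_losses={"SSP585_2061-2080_limited": 85.0,
                               "SSP126_2061-2080_limited": 7.7})

print(f"EOO {rm.eoo_km2:.1f} km2, AOO {rm.aoo_km2:.0f} km2 "
      f"({rm.occupied_cells} occupied 2-km cells)")
print(f"current category: {a.category}  [{a.criteria_string}]")
for crit, cat in a.basis.items():
    print(f"  {crit}: {cat}")
# EN under criterion B (small range, few locations, continuing decline)
# and C2a(i) (small declining population in small subpopulations); the
# A3(c) entries show the proposed future categories: projected AOO loss
# below 15% stays LC, loss of 85% proposes CR.
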