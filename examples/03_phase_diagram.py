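"""A coarse phase diagram over future yield and consumption ceilings.

Replaces the yield and consumption curves with smooth logistic
continuations at 2009 over a 10x10 grid of asymptotic gains (population
unchanged) and classifies each future: NFR (no forest remaining), NFT (no
transition), CFT (classical transition), OFT (overshot) or FFT (false
transition, a relapse into deforestation).  High yield ceilings with
restrained consumption produce transitions; the printed onset statistics
show when they would begin.
"""

import numpy as np

from landshift import default_scan_grid, scan_phase_diagram
from landshift.config import RunConfig, build_driver_set, build_model_params

cfg = RunConfig()
ds = build_driver_set(cfg)
mp = build_model_params(cfg)

n = 10
ky = default_scan_grid(ds.y, 2009.0, n)
kc = default_scan_grid(ds.c, 2009.0, n)
diagram = scan_phase_diagram(ds, mp, ky, kc, 2009.0)

print(f"{n}x{n} scan of asymptotic gains "
      f"(K_y in {ky[0]:.0f}..{ky[-1]:.0f} kg/ha/yr, "
      f"K_c in {kc[0]:.0f}..{kc[-1]:.0f} kg/person/yr)")
print("rows: low -> high K_y; columns: low -> high K_c")
for row in diagram.cells[::-1]:
    print(" ".join(rep.phase for rep in row))
print("phase counts:", diagram.phase_counts())
onsets = [rep.t_transition - 2009 for _, _, rep in diagram.transition_cells()]
if onsets:
    print(f"transition onsets: median {np.median(onsets):.0f}, "
          f"max {max(onsets):.0f} years after 2009")
    print(f"forest cover at transition: up to "
          f"{100 * diagram.max_forest_at_transition():.1f}% of non-barren land")
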