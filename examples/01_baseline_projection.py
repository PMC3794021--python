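"""Baseline run: historical fit and the long-run fate of global land cover.

Integrates the default calibration from a medieval pre-agricultural
landscape until the dynamics stabilise, then prints the 2050 agricultural
projection and the ultimate land-cover shares.  The agricultural area is
pinned to the world food equation A = c p / y throughout, so the 2050
number is the "pessimistic" demand projection; the ultimate shares say how
much forest and wild pasture survive a fully industrialised world.
"""

from landshift import RunConfig, baseline_run, required_agricultural_area
from landshift.config import build_driver_set, build_model_params

cfg = RunConfig()
ds = build_driver_set(cfg)
mp = build_model_params(cfg)

print(f"Required agricultural area in 2050: "
      f"{required_agricultural_area(ds, 2050) / 1e6:.0f} Mha")

res = baseline_run(cfg)
traj = res.trajectory
end = traj.final_state
print(f"Dynamics stabilise by year {traj.times[-1]:.0f} "
      f"({traj.termination}); phase: {res.report.phase}")
print(f"Ultimate forest:       {100 * end.F / mp.T:5.1f}% of non-barren land "
      f"({100 * end.F / mp.total_land_with_barren:.1f}% of all land)")
print(f"Ultimate wild pasture: {100 * end.P / mp.T:5.1f}% of non-barren land "
      f"({100 * end.P / mp.total_land_with_barren:.1f}% of all land)")
print(f"Ultimate agriculture:  {100 * end.A / mp.T:5.1f}% of non-barren land")
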