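"""Sustained linear growth in yield and consumption after 2009.

Instead of letting yield and consumption saturate, both continue along
their 2009 tangent lines.  Yield growth then eventually outruns the
consumption-population product, required farmland peaks, abandonment sets
in, and a global forest transition occurs — the printed year says when the
forest area first turns around.
"""

from landshift import ScenarioSpec, detect_transition, run_scenario
from landshift.scenarios import DriverOverride

spec = ScenarioSpec(
    name="linear-growth",
    c=DriverOverride(mode="linear", t_e=2009.0),
    y=DriverOverride(mode="linear", t_e=2009.0),
)
res = run_scenario(spec)
traj = res.trajectory
t_tr = detect_transition(traj)
i = list(traj.times).index(t_tr)
print(f"Required farmland peaks near {traj.times[traj.D.argmax()]:.0f}")
print(f"Forest transition onset: {t_tr:.0f} "
      f"({t_tr - 2009:.0f} years after 2009)")
print(f"Forest cover at onset: {100 * traj.F[i] / traj.params.T:.1f}% "
      f"of non-barren land")
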