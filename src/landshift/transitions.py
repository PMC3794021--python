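"""Forest-transition detection, five-phase classification and phase scans.

A *forest transition* is the switch from net declining to net expanding
forest area.  On top of transition detection, trajectories are sorted into
five qualitative regimes, understood through the number of interior turning
points of the required agricultural area ``D(t) = c p / y``:

* **NFR** — No Forest Remaining: forest is effectively exhausted.
* **NFT** — No Forest Transition: forest declines monotonically to its
  equilibrium (D never turns down, or recovery never outpaces urban loss).
* **CFT** — Classical Forest Transition: D has a single interior maximum;
  abandonment drives a lasting recovery.
* **OFT** — Overshot Forest Transition: D turns down and later rises again
  but stabilises below its earlier peak.
* **FFT** — False Forest Transition: the late rise of D passes the earlier
  peak, launching a second deforestation era after the apparent transition.

The two-parameter phase scan re-runs the model over a grid of smooth
logistic continuations of the yield and consumption drivers (population
unchanged), classifying each cell and recording the transition year and the
forest cover at transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    LandState,
    ModelParams,
    Trajectory,
    run_to_steady_state,
)
from .drivers import DriverSet, LogisticDriver, make_continuation

__all__ = [
    "PHASES",
    "TransitionError",
    "SteadyStateNotReached",
    "TransitionReport",
    "PhaseDiagram",
    "detect_transition",
    "classify_phase",
    "default_scan_grid",
    "scan_phase_diagram",
]

log = logging.getLogger(__name__)

PHASES = ("NFR", "NFT", "CFT", "OFT", "FFT")

#: phases for which a transition year is defined
_TRANSITION_PHASES = frozenset({"CFT", "OFT", "FFT"})


class TransitionError(ValueError):
    """Invalid input to transition analysis."""


class SteadyStateNotReached(TransitionError):
    """The trajectory did not stabilise, so classification would be a guess."""


@dataclass(frozen=True)
class TransitionReport:
    """Classification of one trajectory.

    ``t_transition`` / ``F_at_transition`` are present exactly for the
    transition-bearing phases (CFT, OFT, FFT); fractions are of the
    non-barren total T.  ``converged`` records whether the underlying run
    reached steady state; ``infeasible`` marks runs whose conversion demand
    exhausted every land source (labelled NFR with this flag set).
    """

    phase: str
    t_transition: float | None
    F_at_transition: float | None
    F_final: float
    D_turning_points: int
    converged: bool = True
    infeasible: bool = False

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise TransitionError(f"unknown phase {self.phase!r}")
        has_t = self.t_transition is not None
        if has_t != (self.phase in _TRANSITION_PHASES):
            raise TransitionError(
                "t_transition must be present exactly for CFT/OFT/FFT"
            )
        for frac in (self.F_at_transition, self.F_final):
            if frac is not None and not -1e-9 <= frac <= 1.0 + 1e-9:
                raise TransitionError("fractions must lie in [0, 1]")


def detect_transition(traj: Trajectory, eps_rate: float | None = None) -> float | None:
    """First year the forest rate crosses from below -eps to above +eps.

    Returns None when forest never recovers (or never declined beyond the
    dead band first).  ``eps_rate`` defaults to 1e-7 * T per year.
    """
    if eps_rate is None:
        eps_rate = 1e-7 * traj.params.T
    f_rate = traj.F_rate()
    armed = False
    for t, rate in zip(traj.times, f_rate):
        if rate < -eps_rate:
            armed = True
        elif armed and rate > eps_rate:
            return float(t)
    return None


def _sign_series(x: np.ndarray, dead_band: float) -> list[int]:
    """Compressed sign sequence of ``x`` ignoring the dead band."""
    signs: list[int] = []
    for v in x:
        s = 1 if v > dead_band else -1 if v < -dead_band else 0
        if s != 0 and (not signs or signs[-1] != s):
            signs.append(s)
    return signs


def classify_phase(
    traj: Trajectory,
    mp: ModelParams,
    *,
    eps_rate: float | None = None,
    allow_unconverged: bool = False,
) -> TransitionReport:
    """Assign one of the five phases to a stabilised trajectory.

    Order of decision: NFR if forest cover ever falls to <= 1e-3 * T (or the
    run was infeasible); NFT if no forest upturn is detected; otherwise the
    sign changes of dD/dt (with a dead band of 1e-7 of the D scale to
    suppress numerical chatter) separate CFT (one interior maximum of D)
    from OFT/FFT (D re-rises; FFT when its asymptote exceeds the first
    interior maximum, i.e. a second deforestation era passes the first).

    Raises :class:`SteadyStateNotReached` for un-stabilised trajectories
    unless ``allow_unconverged`` is set, in which case the report carries
    ``converged=False``.
    """
    converged = traj.steady_state
    if not converged and not traj.infeasible and not allow_unconverged:
        raise SteadyStateNotReached(
            "trajectory did not reach steady state; re-run with a longer "
            "horizon or pass allow_unconverged=True"
        )

    T = mp.T
    D_dot = traj.D_rate()
    dead_band = 1e-7 * float(np.max(traj.D))
    signs = _sign_series(D_dot, dead_band)
    n_turns = max(0, len(signs) - 1)
    F_final = float(traj.F[-1]) / T

    if traj.infeasible or float(np.min(traj.F)) <= 1e-3 * T:
        return TransitionReport(
            phase="NFR",
            t_transition=None,
            F_at_transition=None,
            F_final=F_final,
            D_turning_points=n_turns,
            converged=converged,
            infeasible=traj.infeasible,
        )

    t_tr = detect_transition(traj, eps_rate)
    if t_tr is None:
        return TransitionReport(
            phase="NFT",
            t_transition=None,
            F_at_transition=None,
            F_final=F_final,
            D_turning_points=n_turns,
            converged=converged,
        )

    F_at = float(traj.F[int(np.argmin(np.abs(traj.times - t_tr)))]) / T

    if n_turns <= 1:
        phase = "CFT"
    else:
        # index of the first + -> - flip bounds the first interior maximum
        first_down = None
        seen_pos = False
        for i, v in enumerate(D_dot):
            s = 1 if v > dead_band else -1 if v < -dead_band else 0
            if s > 0:
                seen_pos = True
            elif s < 0 and seen_pos:
                first_down = i
                break
        D_first_max = float(np.max(traj.D[: (first_down or len(traj.D))]))
        D_final = float(traj.D[-1])
        phase = "FFT" if D_final > D_first_max else "OFT"

    return TransitionReport(
        phase=phase,
        t_transition=t_tr,
        F_at_transition=F_at,
        F_final=F_final,
        D_turning_points=n_turns,
        converged=converged,
    )


@dataclass
class PhaseDiagram:
    """Grid of transition reports over continuation asymptotes (K_y, K_c).

    ``ky_values`` / ``kc_values`` are the scanned asymptotic gains (above
    the floors) of the yield and consumption continuations; ``cells[i][j]``
    is the report for ``(ky_values[i], kc_values[j])``.
    """

    ky_values: np.ndarray
    kc_values: np.ndarray
    cells: list
    t_e: float

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.ky_values) or any(
            len(row) != len(self.kc_values) for row in self.cells
        ):
            raise TransitionError("phase diagram grid is incomplete")

    def report(self, i: int, j: int) -> TransitionReport:
        return self.cells[i][j]

    def transition_cells(self):
        """Yield (ky, kc, report) for every transition-bearing cell."""
        for i, ky in enumerate(self.ky_values):
            for j, kc in enumerate(self.kc_values):
                rep = self.cells[i][j]
                if rep.phase in _TRANSITION_PHASES:
                    yield float(ky), float(kc), rep

    def phase_counts(self) -> dict[str, int]:
        counts = {p: 0 for p in PHASES}
        for row in self.cells:
            for rep in row:
                counts[rep.phase] += 1
        return counts

    def max_onset_after(self) -> float | None:
        """Latest transition onset, in years after t_e; None if no transitions."""
        onsets = [rep.t_transition - self.t_e for _, _, rep in self.transition_cells()]
        return max(onsets) if onsets else None

    def max_forest_at_transition(self) -> float | None:
        """Largest forest fraction (of T) at transition over transition cells."""
        vals = [rep.F_at_transition for _, _, rep in self.transition_cells()]
        return max(vals) if vals else None

    def to_frame(self):
        """Long-format table: Ky, Kc, phase, t_transition, fractions, flags."""
        import pandas as pd

        rows = []
        for i, ky in enumerate(self.ky_values):
            for j, kc in enumerate(self.kc_values):
                rep = self.cells[i][j]
                rows.append(
                    {
                        "Ky": float(ky),
                        "Kc": float(kc),
                        "phase": rep.phase,
                        "t_transition": rep.t_transition,
                        "F_at_transition": rep.F_at_transition,
                        "F_final": rep.F_final,
                        "D_turning_points": rep.D_turning_points,
                        "converged": rep.converged,
                        "infeasible": rep.infeasible,
                    }
                )
        return pd.DataFrame(rows)

    def plot(self, path) -> None:
        """Raster plot of the phase labels (optional output)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        idx = {p: k for k, p in enumerate(PHASES)}
        grid = np.array([[idx[rep.phase] for rep in row] for row in self.cells])
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.pcolormesh(
            self.kc_values, self.ky_values, grid, cmap="viridis", vmin=0, vmax=4
        )
        cbar = fig.colorbar(im, ax=ax, ticks=range(5))
        cbar.ax.set_yticklabels(PHASES)
        ax.set_xlabel("consumption asymptotic gain K_c (kg/person/yr)")
        ax.set_ylabel("yield asymptotic gain K_y (kg/ha/yr)")
        ax.set_title(f"Phase diagram of continuations at t_e = {self.t_e:.0f}")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def default_scan_grid(
    d: LogisticDriver,
    t_e: float,
    n: int = 30,
    lo_factor: float = 1.02,
    hi_factor: float = 3.0,
) -> np.ndarray:
    """Continuation-gain grid from just above to a multiple of the t_e value.

    The scanned asymptotic gains run from ``lo_factor`` to ``hi_factor``
    times the driver's current value above its floor at ``t_e`` (the 2009
    values sit approximately at the grid origin).  ``lo_factor`` must exceed
    1 because a continuation requires headroom above the current value.
    """
    if not lo_factor > 1.0:
        raise TransitionError("lo_factor must exceed 1 (continuation headroom)")
    gain_now = d.value(t_e) - d.x0
    return np.linspace(lo_factor * gain_now, hi_factor * gain_now, n)


def scan_phase_diagram(
    base: DriverSet,
    mp: ModelParams,
    Ky_grid,
    Kc_grid,
    t_e: float = 2009.0,
    *,
    t_start: float = 1000.0,
    preag_forest_frac: float = 0.575,
    dt: float = 0.1,
    horizon_cap: float = 2000.0,
    state_at_te: LandState | None = None,
    reexpand_from_abandoned: bool = False,
    progress: bool = False,
) -> PhaseDiagram:
    """Classify the model over a grid of yield/consumption continuations.

    For each cell the yield and consumption drivers are replaced by smooth
    logistic continuations at ``t_e`` with asymptotic gains ``(Ky, Kc)``
    (population unchanged), the model is re-run from the baseline state at
    ``t_e`` to steady state, and the trajectory is classified.  Cells whose
    run exhausts all land sources are marked NFR with the infeasible flag.

    ``state_at_te`` short-circuits the (cell-independent) baseline spin-up
    from ``t_start``; when omitted it is computed once internally.
    """
    from .core import initialize_state, integrate  # local to avoid cycle noise

    Ky_grid = np.asarray(Ky_grid, dtype=float)
    Kc_grid = np.asarray(Kc_grid, dtype=float)

    if state_at_te is None:
        s0 = initialize_state(mp, base, t_start, preag_forest_frac)
        spin = integrate(s0, mp, base, t_start, t_e, dt)
        state_at_te = spin.final_state

    cells: list[list[TransitionReport]] = []
    for i, ky in enumerate(Ky_grid):
        row: list[TransitionReport] = []
        for kc in Kc_grid:
            ds_cell = base.replace(
                y=make_continuation(base.y, t_e, float(ky)),
                c=make_continuation(base.c, t_e, float(kc)),
            )
            try:
                traj = run_to_steady_state(
                    state_at_te,
                    mp,
                    ds_cell,
                    t_e,
                    dt,
                    horizon_cap,
                    reexpand_from_abandoned=reexpand_from_abandoned,
                )
                rep = classify_phase(traj, mp, allow_unconverged=True)
            except Exception as exc:  # noqa: BLE001 - cell marked, scan continues
                log.warning("scan cell (Ky=%.4g, Kc=%.4g) failed: %s", ky, kc, exc)
                rep = TransitionReport(
                    phase="NFR",
                    t_transition=None,
                    F_at_transition=None,
                    F_final=0.0,
                    D_turning_points=0,
                    converged=False,
                    infeasible=True,
                )
            row.append(rep)
        cells.append(row)
        if progress:
            log.info("phase scan row %d/%d done", i + 1, len(Ky_grid))
    return PhaseDiagram(ky_values=Ky_grid, kc_values=Kc_grid, cells=cells, t_e=t_e)
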