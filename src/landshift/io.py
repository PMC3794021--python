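"""Tabular output helpers: stamped CSVs and trajectory round trips."""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .core import STOCKS, ModelParams, Trajectory

__all__ = ["write_csv", "load_trajectory_csv"]


def write_csv(df: pd.DataFrame, path, cfg: RunConfig | None = None) -> None:
    """Write a DataFrame as CSV with a provenance header comment.

    The header records the package version and the config hash so outputs
    can be traced to the run that produced them.  The file is written via a
    temp file and atomically renamed, so failures leave no partial output.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# landshift {__version__}"
    if cfg is not None:
        header += f" config_hash={config_hash(cfg)}"
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_trajectory_csv(path, mp: ModelParams) -> Trajectory:
    """Rebuild a :class:`Trajectory` from an exported trajectory CSV.

    The drivers are not recoverable from the file, so rates are estimated
    by finite differences and the steady-state flag is inferred from the
    final 50 recorded years.
    """
    df = pd.read_csv(path, comment="#")
    needed = ("year",) + STOCKS + ("D",)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {missing}")
    times = df["year"].to_numpy(dtype=float)
    states = df[list(STOCKS)].to_numpy(dtype=float)
    rates = np.gradient(states, times, axis=0)
    tail = times >= times[-1] - 50.0
    steady = bool(np.max(np.abs(rates[tail])) < 1e-6 * mp.T)
    return Trajectory(
        times=times,
        states=states,
        rates=rates,
        D=df["D"].to_numpy(dtype=float),
        drivers=None,
        params=mp,
        steady_state=steady,
    )
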