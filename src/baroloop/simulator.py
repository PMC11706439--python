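"""Closed-loop simulation driver and clinical output extraction.

`simulate` integrates a model variant to a converged periodic state and
returns a densely sampled :class:`Trajectory`; `extract_outputs` reduces the
final complete cardiac cycle to the clinical measurement vector
(:class:`OutputSet`: 10 outputs for the one-chamber model, 16 for the
four-chamber model); `derive_unregulated_equivalent` implements the
regulated-to-unregulated comparison protocol (trailing-window means of the
effector states overriding the unregulated base values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .parameters import (ModelParameters, default_parameters, get_value,
                         set_value)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "OutputSet",
    "simulate",
    "extract_outputs",
    "derive_unregulated_equivalent",
    "evaluate_outputs",
    "output_names",
    "STATE_COLUMNS",
    "AUX_COLUMNS",
]

STATE_COLUMNS = ["p_lv", "p_art", "p_ven", "p_rv", "p_pula", "p_pulv",
                 "p_tilde", "d_e_lvmax", "d_e_rvmax", "d_r_sys", "d_v_unv",
                 "d_tau_s", "d_tau_v"]
AUX_COLUMNS = ["tau_held", "e_lvmax_held", "e_rvmax_held", "r_sys_t",
               "delta_v_unv", "v_lv", "v_rv", "total_volume"]


@dataclass
class SimulationConfig:
    """Integration settings.

    ``t_end`` defaults to 150 s model time for the one-chamber variants and
    300 s for the four-chamber ones — comfortably past the effector settling
    horizon (longest effector time constant 20 s, delays up to 5 s); the
    trailing-mean insensitivity to doubling ``t_end`` is part of the test
    suite.  ``dt`` is the fixed RK4 step of the production integrator;
    ``abs_tol``/``rel_tol`` apply to the adaptive reference integrator
    (:mod:`baroloop.reference`).
    """

    t_end: float | None = None
    sample_dt: float = 0.01
    dt: float = 5e-4
    abs_tol: float = 1e-6
    rel_tol: float = 1e-6
    steady_window: int = 200
    promotion_sigma: float = 1e-3
    periodicity_rtol: float = 1e-3

    def resolve_t_end(self, variant: str) -> float:
        if self.t_end is not None:
            return float(self.t_end)
        return 150.0 if variant == "1ch" else 300.0


@dataclass
class OutputSet:
    """Named clinical measurement vector over the last complete cycle."""

    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([self.values[n] for n in names])

    def to_csv(self, path) -> None:
        pd.Series(self.values, name="value").rename_axis("output").to_csv(path)


def output_names(variant: str, include_tau: bool = True) -> list[str]:
    """Output naming: CO (ml/s), heart period (s), LV volume extrema (ml) and
    per-compartment pressure extrema (mmHg).  Unregulated sensitivity
    analyses drop ``tau_hr`` (constant there), via ``include_tau=False``."""
    base = ["co", "tau_hr", "v_lv_max", "v_lv_min",
            "p_lv_max", "p_lv_min", "p_art_max", "p_art_min",
            "p_ven_max", "p_ven_min"]
    if variant == "4ch":
        base += ["p_rv_max", "p_rv_min", "p_pula_max", "p_pula_min",
                 "p_pulv_max", "p_pulv_min"]
    if not include_tau:
        base = [n for n in base if n != "tau_hr"]
    return base


@dataclass
class Trajectory:
    """Densely sampled closed-loop trajectory with beat bookkeeping."""

    times: np.ndarray
    states: np.ndarray          # (n, 13), columns STATE_COLUMNS
    aux: np.ndarray             # (n, 8), columns AUX_COLUMNS
    beat_onsets: np.ndarray
    beat_tau: np.ndarray        # held heart period promoted at each onset
    variant: str
    regulated: bool
    params: ModelParameters | None = None
    last_cycle: dict | None = None   # engine-tracked extrema of the final cycle
    warnings_: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        ncol = 3 if self.variant == "1ch" else 6
        cols = STATE_COLUMNS[:ncol] + STATE_COLUMNS[6:]
        data = np.column_stack([self.states[:, :ncol], self.states[:, 6:],
                                self.aux])
        return pd.DataFrame(data, columns=cols + AUX_COLUMNS,
                            index=pd.Index(self.times, name="t"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def trailing_mean(self, column: str, window: int = 200) -> float:
        """Mean of the final ``window`` samples of a state or aux column."""
        if column in AUX_COLUMNS:
            series = self.aux[:, AUX_COLUMNS.index(column)]
        elif column in STATE_COLUMNS:
            series = self.states[:, STATE_COLUMNS.index(column)]
        else:
            raise KeyError(column)
        return float(np.mean(series[-window:]))


def simulate(params: ModelParameters, config: SimulationConfig | None = None,
             ) -> Trajectory:
    """Integrate the model over [0, t_end] from the mcfp-uniform initial state.

    All compartment pressures start at the mean circulatory filling pressure
    (the state of the stopped circulation), which also fixes the conserved
    total blood volume; effector deviations start at zero and held effectors
    at their base values.  Warns (and records) if the final cycles are not
    periodic to ``periodicity_rtol`` or if the conserved volume drifts.
    """
    config = config or SimulationConfig()
    params.validate()
    p = _engine.pack(params)
    four = params.variant == "4ch"
    t_end = config.resolve_t_end(params.variant)
    (ts, y, aux, beat_t, beat_tau, last_lo, last_hi, cyc_tau, n_cycles,
     ok) = _engine._integrate(p, four, params.regulated, t_end,
                              config.dt, config.sample_dt)
    if not ok:
        bad = np.where(~np.isfinite(y).all(axis=1))[0]
        t_bad = ts[bad[0]] if bad.size else ts[-1]
        raise RuntimeError(f"integration produced non-finite state near "
                           f"t = {t_bad:.3f} s")
    traj = Trajectory(ts, y, aux, beat_t, beat_tau, params.variant,
                      params.regulated, params=params)
    if n_cycles >= 1:
        names = ["p_lv", "p_art", "p_ven", "p_rv", "p_pula", "p_pulv"]
        n_press = 6 if four else 3
        traj.last_cycle = {"tau": float(cyc_tau)}
        for i, nm in enumerate(names[:n_press]):
            traj.last_cycle[nm] = (float(last_lo[i]), float(last_hi[i]))
        traj.last_cycle["v_lv"] = (float(last_lo[6]), float(last_hi[6]))
    # periodicity check on arterial pressure over the final two beats
    if len(beat_t) >= 3:
        t1, t2 = beat_t[-2], beat_t[-1]
        tau = t2 - t1
        if t1 - tau >= 0:
            grid = np.linspace(0.0, tau * 0.99, 25)
            pa = np.interp(t1 + grid, ts, y[:, 1])
            pb = np.interp(t1 - tau + grid, ts, y[:, 1])
            rel = np.max(np.abs(pa - pb)) / max(np.max(np.abs(pa)), 1e-12)
            if rel > config.periodicity_rtol:
                msg = (f"periodicity check failed: cycle-to-cycle arterial "
                       f"pressure change {rel:.2e} relative")
                traj.warnings_.append(msg)
                warnings.warn(msg, stacklevel=2)
    vol = aux[:, AUX_COLUMNS.index("total_volume")]
    drift = abs(vol[-1] - vol[0]) / max(abs(vol[0]), 1e-12)
    if drift > 1e-3:
        msg = f"conserved-volume drift {drift:.2e} relative over the run"
        traj.warnings_.append(msg)
        warnings.warn(msg, stacklevel=2)
    return traj


def extract_outputs(trajectory: Trajectory, variant: str | None = None,
                    ) -> OutputSet:
    """Clinical outputs over the final complete cardiac cycle.

    Cardiac output is the left-ventricular stroke volume divided by that
    cycle's heart period (ml/s); ``tau_hr`` is the final held heart period.
    Prefers the integrator's per-step extrema when available, otherwise falls
    back to the sampled trajectory between the last two beat onsets.
    """
    variant = variant or trajectory.variant
    names = output_names(variant)
    if len(trajectory.beat_onsets) < 2:
        raise ValueError("need at least 2 complete beats to extract outputs")
    if trajectory.last_cycle is not None:
        lc = trajectory.last_cycle
        tau = lc["tau"]
        vals = {"co": (lc["v_lv"][1] - lc["v_lv"][0]) / tau, "tau_hr": tau,
                "v_lv_max": lc["v_lv"][1], "v_lv_min": lc["v_lv"][0]}
        pressures = ["p_lv", "p_art", "p_ven"]
        if variant == "4ch":
            pressures += ["p_rv", "p_pula", "p_pulv"]
        for nm in pressures:
            vals[f"{nm}_max"] = lc[nm][1]
            vals[f"{nm}_min"] = lc[nm][0]
        return OutputSet({n: float(vals[n]) for n in names})
    t0, t1 = trajectory.beat_onsets[-2], trajectory.beat_onsets[-1]
    sel = (trajectory.times >= t0 - 1e-12) & (trajectory.times <= t1 + 1e-12)
    if not np.any(sel):
        raise ValueError("no samples inside the final cycle")
    tau = float(t1 - t0)
    v_lv = trajectory.aux[sel, AUX_COLUMNS.index("v_lv")]
    vals = {"co": (v_lv.max() - v_lv.min()) / tau, "tau_hr": tau,
            "v_lv_max": float(v_lv.max()), "v_lv_min": float(v_lv.min())}
    pressures = ["p_lv", "p_art", "p_ven"]
    if variant == "4ch":
        pressures += ["p_rv", "p_pula", "p_pulv"]
    for nm in pressures:
        col = trajectory.states[sel, STATE_COLUMNS.index(nm)]
        vals[f"{nm}_max"] = float(col.max())
        vals[f"{nm}_min"] = float(col.min())
    return OutputSet({n: float(vals[n]) for n in names})


def evaluate_outputs(params: ModelParameters,
                     config: SimulationConfig | None = None,
                     include_tau: bool | None = None) -> np.ndarray:
    """Run the model and return the output vector used by the sensitivity
    drivers (``tau_hr`` dropped for unregulated models unless overridden)."""
    if include_tau is None:
        include_tau = params.regulated
    traj = simulate(params, config)
    out = extract_outputs(traj)
    return out.vector(output_names(params.variant, include_tau))


def derive_unregulated_equivalent(params_regulated: ModelParameters,
                                  config: SimulationConfig | None = None,
                                  ) -> tuple[ModelParameters, dict[str, float]]:
    """Regulated-to-unregulated comparison protocol.

    Runs the regulated model to its steady periodic state, takes the mean of
    the final ``steady_window`` samples (default 200, i.e. 2 s at the default
    sampling interval) of each effector's absolute value, and returns an
    unregulated parameter set with those means overriding the base values,
    together with the override dictionary.
    """
    if not params_regulated.regulated:
        raise ValueError("expected a regulated parameter set")
    config = config or SimulationConfig()
    traj = simulate(params_regulated, config)
    if any("periodicity" in w for w in traj.warnings_):
        raise RuntimeError("steady state not reached: " + traj.warnings_[0])
    w = config.steady_window
    overrides = {
        "tau_hr0": traj.trailing_mean("tau_held", w),
        "e_lvmax": traj.trailing_mean("e_lvmax_held", w),
        "r_sys": traj.trailing_mean("r_sys_t", w),
    }
    if params_regulated.variant == "4ch":
        overrides["e_rvmax"] = traj.trailing_mean("e_rvmax_held", w)
        # unstressed venous volume V_un = V_init + Delta; recorded for
        # bookkeeping (the unregulated dynamics carry no V_un coupling)
        v_un = (params_regulated.circulation.v_unv_init
                + traj.trailing_mean("delta_v_unv", w))
        overrides["v_unv_init"] = v_un
    equivalent = default_parameters(params_regulated.variant, regulated=False)
    # carry over the regulated run's mechanical base values before overriding
    for name in equivalent.free_parameter_order:
        set_value(equivalent, name, get_value(params_regulated, name))
    for name, value in overrides.items():
        if name == "v_unv_init" and value < 0:
            continue  # non-physical as a structural volume; bookkeeping only
        set_value(equivalent, name, value)
    return equivalent.validate(), overrides
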