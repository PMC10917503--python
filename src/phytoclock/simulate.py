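"""Entrainment/free-run integration of the clock models.

Trajectories are integrated piecewise between light transitions (which are
genuine discontinuities of the forcing when ``twilight_h == 0`` and near-
discontinuities otherwise), with a stiff-capable solver and dense output
resampled onto a regular grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .clock_models import (
    LightProtocol,
    ModelVariant,
    ParameterSet,
    Release,
    SplitCoupling,
    get_variant,
    rhs,
    split_parameter_names,
)
from .genotypes import Genotype, KnockoutMode, apply_knockout

__all__ = [
    "SolverOptions",
    "IntegrationError",
    "Trajectory",
    "run_simulation",
    "residual_check",
    "write_trajectory",
    "read_trajectory",
]

DEFAULT_INITIAL_VALUE = 0.1


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if self.rtol > 1e-6:
            raise ValueError("solver rtol must be <= 1e-6 for trustworthy trajectories")


@dataclass
class Trajectory:
    """Densely sampled time course with ZT/CT phase bookkeeping.

    ``time_h`` runs from 0 (start of entrainment) in hours; ``states`` has
    shape (n_states, n_times) ordered as ``variant.component_names``.
    """

    time_h: np.ndarray
    states: np.ndarray
    variant: ModelVariant
    genotype: Genotype
    protocol: LightProtocol
    sampling_step_h: float = 0.1
    coupling: SplitCoupling = SplitCoupling.SUM_HALVED

    @property
    def release_time_h(self) -> float:
        return self.protocol.release_time_h

    def component(self, name: str) -> np.ndarray:
        return self.states[self.variant.index(name)]

    def phase_frame(self) -> np.ndarray:
        """'ZT' before release, 'CT' from release onwards."""
        return np.where(self.time_h < self.release_time_h, "ZT", "CT")

    def zt_or_ct(self) -> np.ndarray:
        """ZT(t) = t mod cycle during entrainment; CT(t) = (t - release) mod 24
        afterwards, anchored so that subjective dawn (CT 0) coincides with the
        last entrained dawn."""
        zt = np.mod(self.time_h, self.protocol.cycle_h)
        ct = np.mod(self.time_h - self.release_time_h, 24.0)
        return np.where(self.time_h < self.release_time_h, zt, ct)

    def free_run(self) -> "Trajectory":
        """The sub-trajectory from release onwards."""
        m = self.time_h >= self.release_time_h
        return Trajectory(
            self.time_h[m], self.states[:, m], self.variant, self.genotype,
            self.protocol, self.sampling_step_h, self.coupling,
        )


def run_simulation(
    variant: ModelVariant | str,
    params: ParameterSet,
    genotype: Genotype | None = None,
    protocol: LightProtocol | None = None,
    solver: SolverOptions | None = None,
    sampling_step_h: float = 0.1,
    initial_state: np.ndarray | float = DEFAULT_INITIAL_VALUE,
    knockout_mode: KnockoutMode = KnockoutMode.BASAL_AND_LIGHT,
    extra_entrain_cycles: int = 0,
    coupling: SplitCoupling = SplitCoupling.SUM_HALVED,
) -> Trajectory:
    """Integrate a model/genotype through entrainment and free run.

    If ``genotype`` is given, the knockout is resolved here; otherwise
    ``params`` is assumed to be knockout-resolved already.  All components
    start at 0.1 model units by default; the entrainment days act as the
    burn-in.  ``extra_entrain_cycles`` prepends silent entrainment cycles
    (integrated but discarded) for limit-cycle pre-convergence checks.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    protocol = protocol or LightProtocol()
    solver = solver or SolverOptions()
    if genotype is not None:
        params = apply_knockout(params, genotype, variant, mode=knockout_mode)
    else:
        genotype = Genotype(frozenset())
    params.require(split_parameter_names(variant))

    y0 = np.asarray(initial_state, dtype=float)
    if y0.ndim == 0:
        y0 = np.full(variant.n_states, float(y0))
    if y0.shape != (variant.n_states,):
        raise ValueError(
            f"initial state must have {variant.n_states} entries, got {y0.shape}"
        )

    if extra_entrain_cycles:
        burn = LightProtocol(
            entrain_days=extra_entrain_cycles,
            photoperiod_light_h=protocol.photoperiod_light_h,
            cycle_h=protocol.cycle_h,
            release=protocol.release,
            free_run_days=1,
            twilight_h=protocol.twilight_h,
        )
        pre = _integrate(variant, params, burn, solver, sampling_step_h, y0,
                         coupling, t_end=burn.release_time_h)
        y0 = pre.states[:, -1]

    return _integrate(variant, params, protocol, solver, sampling_step_h, y0,
                      coupling, t_end=protocol.total_h, genotype=genotype)


def _integrate(
    variant: ModelVariant,
    params: ParameterSet,
    protocol: LightProtocol,
    solver: SolverOptions,
    sampling_step_h: float,
    y0: np.ndarray,
    coupling: SplitCoupling,
    t_end: float,
    genotype: Genotype | None = None,
) -> Trajectory:
    breakpoints = [t for t in protocol.light_transitions() if 0.0 < t < t_end]
    edges = np.unique(np.concatenate([[0.0], breakpoints, [t_end]]))
    grid = np.round(np.arange(0.0, t_end + sampling_step_h / 2, sampling_step_h), 9)

    def f(t, y):
        return rhs(variant, y, t, params, protocol, coupling)

    times: list[np.ndarray] = []
    values: list[np.ndarray] = []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(
            f, (a, b), y, method=solver.method, rtol=solver.rtol,
            atol=solver.atol, max_step=solver.max_step, dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in [{a:.2f}, {b:.2f}] h at t={sol.t[-1]:.4f}: "
                f"{sol.message}; state={sol.y[:, -1]}"
            )
        seg = grid[(grid >= a) & (grid < b)] if b < t_end else grid[(grid >= a)]
        seg = seg[seg <= b]
        ys = sol.sol(seg)
        if not np.all(np.isfinite(ys)):
            raise IntegrationError(f"non-finite state in [{a:.2f}, {b:.2f}] h")
        times.append(seg)
        values.append(ys)
        y = sol.y[:, -1]

    time_h = np.concatenate(times)
    states = np.concatenate(values, axis=1)
    # de-duplicate breakpoint samples (kept from the left segment)
    keep = np.concatenate([[True], np.diff(time_h) > 1e-12])
    return Trajectory(
        time_h[keep], states[:, keep], variant,
        genotype or Genotype(frozenset()), protocol, sampling_step_h, coupling,
    )


def residual_check(
    trajectory: Trajectory,
    params: ParameterSet,
    n_points: int = 200,
    seed: int = 0,
) -> float:
    """Max |finite-difference derivative - rhs| over a random subsample.

    Central differences on the stored grid; samples adjacent to light
    transitions are excluded (the forcing is discontinuous there).
    """
    t = trajectory.time_h
    y = trajectory.states
    step = trajectory.sampling_step_h
    interior = np.arange(1, len(t) - 1)
    edges = np.asarray(trajectory.protocol.light_transitions())
    safe = interior[
        np.min(np.abs(t[interior][:, None] - edges[None, :]), axis=1) > 1.5 * step
    ]
    rng = np.random.default_rng(seed)
    idx = rng.choice(safe, size=min(n_points, len(safe)), replace=False)
    worst = 0.0
    for i in idx:
        fd = (y[:, i + 1] - y[:, i - 1]) / (t[i + 1] - t[i - 1])
        f = rhs(trajectory.variant, y[:, i], t[i], params, trajectory.protocol,
                trajectory.coupling)
        worst = max(worst, float(np.max(np.abs(fd - f))))
    return worst


# ---------------------------------------------------------------------------
# long-format CSV + JSON sidecar I/O


def write_trajectory(trajectory: Trajectory, csv_path: str | Path) -> Path:
    """Write long-format CSV (time_h, zt_or_ct, phase_frame, component, value)
    plus a JSON metadata sidecar next to it."""
    csv_path = Path(csv_path)
    n = len(trajectory.time_h)
    comps = trajectory.variant.component_names
    frame = pd.DataFrame({
        "time_h": np.tile(trajectory.time_h, len(comps)),
        "zt_or_ct": np.tile(trajectory.zt_or_ct(), len(comps)),
        "phase_frame": np.tile(trajectory.phase_frame(), len(comps)),
        "component": np.repeat(comps, n),
        "value": trajectory.states.reshape(-1),
    })
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "variant": trajectory.variant.name,
        "genotype": trajectory.genotype.label,
        "coupling": trajectory.coupling.value,
        "sampling_step_h": trajectory.sampling_step_h,
        "protocol": {
            "entrain_days": trajectory.protocol.entrain_days,
            "photoperiod_light_h": trajectory.protocol.photoperiod_light_h,
            "cycle_h": trajectory.protocol.cycle_h,
            "release": trajectory.protocol.release.name,
            "free_run_days": trajectory.protocol.free_run_days,
            "twilight_h": trajectory.protocol.twilight_h,
        },
    }
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def read_trajectory(csv_path: str | Path) -> Trajectory:
    """Round-trip reader for :func:`write_trajectory` output."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    from .genotypes import parse_genotype

    variant = get_variant(meta["variant"])
    proto = meta["protocol"]
    protocol = LightProtocol(
        entrain_days=proto["entrain_days"],
        photoperiod_light_h=proto["photoperiod_light_h"],
        cycle_h=proto["cycle_h"],
        release=Release[proto["release"]],
        free_run_days=proto["free_run_days"],
        twilight_h=proto["twilight_h"],
    )
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    comps = variant.component_names
    first = frame[frame["component"] == comps[0]]
    time_h = first["time_h"].to_numpy()
    states = np.empty((len(comps), len(time_h)))
    for i, c in enumerate(comps):
        states[i] = frame.loc[frame["component"] == c, "value"].to_numpy()
    return Trajectory(
        time_h, states, variant, parse_genotype(meta["genotype"]), protocol,
        meta["sampling_step_h"], SplitCoupling(meta["coupling"]),
    )
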