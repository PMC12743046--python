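"""Conductance-based nonlinear integrate-and-fire network simulation.

Each neuron's membrane potential obeys

    dv_i/dt = -(v_i - V_R)/tau - [f_i g_E,i(t) + g_S,i(t)] (v_i - V_E),

in nondimensional voltage units (rest/reset V_R = 0, threshold V_T = 1,
excitatory reversal V_E = 3) with time in milliseconds.  The leak
conductance is 1/tau (tau = 20 ms, i.e. 50 1/s); synaptic conductances are
measured in the same units, so excitatory input depolarizes the cell
toward V_E.  When v_i crosses V_T the neuron spikes, v_i resets to V_R,
and every postsynaptic neuron k receives a conductance increment of weight
A[k, i] at the next step boundary.

Conductance time courses are alpha functions

    G(t; t_s, tau_x) = ((t - t_s)/tau_x^2) exp(-(t - t_s)/tau_x),  t >= t_s,

unit-area kernels with peak at offset tau_x.  Rather than summing kernels
over growing spike lists, each kernel class is realized exactly as a
two-state linear filter per neuron:

    dh/dt = -h/tau_x + (impulses)/tau_x,      dg/dt = -g/tau_x + h/tau_x,

whose impulse response is exactly the alpha function.  The filters are
advanced with their closed-form propagator, and the voltage with an
exponential rule using midpoint conductances (second-order accurate for
smooth input).

External drive is a per-neuron homogeneous Poisson spike train (rate
nu_E = 500 1/s, strength f_E = 0.1) with kernel scale tau_E = 2.728 ms;
each region scales f_E by a weight w_g drawn uniformly from [0.8, 1.2].
Recurrent kernels use tau_S = 1 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .netgen import Connectome, RegionLayout

__all__ = [
    "NeuronParams",
    "DriveParams",
    "SimConfig",
    "SpikeRaster",
    "RegionalTraces",
    "VoltageTraces",
    "SimResult",
    "alpha_kernel",
    "generate_poisson_drive",
    "draw_region_weights",
    "regional_average_voltage",
    "run_simulation",
    "write_raster_csv",
    "read_raster_csv",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and synaptic constants (times in ms, voltages nondimensional).

    ``g_rec`` converts connection strength to recurrent conductance: a
    presynaptic spike across an edge of strength A contributes a unit-area
    alpha transient of total conductance g_rec * A (in the same 1/ms units
    as the leak conductance 1/tau).  The default 1.0 puts recurrent and
    external synapses on the same conductance scale; note that the purely
    excitatory network then loses its stationary firing state once the
    total in-strength times the driving force outweighs the leak, entering
    a synchronous high-firing regime (rate bounded by 1/dt).
    """

    tau: float = 20.0
    tau_S: float = 1.0
    tau_E: float = 2.728
    V_R: float = 0.0
    V_T: float = 1.0
    V_E: float = 3.0
    g_rec: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau > 0 and self.tau_S > 0 and self.tau_E > 0):
            raise ValueError("all time constants must be positive")
        if self.g_rec < 0:
            raise ValueError("recurrent conductance scale must be nonnegative")
        if not self.V_R < self.V_T < self.V_E:
            raise ValueError(
                f"require V_R < V_T < V_E; got {self.V_R}, {self.V_T}, {self.V_E}"
            )


@dataclass(frozen=True)
class DriveParams:
    """External Poisson-drive parameters.

    f_E : base EPSP strength (dimensionless conductance weight).
    nu_E : Poisson rate in spikes per second.
    w_low, w_high : bounds of the per-region uniform weight factor w_g;
        every neuron in region g uses strength f_i = w_g * f_E.
    w : optional per-region weights; drawn at simulation time when None.
    """

    f_E: float = 0.1
    nu_E: float = 500.0
    w_low: float = 0.8
    w_high: float = 1.2
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nu_E < 0:
            raise ValueError(f"Poisson rate must be nonnegative; got {self.nu_E}")
        if self.w_low > self.w_high:
            raise ValueError("w_low must not exceed w_high")
        if self.w is not None:
            w = np.asarray(self.w, dtype=float)
            if np.any(w < self.w_low) or np.any(w > self.w_high):
                raise ValueError("region weights must lie within [w_low, w_high]")


@dataclass(frozen=True)
class SimConfig:
    """Integration settings (times in ms).

    ``literal_sign=True`` keeps the hyperpolarizing conductance sign
    +g(v - V_E) for comparison runs; the default uses the conventional
    depolarizing form -g(v - V_E).
    """

    dt: float = 0.1
    duration: float = 4000.0
    transient: float = 500.0
    record_dt: float = 1.0
    seed: int | np.random.SeedSequence | None = None
    record_full: bool = False
    literal_sign: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.dt <= self.record_dt:
            raise ValueError("require 0 < dt <= record_dt")
        if not self.transient < self.duration:
            raise ValueError("transient must be shorter than duration")


@dataclass(frozen=True)
class SpikeRaster:
    """Spike events (neuron index, time in ms), time-sorted."""

    neuron_ids: np.ndarray  # (n_events,) int
    times: np.ndarray  # (n_events,) float, ms
    layout: RegionLayout | None = None

    @property
    def n_events(self) -> int:
        return self.times.size

    def region_ids(self) -> np.ndarray:
        if self.layout is None:
            raise ValueError("raster has no layout attached")
        return self.layout.membership[self.neuron_ids]

    def after(self, t: float) -> "SpikeRaster":
        keep = self.times >= t
        return SpikeRaster(self.neuron_ids[keep], self.times[keep], self.layout)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"neuron_id": self.neuron_ids, "time_ms": self.times})
        if self.layout is not None:
            df.insert(1, "region_id", self.region_ids())
        return df


@dataclass(frozen=True)
class RegionalTraces:
    """Region-averaged voltages L_i(t) plus the full-network mean L(t)."""

    times: np.ndarray  # (T,) ms
    L: np.ndarray  # (T, z)
    L_global: np.ndarray  # (T,)

    @property
    def z(self) -> int:
        return self.L.shape[1]

    def after(self, t: float) -> "RegionalTraces":
        keep = self.times >= t
        return RegionalTraces(self.times[keep], self.L[keep], self.L_global[keep])


@dataclass(frozen=True)
class VoltageTraces:
    """Full per-neuron sampled membrane potentials."""

    times: np.ndarray  # (T,) ms
    V: np.ndarray  # (T, n)


@dataclass(frozen=True)
class SimResult:
    raster: SpikeRaster
    traces: RegionalTraces
    voltages: VoltageTraces | None
    region_weights: np.ndarray  # (z,) realized w_g


def alpha_kernel(t, t_spike, tau: float):
    """Alpha-function conductance density; zero before the spike time.

    Unit area over [t_spike, inf), peak value exp(-1)/tau at offset tau.
    """
    if tau <= 0:
        raise ValueError("kernel scale tau must be positive")
    t = np.asarray(t, dtype=float)
    s = t - t_spike
    out = np.where(s >= 0, (np.maximum(s, 0.0) / tau**2) * np.exp(-np.maximum(s, 0.0) / tau), 0.0)
    return out if out.ndim else float(out)


def generate_poisson_drive(
    n: int, nu: float, duration: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-neuron homogeneous Poisson event times on [0, duration) ms.

    ``nu`` is in spikes per second, times are in ms; inter-arrival times
    are i.i.d. exponential with mean 1000/nu ms.
    """
    if nu < 0:
        raise ValueError(f"Poisson rate must be nonnegative; got {nu}")
    if nu == 0:
        return [np.empty(0) for _ in range(n)]
    rate_ms = nu / 1000.0
    events = []
    for _ in range(n):
        count = rng.poisson(rate_ms * duration)
        times = np.sort(rng.random(count)) * duration
        events.append(times)
    return events


def draw_region_weights(
    z: int, w_low: float, w_high: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. uniform per-region external-drive weight factors w_g."""
    if w_low > w_high:
        raise ValueError("w_low must not exceed w_high")
    return rng.uniform(w_low, w_high, size=z)


def regional_average_voltage(
    voltages: np.ndarray, layout: RegionLayout, times: np.ndarray | None = None
) -> RegionalTraces:
    """Average sampled voltages over each region: L_i(t) = mean over Y_i of v_j(t)."""
    V = np.asarray(voltages, dtype=float)
    if V.shape[1] != layout.n:
        raise ValueError(f"expected {layout.n} neuron columns, got {V.shape[1]}")
    L = V.reshape(V.shape[0], layout.z, layout.m).mean(axis=2)
    L_global = V.mean(axis=1)
    if times is None:
        times = np.arange(V.shape[0], dtype=float)
    return RegionalTraces(times=np.asarray(times, float), L=L, L_global=L_global)


def _advance_filter(h: np.ndarray, g: np.ndarray, decay: float, dt_over_tau: float) -> None:
    """Exact half/full-step propagator of the two-state alpha filter (in place)."""
    g += h * dt_over_tau
    g *= decay
    h *= decay


def _bin_events(events: list[np.ndarray], dt: float, n_steps: int):
    """Bin frozen event times to the nearest step boundary.

    Rounding (rather than truncating) keeps an event time that is an exact
    multiple of a coarser step on the same boundary as the step refines,
    so timestep-halving studies converge at the integrator's own order.
    """
    steps = []
    neurons = []
    for i, t in enumerate(events):
        idx = np.round(np.asarray(t, float) / dt).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        steps.append(idx)
        neurons.append(np.full(idx.size, i, dtype=np.int64))
    if not steps:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    steps = np.concatenate(steps)
    neurons = np.concatenate(neurons)
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order]


def run_simulation(
    conn: Connectome,
    neuron: NeuronParams | None = None,
    drive: DriveParams | None = None,
    cfg: SimConfig | None = None,
    external_events: list[np.ndarray] | None = None,
) -> SimResult:
    """Integrate the network and return spikes, regional traces, optional voltages.

    Threshold crossings within a step are recorded at the linearly
    interpolated crossing time; the voltage resets to V_R and the recurrent
    increments (weighted by the connectome) reach postsynaptic filters at
    the next step boundary.  ``external_events`` freezes the external drive
    to explicit per-neuron event-time lists (events are delivered at the
    boundary of the step containing them); otherwise Poisson input is drawn
    on the fly from the config seed.
    """
    neuron = neuron or NeuronParams()
    drive = drive or DriveParams()
    cfg = cfg or SimConfig()
    layout = conn.layout
    n, z, m = layout.n, layout.z, layout.m
    dt = cfg.dt

    if dt > neuron.tau_S:
        warnings.warn(
            f"dt={dt} ms exceeds tau_S={neuron.tau_S} ms; the synaptic kernel "
            "is under-resolved",
            stacklevel=2,
        )

    ss = cfg.seed if isinstance(cfg.seed, np.random.SeedSequence) else np.random.SeedSequence(cfg.seed)
    rng_w, rng_drive = (np.random.default_rng(c) for c in ss.spawn(2))

    if drive.w is not None:
        w = np.asarray(drive.w, dtype=float)
        if w.shape != (z,):
            raise ValueError(f"region weights must have shape ({z},)")
    else:
        w = draw_region_weights(z, drive.w_low, drive.w_high, rng_w)
    f_i = (w[layout.membership] * drive.f_E).astype(np.float64)

    n_steps = int(round(cfg.duration / dt))
    record_every = max(1, int(round(cfg.record_dt / dt)))
    n_rec = n_steps // record_every

    frozen = external_events is not None
    if frozen:
        if len(external_events) != n:
            raise ValueError(f"external_events must have {n} per-neuron lists")
        ev_steps, ev_neurons = _bin_events(external_events, dt, n_steps)
        ev_ptr = 0
        rate_dt = 0.0
    else:
        rate_dt = drive.nu_E / 1000.0 * dt

    inv_tau = 1.0 / neuron.tau
    half_S = np.exp(-0.5 * dt / neuron.tau_S)
    half_E = np.exp(-0.5 * dt / neuron.tau_E)
    hdt_S = 0.5 * dt / neuron.tau_S
    hdt_E = 0.5 * dt / neuron.tau_E
    sign = 1.0 if cfg.literal_sign else -1.0

    v = np.full(n, neuron.V_R, dtype=np.float64)
    hS = np.zeros(n)
    gS = np.zeros(n)
    hE = np.zeros(n)
    gE = np.zeros(n)

    # column-major copy: delivering a volley gathers presynaptic columns
    A_cols = np.asfortranarray(conn.A)
    spike_vec = np.zeros(n)
    pending: np.ndarray | None = None
    pending_lag = np.empty(0)  # next-boundary minus firing time, per pending spike

    rec_times = np.empty(n_rec)
    rec_L = np.empty((n_rec, z))
    rec_Lg = np.empty(n_rec)
    rec_V = np.empty((n_rec, n)) if cfg.record_full else None
    rec_i = 0

    spike_neurons: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []

    for step in range(n_steps):
        t = step * dt
        # deliver recurrent increments from spikes of the previous step; the
        # alpha kernel is anchored at the interpolated firing time, so the
        # filter state arrives pre-aged by the boundary-crossing lag
        if pending is not None and pending.size:
            lag = pending_lag / neuron.tau_S
            wh = np.exp(-lag)
            wg = lag * wh
            if pending.size > 64:  # large volley: BLAS matvec beats a gather
                spike_vec[pending] = wh
                inc_h = A_cols @ spike_vec
                spike_vec[pending] = wg
                inc_g = A_cols @ spike_vec
                spike_vec[pending] = 0.0
            else:
                cols = A_cols[:, pending]
                inc_h = cols @ wh
                inc_g = cols @ wg
            hS += (neuron.g_rec / neuron.tau_S) * inc_h
            gS += (neuron.g_rec / neuron.tau_S) * inc_g
        # deliver external events falling in [t, t + dt)
        if frozen:
            j = ev_ptr
            while j < ev_steps.size and ev_steps[j] == step:
                j += 1
            if j > ev_ptr:
                np.add.at(hE, ev_neurons[ev_ptr:j], 1.0 / neuron.tau_E)
                ev_ptr = j
        elif rate_dt > 0.0:
            counts = rng_drive.poisson(rate_dt, n)
            hE += counts / neuron.tau_E

        # conductances at the step midpoint (exact half-step propagation)
        _advance_filter(hS, gS, half_S, hdt_S)
        _advance_filter(hE, gE, half_E, hdt_E)
        G = f_i * gE + gS

        # exponential step for dv/dt = b - a v with midpoint conductances;
        # with the conventional sign a >= 1/tau > 0 always, the literal-sign
        # variant can drive a through zero and needs the linear fallback
        a = inv_tau - sign * G
        b = neuron.V_R * inv_tau - sign * G * neuron.V_E
        v_old = v.copy()
        if cfg.literal_sign:
            small = np.abs(a) < 1e-12
            a_safe = np.where(small, 1.0, a)
            v_inf = b / a_safe
            v = v_inf + (v_old - v_inf) * np.exp(-a * dt)
            if np.any(small):
                v[small] = v_old[small] + b[small] * dt
        else:
            v_inf = b / a
            v = v_inf + (v_old - v_inf) * np.exp(-a * dt)

        # remaining half step of the conductance filters
        _advance_filter(hS, gS, half_S, hdt_S)
        _advance_filter(hE, gE, half_E, hdt_E)

        # threshold crossings: interpolate the crossing time, record, reset,
        # then integrate the remainder of the step from the reset value so
        # sampled voltages stay meaningful in high-rate regimes
        fired = np.nonzero(v >= neuron.V_T)[0]
        if fired.size:
            dv = v[fired] - v_old[fired]
            frac = np.clip((neuron.V_T - v_old[fired]) / np.where(dv > 0, dv, 1.0),
                           0.0, 1.0)
            ts = t + dt * frac
            spike_neurons.append(fired)
            spike_times.append(ts)
            rest = (1.0 - frac) * dt
            vf = v_inf[fired]
            # the continuation may re-reach threshold under extreme drive;
            # the neuron then fires again at the next step boundary, so the
            # per-neuron rate is bounded by 1/dt
            v[fired] = vf + (neuron.V_R - vf) * np.exp(-a[fired] * rest)
            pending_lag = rest
        pending = fired

        if (step + 1) % record_every == 0:
            rec_times[rec_i] = (step + 1) * dt
            by_region = v.reshape(z, m)
            rec_L[rec_i] = by_region.mean(axis=1)
            rec_Lg[rec_i] = v.mean()
            if rec_V is not None:
                rec_V[rec_i] = v
            rec_i += 1

        if step % 200 == 0 and not np.all(np.isfinite(v)):
            bad = int(np.nonzero(~np.isfinite(v))[0][0])
            raise FloatingPointError(
                f"non-finite membrane potential at t={t:.2f} ms (neuron {bad})"
            )

    if not np.all(np.isfinite(v)):
        bad = int(np.nonzero(~np.isfinite(v))[0][0])
        raise FloatingPointError(
            f"non-finite membrane potential at end of run (neuron {bad})"
        )

    if spike_times:
        all_n = np.concatenate(spike_neurons)
        all_t = np.concatenate(spike_times)
        order = np.argsort(all_t, kind="stable")
        raster = SpikeRaster(all_n[order], all_t[order], layout)
    else:
        raster = SpikeRaster(np.empty(0, np.int64), np.empty(0), layout)

    traces = RegionalTraces(times=rec_times, L=rec_L, L_global=rec_Lg)
    voltages = VoltageTraces(times=rec_times, V=rec_V) if rec_V is not None else None
    return SimResult(raster=raster, traces=traces, voltages=voltages, region_weights=w)


# ---------------------------------------------------------------------------
# External interfaces: CSV rasters and traces, optional HDF5 voltage dumps


def write_raster_csv(raster: SpikeRaster, path: str | Path) -> None:
    raster.to_dataframe().to_csv(path, index=False)


def read_raster_csv(path: str | Path, layout: RegionLayout | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    return SpikeRaster(
        df["neuron_id"].to_numpy(np.int64), df["time_ms"].to_numpy(float), layout
    )


def write_traces_csv(traces: RegionalTraces, path: str | Path) -> None:
    cols = {"time_ms": traces.times}
    for i in range(traces.z):
        cols[f"L_{i}"] = traces.L[:, i]
    cols["L_global"] = traces.L_global
    pd.DataFrame(cols).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> RegionalTraces:
    df = pd.read_csv(path)
    lcols = [c for c in df.columns if c.startswith("L_") and c != "L_global"]
    lcols.sort(key=lambda c: int(c.split("_")[1]))
    return RegionalTraces(
        times=df["time_ms"].to_numpy(float),
        L=df[lcols].to_numpy(float),
        L_global=df["L_global"].to_numpy(float),
    )


def write_voltages_h5(voltages: VoltageTraces, path: str | Path) -> None:
    """Optional full voltage dump (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=voltages.times)
        f.create_dataset("V", data=voltages.V, compression="gzip")
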