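"""Pulsatile network hemodynamics via Womersley harmonic superposition.

The inlet waveform is a periodic modulation of the measured mean
velocities (mean factor 1 plus a small set of complex harmonics).  Since
the reduced model is linear (rigid walls, no-slip, laminar, convective
acceleration neglected), each harmonic is solved independently:

* harmonic 0 is the steady Poiseuille solve;
* harmonic k uses complex segment impedances from the rigid-tube
  Womersley solution

      Z(w) = (i w rho L / (pi r^2)) * [1 - 2 J1(L) / (L J0(L))]^{-1},
      L = i^{3/2} alpha,   alpha = r sqrt(w / nu),

  with boundary flows scaled by the harmonic amplitude (the outlet
  area-proportional split is frequency independent, so it holds at every
  instant).

Time snapshots are reconstructed on a uniform periodic grid and the
cycle average of every flow equals the harmonic-0 solution by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

from .network import SectionPlane, VascularNetwork, equivalent_radius
from .steady import (BloodProperties, InletConditions, PressureFlowState,
                     boundary_flows, segment_conductance, solve_network,
                     solve_steady)
from .units import PA_PER_MMHG, mm_s_to_cm_s

DEFAULT_PERIOD_S = 0.137   # one murine cardiac cycle
DEFAULT_TIME_STEP_S = 0.005


class WaveformError(ValueError):
    pass


@dataclass
class Waveform:
    """Dimensionless periodic velocity modulation, mean exactly 1.

    ``harmonics`` is a list of (order k >= 1, complex amplitude c_k); the
    reconstructed factor is  1 + sum_k Re(c_k exp(i 2 pi k t / T)).
    """

    period: float = DEFAULT_PERIOD_S
    harmonics: list[tuple[int, complex]] = field(default_factory=list)

    def __post_init__(self):
        if self.period <= 0:
            raise WaveformError("period must be positive")
        for k, _ in self.harmonics:
            if k < 1:
                raise WaveformError("harmonic orders must be >= 1")

    def reconstruct(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.ones_like(t)
        for k, c in self.harmonics:
            out += np.real(c * np.exp(2j * math.pi * k * t / self.period))
        return out

    def check_positive(self, n_samples: int = 2048) -> bool:
        t = np.linspace(0.0, self.period, n_samples, endpoint=False)
        return bool(np.min(self.reconstruct(t)) > 0.0)

    @classmethod
    def murine_default(cls, n_harmonics: int = 8, period: float = DEFAULT_PERIOD_S,
                       peak_factor: float = 1.6, systole_frac: float = 0.18,
                       width_frac: float = 0.085) -> "Waveform":
        """Parametric murine arterial waveform.

        A periodic Gaussian systolic pulse on a diastolic baseline,
        normalised to mean 1 and scaled so the continuous pulse peaks at
        ``peak_factor`` times the mean, then truncated to the first
        ``n_harmonics`` Fourier harmonics.  A stand-in for a measured
        murine velocity waveform; fully overridable.
        """
        n = 4096
        phase = np.linspace(0.0, 1.0, n, endpoint=False)
        # wrapped Gaussian pulse centred on systole
        d = (phase - systole_frac + 0.5) % 1.0 - 0.5
        pulse = np.exp(-0.5 * (d / width_frac) ** 2)
        pulse -= pulse.mean()
        shape = 1.0 + (peak_factor - 1.0) * pulse / pulse.max()
        coef = np.fft.fft(shape) / n
        harmonics = [(k, 2.0 * complex(coef[k])) for k in range(1, n_harmonics + 1)]
        wf = cls(period=period, harmonics=harmonics)
        if not wf.check_positive():
            raise WaveformError("default waveform reconstruction is not positive")
        return wf


@dataclass(frozen=True)
class TransientConfig:
    """Time discretisation of one cardiac cycle.

    The protocol step (0.005 s) does not divide the 0.137 s cycle; by
    default the grid uses ceil(T/dt) = 28 uniform intervals so that cycle
    averages are exact.  ``strict_grid`` keeps the literal step instead
    (averages then carry an O(dt) windowing error).
    """

    time_step: float = DEFAULT_TIME_STEP_S
    n_harmonics: int = 8
    strict_grid: bool = False
    reject_reversed_inflow: bool = False

    def grid(self, period: float) -> np.ndarray:
        if not 0 < self.time_step < period:
            raise ValueError("need 0 < time_step < period")
        if self.strict_grid:
            return np.arange(0.0, period, self.time_step)
        n = math.ceil(period / self.time_step)
        return np.linspace(0.0, period, n, endpoint=False)


@dataclass
class TimeSeriesState:
    times: np.ndarray
    snapshots: list[PressureFlowState]
    average: PressureFlowState
    harmonic_orders: list[int] = field(default_factory=list)
    harmonic_flows: dict[str, list[complex]] = field(default_factory=dict)
    period: float = DEFAULT_PERIOD_S


def womersley_alpha(radius: float, angular_frequency: float,
                    kinematic_viscosity: float) -> float:
    """Womersley number alpha = r sqrt(w / nu) (dimensionless)."""
    if radius <= 0 or angular_frequency <= 0 or kinematic_viscosity <= 0:
        raise ValueError("radius, angular frequency and viscosity must be positive")
    return radius * math.sqrt(angular_frequency / kinematic_viscosity)


_ALPHA_OVERFLOW = 600.0


def _lambda(alpha: float) -> complex:
    return 1j ** 1.5 * alpha


def womersley_f(alpha: float) -> complex:
    """F(alpha) = 1 - 2 J1(L)/(L J0(L)) with L = i^{3/2} alpha."""
    lam = _lambda(alpha)
    return 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))


def segment_impedance(seg, blood: BloodProperties, angular_frequency: float) -> complex:
    """Longitudinal impedance of a rigid tube, mmHg per (mm^3/s).

    At w = 0 this is the real Poiseuille resistance; for w > 0 the real
    part stays positive (viscous dissipation) while the imaginary part is
    the fluid inertance contribution.
    """
    if angular_frequency < 0:
        raise ValueError("angular frequency must be >= 0")
    if angular_frequency == 0.0:
        return complex(1.0 / segment_conductance(seg, blood))
    r = equivalent_radius(seg.area)
    alpha = womersley_alpha(r, angular_frequency, blood.kinematic_viscosity)
    if alpha > _ALPHA_OVERFLOW:
        raise OverflowError(
            f"Womersley number {alpha:.1f} too large for Bessel evaluation; "
            "split the segment or reduce the harmonic order")
    z_pa = (1j * angular_frequency * blood.density * seg.length
            / (math.pi * r ** 2)) / womersley_f(alpha)
    return z_pa / PA_PER_MMHG


def solve_transient(net: VascularNetwork, inlets: InletConditions,
                    blood: BloodProperties, waveform: Waveform | None = None,
                    cfg: TransientConfig | None = None) -> TimeSeriesState:
    """Harmonic-superposition pulsatile solve over one cardiac cycle."""
    waveform = waveform if waveform is not None else Waveform.murine_default()
    cfg = cfg if cfg is not None else TransientConfig()

    if not waveform.check_positive():
        msg = "waveform reconstruction reverses inlet flow within the cycle"
        if cfg.reject_reversed_inflow:
            raise WaveformError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)

    dc = solve_steady(net, inlets, blood)
    bnd = boundary_flows(net, inlets)

    seg_ids = list(net.segments)
    node_ids = list(net.nodes)
    amp = dict(waveform.harmonics[:cfg.n_harmonics])
    harmonic_orders = sorted(amp)
    harmonic_flows: dict[str, list[complex]] = {sid: [] for sid in seg_ids}
    harmonic_press: dict[str, list[complex]] = {nid: [] for nid in node_ids}
    for k in harmonic_orders:
        w = 2.0 * math.pi * k / waveform.period
        adm = {seg.id: 1.0 / segment_impedance(seg, blood, w)
               for seg in net.segments.values()}
        bnd_k = {nid: amp[k] * q for nid, q in bnd.items()}
        st = solve_network(net, adm, bnd_k)
        for sid in seg_ids:
            harmonic_flows[sid].append(st.flows[sid])
        for nid in node_ids:
            harmonic_press[nid].append(st.pressures[nid])

    times = cfg.grid(waveform.period)
    snapshots: list[PressureFlowState] = []
    for t in times:
        phase = {k: np.exp(2j * math.pi * k * t / waveform.period)
                 for k in harmonic_orders}
        flows = {
            sid: dc.flows[sid] + sum(
                float(np.real(qk * phase[k]))
                for k, qk in zip(harmonic_orders, harmonic_flows[sid]))
            for sid in seg_ids
        }
        pressures = {
            nid: dc.pressures[nid] + sum(
                float(np.real(pk * phase[k]))
                for k, pk in zip(harmonic_orders, harmonic_press[nid]))
            for nid in node_ids
        }
        factor = float(waveform.reconstruct(np.array([t]))[0])
        bnd_t = {nid: q * factor for nid, q in bnd.items()}
        snapshots.append(PressureFlowState(pressures=pressures, flows=flows,
                                           boundary=bnd_t))

    avg = PressureFlowState(
        pressures={nid: float(np.mean([s.pressures[nid] for s in snapshots]))
                   for nid in node_ids},
        flows={sid: float(np.mean([s.flows[sid] for s in snapshots]))
               for sid in seg_ids},
        boundary=dict(bnd),
    )
    return TimeSeriesState(times=times, snapshots=snapshots, average=avg,
                           harmonic_orders=harmonic_orders,
                           harmonic_flows=harmonic_flows, period=waveform.period)


def womersley_profile_shape(alpha: float, y: np.ndarray) -> np.ndarray:
    """Flow-normalised oscillatory profile u(y)/u_mean at radial fractions y.

    u(y)/u_mean = [1 - J0(L y)/J0(L)] / F(alpha); the parabolic 2(1-y^2)
    limit is recovered as alpha -> 0.
    """
    lam = _lambda(alpha)
    return (1.0 - jv(0, lam * np.asarray(y)) / jv(0, lam)) / womersley_f(alpha)


def max_velocity(state, net: VascularNetwork, section: SectionPlane | int,
                 blood: BloodProperties, mode: str = "steady",
                 n_radial: int = 200) -> float:
    """Peak velocity magnitude (cm/s) over the sectional plane.

    steady mode: the Poiseuille profile peak, 2x the mean velocity.
    transient mode: the Womersley radial profile is reconstructed from the
    per-harmonic segment flows at each time on ``n_radial`` radial points,
    its spatial maximum taken per snapshot, and the result cycle-averaged.
    """
    if isinstance(section, int):
        section = net.sections[section]
    if section.area <= 0:
        raise ValueError("section area must be positive")

    if mode == "steady":
        if not isinstance(state, PressureFlowState):
            state = state.average
        v_mean = state.flows[section.segment_id] / section.area  # mm/s
        return mm_s_to_cm_s(2.0 * abs(v_mean))

    if mode != "transient":
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(state, TimeSeriesState):
        raise TypeError("transient mode needs a TimeSeriesState")

    sid = section.segment_id
    seg = net.segments[sid]
    y = np.linspace(0.0, 1.0, n_radial)
    profile_dc = 2.0 * (1.0 - y ** 2) * (state.average.flows[sid] / section.area)

    # per-harmonic profiles scaled by that harmonic's mean-velocity amplitude;
    # alpha is evaluated with the carrying segment's radius
    shapes = []
    for k, qk in zip(state.harmonic_orders, state.harmonic_flows[sid]):
        w = 2.0 * math.pi * k / state.period
        alpha = womersley_alpha(equivalent_radius(seg.area), w, blood.kinematic_viscosity)
        shapes.append((k, womersley_profile_shape(alpha, y) * (qk / section.area)))

    peaks = []
    for t in state.times:
        u = profile_dc.copy()
        for k, prof in shapes:
            u = u + np.real(prof * np.exp(2j * math.pi * k * t / state.period))
        peaks.append(np.max(np.abs(u)))
    return mm_s_to_cm_s(float(np.mean(peaks)))
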