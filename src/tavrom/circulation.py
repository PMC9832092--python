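"""Closed-loop reduced-order model of the left heart and systemic afterload.

The model couples a time-varying elastance description of the left atrium
(LA) and left ventricle (LV) to a three-element Windkessel afterload through
a lumped aortic-valve surrogate.  Chamber pressures follow ``P = E(t) * Vhat``
where ``Vhat = C(t) * P`` is the volume-like state actually integrated, so the
atrial and ventricular balance laws

    d(C_LA P_LA)/dt = Q_vein - Q_MV
    d(C_LV P_LV)/dt = Q_MV - Q_LVOT

integrate exactly as written without differentiating the compliance
waveforms.  The mitral valve is an ideal diode with series resistance; the
aortic valve is a diode plus Gorlin-type orifice (or linear resistance)
standing in for a full 3D fluid-structure valve model.  Both valve states are
lagged: they are updated once per time step from the previous step's
pressures, with no event location.

Units: pressures mmHg, flows mL/s, volumes mL, resistances mmHg*s/mL,
compliances mL/mmHg, elastances mmHg/mL, times s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TwoHillElastance",
    "CirculationParams",
    "ValveSurrogate",
    "CirculationModel",
    "CirculationResult",
    "CycleMetrics",
    "WaveformSet",
    "default_circulation_params",
    "mitral_flow",
    "solve_aortic_flow",
    "valve_pressure_drop",
    "prescribed_flow_experiment",
    "synth_flow_waveform",
]

#: Gorlin-type constant linking flow (mL/s), pressure (mmHg) and area (cm^2).
GORLIN_CONSTANT = 51.6

# grid resolution used to normalize the two-Hill waveform peak
_NORMALIZATION_GRID = 100_000


@dataclass
class TwoHillElastance:
    """Two-Hill chamber elastance waveform ``E(t) = k*h(t) + Emin``.

    The shape factor is a product of an activating and a deactivating Hill
    sigmoid,

        h(t) = [g1/(1+g1)] * [1/(1+g2)],   g_i = (t/tau_i)^m_i,

    and the gain ``k = (Emax - Emin)/max h`` is normalized numerically on a
    fine grid so the waveform's maximum over one period equals ``Emax``
    exactly (to grid resolution).  ``phase_shift_s`` delays the waveform:
    the shape is evaluated at ``(t - phase_shift_s) mod T``.

    Parameters are stored in seconds / mmHg/mL; :meth:`from_fractions`
    accepts the conventional tau-as-fraction-of-period parameterization.
    """

    tau1_s: float
    tau2_s: float
    m1: float
    m2: float
    Emin: float
    Emax: float
    T: float
    phase_shift_s: float = 0.0
    _gain: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.tau1_s > 0 and self.tau2_s > 0 and self.T > 0):
            raise ValueError("tau1, tau2 and T must be positive")
        if not self.Emax > self.Emin > 0:
            raise ValueError("require Emax > Emin > 0")

    @classmethod
    def from_fractions(
        cls,
        tau1_frac: float,
        tau2_frac: float,
        m1: float,
        m2: float,
        Emin: float,
        Emax: float,
        T: float,
        phase_shift_s: float = 0.0,
    ) -> "TwoHillElastance":
        """Build from tau values expressed as fractions of the period T."""
        return cls(tau1_frac * T, tau2_frac * T, m1, m2, Emin, Emax, T, phase_shift_s)

    def shifted(self, phase_shift_s: float) -> "TwoHillElastance":
        return replace(self, phase_shift_s=phase_shift_s, _gain=self._gain)

    def shape(self, t):
        """Un-normalized two-Hill shape factor h(t) on the raw time axis."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            g1 = (t / self.tau1_s) ** self.m1
            g2 = (t / self.tau2_s) ** self.m2
        return (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2))

    @property
    def gain(self) -> float:
        """Normalization gain k = (Emax - Emin)/max h, cached."""
        if self._gain is None:
            tt = np.linspace(0.0, self.T, _NORMALIZATION_GRID, endpoint=False)
            self._gain = (self.Emax - self.Emin) / float(np.max(self.shape(tt)))
        return self._gain

    def __call__(self, t):
        """Elastance E(t) in mmHg/mL; periodic with period T."""
        tloc = np.mod(np.asarray(t, dtype=float) - self.phase_shift_s, self.T)
        return self.gain * self.shape(tloc) + self.Emin


@dataclass
class CirculationParams:
    """All constants of the coupled left-heart + Windkessel model."""

    Qvein_mL_s: float
    Rmv: float
    Rlvot: float
    Rc: float
    Rp: float
    Cwk: float
    T: float
    elastance_lv: TwoHillElastance
    elastance_la: TwoHillElastance
    #: LA activation delay relative to the LV waveform, as a fraction of T.
    la_shift_frac: float = 0.85
    #: "delay" (default) shifts the LA waveform later by la_shift_frac*T;
    #: "advance" applies the opposite sign.
    la_shift_sign: str = "delay"

    def __post_init__(self) -> None:
        if min(self.Rmv, self.Rlvot, self.Rc, self.Rp) < 0:
            raise ValueError("resistances must be nonnegative")
        if self.Cwk <= 0 or self.Qvein_mL_s <= 0:
            raise ValueError("require Cwk > 0 and Qvein > 0")
        if self.la_shift_sign not in ("delay", "advance"):
            raise ValueError("la_shift_sign must be 'delay' or 'advance'")

    def la_elastance(self) -> TwoHillElastance:
        """LA elastance with the configured phase shift applied."""
        shift = self.la_shift_frac * self.T
        if self.la_shift_sign == "advance":
            shift = -shift
        return self.elastance_la.shifted(shift)


def default_circulation_params() -> CirculationParams:
    """Parameter set calibrated to human ventricular/aortic pressure-flow data.

    Venous return 5.8 L/min; cardiac period 0.8512 s; LV elastance
    (tau1, tau2) = (0.0725, 0.4503) T with exponents (2.7463, 21.5683) and
    (Emin, Emax) = (0.01, 0.1191) mmHg/mL; LA elastance (0.1150, 0.1882) T,
    (1.32, 13.1), (0.08, 0.17) mmHg/mL, delayed by 0.85 T.
    """
    T = 0.8512
    elv = TwoHillElastance.from_fractions(0.0725, 0.4503, 2.7463, 21.5683, 0.01, 0.1191, T)
    ela = TwoHillElastance.from_fractions(0.1150, 0.1882, 1.32, 13.1, 0.08, 0.17, T)
    return CirculationParams(
        Qvein_mL_s=5800.0 / 60.0,
        Rmv=0.005,
        Rlvot=0.0043,
        Rc=0.042,
        Rp=0.9046,
        Cwk=1.9504,
        T=T,
        elastance_lv=elv,
        elastance_la=ela,
    )


@dataclass
class ValveSurrogate:
    """Lumped aortic-valve pressure-flow law.

    kind="orifice": quadratic Gorlin orifice, dP = (Q / (51.6 * EOA))^2.
    kind="linear_resistance": dP = R * Q.
    kind="ideal_diode": no forward drop.
    All kinds are diodes: a closed valve carries zero forward flow and the
    open/closed state is updated lagged by the integrator.
    """

    kind: str = "orifice"
    EOA_cm2: float = 1.5
    R: float = 0.0
    gorlin_constant: float = GORLIN_CONSTANT

    def __post_init__(self) -> None:
        if self.kind not in ("orifice", "linear_resistance", "ideal_diode"):
            raise ValueError(f"unknown valve kind {self.kind!r}")
        if self.kind == "orifice" and not self.EOA_cm2 > 0:
            raise ValueError("orifice valve requires EOA_cm2 > 0")
        if self.kind == "linear_resistance" and self.R < 0:
            raise ValueError("linear valve requires R >= 0")


def mitral_flow(P_LA: float, P_LV: float, Rmv: float) -> float:
    """Instantaneous mitral diode flow: 0 for P_LA <= P_LV, else dP/Rmv."""
    if Rmv <= 0:
        raise ValueError("Rmv must be positive")
    return 0.0 if P_LA <= P_LV else (P_LA - P_LV) / Rmv


def solve_aortic_flow(
    P_LV: float,
    P_Wk: float,
    params: CirculationParams,
    valve: ValveSurrogate,
    open_state: bool = True,
) -> float:
    """Flow through the open aortic valve surrogate.

    For the orifice kind the flow is the nonnegative root of

        (Q / (51.6 EOA))^2 + (Rlvot + Rc) Q - (P_LV - P_Wk) = 0,

    solved in closed form.  Returns 0 for a closed valve or nonpositive
    driving pressure (the caller closes the valve on the next step).
    """
    if not open_state:
        return 0.0
    dp = P_LV - P_Wk
    if dp <= 0.0:
        return 0.0
    r_series = params.Rlvot + params.Rc
    if valve.kind == "orifice":
        a = 1.0 / (valve.gorlin_constant * valve.EOA_cm2) ** 2
        # aQ^2 + bQ - dp = 0, positive root
        return (-r_series + math.sqrt(r_series * r_series + 4.0 * a * dp)) / (2.0 * a)
    if valve.kind == "linear_resistance":
        return dp / (r_series + valve.R)
    # ideal diode
    if r_series <= 0:
        raise ValueError("ideal diode with zero series resistance is ill-posed")
    return dp / r_series


@dataclass
class WaveformSet:
    """Uniformly sampled pressure/flow traces over the whole simulation."""

    t: np.ndarray
    P_LA: np.ndarray
    P_LV: np.ndarray
    P_LVOT: np.ndarray
    P_Ao: np.ndarray
    P_Wk: np.ndarray
    Q_MV: np.ndarray
    Q_LVOT: np.ndarray
    av_open: np.ndarray
    mv_open: np.ndarray
    T: float
    dt: float
    steps_per_cycle: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "P_LA_mmHg": self.P_LA,
                "P_LV_mmHg": self.P_LV,
                "P_LVOT_mmHg": self.P_LVOT,
                "P_Ao_mmHg": self.P_Ao,
                "P_Wk_mmHg": self.P_Wk,
                "Q_MV_mLs": self.Q_MV,
                "Q_LVOT_mLs": self.Q_LVOT,
            }
        )

    def final_cycle(self) -> "WaveformSet":
        """Slice containing only the last full cycle."""
        n = self.steps_per_cycle
        sl = slice(len(self.t) - n, len(self.t))
        return WaveformSet(
            self.t[sl], self.P_LA[sl], self.P_LV[sl], self.P_LVOT[sl],
            self.P_Ao[sl], self.P_Wk[sl], self.Q_MV[sl], self.Q_LVOT[sl],
            self.av_open[sl], self.mv_open[sl], self.T, self.dt, n,
        )


@dataclass
class CycleMetrics:
    """Clinical summary metrics of one converged cardiac cycle."""

    SV_mL: float
    CO_L_min: float
    mean_systolic_dP_mmHg: float
    peak_diastolic_dP_mmHg: float
    EOA_cm2: float
    cycle_index: int
    convergence_residual_mmHg: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "SV_mL": self.SV_mL,
            "CO_L_min": self.CO_L_min,
            "mean_systolic_dP_mmHg": self.mean_systolic_dP_mmHg,
            "peak_diastolic_dP_mmHg": self.peak_diastolic_dP_mmHg,
            "EOA_cm2": self.EOA_cm2,
            "cycle_index": self.cycle_index,
            "convergence_residual_mmHg": self.convergence_residual_mmHg,
            "converged": self.converged,
        }


def cycle_metrics(w: WaveformSet, T: float | None = None) -> CycleMetrics:
    """Compute stroke volume, cardiac output, transvalvular gradients and EOA.

    Systole is the set of samples with forward aortic flow; the mean systolic
    gradient averages ``P_LVOT - P_Ao`` over that window.  The peak diastolic
    gradient is the maximum of ``P_Ao - P_LVOT`` over closed-valve samples.
    The effective orifice area follows the Gorlin-type continuity convention
    ``EOA = Q_rms,systole / (51.6 sqrt(mean systolic dP))``.
    """
    if T is None:
        T = w.T
    cyc = w.final_cycle()
    q = cyc.Q_LVOT
    sys_mask = q > 0.0
    if not np.any(sys_mask):
        raise ValueError("no systolic samples (aortic flow never positive)")
    sv = float(np.trapezoid(q, cyc.t))
    co = sv * 60.0 / T / 1000.0
    dp = cyc.P_LVOT - cyc.P_Ao
    mean_sys_dp = float(np.mean(dp[sys_mask]))
    dia_mask = ~sys_mask
    peak_dia_dp = float(np.max(-dp[dia_mask])) if np.any(dia_mask) else float("nan")
    q_rms = float(np.sqrt(np.mean(q[sys_mask] ** 2)))
    eoa = q_rms / (GORLIN_CONSTANT * math.sqrt(mean_sys_dp)) if mean_sys_dp > 0 else float("inf")
    return CycleMetrics(
        SV_mL=sv,
        CO_L_min=co,
        mean_systolic_dP_mmHg=mean_sys_dp,
        peak_diastolic_dP_mmHg=peak_dia_dp,
        EOA_cm2=eoa,
        cycle_index=-1,
        convergence_residual_mmHg=float("nan"),
        converged=True,
    )


class CirculationModel:
    """Closed-loop circulation model; ``simulate()`` returns the fitted orbit.

    Parameters
    ----------
    params : CirculationParams
    valve : ValveSurrogate
        Aortic-valve surrogate coupled between the LVOT and the Windkessel.
    """

    def __init__(self, params: CirculationParams | None = None,
                 valve: ValveSurrogate | None = None):
        self.params = params if params is not None else default_circulation_params()
        self.valve = valve if valve is not None else ValveSurrogate()

    def simulate(
        self,
        n_cycles: int = 20,
        dt: float = 1e-4,
        convergence_tol_mmHg: float = 0.5,
        P_Wk0: float = 80.0,
        P_LA0: float = 10.0,
        P_LV0: float = 8.0,
    ) -> "CirculationResult":
        """Integrate to a periodic orbit with classical fixed-step RK4.

        The step is snapped to an integer divisor of the period so cycles
        align sample-for-sample; valve states are updated once per step from
        the previous step's pressures (lagged).  Integration stops when the
        cycle-to-cycle maximum change of aortic pressure falls below
        ``convergence_tol_mmHg`` or after ``n_cycles``.
        """
        if dt > 1e-3:
            raise ValueError("dt must be <= 1e-3 s")
        if n_cycles < 2:
            raise ValueError("need n_cycles >= 2")
        p = self.params
        valve = self.valve
        n_per = int(round(p.T / dt))
        dt = p.T / n_per

        # Periodic elastance tables at half-step resolution for the RK4 stages.
        elv = p.elastance_lv
        ela = p.la_elastance()
        t_half = np.arange(2 * n_per) * (dt / 2.0)
        Elv_tab = np.asarray(elv(t_half))
        Ela_tab = np.asarray(ela(t_half))

        # volume-like states Vhat = C(t) P = P / E(t)
        y = np.array([P_LA0 / Ela_tab[0], P_LV0 / Elv_tab[0], P_Wk0])

        max_steps = n_cycles * n_per
        t_out = np.arange(max_steps) * dt
        P_LA = np.empty(max_steps)
        P_LV = np.empty(max_steps)
        P_LVOT = np.empty(max_steps)
        P_Ao = np.empty(max_steps)
        P_Wk = np.empty(max_steps)
        Q_MV = np.empty(max_steps)
        Q_LVOT = np.empty(max_steps)
        av_tr = np.empty(max_steps, dtype=bool)
        mv_tr = np.empty(max_steps, dtype=bool)

        Qvein, Rmv, Rlvot, Rc, Rp, Cwk = p.Qvein_mL_s, p.Rmv, p.Rlvot, p.Rc, p.Rp, p.Cwk
        av_open = False
        mv_open = P_LA0 > P_LV0

        def rhs(yv, ela_t, elv_t, mv_o, av_o):
            pla = yv[0] * ela_t
            plv = yv[1] * elv_t
            pwk = yv[2]
            qmv = max((pla - plv) / Rmv, 0.0) if mv_o else 0.0
            qlv = solve_aortic_flow(plv, pwk, p, valve, av_o)
            return (
                np.array([Qvein - qmv, qmv - qlv, (qlv - pwk / Rp) / Cwk]),
                qmv,
                qlv,
            )

        residual = float("inf")
        n_done = 0
        for i in range(max_steps):
            j = (i % n_per) * 2
            ela0, elv0 = Ela_tab[j], Elv_tab[j]
            ela1, elv1 = Ela_tab[j + 1], Elv_tab[j + 1]
            j2 = (j + 2) % (2 * n_per)
            ela2, elv2 = Ela_tab[j2], Elv_tab[j2]

            # lagged valve states from previous-step pressures
            pla = y[0] * ela0
            plv = y[1] * elv0
            pwk = y[2]
            mv_open = pla > plv
            av_open = plv > pwk

            k1, qmv0, qlv0 = rhs(y, ela0, elv0, mv_open, av_open)
            k2, _, _ = rhs(y + 0.5 * dt * k1, ela1, elv1, mv_open, av_open)
            k3, _, _ = rhs(y + 0.5 * dt * k2, ela1, elv1, mv_open, av_open)
            k4, _, _ = rhs(y + dt * k3, ela2, elv2, mv_open, av_open)

            P_LA[i] = pla
            P_LV[i] = plv
            P_Wk[i] = pwk
            Q_MV[i] = qmv0
            Q_LVOT[i] = qlv0
            P_LVOT[i] = plv - qlv0 * Rlvot
            P_Ao[i] = pwk + qlv0 * Rc
            av_tr[i] = av_open
            mv_tr[i] = mv_open

            y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError(
                    f"non-finite circulation state at t = {i * dt:.4f} s: {y}"
                )

            if (i + 1) % n_per == 0:
                n_done = (i + 1) // n_per
                if n_done >= 2:
                    a = P_Ao[i + 1 - n_per : i + 1]
                    b = P_Ao[i + 1 - 2 * n_per : i + 1 - n_per]
                    residual = float(np.max(np.abs(a - b)))
                    if residual < convergence_tol_mmHg:
                        break

        end = n_done * n_per
        waves = WaveformSet(
            t_out[:end], P_LA[:end], P_LV[:end], P_LVOT[:end], P_Ao[:end],
            P_Wk[:end], Q_MV[:end], Q_LVOT[:end], av_tr[:end], mv_tr[:end],
            p.T, dt, n_per,
        )
        converged = residual < convergence_tol_mmHg
        metrics = cycle_metrics(waves)
        metrics.cycle_index = n_done
        metrics.convergence_residual_mmHg = residual
        metrics.converged = converged
        return CirculationResult(self, waves, metrics)


@dataclass
class CirculationResult:
    """Result of a closed-loop simulation: waveforms plus cycle metrics."""

    model: CirculationModel
    waveforms: WaveformSet
    metrics: CycleMetrics

    def summary(self) -> str:
        m = self.metrics
        p = self.model.params
        v = self.model.valve
        lines = [
            "Closed-loop circulation (elastance left heart + 3-element Windkessel)",
            "=" * 70,
            f"period T        : {p.T:.4f} s    valve: {v.kind}"
            + (f" (EOA = {v.EOA_cm2:.2f} cm^2)" if v.kind == "orifice" else ""),
            f"cycles run      : {m.cycle_index}  (converged: {m.converged}, "
            f"residual {m.convergence_residual_mmHg:.3f} mmHg)",
            "-" * 70,
            f"stroke volume   : {m.SV_mL:8.2f} mL",
            f"cardiac output  : {m.CO_L_min:8.2f} L/min",
            f"mean systolic transvalvular dP : {m.mean_systolic_dP_mmHg:6.2f} mmHg",
            f"peak diastolic transvalvular dP: {m.peak_diastolic_dP_mmHg:6.2f} mmHg",
            f"effective orifice area (EOA)   : {m.EOA_cm2:6.2f} cm^2",
            "=" * 70,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# prescribed-flow experiment


def valve_pressure_drop(Q, valve: ValveSurrogate, R_series: float = 0.0):
    """Transvalvular pressure drop dP(Q) for forward flow through the valve."""
    Q = np.asarray(Q, dtype=float)
    if valve.kind == "orifice":
        dp = (Q / (valve.gorlin_constant * valve.EOA_cm2)) ** 2 + Q * R_series
    elif valve.kind == "linear_resistance":
        dp = Q * (valve.R + R_series)
    else:
        dp = Q * R_series
    return dp


def synth_flow_waveform(
    SV_mL: float = 45.32,
    t_ej_s: float = 0.3,
    T_s: float = 0.7836,
    n: int = 2000,
) -> pd.DataFrame:
    """Half-sine systolic flow pulse with exact stroke volume.

    Emulates a prescribed transvalvular flow experiment on a patient with
    severe aortic stenosis awaiting replacement: stroke volume 45.32 mL at a
    cardiac output of 3.47 L/min (hence T = 0.7836 s), ejected in a single
    half-sine pulse of duration ``t_ej_s``.  Q(t) = pi*SV/(2 t_ej) *
    sin(pi t / t_ej) on [0, t_ej], zero on [t_ej, T).
    """
    if not 0 < t_ej_s < T_s:
        raise ValueError("require 0 < t_ej < T")
    t = np.linspace(0.0, T_s, n, endpoint=False)
    q = np.where(
        t < t_ej_s,
        (math.pi * SV_mL / (2.0 * t_ej_s)) * np.sin(math.pi * np.minimum(t, t_ej_s) / t_ej_s),
        0.0,
    )
    q = np.maximum(q, 0.0)
    return pd.DataFrame({"t_s": t, "Q_mLs": q})


def prescribed_flow_experiment(
    flow: pd.DataFrame,
    valves: dict[str, ValveSurrogate],
    R_series: float = 0.0,
) -> dict[str, dict]:
    """Drive each valve surrogate with a common flow waveform.

    For every valve, evaluates the transvalvular pressure-drop waveform
    sample by sample and summarizes the mean systolic gradient (over samples
    with Q > 0) and the continuity-equation EOA.  Returns
    ``{name: {"dP_mmHg": array, "mean_systolic_dP_mmHg": float,
    "EOA_cm2": float}}``.
    """
    t = np.asarray(flow["t_s"], dtype=float)
    q = np.asarray(flow["Q_mLs"], dtype=float)
    if np.any(q < 0):
        raise ValueError("prescribed flow must be nonnegative")
    out: dict[str, dict] = {}
    sys_mask = q > 0
    for name, valve in valves.items():
        dp = valve_pressure_drop(q, valve, R_series)
        if np.any(sys_mask):
            mean_dp = float(np.mean(dp[sys_mask]))
            q_rms = float(np.sqrt(np.mean(q[sys_mask] ** 2)))
            eoa = (
                q_rms / (GORLIN_CONSTANT * math.sqrt(mean_dp))
                if mean_dp > 0
                else float("inf")
            )
        else:
            mean_dp, eoa = 0.0, float("inf")
        out[name] = {
            "t_s": t,
            "dP_mmHg": dp,
            "mean_systolic_dP_mmHg": mean_dp,
            "EOA_cm2": eoa,
        }
    return out
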