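"""Beam-spring network model of a self-expanding stent frame.

The stent is a Lagrangian point cloud on a cylindrical diamond-cell lattice.
Adjacent rings are connected by diagonal struts modeled as linear springs,

    E_spring = k/2 (l - l0)^2,

and the zig-zag vertical curves carry a discrete bending energy penalizing
deviation of the second-difference magnitude from its rest value,

    E_beam = kb/2 (|x_{a} - 2 x_{b} + x_{c}| - |d2_ref|)^2,

which is invariant under rigid rotation and translation.  The rest lengths
and rest curvatures are taken from the generated geometry, so the nominal
(expanded) configuration is an exact equilibrium: the stent is
self-expanding and returns to it when released from any crimped state.

Crimping is performed by a cylindrical crimper realized as a radial penalty
barrier: a contracting radius r(t) moving inward at constant speed, with
nodes outside r(t) tethered back to it by a stiff spring constant
(default 3.0e8 dyne/cm, moving at 50.0 cm/s).  Dynamics are overdamped
(first-order gradient flow), appropriate because only equilibria and
quasi-static paths are of interest.

Units are CGS: cm, dyne, dyne/cm, erg, seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StentFrame",
    "Crimper",
    "synthesize_frame",
    "elastic_forces",
    "elastic_energy",
    "crimp",
    "release_and_expand",
    "diameter_metrics",
]

MM_PER_FR = 1.0 / 3.0


@dataclass
class StentFrame:
    """Lagrangian stent frame: nodes plus spring and beam connectivity."""

    nodes: np.ndarray          # (N, 3) current positions, cm
    reference: np.ndarray      # (N, 3) rest positions, cm
    springs: np.ndarray        # (M, 2) node index pairs
    spring_k: np.ndarray       # (M,) dyne/cm
    spring_rest: np.ndarray    # (M,) cm
    beams: np.ndarray          # (B, 3) node index triples (a, b, c)
    beam_k: np.ndarray         # (B,) dyne/cm (per second-difference length)
    beam_rest: np.ndarray      # (B,) rest |second difference|, cm
    damping: float = 1.0e4     # dyne*s/cm, isotropic per node

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.springs.size and (self.springs.min() < 0 or self.springs.max() >= n):
            raise ValueError("spring connectivity references invalid nodes")
        if self.beams.size and (self.beams.min() < 0 or self.beams.max() >= n):
            raise ValueError("beam connectivity references invalid nodes")

    def copy(self) -> "StentFrame":
        return StentFrame(
            self.nodes.copy(), self.reference.copy(), self.springs,
            self.spring_k, self.spring_rest, self.beams, self.beam_k,
            self.beam_rest, self.damping,
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class Crimper:
    """Contracting radial barrier emulating a crimping device.

    The barrier radius moves inward at ``radial_speed_cm_s`` until
    ``stop_radius_cm``; nodes outside it feel a stiff radial tether force
    ``-tether_stiffness * (rho - r(t))`` toward the axis.
    """

    stop_radius_cm: float
    radial_speed_cm_s: float = 50.0
    tether_stiffness: float = 3.0e8
    axial_extent_cm: float = math.inf

    def __post_init__(self) -> None:
        if not self.stop_radius_cm > 0:
            raise ValueError("stop_radius must be positive")
        if not self.radial_speed_cm_s > 0:
            raise ValueError("radial_speed must be positive")


def synthesize_frame(
    n_circumferential: int = 12,
    n_rows: int = 5,
    diameter_mm: float = 26.0,
    height_mm: float = 45.0,
    spring_k: float = 1.0e5,
    beam_k: float = 1.0e3,
    damping: float = 1.0e4,
) -> StentFrame:
    """Idealized cylindrical diamond-cell lattice at the nominal diameter.

    Rings ``r = 0..n_rows`` of ``n_circumferential`` nodes each sit at
    height ``r * height/n_rows``; odd rings are rotated half a cell so the
    diagonal struts form diamond cells.  Each ring also carries
    circumferential chord springs (the crown connections of a laser-cut
    frame), which pin the ring radius and remove the end-ring flaring
    mechanism a pure diamond lattice would have.  Node count is
    ``n_circumferential * (n_rows + 1)``.  Rest lengths and curvatures are
    measured from this geometry, so the generated frame is exactly at
    equilibrium.
    """
    if n_circumferential < 3 or n_rows < 1:
        raise ValueError("need n_circumferential >= 3 and n_rows >= 1")
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("degenerate stent dimensions")
    R = diameter_mm / 20.0  # radius in cm
    dz = height_mm / 10.0 / n_rows
    nc = n_circumferential
    dphi = 2.0 * math.pi / nc

    def idx(r, j):
        return r * nc + (j % nc)

    pts = np.zeros(((n_rows + 1) * nc, 3))
    for r in range(n_rows + 1):
        off = 0.5 * (r % 2)
        for j in range(nc):
            phi = (j + off) * dphi
            pts[idx(r, j)] = (R * math.cos(phi), R * math.sin(phi), r * dz)

    springs = []
    for r in range(n_rows):
        step = 1 if r % 2 == 0 else -1
        for j in range(nc):
            springs.append((idx(r, j), idx(r + 1, j)))
            springs.append((idx(r, j), idx(r + 1, j + step)))
    for r in range(n_rows + 1):
        for j in range(nc):
            springs.append((idx(r, j), idx(r, j + 1)))
    springs = np.array(springs, dtype=int)

    # vertical zig-zag curves: straight-index chains (r-1, j), (r, j), (r+1, j)
    beams = []
    for r in range(1, n_rows):
        for j in range(nc):
            beams.append((idx(r - 1, j), idx(r, j), idx(r + 1, j)))
    beams = np.array(beams, dtype=int).reshape(-1, 3)

    d = pts[springs[:, 1]] - pts[springs[:, 0]]
    rest_len = np.linalg.norm(d, axis=1)
    d2 = pts[beams[:, 0]] - 2.0 * pts[beams[:, 1]] + pts[beams[:, 2]]
    rest_curv = np.linalg.norm(d2, axis=1)

    return StentFrame(
        nodes=pts.copy(),
        reference=pts,
        springs=springs,
        spring_k=np.full(len(springs), float(spring_k)),
        spring_rest=rest_len,
        beams=beams,
        beam_k=np.full(len(beams), float(beam_k)),
        beam_rest=rest_curv,
        damping=float(damping),
    )


def elastic_energy(frame: StentFrame, nodes: np.ndarray | None = None) -> float:
    """Total elastic energy (erg) of springs plus discrete bending."""
    x = frame.nodes if nodes is None else nodes
    d = x[frame.springs[:, 1]] - x[frame.springs[:, 0]]
    ln = np.linalg.norm(d, axis=1)
    e = 0.5 * np.sum(frame.spring_k * (ln - frame.spring_rest) ** 2)
    if len(frame.beams):
        d2 = x[frame.beams[:, 0]] - 2.0 * x[frame.beams[:, 1]] + x[frame.beams[:, 2]]
        m = np.linalg.norm(d2, axis=1)
        e += 0.5 * np.sum(frame.beam_k * (m - frame.beam_rest) ** 2)
    return float(e)


def elastic_forces(frame: StentFrame, nodes: np.ndarray | None = None) -> np.ndarray:
    """Per-node elastic force = -grad of :func:`elastic_energy` (dyne)."""
    x = frame.nodes if nodes is None else nodes
    f = np.zeros_like(x)
    i, j = frame.springs[:, 0], frame.springs[:, 1]
    d = x[j] - x[i]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln < 1e-12):
        raise FloatingPointError("coincident nodes in a spring segment")
    t = frame.spring_k * (ln - frame.spring_rest)  # tension, positive if stretched
    fv = (t / ln)[:, None] * d
    np.add.at(f, i, fv)
    np.add.at(f, j, -fv)
    if len(frame.beams):
        a, b, c = frame.beams[:, 0], frame.beams[:, 1], frame.beams[:, 2]
        d2 = x[a] - 2.0 * x[b] + x[c]
        m = np.linalg.norm(d2, axis=1)
        ok = m > 1e-12
        s = np.where(ok, frame.beam_k * (m - frame.beam_rest) / np.where(ok, m, 1.0), 0.0)
        g = s[:, None] * d2  # dE/d(x_a) = s*d2 ; dE/d(x_b) = -2 s d2
        np.add.at(f, a, -g)
        np.add.at(f, b, 2.0 * g)
        np.add.at(f, c, -g)
    return f


def _crimper_forces(nodes: np.ndarray, radius: float, crimper: Crimper) -> np.ndarray:
    rho = np.hypot(nodes[:, 0], nodes[:, 1])
    out = rho > radius
    f = np.zeros_like(nodes)
    if np.any(out):
        scale = -crimper.tether_stiffness * (rho[out] - radius) / rho[out]
        f[out, 0] = scale * nodes[out, 0]
        f[out, 1] = scale * nodes[out, 1]
    return f


def _stable_dt(frame: StentFrame, extra_k: float = 0.0) -> float:
    kmax = max(float(frame.spring_k.max(initial=0.0)),
               6.0 * float(frame.beam_k.max(initial=0.0)),
               extra_k)
    return frame.damping / (4.0 * kmax)


@dataclass
class CrimpResult:
    """Trajectory summary of a crimping or expansion run."""

    frame: StentFrame
    t_s: np.ndarray
    diameter_mm: np.ndarray
    energy_erg: np.ndarray
    snapshots: list = field(default_factory=list)
    converged: bool = True


def crimp(
    frame: StentFrame,
    crimper: Crimper,
    dt: float | None = None,
    settle_time_s: float = 0.01,
    record_every: int = 200,
    keep_snapshots: bool = False,
) -> CrimpResult:
    """Radially crimp the frame with the moving barrier.

    The barrier starts at the frame's current maximum radius and contracts
    at the crimper speed to ``stop_radius_cm``, then holds for
    ``settle_time_s`` while the overdamped dynamics relax the residual
    penetration.  Final penetration past the barrier is bounded by the
    elastic radial force divided by the tether stiffness.
    """
    fr = frame.copy()
    x = fr.nodes
    rho0 = float(np.hypot(x[:, 0], x[:, 1]).max())
    if crimper.stop_radius_cm >= rho0:
        return CrimpResult(fr, np.array([0.0]),
                           np.array([2.0 * rho0 * 10.0]),
                           np.array([elastic_energy(fr)]))
    if dt is None:
        dt = _stable_dt(fr, extra_k=crimper.tether_stiffness)
    t_travel = (rho0 - crimper.stop_radius_cm) / crimper.radial_speed_cm_s
    n_steps = int(math.ceil((t_travel + settle_time_s) / dt))
    ts, dias, ens, snaps = [], [], [], []
    e_prev = elastic_energy(fr)
    for n in range(n_steps + 1):
        t = n * dt
        radius = max(rho0 - crimper.radial_speed_cm_s * t, crimper.stop_radius_cm)
        f = elastic_forces(fr) + _crimper_forces(x, radius, crimper)
        if n % record_every == 0 or n == n_steps:
            e = elastic_energy(fr)
            if e > 10.0 * max(e_prev, 1.0) and radius == crimper.stop_radius_cm:
                raise FloatingPointError(
                    f"crimp dynamics unstable (energy blow-up); retry with dt <= {dt / 4:g}"
                )
            e_prev = max(e_prev, e)
            ts.append(t)
            dias.append(diameter_metrics(fr)["diameter_mm"])
            ens.append(e)
            if keep_snapshots:
                snaps.append(x.copy())
        x += (dt / fr.damping) * f
    return CrimpResult(fr, np.array(ts), np.array(dias), np.array(ens), snaps)


def release_and_expand(
    frame: StentFrame,
    dt: float | None = None,
    t_max_s: float = 2.0,
    force_tol_dyne: float = 1.0,
    record_every: int = 50,
) -> CrimpResult:
    """Overdamped self-expansion of a released frame toward equilibrium.

    Integrates the pure gradient flow (no crimper) until the per-node force
    infinity norm falls below ``force_tol_dyne`` or ``t_max_s`` elapses.
    """
    fr = frame.copy()
    x = fr.nodes
    if dt is None:
        dt = _stable_dt(fr)
    n_steps = int(math.ceil(t_max_s / dt))
    ts, dias, ens = [], [], []
    converged = False
    for n in range(n_steps + 1):
        f = elastic_forces(fr)
        fmax = float(np.abs(f).max())
        if n % record_every == 0:
            ts.append(n * dt)
            dias.append(diameter_metrics(fr)["diameter_mm"])
            ens.append(elastic_energy(fr))
        if fmax < force_tol_dyne:
            converged = True
            break
        x += (dt / fr.damping) * f
    ts.append(n * dt)
    dias.append(diameter_metrics(fr)["diameter_mm"])
    ens.append(elastic_energy(fr))
    return CrimpResult(fr, np.array(ts), np.array(dias), np.array(ens),
                       converged=converged)


def diameter_metrics(frame: StentFrame) -> dict:
    """Outer diameter about the lattice z-axis, in mm and French (1 Fr = 1/3 mm)."""
    rho = np.hypot(frame.nodes[:, 0], frame.nodes[:, 1])
    d_mm = 2.0 * float(rho.max()) * 10.0
    return {"diameter_mm": d_mm, "diameter_Fr": d_mm / MM_PER_FR}
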