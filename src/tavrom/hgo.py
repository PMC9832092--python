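"""Fiber-reinforced hyperelasticity for valve leaflet and pericardial tissue.

Implements a modified Holzapfel--Gasser--Ogden (HGO) strain energy with an
exponential isotropic ground matrix and two tension-only fiber families,

    W(Fbar) = C10 {exp[C01 (I1bar - 3)] - 1}
              + k1/(2 k2) sum_i {exp[k2 (I4bar_i* - 1)^2] - 1},

split from a volumetric stabilization term

    U(J) = beta [J ln J - J + 1],

where I1bar = tr(Cbar) is the first invariant of the modified right
Cauchy--Green tensor Cbar = Fbar^T Fbar (Fbar = J^{-1/3} F), and
I4bar_i* = max(f0_i . Cbar f0_i, 1) switches the i-th fiber family off in
compression.  The two fiber families sit in the material plane at the mean
fiber angle +/- theta, a simple account of in-plane fiber dispersion.

Canonical stress unit is kPa; k1 and beta are conventionally quoted in MPa
and converted on load (1 MPa = 1000 kPa).

The module also provides the plane-stress, exactly incompressible biaxial
response used to emulate planar biaxial tensile tests, a synthetic biaxial
data generator, and :class:`HGOBiaxialModel` for recovering constitutive
parameters from such data by multi-start trust-region least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HGOParams",
    "Deformation",
    "StressState",
    "kinematics",
    "fiber_invariant",
    "fiber_directions",
    "strain_energy",
    "first_pk_stress",
    "cauchy_and_von_mises",
    "biaxial_plane_stress",
    "generate_biaxial_dataset",
    "stenotic_stiffening",
    "HGOBiaxialModel",
    "HGOFitResult",
    "PORCINE_PERICARDIUM",
    "NATIVE_LEAFLET",
]

MPA_PER_KPA = 1e-3
KPA_PER_MPA = 1e3

#: Arguments of exp() are capped here; beyond it the value is continued
#: linearly (exp(c)*(1 + x - c)) and the evaluation is flagged.  Parameter
#: fitting explores extreme fiber exponents where the bare exponential
#: overflows double precision.
EXP_CAP = 50.0


def _capped_exp(x):
    """exp with linear continuation above EXP_CAP; returns (value, capped?)."""
    x = np.asarray(x, dtype=float)
    capped = x > EXP_CAP
    safe = np.where(capped, EXP_CAP, x)
    val = np.exp(safe)
    val = np.where(capped, val * (1.0 + (x - EXP_CAP)), val)
    return val, bool(np.any(capped))


@dataclass(frozen=True)
class HGOParams:
    """Constitutive constants of one tissue.

    C10 in kPa, k1 and beta in MPa (as conventionally tabulated); C01, k2
    dimensionless; theta is the fiber half-dispersion angle and
    mean_fiber_deg the mean fiber direction, both in degrees measured in the
    material 1-2 plane from axis 1.
    """

    C10_kPa: float
    C01: float
    k1_MPa: float
    k2: float
    theta_deg: float
    beta_MPa: float
    mean_fiber_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.C10_kPa > 0:
            raise ValueError("C10 must be positive")
        if self.C01 < 0 or self.k1_MPa < 0:
            raise ValueError("C01 and k1 must be nonnegative")
        if not self.k2 > 0:
            raise ValueError("k2 must be positive")
        if not self.beta_MPa > 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.theta_deg < 90.0:
            raise ValueError("theta must lie in [0, 90) degrees")

    @property
    def k1_kPa(self) -> float:
        return self.k1_MPa * KPA_PER_MPA

    @property
    def beta_kPa(self) -> float:
        return self.beta_MPa * KPA_PER_MPA

    def to_dict(self) -> dict:
        return {
            "C10_kPa": self.C10_kPa,
            "C01": self.C01,
            "k1_MPa": self.k1_MPa,
            "k2": self.k2,
            "theta_deg": self.theta_deg,
            "beta_MPa": self.beta_MPa,
            "mean_fiber_deg": self.mean_fiber_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HGOParams":
        return cls(**{k: float(d[k]) for k in (
            "C10_kPa", "C01", "k1_MPa", "k2", "theta_deg", "beta_MPa",
            "mean_fiber_deg")})


#: Glutaraldehyde-fixed porcine pericardium (prosthetic leaflets and sealing
#: skirt); mean fiber direction 45 deg in the leaflet plane.
PORCINE_PERICARDIUM = HGOParams(
    C10_kPa=15.14, C01=13.48, k1_MPa=0.1526, k2=107.3,
    theta_deg=7.81, beta_MPa=5.840, mean_fiber_deg=45.0,
)

#: Healthy native aortic valve leaflet; mean fiber direction commissure to
#: commissure (axis 1 of the material frame).
NATIVE_LEAFLET = HGOParams(
    C10_kPa=0.1463, C01=26.21, k1_MPa=0.007072, k2=147.5,
    theta_deg=26.21, beta_MPa=141.0, mean_fiber_deg=0.0,
)


def stenotic_stiffening(p: HGOParams, factor: float = 1e3) -> HGOParams:
    """Stenotic tissue variant: isotropic stiffness C10 scaled by `factor`."""
    if not factor > 0:
        raise ValueError("factor must be positive")
    return replace(p, C10_kPa=p.C10_kPa * factor)


# ---------------------------------------------------------------------------
# kinematics

@dataclass(frozen=True)
class Deformation:
    """Deformation gradient F with its derived isochoric quantities.

    F maps reference coordinates X to current coordinates x = chi(X, t);
    J = det F, Fbar = J^{-1/3} F, Cbar = Fbar^T Fbar, I1bar = tr(Cbar).
    """

    F: np.ndarray
    J: float
    Fbar: np.ndarray
    Cbar: np.ndarray
    I1bar: float

    @classmethod
    def from_F(cls, F) -> "Deformation":
        F = np.asarray(F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        J = float(np.linalg.det(F))
        if not J > 0:
            raise ValueError(
                f"deformation gradient must have positive determinant (det F = {J:g})"
            )
        Fbar = J ** (-1.0 / 3.0) * F
        Cbar = Fbar.T @ Fbar
        return cls(F=F, J=J, Fbar=Fbar, Cbar=Cbar, I1bar=float(np.trace(Cbar)))


def kinematics(F) -> Deformation:
    """Decompose a deformation gradient into J, Fbar, Cbar, I1bar."""
    return Deformation.from_F(F)


def fiber_invariant(deformation: Deformation, f0) -> float:
    """Tension-only fourth invariant I4bar* = max(f0 . Cbar f0, 1)."""
    f0 = np.asarray(f0, dtype=float)
    if abs(np.linalg.norm(f0) - 1.0) > 1e-8:
        raise ValueError("fiber direction f0 must be a unit vector")
    return max(float(f0 @ deformation.Cbar @ f0), 1.0)


def fiber_directions(mean_angle_deg: float, theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Two in-plane unit fiber vectors at mean_angle +/- theta (degrees)."""
    out = []
    for a in (mean_angle_deg - theta_deg, mean_angle_deg + theta_deg):
        r = math.radians(a)
        out.append(np.array([math.cos(r), math.sin(r), 0.0]))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# energy and stress

def _fiber_stretch_invariants(deformation: Deformation, p: HGOParams):
    f1, f2 = fiber_directions(p.mean_fiber_deg, p.theta_deg)
    C = deformation.Cbar
    return (
        (f1, max(float(f1 @ C @ f1), 1.0)),
        (f2, max(float(f2 @ C @ f2), 1.0)),
    )


def strain_energy(deformation: Deformation, p: HGOParams,
                  return_flag: bool = False):
    """Total strain energy Psi = W(Fbar) + U(J) in kPa.

    Each summand is nonnegative and vanishes at F = I.  Exponential
    arguments beyond EXP_CAP are continued linearly and flagged.
    """
    e_iso, cap1 = _capped_exp(p.C01 * (deformation.I1bar - 3.0))
    W = p.C10_kPa * (float(e_iso) - 1.0)
    capped = cap1
    if p.k1_MPa > 0:
        for _, i4 in _fiber_stretch_invariants(deformation, p):
            e = i4 - 1.0
            ef, capf = _capped_exp(p.k2 * e * e)
            W += p.k1_kPa / (2.0 * p.k2) * (float(ef) - 1.0)
            capped = capped or capf
    J = deformation.J
    U = p.beta_kPa * (J * math.log(J) - J + 1.0)
    psi = W + U
    if return_flag:
        return psi, capped
    return psi


def first_pk_stress(deformation: Deformation, p: HGOParams) -> np.ndarray:
    """Analytic first Piola-Kirchhoff stress P = dPsi/dF in kPa.

    The isochoric part carries the deviatoric projection arising from the
    Fbar dependence; the volumetric part is beta J ln(J) F^{-T}.
    """
    F, J, Cbar = deformation.F, deformation.J, deformation.Cbar
    e_iso, _ = _capped_exp(p.C01 * (deformation.I1bar - 3.0))
    W1 = p.C10_kPa * p.C01 * float(e_iso)
    Stil = 2.0 * W1 * np.eye(3)
    if p.k1_MPa > 0:
        for f0, i4 in _fiber_stretch_invariants(deformation, p):
            e = i4 - 1.0
            if e > 0.0:
                ef, _ = _capped_exp(p.k2 * e * e)
                W4 = p.k1_kPa * e * float(ef)
                Stil += 2.0 * W4 * np.outer(f0, f0)
    Cbar_inv = np.linalg.inv(Cbar)
    S_iso = J ** (-2.0 / 3.0) * (
        Stil - (np.tensordot(Stil, Cbar) / 3.0) * Cbar_inv
    )
    F_invT = np.linalg.inv(F).T
    P_vol = p.beta_kPa * J * math.log(J) * F_invT
    return F @ S_iso + P_vol


@dataclass(frozen=True)
class StressState:
    """First Piola-Kirchhoff stress, Cauchy stress, and von Mises scalar."""

    P: np.ndarray
    sigma: np.ndarray
    von_mises: float


def cauchy_and_von_mises(deformation: Deformation, P: np.ndarray) -> StressState:
    """Push P forward to Cauchy stress sigma = J^{-1} P F^T (symmetrized)
    and form the von Mises intensity from its deviator."""
    sigma = (P @ deformation.F.T) / deformation.J
    sigma = 0.5 * (sigma + sigma.T)
    dev = sigma - np.trace(sigma) / 3.0 * np.eye(3)
    vm = math.sqrt(max(1.5 * float(np.tensordot(dev, dev)), 0.0))
    return StressState(P=np.asarray(P, dtype=float), sigma=sigma, von_mises=vm)


# ---------------------------------------------------------------------------
# plane-stress biaxial response

def biaxial_plane_stress(lam1, lam2, p: HGOParams):
    """In-plane Cauchy stresses of an incompressible plane-stress membrane.

    Enforces lambda3 = 1/(lambda1 lambda2) exactly (so J = 1 and the
    volumetric term drops) and eliminates the hydrostatic pressure with the
    plane-stress condition sigma33 = 0.  Fibers lie in the 1-2 plane at
    mean_fiber_deg +/- theta.  Vectorized over stretch arrays; returns
    (sigma11, sigma22) in kPa.
    """
    l1 = np.asarray(lam1, dtype=float)
    l2 = np.asarray(lam2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("stretches must be positive")
    l3sq = 1.0 / (l1 * l1 * l2 * l2)
    I1 = l1 * l1 + l2 * l2 + l3sq
    e_iso, _ = _capped_exp(p.C01 * (I1 - 3.0))
    W1 = p.C10_kPa * p.C01 * e_iso
    s11 = 2.0 * W1 * (l1 * l1 - l3sq)
    s22 = 2.0 * W1 * (l2 * l2 - l3sq)
    if p.k1_MPa > 0:
        for ang in (p.mean_fiber_deg - p.theta_deg, p.mean_fiber_deg + p.theta_deg):
            c = math.cos(math.radians(ang))
            s = math.sin(math.radians(ang))
            I4 = l1 * l1 * c * c + l2 * l2 * s * s
            e = np.maximum(I4 - 1.0, 0.0)
            ef, _ = _capped_exp(p.k2 * e * e)
            W4 = p.k1_kPa * e * ef
            s11 = s11 + 2.0 * W4 * l1 * l1 * c * c
            s22 = s22 + 2.0 * W4 * l2 * l2 * s * s
    return s11, s22


def generate_biaxial_dataset(
    p: HGOParams,
    stretch_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    noise_rel: float = 0.0,
    protocol: str = "grid",
) -> pd.DataFrame:
    """Synthetic planar-biaxial dataset from the plane-stress HGO response.

    By default stretches cover a 20x20 tensor grid on the physiologic range
    [1.0, 1.25] in both directions.  ``noise_sd`` adds i.i.d. Gaussian noise
    in kPa; ``noise_rel`` applies multiplicative lognormal-free Gaussian
    noise (sigma -> sigma * (1 + eps), eps ~ N(0, noise_rel)).  With both
    zero the dataset reproduces :func:`biaxial_plane_stress` exactly.
    Reproducible given ``seed``.
    """
    if noise_sd < 0 or noise_rel < 0:
        raise ValueError("noise levels must be nonnegative")
    if stretch_grid is None:
        stretch_grid = np.linspace(1.0, 1.25, 20)
    g = np.asarray(stretch_grid, dtype=float)
    L1, L2 = np.meshgrid(g, g, indexing="ij")
    l1, l2 = L1.ravel(), L2.ravel()
    s11, s22 = biaxial_plane_stress(l1, l2, p)
    if noise_sd > 0 or noise_rel > 0:
        rng = np.random.default_rng(seed)
        if noise_rel > 0:
            s11 = s11 * (1.0 + noise_rel * rng.standard_normal(s11.shape))
            s22 = s22 * (1.0 + noise_rel * rng.standard_normal(s22.shape))
        if noise_sd > 0:
            s11 = s11 + noise_sd * rng.standard_normal(s11.shape)
            s22 = s22 + noise_sd * rng.standard_normal(s22.shape)
    return pd.DataFrame(
        {
            "lambda1": l1,
            "lambda2": l2,
            "sigma11_kPa": s11,
            "sigma22_kPa": s22,
        }
    )


# ---------------------------------------------------------------------------
# parameter fitting

_FIT_KEYS = ("C10_kPa", "C01", "k1_MPa", "k2", "theta_deg")


class HGOBiaxialModel:
    """Recover HGO constants from biaxial stress-stretch data.

    The model fits (C10, C01, k1, k2, theta) by weighted trust-region least
    squares on the (sigma11, sigma22) residuals; the mean fiber direction is
    a protocol property and stays fixed, and beta is not identifiable from
    incompressible plane-stress data, so it is carried through unchanged.
    Residuals are weighted by 1/max(|sigma|, w_floor): biaxial stresses of
    exponentially stiffening tissue span many orders of magnitude and a
    relative objective keeps the small-stretch response informative.

    A fixed 8-point multi-start schedule, log-spaced over (k1, k2), guards
    against the exponential model's local minima; the procedure is fully
    deterministic.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        mean_fiber_deg: float = 0.0,
        beta_MPa: float = 1.0,
        weight_floor_kPa: float = 0.1,
    ):
        required = {"lambda1", "lambda2", "sigma11_kPa", "sigma22_kPa"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if len(data) < 3 * len(_FIT_KEYS):
            raise ValueError(
                f"need at least {3 * len(_FIT_KEYS)} rows to fit "
                f"{len(_FIT_KEYS)} parameters, got {len(data)}"
            )
        self.data = data.reset_index(drop=True)
        self.mean_fiber_deg = mean_fiber_deg
        self.beta_MPa = beta_MPa
        self.l1 = data["lambda1"].to_numpy(float)
        self.l2 = data["lambda2"].to_numpy(float)
        self.s11 = data["sigma11_kPa"].to_numpy(float)
        self.s22 = data["sigma22_kPa"].to_numpy(float)
        if np.any(self.l1 <= 0) or np.any(self.l2 <= 0):
            raise ValueError("stretches must be positive")
        if not np.all(np.isfinite(self.s11)) or not np.all(np.isfinite(self.s22)):
            raise ValueError("stresses must be finite")
        w = np.concatenate([np.abs(self.s11), np.abs(self.s22)])
        self.weights = 1.0 / np.maximum(w, weight_floor_kPa)

    def _params_from_x(self, x) -> HGOParams:
        return HGOParams(
            C10_kPa=math.exp(x[0]),
            C01=math.exp(x[1]),
            k1_MPa=math.exp(x[2]),
            k2=math.exp(x[3]),
            theta_deg=x[4],
            beta_MPa=self.beta_MPa,
            mean_fiber_deg=self.mean_fiber_deg,
        )

    def _residuals(self, x) -> np.ndarray:
        p = self._params_from_x(x)
        m11, m22 = biaxial_plane_stress(self.l1, self.l2, p)
        r = np.concatenate([m11 - self.s11, m22 - self.s22])
        return r * self.weights

    def fit(
        self,
        bounds: dict | None = None,
        starts: list[tuple[float, float]] | None = None,
        xtol: float = 1e-14,
    ) -> "HGOFitResult":
        """Run the multi-start fit and return the best candidate.

        ``starts`` overrides the default 8 log-spaced (k1_MPa, k2) start
        pairs.  ``bounds`` may narrow the box per parameter, e.g.
        ``{"k2": (10.0, 500.0)}``.
        """
        default_bounds = {
            "C10_kPa": (1e-4, 1e4),
            "C01": (1e-3, 1e3),
            "k1_MPa": (1e-6, 1e2),
            "k2": (1e-1, 1e4),
            "theta_deg": (0.0, 89.0),
        }
        if bounds:
            default_bounds.update(bounds)
        lo, hi = [], []
        for k in _FIT_KEYS:
            b = default_bounds[k]
            if k == "theta_deg":
                lo.append(b[0])
                hi.append(b[1])
            else:
                lo.append(math.log(b[0]))
                hi.append(math.log(b[1]))
        lo, hi = np.array(lo), np.array(hi)

        if starts is None:
            k1s = np.logspace(-3, 0, 2)      # MPa
            k2s = np.logspace(1.0, 2.5, 4)
            starts = [(a, b) for a in k1s for b in k2s]
        best = None
        tried = []
        for k1_0, k2_0 in starts:
            x0 = np.array([
                math.log(1.0),       # C10 = 1 kPa
                math.log(5.0),       # C01
                math.log(k1_0),
                math.log(k2_0),
                15.0,                # theta (deg)
            ])
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(
                self._residuals, x0, bounds=(lo, hi), method="trf",
                xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=4000,
            )
            tried.append((float(np.sum(sol.fun ** 2)), sol))
            if best is None or tried[-1][0] < best[0]:
                best = tried[-1]
        cost, sol = best
        params = self._params_from_x(sol.x)
        return HGOFitResult(
            model=self,
            params=params,
            residual_norm=math.sqrt(cost),
            n_obs=2 * len(self.l1),
            converged=bool(sol.success),
            n_starts=len(starts),
            optimizer_status=int(sol.status),
            start_costs=sorted(c for c, _ in tried),
        )


@dataclass
class HGOFitResult:
    """Estimates and diagnostics from :meth:`HGOBiaxialModel.fit`."""

    model: HGOBiaxialModel
    params: HGOParams
    residual_norm: float
    n_obs: int
    converged: bool
    n_starts: int
    optimizer_status: int
    start_costs: list

    def summary(self) -> str:
        p = self.params
        lines = [
            "HGO biaxial fit (weighted trust-region least squares)",
            "=" * 60,
            f"observations : {self.n_obs}   multi-starts: {self.n_starts}",
            f"weighted residual norm : {self.residual_norm:.3e}",
            f"converged    : {self.converged}",
            "-" * 60,
            f"C10   = {p.C10_kPa:12.6g} kPa",
            f"C01   = {p.C01:12.6g}",
            f"k1    = {p.k1_MPa:12.6g} MPa",
            f"k2    = {p.k2:12.6g}",
            f"theta = {p.theta_deg:12.6g} deg",
            f"beta  = {p.beta_MPa:12.6g} MPa  (fixed; not identifiable from biaxial data)",
            f"mean fiber direction = {p.mean_fiber_deg:g} deg (fixed protocol property)",
            "=" * 60,
        ]
        if not self.converged:
            lines.insert(1, "WARNING: optimizer did not report convergence; "
                            "best candidate shown")
        return "\n".join(lines)
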