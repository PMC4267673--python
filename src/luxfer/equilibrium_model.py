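"""Equilibrium models of an inducible LuxR-type genetic device.

The device is a receptor/promoter pair: a receptor protein R dimerizes
(R2), the dimer binds one molecule of the inducing ligand L (forming Q),
and either the free dimer (R2) or the ligand-bound dimer (Q) can occupy
the promoter P, forming the transcriptional complexes S_R and S_L.  The
promoter also transcribes weakly when naked.  Transcription of the
reporter mRNA (mG) and its translation to protein (G) are first-order
birth/death processes on top of the (fast) binding equilibria.

Two closed-form steady-state transfer functions are provided:

* the *simple* model — no leak pathways (naked-promoter rate and
  free-dimer binding both zero) — which collapses to a Michaelis-Menten
  form with apparent parameters ``G_m^app(phi)`` and ``K^app(phi)``;
* the *leaky* model — both leak pathways retained — which collapses to
  the three-parameter hyperbola ``G* = a1 (a2 + L) / (a3 + L)``.

``phi`` is the strength of the ribosome-binding site driving receptor
translation, normalized to a canonical part; the total dimer pool is
taken linear in it, ``[R2_T] = r' * phi``.

A numerical ``equilibrium_oracle`` solves the full mass-action network
with exact conservation (no excess-receptor approximation) and serves as
an independent check of the closed forms, and ``simulate_dynamics``
integrates the mRNA/protein kinetics under quasi-equilibrium binding.

Internal units are molar for concentrations and minutes for time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "EquilibriumConstants",
    "RateConstants",
    "DeviceParams",
    "HyperbolicParams",
    "SpeciesState",
    "Observables",
    "simple_gmax",
    "simple_kapp",
    "simple_transfer",
    "closed_form_sL",
    "leaky_coefficients",
    "leaky_transfer",
    "basal_output",
    "max_output",
    "observables",
    "dimer_partition",
    "dimer_total",
    "equilibrium_oracle",
    "simulate_dynamics",
    "steady_state_output",
    "EquilibriumError",
]


def _check_nonnegative(obj, fields: Sequence[str]) -> None:
    for name in fields:
        v = getattr(obj, name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Association constants of the binding network (per molar).

    K0: monomer dimerization, [R2]/[R]^2.
    K1: ligand-dimer association, [Q]/([R2][L]).
    K2: free-dimer-promoter association, [S_R]/([R2][P]).
    K3: ligand-bound-dimer-promoter association, [S_L]/([Q][P]).

    Setting ``K2 = 0`` (and ignoring dimerization, which only maps the
    monomer pool onto the dimer pool) recovers the leak-free simple model.
    """

    K0: float = 0.0
    K1: float = 1.0
    K2: float = 0.0
    K3: float = 1.0

    def __post_init__(self) -> None:
        _check_nonnegative(self, ("K0", "K1", "K2", "K3"))


@dataclass(frozen=True)
class RateConstants:
    """First-order kinetic constants (per minute).

    k_m0, k_mR, k_mL: transcription from the naked promoter, the
    free-dimer complex and the ligand-bound complex; k_md and k_pd are
    mRNA and protein decay; k_p is translation.  A steady state exists
    only when both decay rates are positive; zero decay is accepted so
    that frozen (all-zero) kinetics remain representable.
    """

    k_m0: float = 0.0
    k_mR: float = 0.0
    k_mL: float = 1.0
    k_md: float = 1.0
    k_p: float = 1.0
    k_pd: float = 1.0

    def __post_init__(self) -> None:
        _check_nonnegative(self, ("k_m0", "k_mR", "k_mL", "k_md", "k_p", "k_pd"))


@dataclass(frozen=True)
class DeviceParams:
    """Lumped device-level parameters of the closed-form transfer functions.

    phi      -- normalized RBS strength of the receptor (dimensionless).
    r_prime  -- scale mapping phi to the total dimer pool, [R2_T] = r'*phi (molar).
    P_T      -- total promoter concentration (molar); optional, only the
                lumped products below enter the closed forms.
    V        -- machinery efficiency gamma*g*k_mL*[P_T], the ceiling of the
                induced output (output units).
    V0       -- naked-promoter leak gamma*g*k_m0*[P_T] (output units).
    eps_R    -- k_mR / k_m0, free-receptor-complex transcription relative to leak.
    eps_L    -- k_mL / k_m0, induced transcription relative to leak.
    """

    phi: float = 1.0
    r_prime: float = 1.0
    P_T: float = float("nan")
    V: float = 1.0
    V0: float = 0.0
    eps_R: float = 1.0
    eps_L: float = 1.0

    def __post_init__(self) -> None:
        _check_nonnegative(self, ("V", "V0", "eps_R", "eps_L"))
        # phi may be NaN for a parameter set shared across constructs
        if not np.isnan(self.phi):
            _check_nonnegative(self, ("phi",))
        if not (np.isfinite(self.r_prime) and self.r_prime > 0):
            raise ValueError(f"r_prime must be finite and > 0, got {self.r_prime!r}")


@dataclass(frozen=True)
class HyperbolicParams:
    """Compact parameters of the leaky transfer function a1*(a2+L)/(a3+L).

    a1 is the saturating amplitude (output units), a2 the basality
    constant and a3 the ligand affinity constant (both molar).  The
    curve is increasing in L (activation) exactly when a3 > a2.
    """

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        _check_nonnegative(self, ("a1", "a2"))
        if not (np.isfinite(self.a3) and self.a3 > 0):
            raise ValueError(f"a3 must be finite and > 0, got {self.a3!r}")

    @property
    def is_activating(self) -> bool:
        return self.a3 > self.a2


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations of all molecular species (molar)."""

    R: float = 0.0
    R2: float = 0.0
    Q: float = 0.0
    P: float = 0.0
    S_R: float = 0.0
    S_L: float = 0.0
    mG: float = 0.0
    G: float = 0.0
    L: float = 0.0

    def __post_init__(self) -> None:
        _check_nonnegative(self, ("R", "R2", "Q", "P", "S_R", "S_L", "mG", "G", "L"))

    @property
    def receptor_total(self) -> float:
        """Total receptor in monomer equivalents, R + 2*(R2 + Q + S_R + S_L)."""
        return self.R + 2.0 * (self.R2 + self.Q + self.S_R + self.S_L)

    @property
    def promoter_total(self) -> float:
        """Total promoter, P + S_R + S_L."""
        return self.P + self.S_R + self.S_L


class Observables(NamedTuple):
    """Measurable summary of a leaky transfer curve."""

    G0: float
    Gm: float
    L05: float | None


# ---------------------------------------------------------------------------
# Simple (leak-free) model
# ---------------------------------------------------------------------------


def dimer_total(phi: float, r_prime: float) -> float:
    """Total dimer pool [R2_T] = r' * phi implied by an RBS of strength phi."""
    return r_prime * phi


def simple_gmax(phi: float, dp: DeviceParams, K3: float) -> float:
    """Apparent maximal output G_m^app(phi) = V * phi / ((K3 r')^-1 + phi).

    Monotone increasing in phi, saturating at the machinery efficiency V.
    The degenerate 0/0 form at ``phi = 0`` with ``K3*r' = 0`` is resolved
    by the continuous limit of the phi-saturable form, which is 0.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    x = K3 * dp.r_prime * phi
    if K3 * dp.r_prime == 0.0 and phi == 0.0:
        warnings.warn(
            "simple_gmax is a 0/0 form at phi=0 with K3*r'=0; returning the continuous limit 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    # V*phi/((K3 r')^-1 + phi) rewritten to avoid the infinite reciprocal
    return dp.V * x / (1.0 + x)


def simple_kapp(phi: float, K1: float, K3: float, r_prime: float) -> float:
    """Apparent affinity constant K^app(phi) = K1^-1 / (1 + K3 r' phi).

    Equals the intrinsic ligand dissociation constant K1^-1 at phi = 0
    and decays as 1/phi once phi >> (K3 r')^-1.
    """
    if K1 <= 0:
        raise ValueError(f"K1 must be > 0 for a defined affinity, got {K1}")
    if K3 * r_prime <= 0:
        raise ValueError("K3 * r_prime must be > 0 in the simple model")
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    return (1.0 / K1) / (1.0 + K3 * r_prime * phi)


def simple_transfer(L, phi: float, dp: DeviceParams, K1: float, K3: float):
    """Leak-free steady-state output G* = G_m^app * L / (K^app + L).

    Hyperbolic in the ligand concentration; half-saturates at L = K^app.
    Accepts scalar or array L (molar).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    gm = simple_gmax(phi, dp, K3)
    ka = simple_kapp(phi, K1, K3, dp.r_prime)
    out = gm * L / (ka + L)
    return float(out) if out.ndim == 0 else out


def closed_form_sL(R2T: float, P_T: float, L: float, K1: float, K3: float) -> float:
    """Ligand-bound transcriptional complex [S_L] under excess receptor.

    With the dimer pool unperturbed by promoter binding (R_T >> P_T) and
    free ligand fixed, [S_L] = P_T * x / (1 + x) with
    x = K1 K3 R2T L / (1 + K1 L).
    """
    x = K1 * K3 * R2T * L / (1.0 + K1 * L)
    return P_T * x / (1.0 + x)


# ---------------------------------------------------------------------------
# Leaky model
# ---------------------------------------------------------------------------


def leaky_coefficients(phi: float, ec: EquilibriumConstants, dp: DeviceParams) -> HyperbolicParams:
    """Map mechanistic parameters to the hyperbola coefficients (a1, a2, a3).

        a1 = V0 (1 + eps_L K3 r' phi) / (1 + K3 r' phi)
        a2 = K1^-1 (1 + eps_R K2 r' phi) / (1 + eps_L K3 r' phi)
        a3 = K1^-1 (1 + K2 r' phi) / (1 + K3 r' phi)

    These satisfy identically the measurable limits of the leaky model:
    a1*a2/a3 equals the basal output gamma*g*P_T*(k_m0 + k_mR K2 r' phi)/(1 + K2 r' phi)
    and a1 equals the maximal output gamma*g*P_T*(k_m0 + k_mL K3 r' phi)/(1 + K3 r' phi).
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    if ec.K1 <= 0:
        raise ValueError("K1 must be > 0: the ligand affinity scale is 1/K1")
    x2 = ec.K2 * dp.r_prime * phi
    x3 = ec.K3 * dp.r_prime * phi
    k1inv = 1.0 / ec.K1
    a1 = dp.V0 * (1.0 + dp.eps_L * x3) / (1.0 + x3)
    a2 = k1inv * (1.0 + dp.eps_R * x2) / (1.0 + dp.eps_L * x3)
    a3 = k1inv * (1.0 + x2) / (1.0 + x3)
    return HyperbolicParams(a1=a1, a2=a2, a3=a3)


def leaky_transfer(L, hp: HyperbolicParams):
    """Leaky steady-state output G* = a1 * (a2 + L) / (a3 + L).

    Equals a1*a2/a3 at L = 0, tends to a1 as L -> infinity, and is
    strictly increasing in L iff a3 > a2.  Accepts scalar or array L.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    out = hp.a1 * (hp.a2 + L) / (hp.a3 + L)
    return float(out) if out.ndim == 0 else out


def basal_output(phi: float, ec: EquilibriumConstants, dp: DeviceParams) -> float:
    """Basal output G0(phi) = V0 (1 + eps_R K2 r' phi) / (1 + K2 r' phi).

    The zero-ligand limit of the leaky model, written directly in
    mechanistic parameters (independent of the a1/a2/a3 factorization).
    """
    x2 = ec.K2 * dp.r_prime * phi
    return dp.V0 * (1.0 + dp.eps_R * x2) / (1.0 + x2)


def max_output(phi: float, ec: EquilibriumConstants, dp: DeviceParams) -> float:
    """Maximal output Gm(phi) = V0 (1 + eps_L K3 r' phi) / (1 + K3 r' phi).

    The saturating-ligand limit of the leaky model in mechanistic form.
    """
    x3 = ec.K3 * dp.r_prime * phi
    return dp.V0 * (1.0 + dp.eps_L * x3) / (1.0 + x3)


def observables(hp: HyperbolicParams) -> Observables:
    """Basal output G0, maximal output Gm and turning point L05 of a curve.

    G0 = a1 a2 / a3, Gm = a1, and the half-maximal ligand concentration
    L05 = a3 - 2 a2 (at which the curve equals exactly Gm/2).  When
    a3 <= 2 a2 the basal output already exceeds half-max and the turning
    point does not exist; it is reported as None.
    """
    g0 = hp.a1 * hp.a2 / hp.a3
    l05 = hp.a3 - 2.0 * hp.a2
    return Observables(G0=g0, Gm=hp.a1, L05=l05 if l05 > 0 else None)


# ---------------------------------------------------------------------------
# Full-network numerics
# ---------------------------------------------------------------------------


def dimer_partition(R_T: float, K0: float) -> tuple[float, float]:
    """Partition a total monomer pool R_T between monomer and dimer.

    Solves R + 2 K0 R^2 = R_T for the free monomer R >= 0 and returns
    (R, R2) with R2 = K0 R^2.  Uses the cancellation-free form of the
    positive quadratic root, so conservation holds to ~1e-15 relative.
    """
    if R_T < 0:
        raise ValueError(f"R_T must be >= 0, got {R_T}")
    if K0 == 0.0 or R_T == 0.0:
        return R_T, 0.0
    R = 2.0 * R_T / (1.0 + np.sqrt(1.0 + 8.0 * K0 * R_T))
    return R, K0 * R * R


class EquilibriumError(RuntimeError):
    """Raised when the mass-action equilibrium solve does not converge."""


_ORACLE_RTOL = 1e-10


def equilibrium_oracle(R_T: float, P_T: float, L: float, ec: EquilibriumConstants) -> SpeciesState:
    """Solve the full binding network with exact conservation.

    Given total receptor monomer R_T, total promoter P_T and *free*
    ligand L (the ligand pool is treated as unconsumed, i.e. buffered by
    the experimental excess), finds the unique composition satisfying
    the four association-constant definitions together with

        R_T = R + 2 (R2 + Q + S_R + S_L)
        P_T = P + S_R + S_L

    No excess-receptor approximation is made, so this serves as a
    brute-force oracle for the closed forms.  The network reduces to a
    single monotone equation in the free monomer R, solved by bracketed
    root-finding; all residuals are verified to 1e-10 relative.
    """
    for name, v in (("R_T", R_T), ("P_T", P_T), ("L", L)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def composition(R: float) -> SpeciesState:
        R2 = ec.K0 * R * R
        Q = ec.K1 * L * R2
        occ = ec.K2 * R2 + ec.K3 * Q
        P = P_T / (1.0 + occ)
        return SpeciesState(R=R, R2=R2, Q=Q, P=P, S_R=ec.K2 * R2 * P, S_L=ec.K3 * Q * P, L=L)

    def residual(R: float) -> float:
        return composition(R).receptor_total - R_T

    if R_T == 0.0 or ec.K0 == 0.0:
        # no dimers can form; all receptor remains monomeric
        st = composition(R_T)
    else:
        R = brentq(residual, 0.0, R_T, xtol=1e-300, rtol=8.9e-16, maxiter=300)
        st = composition(R)

    scale_R = max(R_T, 1.0e-300)
    scale_P = max(P_T, 1.0e-300)
    res = {
        "receptor conservation": abs(st.receptor_total - R_T) / scale_R,
        "promoter conservation": abs(st.promoter_total - P_T) / scale_P,
    }
    if st.R2 > 0 and L > 0:
        res["K1 definition"] = abs(st.Q / (st.R2 * L) - ec.K1) / max(ec.K1, 1e-300)
    if st.R2 > 0 and st.P > 0:
        res["K2 definition"] = abs(st.S_R / (st.R2 * st.P) - ec.K2) / max(ec.K2, 1e-300) if ec.K2 else 0.0
    if st.Q > 0 and st.P > 0:
        res["K3 definition"] = abs(st.S_L / (st.Q * st.P) - ec.K3) / max(ec.K3, 1e-300) if ec.K3 else 0.0
    bad = {k: v for k, v in res.items() if v > _ORACLE_RTOL}
    if bad:
        raise EquilibriumError(f"equilibrium solve did not converge; residuals: {bad}")
    return st


def simulate_dynamics(
    state0: SpeciesState,
    rc: RateConstants,
    ec: EquilibriumConstants,
    totals: tuple[float, float, float],
    t_grid,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate reporter mRNA and protein under quasi-equilibrium binding.

    Binding is fast relative to gene expression, so the promoter
    occupancies (P, S_R, S_L) are pinned to ``equilibrium_oracle`` for
    the given totals ``(R_T, P_T, L)`` and only

        d[mG]/dt = k_m0 [P] + k_mR [S_R] + k_mL [S_L] - k_md [mG]
        d[G]/dt  = k_p [mG] - k_pd [G]

    integrate in time.  Returns (mG, G) evaluated on ``t_grid`` (minutes,
    strictly increasing); initial values are taken from ``state0``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    R_T, P_T, L = totals
    eq = equilibrium_oracle(R_T, P_T, L, ec)
    synth = rc.k_m0 * eq.P + rc.k_mR * eq.S_R + rc.k_mL * eq.S_L

    def rhs(_t, y):
        mG, G = y
        return [synth - rc.k_md * mG, rc.k_p * mG - rc.k_pd * G]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [state0.mG, state0.G],
        t_eval=t,
        method="LSODA",
        rtol=1e-10,
        atol=1e-14 * max(1.0, synth),
    )
    if not sol.success:
        raise RuntimeError(f"dynamics integration failed: {sol.message}")
    return sol.y[0], sol.y[1]


def steady_state_output(rc: RateConstants, ec: EquilibriumConstants, totals: tuple[float, float, float]) -> float:
    """Closed-form steady state of the reporter under quasi-equilibrium binding.

    G* = (k_p / (k_pd k_md)) * (k_m0 [P] + k_mR [S_R] + k_mL [S_L]) with
    the occupancies from ``equilibrium_oracle``.  Requires positive decay
    rates.
    """
    if rc.k_md <= 0 or rc.k_pd <= 0:
        raise ValueError("steady state requires k_md > 0 and k_pd > 0")
    R_T, P_T, L = totals
    eq = equilibrium_oracle(R_T, P_T, L, ec)
    synth = rc.k_m0 * eq.P + rc.k_mR * eq.S_R + rc.k_mL * eq.S_L
    return rc.k_p * synth / (rc.k_pd * rc.k_md)
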