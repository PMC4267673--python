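"""Hill and mechanistic fits of device transfer curves.

Two empirical forms are fitted to a measured transfer curve
(inducer concentration L -> steady-state per-cell output Theta):

* the Hill form  Theta = a + b L^n / (K05^n + L^n), the field's default
  descriptive fit with a free cooperativity exponent n;
* the leaky hyperbola  Theta = a1 (a2 + L) / (a3 + L), the closed form
  of the equilibrium model with leak pathways, whose parameters map
  onto measurable quantities (basal output a1*a2/a3, amplitude a1,
  turning point a3 - 2*a2).

The two are connected: any leaky hyperbola with a3 > a2 is exactly a
Hill curve with n = 1, a = a1*a2/a3, b = a1*(a3-a2)/a3 and K05 = a3, so
a free-exponent Hill fit to noiseless hyperbolic data must return n = 1.

A third fitter estimates one shared mechanistic parameter set
(V0, K2*r', K3*r', eps_R, eps_L, 1/K1) jointly across constructs that
differ only in their receptor RBS strength phi, through the
phi-dependence of (a1, a2, a3).

Fits use bounded trust-region nonlinear least squares on the linear
output scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .equilibrium_model import DeviceParams, EquilibriumConstants, HyperbolicParams, leaky_coefficients, leaky_transfer

__all__ = [
    "HillParams",
    "TransferCurve",
    "FitError",
    "LeakyFit",
    "MechanisticFit",
    "hill_curve",
    "fit_hill",
    "fit_leaky",
    "fit_mechanistic_shared",
    "pearson",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge.

    Carries the best iterate and its residual norm for diagnosis.
    """

    def __init__(self, message: str, best_params=None, residual_norm: float | None = None):
        super().__init__(message)
        self.best_params = best_params
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class TransferCurve:
    """Measured (inducer, output) pairs for one construct.

    Ligand concentrations are molar, may include 0, and must be distinct
    and sorted ascending.
    """

    ligand: np.ndarray
    theta: np.ndarray
    construct: str = ""
    phi: float = float("nan")

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        if lig.shape != th.shape or lig.ndim != 1:
            raise ValueError("ligand and theta must be 1-D arrays of equal length")
        if np.any(lig < 0):
            raise ValueError("ligand concentrations must be >= 0")
        if np.any(np.diff(lig) <= 0):
            raise ValueError("ligand concentrations must be distinct and sorted ascending")
        object.__setattr__(self, "ligand", lig)
        object.__setattr__(self, "theta", th)

    def __len__(self) -> int:
        return self.ligand.size


@dataclass(frozen=True)
class HillParams:
    """Hill-fit parameters: basal a, amplitude b, half-max K05, exponent n."""

    a: float
    b: float
    K05: float
    n: float
    r2: float | None = None
    se: dict | None = None

    def __post_init__(self) -> None:
        if self.b < 0 or self.K05 <= 0 or self.n <= 0:
            raise ValueError("require b >= 0, K05 > 0, n > 0")


def hill_curve(L, hp: HillParams):
    """Evaluate Theta = a + b L^n / (K05^n + L^n) (L = 0 maps to a)."""
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore"):
        Ln = np.where(L > 0, L, np.nan) ** hp.n
    out = hp.a + np.where(L > 0, hp.b * Ln / (hp.K05 ** hp.n + Ln), 0.0)
    return float(out) if out.ndim == 0 else out


def _r2(resid: np.ndarray, y: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")


def _asymptotic_se(res, names) -> dict | None:
    # s^2 (J^T J)^-1 from the trust-region Jacobian at the solution
    dof = res.fun.size - res.x.size
    if dof <= 0:
        return None
    s2 = float(np.sum(res.fun**2)) / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return None
    return dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))


def _mid_signal_ligand(lig: np.ndarray, th: np.ndarray) -> float:
    """Geometric-mean ligand concentration bracketing the half-signal level."""
    pos = lig > 0
    lp, tp = lig[pos], th[pos]
    mid = 0.5 * (np.nanmin(th) + np.nanmax(th))
    above = tp >= mid
    if above.all() or not above.any():
        return float(np.exp(np.mean(np.log(lp))))
    lo = lp[~above].max()
    hi = lp[above].min()
    return float(np.sqrt(lo * hi))


def _check_design(tc: TransferCurve, n_params: int) -> None:
    if len(tc) < max(5, n_params + 1):
        raise ValueError(f"need at least {max(5, n_params + 1)} points, got {len(tc)}")
    pos = tc.ligand[tc.ligand > 0]
    if pos.size and np.log10(pos.max() / pos.min()) < 2:
        raise ValueError("ligand design must span at least two decades")


def _loss_weights(y: np.ndarray, relative: bool) -> np.ndarray:
    """Unit weights, or inverse-signal weights for multiplicative noise."""
    if not relative:
        return np.ones_like(y)
    floor = 1e-3 * float(np.nanmax(np.abs(y))) or 1.0
    return 1.0 / np.maximum(np.abs(y), floor)


def fit_hill(tc: TransferCurve, init: HillParams | None = None, relative_weights: bool = False) -> HillParams:
    """Fit the four-parameter Hill form by bounded nonlinear least squares.

    Parameters are constrained nonnegative (K05 and n strictly
    positive).  Initialization, unless given: a = min(Theta),
    b = max - min, K05 = geometric-mean ligand at mid-signal, n = 1.
    The loss is on the linear output scale; ``relative_weights`` divides
    residuals by the signal, appropriate when noise is multiplicative.
    Returns estimates with r-squared and asymptotic standard errors.
    """
    _check_design(tc, 4)
    lig, y = tc.ligand, tc.theta
    w = _loss_weights(y, relative_weights)
    if init is None:
        a0 = float(np.nanmin(y))
        b0 = max(float(np.nanmax(y) - np.nanmin(y)), 1e-12)
        k0 = _mid_signal_ligand(lig, y)
        p0 = np.array([max(a0, 0.0), b0, k0, 1.0])
    else:
        p0 = np.array([init.a, init.b, init.K05, init.n])

    def resid(p):
        a, b, k, n = p
        with np.errstate(over="ignore", invalid="ignore"):
            Ln = np.where(lig > 0, lig, 1.0) ** n
            model = a + np.where(lig > 0, b * Ln / (k**n + Ln), 0.0)
        return w * (model - y)

    res = least_squares(
        resid,
        p0,
        bounds=([0.0, 0.0, 1e-300, 1e-3], [np.inf, np.inf, np.inf, 20.0]),
        method="trf",
        x_scale=np.maximum(np.abs(p0), [1.0, 1.0, 1e-12, 0.1]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10_000,
    )
    if not res.success:
        raise FitError(
            f"Hill fit did not converge: {res.message}",
            best_params=res.x,
            residual_norm=float(np.linalg.norm(res.fun)),
        )
    a, b, k, n = res.x
    return HillParams(
        a=a, b=b, K05=k, n=n, r2=_r2(res.fun / w, y), se=_asymptotic_se(res, ("a", "b", "K05", "n"))
    )


@dataclass(frozen=True)
class LeakyFit:
    """Result of a leaky-hyperbola fit with derived observables."""

    params: HyperbolicParams
    r2: float
    se: dict | None
    G0: float
    L05: float | None


def fit_leaky(
    tc: TransferCurve, init: HyperbolicParams | None = None, relative_weights: bool = False
) -> LeakyFit:
    """Fit Theta = a1 (a2 + L)/(a3 + L) by bounded least squares.

    The zero-inducer point, when present, anchors the basality constant
    a2 and is always kept in the loss.  All parameters are constrained
    nonnegative (a3 strictly positive); a2 may reach 0, in which case
    the model degenerates to a two-parameter Michaelis-Menten form.
    Derived observables (basal output G0 = a1 a2 / a3 and turning point
    L05 = a3 - 2 a2) are reported alongside.  A fitted a3 within one
    standard error of a2 means the curve is flat and the affinity is
    unidentifiable; this is warned about.
    """
    _check_design(tc, 3)
    lig, y = tc.ligand, tc.theta
    w = _loss_weights(y, relative_weights)
    if init is None:
        a1_0 = max(float(np.nanmax(y)), 1e-12)
        a3_0 = _mid_signal_ligand(lig, y)
        base = max(float(np.nanmin(y)), 0.0)
        a2_0 = max(base / a1_0 * a3_0, 1e-6 * a3_0)
        p0 = np.array([a1_0, a2_0, a3_0])
    else:
        p0 = np.array([init.a1, init.a2, init.a3])

    def resid(p):
        a1, a2, a3 = p
        return w * (a1 * (a2 + lig) / (a3 + lig) - y)

    res = least_squares(
        resid,
        p0,
        bounds=([0.0, 0.0, 1e-300], [np.inf, np.inf, np.inf]),
        method="trf",
        x_scale=np.maximum(np.abs(p0), [1.0, 1e-14, 1e-12]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10_000,
    )
    if not res.success:
        raise FitError(
            f"leaky fit did not converge: {res.message}",
            best_params=res.x,
            residual_norm=float(np.linalg.norm(res.fun)),
        )
    a1, a2, a3 = res.x
    se = _asymptotic_se(res, ("a1", "a2", "a3"))
    if se is not None and abs(a3 - a2) <= se.get("a3", 0.0):
        warnings.warn("flat curve, affinity unidentifiable (a3 ~ a2 within fitted uncertainty)", RuntimeWarning)
    hp = HyperbolicParams(a1=a1, a2=a2, a3=max(a3, 1e-300))
    l05 = a3 - 2.0 * a2
    return LeakyFit(params=hp, r2=_r2(res.fun / w, y), se=se, G0=a1 * a2 / a3, L05=l05 if l05 > 0 else None)


@dataclass(frozen=True)
class MechanisticFit:
    """Shared mechanistic parameters fitted jointly across constructs.

    Only the products K2*r' and K3*r' are identifiable from transfer
    curves, so the returned EquilibriumConstants use r' = 1 by
    convention (K2 and K3 then carry the products).
    """

    device: DeviceParams
    constants: EquilibriumConstants
    coefficients: dict[str, HyperbolicParams]
    predictions: dict[str, np.ndarray]
    r2: float
    cost: float


_MECH_NAMES = ("V0", "K2r", "K3r", "eps_R", "eps_L", "K1_inv")


def _mech_coeffs(p: np.ndarray, phi: float) -> HyperbolicParams:
    V0, K2r, K3r, eps_R, eps_L, K1_inv = p
    dp = DeviceParams(phi=phi, r_prime=1.0, V=V0 * eps_L, V0=V0, eps_R=eps_R, eps_L=eps_L)
    ec = EquilibriumConstants(K0=0.0, K1=1.0 / K1_inv, K2=K2r, K3=K3r)
    return leaky_coefficients(phi, ec, dp)


def fit_mechanistic_shared(
    curves: dict[str, TransferCurve] | list[TransferCurve],
    init: dict[str, float] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> MechanisticFit:
    """Fit one shared parameter set across constructs differing only in phi.

    Minimizes the pooled weighted squared error (each construct weighted
    by the inverse of its maximal output, so curves of different
    amplitude contribute comparably) over
    (V0, K2*r', K3*r', eps_R, eps_L, 1/K1), which determine each
    construct's (a1, a2, a3) through the RBS strength phi.  The search
    runs in log-parameter space from a data-driven start plus seeded
    random restarts, keeping the lowest cost.
    """
    if isinstance(curves, dict):
        curve_list = list(curves.values())
    else:
        curve_list = list(curves)
    if len(curve_list) < 2:
        raise ValueError(
            "at least two constructs with distinct phi are required: with a single curve the "
            "pairs (V0, eps_L), (K2*r', eps_R) and (K3*r', 1/K1) are unidentifiable"
        )
    phis = [tc.phi for tc in curve_list]
    if any(not np.isfinite(p) for p in phis):
        raise ValueError("every curve must carry a known phi")
    if len(set(phis)) < 2:
        raise ValueError("constructs must have distinct phi values")
    labels = [tc.construct or f"phi={tc.phi:g}" for tc in curve_list]

    weights = [1.0 / max(float(np.nanmax(tc.theta)), 1e-300) for tc in curve_list]

    def resid_log(q):
        p = np.exp(q)
        parts = []
        for tc, w in zip(curve_list, weights):
            hp = _mech_coeffs(p, tc.phi)
            parts.append(w * (leaky_transfer(tc.ligand, hp) - tc.theta))
        return np.concatenate(parts)

    # data-driven start: per-construct hyperbola fits anchor the scales
    if init is not None:
        p0 = np.array([init[k] for k in _MECH_NAMES], dtype=float)
    else:
        per = {}
        for tc in curve_list:
            try:
                per[tc.phi] = fit_leaky(tc).params
            except (FitError, ValueError):
                continue
        weak_phi = min(per) if per else min(phis)
        strong_phi = max(per) if per else max(phis)
        if per:
            k1_inv0 = per[weak_phi].a3
            v0_0 = max(per[weak_phi].a1 * per[weak_phi].a2 / per[weak_phi].a3, 1e-6)
            eps_l0 = max(per[strong_phi].a1 / v0_0, 2.0)
            k3r0 = max(1.0 / max(strong_phi, 1e-6), 10.0)
        else:
            k1_inv0, v0_0, eps_l0, k3r0 = 1e-6, 1.0, 10.0, 100.0
        p0 = np.array([v0_0, 1.0, k3r0, 10.0, eps_l0, k1_inv0])

    rng = np.random.default_rng(seed)
    starts = [np.log(p0)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.log(p0) + rng.uniform(-2.0, 2.0, size=p0.size))

    best = None
    for q0 in starts:
        try:
            res = least_squares(resid_log, q0, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20_000)
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("shared mechanistic fit failed from every start")

    p = np.exp(best.x)
    V0, K2r, K3r, eps_R, eps_L, K1_inv = p
    device = DeviceParams(phi=float("nan"), r_prime=1.0, V=V0 * eps_L, V0=V0, eps_R=eps_R, eps_L=eps_L)
    constants = EquilibriumConstants(K0=0.0, K1=1.0 / K1_inv, K2=K2r, K3=K3r)
    coeffs = {lab: _mech_coeffs(p, tc.phi) for lab, tc in zip(labels, curve_list)}
    preds = {lab: leaky_transfer(tc.ligand, coeffs[lab]) for lab, tc in zip(labels, curve_list)}
    all_y = np.concatenate([tc.theta for tc in curve_list])
    all_pred = np.concatenate([preds[lab] for lab in labels])
    return MechanisticFit(
        device=device,
        constants=constants,
        coefficients=coeffs,
        predictions=preds,
        r2=_r2(all_pred - all_y, all_y),
        cost=float(best.cost),
    )


def pearson(model_values, data_values) -> float:
    """Product-moment correlation between model and data vectors."""
    x = np.asarray(model_values, dtype=float)
    y = np.asarray(data_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)
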