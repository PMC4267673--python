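"""Synthetic plate-reader experiments for the inducible Lux device.

The generator emulates the characterization experiment the analysis
pipeline expects: three constructs differing only in receptor RBS
strength (phi = 1, 0.3, 0.03), eight nonzero inducer concentrations
spanning 1e-10 to 1e-4 M plus a zero-inducer condition, readings every
10 minutes for 14 hours, six replicate experiments, and cell-free
background wells for both absorbance and fluorescence.

Per construct, the per-cell reporter level approaches the steady-state
transfer function Theta*(L) = a1 (a2 + L)/(a3 + L) through the
two-exponential relaxation of the linear mRNA/protein kinetics
(timescales 1/k_md and 1/k_pd).  Growth is logistic.  The raw
fluorescence of a sample well is constructed as

    f_S(t) = f_B(t) + Theta_true(t, L) * (OD_S(t) - OD_B(t)) * noise

so that the Theta transform (background-corrected fluorescence over
background-corrected OD) is its exact inverse at zero noise; every
latent quantity is emitted alongside for recovery tests.

The GFP channel reports receptor expression: a constant per-cell level
proportional to phi, with an optional phenomenological "burden" mode
that depresses it at high inducer (as seen for strong-RBS constructs);
burden is a test knob, not a mechanistic claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .equilibrium_model import HyperbolicParams, leaky_transfer
from .steady_state import PlateTimeSeries

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "Kinetics",
    "CHARACTERIZED_PARAMS",
    "growth_curve",
    "expression_relaxation",
    "simulate_plate",
    "PlateSimulation",
    "export_ground_truth",
    "load_ground_truth",
]


def _default_conditions() -> list[float]:
    # zero-inducer well plus 8 log-spaced levels spanning 1e-10..1e-4 M
    return [0.0] + list(np.logspace(-10, -4, 8))


#: transfer-curve parameters of the three characterized constructs
#: (amplitude a1 in Theta units, a2 and a3 in molar)
CHARACTERIZED_PARAMS: dict[str, HyperbolicParams] = {
    "strong": HyperbolicParams(a1=3.6e4, a2=3.2e-10, a3=1.5e-8),
    "medium": HyperbolicParams(a1=4.0e4, a2=4.0e-10, a3=2.6e-8),
    "weak": HyperbolicParams(a1=4.1e4, a2=12.7e-10, a3=22.0e-8),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one characterization run.

    Defaults reproduce the study design: readings every 10 min for
    14 h, six replicates, zero plus eight inducer levels, and the
    strong/medium/weak RBS constructs (phi = 1, 0.3, 0.03).
    """

    conditions: list[float] = field(default_factory=_default_conditions)
    t_end: float = 840.0
    dt: float = 10.0
    replicates: int = 6
    constructs: list[tuple[str, float]] = field(
        default_factory=lambda: [("strong", 1.0), ("medium", 0.3), ("weak", 0.03)]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.dt, self.dt)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the virtual plate reader.

    od_sd            -- additive absorbance noise sd (OD units);
    fluor_cv         -- multiplicative noise on the fluorescence signal;
    background_od    -- blank-well absorbance (LB medium);
    background_fluor -- blank-well fluorescence (counts);
    background_fluor_slope -- linear drift of blank fluorescence per min.
    """

    od_sd: float = 0.002
    fluor_cv: float = 0.05
    background_od: float = 0.04
    background_fluor: float = 50.0
    background_fluor_slope: float = 0.02

    def __post_init__(self) -> None:
        for name in ("od_sd", "fluor_cv", "background_od", "background_fluor", "background_fluor_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise parameter {name} must be >= 0")


@dataclass(frozen=True)
class Kinetics:
    """Expression kinetics shaping the approach to steady state.

    Defaults: mRNA half-life ~5 min (k_md = 0.14/min) and protein
    dilution at a ~40 min doubling time (k_pd = 0.017/min), so the
    per-cell signal is within a fraction of a percent of steady state
    well before the 14 h endpoint.
    """

    k_md: float = 0.14
    k_pd: float = 0.017
    maturation_min: float = 0.0  # optional first-order maturation lag, off by default

    def __post_init__(self) -> None:
        if self.k_md <= 0 or self.k_pd <= 0:
            raise ValueError("decay rates must be > 0")
        if self.maturation_min < 0:
            raise ValueError("maturation lag must be >= 0")


def growth_curve(t, od0: float = 0.15, od_max: float = 1.2, rate: float = 0.01):
    """Logistic culture growth: OD(0) = od0, OD -> od_max, inflection at od_max/2."""
    if rate <= 0:
        raise ValueError("growth rate must be > 0")
    if not od_max > od0 > 0:
        raise ValueError("require od_max > od0 > 0")
    t = np.asarray(t, dtype=float)
    out = od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-rate * t))
    return float(out) if out.ndim == 0 else out


def expression_relaxation(t, kin: Kinetics):
    """Fractional approach of the per-cell reporter to its steady state.

    For mRNA and protein starting at zero, G(t)/G* =
    1 - (k_pd e^{-k_md t} - k_md e^{-k_pd t}) / (k_pd - k_md); an extra
    first-order stage models fluorophore maturation when enabled.
    """
    t = np.asarray(t, dtype=float)
    a, b = kin.k_md, kin.k_pd
    if np.isclose(a, b):
        frac = 1.0 - np.exp(-a * t) * (1.0 + a * t)
    else:
        frac = 1.0 - (b * np.exp(-a * t) - a * np.exp(-b * t)) / (b - a)
    if kin.maturation_min > 0:
        km = 1.0 / kin.maturation_min
        frac = frac * (1.0 - np.exp(-km * t))
    return float(frac) if frac.ndim == 0 else frac


@dataclass
class PlateSimulation:
    """One simulated run: plates per construct plus the full ground truth."""

    plates: dict[str, PlateTimeSeries]
    truth: dict


def simulate_plate(
    design: ExperimentDesign,
    transfer_params: dict[str, HyperbolicParams] | None = None,
    noise: NoiseModel | None = None,
    kinetics: Kinetics | None = None,
    gfp_scale: float = 2.0e4,
    burden_fraction: float = 0.0,
    growth: dict | None = None,
) -> PlateSimulation:
    """Simulate the full plate-reader characterization experiment.

    One plate table per construct, in the tidy long format the analysis
    pipeline reads.  ``transfer_params`` gives each construct's true
    steady-state curve (defaults to the characterized strong/medium/weak
    parameter sets).  All randomness flows from ``design.seed``; the same
    seed yields bit-identical output.

    The GFP (receptor) channel is a constant per-cell level
    ``gfp_scale * phi``; with ``burden_fraction > 0`` it is reduced by up
    to that fraction at saturating inducer, scaled by phi so the strong
    construct is most affected.
    """
    transfer_params = dict(transfer_params or CHARACTERIZED_PARAMS)
    noise = noise or NoiseModel()
    kinetics = kinetics or Kinetics()
    growth = growth or {}
    rng = np.random.default_rng(design.seed)

    times = design.times
    conds = np.asarray(design.conditions, dtype=float)
    T, C, R = times.size, conds.size, design.replicates

    od_true = growth_curve(times, **growth)  # shared growth across conditions
    relax = expression_relaxation(times, kinetics)
    bg_od = noise.background_od
    bg_fluor_t = noise.background_fluor + noise.background_fluor_slope * times

    plates: dict[str, PlateTimeSeries] = {}
    truth: dict = {
        "design": {
            "conditions_M": conds.tolist(),
            "t_end_min": design.t_end,
            "dt_min": design.dt,
            "replicates": R,
            "constructs": [list(c) for c in design.constructs],
            "seed": design.seed,
        },
        "noise": asdict(noise),
        "kinetics": asdict(kinetics),
        "gfp_scale": gfp_scale,
        "burden_fraction": burden_fraction,
        "constructs": {},
    }

    for label, phi in design.constructs:
        if label not in transfer_params:
            raise ValueError(f"no transfer parameters for construct {label!r}")
        hp = transfer_params[label]
        theta_ss = leaky_transfer(conds, hp)  # (C,)
        theta_rfp = np.outer(relax, theta_ss)  # (T, C)
        burden = 1.0 - burden_fraction * phi * conds / (conds + hp.a3)  # (C,)
        theta_gfp = gfp_scale * phi * burden[None, :] * np.ones((T, 1))

        rows = []
        for rep in range(1, R + 1):
            od_S = od_true[:, None] + rng.normal(0.0, noise.od_sd, size=(T, C))
            od_B = bg_od + rng.normal(0.0, noise.od_sd, size=(T, C))
            f_B_rfp = bg_fluor_t[:, None] + rng.normal(0.0, noise.od_sd * 100, size=(T, C))
            f_B_gfp = bg_fluor_t[:, None] + rng.normal(0.0, noise.od_sd * 100, size=(T, C))
            span = od_true[:, None] - bg_od
            mult_r = 1.0 + rng.normal(0.0, noise.fluor_cv, size=(T, C)) if noise.fluor_cv else 1.0
            mult_g = 1.0 + rng.normal(0.0, noise.fluor_cv, size=(T, C)) if noise.fluor_cv else 1.0
            f_S_rfp = bg_fluor_t[:, None] + theta_rfp * span * mult_r
            f_S_gfp = bg_fluor_t[:, None] + theta_gfp * span * mult_g

            tt = np.repeat(times, C)
            cc = np.tile(conds, T)
            for channel, wt, vk, vals in (
                ("", "sample", "od", od_S),
                ("", "background", "od", od_B),
                ("RFP", "sample", "fluor", f_S_rfp),
                ("RFP", "background", "fluor", f_B_rfp),
                ("GFP", "sample", "fluor", f_S_gfp),
                ("GFP", "background", "fluor", f_B_gfp),
            ):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_min": tt,
                            "condition_M": cc,
                            "channel": channel,
                            "well_type": wt,
                            "value_kind": vk,
                            "value": vals.ravel(),
                            "replicate": rep,
                        }
                    )
                )
        plates[label] = PlateTimeSeries(data=pd.concat(rows, ignore_index=True), label=label)
        truth["constructs"][label] = {
            "phi": phi,
            "a1": hp.a1,
            "a2": hp.a2,
            "a3": hp.a3,
            "theta_steady": theta_ss.tolist(),
            "theta_final": (theta_ss * relax[-1]).tolist(),
            "gfp_per_cell": (gfp_scale * phi * burden).tolist(),
        }
    return PlateSimulation(plates=plates, truth=truth)


GROUND_TRUTH_SCHEMA = "luxfer-ground-truth/1"


def export_ground_truth(run: PlateSimulation, path) -> None:
    """Serialize every latent parameter and noiseless signal to JSON."""
    doc = {"schema": GROUND_TRUTH_SCHEMA, **run.truth}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_ground_truth(path) -> dict:
    """Read a ground-truth sidecar, checking its schema tag."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != GROUND_TRUTH_SCHEMA:
        raise ValueError(f"unexpected ground-truth schema: {doc.get('schema')!r}")
    doc.pop("schema")
    return doc
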