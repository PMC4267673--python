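"""Delimited-text formats and unit-checked configuration.

All tabular interchange is comma-separated text:

* plate tables — one tidy row per reading:
  ``time_min, condition_M, channel, well_type, value_kind, value, replicate``;
* transfer curves — ``ligand_M, output, construct, phi``.

Configuration and parameter files are YAML.  Every key that carries a
dimensioned quantity must state its unit as a suffix (``_M``, ``_uM``,
``_nM``, ``_per_M``, ``_per_uM``, ``_min``, ``_h``); values are converted
to the internal units (molar, minutes) on read.  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .fitting import TransferCurve
from .steady_state import PLATE_COLUMNS, PlateTimeSeries

__all__ = [
    "read_plate",
    "write_plate",
    "read_transfer_curve",
    "write_transfer_curve",
    "split_unit_key",
    "convert_quantity",
    "RunConfig",
    "load_config",
]

# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------


def read_plate(path, label: str | None = None) -> PlateTimeSeries:
    """Read a long-format plate table, validating schema and row contents.

    Row order is immaterial.  Malformed rows (non-numeric value, unknown
    well_type or value_kind) are reported with their file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"channel": str}, keep_default_na=True, float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns: {missing}")
    df["channel"] = df["channel"].fillna("")

    def lines(mask) -> list[int]:
        # +2: one for the header, one for 0-based indexing
        return [int(i) + 2 for i in df.index[mask][:10]]

    problems = []
    for col in ("time_min", "condition_M", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            problems.append(f"non-numeric {col} at line(s) {lines(bad)}")
    bad_wt = ~df["well_type"].isin(["sample", "background"])
    if bad_wt.any():
        problems.append(f"unknown well_type at line(s) {lines(bad_wt)}")
    bad_vk = ~df["value_kind"].isin(["od", "fluor"])
    if bad_vk.any():
        problems.append(f"unknown value_kind at line(s) {lines(bad_vk)}")
    if problems:
        raise ValueError(f"{path.name}: malformed rows: " + "; ".join(problems))
    for col in ("time_min", "condition_M", "value"):
        df[col] = pd.to_numeric(df[col])
    df = df.sort_values(["replicate", "value_kind", "channel", "well_type", "time_min", "condition_M"]).reset_index(
        drop=True
    )
    return PlateTimeSeries(data=df, label=label if label is not None else path.stem)


def write_plate(plate: PlateTimeSeries, path) -> None:
    # %.17g keeps the text round trip bit-exact for float64
    plate.data.to_csv(path, index=False, columns=list(PLATE_COLUMNS), float_format="%.17g")


# ---------------------------------------------------------------------------
# transfer curves
# ---------------------------------------------------------------------------


def read_transfer_curve(path) -> TransferCurve:
    """Read ``ligand_M, output[, construct, phi]`` into a TransferCurve."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("ligand_M", "output"):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    df = df.sort_values("ligand_M")
    construct = str(df["construct"].iloc[0]) if "construct" in df.columns else path.stem
    phi = float(df["phi"].iloc[0]) if "phi" in df.columns else float("nan")
    return TransferCurve(
        ligand=df["ligand_M"].to_numpy(dtype=float),
        theta=df["output"].to_numpy(dtype=float),
        construct=construct,
        phi=phi,
    )


def write_transfer_curve(tc: TransferCurve, path) -> None:
    pd.DataFrame(
        {"ligand_M": tc.ligand, "output": tc.theta, "construct": tc.construct, "phi": tc.phi}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

#: unit suffix -> (dimension, factor to internal units)
_UNIT_SUFFIXES = {
    "M": ("concentration", 1.0),
    "mM": ("concentration", 1e-3),
    "uM": ("concentration", 1e-6),
    "nM": ("concentration", 1e-9),
    "per_M": ("association", 1.0),
    "per_mM": ("association", 1e3),
    "per_uM": ("association", 1e6),
    "per_nM": ("association", 1e9),
    "min": ("time", 1.0),
    "h": ("time", 60.0),
    "per_min": ("rate", 1.0),
    "per_h": ("rate", 1.0 / 60.0),
}

#: bare parameter names whose values are dimensioned and therefore MUST
#: carry a unit suffix in config files
_DIMENSIONED_STEMS = frozenset(
    {"conditions", "condition", "r_prime", "K1_inv", "P_T", "R_T", "L", "t_end", "dt", "K1", "K2", "K3", "K0"}
)


def split_unit_key(key: str) -> tuple[str, str | None]:
    """Split ``"r_prime_uM"`` into ``("r_prime", "uM")``; no suffix -> None."""
    for suffix in sorted(_UNIT_SUFFIXES, key=len, reverse=True):
        if key.endswith("_" + suffix):
            return key[: -(len(suffix) + 1)], suffix
    return key, None


def convert_quantity(key: str, value):
    """Convert a suffixed config entry to internal units.

    Returns ``(bare_name, converted_value)``.  A dimensioned parameter
    without a recognized unit suffix is an error naming the column/key.
    """
    stem, suffix = split_unit_key(key)
    if suffix is None:
        if stem in _DIMENSIONED_STEMS:
            raise ValueError(
                f"key {key!r} carries a dimensioned quantity but has no recognized unit suffix "
                f"(expected one of {sorted(_UNIT_SUFFIXES)})"
            )
        return key, value
    _, factor = _UNIT_SUFFIXES[suffix]
    if isinstance(value, (list, tuple)):
        return stem, [float(v) * factor for v in value]
    return stem, float(value) * factor


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated, unit-normalized pipeline configuration."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    steady_state: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


_TOP_KEYS = {"seed", "design", "noise", "steady_state", "fit", "paths", "params"}
_SECTION_KEYS = {
    "design": {"conditions", "t_end", "dt", "replicates", "constructs"},
    "noise": {"od_sd", "fluor_cv", "background_od", "background_fluor", "background_fluor_slope"},
    "steady_state": {"window_points", "alpha_threshold", "threshold_fraction", "od_floor", "channel"},
    "fit": {"model", "relative_weights"},
    "paths": {"outdir", "plate", "curve"},
    "params": {"V", "V0", "eps_R", "eps_L", "K0", "K1", "K2", "K3", "r_prime", "K1_inv", "P_T", "phi"},
}


def _normalize_section(name: str, section: dict) -> dict:
    out = {}
    for key, value in section.items():
        stem, converted = convert_quantity(key, value)
        if stem not in _SECTION_KEYS[name]:
            raise ValueError(f"unknown key {key!r} in config section {name!r}")
        out[stem] = converted
    return out


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = RunConfig(seed=int(doc.get("seed", 0)))
    for name in ("design", "noise", "steady_state", "fit", "paths", "params"):
        section = doc.get(name) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        setattr(cfg, name, _normalize_section(name, section))
    return cfg
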