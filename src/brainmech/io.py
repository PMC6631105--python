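"""Delimited-text and config-file I/O.

All tabular artifacts are comma-delimited text with period decimals and
exact header names; stress-strain tables carry ``true_strain``,
``true_stress_kPa``, ``rate_per_s``, ``label``.  Config files are YAML with
keys named exactly as the corresponding dataclass fields.  Round trips are
lossless at full double precision.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialConstants, StressStrainCurve, WaterEOSParams
from .shpb import BarSpec, GaugeRecordSet, SHPBConfig

__all__ = [
    "CurveTableError",
    "read_curve_table",
    "write_curve_table",
    "read_gauge_table",
    "write_gauge_table",
    "load_material_constants",
    "save_material_constants",
    "default_material_constants",
    "load_water_eos",
    "load_shpb_config",
    "save_shpb_config",
]

CURVE_COLUMNS = ("true_strain", "true_stress_kPa", "rate_per_s", "label")
GAUGE_COLUMNS = ("time_s", "incident_strain", "transmitted_strain")


class CurveTableError(ValueError):
    """Malformed curve/gauge table (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _sniff_locale(path: Path) -> None:
    """Reject decimal-comma / semicolon-delimited dialects explicitly."""
    with open(path) as fh:
        fh.readline()  # header
        for raw in fh:
            if raw.strip():
                if ";" in raw or ('"' in raw and "," in raw.split('"')[1]):
                    raise CurveTableError(
                        "file appears to use a decimal-comma locale dialect "
                        "(semicolon delimiter or quoted decimal commas); "
                        "tables must use comma delimiters with period "
                        "decimals")
                return


def write_curve_table(curve: StressStrainCurve, path) -> Path:
    """Write one stress-strain curve as delimited text (full precision)."""
    path = Path(path)
    frame = pd.DataFrame({
        "true_strain": curve.true_strain,
        "true_stress_kPa": curve.true_stress,
        "rate_per_s": curve.nominal_rate,
        "label": curve.label,
    })
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_curve_table(path) -> StressStrainCurve:
    """Read a stress-strain curve, validating header, dialect and
    monotonicity (errors carry 1-based file line numbers)."""
    path = Path(path)
    _sniff_locale(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise CurveTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveTableError(
            f"missing required column(s) {missing}; header must contain "
            f"{list(CURVE_COLUMNS)}")
    strain = frame["true_strain"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(strain) <= 0)[0]
    if bad.size:
        raise CurveTableError("true_strain must be strictly increasing",
                              line=int(bad[0]) + 3)  # header + 1-based + next
    rates = frame["rate_per_s"].unique()
    labels = frame["label"].unique()
    return StressStrainCurve(
        strain, frame["true_stress_kPa"].to_numpy(dtype=float),
        nominal_rate=float(rates[0]),
        label=str(labels[0]) if len(labels) else "",
        meta={"path": str(path)})


def write_gauge_table(gauges: GaugeRecordSet, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_s": gauges.time,
        "incident_strain": gauges.incident_strain,
        "transmitted_strain": gauges.transmitted_strain,
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_gauge_table(path) -> GaugeRecordSet:
    path = Path(path)
    _sniff_locale(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAUGE_COLUMNS if c not in frame.columns]
    if missing:
        raise CurveTableError(
            f"missing required column(s) {missing}; header must contain "
            f"{list(GAUGE_COLUMNS)}")
    return GaugeRecordSet(
        time=frame["time_s"].to_numpy(dtype=float),
        incident_strain=frame["incident_strain"].to_numpy(dtype=float),
        transmitted_strain=frame["transmitted_strain"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def load_material_constants(path) -> MaterialConstants:
    """Material constants from a YAML key-value file (keys = field names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a key-value mapping")
    return MaterialConstants.from_dict(data)


def save_material_constants(consts: MaterialConstants, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(consts.as_dict(), fh, sort_keys=False)
    return path


def default_material_constants() -> MaterialConstants:
    """The packaged dry-brain constants file, parsed."""
    ref = resources.files("brainmech.data") / "dry_brain_tp11.yaml"
    return MaterialConstants.from_dict(yaml.safe_load(ref.read_text()))


def load_water_eos(path=None) -> WaterEOSParams:
    """Water EOS parameters from YAML (packaged defaults when no path)."""
    if path is None:
        ref = resources.files("brainmech.data") / "water_eos.yaml"
        data = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return WaterEOSParams(**data)


_BAR_FIELDS = [f.name for f in dataclasses.fields(BarSpec)]


def load_shpb_config(path) -> SHPBConfig:
    """SHPB configuration from YAML: bar sub-mappings plus scalar fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kwargs = {}
    for name in ("striker", "incident", "transmitted"):
        if name in data:
            kwargs[name] = BarSpec(**data.pop(name))
    if "extra_incident_gauges" in data:
        data["extra_incident_gauges"] = tuple(data["extra_incident_gauges"])
    kwargs.update(data)
    return SHPBConfig(**kwargs)


def save_shpb_config(config: SHPBConfig, path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(config)
    data["extra_incident_gauges"] = list(config.extra_incident_gauges)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
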