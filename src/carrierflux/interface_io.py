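"""Unit conversion and file I/O for vesicle uptake datasets.

Vesicle uptake is counted per mg membrane protein but modelled as an
intravesicular concentration; the bridge is the vesicle volume conversion
factor (µl of intravesicular water per mg protein, default 1.6), itself
measurable from an equilibrium uptake experiment:

    concentration [µmol l⁻¹] = uptake [pmol mg⁻¹] / volume factor [µl mg⁻¹]

since pmol/µl ≡ µmol/l.

CSV schemas (header-validated; leading ``# key: value`` lines carry unit
metadata):

* initial-rate: ``conc_tracer_uM, conc_unlabelled_uM, rate, replicate``
  with ``rate_units`` either ``umol_l_min`` (already concentration-based)
  or ``pmol_mg_15s`` (protein-normalized uptake over a 15 s window,
  auto-converted on read via the volume factor; the conversion is logged).
* time-course: ``condition_B_out_uM, time_s, A_in_mean, A_in_sd, n`` with
  ``a_units`` either ``umol_l`` or ``pmol_mg``, plus ``tracer_out_uM``.

Time is stored in seconds (the experimental convention) and converted to
minutes inside the package.  Floats are written at 12 significant digits so
write → read round-trips are lossless for practical purposes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .estimation import TimeCourseDataset, UptakeDataset

__all__ = [
    "VolumeFactor",
    "SchemaError",
    "protein_to_concentration",
    "concentration_to_protein",
    "volume_factor_from_equilibrium",
    "read_initial_rate_csv",
    "write_initial_rate_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

logger = logging.getLogger("carrierflux")

_FLOAT_FMT = "%.12g"
_IR_COLUMNS = ["conc_tracer_uM", "conc_unlabelled_uM", "rate", "replicate"]
_TC_COLUMNS = ["condition_B_out_uM", "time_s", "A_in_mean", "A_in_sd", "n"]


class SchemaError(ValueError):
    """A dataset file does not match its declared schema."""


@dataclass(frozen=True)
class VolumeFactor:
    """Intravesicular volume per mg membrane protein, µl mg⁻¹.

    The default 1.6 µl mg⁻¹ corresponds to an equilibrium uptake of
    1.60 nmol mg⁻¹ at a bath concentration of 1 nmol µl⁻¹.
    """

    value: float = 1.6
    note: str = "equilibrium uptake 1.60 nmol/mg at 1 nmol/ul bath"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value) and self.value > 0):
            raise ValueError(f"volume factor must be > 0, got {self.value!r}")


def protein_to_concentration(uptake, vf: VolumeFactor = VolumeFactor()):
    """Protein-normalized uptake (pmol mg⁻¹) → concentration (µmol l⁻¹)."""
    uptake = np.asarray(uptake, dtype=float)
    if np.any(uptake < 0):
        raise ValueError("uptake must be >= 0")
    out = uptake / vf.value
    return float(out) if out.ndim == 0 else out


def concentration_to_protein(conc, vf: VolumeFactor = VolumeFactor()):
    """Concentration (µmol l⁻¹) → protein-normalized uptake (pmol mg⁻¹)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    out = conc * vf.value
    return float(out) if out.ndim == 0 else out


def volume_factor_from_equilibrium(equilibrium_uptake: float,
                                   bath_concentration: float,
                                   note: str = "") -> VolumeFactor:
    """Volume factor from an equilibrium uptake measurement.

    At equilibrium the intravesicular concentration equals the bath
    concentration, so uptake [nmol mg⁻¹] / bath [nmol µl⁻¹] is the vesicle
    water space in µl mg⁻¹.
    """
    if bath_concentration <= 0:
        raise ValueError("bath_concentration must be > 0")
    if equilibrium_uptake < 0:
        raise ValueError("equilibrium_uptake must be >= 0")
    value = equilibrium_uptake / bath_concentration
    return VolumeFactor(value=value,
                        note=note or f"from equilibrium uptake "
                                     f"{equilibrium_uptake}/{bath_concentration}")


# ---------------------------------------------------------------------------
# CSV with '# key: value' metadata header
# ---------------------------------------------------------------------------

def _read_with_metadata(path):
    meta = {}
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    frame = pd.read_csv(io.StringIO("".join(lines)))
    return meta, frame


def _write_with_metadata(frame: pd.DataFrame, path, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _require_columns(frame: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_initial_rate_csv(path: Union[str, Path],
                          vf: VolumeFactor = VolumeFactor()) -> UptakeDataset:
    """Read an initial-rate dataset, converting units if declared in protein terms.

    Raises :class:`SchemaError` on missing columns or an undeclared /
    unknown ``rate_units`` metadata value.
    """
    meta, frame = _read_with_metadata(path)
    _require_columns(frame, _IR_COLUMNS, path)
    units = meta.get("rate_units")
    if units is None:
        raise SchemaError(f"{path}: metadata 'rate_units' not declared "
                          "(umol_l_min or pmol_mg_15s)")
    rate = frame["rate"].to_numpy(float)
    if units == "pmol_mg_15s":
        # pmol/mg accumulated over 15 s -> µmol/l divided by 0.25 min
        rate = protein_to_concentration(rate, vf) / (15.0 / 60.0)
        logger.info("converted rates from pmol/mg per 15 s using volume "
                    "factor %.4g ul/mg", vf.value)
    elif units != "umol_l_min":
        raise SchemaError(f"{path}: unknown rate_units {units!r}")
    return UptakeDataset(pd.DataFrame({
        "A_out0": frame["conc_tracer_uM"].to_numpy(float),
        "B_out0": frame["conc_unlabelled_uM"].to_numpy(float),
        "rate": rate,
        "replicate": frame["replicate"].to_numpy(),
    }))


def write_initial_rate_csv(dataset: UptakeDataset, path: Union[str, Path]) -> None:
    """Write an initial-rate dataset (always in µmol l⁻¹ min⁻¹)."""
    frame = pd.DataFrame({
        "conc_tracer_uM": dataset.data["A_out0"],
        "conc_unlabelled_uM": dataset.data["B_out0"],
        "rate": dataset.data["rate"],
        "replicate": dataset.data["replicate"],
    })
    _write_with_metadata(frame, path, {"rate_units": "umol_l_min"})


def read_timecourse_csv(path: Union[str, Path],
                        vf: VolumeFactor = VolumeFactor()) -> TimeCourseDataset:
    """Read a time-course dataset; protein-normalized values are converted."""
    meta, frame = _read_with_metadata(path)
    _require_columns(frame, _TC_COLUMNS, path)
    units = meta.get("a_units")
    if units is None:
        raise SchemaError(f"{path}: metadata 'a_units' not declared "
                          "(umol_l or pmol_mg)")
    if "tracer_out_uM" not in meta:
        raise SchemaError(f"{path}: metadata 'tracer_out_uM' not declared")
    mean = frame["A_in_mean"].to_numpy(float)
    sd = frame["A_in_sd"].to_numpy(float)
    if units == "pmol_mg":
        mean = protein_to_concentration(mean, vf)
        sd = sd / vf.value
        logger.info("converted tracer amounts from pmol/mg using volume "
                    "factor %.4g ul/mg", vf.value)
    elif units != "umol_l":
        raise SchemaError(f"{path}: unknown a_units {units!r}")
    return TimeCourseDataset(
        A_out0=float(meta["tracer_out_uM"]),
        data=pd.DataFrame({
            "B_out0": frame["condition_B_out_uM"].to_numpy(float),
            "time_s": frame["time_s"].to_numpy(float),
            "A_in_mean": mean,
            "A_in_sd": sd,
            "n": frame["n"].to_numpy(int),
        }))


def write_timecourse_csv(dataset: TimeCourseDataset,
                         path: Union[str, Path]) -> None:
    """Write a time-course dataset (always in µmol l⁻¹)."""
    frame = pd.DataFrame({
        "condition_B_out_uM": dataset.data["B_out0"],
        "time_s": dataset.data["time_s"],
        "A_in_mean": dataset.data["A_in_mean"],
        "A_in_sd": dataset.data["A_in_sd"],
        "n": dataset.data["n"],
    })
    _write_with_metadata(frame, path, {
        "a_units": "umol_l",
        "tracer_out_uM": _FLOAT_FMT % dataset.A_out0,
    })
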