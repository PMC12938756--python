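"""Plain-text file formats and run configuration.

Histograms travel as tab-delimited text with a ``# key = value`` header
block (wavelength, site, subject, segment, acquisition duration, bin
width, role) followed by two columns ``bin_start_ps`` and ``counts``.
Measurement counts must be nonnegative integers; IRF counts may be
fractional.  Reading back a written file reproduces the object
bit-exactly, and unknown header keys are preserved in ``meta``.

The run configuration is a YAML document with ``cohort``, ``fit`` and
``statistics`` sections mirroring :class:`~neotrs.cohort.CohortConfig`
and :class:`~neotrs.inversion.FitOptions`; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .forward import TimeAxis
from .inversion import FitOptions, InstrumentResponse, TimeHistogram

_MANDATORY_KEYS = ("bin_width_ps", "role")
_KNOWN_KEYS = ("wavelength_nm", "site", "subject_id", "segment_id",
               "acquisition_s", "bin_width_ps", "role", "total_incident")


class HistogramFormatError(ValueError):
    """Malformed histogram file."""


def _format_number(x: float) -> str:
    """Round-trip-exact decimal representation."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_histogram(obj: Union[TimeHistogram, InstrumentResponse],
                    path) -> None:
    path = Path(path)
    lines = ["# neotrs histogram v1"]
    if isinstance(obj, InstrumentResponse):
        header = {"role": "irf",
                  "bin_width_ps": obj.axis.bin_width,
                  "acquisition_s": obj.acquisition_s}
        if obj.total_incident is not None:
            header["total_incident"] = obj.total_incident
    else:
        header = {"role": "measurement",
                  "bin_width_ps": obj.axis.bin_width,
                  "acquisition_s": obj.acquisition_s}
        if obj.wavelength_nm is not None:
            header["wavelength_nm"] = obj.wavelength_nm
        if obj.site is not None:
            header["site"] = obj.site
        if obj.segment_id is not None:
            header["segment_id"] = obj.segment_id
    for k, v in obj.meta.items():
        header.setdefault(k, v)
    for k, v in header.items():
        v = _format_number(v) if isinstance(v, (int, float)) \
            and not isinstance(v, bool) else v
        lines.append(f"# {k} = {v}")
    lines.append("bin_start_ps\tcounts")
    starts = obj.axis.bin_edges[:-1]
    integral = header["role"] == "measurement"
    for t, c in zip(starts, obj.counts):
        cs = str(int(round(c))) if integral else _format_number(c)
        lines.append(f"{_format_number(t)}\t{cs}")
    path.write_text("\n".join(lines) + "\n")


def read_histogram(path) -> Union[TimeHistogram, InstrumentResponse]:
    path = Path(path)
    header: dict = {}
    starts: list = []
    counts: list = []
    role = None
    with path.open() as fh:
        in_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            if not in_data:
                if line.split("\t")[:2] != ["bin_start_ps", "counts"]:
                    raise HistogramFormatError(
                        f"{path}: line {lineno}: expected column header "
                        "'bin_start_ps\\tcounts'")
                in_data = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HistogramFormatError(
                    f"{path}: line {lineno}: expected 2 columns, "
                    f"got {len(parts)}")
            try:
                t = float(parts[0])
                c = float(parts[1])
            except ValueError:
                raise HistogramFormatError(
                    f"{path}: line {lineno}: non-numeric value") from None
            if c < 0:
                raise HistogramFormatError(
                    f"{path}: line {lineno}: negative count {parts[1]}")
            starts.append(t)
            counts.append((c, lineno, parts[1]))
    for key in _MANDATORY_KEYS:
        if key not in header:
            raise HistogramFormatError(
                f"{path}: missing mandatory header key {key!r}")
    role = header["role"]
    if role not in ("measurement", "irf"):
        raise HistogramFormatError(f"{path}: unknown role {role!r}")
    if len(starts) < 2:
        raise HistogramFormatError(f"{path}: fewer than 2 data rows")
    width = float(header["bin_width_ps"])
    starts_arr = np.asarray(starts)
    inferred = np.diff(starts_arr)
    if np.max(np.abs(inferred - width)) > 1e-6:
        raise HistogramFormatError(
            f"{path}: bin width inferred from rows "
            f"({np.median(inferred)} ps) does not match header ({width} ps)")
    if role == "measurement":
        for c, lineno, text in counts:
            if not float(c).is_integer():
                raise HistogramFormatError(
                    f"{path}: line {lineno}: measurement count {text!r} "
                    "is not an integer")
    values = np.array([c for c, _, _ in counts])
    axis = TimeAxis(np.append(starts_arr, starts_arr[-1] + width))
    known = {k: header[k] for k in _KNOWN_KEYS if k in header}
    meta = {k: v for k, v in header.items() if k not in _KNOWN_KEYS}
    if role == "irf":
        return InstrumentResponse(
            axis, values,
            total_incident=float(known["total_incident"])
            if "total_incident" in known else None,
            acquisition_s=float(known.get("acquisition_s", 1.0)),
            meta=meta)
    return TimeHistogram(
        axis, values,
        acquisition_s=float(known.get("acquisition_s", 1.0)),
        wavelength_nm=float(known["wavelength_nm"])
        if "wavelength_nm" in known else None,
        site=known.get("site"),
        segment_id=known.get("segment_id"),
        meta=meta)


def write_table(df: pd.DataFrame, path, header_lines=()) -> None:
    """Tab-delimited table with '#'-prefixed comment header."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class StatisticsOptions:
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Full pipeline configuration (cohort + fit + statistics)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitOptions = field(default_factory=FitOptions)
    statistics: StatisticsOptions = field(default_factory=StatisticsOptions)
    extinction_path: Optional[str] = None
    background_path: Optional[str] = None

    @classmethod
    def default(cls) -> "RunConfig":
        return cls()

    @classmethod
    def from_mapping(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        cfg = cls()
        sections = {"cohort": cfg.cohort, "fit": cfg.fit,
                    "statistics": cfg.statistics}
        for name, target in sections.items():
            sub = doc.pop(name, {}) or {}
            valid = {f.name for f in fields(target)}
            for key, value in sub.items():
                if key not in valid:
                    raise ValueError(
                        f"unknown config key {name}.{key!r}")
                if isinstance(value, list):
                    value = tuple(value)
                current = getattr(target, key)
                # PyYAML reads "1.0e5" (no sign) as a string; coerce
                # numerics to the field's type
                if isinstance(value, str) and isinstance(current, (int, float)) \
                        and not isinstance(current, bool):
                    value = type(current)(float(value))
                setattr(target, key, value)
        for key in ("extinction_path", "background_path"):
            if key in doc:
                setattr(cfg, key, doc.pop(key))
        if doc:
            raise ValueError(f"unknown config keys {sorted(doc)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict:
        def clean(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in d.items()}
        doc = {"cohort": clean(self.cohort), "fit": clean(self.fit),
               "statistics": clean(self.statistics)}
        if self.extinction_path:
            doc["extinction_path"] = self.extinction_path
        if self.background_path:
            doc["background_path"] = self.background_path
        return doc

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_mapping(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_mapping(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
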