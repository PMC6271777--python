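"""Reading, validating and writing compression-isotherm records.

The canonical on-disk dialect is UTF-8, comma-delimited text with a header
row naming the columns::

    area_A2_per_molecule,surface_pressure_mN_per_m[,surface_potential_mV]

Metadata travel either in a JSON sidecar (``<path>.meta.json``) or embedded
as ``# key: value`` comment lines above the header.  A plain ``two_column``
dialect (area, pressure; header optional) is accepted for quick imports from
instrument exports.

Rows are canonicalized to compression order (strictly decreasing area);
duplicate-area rows are averaged, provided they make up no more than 1 % of
the file.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    IsothermFormatError,
    IsothermValidationError,
)

logger = logging.getLogger(__name__)

AREA_COL = "area_A2_per_molecule"
PRESSURE_COL = "surface_pressure_mN_per_m"
POTENTIAL_COL = "surface_potential_mV"

_MIN_ROWS = 20
_MAX_DUPLICATE_FRACTION = 0.01
_PRESSURE_FLOOR = -1.0  # small negative baseline tolerated pre-calibration


@dataclass
class IsothermMetadata:
    """Descriptive metadata for one compression run.

    Units: concentration µg/mL, temperature °C, compression rate
    Å²/chain/min, trough area cm², subphase volume mL.
    """

    lipid: str = ""
    subphase_additive: str = "water"
    additive_concentration: Optional[float] = None
    temperature: float = 23.0
    compression_rate: Optional[float] = None
    trough_area: Optional[float] = None
    subphase_volume: Optional[float] = None
    source: str = ""
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature):
            raise IsothermValidationError("temperature must be finite")
        if self.additive_concentration is not None and self.additive_concentration < 0:
            raise IsothermValidationError("additive concentration must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["processing"] = list(self.processing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IsothermMetadata":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "processing" in kwargs and kwargs["processing"] is not None:
            kwargs["processing"] = tuple(kwargs["processing"])
        return cls(**kwargs)


@dataclass
class CompressionIsotherm:
    """Ordered (area, π, optional Δψ) samples for one compression run.

    ``area`` is strictly decreasing (compression direction), in Å²/molecule;
    ``pressure`` in mN/m; ``potential`` (if present) in mV.
    """

    area: np.ndarray
    pressure: np.ndarray
    potential: Optional[np.ndarray] = None
    metadata: IsothermMetadata = field(default_factory=IsothermMetadata)

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.potential is not None:
            self.potential = np.asarray(self.potential, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = len(self.area)
        if len(self.pressure) != n or (
            self.potential is not None and len(self.potential) != n
        ):
            raise IsothermValidationError("area/pressure/potential lengths differ")
        cols = [self.area, self.pressure] + (
            [self.potential] if self.potential is not None else []
        )
        for c in cols:
            if not np.all(np.isfinite(c)):
                raise IsothermValidationError("non-finite values after validation")
        if np.any(np.diff(self.area) >= 0):
            raise IsothermValidationError("area must be strictly decreasing")
        if np.any(self.pressure <= _PRESSURE_FLOOR):
            raise IsothermValidationError(
                f"surface pressure must exceed {_PRESSURE_FLOOR} mN/m"
            )

    def __len__(self) -> int:
        return len(self.area)

    @property
    def has_potential(self) -> bool:
        return self.potential is not None

    def replace(self, **kwargs) -> "CompressionIsotherm":
        return dataclasses.replace(self, **kwargs)


def canonicalize(
    area: Sequence[float],
    pressure: Sequence[float],
    potential: Optional[Sequence[float]] = None,
    metadata: Optional[IsothermMetadata] = None,
) -> CompressionIsotherm:
    """Build a validated, compression-ordered isotherm from raw columns.

    Rows with any missing field are dropped (with a logged count), the
    remainder sorted into decreasing area, and duplicate-area rows averaged.
    A stable sort is used so that (area, π, Δψ) triples are never reordered
    relative to each other.
    """
    cols = {AREA_COL: np.asarray(area, float), PRESSURE_COL: np.asarray(pressure, float)}
    if potential is not None:
        cols[POTENTIAL_COL] = np.asarray(potential, float)
    df = pd.DataFrame(cols)
    n_raw = len(df)
    df = df.dropna()
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing fields", n_dropped)
    if len(df) < _MIN_ROWS:
        raise InsufficientDataError(
            f"only {len(df)} valid rows; at least {_MIN_ROWS} required"
        )
    df = df.sort_values(AREA_COL, ascending=False, kind="stable").reset_index(drop=True)
    n_dup = int(df[AREA_COL].duplicated().sum())
    if n_dup:
        if n_dup > _MAX_DUPLICATE_FRACTION * len(df):
            raise IsothermValidationError(
                f"{n_dup} duplicate-area rows exceed the "
                f"{_MAX_DUPLICATE_FRACTION:.0%} tolerance"
            )
        logger.info("averaging %d duplicate-area rows", n_dup)
        df = df.groupby(AREA_COL, as_index=False, sort=False).mean()
    pot = df[POTENTIAL_COL].to_numpy() if POTENTIAL_COL in df else None
    return CompressionIsotherm(
        area=df[AREA_COL].to_numpy(),
        pressure=df[PRESSURE_COL].to_numpy(),
        potential=pot,
        metadata=metadata or IsothermMetadata(),
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _parse_comment_header(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key = key.strip()
        value = value.strip()
        try:
            meta[key] = json.loads(value)
        except (json.JSONDecodeError, ValueError):
            meta[key] = value
    return meta


def read_isotherm(path, dialect: str = "canonical") -> CompressionIsotherm:
    """Read one compression isotherm from a delimited text file.

    ``dialect='canonical'`` requires the canonical header names;
    ``dialect='two_column'`` accepts a bare (area, pressure) file with or
    without a header row.  Files in either area order are canonicalized to
    compression (decreasing-area) order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    comment_lines = [ln for ln in lines if ln.startswith("#")]
    data_lines = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    if not data_lines:
        raise InsufficientDataError(f"{path} contains no data rows")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    elif comment_lines:
        meta = _parse_comment_header(comment_lines)
    metadata = IsothermMetadata.from_dict(meta) if meta else IsothermMetadata()

    buf = _stdio.StringIO("\n".join(data_lines))
    if dialect == "canonical":
        df = pd.read_csv(buf, float_precision="round_trip")
        df.columns = [c.strip() for c in df.columns]
        if AREA_COL not in df.columns or PRESSURE_COL not in df.columns:
            raise IsothermFormatError(
                f"{path}: expected header columns {AREA_COL!r}, {PRESSURE_COL!r} "
                f"(optionally {POTENTIAL_COL!r}); found {list(df.columns)}"
            )
        extra = set(df.columns) - {AREA_COL, PRESSURE_COL, POTENTIAL_COL}
        if extra:
            raise IsothermFormatError(f"{path}: unknown columns {sorted(extra)}")
        pot = df[POTENTIAL_COL] if POTENTIAL_COL in df.columns else None
    elif dialect == "two_column":
        first = data_lines[0].split(",")[0].strip()
        try:
            float(first)
            header = None
        except ValueError:
            header = 0
        df = pd.read_csv(buf, header=header, float_precision="round_trip")
        if df.shape[1] != 2:
            raise IsothermFormatError(
                f"{path}: two_column dialect expects exactly 2 columns, "
                f"found {df.shape[1]}"
            )
        df.columns = [AREA_COL, PRESSURE_COL]
        pot = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return canonicalize(
        df[AREA_COL], df[PRESSURE_COL], pot, metadata=metadata
    )


def write_isotherm(iso: CompressionIsotherm, path) -> Path:
    """Write an isotherm in the canonical dialect, full precision.

    Values survive a write/read round trip bitwise.  Metadata go to a JSON
    sidecar next to the data file.
    """
    path = Path(path)
    cols = {AREA_COL: iso.area, PRESSURE_COL: iso.pressure}
    if iso.potential is not None:
        cols[POTENTIAL_COL] = iso.potential
    df = pd.DataFrame(cols)
    # %.17g preserves float64 exactly
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
    _sidecar_path(path).write_text(
        json.dumps(iso.metadata.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path
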