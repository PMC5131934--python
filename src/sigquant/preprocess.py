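"""Reading raw pen trajectories and normalizing them for feature extraction.

A raw signature is a pair of discrete-time coordinate series (x_t, y_t),
typically tablet samples at ~100 Hz with widely varying lengths.  Before
symbolization each signature is

a) rescaled into the unit square [0, 1] x [0, 1] (per-axis min-max), and
b) expanded to a fixed length ``M = 5000`` with a shape-preserving cubic
   Hermite (PCHIP) interpolant against the normalized sample index.

Step (a) removes translation and scale; step (b) equalizes lengths so
every signature yields the same number of ordinal windows.  Timestamps,
when present in a file, are parsed but not used for resampling.

Two plain-text dialects are supported: ``columns`` (rows of ``x y [t]``,
``#`` comments) and ``svc`` (first line a sample count, then rows starting
``x y``; extra columns such as time and pressure are ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 5000

MANIFEST_COLUMNS = ("path", "subject_id", "signature_id", "authenticity")

__all__ = [
    "DEFAULT_LENGTH",
    "MANIFEST_COLUMNS",
    "RawSignature",
    "Trajectory",
    "read_signature",
    "rescale_unit_square",
    "hermite_resample",
    "preprocess",
    "write_signature",
    "read_manifest",
    "write_manifest",
    "iter_cohort",
]


@dataclass
class RawSignature:
    """One signature's raw coordinate samples plus identity labels."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray | None = None
    subject_id: str = ""
    signature_id: str = ""
    authenticity: str = "genuine"  # "genuine" or "forgery"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ValueError("x and y must be one-dimensional and of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates contain non-finite values")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if len(self.t) != len(self.x):
                raise ValueError("timestamps must match the coordinate length")
            if np.any(np.diff(self.t) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.authenticity not in ("genuine", "forgery"):
            raise ValueError(f"authenticity must be 'genuine' or 'forgery', got {self.authenticity!r}")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class Trajectory:
    """Preprocessed pair of unit-interval series of a fixed common length."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("trajectory coordinates must have equal length")
        for name, v in (("x", self.x), ("y", self.y)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"trajectory {name} values must lie in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.x)


class SignatureParseError(ValueError):
    """Raised when a signature file cannot be parsed."""


def _parse_row(line: str, lineno: int, path) -> list[float]:
    try:
        return [float(tok) for tok in line.replace(",", " ").split()]
    except ValueError as exc:
        raise SignatureParseError(f"{path}:{lineno}: malformed row {line!r}") from exc


def read_signature(
    path,
    dialect: str = "columns",
    subject_id: str = "",
    signature_id: str = "",
    authenticity: str = "genuine",
) -> RawSignature:
    """Parse one signature file in the ``columns`` or ``svc`` dialect."""
    path = Path(path)
    lines = path.read_text().splitlines()
    xs: list[float] = []
    ys: list[float] = []
    ts: list[float] = []
    if dialect == "columns":
        for lineno, line in enumerate(lines, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            fields = _parse_row(stripped, lineno, path)
            if len(fields) not in (2, 3):
                raise SignatureParseError(
                    f"{path}:{lineno}: expected 2-3 numeric fields, got {len(fields)}"
                )
            xs.append(fields[0])
            ys.append(fields[1])
            if len(fields) == 3:
                ts.append(fields[2])
        if ts and len(ts) != len(xs):
            raise SignatureParseError(f"{path}: timestamps present on only some rows")
    elif dialect == "svc":
        body = [ln for ln in lines if ln.strip()]
        if not body:
            raise SignatureParseError(f"{path}: empty svc file")
        try:
            declared = int(body[0].split()[0])
        except ValueError as exc:
            raise SignatureParseError(f"{path}:1: svc header is not an integer count") from exc
        rows = body[1:]
        if len(rows) != declared:
            raise SignatureParseError(
                f"{path}: svc header declares {declared} samples but file has {len(rows)}"
            )
        for lineno, line in enumerate(rows, start=2):
            fields = _parse_row(line.strip(), lineno, path)
            if len(fields) < 2:
                raise SignatureParseError(f"{path}:{lineno}: expected at least x y")
            xs.append(fields[0])
            ys.append(fields[1])
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'columns' or 'svc')")
    return RawSignature(
        x=np.array(xs),
        y=np.array(ys),
        t=np.array(ts) if ts else None,
        subject_id=subject_id,
        signature_id=signature_id,
        authenticity=authenticity,
    )


def write_signature(path, sig: RawSignature) -> None:
    """Write a signature in the ``columns`` dialect (x y per row)."""
    path = Path(path)
    with open(path, "w") as fh:
        for xv, yv in zip(sig.x, sig.y):
            fh.write(f"{xv:.6f} {yv:.6f}\n")


def rescale_unit_square(sig: RawSignature) -> RawSignature:
    """Min-max rescale each axis independently into [0, 1].

    A degenerate constant axis is mapped to the constant 0 with a warning.
    """
    if len(sig) == 0:
        raise ValueError("cannot rescale an empty signature")

    def _scale(v: np.ndarray, axis: str) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            logger.warning("constant %s axis in signature %s/%s; mapping to 0",
                           axis, sig.subject_id, sig.signature_id)
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    return RawSignature(
        x=_scale(sig.x, "x"),
        y=_scale(sig.y, "y"),
        t=None if sig.t is None else sig.t.copy(),
        subject_id=sig.subject_id,
        signature_id=sig.signature_id,
        authenticity=sig.authenticity,
    )


def hermite_resample(sig: RawSignature, m: int = DEFAULT_LENGTH) -> Trajectory:
    """Expand both coordinates to ``m`` samples with a monotone cubic Hermite.

    Each coordinate is treated as a function of the normalized sample index
    ``u_i = i/(n-1)`` and evaluated at ``m`` equispaced parameters with a
    shape-preserving (PCHIP) interpolant; endpoints are reproduced exactly
    and any residual overshoot is clipped into [0, 1].
    """
    if m < 2:
        raise ValueError(f"target length must be >= 2, got {m}")
    n = len(sig)
    if n < 2:
        raise ValueError("need at least 2 samples to interpolate")
    u = np.linspace(0.0, 1.0, n)
    grid = np.linspace(0.0, 1.0, m)
    x_new = PchipInterpolator(u, sig.x)(grid)
    y_new = PchipInterpolator(u, sig.y)(grid)
    # pin endpoints: polynomial evaluation at the last knot can be 1 ulp off
    x_new[0], x_new[-1] = sig.x[0], sig.x[-1]
    y_new[0], y_new[-1] = sig.y[0], sig.y[-1]
    return Trajectory(x=np.clip(x_new, 0.0, 1.0), y=np.clip(y_new, 0.0, 1.0))


def preprocess(sig: RawSignature, m: int = DEFAULT_LENGTH) -> Trajectory:
    """Full pipeline: rescale to the unit square, then resample to ``m``."""
    return hermite_resample(rescale_unit_square(sig), m=m)


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV (path, subject_id, signature_id, authenticity)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "signature_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {', '.join(missing)}")
    bad = set(df["authenticity"]) - {"genuine", "forgery"}
    if bad:
        raise ValueError(f"manifest {path} has invalid authenticity labels: {sorted(bad)}")
    return df


def write_manifest(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def iter_cohort(manifest_path, dialect: str = "columns"):
    """Yield RawSignature objects listed in a manifest, resolving relative paths."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        try:
            yield read_signature(
                p,
                dialect=dialect,
                subject_id=row.subject_id,
                signature_id=row.signature_id,
                authenticity=row.authenticity,
            )
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"manifest entry not readable: {p}") from exc
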