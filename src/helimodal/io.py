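"""Reading, validation, curation and subsampling of helical-parameter tables.

Inter-base-pair helical parameters come in six flavours: three translations
(shift, slide, rise; Å) and three rotations (tilt, roll, twist; degrees).
Under the nearest-neighbour model there are 10 unique dinucleotide steps.
Angles are handled as plain reals: B-DNA fluctuations span far less than a
full turn, so linear moments are valid and no circular statistics are used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PARAMETERS: tuple[str, ...] = ("shift", "slide", "rise", "tilt", "roll", "twist")
STEP_TYPES: tuple[str, ...] = ("AA", "AC", "AG", "AT", "CC", "CG", "GA", "GC", "GG", "TA")
ORIGINS: tuple[str, ...] = ("md", "xray_naked", "xray_protein", "xray_intercalator")

#: Units per parameter (translations in Å, rotations in degrees).
PARAMETER_UNITS: Mapping[str, str] = {
    "shift": "A", "slide": "A", "rise": "A",
    "tilt": "deg", "roll": "deg", "twist": "deg",
}


class FormatError(ValueError):
    """Input table does not conform to the expected layout."""


class EmptyInputError(ValueError):
    """Input contains no usable records."""


@dataclass(frozen=True)
class HelicalRecord:
    """A single helical-parameter measurement for one base-pair step."""

    step_type: str
    parameter: str
    value: float
    origin: str
    context: str | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step type {self.step_type!r}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.time is not None and self.time < 0:
            raise ValueError("time must be non-negative")


@dataclass
class HelicalEnsemble:
    """Sample of one helical parameter for a (step_type, parameter, origin) triple.

    ``values`` holds the measurements; ``times`` (ns) is present for MD
    series and must then be strictly increasing.
    """

    step_type: str
    parameter: str
    origin: str
    values: np.ndarray
    times: np.ndarray | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step type {self.step_type!r}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.values.shape:
                raise ValueError("times must match values in length")
            if np.any(self.times < 0):
                raise ValueError("times must be non-negative")
            if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.step_type, self.parameter, self.origin)

    def records(self) -> list[HelicalRecord]:
        ts = self.times if self.times is not None else [None] * self.n
        return [
            HelicalRecord(self.step_type, self.parameter, float(v), self.origin,
                          context=self.context, time=None if t is None else float(t))
            for v, t in zip(self.values, ts)
        ]


_REQUIRED_COLUMNS = ("step_type", "parameter", "value", "origin")


def read_table(
    path: str | Path,
    dialect: str = "tsv",
    ser_config: Mapping[str, object] | None = None,
) -> list[HelicalEnsemble]:
    """Read a helical-parameter table into per-(step, parameter, origin) ensembles.

    Parameters
    ----------
    path
        Input file. For ``tsv``/``csv`` the mandatory columns are
        ``step_type, parameter, value, origin``; ``context`` and ``time_ns``
        are optional. The ``curves_ser`` dialect is a whitespace-separated
        matrix, one snapshot per row and one step per column; column labels
        come from ``ser_config``.
    dialect
        One of ``tsv``, ``csv``, ``curves_ser``.
    ser_config
        Required for ``curves_ser``: keys ``parameter`` (one of the six),
        ``steps`` (step-type label per column), ``origin`` and optionally
        ``dt_ns`` (snapshot spacing; produces a time axis) and
        ``time_column`` (0-based index of a leading time column).

    Returns
    -------
    list of HelicalEnsemble, grouped and ordered by (step, parameter, origin).

    Malformed numeric fields are skipped with a warning naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "curves_ser":
        return _read_curves_ser(path, ser_config)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (np.flatnonzero(bad) + 2).tolist()
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} non-numeric/non-finite value(s) "
            f"at line(s) {lines}",
            stacklevel=2,
        )
        df = df.loc[~bad].copy()
        values = values.loc[~bad]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid records")
    df = df.assign(value=values.astype(float))
    return _group_dataframe(df)


def _group_dataframe(df: pd.DataFrame) -> list[HelicalEnsemble]:
    out: list[HelicalEnsemble] = []
    has_time = "time_ns" in df.columns
    has_ctx = "context" in df.columns
    for (st, par, org), grp in df.groupby(["step_type", "parameter", "origin"], sort=True):
        times = grp["time_ns"].to_numpy(dtype=float) if has_time else None
        if times is not None and np.all(np.isnan(times)):
            times = None
        ctx = None
        if has_ctx:
            vals = grp["context"].dropna().unique()
            ctx = str(vals[0]) if len(vals) == 1 else None
        out.append(HelicalEnsemble(step_type=str(st), parameter=str(par), origin=str(org),
                                   values=grp["value"].to_numpy(dtype=float),
                                   times=times, context=ctx))
    return out


def _read_curves_ser(path: Path, cfg: Mapping[str, object] | None) -> list[HelicalEnsemble]:
    if cfg is None:
        raise FormatError("curves_ser dialect requires a ser_config with "
                          "'parameter', 'steps' and 'origin'")
    for key in ("parameter", "steps", "origin"):
        if key not in cfg:
            raise FormatError(f"ser_config missing key {key!r}")
    parameter = str(cfg["parameter"])
    steps = [str(s) for s in cfg["steps"]]  # type: ignore[union-attr]
    origin = str(cfg["origin"])
    time_col = cfg.get("time_column")
    dt_ns = cfg.get("dt_ns")
    try:
        mat = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed numeric field ({exc})") from exc
    if mat.size == 0:
        raise EmptyInputError(f"{path} is empty")
    times = None
    if time_col is not None:
        times = mat[:, int(time_col)]
        mat = np.delete(mat, int(time_col), axis=1)
    elif dt_ns is not None:
        times = np.arange(mat.shape[0], dtype=float) * float(dt_ns)
    if mat.shape[1] != len(steps):
        raise FormatError(
            f"{path}: {mat.shape[1]} data columns but {len(steps)} step labels")
    return [
        HelicalEnsemble(step_type=steps[j], parameter=parameter, origin=origin,
                        values=mat[:, j], times=times)
        for j in range(mat.shape[1])
    ]


def write_table(ensembles: Iterable[HelicalEnsemble], path: str | Path) -> None:
    """Write ensembles to TSV at full double precision (round-trips exactly)."""
    rows = []
    for ens in ensembles:
        ts = ens.times if ens.times is not None else np.full(ens.n, np.nan)
        for v, t in zip(ens.values, ts):
            rows.append((ens.step_type, ens.parameter, repr(float(v)), ens.origin,
                         "" if ens.context is None else ens.context,
                         "" if np.isnan(t) else repr(float(t))))
    df = pd.DataFrame(rows, columns=["step_type", "parameter", "value", "origin",
                                     "context", "time_ns"])
    df.to_csv(path, sep="\t", index=False)


def filter_outliers(ens: HelicalEnsemble, k_sd: float = 3.0) -> tuple[HelicalEnsemble, int]:
    """Remove records farther than ``k_sd`` standard deviations from the mean.

    Mean and SD are computed once on the input sample (a single pass; the
    filter is deliberately not re-applied to its own output). With zero
    sample variance every record is retained.

    Returns the curated ensemble and the number of removed records.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if ens.n < 2:
        raise ValueError("need at least 2 records to estimate spread")
    mean = float(np.mean(ens.values))
    sd = float(np.std(ens.values))
    keep = np.abs(ens.values - mean) <= k_sd * sd
    removed = int(ens.n - keep.sum())
    if removed == 0:
        return ens, 0
    out = HelicalEnsemble(
        step_type=ens.step_type, parameter=ens.parameter, origin=ens.origin,
        values=ens.values[keep],
        times=None if ens.times is None else ens.times[keep],
        context=ens.context,
    )
    return out, removed


def subsample(ens: HelicalEnsemble, m: int, seed: int) -> HelicalEnsemble:
    """Uniform subsample of ``m`` records without replacement (seeded).

    When ``m >= n`` the ensemble is returned unchanged. Relative record
    order is preserved, so a subsampled time series keeps increasing times.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= ens.n:
        return ens
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(ens.n, size=m, replace=False))
    return HelicalEnsemble(
        step_type=ens.step_type, parameter=ens.parameter, origin=ens.origin,
        values=ens.values[idx],
        times=None if ens.times is None else ens.times[idx],
        context=ens.context,
    )


def curation_log(n_in: int, n_out: int, k_sd: float, seed: int | None = None) -> str:
    """JSON curation-log entry for one ensemble."""
    return json.dumps({"n_in": n_in, "n_out": n_out,
                       "removed_count": n_in - n_out, "k_sd": k_sd, "seed": seed})
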