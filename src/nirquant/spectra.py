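"""Containers and CSV I/O for NIR spectra and reference chemistry values.

Spectra live on a shared uniform wavenumber grid stored high-to-low
(acquisition order of FT-NIR instruments).  The on-disk format is a wide
CSV: first column ``sample_id``, remaining headers the wavenumbers in
cm^-1 as decimal strings in descending order.  Reference values (analyte
contents in mg/g) travel in a separate narrow CSV keyed by sample id.
Gzip-compressed files are accepted transparently for both.
"""

from __future__ import annotations

import csv
import gzip

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectraSet",
    "ReferenceValues",
    "SpectraFormatError",
    "GridError",
    "read_spectra",
    "write_spectra",
    "read_reference_values",
    "write_reference_values",
    "reference_table",
    "select_range",
    "average_replicates",
]

#: rounding slack allowed between `total` and `oa + ua` (mg/g); reference
#: tables report one decimal so the sum can be off by up to half a unit
#: in the last place on each term.
TOTAL_SLACK = 0.05


class SpectraFormatError(ValueError):
    """Malformed spectra or reference file."""


class GridError(ValueError):
    """Wavenumber axis violates the uniform descending-grid contract."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1, strictly descending.

    Parameters
    ----------
    values
        Wavenumbers in cm^-1, ordered high to low.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        if not np.all(np.isfinite(values)):
            raise GridError("grid contains non-finite wavenumbers")
        if np.any(values <= 0):
            raise GridError("wavenumbers must be positive")
        diffs = values[:-1] - values[1:]
        if np.any(diffs <= 0):
            raise GridError("grid must be strictly decreasing (high -> low)")
        step = float(diffs.mean())
        if np.any(np.abs(diffs - step) > 1e-6 * step):
            raise GridError("grid spacing is not uniform")

    @property
    def step(self) -> float:
        """Nominal spacing in cm^-1 (positive)."""
        return float(self.values[0] - self.values[1])

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_range(cls, hi: float, lo: float, step: float) -> "WavenumberGrid":
        """Build the grid hi, hi-step, ..., down to lo (inclusive if on-grid)."""
        n = int(round((hi - lo) / step)) + 1
        return cls(hi - step * np.arange(n))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0, atol=1e-9)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a :class:`WavenumberGrid`."""

    grid: WavenumberGrid
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.ndim != 1 or a.size != self.grid.n_points:
            raise ValueError("absorbance length does not match grid")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")


@dataclass(frozen=True)
class SpectraSet:
    """A stack of spectra sharing one grid.

    ``lineage`` is ``None`` for raw (as-acquired) data and carries the
    fingerprint of the fitted pretreatment state after preprocessing, so
    downstream model evaluation can refuse mismatched inputs.
    """

    sample_ids: tuple
    grid: WavenumberGrid
    absorbance: np.ndarray
    lineage: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance matrix must be 2-D")
        object.__setattr__(self, "absorbance", a)
        if a.shape[0] != len(ids):
            raise ValueError(
                f"{a.shape[0]} spectra for {len(ids)} sample ids"
            )
        if a.shape[1] != self.grid.n_points:
            raise ValueError("column count does not match grid length")
        if a.size and not np.all(np.isfinite(a)):
            raise ValueError("absorbance matrix contains non-finite entries")
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def spectrum(self, sample_id: str) -> Spectrum:
        i = self.sample_ids.index(sample_id)
        return Spectrum(self.grid, self.absorbance[i])

    def with_lineage(self, lineage: str | None) -> "SpectraSet":
        return SpectraSet(self.sample_ids, self.grid, self.absorbance, lineage)

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Row subset in the order given by ``ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectraSet(tuple(ids), self.grid, self.absorbance[rows], self.lineage)


@dataclass(frozen=True)
class ReferenceValues:
    """Per-sample analyte contents in mg/g (oleanolic acid, ursolic acid, sum)."""

    sample_id: str
    oa: float
    ua: float
    total: float

    def __post_init__(self) -> None:
        for name in ("oa", "ua", "total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if abs(self.total - (self.oa + self.ua)) > TOTAL_SLACK + 1e-12:
            raise ValueError(
                f"sample {self.sample_id!r}: total {self.total} inconsistent "
                f"with oa+ua = {self.oa + self.ua}"
            )


def _open_text(path, mode: str):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode + "t", encoding="utf-8", newline="")
    return open(p, mode, encoding="utf-8", newline="")


def _format_float(x: float) -> str:
    # repr gives the shortest string that round-trips the double exactly
    return repr(float(x))


def read_spectra(path) -> SpectraSet:
    """Read a wide spectra CSV (see module docstring for the dialect).

    Raises
    ------
    SpectraFormatError
        On ragged rows (the offending sample id is named) or a bad header.
    GridError
        If the header wavenumbers are not a uniform descending grid.
    """
    with _open_text(path, "r") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraFormatError(f"{path}: empty file") from None
        if not header or header[0] != "sample_id":
            raise SpectraFormatError(
                f"{path}: first header field must be 'sample_id', got {header[:1]!r}"
            )
        try:
            wavenumbers = np.array([float(h) for h in header[1:]])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric wavenumber header: {exc}") from None
        grid = WavenumberGrid(wavenumbers)
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            sid = row[0]
            if len(row) - 1 != grid.n_points:
                raise SpectraFormatError(
                    f"{path}: row for sample {sid!r} (line {lineno}) has "
                    f"{len(row) - 1} values, expected {grid.n_points}"
                )
            try:
                rows.append(np.array([float(v) for v in row[1:]]))
            except ValueError as exc:
                raise SpectraFormatError(
                    f"{path}: sample {sid!r} (line {lineno}): {exc}"
                ) from None
            ids.append(sid)
    matrix = np.vstack(rows) if rows else np.empty((0, grid.n_points))
    return SpectraSet(tuple(ids), grid, matrix)


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write the wide CSV dialect; full float precision, deterministic bytes."""
    with _open_text(path, "w") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id"] + [_format_float(v) for v in spectra.grid.values])
        for sid, row in zip(spectra.sample_ids, spectra.absorbance):
            writer.writerow([sid] + [_format_float(v) for v in row])


def read_reference_values(path) -> list[ReferenceValues]:
    """Read the reference CSV (``sample_id,oa,ua[,total]``), order preserved.

    ``total`` is computed as ``oa + ua`` when the column is absent or empty;
    an inconsistent explicit total (beyond the 0.05 mg/g rounding slack)
    raises ``ValueError`` via the record invariant.
    """
    records: list[ReferenceValues] = []
    seen: set[str] = set()
    with _open_text(path, "r") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        for required in ("sample_id", "oa", "ua"):
            if required not in fields:
                raise SpectraFormatError(f"{path}: missing column {required!r}")
        for row in reader:
            sid = row["sample_id"]
            if sid in seen:
                raise SpectraFormatError(f"{path}: duplicate sample id {sid!r}")
            seen.add(sid)
            oa, ua = float(row["oa"]), float(row["ua"])
            raw_total = row.get("total")
            total = float(raw_total) if raw_total not in (None, "") else oa + ua
            records.append(ReferenceValues(sid, oa, ua, total))
    return records


def write_reference_values(records: Iterable[ReferenceValues], path) -> None:
    with _open_text(path, "w") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "oa", "ua", "total"])
        for r in records:
            writer.writerow([r.sample_id] + [_format_float(v) for v in (r.oa, r.ua, r.total)])


def reference_table(records: Sequence[ReferenceValues], ids: Sequence[str],
                    target: str = "total") -> np.ndarray:
    """Vector of reference values for ``ids`` in order; ``target`` in {oa, ua, total}."""
    if target not in ("oa", "ua", "total"):
        raise ValueError(f"unknown target {target!r}")
    by_id = {r.sample_id: getattr(r, target) for r in records}
    try:
        return np.array([by_id[s] for s in ids], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no reference value for sample {exc.args[0]!r}") from None


def select_range(spectra: SpectraSet, lo_cm: float, hi_cm: float) -> SpectraSet:
    """Keep exactly the on-grid columns with lo_cm <= wavenumber <= hi_cm.

    Closed interval; never interpolates.  Raises ``ValueError`` when the
    interval misses the grid entirely.
    """
    if not lo_cm < hi_cm:
        raise ValueError(f"need lo_cm < hi_cm, got [{lo_cm}, {hi_cm}]")
    v = spectra.grid.values
    mask = (v >= lo_cm - 1e-9) & (v <= hi_cm + 1e-9)
    if not mask.any():
        raise ValueError(
            f"selection [{lo_cm}, {hi_cm}] cm^-1 does not intersect the grid "
            f"[{v[-1]}, {v[0]}]"
        )
    return SpectraSet(spectra.sample_ids, WavenumberGrid(v[mask]),
                      spectra.absorbance[:, mask], spectra.lineage)


def average_replicates(replicates: Sequence[SpectraSet]) -> SpectraSet:
    """Element-wise mean across replicate acquisitions of the same samples."""
    if not replicates:
        raise ValueError("no replicate sets given")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.grid != first.grid:
            raise ValueError("replicate grids differ")
        if rep.sample_ids != first.sample_ids:
            raise ValueError("replicate sample ids differ")
    mean = np.mean([rep.absorbance for rep in replicates], axis=0)
    return SpectraSet(first.sample_ids, first.grid, mean)
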