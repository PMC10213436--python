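"""Spectral data containers and CSV I/O.

A :class:`SpectraSet` is an n_samples x n_points absorbance matrix on a
strictly increasing wavenumber grid (cm^-1), with string sample IDs; a
:class:`ReferenceValues` carries the per-sample analyte concentration used
as the regression target. The interchange format is a self-describing CSV:
first column ``sample_id``, an optional ``nicotine`` reference column, and
the remaining headers parseable as wavenumbers. Units of the reference
value are treated as opaque pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_COLUMN = "nicotine"
ID_COLUMN = "sample_id"


class FormatError(ValueError):
    """The file does not follow the spectra-CSV dialect."""


class ValidationError(ValueError):
    """Structurally well-formed input with invalid content."""


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance spectra on a common ascending wavenumber grid."""

    absorbance: np.ndarray  # (n_samples, n_points) float64
    wavenumbers: np.ndarray  # (n_points,) cm^-1, strictly increasing
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=np.float64)
        wn = np.asarray(self.wavenumbers, dtype=np.float64)
        if A.ndim != 2:
            raise ValidationError("absorbance must be a 2-D matrix")
        if wn.ndim != 1 or wn.size != A.shape[1]:
            raise ValidationError("wavenumber grid length must equal n_points")
        if wn.size < 3:
            raise ValidationError("need at least 3 wavenumber points")
        if not np.all(np.isfinite(wn)) or np.any(np.diff(wn) <= 0):
            raise ValidationError("wavenumbers must be finite and strictly increasing")
        if not np.all(np.isfinite(A)):
            bad = np.where(~np.isfinite(A).all(axis=1))[0]
            ids = [self._id(i) for i in bad[:5]]
            raise ValidationError(f"non-finite absorbance in samples {ids}")
        ids = self.sample_ids or tuple(f"s{i}" for i in range(A.shape[0]))
        if len(ids) != A.shape[0]:
            raise ValidationError("sample_ids length must equal n_samples")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample IDs")
        object.__setattr__(self, "absorbance", A)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in ids))

    def _id(self, i: int) -> str:
        return self.sample_ids[i] if self.sample_ids else f"s{i}"

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, A: np.ndarray) -> "SpectraSet":
        """Same grid and IDs, new absorbance matrix."""
        return SpectraSet(A, self.wavenumbers, self.sample_ids)

    def subset(self, indices: np.ndarray) -> "SpectraSet":
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.absorbance[indices],
            self.wavenumbers,
            tuple(self.sample_ids[i] for i in indices),
        )


@dataclass(frozen=True)
class ReferenceValues:
    """Per-sample analyte concentrations aligned with a SpectraSet."""

    values: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValidationError("reference values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def subset(self, indices: np.ndarray) -> "ReferenceValues":
        return ReferenceValues(self.values[np.asarray(indices, dtype=int)])


def read_spectra_csv(path) -> tuple[SpectraSet, ReferenceValues | None]:
    """Load a spectra CSV; wavenumber columns are sorted ascending no matter
    their order in the file. Returns the reference values when a
    ``nicotine`` column is present."""
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if ID_COLUMN not in df.columns:
        raise FormatError(f"missing required {ID_COLUMN!r} column")
    has_ref = REFERENCE_COLUMN in df.columns
    wn_cols = [c for c in df.columns if c not in (ID_COLUMN, REFERENCE_COLUMN)]
    try:
        wn = np.array([float(c) for c in wn_cols], dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from exc
    if wn.size < 3:
        raise FormatError("need at least 3 wavenumber columns")
    ids = df[ID_COLUMN].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs: {dupes[:5]}")
    raw = df[wn_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad_rows = np.where(~np.isfinite(raw).all(axis=1))[0]
    if bad_rows.size:
        names = [ids[i] for i in bad_rows[:5]]
        raise ValidationError(f"missing/non-numeric absorbance in samples {names}")
    order = np.argsort(wn, kind="stable")
    spectra = SpectraSet(raw[:, order], wn[order], tuple(ids))
    if not has_ref:
        return spectra, None
    yraw = pd.to_numeric(df[REFERENCE_COLUMN], errors="coerce").to_numpy(np.float64)
    bad = np.where(~np.isfinite(yraw))[0]
    if bad.size:
        names = [ids[i] for i in bad[:5]]
        raise ValidationError(f"missing/non-numeric reference values in samples {names}")
    return spectra, ReferenceValues(yraw)


def write_spectra_csv(s: SpectraSet, y: ReferenceValues | None, path) -> None:
    """Write the spectra (and, when given, the reference column) as CSV.
    Values are serialized with 17 significant digits, so a read/write
    round-trip is lossless at double precision."""
    if y is not None and len(y) != s.n_samples:
        raise ValidationError("reference values length must equal n_samples")
    cols: dict[str, object] = {ID_COLUMN: list(s.sample_ids)}
    if y is not None:
        cols[REFERENCE_COLUMN] = y.values
    for j, w in enumerate(s.wavenumbers):
        cols[np.format_float_positional(w, trim="-")] = s.absorbance[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
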