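"""Reading, writing, validating and normalising activity-pattern matrices.

A pattern matrix holds the per-voxel response amplitudes (beta estimates)
of one region of interest, one column per stimulus.  The canonical
orientation is voxels-as-rows; files in the transposed orientation are
handled with an explicit ``transpose`` flag rather than by guessing.

Columns are z-scored across voxels with the population (divide-by-N)
variance, so that after normalisation every column has mean 0 and squared
Euclidean norm equal to the number of voxels.  The downstream
cross-validation shortcut relies on that identity exactly, which is why
sample-variance (divide-by-N-1) z-scoring is deliberately not offered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatternMatrix",
    "StimulusTable",
    "PatternFormatError",
    "DegenerateColumnError",
    "load_pattern_matrix",
    "write_pattern_matrix",
    "load_stimulus_table",
    "write_stimulus_table",
    "znormalise",
    "subset_stimuli",
]

CATEGORIES = ("face", "place", "object", "other")
ANIMACIES = ("animate", "inanimate", "unknown")

#: |column mean| below this counts as exactly demeaned.
_MEAN_TOL = 1e-10


class PatternFormatError(ValueError):
    """Raised when a pattern file cannot be parsed into a numeric matrix."""


class DegenerateColumnError(ValueError):
    """Raised when a stimulus column has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class PatternMatrix:
    """Voxels x stimuli matrix of activity estimates for one region.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_voxels, n_stimuli)``; must be finite.
    voxel_ids, stimulus_ids
        Row and column identifiers.  Generated (``v0001`` / ``s0001`` style)
        when not supplied.
    normalised
        True when every column is z-scored across voxels (mean 0, squared
        norm equal to ``n_voxels``).
    """

    values: np.ndarray
    voxel_ids: tuple[str, ...] = field(default=())
    stimulus_ids: tuple[str, ...] = field(default=())
    normalised: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"pattern matrix must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"pattern matrix must be non-empty, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite entry at voxel row {i}, stimulus column {j}"
            )
        object.__setattr__(self, "values", arr)
        vids = tuple(self.voxel_ids) or tuple(
            f"v{i + 1:04d}" for i in range(arr.shape[0])
        )
        sids = tuple(self.stimulus_ids) or tuple(
            f"s{i + 1:04d}" for i in range(arr.shape[1])
        )
        if len(vids) != arr.shape[0]:
            raise ValueError(
                f"{len(vids)} voxel ids for {arr.shape[0]} rows"
            )
        if len(sids) != arr.shape[1]:
            raise ValueError(
                f"{len(sids)} stimulus ids for {arr.shape[1]} columns"
            )
        object.__setattr__(self, "voxel_ids", vids)
        object.__setattr__(self, "stimulus_ids", sids)
        if self.normalised:
            _check_normalised(arr)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


def _check_normalised(arr: np.ndarray) -> None:
    n_vox = arr.shape[0]
    means = arr.mean(axis=0)
    if np.any(np.abs(means) >= _MEAN_TOL):
        j = int(np.argmax(np.abs(means)))
        raise ValueError(
            f"normalised flag set but column {j} has mean {means[j]:.3e}"
        )
    sqnorms = np.einsum("ij,ij->j", arr, arr)
    if np.any(np.abs(sqnorms - n_vox) >= _MEAN_TOL * n_vox):
        j = int(np.argmax(np.abs(sqnorms - n_vox)))
        raise ValueError(
            f"normalised flag set but column {j} has squared norm "
            f"{sqnorms[j]:.6g} != {n_vox}"
        )


@dataclass(frozen=True)
class StimulusTable:
    """Per-stimulus annotations: category and animacy."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = {"stimulus_id", "category", "animacy"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"stimulus table missing columns: {sorted(missing)}")
        df["stimulus_id"] = df["stimulus_id"].astype(str)
        if df["stimulus_id"].duplicated().any():
            dup = df.loc[df["stimulus_id"].duplicated(), "stimulus_id"].iloc[0]
            raise ValueError(f"duplicate stimulus_id {dup!r}")
        bad_cat = set(df["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown categories: {sorted(bad_cat)}")
        bad_ani = set(df["animacy"]) - set(ANIMACIES)
        if bad_ani:
            raise ValueError(f"unknown animacy values: {sorted(bad_ani)}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# File IO


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "," if "," in sample else "\t"


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def load_pattern_matrix(
    path: str | Path,
    format: str = "auto",
    transpose: bool = False,
) -> PatternMatrix:
    """Load a pattern matrix from delimited text or an HDF5 container.

    Delimited files may carry an optional header row of stimulus ids and an
    optional first column of voxel ids; both are autodetected (a leading
    cell that does not parse as a number marks them).  ``transpose`` flips a
    stimuli-as-rows file into the canonical voxels-as-rows orientation.

    Raises
    ------
    PatternFormatError
        For ragged rows or any cell that is not a finite number, naming the
        offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        m = _load_hdf5(path)
    else:
        m = _load_delimited(path)
    if transpose:
        m = PatternMatrix(
            m.values.T, voxel_ids=m.stimulus_ids, stimulus_ids=m.voxel_ids
        )
    return m


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in {"csv", "tsv", "delimited", "hdf5", "h5"}:
            raise ValueError(f"unknown format {format!r}")
        return "hdf5" if format in {"hdf5", "h5"} else "delimited"
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return "hdf5"
    return "delimited"


def _load_delimited(path: Path) -> PatternMatrix:
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PatternFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = [ln.split(delim) for ln in lines]

    widths = {len(r) for r in rows}
    # A header row with a voxel-id column below it may be one cell short.
    has_header = not _is_number(rows[0][-1])
    body = rows[1:] if has_header else rows
    if not body:
        raise PatternFormatError(f"{path}: header but no data rows")
    if len({len(r) for r in body}) != 1:
        lengths = [len(r) for r in body]
        bad = next(i for i, w in enumerate(lengths) if w != lengths[0])
        raise PatternFormatError(
            f"{path}: ragged rows — data row {bad} has {lengths[bad]} cells, "
            f"expected {lengths[0]}"
        )
    has_rowids = not _is_number(body[0][0])
    ncols = len(body[0]) - int(has_rowids)
    if has_header and len(rows[0]) not in {ncols, ncols + 1}:
        raise PatternFormatError(
            f"{path}: header has {len(rows[0])} cells for {ncols} data columns"
        )

    voxel_ids: list[str] = []
    data = np.empty((len(body), ncols), dtype=float)
    for i, row in enumerate(body):
        cells = row[1:] if has_rowids else row
        if has_rowids:
            voxel_ids.append(row[0].strip())
        for j, cell in enumerate(cells):
            token = cell.strip()
            try:
                val = float(token)
            except ValueError:
                raise PatternFormatError(
                    f"{path}: non-numeric cell {token!r} at data row {i}, "
                    f"column {j}"
                ) from None
            if not np.isfinite(val):
                raise PatternFormatError(
                    f"{path}: non-finite value {token!r} at data row {i}, "
                    f"column {j}"
                )
            data[i, j] = val
    stimulus_ids = (
        tuple(c.strip() for c in rows[0][-ncols:]) if has_header else ()
    )
    del widths
    return PatternMatrix(
        data, voxel_ids=tuple(voxel_ids), stimulus_ids=stimulus_ids
    )


def _load_hdf5(path: Path) -> PatternMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise PatternFormatError(f"{path}: missing 'values' dataset")
        values = np.asarray(f["values"], dtype=float)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise PatternFormatError(
                f"{path}: non-finite value at row {i}, column {j}"
            )
        voxel_ids = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.get("voxel_ids", ())
        )
        stimulus_ids = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.get("stimulus_ids", ())
        )
    return PatternMatrix(values, voxel_ids=voxel_ids, stimulus_ids=stimulus_ids)


def write_pattern_matrix(
    m: PatternMatrix, path: str | Path, format: str = "auto"
) -> None:
    """Write a pattern matrix as CSV/TSV (with ids) or an HDF5 container."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=m.values)
            f.create_dataset("voxel_ids", data=list(m.voxel_ids))
            f.create_dataset("stimulus_ids", data=list(m.stimulus_ids))
        return
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(m.values, index=list(m.voxel_ids), columns=list(m.stimulus_ids))
    df.to_csv(path, sep=delim, index_label="voxel_id", float_format="%.17g")


def load_stimulus_table(path: str | Path) -> StimulusTable:
    df = pd.read_csv(path, dtype=str)
    return StimulusTable(df)


def write_stimulus_table(t: StimulusTable, path: str | Path) -> None:
    t.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalisation and subsetting


def znormalise(m: PatternMatrix) -> PatternMatrix:
    """Z-score every stimulus column across voxels (population variance).

    After normalisation each column has mean 0 and squared norm equal to
    the number of voxels, the identity the leave-one-out shortcut needs.
    Idempotent.  Raises :class:`DegenerateColumnError` on a constant column.
    """
    arr = m.values
    if arr.shape[0] < 2:
        raise ValueError("z-normalisation needs at least 2 voxels")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0)  # population convention (ddof=0)
    if np.any(sds <= 0):
        j = int(np.argmin(sds))
        raise DegenerateColumnError(
            f"stimulus column {j} ({m.stimulus_ids[j]!r}) is constant; "
            "zero variance cannot be z-scored"
        )
    out = (arr - means) / sds
    return replace(m, values=out, normalised=True)


def _match_selector(t: StimulusTable, selector: str | Iterable[str]) -> pd.Series:
    if isinstance(selector, str):
        selectors: Sequence[str] = (selector,)
    else:
        selectors = tuple(selector)
    df = t.frame
    mask = pd.Series(False, index=df.index)
    for sel in selectors:
        if sel == "all":
            mask |= True
        elif sel in CATEGORIES:
            mask |= df["category"] == sel
        elif sel in ANIMACIES:
            mask |= df["animacy"] == sel
        else:
            raise ValueError(
                f"selector {sel!r} names no category or animacy in the table "
                f"(choose from {CATEGORIES + ANIMACIES + ('all',)})"
            )
    return mask


def subset_stimuli(
    m: PatternMatrix, t: StimulusTable, selector: str | Iterable[str]
) -> PatternMatrix:
    """Restrict the matrix columns to stimuli matching a selector.

    ``selector`` is a category (``face``, ``place``, ...), an animacy
    (``animate``/``inanimate``), ``all``, or an iterable of those (union).
    Column order is preserved.  The result has ``normalised=False``:
    z-scoring is recomputed per analysis subset so the squared-norm
    identity holds for the subset actually analysed.
    """
    mask = _match_selector(t, selector)
    keep_ids = set(t.frame.loc[mask, "stimulus_id"])
    keep = [i for i, sid in enumerate(m.stimulus_ids) if sid in keep_ids]
    if not keep:
        raise ValueError(f"selector {selector!r} matches no stimulus of the matrix")
    return PatternMatrix(
        m.values[:, keep],
        voxel_ids=m.voxel_ids,
        stimulus_ids=tuple(m.stimulus_ids[i] for i in keep),
        normalised=False,
    )
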