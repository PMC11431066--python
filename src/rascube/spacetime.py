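"""Space-time data-cube kernel and the raster-to-RA data flow.

A stack of categorical raster time slices (e.g. NLCD land-cover grids,
30 m cells, one layer per epoch) is swept by a kernel that, for every
interior cell, collects the center value and its four von Neumann
neighbours (north, west, east, south) at each lagged time plus the center
value at the final time.  With T slices the row layout is

    Z1, N1, W1, E1, S1, Z2, ..., S(T-1), Z(T)

where Z(T) is the DV.  Rows are then filtered (drop all-uniform rows, keep
rows containing the target class anywhere), stratified 50/50 on the DV,
split into train/test, and rebinned from raw class codes to the five
collapsed classes WDA/GRS/SHB/MFO/EFO with a binary DV (EFO vs non-EFO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CategoricalDataset, VariableSpec

__all__ = [
    "RasterStack",
    "KernelRowTable",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "extract_rows",
    "apply_row_filters",
    "recode_and_rebin",
    "stratify_split",
    "default_rebin_map",
    "kernel_variable_specs",
    "CLASS_LABELS",
    "DEFAULT_EFO_CODE",
]

log = logging.getLogger(__name__)

DEFAULT_EFO_CODE = 42
DEFAULT_NODATA = -9999

CLASS_LABELS = ("WDA", "GRS", "SHB", "MFO", "EFO")

# NLCD 15-class -> 5-class collapse.  Water/developed/agriculture lumps the
# urban, water, wetland, barren and crop codes; grasses, shrubs, mixed or
# deciduous forest, and evergreen forest keep their own bins.
_DEFAULT_REBIN = {
    11: 0, 21: 0, 22: 0, 23: 0, 24: 0, 31: 0, 81: 0, 82: 0, 90: 0, 95: 0,
    71: 1,
    52: 2,
    41: 3, 43: 3,
    42: 4,
}


def default_rebin_map() -> dict[int, int]:
    return dict(_DEFAULT_REBIN)


@dataclass
class RasterStack:
    """T x H x W integer-coded grid stack."""

    grid: np.ndarray
    time_labels: tuple = ()
    nodata: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be T x H x W")
        if self.grid.shape[0] < 2:
            raise ValueError("need at least two time slices")
        if not self.time_labels:
            self.time_labels = tuple(range(1, self.grid.shape[0] + 1))
        if len(self.time_labels) != self.grid.shape[0]:
            raise ValueError("one time label per slice required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class KernelRowTable:
    """Extracted kernel rows: one row per interior cell, Z/N/W/E/S per lag."""

    df: pd.DataFrame
    coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)


def kernel_columns(T: int) -> list[str]:
    cols = []
    for t in range(1, T):
        cols += [f"Z{t}", f"N{t}", f"W{t}", f"E{t}", f"S{t}"]
    cols.append(f"Z{T}")
    return cols


# ---------------------------------------------------------------------------
# ESRI ASCII grid IO


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read one ESRI ASCII grid; returns (2-D int array, header dict)."""
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                key = parts[0].lower()
                header[key] = float(parts[1]) if "." in parts[1] else int(
                    float(parts[1])
                )
            else:
                fh.seek(pos)
                break
        arr = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    if "ncols" in header and arr.shape != (header["nrows"], header["ncols"]):
        raise ValueError(f"{path}: grid shape does not match header")
    return arr, header


def write_ascii_grid(
    path, arr: np.ndarray, nodata: int = DEFAULT_NODATA, cellsize: float = 30.0
) -> None:
    arr = np.asarray(arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_stack(paths, time_labels=None, nodata: int | None = None) -> RasterStack:
    """Read an ordered sequence of ASCII grids into a stack."""
    layers, headers = [], []
    for p in paths:
        arr, hdr = read_ascii_grid(p)
        layers.append(arr)
        headers.append(hdr)
    grid = np.stack(layers)
    nd = nodata
    if nd is None:
        nd = int(headers[0].get("nodata_value", DEFAULT_NODATA))
    return RasterStack(grid, tuple(time_labels or ()), nodata=nd)


def write_stack(stack: RasterStack, out_dir, prefix: str = "slice") -> list[str]:
    import os

    paths = []
    for t, label in enumerate(stack.time_labels):
        p = os.path.join(out_dir, f"{prefix}_{label}.asc")
        write_ascii_grid(p, stack.grid[t], nodata=stack.nodata)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# kernel extraction and filtering


def extract_rows(stack: RasterStack, keep_coords: bool = False) -> KernelRowTable:
    """Sweep the space-time kernel over the stack.

    One row per interior cell (the border ring, lacking a full von Neumann
    neighbourhood, is excluded).  Row 0 of the grid is the north edge, so
    N = (r-1, c), S = (r+1, c), W = (r, c-1), E = (r, c+1).  Rows touching a
    nodata cell are dropped (count logged in ``meta``).
    """
    T, H, W = stack.shape
    if H < 3 or W < 3:
        raise ValueError("grid must be at least 3 x 3")
    g = stack.grid
    cols = {}
    for t in range(T - 1):
        cols[f"Z{t + 1}"] = g[t, 1:-1, 1:-1]
        cols[f"N{t + 1}"] = g[t, :-2, 1:-1]
        cols[f"W{t + 1}"] = g[t, 1:-1, :-2]
        cols[f"E{t + 1}"] = g[t, 1:-1, 2:]
        cols[f"S{t + 1}"] = g[t, 2:, 1:-1]
    cols[f"Z{T}"] = g[T - 1, 1:-1, 1:-1]
    order = kernel_columns(T)
    mat = np.stack([cols[c].ravel() for c in order], axis=1)
    rr, cc = np.meshgrid(np.arange(1, H - 1), np.arange(1, W - 1), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    ok = ~(mat == stack.nodata).any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d rows touching nodata", n_dropped)
    table = KernelRowTable(
        pd.DataFrame(mat[ok], columns=order),
        coords=coords[ok] if keep_coords else None,
        meta={"n_interior": mat.shape[0], "n_nodata_dropped": n_dropped},
    )
    return table


def apply_row_filters(
    table: KernelRowTable, efo_code: int = DEFAULT_EFO_CODE
) -> KernelRowTable:
    """Drop all-uniform rows, then keep rows containing *efo_code* anywhere.

    Uniform removal comes first (matching the raw-data flow), so an
    all-EFO row is removed by the uniform filter despite containing the
    target code.
    """
    mat = table.df.to_numpy()
    uniform = (mat == mat[:, [0]]).all(axis=1)
    mat2 = mat[~uniform]
    coords = table.coords[~uniform] if table.coords is not None else None
    has_efo = (mat2 == efo_code).any(axis=1)
    meta = dict(table.meta)
    meta.update(
        {
            "n_input": len(mat),
            "n_uniform_removed": int(uniform.sum()),
            "n_after_uniform": len(mat2),
            "n_after_efo": int(has_efo.sum()),
        }
    )
    log.info(
        "row filters: %d -> %d after uniform removal -> %d containing code %d",
        len(mat), len(mat2), int(has_efo.sum()), efo_code,
    )
    return KernelRowTable(
        pd.DataFrame(mat2[has_efo], columns=table.columns),
        coords=coords[has_efo] if coords is not None else None,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# rebinning and stratified splitting


def kernel_variable_specs(
    columns,
    rebin_map: dict[int, int] | None = None,
    efo_code: int = DEFAULT_EFO_CODE,
    permissive: bool = False,
) -> list[VariableSpec]:
    """Variable declarations for a kernel row table.

    IVs get the 5-class rebin (cardinality 5); the final column (the DV)
    becomes binary: 1 iff the raw code equals *efo_code*.
    """
    rebin_map = dict(rebin_map or _DEFAULT_REBIN)
    dv_rebin = {code: (1 if code == efo_code else 0) for code in rebin_map}
    specs = []
    for i, col in enumerate(columns):
        if i == len(columns) - 1:
            specs.append(
                VariableSpec(
                    col, 2, role="dv", rebin=dv_rebin,
                    labels=("non-EFO", "EFO"),
                )
            )
        else:
            specs.append(
                VariableSpec(col, 5, role="iv", rebin=rebin_map, labels=CLASS_LABELS)
            )
    return specs


def recode_and_rebin(
    table: KernelRowTable,
    rebin_map: dict[int, int] | None = None,
    efo_code: int = DEFAULT_EFO_CODE,
    permissive: bool = False,
) -> CategoricalDataset:
    """Collapse raw codes to the 5 classes and binarise the DV.

    Unmapped codes raise (naming the code) unless *permissive*, in which
    case they fall into the WDA catch-all class.
    """
    rebin_map = dict(rebin_map or _DEFAULT_REBIN)
    if permissive:
        present = set(np.unique(table.df.to_numpy()))
        for code in present - set(rebin_map):
            rebin_map[int(code)] = 0
    specs = kernel_variable_specs(table.columns, rebin_map, efo_code)
    return CategoricalDataset.from_dataframe(table.df, specs)


def stratify_split(
    table: KernelRowTable | pd.DataFrame,
    efo_code: int | None = DEFAULT_EFO_CODE,
    n_per_file: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balance the DV 50/50, shuffle, and split into equal train/test halves.

    The DV is the last column; a row is in the positive class when that
    value equals *efo_code* (or is truthy when *efo_code* is None, for
    already-binary data).  The majority class is downsampled without
    replacement to the minority count, capped at ``n_per_file / 2`` per
    class and file when *n_per_file* is given.  Identical seeds reproduce
    identical partitions.
    """
    df = table.df if isinstance(table, KernelRowTable) else table
    dv = df.columns[-1]
    positive = (
        (df[dv].to_numpy() == efo_code) if efo_code is not None
        else df[dv].to_numpy().astype(bool)
    )
    idx_pos = np.flatnonzero(positive)
    idx_neg = np.flatnonzero(~positive)
    if len(idx_pos) == 0 or len(idx_neg) == 0:
        raise ValueError("both DV classes must be present to stratify")
    m = min(len(idx_pos), len(idx_neg))
    if n_per_file is not None:
        m = min(m, n_per_file)
    m -= m % 2  # each class contributes m/2 rows to each half
    if m < 2:
        raise ValueError("too few rows in the minority class to split")
    rng = np.random.default_rng(seed)
    pos = rng.permutation(idx_pos)[:m]
    neg = rng.permutation(idx_neg)[:m]
    half = m // 2
    train_idx = np.concatenate([pos[:half], neg[:half]])
    test_idx = np.concatenate([pos[half:], neg[half:]])
    train_idx = rng.permutation(train_idx)
    test_idx = rng.permutation(test_idx)
    return df.iloc[train_idx].reset_index(drop=True), df.iloc[test_idx].reset_index(
        drop=True
    )
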