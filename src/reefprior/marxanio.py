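"""Interchange formats: Marxan dat dialect, ASCII grid rasters, CSV.

Writers emit the exact classic formats (tab-separated dat files with header
rows, ``puvspr.dat`` sorted by species then planning unit) so a real Marxan
binary can be substituted for the internal solver; readers are tolerant of
comma, tab or whitespace separation.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .reefscape import Reefscape

__all__ = [
    "write_pu_dat",
    "read_pu_dat",
    "write_spec_dat",
    "read_spec_dat",
    "write_puvspr_dat",
    "read_puvspr_dat",
    "write_solution_csv",
    "write_ssoln_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_reefscape",
    "read_reefscape",
]

NODATA = -9999.0


def _read_table(path) -> pd.DataFrame:
    # tolerate tab, comma or whitespace separators
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ("," if "," in text.splitlines()[0] else r"\s+")
    return pd.read_csv(io.StringIO(text), sep=sep)


def write_pu_dat(path, costs: pd.Series, status: pd.Series | None = None) -> None:
    """pu.dat: columns id, cost, status (0 = available)."""
    ids = costs.index
    df = pd.DataFrame(
        {
            "id": ids.astype(int),
            "cost": costs.to_numpy(),
            "status": 0 if status is None else status.loc[ids].astype(int).to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pu_dat(path) -> pd.DataFrame:
    df = _read_table(path)
    if not {"id", "cost"} <= set(df.columns):
        raise ValueError("pu.dat must have id and cost columns")
    return df


def write_spec_dat(
    path, feature_ids, prop: float, spf: np.ndarray, names=None
) -> None:
    """spec.dat: columns id, name, prop, spf."""
    feature_ids = list(feature_ids)
    df = pd.DataFrame(
        {
            "id": [int(f) for f in feature_ids],
            "name": names if names is not None else [f"class_{f}" for f in feature_ids],
            "prop": prop,
            "spf": np.asarray(spf, dtype=float),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_spec_dat(path) -> pd.DataFrame:
    df = _read_table(path)
    if not {"id", "prop", "spf"} <= set(df.columns):
        raise ValueError("spec.dat must have id, prop and spf columns")
    return df


def write_puvspr_dat(path, features: pd.DataFrame) -> None:
    """puvspr.dat: columns species, pu, amount — sorted by species then pu."""
    df = pd.DataFrame(
        {
            "species": features["class_id"].astype(int),
            "pu": features["pu_id"].astype(int),
            "amount": features["amount_km2"].astype(float),
        }
    ).sort_values(["species", "pu"])
    df.to_csv(path, sep="\t", index=False)


def read_puvspr_dat(path) -> pd.DataFrame:
    df = _read_table(path)
    if not {"species", "pu", "amount"} <= set(df.columns):
        raise ValueError("puvspr.dat must have species, pu and amount columns")
    return df.rename(
        columns={"species": "class_id", "pu": "pu_id", "amount": "amount_km2"}
    )


def write_solution_csv(path, pu_ids, selected_ids) -> None:
    sel = set(int(i) for i in selected_ids)
    pd.DataFrame(
        {"pu_id": [int(i) for i in pu_ids], "selected": [int(i in sel) for i in pu_ids]}
    ).to_csv(path, index=False)


def write_ssoln_csv(path, frequency: pd.Series) -> None:
    """ssoln-style table: pu_id, frequency (count of selecting replicates)."""
    pd.DataFrame(
        {"pu_id": frequency.index.astype(int), "frequency": frequency.to_numpy()}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rasters


def write_ascii_grid(path, array: np.ndarray, cell_size_km: float) -> None:
    """ESRI-style ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA)."""
    arr = np.asarray(array, dtype=float)
    rows, cols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_km}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for r in range(rows):
            fh.write(" ".join(repr(float(v)) for v in arr[r]) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            k, v = fh.readline().split()
            header[k.lower()] = float(v)
        arr = np.loadtxt(fh)
    arr = arr.reshape(int(header["nrows"]), int(header["ncols"]))
    return arr, header["cellsize"]


def write_reefscape(reefscape: Reefscape, directory) -> None:
    """Serialise a reefscape: reef-fraction raster plus a class-table CSV
    (cell_id, l1..l5, reef_fraction) over reef cells."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(d / "reef_fraction.asc", reefscape.reef_fraction, reefscape.cell_size_km)
    rows, cols = reefscape.shape
    mask = reefscape.reef_mask
    rr, cc = np.nonzero(mask)
    tab = pd.DataFrame({"cell_id": rr * cols + cc})
    for lev in range(5):
        tab[f"l{lev + 1}"] = reefscape.labels[lev][mask]
    tab["reef_fraction"] = reefscape.reef_fraction[mask]
    tab.to_csv(d / "classes.csv", index=False)


def read_reefscape(directory) -> Reefscape:
    d = Path(directory)
    frac, cell_size = read_ascii_grid(d / "reef_fraction.asc")
    tab = pd.read_csv(d / "classes.csv")
    rows, cols = frac.shape
    labels = np.full((5, rows, cols), -1, dtype=np.int64)
    rr, cc = tab["cell_id"].to_numpy() // cols, tab["cell_id"].to_numpy() % cols
    for lev in range(5):
        labels[lev, rr, cc] = tab[f"l{lev + 1}"].to_numpy()
    return Reefscape(reef_fraction=frac, labels=labels, cell_size_km=cell_size)
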