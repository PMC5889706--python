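"""File formats: CSV survey tables, ASCII rasters, state-space files.

All tables are plain CSV (comma, header row, UTF-8, "." decimal) with
projected-meter coordinates; timestamps are ISO-8601.  Rasters use the
headered ASCII grid format (ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value followed by rows north to south), which every GIS reads.

A dataset directory holds: traps.csv (trap_id,x,y,nights),
captures.csv (individual,trap_id,count), cameras.csv (station_id,x,y),
resights.csv (individual,station_id,occasion),
unmarked.csv (station_id,occasion,count),
baiting.csv (station_id,occasion_of_baiting),
telemetry.csv (individual,x,y,timestamp), sexes.csv (individual,sex)
and statespace.csv.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .habitat import CanopyGrid, CoverGrid, StateSpace
from .smr.data import SMRData, thin_locations

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_state_space",
    "write_state_space",
    "write_dataset",
    "read_dataset",
]

_EPOCH = pd.Timestamp("2015-12-01T00:00:00")


def read_ascii_grid(path, kind: str = "canopy") -> CanopyGrid:
    """Read a headered ASCII grid; ``kind`` is ``"canopy"`` or ``"cover"``."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_head = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_head += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} is missing header field {key!r}")
    values = np.loadtxt(lines[n_head:], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"ASCII grid {path} data shape does not match its header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    values = values[::-1]  # file rows run north->south; internal row 0 is south
    cls = CoverGrid if kind == "cover" else CanopyGrid
    return cls(
        values,
        origin=(header["xllcorner"], header["yllcorner"]),
        pixel_size=header["cellsize"],
    )


def write_ascii_grid(grid: CanopyGrid, path, nodata: float = -9999.0) -> None:
    path = Path(path)
    nrow, ncol = grid.values.shape
    vals = np.where(np.isfinite(grid.values), grid.values, nodata)[::-1]
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.pixel_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.1f}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_state_space(ss: StateSpace, path) -> None:
    """CSV of cells, with grid metadata in commented header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cell_size {ss.cell_size:.6f}\n")
        fh.write(f"# grid_shape {ss.grid_shape[0]} {ss.grid_shape[1]}\n")
        fh.write(f"# grid_origin {ss.grid_origin[0]:.6f} {ss.grid_origin[1]:.6f}\n")
        pd.DataFrame(
            {
                "x": ss.x,
                "y": ss.y,
                "area_km2": ss.area_km2,
                "veg": ss.veg,
                "habitat": ss.habitat.astype(int),
                "row": ss.row,
                "col": ss.col,
            }
        ).to_csv(fh, index=False)


def read_state_space(path) -> StateSpace:
    path = Path(path)
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            meta[parts[0]] = parts[1:]
    df = pd.read_csv(path, comment="#")
    return StateSpace(
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        area_km2=df["area_km2"].to_numpy(),
        veg=df["veg"].to_numpy(),
        habitat=df["habitat"].to_numpy().astype(bool),
        cell_size=float(meta["cell_size"][0]),
        row=df["row"].to_numpy(dtype=np.int64),
        col=df["col"].to_numpy(dtype=np.int64),
        grid_shape=(int(meta["grid_shape"][0]), int(meta["grid_shape"][1])),
        grid_origin=(float(meta["grid_origin"][0]), float(meta["grid_origin"][1])),
    )


def write_dataset(data: SMRData, outdir) -> None:
    """Write every survey table of a dataset to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "trap_id": data.trap_ids,
            "x": data.trap_xy[:, 0],
            "y": data.trap_xy[:, 1],
            "nights": data.Ktrap,
        }
    ).to_csv(outdir / "traps.csv", index=False)

    rows = [
        {"individual": data.individual_ids[i], "trap_id": data.trap_ids[j],
         "count": int(data.ycap[i, j])}
        for i in range(data.n_marked)
        for j in np.nonzero(data.ycap[i])[0]
    ]
    pd.DataFrame(rows, columns=["individual", "trap_id", "count"]).to_csv(
        outdir / "captures.csv", index=False
    )

    pd.DataFrame(
        {"station_id": data.camera_ids, "x": data.cam_xy[:, 0], "y": data.cam_xy[:, 1]}
    ).to_csv(outdir / "cameras.csv", index=False)

    rows = [
        {"individual": data.individual_ids[i], "station_id": data.camera_ids[j],
         "occasion": int(k)}
        for i in range(data.n_marked)
        for j, k in zip(*np.nonzero(data.ycam[i]))
    ]
    pd.DataFrame(rows, columns=["individual", "station_id", "occasion"]).to_csv(
        outdir / "resights.csv", index=False
    )

    jj, kk = np.nonzero(data.nU)
    pd.DataFrame(
        {
            "station_id": [data.camera_ids[j] for j in jj],
            "occasion": kk,
            "count": data.nU[jj, kk],
        }
    ).to_csv(outdir / "unmarked.csv", index=False)

    # baiting events: occasions where the days counter resets to 0
    rows = [
        {"station_id": data.camera_ids[j], "occasion_of_baiting": int(k)}
        for j in range(data.n_cameras)
        for k in range(data.n_occasions)
        if data.days[j, k] == 0
    ]
    pd.DataFrame(rows, columns=["station_id", "occasion_of_baiting"]).to_csv(
        outdir / "baiting.csv", index=False
    )

    rows = []
    for i, locs in enumerate(data.telemetry):
        for t, (x, y) in enumerate(locs):
            stamp = (_EPOCH + pd.Timedelta(hours=t)).isoformat()
            rows.append(
                {"individual": data.individual_ids[i], "x": x, "y": y,
                 "timestamp": stamp}
            )
    pd.DataFrame(rows, columns=["individual", "x", "y", "timestamp"]).to_csv(
        outdir / "telemetry.csv", index=False
    )

    pd.DataFrame(
        {
            "individual": data.individual_ids,
            "sex": np.where(data.sex == 1, "female", "male"),
        }
    ).to_csv(outdir / "sexes.csv", index=False)

    write_state_space(data.state_space, outdir / "statespace.csv")


def read_dataset(indir, n_occasions: int | None = None) -> SMRData:
    """Assemble an :class:`SMRData` from a dataset directory.

    Telemetry is thinned to fixes >= 1 h apart on read.  ``n_occasions``
    defaults to one past the largest occasion index present in the resight,
    unmarked and baiting tables.
    """
    indir = Path(indir)
    traps = pd.read_csv(indir / "traps.csv")
    cams = pd.read_csv(indir / "cameras.csv")
    captures = pd.read_csv(indir / "captures.csv")
    resights = pd.read_csv(indir / "resights.csv")
    unmarked = pd.read_csv(indir / "unmarked.csv")
    baiting = pd.read_csv(indir / "baiting.csv")
    telemetry = pd.read_csv(indir / "telemetry.csv")
    sexes = pd.read_csv(indir / "sexes.csv")
    ss = read_state_space(indir / "statespace.csv")

    trap_ids = traps["trap_id"].astype(str).tolist()
    cam_ids = cams["station_id"].astype(str).tolist()
    ind_ids = sexes["individual"].astype(str).tolist()
    trap_pos = {t: j for j, t in enumerate(trap_ids)}
    cam_pos = {c: j for j, c in enumerate(cam_ids)}
    ind_pos = {i: n for n, i in enumerate(ind_ids)}
    nm, J, C = len(ind_ids), len(trap_ids), len(cam_ids)

    if n_occasions is None:
        cands = [0]
        for df, col in (
            (resights, "occasion"),
            (unmarked, "occasion"),
            (baiting, "occasion_of_baiting"),
        ):
            if len(df):
                cands.append(int(df[col].max()) + 1)
        n_occasions = max(cands)
    K = n_occasions

    ycap = np.zeros((nm, J), dtype=np.int64)
    for ind, trap, cnt in zip(
        captures["individual"], captures["trap_id"], captures["count"]
    ):
        i = ind_pos.get(str(ind))
        j = trap_pos.get(str(trap))
        if i is None or j is None:
            raise ValueError(f"captures.csv references unknown id: {(ind, trap)}")
        ycap[i, j] = int(cnt)

    ycam = np.zeros((nm, C, K), dtype=np.int8)
    for ind, cam, occ in zip(
        resights["individual"], resights["station_id"], resights["occasion"]
    ):
        i = ind_pos.get(str(ind))
        j = cam_pos.get(str(cam))
        if i is None or j is None:
            raise ValueError(f"resights.csv references unknown id: {(ind, cam)}")
        ycam[i, j, int(occ)] = 1

    nU = np.zeros((C, K), dtype=np.int64)
    for cam, occ, cnt in zip(
        unmarked["station_id"], unmarked["occasion"], unmarked["count"]
    ):
        nU[cam_pos[str(cam)], int(occ)] += int(cnt)

    days = np.zeros((C, K), dtype=np.int64)
    for j, cid in enumerate(cam_ids):
        resets = np.sort(
            baiting.loc[
                baiting["station_id"].astype(str) == cid, "occasion_of_baiting"
            ].to_numpy()
        )
        if resets.size == 0 or resets[0] != 0:
            raise ValueError(f"station {cid!r} has no baiting event at occasion 0")
        occ = np.arange(K)
        last = resets[np.searchsorted(resets, occ, side="right") - 1]
        days[j] = occ - last

    tel: list[np.ndarray] = [np.empty((0, 2)) for _ in range(nm)]
    if len(telemetry):
        telemetry["timestamp"] = pd.to_datetime(telemetry["timestamp"])
        for ind, grp in telemetry.groupby("individual", sort=False):
            i = ind_pos.get(str(ind))
            if i is None:
                raise ValueError(f"telemetry.csv references unknown individual {ind!r}")
            grp = grp.sort_values("timestamp")
            times = (
                grp["timestamp"] - grp["timestamp"].iloc[0]
            ).dt.total_seconds().to_numpy()
            tel[i] = thin_locations(grp[["x", "y"]].to_numpy(), times)

    sex = np.where(sexes["sex"].astype(str).str.lower().isin(("female", "f", "1")), 1, 0)

    return SMRData(
        ycap=ycap,
        Ktrap=traps["nights"].to_numpy(dtype=np.int64),
        trap_xy=traps[["x", "y"]].to_numpy(dtype=float),
        ycam=ycam,
        cam_xy=cams[["x", "y"]].to_numpy(dtype=float),
        nU=nU,
        days=days,
        sex=sex,
        telemetry=tel,
        state_space=ss,
        individual_ids=ind_ids,
        trap_ids=trap_ids,
        camera_ids=cam_ids,
    )
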