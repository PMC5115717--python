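"""Recompute the published evaluation tables from the deposited volumes.

The deposited data comprise fifteen raw volumes: five ITM oxygen fields
(30³ voxels at 100 μm), five CTM oxygen fields (300³ at 10 μm) and five
vessel masks (330³ at 10 μm, i.e. the CTM grids before the 15-voxel pad
was cropped). Given a directory containing them (files named S1 … S15,
any of the extensions .bin/.raw or none, unzipped), this module rebuilds
the per-sample summary table (hypoxic fractions, vascular fraction,
mean/SD), the pairwise RMSD table and the pairwise KS battery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import distribution, ks_two_sample, rmsd, vascular_fraction
from .fields import downsample_block_mean
from .rawvol import RawVolumeSpec, read_raw_volume

__all__ = ["find_supplementary", "reproduce_tables"]

ITM_SHAPE = (30, 30, 30)
CTM_SHAPE = (300, 300, 300)
VESSEL_SHAPE = (330, 330, 330)
PAD_VOX = 15   # vessel volumes carry the pad the oxygen volumes had cropped


def find_supplementary(directory: str | Path) -> dict[int, Path]:
    """Locate S1..S15 in a directory (extensions .bin, .raw or none)."""
    directory = Path(directory)
    found: dict[int, Path] = {}
    for i in range(1, 16):
        for ext in (".bin", ".raw", ""):
            p = directory / f"S{i}{ext}"
            if p.is_file():
                found[i] = p
                break
    return found


def reproduce_tables(directory: str | Path, alpha: float = 0.001,
                     itm_shape=ITM_SHAPE, ctm_shape=CTM_SHAPE,
                     vessel_shape=VESSEL_SHAPE, pad_vox: int = PAD_VOX):
    """Rebuild the evaluation tables from the deposited volumes.

    Returns a dict with ``summary`` (one row per sample: HF_0.01, HF_1,
    HF_5, VF, mean, SD for CTM 1–5, CTM_DS 1 and ITM 1–5), ``rmsd``
    (pairwise CTM RMSD plus the CTM_DS-vs-CTM-1 and ITM-vs-CTM rows) and
    ``ks`` (pairwise CTM KS decisions at ``alpha``). The shape arguments
    exist so the machinery can run on reduced-size volumes laid out in the
    same dialect.
    """
    files = find_supplementary(directory)
    missing = sorted(set(range(1, 16)) - set(files))
    if missing:
        raise FileNotFoundError(
            f"missing supplementary volumes S{missing} in {directory}; "
            "download the deposited data and unzip each archive to a flat "
            "raw file named S<n>")

    ds_factor = round(ctm_shape[0] / itm_shape[0])
    itm = [read_raw_volume(RawVolumeSpec(files[i], itm_shape, spacing=100.0))
           for i in range(1, 6)]
    ctm = [read_raw_volume(RawVolumeSpec(files[i], ctm_shape, spacing=10.0))
           for i in range(6, 11)]
    vessels = [read_raw_volume(RawVolumeSpec(files[i], vessel_shape, spacing=10.0))
               for i in range(11, 16)]
    vf = [vascular_fraction(v.values != 0, crop=pad_vox) for v in vessels]

    rows = []
    dists = {}
    for i, grid in enumerate(ctm):
        d = distribution(grid)
        dists[f"CTM {i + 1}"] = d
        rows.append({"sample": f"CTM {i + 1}", **d.as_dict(), "VF": vf[i]})
    ds1 = downsample_block_mean(ctm[0].values, ds_factor)
    d = distribution(ds1)
    dists["CTM_DS 1"] = d
    rows.append({"sample": "CTM_DS 1", **d.as_dict(), "VF": vf[0]})
    for i, grid in enumerate(itm):
        d = distribution(grid)
        dists[f"ITM {i + 1}"] = d
        rows.append({"sample": f"ITM {i + 1}", **d.as_dict(), "VF": vf[i]})
    summary = pd.DataFrame(rows).set_index("sample")

    ctm_names = [f"CTM {i}" for i in range(1, 6)]
    rmsd_rows = []
    for a in ctm_names:
        rmsd_rows.append({"sample": a, **{
            b: rmsd(dists[a], dists[b]) for b in ctm_names}})
    rmsd_rows.append({"sample": "CTM_DS 1", "CTM 1": rmsd(dists["CTM_DS 1"],
                                                          dists["CTM 1"])})
    for i in range(1, 6):
        rmsd_rows.append({"sample": f"ITM {i}",
                          f"CTM {i}": rmsd(dists[f"ITM {i}"], dists[f"CTM {i}"])})
    rmsd_table = pd.DataFrame(rmsd_rows).set_index("sample")

    ks_rows = []
    for i in range(5):
        for j in range(i + 1, 5):
            res = ks_two_sample(ctm[i].values, ctm[j].values, alpha=alpha)
            ks_rows.append({"a": ctm_names[i], "b": ctm_names[j],
                            "D_KS": res.d_ks, "threshold": res.threshold,
                            "reject": res.reject})
    ks_table = pd.DataFrame(ks_rows)
    return {"summary": summary, "rmsd": rmsd_table, "ks": ks_table,
            "distributions": dists}
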