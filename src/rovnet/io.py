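"""File-format plumbing: NIfTI volumes, tab-delimited tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from rovnet.grid import GridGeometry
from rovnet.rov import ROV, define_rov
from rovnet.variance import SubjectContrast


def save_volume(values: np.ndarray, geometry: GridGeometry, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), geometry.affine), str(path))


def load_volume(path) -> tuple[np.ndarray, GridGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return data, GridGeometry(shape=data.shape, affine=img.affine)


def save_contrast_cohort(cohort: list[SubjectContrast], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sc in enumerate(cohort):
        sid = f"sub-{i + 1:03d}"
        save_volume(sc.con, sc.geometry, out / f"{sid}_con.nii.gz")
        save_volume(sc.resms, sc.geometry, out / f"{sid}_resms.nii.gz")
    (out / "n_scans.json").write_text(json.dumps({"n_scans": cohort[0].n_scans}))


def load_contrast_cohort(in_dir) -> list[SubjectContrast]:
    in_dir = Path(in_dir)
    n_scans = json.loads((in_dir / "n_scans.json").read_text())["n_scans"]
    cohort = []
    for con_path in sorted(in_dir.glob("*_con.nii.gz")):
        resms_path = con_path.with_name(con_path.name.replace("_con", "_resms"))
        con, geom = load_volume(con_path)
        resms, _ = load_volume(resms_path)
        cohort.append(SubjectContrast(con=con, resms=resms, n_scans=n_scans, geometry=geom))
    return cohort


def save_rov_table(rovs: list[ROV], path) -> None:
    df = pd.DataFrame(
        {
            "label": [r.label for r in rovs],
            "kind": [r.kind for r in rovs],
            "x": [r.center_mm[0] for r in rovs],
            "y": [r.center_mm[1] for r in rovs],
            "z": [r.center_mm[2] for r in rovs],
            "radius": [r.radius_mm for r in rovs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_rov_table(path, geometry: GridGeometry) -> list[ROV]:
    df = pd.read_csv(path, sep="\t")
    return [
        define_rov(row.label, row.kind, (row.x, row.y, row.z), geometry, row.radius)
        for row in df.itertuples()
    ]


def save_networks(nets, out_dir, prefix: str = "net") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"state": nets[0].state, "nodes": nets[0].nodes, "n_subjects": len(nets)}
    (out / f"{prefix}_header.json").write_text(json.dumps(header, indent=2))
    for i, net in enumerate(nets):
        pd.DataFrame(net.edges, index=net.nodes, columns=net.nodes).to_csv(
            out / f"{prefix}_sub-{i + 1:03d}.tsv", sep="\t"
        )


def load_networks(in_dir, prefix: str = "net"):
    from rovnet.connectivity import FCNetwork

    in_dir = Path(in_dir)
    header = json.loads((in_dir / f"{prefix}_header.json").read_text())
    nets = []
    for path in sorted(in_dir.glob(f"{prefix}_sub-*.tsv")):
        df = pd.read_csv(path, sep="\t", index_col=0)
        nets.append(
            FCNetwork(state=header["state"], nodes=list(df.columns), edges=df.to_numpy())
        )
    return nets
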