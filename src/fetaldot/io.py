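"""Plain-text exporters: VTK unstructured grids, channel tables, layouts."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import Channel, ChannelGroup, ProbeLayout, TetMesh

_VTK_TETRA = 10


def write_vtu(
    path: str | Path,
    mesh: TetMesh,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
) -> Path:
    """Write an ASCII VTK XML unstructured grid (.vtu).

    Element labels are always included as cell data ``tissue_label``.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = {"tissue_label": mesh.element_labels, **(cell_data or {})}

    def arr(name, data, ncomp=1):
        data = np.asarray(data)
        flat = " ".join(f"{v:.9g}" for v in data.ravel())
        dtype = "Int64" if np.issubdtype(data.dtype, np.integer) else "Float64"
        comp = f' NumberOfComponents="{ncomp}"' if ncomp > 1 else ""
        return (f'<DataArray type="{dtype}" Name="{name}"{comp} '
                f'format="ascii">{flat}</DataArray>')

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.num_nodes}" '
        f'NumberOfCells="{mesh.num_elements}">',
        "<Points>", arr("Points", mesh.nodes, ncomp=3), "</Points>",
        "<Cells>",
        arr("connectivity", mesh.elements),
        arr("offsets", np.arange(1, mesh.num_elements + 1) * 4),
        arr("types", np.full(mesh.num_elements, _VTK_TETRA, dtype=np.int64)),
        "</Cells>",
    ]
    lines.append("<PointData>")
    for name, data in point_data.items():
        lines.append(arr(name, data))
    lines.append("</PointData>")
    lines.append("<CellData>")
    for name, data in cell_data.items():
        lines.append(arr(name, data))
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


def layout_to_json(layout: ProbeLayout, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "grid_shape": list(layout.grid_shape),
        "grid_extent": list(layout.grid_extent),
        "source_positions": np.asarray(layout.source_positions).tolist(),
        "detector_positions": np.asarray(layout.detector_positions).tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def layout_from_json(path: str | Path) -> ProbeLayout:
    payload = json.loads(Path(path).read_text())
    return ProbeLayout(
        source_positions=np.asarray(payload["source_positions"]),
        detector_positions=np.asarray(payload["detector_positions"]),
        grid_shape=tuple(payload["grid_shape"]),
        grid_extent=tuple(payload["grid_extent"]),
    )


def channels_to_frame(
    channels: Sequence[Channel],
    groups: Sequence[ChannelGroup] | None = None,
) -> pd.DataFrame:
    labels = {}
    if groups:
        for g in groups:
            for ch in g.channels:
                labels[(ch.source_id, ch.detector_id)] = g.label
    return pd.DataFrame(
        {
            "source_id": [c.source_id for c in channels],
            "detector_id": [c.detector_id for c in channels],
            "distance_mm": [c.distance for c in channels],
            "group": [
                labels.get((c.source_id, c.detector_id), "") for c in channels
            ],
        }
    )
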