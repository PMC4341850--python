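"""Volume and graph I/O, parameter handling.

Conventions
-----------
Voxel arrays are indexed ``voxels[x, y, z]`` with 0-based integer indices.
The physical position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
per axis; spacing is strictly positive and may be anisotropic.

Supported volume formats: NRRD, NIfTI (``.nii``/``.nii.gz``), MetaImage
(``.mha``/``.mhd``) via SimpleITK, and multi-page TIFF via tifffile.  TIFF
stacks carry no reliable spacing metadata; missing spacing falls back to unit
spacing with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .errors import EmptyVolumeError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_SITK_SUFFIXES = (".nrrd", ".nii", ".nii.gz", ".mha", ".mhd")
_TIFF_SUFFIXES = (".tif", ".tiff")


@dataclass
class LabelVolume:
    """A binary 3D foreground mask with physical voxel spacing and origin.

    ``voxels`` is a 3D boolean array indexed ``[x, y, z]``.  An empty
    (all-background) volume is representable, but every downstream operation
    that needs foreground raises :class:`~airway_topo.errors.EmptyVolumeError`.
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValidationError("spacing and origin must be 3-vectors")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def physical(self, index) -> np.ndarray:
        """Physical position of a (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass(frozen=True)
class Parameters:
    """Tunable parameters of the topology-extraction pipeline.

    min_branch_length
        Physical length below which a candidate branch is suppressed as noise.
        ``None`` means 5% of the main-path length, resolved per volume.
    junction_merge_distance
        Physical length below which adjacent junctions are merged into one
        higher-degree junction.  ``None`` means three voxels at mean spacing.
    main_path_fraction
        Fraction of the main-airway length within which junctions are counted.
    mst_neighbor_count
        Nearest-neighbour candidate-edge count for minimum-spanning-tree
        construction over the skeleton point cloud.
    rng_seed
        Seed for any stochastic step.
    """

    min_branch_length: float | None = None
    junction_merge_distance: float | None = None
    main_path_fraction: float = 0.75
    mst_neighbor_count: int = 26
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_branch_length is not None and not self.min_branch_length > 0:
            raise ValidationError("min_branch_length must be > 0")
        if self.junction_merge_distance is not None and self.junction_merge_distance < 0:
            raise ValidationError("junction_merge_distance must be >= 0")
        if not (0 < self.main_path_fraction <= 1):
            raise ValidationError("main_path_fraction must lie in (0, 1]")
        if self.mst_neighbor_count < 1:
            raise ValidationError("mst_neighbor_count must be >= 1")

    def resolve_merge_distance(self, spacing) -> float:
        if self.junction_merge_distance is not None:
            return float(self.junction_merge_distance)
        return 3.0 * float(np.mean(spacing))

    def with_overrides(self, **kwargs) -> "Parameters":
        return replace(self, **kwargs)


_PARAM_KEYS = frozenset(
    (
        "min_branch_length",
        "junction_merge_distance",
        "main_path_fraction",
        "mst_neighbor_count",
        "rng_seed",
    )
)


def load_parameters(path=None, **overrides) -> Parameters:
    """Load :class:`Parameters` from a JSON key/value document.

    Absent keys take the documented defaults; unknown keys are rejected so a
    typo never silently falls back to a default.  ``path=None`` yields the
    defaults, optionally updated by keyword overrides.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise ValidationError("parameter file must contain a JSON object")
        unknown = set(data) - _PARAM_KEYS
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        values.update(data)
    values.update(overrides)
    return Parameters(**values)


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path, binarize_threshold: float = 0.0) -> LabelVolume:
    """Read a volume file and binarize it with a strict ``>`` threshold.

    Raises
    ------
    FormatError
        If the file suffix is not a supported volume format.
    EmptyVolumeError
        If no voxel exceeds the threshold.
    """
    path = Path(path)
    if not np.isfinite(binarize_threshold):
        raise ValidationError("binarize_threshold must be finite")
    suffix = _suffix(path)
    if suffix in _SITK_SUFFIXES:
        img = sitk.ReadImage(str(path))
        raw = sitk.GetArrayFromImage(img)  # (z, y, x)
        if raw.ndim != 3:
            raise FormatError(f"{path}: expected a 3D image, got ndim={raw.ndim}")
        voxels = np.ascontiguousarray(raw.transpose(2, 1, 0))
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    elif suffix in _TIFF_SUFFIXES:
        raw = tifffile.imread(str(path))  # (pages=z, y, x)
        if raw.ndim != 3:
            raise FormatError(f"{path}: expected a multi-page TIFF stack")
        voxels = np.ascontiguousarray(raw.transpose(2, 1, 0))
        logger.warning("%s: TIFF carries no spacing metadata, assuming unit spacing", path)
        spacing = np.ones(3)
        origin = np.zeros(3)
    else:
        raise FormatError(f"unsupported volume format: {path}")
    mask = voxels > binarize_threshold
    if not mask.any():
        raise EmptyVolumeError(f"{path}: no foreground voxel above threshold {binarize_threshold}")
    return LabelVolume(mask, spacing=spacing, origin=origin)


def write_volume(volume: LabelVolume, path) -> None:
    """Write a binary volume (foreground = 1) to a supported format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = _suffix(path)
    data = volume.voxels.astype(np.uint8)
    if suffix in _SITK_SUFFIXES:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(
            str(path), np.ascontiguousarray(data.transpose(2, 1, 0)), photometric="minisblack"
        )
    else:
        raise FormatError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# Topology-graph serialization
# ---------------------------------------------------------------------------

def _graph_to_records(tg):
    nodes = []
    for n, d in sorted(tg.graph.nodes(data=True)):
        px, py, pz = (float(v) for v in d["position"])
        nodes.append(
            dict(
                id=int(n),
                kind=d["kind"],
                px=px,
                py=py,
                pz=pz,
                arc_length=float(d["arc_length"]),
                degree=int(tg.graph.degree(n)),
            )
        )
    edges = [
        dict(source=int(min(u, v)), target=int(max(u, v)), length=float(d["length"]))
        for u, v, d in sorted(tg.graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1])))
    ]
    return nodes, edges


def write_topology_graph(tg, path, fmt: str | None = None) -> None:
    """Serialize a :class:`~airway_topo.topology.TopologyGraph`.

    GraphML stores one node element per topology node (kind, position,
    arc-length from the entrance, degree) and one edge element per branch
    (physical length).  CSV writes two files, ``<stem>_nodes.csv`` and
    ``<stem>_edges.csv``, with the same attributes.  Re-reading with
    :func:`read_topology_graph` reproduces the graph exactly.
    """
    import networkx as nx

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "graphml"
    nodes, edges = _graph_to_records(tg)
    if fmt == "graphml":
        g = nx.Graph(
            entrance=int(tg.entrance), main_path_length=float(tg.main_path_length)
        )
        for rec in nodes:
            g.add_node(rec["id"], **{k: v for k, v in rec.items() if k != "id"})
        for rec in edges:
            g.add_edge(rec["source"], rec["target"], length=rec["length"])
        nx.write_graphml(g, str(path))
    elif fmt == "csv":
        node_path, edge_path = _csv_pair(path)
        ndf = pd.DataFrame(nodes, columns=["id", "kind", "px", "py", "pz", "arc_length", "degree"])
        ndf.insert(0, "main_path_length", float(tg.main_path_length))
        ndf.insert(0, "entrance", int(tg.entrance))
        ndf.to_csv(node_path, index=False)
        pd.DataFrame(edges, columns=["source", "target", "length"]).to_csv(edge_path, index=False)
    else:
        raise FormatError(f"unsupported graph format: {fmt}")


def _csv_pair(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_nodes.csv"), Path(f"{stem}_edges.csv")


def read_topology_graph(path, fmt: str | None = None):
    """Read a topology graph written by :func:`write_topology_graph`."""
    import networkx as nx

    from .topology import TopologyGraph

    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "graphml"
    g = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(str(path))
        entrance = int(raw.graph["entrance"])
        main_len = float(raw.graph["main_path_length"])
        for n, d in raw.nodes(data=True):
            g.add_node(
                int(n),
                kind=d["kind"],
                position=(float(d["px"]), float(d["py"]), float(d["pz"])),
                arc_length=float(d["arc_length"]),
            )
        for u, v, d in raw.edges(data=True):
            g.add_edge(int(u), int(v), length=float(d["length"]))
    elif fmt == "csv":
        node_path, edge_path = _csv_pair(path)
        ndf = pd.read_csv(node_path)
        edf = pd.read_csv(edge_path)
        entrance = int(ndf["entrance"].iloc[0])
        main_len = float(ndf["main_path_length"].iloc[0])
        for rec in ndf.itertuples():
            g.add_node(
                int(rec.id),
                kind=rec.kind,
                position=(float(rec.px), float(rec.py), float(rec.pz)),
                arc_length=float(rec.arc_length),
            )
        for rec in edf.itertuples():
            g.add_edge(int(rec.source), int(rec.target), length=float(rec.length))
    else:
        raise FormatError(f"unsupported graph format: {fmt}")
    return TopologyGraph(graph=g, entrance=entrance, main_path_length=main_len)
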