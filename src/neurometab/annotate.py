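"""Spatial contiguity testing and atlas annotation of voxel communities.

Each community's voxels are mapped back to the 3D grid; a community is
annotated with an atlas region name only when (a) its largest 26-connected
component holds at least ``contig_min`` of its voxels and (b) a single
region holds at least ``majority_min`` of them; otherwise the verdict is
"N/A", mirroring how scattered clusters fail to map to a contiguous brain
region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .volumes import GMMask

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class AtlasVolume:
    labels: np.ndarray            # integer 3D array, 0 = background
    names: pd.DataFrame           # columns: label, name

    def name_of(self, label: int) -> str:
        row = self.names.loc[self.names["label"] == label, "name"]
        return str(row.iloc[0]) if len(row) else f"label_{label}"


@dataclass
class ClusterAnnotation:
    community: int | str
    n_voxels: int
    largest_connected_fraction: float
    majority_label: int
    majority_fraction: float
    verdict: str


def connected_components(
    voxel_grid_ids: np.ndarray, mask: GMMask, connectivity: int = 26
) -> list[int]:
    """Sizes of 26- (or 6-) connected components, sorted descending."""
    voxel_grid_ids = np.asarray(voxel_grid_ids, dtype=np.int64)
    if voxel_grid_ids.size == 0:
        return []
    vol = np.zeros(mask.mask.shape, dtype=bool)
    vol.ravel()[voxel_grid_ids] = True
    if not np.all(mask.mask.ravel()[voxel_grid_ids]):
        raise InputError("some voxel ids fall outside the mask")
    struct = STRUCT_26 if connectivity == 26 else STRUCT_6
    labeled, n = ndimage.label(vol, structure=struct)
    sizes = np.bincount(labeled.ravel())[1:]
    return sorted((int(s) for s in sizes), reverse=True)


def annotate_cluster(
    voxel_grid_ids: np.ndarray,
    atlas: AtlasVolume,
    mask: GMMask,
    community: int | str = 0,
    contig_min: float = 0.5,
    majority_min: float = 0.5,
    connectivity: int = 26,
) -> ClusterAnnotation:
    """Assign an atlas region or N/A based on contiguity and label majority."""
    if atlas.labels.shape != mask.mask.shape:
        raise InputError("atlas grid does not match the mask grid")
    voxel_grid_ids = np.asarray(voxel_grid_ids, dtype=np.int64)
    n = voxel_grid_ids.size
    if n == 0:
        return ClusterAnnotation(community, 0, 0.0, 0, 0.0, "N/A")
    sizes = connected_components(voxel_grid_ids, mask, connectivity)
    largest_frac = sizes[0] / n
    labels = atlas.labels.ravel()[voxel_grid_ids]
    counts = np.bincount(labels)
    majority = int(np.argmax(counts))
    majority_frac = counts[majority] / n
    contiguous = largest_frac >= contig_min
    dominant = majority_frac >= majority_min and majority != 0
    verdict = atlas.name_of(majority) if (contiguous and dominant) else "N/A"
    return ClusterAnnotation(
        community=community,
        n_voxels=int(n),
        largest_connected_fraction=float(largest_frac),
        majority_label=majority,
        majority_fraction=float(majority_frac),
        verdict=verdict,
    )


def annotate_communities(
    communities, mask: GMMask, atlas: AtlasVolume,
    voxel_name_to_id: dict[str, int],
    contig_min: float = 0.5,
    majority_min: float = 0.5,
) -> pd.DataFrame:
    """Annotation report for every community of a CommunitySet."""
    rows = []
    for c in communities.communities:
        vox_names = [
            v for v in communities.nodes_in(c)
            if communities.node_types[v] == "voxel"
        ]
        if not vox_names:
            continue
        ids = mask.to_grid_ids(np.array([voxel_name_to_id[v] for v in vox_names]))
        ann = annotate_cluster(
            ids, atlas, mask, community=c,
            contig_min=contig_min, majority_min=majority_min,
        )
        rows.append(
            (c, ann.n_voxels, ann.largest_connected_fraction,
             ann.majority_label, ann.majority_fraction, ann.verdict)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "community", "n_voxels", "largest_connected_fraction",
            "majority_label", "majority_fraction", "verdict",
        ],
    )
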