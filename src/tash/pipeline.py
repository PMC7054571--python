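"""The Heschl's gyrus delineation algorithm.

Starting from a Destrieux-style parcellation and a white-surface mean
curvature field, the pipeline:

1. merges the transverse temporal gyrus (HG), transverse temporal sulcus
   (HS) and planum temporale (PT) ROIs into a *raw auditory complex*, and
   those three plus the posterior segment of the lateral sulcus into a
   *raw expansion mask* (the latter recovers the medial-most portion of HG
   that atlas parcellations often mislabel);
2. restricts each to gyral vertices (mean curvature < 0) and applies a
   vertex-graph morphological opening, removing thin formations that run
   along the superior temporal gyrus but do not belong to HG;
3. thresholds the refined auditory complex at curvature < −0.1 to find the
   gyral crowns;
4. grows the crowns back within the refined expansion mask to recover the
   full extent of each transverse gyrus;
5. drops connected clusters smaller than 100 vertices and selects the most
   anterior surviving gyrus by area-weighted centroid.

Common-stem duplications stay connected through the stem and are therefore
included in the output; fully separated posterior duplications form their
own cluster, lie further posterior, and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import mesh
from .errors import ConfigurationError, ParameterError, PipelineError
from .types import CorticalParcellation, SurfaceLabel, TriangleSurface, VertexScalarField

logger = logging.getLogger(__name__)

DEFAULT_ROI_NAMES = (
    "G_temp_sup-G_T_transv",   # transverse temporal gyrus (HG)
    "S_temporal_transverse",   # transverse temporal sulcus (HS)
    "G_temp_sup-Plan_tempo",   # planum temporale (PT)
    "Lat_Fis-post",            # posterior segment of the lateral sulcus
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable constants of the delineation.

    roi_names
        The four Destrieux ROI names: gyrus, sulcus, planum temporale,
        posterior lateral sulcus (case-sensitive).
    gyral_threshold
        Strict upper cutoff on mean curvature for a vertex to count as
        gyral (default 0: keep curvature < 0).
    crown_threshold
        Strict cutoff for gyral crowns (default −0.1 mm⁻¹).
    opening_depth
        Erosion/dilation depth in hop layers (default 3: strips three
        vertex layers, discarding formations up to six vertices wide).
    min_cluster_vertices
        Clusters smaller than this are eliminated before selection
        (default 100).
    anterior_axis
        RAS coordinate index used for the anterior ordering (default 1,
        i.e. +Y anterior).
    """

    roi_names: tuple[str, str, str, str] = DEFAULT_ROI_NAMES
    gyral_threshold: float = 0.0
    crown_threshold: float = -0.1
    opening_depth: int = 3
    min_cluster_vertices: int = 100
    anterior_axis: int = 1

    def __post_init__(self) -> None:
        if len(self.roi_names) != 4:
            raise ParameterError("roi_names must name exactly 4 ROIs")
        if not self.crown_threshold < self.gyral_threshold:
            raise ParameterError(
                "crown_threshold must be below gyral_threshold "
                f"({self.crown_threshold} vs {self.gyral_threshold})"
            )
        if self.opening_depth < 1:
            raise ParameterError("opening_depth must be ≥ 1")
        if self.min_cluster_vertices < 1:
            raise ParameterError("min_cluster_vertices must be ≥ 1")
        if self.anterior_axis not in (0, 1, 2):
            raise ParameterError("anterior_axis must be 0, 1 or 2")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


@dataclass
class GyrusCandidate:
    """One connected gyrus recovered by the regrowth step."""

    vertices: np.ndarray
    centroid: np.ndarray
    anterior_coord: float

    @property
    def size(self) -> int:
        return int(self.vertices.size)


@dataclass
class TashResult:
    """Final label plus the audit trail of the run."""

    hg_label: SurfaceLabel
    candidates: list[GyrusCandidate]
    selected: GyrusCandidate
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)
    config_used: PipelineConfig = field(default_factory=PipelineConfig)


def assemble_masks(
    parc: CorticalParcellation, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Merge the auditory ROIs into the raw complex and raw expansion mask.

    raw complex = HG ∪ HS ∪ PT; raw expansion mask = complex ∪ posterior
    lateral sulcus.  An empty (but named) ROI only warns — a hemisphere may
    lack a distinct transverse temporal sulcus, for instance.
    """
    ids = []
    for name in config.roi_names:
        rid = parc.roi_id(name)
        if rid is None:
            raise ConfigurationError(
                f"ROI {name!r} not found in parcellation; available: "
                f"{sorted(parc.names)}"
            )
        ids.append(rid)
    sets = []
    for name, rid in zip(config.roi_names, ids):
        verts = parc.vertices_of(rid)
        if verts.size == 0:
            logger.warning("ROI %r resolved but contains no vertices", name)
        sets.append(verts)
    raw_complex = np.unique(np.concatenate(sets[:3]))
    raw_expansion = np.unique(np.concatenate(sets))
    logger.info(
        "raw auditory complex: %d vertices; raw expansion mask: %d",
        raw_complex.size, raw_expansion.size,
    )
    return raw_complex, raw_expansion


def gyral_mask(members: np.ndarray, curv: VertexScalarField,
               threshold: float) -> np.ndarray:
    """Keep only vertices with mean curvature strictly below *threshold*."""
    members = np.asarray(members, dtype=np.int64)
    return members[curv.values[members] < threshold]


def refine_mask(members: np.ndarray, graph: mesh.VertexGraph,
                config: PipelineConfig) -> np.ndarray:
    """Morphological opening of a curvature-filtered mask."""
    return mesh.morphological_open(members, graph, config.opening_depth)


def identify_crowns(final_complex: np.ndarray, curv: VertexScalarField,
                    config: PipelineConfig) -> np.ndarray:
    """Gyral crowns: vertices of the final complex with curvature below the
    crown threshold.  Raises if none survive — there is nothing to grow."""
    crowns = gyral_mask(final_complex, curv, config.crown_threshold)
    if crowns.size == 0:
        raise PipelineError(
            f"no gyral crown found (no curvature < {config.crown_threshold} "
            "within the final auditory complex)"
        )
    return crowns


def delineate_gyri(
    crowns: np.ndarray,
    final_expansion: np.ndarray,
    graph: mesh.VertexGraph,
    surface: TriangleSurface,
    areas: VertexScalarField,
    config: PipelineConfig,
) -> list[GyrusCandidate]:
    """Grow the crowns back within the expansion mask and split into gyri."""
    expansion_mask = np.zeros(graph.n, dtype=bool)
    expansion_mask[final_expansion] = True
    inside = expansion_mask[crowns]
    if not inside.all():
        logger.warning(
            "%d crown vertices fall outside the final expansion mask; "
            "intersecting", int((~inside).sum()),
        )
        crowns = crowns[inside]
        if crowns.size == 0:
            raise PipelineError("all crown vertices outside expansion mask")
    grown = mesh.region_grow(crowns, final_expansion, graph)
    candidates = []
    for comp in mesh.connected_components(grown, graph):
        centroid = mesh.weighted_centroid(comp, surface, areas)
        candidates.append(
            GyrusCandidate(
                vertices=comp,
                centroid=centroid,
                anterior_coord=float(centroid[config.anterior_axis]),
            )
        )
    return candidates


def filter_and_select(candidates: list[GyrusCandidate],
                      config: PipelineConfig) -> GyrusCandidate:
    """Drop clusters below the size floor, then take the most anterior gyrus.

    Ties on the anterior coordinate break to the larger candidate, then to
    the one containing the smallest vertex index — fully deterministic.
    """
    if not candidates:
        raise PipelineError("no gyrus candidates to select from")
    survivors = [c for c in candidates if c.size >= config.min_cluster_vertices]
    if not survivors:
        raise PipelineError(
            f"no candidate gyrus ≥ {config.min_cluster_vertices} vertices "
            f"(largest was {max(c.size for c in candidates)})"
        )
    return max(
        survivors,
        key=lambda c: (c.anterior_coord, c.size, -int(c.vertices[0])),
    )


def run_tash(
    white: TriangleSurface,
    curv: VertexScalarField,
    parc: CorticalParcellation,
    config: PipelineConfig | None = None,
    keep_intermediates: bool = False,
    label_name: str = "TASH_HG",
) -> TashResult:
    """Run the full delineation on one hemisphere.

    All inputs must share the white surface's vertex count.  The result's
    label carries white-surface coordinates.  Entirely deterministic.
    """
    config = config or PipelineConfig()
    curv.check_length(white.n_vertices)
    if parc.n_vertices != white.n_vertices:
        raise ConfigurationError(
            f"parcellation has {parc.n_vertices} vertices, "
            f"surface has {white.n_vertices}"
        )
    graph = mesh.build_adjacency(white)
    areas = mesh.vertex_areas(white)

    raw_complex, raw_expansion = assemble_masks(parc, config)

    complex_gyral = gyral_mask(raw_complex, curv, config.gyral_threshold)
    final_complex = refine_mask(complex_gyral, graph, config)
    logger.info("final auditory complex: %d vertices", final_complex.size)

    expansion_gyral = gyral_mask(raw_expansion, curv, config.gyral_threshold)
    final_expansion = refine_mask(expansion_gyral, graph, config)
    logger.info("final expansion mask: %d vertices", final_expansion.size)

    crowns = identify_crowns(final_complex, curv, config)
    logger.info("gyral crowns: %d vertices", crowns.size)

    candidates = delineate_gyri(crowns, final_expansion, graph, white, areas, config)
    logger.info(
        "gyrus candidates: %s",
        [(c.size, round(c.anterior_coord, 2)) for c in candidates],
    )
    selected = filter_and_select(candidates, config)
    logger.info(
        "selected gyrus: %d vertices, anterior coord %.2f mm",
        selected.size, selected.anterior_coord,
    )

    hg_label = SurfaceLabel.from_vertices(selected.vertices, white, name=label_name)
    intermediates: dict[str, np.ndarray] = {}
    if keep_intermediates:
        intermediates = {
            "raw_complex": raw_complex,
            "raw_expansion": raw_expansion,
            "complex_gyral": complex_gyral,
            "final_complex": final_complex,
            "expansion_gyral": expansion_gyral,
            "final_expansion": final_expansion,
            "crowns": crowns,
            "grown": np.unique(np.concatenate([c.vertices for c in candidates])),
        }
    return TashResult(
        hg_label=hg_label,
        candidates=candidates,
        selected=selected,
        intermediates=intermediates,
        config_used=config,
    )
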