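"""Topology of imaged molecules and twist/writhe/linking-number bookkeeping.

Classifies segmented molecules into linear chains, open circles,
plectonemes (interwound supercoils) and compacted particles; measures the
superhelical-axis length of plectonemes from their skeleton; and provides
the arithmetic of White's relation ``dLk = dTw + Wr`` for the
duplex-unwinding mechanism: protein binding that unwinds the double helix
lowers twist, and in a covalently closed circle (fixed linking number) the
deficit reappears as writhe, i.e. supercoiling.

Sign convention: unwinding gives negative dTw; for a closed chain
(dLk = 0) the writhe is Wr = -dTw > 0 (positive supercoiling of an
initially relaxed circle); for a nicked/open chain twist change is
absorbed (Wr = 0, dLk = dTw).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from skimage.morphology import skeletonize

from .errors import ClassificationError, ParameterError
from .image import AFMImage
from .tracing import (
    MoleculeRegion,
    branch_points_of,
    endpoints_of,
    measure_contour_length,
    prune_spurs,
    skeleton_graph,
    trace_backbone,
)

__all__ = [
    "TopologyReport",
    "LinkingState",
    "classify_topology",
    "measure_superhelical_axis",
    "axis_to_contour_ratio",
    "unwinding_model",
]


# =============================================================================
# domain types
# =============================================================================
@dataclass
class TopologyReport:
    molecule_id: int
    mol_class: str  # linear | open_circle | plectoneme | compact
    contour_nm: float | None = None
    axis_nm: float | None = None
    axis_ratio: float | None = None
    n_branches: int = 0


@dataclass
class LinkingState:
    """Linking-number bookkeeping of a closed or nicked duplex.

    White's relation ``dLk = dTw + Wr`` holds exactly by construction.
    """

    lk0: float
    d_lk: float
    d_tw: float
    wr: float
    n_bp: int
    pitch_bp_per_turn: float

    def __post_init__(self) -> None:
        if abs(self.d_lk - self.d_tw - self.wr) > 1e-12 * max(1.0, abs(self.d_lk)):
            raise ParameterError("White's relation dLk = dTw + Wr violated")


# =============================================================================
# image-based classification
# =============================================================================
def _skeleton_heights(image: AFMImage, g: nx.Graph) -> float:
    """Mean image height over the skeleton pixels (the ridge crest)."""
    if len(g) == 0:
        return 0.0
    rc = np.asarray(list(g.nodes))
    return float(image.heights[rc[:, 0], rc[:, 1]].mean())


def classify_topology(
    image: AFMImage,
    region: MoleculeRegion,
    *,
    compact_height_nm: float = 1.2,
    single_strand_height_nm: float | None = None,
    doubled_factor: float = 1.6,
    step_nm: float = 8.0,
) -> TopologyReport:
    """Classify one segmented molecule and measure what its class allows.

    ``compact`` when the region's measured height (its 95th-percentile
    crest) exceeds ``compact_height_nm``.
    Otherwise the pruned skeleton decides: branch points, or a ridge crest
    higher than ``doubled_factor`` x the single-strand calibration, mean a
    plectoneme (interwound body, two unresolved strands); zero endpoints
    and no branches an open circle; two endpoints a linear chain.  Contour
    length is traced for linear/open-circle molecules; for plectonemes the
    underlying DNA length is not observable from the image and stays None.

    ``single_strand_height_nm`` defaults to the blurred crest height of the
    region itself for linear/circular skeletons, so it must be provided
    (from a bare-DNA calibration) to detect doubled bodies reliably.
    """
    crest = region.crest_height_nm or region.mean_height_nm
    if region.class_hint == "compact" or crest > compact_height_nm:
        return TopologyReport(
            molecule_id=region.molecule_id, mol_class="compact"
        )
    skel = skeletonize(region.mask)
    g = prune_spurs(skeleton_graph(skel))
    ends = endpoints_of(g)
    branches = branch_points_of(g)
    crest = _skeleton_heights(image, g)
    doubled = (
        single_strand_height_nm is not None
        and crest > doubled_factor * single_strand_height_nm
    )
    if branches or doubled:
        return TopologyReport(
            molecule_id=region.molecule_id,
            mol_class="plectoneme",
            n_branches=len(branches),
        )
    if len(ends) == 1:
        raise ClassificationError(
            f"molecule {region.molecule_id}: skeleton with a single endpoint"
        )
    if len(ends) > 2:
        raise ClassificationError(
            f"molecule {region.molecule_id}: {len(ends)} endpoints but no branch "
            "points; inconsistent skeleton"
        )
    mol_class = "open_circle" if len(ends) == 0 else "linear"
    hint = "circular" if mol_class == "open_circle" else "linear"
    work = MoleculeRegion(
        mask=region.mask,
        bbox=region.bbox,
        mean_height_nm=region.mean_height_nm,
        area_nm2=region.area_nm2,
        class_hint=hint,
        molecule_id=region.molecule_id,
        crest_height_nm=region.crest_height_nm,
    )
    contour = measure_contour_length(trace_backbone(image, work, step_nm))
    return TopologyReport(
        molecule_id=region.molecule_id, mol_class=mol_class, contour_nm=contour
    )


def measure_superhelical_axis(
    image: AFMImage,
    region: MoleculeRegion,
    *,
    mol_class: str = "plectoneme",
    spur_px: int = 3,
) -> float:
    """Skeletal path length (nm) of the interwound body of a plectoneme.

    Sums the Euclidean path lengths of all skeleton branches; edges that
    belong to cycles (apical end loops that survive skeletonization) count
    half, since a loop's perimeter covers its axis extension twice.
    """
    if mol_class != "plectoneme":
        raise ParameterError(
            f"superhelical axis is defined for plectonemes, not {mol_class!r}"
        )
    skel = skeletonize(region.mask)
    g = prune_spurs(skeleton_graph(skel), spur_px)
    if len(g) == 0:
        raise ClassificationError("no skeleton to measure")
    cycle_edges: set[frozenset] = set()
    for cyc in nx.cycle_basis(g):
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            cycle_edges.add(frozenset((a, b)))
    total = 0.0
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        total += 0.5 * w if frozenset((u, v)) in cycle_edges else w
    return total * image.pixel_nm


def axis_to_contour_ratio(axis_nm: float, contour_nm: float) -> float:
    """Superhelical-axis to DNA-contour ratio, reported to two decimals."""
    if axis_nm <= 0 or contour_nm <= 0:
        raise ParameterError("axis_nm and contour_nm must be > 0")
    return round(axis_nm / contour_nm, 2)


# =============================================================================
# unwinding / linking-number model
# =============================================================================
def unwinding_model(
    n_bp: int,
    n_bound_dimers: int,
    unwind_deg_per_dimer: float,
    d_rise_nm_per_bound_bp: float,
    *,
    pitch_bp_per_turn: float = 10.5,
    rise_nm_per_bp: float = 0.34,
    footprint_bp: int = 9,
    closed: bool = True,
) -> tuple[LinkingState, float]:
    """Pure bookkeeping of duplex unwinding by bound protein dimers.

    Each bound dimer (footprint ``footprint_bp`` base pairs) unwinds the
    duplex by ``unwind_deg_per_dimer`` degrees and stretches each covered
    base pair by ``d_rise_nm_per_bound_bp``.  Twist change is
    ``dTw = -n_dimers * unwind_deg / 360`` turns; a covalently closed chain
    (fixed Lk, dLk = 0) converts it into writhe ``Wr = -dTw``, a nicked or
    linear chain absorbs it (Wr = 0, dLk = dTw).  The relative contour
    extension is ``occupancy * d_rise / rise``.  No mechanics is implied.
    """
    if n_bp <= 0 or footprint_bp <= 0:
        raise ParameterError("n_bp and footprint_bp must be > 0")
    if n_bound_dimers < 0:
        raise ParameterError("n_bound_dimers must be >= 0")
    occupancy = n_bound_dimers * footprint_bp / n_bp
    if occupancy > 1.0 + 1e-12:
        raise ParameterError(
            f"occupancy {occupancy:.3f} > 1: too many dimers for {n_bp} bp"
        )
    d_tw = -n_bound_dimers * unwind_deg_per_dimer / 360.0
    if closed:
        d_lk, wr = 0.0, -d_tw
    else:
        d_lk, wr = d_tw, 0.0
    state = LinkingState(
        lk0=n_bp / pitch_bp_per_turn,
        d_lk=d_lk,
        d_tw=d_tw,
        wr=wr,
        n_bp=n_bp,
        pitch_bp_per_turn=pitch_bp_per_turn,
    )
    extension_fraction = occupancy * d_rise_nm_per_bound_bp / rise_nm_per_bp
    return state, extension_fraction
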