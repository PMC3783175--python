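"""End-to-end recovery experiments used by the analysis drivers and tests.

Each routine runs the full pipeline — generate ground-truth chains, render
AFM-like images, segment and trace, then measure — and returns both the
measured quantities and the generator truth, so parameter recovery can be
assessed without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AfmWlcError, TraceError
from .image import AFMImage
from .synthetic_data import (
    ConditionSpec,
    RenderParams,
    derive_seed,
    generate_compact,
    generate_plectoneme,
    make_condition_ensemble,
)
from .tracing import TraceResult, segment_molecules, trace_backbone
from .topology import classify_topology, measure_superhelical_axis
from .wlc_statistics import (
    contour_length_stats,
    fit_persistence_length,
    tangent_correlation,
)

__all__ = [
    "trace_ensemble",
    "recover_persistence_length",
    "recover_contour_length",
    "topology_benchmark",
]


def trace_ensemble(
    images: list[AFMImage],
    step_nm: float = 8.0,
    min_len_nm: float = 50.0,
) -> list[TraceResult]:
    """Segment and trace every analyzable molecule in a list of images."""
    traces: list[TraceResult] = []
    for i, img in enumerate(images):
        for region in segment_molecules(img, min_len_nm=min_len_nm):
            if region.class_hint not in ("linear", "circular"):
                continue
            try:
                tr = trace_backbone(img, region, step_nm)
            except TraceError:
                continue
            tr.molecule_id = len(traces)
            tr.image_index = i
            traces.append(tr)
    return traces


@dataclass
class LpRecovery:
    fit_lp_nm: float
    true_lp_nm: float
    n_traced: int
    n_generated: int
    traces: list[TraceResult]


def recover_persistence_length(
    seed: int,
    n_molecules: int = 30,
    lp_nm: float = 56.0,
    contour_nm: float = 856.0,
    closed: bool = True,
    fit_range: tuple[float, float] = (8.0, 120.0),
    render: RenderParams | None = None,
) -> LpRecovery:
    """Simulate, render, trace and fit the 2D WLC decay; return the fit.

    Defaults reproduce the plasmid-scale calibration: 30 closed chains of
    856 nm contour at Lp 56 nm, rendered at 2 nm/px with a 0.6 nm ridge
    and 0.05 nm noise, traced at an 8 nm step, fitted over 8-120 nm.
    """
    spec = ConditionSpec(
        n_molecules=n_molecules,
        lp_nm=lp_nm,
        contour_nm=contour_nm,
        closed=closed,
        render=render or RenderParams(),
    )
    pairs = make_condition_ensemble(spec, seed)
    traces = trace_ensemble([img for _, img in pairs])
    curve = tangent_correlation(traces, fit_range[1])
    fit = fit_persistence_length(curve, fit_range)
    return LpRecovery(
        fit_lp_nm=fit.lp,
        true_lp_nm=lp_nm,
        n_traced=len(traces),
        n_generated=n_molecules,
        traces=traces,
    )


@dataclass
class ContourRecovery:
    mean_nm: float
    sd_nm: float
    true_contour_nm: float
    n_traced: int
    n_generated: int
    traces: list[TraceResult]


def recover_contour_length(
    seed: int,
    n_molecules: int = 40,
    contour_nm: float = 328.0,
    lp_nm: float = 56.0,
    render: RenderParams | None = None,
) -> ContourRecovery:
    """Simulate linear molecules, trace them, and measure the mean contour."""
    spec = ConditionSpec(
        n_molecules=n_molecules,
        lp_nm=lp_nm,
        contour_nm=contour_nm,
        closed=False,
        render=render or RenderParams(),
    )
    pairs = make_condition_ensemble(spec, seed)
    traces = trace_ensemble([img for _, img in pairs])
    stats = contour_length_stats(traces)
    return ContourRecovery(
        mean_nm=stats.mean_nm,
        sd_nm=stats.sd_nm,
        true_contour_nm=pairs[0][0].true_contour,
        n_traced=len(traces),
        n_generated=n_molecules,
        traces=traces,
    )


@dataclass
class TopologyBenchmark:
    n_molecules: int
    n_correct: int
    agreement: float
    axis_measured_nm: list[float]
    axis_true_nm: list[float]
    per_class: dict[str, int]


def _first_region(img: AFMImage, min_len_nm: float):
    regions = segment_molecules(img, min_len_nm=min_len_nm)
    return regions[0] if len(regions) == 1 else None


def topology_benchmark(seed: int, n_each: int = 10) -> TopologyBenchmark:
    """Labelled synthetic topology suite: linear, open circle, plectoneme, compact.

    Generates ``n_each`` cleanly segmentable molecules per class (molecules
    whose rendered strands overlap are resampled, mirroring the exclusion
    of overlapping molecules from analysis), classifies each image, and
    measures the superhelical axis of every plectoneme.
    """
    render = RenderParams()
    single = render.blurred_peak_nm
    labelled: list[tuple[str, AFMImage, float | None]] = []

    class_ids = {"linear": 1, "open_circle": 2, "plectoneme": 3, "compact": 4}

    def _collect(truth: str, maker, min_len_nm: float = 50.0) -> None:
        count, attempt = 0, 0
        while count < n_each:
            img, axis_true = maker(derive_seed(seed, class_ids[truth], attempt))
            attempt += 1
            if attempt > 40 * n_each:
                raise AfmWlcError(f"could not build {n_each} {truth} molecules")
            region = _first_region(img, min_len_nm)
            if region is None or region.class_hint == "reject":
                continue
            labelled.append((truth, img, axis_true))
            count += 1

    def _one_chain(closed: bool, contour: float):
        def maker(s: int):
            spec = ConditionSpec(
                n_molecules=1, contour_nm=contour, closed=closed, render=render
            )
            pairs = make_condition_ensemble(spec, s)
            return pairs[0][1], None
        return maker

    _collect("linear", _one_chain(False, 328.0))
    _collect("open_circle", _one_chain(True, 856.0))

    def plect_maker(s: int):
        rng = np.random.default_rng(s)
        ratio = float(rng.uniform(0.35, 0.48))
        truth, img = generate_plectoneme(860.0, ratio, s, params=render)
        return img, truth.axis_nm

    _collect("plectoneme", plect_maker)
    _collect(
        "compact",
        lambda s: (generate_compact(s, params=render), None),
        min_len_nm=15.0,
    )

    n_correct = 0
    per_class: dict[str, int] = {}
    axis_measured, axis_true_list = [], []
    for truth, img, axis_true in labelled:
        region = _first_region(img, 15.0 if truth == "compact" else 50.0)
        rep = classify_topology(img, region, single_strand_height_nm=single)
        per_class[rep.mol_class] = per_class.get(rep.mol_class, 0) + 1
        if rep.mol_class == truth:
            n_correct += 1
        if truth == "plectoneme" and rep.mol_class == "plectoneme":
            axis_measured.append(measure_superhelical_axis(img, region))
            axis_true_list.append(axis_true)
    return TopologyBenchmark(
        n_molecules=len(labelled),
        n_correct=n_correct,
        agreement=n_correct / len(labelled),
        axis_measured_nm=axis_measured,
        axis_true_nm=axis_true_list,
        per_class=per_class,
    )
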