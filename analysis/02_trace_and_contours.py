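#!/usr/bin/env python
"""Trace the simulated conditions and compare contour lengths.

Reads the images written by 01_simulate_conditions.py, traces every
analyzable molecule at an 8 nm step, and reports per-condition contour
statistics plus the percent contour change of the coated condition
against bare DNA (the filament-extension signature; ~6% when the coated
truth is 347 nm vs 328 nm).  Also measures filament heights.  Writes
results/contours.json and per-condition trace CSVs.
"""

import argparse
import json
from pathlib import Path

from afmwlc.errors import AfmWlcError
from afmwlc.image import AFMImage
from afmwlc.experiments import trace_ensemble
from afmwlc.tracing import height_profile, write_traces_csv
from afmwlc.wlc_statistics import contour_length_stats, percent_change


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    report: dict = {}
    for label in ("bare_linear", "coated_linear"):
        image_dir = args.sim / label / "images"
        images = [AFMImage.from_tiff(p) for p in sorted(image_dir.glob("*.tif"))]
        traces = trace_ensemble(images)
        write_traces_csv(traces, args.out / f"traces_{label}.csv")
        stats = contour_length_stats(traces)
        heights = []
        for tr in traces:
            try:
                mean_h, _, _ = height_profile(
                    images[tr.image_index], tr, 50, seed=args.seed + tr.molecule_id
                )
            except AfmWlcError:
                continue
            heights.append(mean_h)
        report[label] = {
            "n_traced": len(traces),
            "contour_mean_nm": round(stats.mean_nm, 1),
            "contour_sd_nm": round(stats.sd_nm, 1),
            "height_mean_nm": round(sum(heights) / len(heights), 3),
        }
    report["contour_change_percent"] = round(
        percent_change(
            report["coated_linear"]["contour_mean_nm"],
            report["bare_linear"]["contour_mean_nm"],
        ),
        2,
    )
    (args.out / "contours.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
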