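#!/usr/bin/env python
"""Persistence-length calibration on closed plasmid-scale chains.

Runs the full recovery experiment: 30 closed 2D worm-like chains
generated at Lp 56 nm (contour 856 nm), rendered, traced at 8 nm, pooled
into a tangent-tangent correlation curve and fitted with the
2D-equilibrated decay exp(-L/(2 Lp)) over 8-120 nm.  Also reports the
bending-angle spread at 10 nm separation and a molecule-level bootstrap
interval.  Writes results/persistence_length.json and the correlation
curve CSV; with matplotlib available, a curve+fit figure.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from afmwlc.experiments import recover_persistence_length
from afmwlc.wlc_statistics import (
    bending_angle_distribution,
    bootstrap_lp,
    tangent_correlation,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rec = recover_persistence_length(seed=args.seed)
    curve = tangent_correlation(rec.traces, 120.0)
    bend = bending_angle_distribution(rec.traces, 10.0)
    lp_point, ci = bootstrap_lp(rec.traces, n_boot=100, fit_range=(8.0, 120.0),
                                seed=args.seed)
    report = {
        "true_lp_nm": rec.true_lp_nm,
        "fitted_lp_nm": round(rec.fit_lp_nm, 2),
        "bootstrap_ci_nm": [round(ci[0], 2), round(ci[1], 2)],
        "n_traced": rec.n_traced,
        "n_generated": rec.n_generated,
        # measured on 10 nm chord tangents of the traced contours; chord
        # averaging keeps this below the instantaneous-tangent value
        # sqrt(L/Lp) (see docs/methods.md)
        "bend_sd_rad_at_10nm": round(float(bend.angles.std(ddof=1)), 4),
    }
    (args.out / "persistence_length.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame({
        "separation_nm": curve.separations,
        "mean_corr": curve.mean_corr,
        "n_pairs": curve.n_pairs,
        "se": curve.se,
    }).to_csv(args.out / "correlation_curve.csv", index=False, float_format="%.6f")
    print(json.dumps(report, indent=2))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(curve.separations, curve.mean_corr, yerr=curve.se, fmt="o",
                    ms=4, label="pooled traces")
        xs = np.linspace(0, 120, 200)
        ax.plot(xs, np.exp(-xs / (2 * rec.fit_lp_nm)), "r-",
                label=f"fit: Lp = {rec.fit_lp_nm:.1f} nm")
        ax.set_xlabel("separation L (nm)")
        ax.set_ylabel(r"$\langle\cos\theta(L)\rangle$")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.out / "correlation_fit.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
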