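# afmwlc

Contour analysis of DNA and DNA–protein complexes in AFM height images:
worm-like-chain tracing, persistence-length estimation, bending-angle and
contour-length statistics, and supercoiling topology — with a synthetic
AFM image generator so the whole pipeline can be exercised, calibrated and
tested without instrument data.

## Who this is for

Single-molecule groups that image DNA (or nucleoprotein filaments) on mica
and want reproducible, scriptable answers to the standard questions: how
stiff is the molecule (persistence length), how long is it (contour
length), how high is it (bare vs protein-coated), and what topology does a
closed circle adopt (open circle vs interwound plectoneme vs compacted
particle).

## The model

Molecules equilibrated in two dimensions on a surface behave as 2D
worm-like chains: the tangent direction θ(s) along the contour performs
Gaussian bending fluctuations, and the tangent–tangent correlation decays
as

    ⟨cos θ(s, s+L)⟩ = exp( −L / (2 Lp) )

where Lp is the persistence length (the factor 2 is specific to chains
equilibrated in 2D).  The pipeline measures this correlation on traced
centerlines resampled at a fixed arc step (8 nm, half the apparent
cross-sectional diameter) and fits the exponential for Lp.

For closed circular DNA the package also keeps the topological books:
White's relation ΔLk = ΔTw + Wr.  Protein binding that unwinds the duplex
lowers the twist; in a covalently closed circle the linking number cannot
change, so the deficit reappears as writhe — the molecule supercoils into
a plectoneme whose superhelical-axis length is measured from the image
skeleton.

## Worked example

The numbered drivers under `analysis/` reproduce the package's synthetic
study end to end and write their tables under `results/`:

```bash
python analysis/01_simulate_conditions.py --seed 1   # render the conditions
python analysis/02_trace_and_contours.py  --seed 1   # trace + contour stats
python analysis/03_persistence_length.py  --seed 1   # correlation + Lp fit
python analysis/04_topology_supercoiling.py --seed 3 # topology + linking
```

With seed 1, step 2 prints (abridged):

```json
{
  "bare_linear":   {"n_traced": 37, "contour_mean_nm": 322.2, "height_mean_nm": 0.501},
  "coated_linear": {"n_traced": 38, "contour_mean_nm": 341.0, "height_mean_nm": 0.828},
  "contour_change_percent": 5.83
}
```

— 40 linear molecules generated at a true contour of 328 nm trace back to
322 nm (−1.8%); the "coated" condition (generated 6% longer and rendered
higher, emulating a nucleoprotein filament) shows the ~6% contour increase
and the elevated height.  Step 3 fits the persistence length on 30 closed
plasmid-scale chains generated at Lp = 56 nm:

```json
{"true_lp_nm": 56.0, "fitted_lp_nm": 59.88, "bootstrap_ci_nm": [53.97, 67.08], "n_traced": 21}
```

The fit recovers the generator value within its bootstrap interval (see
`docs/methods.md` for the small systematic stiffening every
segment-tangent estimator carries).  Step 4 classifies a 40-molecule
labelled suite (10 each: linear, open circle, plectoneme, compact) with
100% agreement, measures plectoneme superhelical axes within 8% of
construction truth, and prints the worked plasmid arithmetic — a 360 nm
axis over an 860 nm contour gives ratio 0.42 — plus the unwinding
bookkeeping (full occupancy of 1000 bp at +0.02 nm rise per covered bp:
ΔTw = −3.7 turns, Wr = +3.7 turns, contour extension 5.9%).

A `click` CLI exposes the same stages (`afmwlc simulate / trace / analyze
/ topology / linking / run`) driven by a YAML config with a single master
seed; reruns are byte-identical.

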