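# gingrec

Automated, curvature-based measurement of gingival recession on bucco-oral
tooth cross-sections, plus the observer-agreement statistics used to evaluate
manual measurements against the automated reference.

The pipeline mirrors the digital workflow of a 3D inspection setup:

1. **mesh** — read dental arch meshes (binary/ASCII STL, mm units), optionally
   refine them, express them in a per-tooth frame (z = long axis,
   x = mesio-distal, +y = buccal), and slice with a plane normal to x to get an
   ordered coronal→apical cross-section polyline of the buccal profile.
2. **curve** — fit a chord-length cubic spline, resample at a uniform 0.01 mm
   arc-length step, and compute signed curvature from analytic spline
   derivatives (convex surface positive, concave negative). Curvature-comb
   geometry can be exported as CSV/SVG.
3. **landmarks** — recognise the cemento-enamel junction (CEJ) as the first
   qualifying convex→concave transition scanning coronal→apical and the
   gingival margin (GM) as the first such transition scanning apico-coronally;
   each landmark is the sample of greatest concavity in its concave run.
4. **measurement** — recession depth as the in-plane CEJ–GM distance; signed
   arc-length deviation of manual picks from the automated reference
   (+ coronal / − apical); long-format batch tables.
5. **agreement** — ICC (two-way random, absolute agreement, single measures,
   F-based CI), Bland–Altman bias and 95% limits of agreement with CIs,
   one-sample t-tests with Bonferroni (configurable) adjustment, and
   curvature-threshold stratification of pick deviations.
6. **synthetic** — G1 arc-chain profiles with exact analytic curvature, known
   CEJ/GM ground truth and exact recession depth; cohort generator with
   LogNormal parameter distributions; a curvature-dependent examiner model
   (flatter landmark ⇒ noisier pick) for mechanism studies.

## CLI

```bash
gingrec defaults                                   # print default config
gingrec section   --config sites.yaml --out out/   # STL -> polyline CSVs
gingrec curvature --polyline out/site1.csv         # curvature + comb export
gingrec measure   --config cfg.json --polyline-dir out/ [--picks picks.csv]
gingrec simulate  --n 60 --seed 1 --out synth/     # synthetic cohort + picks
gingrec agree     --measurements out/measurements.csv --deviations out/deviations.csv
```

A site config is YAML/JSON: `sites: {site_id: {mesh: path.stl, plane_x_offset: 0.0,
frame: {origin: [...], x_axis: [...], y_axis: [...], z_axis: [...]}}}`.
Exit codes: 0 success, 2 partial (some sites flagged), 1 hard failure.

## Notes

- All coordinates are millimetres; curvature is mm⁻¹.
- Landmarks are reported at the 0.01 mm sample grid; no sub-sample
  interpolation. Values are stored at full precision and rounded to 0.01 mm
  only for display/CSV.
- Detection gates (minimum transition run length 0.05 mm, minimum concave
  prominence 0.1 mm⁻¹) are configurable; detection reports list all candidate
  segments so failures are inspectable.
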