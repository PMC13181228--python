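# glycoquant

Quantification of clickable, UV-crosslinkable monosaccharide probe
fluorescence in cultured cells — the image- and gel-analysis half of a
metabolic labeling experiment. Cells are fed an alkyne/diazirine-bearing
N-acetylsaccharide, crosslinked (+UV) or not (−UV), fixed, click-labeled
with a fluorophore, and imaged alongside DAPI, a plasma-membrane marker,
and optionally an antibody marking a nuclear subcompartment (nucleolar
dense fibrillar component, nuclear speckles, or H3K9me3 heterochromatin).
`glycoquant` turns those images into per-cell, per-compartment intensity
statistics, subnuclear enrichment folds, and SDS-PAGE incorporation
ratios — and ships a synthetic scene generator with complete ground truth
so every stage is validated by parameter recovery.

## What it computes

- **Three-compartment segmentation.** Nuclei from DAPI (smooth → Otsu →
  fill holes → area filter → distance-transform watershed); cells by a
  seeded watershed on the membrane marker treated as a ridge landscape;
  each cell partitioned exactly into a plasma-membrane band
  (boundary distance ≤ *w*), cytoplasm, and nucleus.
- **Per-cell intensities.** Mean (and integrated) probe intensity per
  compartment, scalar background from untreated control fields subtracted,
  grouped summaries (n, mean, SD with n−1 denominator, SE), piecewise-linear
  uptake time courses, one-sided pooled-variance Student's t-tests.
- **Subnuclear enrichment.** Per nucleus, the marker channel is Otsu-
  thresholded within that nucleus; enrichment is

  *fold = mean(probe | compartment) / mean(probe | remaining nucleoplasm)*

  on background-corrected intensities, averaged across nuclei, with a
  two-sided Mann–Whitney U test (exact null when n₁·n₂ ≤ 400 and no ties,
  tie-corrected normal approximation with continuity correction otherwise).
- **Gel densitometry.** Lane detection from the column-sum profile, per-lane
  baseline (median of the top/bottom 5% migration windows), and the
  incorporation efficiency S(−UV)/S(+UV) computed per replicate pair —
  −UV retains only covalently bound probe, so this ratio estimates the
  covalently incorporated fraction.
- **Synthetic ground truth.** Fields of non-overlapping elliptical cells
  with nuclei, membrane bands, subnuclear foci or rim bands at configured
  enrichment folds, linear-in-time uptake, Poisson + Gaussian camera noise,
  and multi-lane gels with known integrated signals.

## Worked example

```python
import glycoquant as gq
from glycoquant import subnuclear as sn

spec = gq.FieldSpec(seed=3)                    # 9 cells, DFC fold 1.39, SNR ~ 20
scene = gq.generate_scene(spec)                # +UV, 360 min labeling
masks = gq.segment_field(scene.channels)

records = gq.measure_compartments(scene.channels["probe"], masks)
for s in gq.summarize_conditions(records, grouping=("compartment",)):
    print(f"{s.group['compartment']:>10}: {s.mean:7.2f} ± {s.sd:.2f} AU (n={s.n_cells} cells)")

sub = sn.segment_subcompartment(scene.channels["marker"], masks.nucleus_labels, "DFC")
recs = sn.compute_enrichment(scene.channels["probe"], sub, background=2.0)
summary = sn.summarize_enrichment(recs)
print(f"DFC enrichment: {summary.mean_fold:.3f} ± {summary.se_fold:.3f} fold (n={summary.n_nuclei} nuclei)")
```

prints

```
 cytoplasm:   58.79 ± 0.48 AU (n=9 cells)
   nucleus:  108.84 ± 1.57 AU (n=9 cells)
        pm:   19.95 ± 0.20 AU (n=9 cells)
whole_cell:   59.19 ± 0.99 AU (n=9 cells)
DFC enrichment: 1.392 ± 0.002 fold (n=9 nuclei)
```

The nuclear mean exceeds the cytoplasmic and membrane-band means (the
generator's configured ordering), and the estimated nucleolar enrichment
recovers the configured 1.39-fold to within its standard error. The same
stages are available from the shell: `glycoquant simulate | segment |
quantify | enrich | gel | run-all` (see `glycoquant --help`).

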