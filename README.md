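# cortexflat

Quantification of cortical lesions on an unfolded (flat) map of the mouse
cerebral cortex.

In experimental traumatic brain injury (TBI) work — e.g. the lateral
fluid-percussion model — the location and extent of the cortical lesion are
measured slice by slice on histological sections or MRI, then related to the
cytoarchitectonic cortical areas to link damage to functional outcome.
`cortexflat` automates that translation: it takes per-slice along-surface
distance measurements, maps them onto a 2D unfolded-cortex template, closes
them into a lesion polygon, and reports how much of each cortical region
(and of the whole cortex) is damaged, in mm² and percent — including
time-series input for lesion evolution.

## The method

Each coronal slice contributes four numbers (all in millimetres):

* **MB** — bregma-relative anteroposterior (AP) coordinate of the slice;
* **M1** — medial reference point → medial lesion edge, along the pial
  surface;
* **M2** — medial lesion edge → lateral lesion edge;
* **M3** — lateral lesion edge → rhinal fissure. When the lesion extends
  lateral to the fissure, M2 is measured up to the fissure and M3 is entered
  as a *negative* fissure → lateral-edge distance.

Mapping proceeds in four steps:

1. **Normalization** (per slice). The measured inter-reference distance
   D = M1 + M2 + M3 (or M1 + M2 when M3 < 0) is compared with the atlas
   reference surface length L(MB) at that AP level, and M2, M3 are rescaled
   by the shrinkage-correction ratio ρ = L(MB)/D. M1 is dropped — the two
   lateral distances suffice once the rhinal fissure anchors the lesion.
2. **Translation**. With the template's units-per-millimetre constant r,
   a slice lands at y = ap₀ − r·MB; its lateral lesion edge at
   x = rh(y) − r·M3′ (rh = rhinal fissure position) and its medial edge a
   further r·M2′ medially.
3. **Interpolation**. The per-slice edges are closed anticlockwise into one
   polygon (medial edge by ascending MB, lateral edge descending), either
   linearly or densified with a centripetal Catmull-Rom spline.
4. **Quantification**. The lesion polygon is intersected (polygon Boolean
   operations) with every labeled region A of the template:
   area(lesion ∩ A)/r² in mm², 100·area(lesion ∩ A)/area(A) in percent, and
   the cortex total over the union of all regions.

Templates are plain SVG files (regions = closed paths labeled `A_<name>`,
plus `rhinal_fissure`, `ap_zero` and `units_per_mm` conventions; cubic
Beziers are flattened with de Casteljau subdivision) together with a JSON
file of per-plate atlas reference lengths. A seeded synthetic-template
generator is included, so everything below runs without downloads; a
published template SVG can be supplied instead.

## Worked example

```python
import numpy as np
import cortexflat as cf

svg, atlas = cf.generate_synthetic_template(16, seed=1)
t = cf.parse_template(svg, atlas)

# a 2.4 mm-wide lesion measured every 0.2 mm from MB -2.0 to -0.2,
# with M3 chosen so that M1+M2+M3 equals the atlas length (no shrinkage)
rows = []
for mb in np.arange(-2.0, -0.19, 0.2):
    L = cf.atlas_length_at(t.atlas_lengths, mb)
    rows.append(f"{mb:.1f},1.8,2.4,{L - 1.8 - 2.4:.4f}")

ms = cf.read_measurements("\n".join(rows))
q = cf.quantify(cf.map_lesion(ms, t), t)
print(cf.results_csv(q))
```

prints

```
day,region,area_mm2,percent
1,R04,0.13,3.28
1,R05,1.36,33.33
1,R06,0.14,3.39
1,R08,0.23,5.52
1,R09,2.24,54.90
1,R10,0.22,5.46
1,TOTAL,4.32,6.62
```

i.e. the lesion — 2.4 mm wide over the 1.8 mm AP extent of the slices —
covers exactly 2.4 × 1.8 = 4.32 mm² (the normalization ratio is 1 here),
concentrated in the two regions under its footprint (R05, R09), and amounts
to 6.62 % of the whole cortex.

The same pipeline is available from the shell, for one file or a folder of
files:

```sh
cortexflat --input measurements.csv --out-dir out/            # synthetic template
cortexflat --input-dir cases/ --template ufm.svg \
           --atlas-lengths lengths.json --interp spline --resolution 10
```

Each input yields `results.csv`, `map.tiff`, `map.pdf` and `bundle.zip`
(plus `series.csv`, `chart.png` and PNG transition frames for multi-day
files, whose day is given in an optional fifth column).

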