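# mitoquant

Quantification pipelines for fluorescence-microscopy assays of
mitochondrial quality control, plus mito-stress-test respirometry.

Studies of mitophagy in cultured cells (e.g. patient-derived fibroblasts
with OXPHOS deficiencies) rely on a recurring set of image quantifications
that are usually performed interactively in commercial software:

- **mitolysosome counting and mitophagy flux** with the tandem
  mCherry–GFP reporter: GFP is quenched in acidic lysosomes, so
  mitochondria delivered to lysosomes appear as red-only puncta; flux is
  the ratio of mean per-cell counts with vs. without lysosomal protease
  inhibitors (leupeptin/pepstatin A);
- **depolarized-mitochondria classification** from TMRE (potential-
  sensitive) + MitoTracker Green (mass) staining: individualized
  mitochondria < 1 µm² whose TMRE falls below a background-derived cutoff
  (mean + 3·SD of non-mitochondrial pixels);
- **mitophagosome / contact counting**: vesicles touching (overlapping or
  8-adjacent to) a mitochondrial mask;
- **lysosome radial distribution**: vesicles beyond the 75th-percentile
  nucleus distance of a reference condition, per µm² of mitochondrial
  area;
- **nuclear translocation** of transcription factors/coactivators (PGC1α,
  ATF4) as mean nuclear immunofluorescence;
- **cristae density** as fluorescence peaks per µm along a STED line
  profile;
- **mito-stress-test parameters** from OCR traces
  (basal → oligomycin → FCCP → rotenone+antimycin A), all corrected for
  non-mitochondrial respiration, with the OXPHOS ATP production rate
  `atp_linked × 2 O/O₂ × P/O (2.75)`.

`mitoquant` implements these procedures as an open, deterministic,
seedable pipeline (projection → top-hat → Otsu → watershed → per-cell
statistics, with cell-by-cell segmentation, edge exclusion and
reporter-intensity gating), and ships a synthetic-data generator that
plants known ground truth for every assay so the whole chain is testable
without any microscope data.  Every derived threshold is written to a
JSON-lines provenance log.  See `docs/methods.md` for the full model.

## Worked example

Simulate paired reporter fields with a true flux ratio of 2 and run the
counting pipeline:

```python
from mitoquant.synthetic import FieldParams, generate_mitoqc_pair
from mitoquant import pipelines as pl

params = FieldParams()            # 16 cells/field, 0.3 um/px, high SNR
minus, plus = [], []
for i in range(8):
    m, p, truth = generate_mitoqc_pair(params, flux_ratio=2.0, seed=i)
    minus.append(m); plus.append(p)

res = pl.mitoqc_flux(minus, plus)
print(f"mean -LEUP {res.mean_minus:.2f}  mean +LEUP {res.mean_plus:.2f}  "
      f"flux {res.flux_ratio:.2f}  (n={res.n_minus}/{res.n_plus} cells)")
```

```
mean -LEUP 6.15  mean +LEUP 12.14  flux 1.97  (n=96/96 cells)
```

Read: without inhibitors the cells average ~6 mitolysosomes, with
degradation blocked they accumulate ~12, so the estimated mitophagy flux
is ~2 — the planted value.  The same pipelines are available from the
shell:

```sh
mitoquant simulate --scenario scenario.yaml --out fields/
mitoquant analyze  --assay mitoqc_flux --config analysis.yaml --out results/
```

where the scenario/config are YAML (assay name, channel-role map, pixel
size, pipeline parameters; unknown keys are rejected).  `analyze` writes
`per_cell.csv`, `summary.csv` and `provenance.jsonl`, skips unreadable
fields with a count, and signals partial success with exit status 3.

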