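# Bundled reference tables

- `random_coil.csv` — residue-type-specific random-coil chemical shifts
  (ppm) for backbone CA/CB/CO. Values are the widely used peptide-derived
  random-coil set from the standard literature compilations (refDB-style
  values, rounded to 0.1 ppm). Glycine has no CB entry.
- `structure_refs.csv` — expected secondary-shift deviations (observed minus
  random coil, ppm) for a fully formed alpha-helix (`helix_ppm`) and a fully
  formed beta-strand (`strand_ppm`). These are canonical average deviations
  (helix: CA +2.6..+3.0, CB -0.4, CO +1.7; strand: CA -1.4..-1.8, CB +2.2,
  CO -1.6) with mild residue-type modulation; they are a packaged convention
  for normalising secondary-structure propensities, not a measurement.

Both tables can be replaced by user-supplied CSVs with the same columns via
the corresponding function arguments.
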