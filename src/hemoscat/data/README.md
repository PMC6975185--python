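# Bundled chromophore table (synthetic)

`chromophores_synthetic.csv` — columns `wavelength_nm, eps_oxy, eps_deoxy,
mua_melanin`, 400–600 nm in 1 nm steps.

This table is **synthetic**: an analytic spectral model, not a published
compiled measurement. It is generated by
`scripts/make_chromophore_table.py` (see that file for the exact model) and
is designed to have:

- oxy/deoxy molar extinction (cm⁻¹/M) with a Soret band near 424 nm
  (~5×10⁵ cm⁻¹/M), a Q band near 556 nm (~5×10⁴ cm⁻¹/M) and realistic
  magnitudes elsewhere in 400–600 nm;
- isosbestic crossings at 422, 452, 501 and 584 nm, i.e. *near* the four
  imaging wavelengths 420/450/500/585 nm; at those four bands the
  oxy/deoxy relative mismatch is ≤ 7 % (the package asserts ≤ 10 % on
  load), while clearly non-isosbestic bands such as 560 nm differ by tens
  of percent;
- melanosome absorption as the standard power law
  μa = 6.6×10¹¹ · λ⁻³·³³ cm⁻¹ (λ in nm).

The whole-blood hemoglobin concentration used to convert blood volume
fraction to μa is 150 g/L ÷ 64 500 g/mol = 2.326 mM (tetramer convention);
it is a code constant in `hemoscat.tissue_optics`, not a table column.

All training, estimation and phantom generation in this package use this
single table, so the pipeline is self-consistent end to end.
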