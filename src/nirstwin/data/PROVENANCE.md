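# Packaged numeric tables

## optical_properties.csv

Absorption (`mua_mm`) and reduced scattering (`musp_mm`) coefficients in mm^-1
at 680 and 850 nm for an adult human forehead and for the ISS optical silicone
phantom, as characterized with a frequency-domain oximeter.  These anchor the
semi-infinite diffusion reflectance model and the optical-loss (OL) scale; the
phantom's 850-nm column is the default for OL-vs-SDS calculations.

## extinction_dpf.csv

Decadic specific extinction coefficients (mM^-1 cm^-1) of oxyhemoglobin,
deoxyhemoglobin, and the oxidized-minus-reduced cytochrome-c-oxidase
difference spectrum, together with differential pathlength factors (DPF,
dimensionless, adult head), at the instrument's measured LED peak wavelengths
774, 817, 865, and 892 nm.

The entries are representative values compiled from the widely used published
hemoglobin and oxCCO-difference tabulations (UCL Biomedical Optics compiled
spectra) and adult-head DPF measurements, read off at these four wavelengths.
They are suitable for simulation and algorithm validation; for quantitative
work on real recordings users can substitute their own tables via
`ExtinctionSystem` (values are plain CSV columns).

Unit conventions: extinction coefficients are decadic (base-10) and are
converted internally to ln-based muM^-1 mm^-1; concentrations are muM;
pathlengths mm.
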