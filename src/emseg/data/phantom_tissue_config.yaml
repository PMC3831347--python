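# Four-class tissue configuration matching the default synthetic phantom
# (air / CSF shell / GM shell / WM core).  Quantile bounds are fractions of
# the full-image histogram and are conservative: each class's intensity range
# stays inside its interval for noise levels up to ~9% of the WM mean.
# Orderings: T1 air < CSF < GM < WM; T2 air < WM < GM < CSF.
modalities: [T1, T2]
tissues:
  - {name: Air, super_class: Background, weight: 1, bias: false, quantiles: {T1: [0, 0.85],   T2: [0, 0.75]}}
  - {name: Csf, super_class: CSF,        weight: 1, bias: true,  quantiles: {T1: [0.05, 0.93], T2: [0.8, 1]}}
  - {name: Gm,  super_class: GM,         weight: 1, bias: true,  quantiles: {T1: [0.78, 0.99], T2: [0.7, 0.9]}}
  - {name: Wm,  super_class: WM,         weight: 1, bias: true,  quantiles: {T1: [0.88, 1],   T2: [0.6, 0.8]}}
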