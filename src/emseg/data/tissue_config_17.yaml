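# Default extended tissue configuration: 17 classes (12 biological + 5
# background / "Not-" nuisance classes).  Quantile bounds are per-modality
# fractions of the masked image histogram; "bias" marks classes whose
# posteriors drive bias-field estimation.
modalities: [T1, T2]
tissues:
  - {name: Accumben,    super_class: GM,         weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Caudate,     super_class: GM,         weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Crbl Gm,     super_class: GM,         weight: 1,   bias: true,  quantiles: {T1: [0.03, 0.9],  T2: [0.02, 0.99]}}
  - {name: Hippocampus, super_class: GM,         weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Putamen,     super_class: GM,         weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Surf Gm,     super_class: GM,         weight: 1,   bias: true,  quantiles: {T1: [0.04, 0.75], T2: [0.25, 0.96]}}
  - {name: Wm,          super_class: WM,         weight: 1,   bias: true,  quantiles: {T1: [0.5, 1],     T2: [0.05, 0.7]}}
  - {name: Crbl Wm,     super_class: WM,         weight: 1.5, bias: true,  quantiles: {T1: [0.1, 1],     T2: [0.03, 0.9]}}
  - {name: Csf,         super_class: CSF,        weight: 1,   bias: true,  quantiles: {T1: [0, 0.6],     T2: [0.2, 1]}}
  - {name: Thalamus,    super_class: WM&GM,      weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Globus,      super_class: WM&GM,      weight: 1,   bias: false, quantiles: {T1: [0.05, 0.95], T2: [0.15, 0.97]}}
  - {name: Vb,          super_class: VB,         weight: 1,   bias: false, quantiles: {T1: [0.04, 0.75], T2: [0, 0.2]}}
  - {name: Not Csf,     super_class: Background, weight: 1,   bias: false, quantiles: {T1: [0, 0.6],     T2: [0.2, 1]}}
  - {name: Not Gm,      super_class: Background, weight: 1,   bias: false, quantiles: {T1: [0.15, 0.9],  T2: [0.35, 1]}}
  - {name: Not Vb,      super_class: Background, weight: 1,   bias: false, quantiles: {T1: [0.15, 0.9],  T2: [0, 0.3]}}
  - {name: Not Wm,      super_class: Background, weight: 1,   bias: false, quantiles: {T1: [0.4, 1],     T2: [0.1, 0.85]}}
  - {name: Air,         super_class: Background, weight: 1,   bias: false, quantiles: {T1: [0, 0.1],     T2: [0, 0.1]}}
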