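# statescope

Conformational-state analysis of SH2-domain ensembles, and validation of
those ensembles against NMR residual dipolar couplings (RDCs).

## The scientific problem

The N-terminal SH2 domain (N-SH2) of the tyrosine phosphatase SHP2 keeps
the enzyme autoinhibited until a phosphopeptide binds.  Which
conformation the free domain adopts in solution — and which structural
feature (binding-cleft opening vs central β-sheet "unzipping") actually
drives activation — cannot be settled from crystal structures alone,
because crystal packing biases the flexible loops.  Two complementary
tools address this:

1. **Structure descriptors and state classification.**  Four diagnostic
   distances summarise the domain's functional geometry (author
   numbering of SHP2 N-SH2):

   | descriptor | atoms | closed → open |
   |---|---|---|
   | pY loop opening | Lys35 Cα – Thr42 Cα | ~9 → ~11 Å |
   | β-sheet spread | Gly39 C – Asn58 N | ~4 → ~12 Å |
   | binding-cleft opening | Gly67 Cα – Lys89 Cα | ~5 → ~14 Å |
   | +5 site opening | Tyr66 Cα – Leu88 Cα | ~7 → ~12 Å |

   For collective motions, PCA of the superposed Cα coordinates yields a
   dominant mode **v**; restricting the motion along **v** to the pY-site
   residues (Ser34–Phe41) and the +5-site residues (Gln57–Glu97) gives two
   unit *subvectors* that span the **essential plane**.  Projections onto
   that plane classify every structure into one of four states: α
   (pY closed / +5 closed), β (open/open), γ (closed/open), δ
   (open/closed), with the sign convention that a positive projection
   means a closed site.  A survey module screens whole sets of SH2
   structures against a reference domain, excluding entries whose pY loop
   length differs from the reference's eight residues or whose backbone is
   incomplete, and stratifies the remaining observations by experimental
   method (X-ray vs NMR).

2. **Ensemble-vs-experiment scoring via RDCs.**  An RDC measures the
   orientation of an internuclear vector **u** relative to the molecular
   alignment frame,

   D = D_max · **u**ᵀ **S** **u**,

   where **S** is the symmetric, traceless Saupe order matrix (5
   independent elements) and D_max ∝ γᵢγⱼ/r³ is the static dipolar
   constant.  Given measured couplings and a structural ensemble, the
   single best-fitting tensor is obtained by linear least squares (SVD)
   over **frame-averaged** orientational coefficients, so all members of
   the ensemble are fitted simultaneously and yield one tensor plus an
   ensemble-averaged set of back-calculated RDCs.  Agreement is scored by
   the Pearson correlation r, the Q factor rms(residual)/rms(observed),
   and per-residue outlier flags.

Everything is testable without any external downloads: a synthetic-data
module generates a deterministic toy fold (a genuine three-strand
antiparallel β-sheet plus an α-helix), two-state conformational ensembles
with known labels, and RDC datasets from a known alignment tensor.

## Worked example

Classify a two-state synthetic ensemble and refit a known alignment
tensor from noisy synthetic couplings:

```python
import numpy as np
from statescope.synthetic_data import (make_endpoint_pair, make_two_state_ensemble,
                                       TwoStateSpec, make_synthetic_rdcs, RDCSimSpec)
from statescope.ensemble_io import Ensemble
from statescope.superposition import superpose_ensemble
from statescope.conformational_states import (fit_pca, extract_subvectors,
                                              essential_plane, classify_state)
from statescope.rdc_analysis import svd_fit

alpha, beta, lay = make_endpoint_pair()
ens, labels = make_two_state_ensemble(TwoStateSpec(alpha, beta, n_frames=200, seed=2024))
fitted = superpose_ensemble(ens, beta, lay.core_range)
model = fit_pca(fitted, lay.full_range)
alpha_fit = superpose_ensemble(Ensemble([alpha]), beta, lay.core_range).frames[0]
subs = extract_subvectors(model, fitted, lay.py_loop_range, lay.plus5_range,
                          closed_reference=alpha_fit)
states = [classify_state(p) for p in essential_plane(fitted, subs, model)]

records, truth = make_synthetic_rdcs(ens, RDCSimSpec(noise_sd=0.5,
                                     coupling_types=("H-N",), seed=2024))
fit = svd_fit(ens, records, max_structures=100, seed=2024)
```

This prints (values from an actual run):

```
mode-1 variance fraction: 0.570
state counts: alpha=99, beta=101
label recovery: 100.0%
RDC fit over 63 H-N couplings, 100 structures: r = 0.9794, Q = 0.2011
Saupe magnitude: fitted 8.154e-04 (true 8.095e-04)
```

The first PCA mode carries 57% of the coordinate variance (the two-state
transition); every frame lands in the generating quadrant of the
essential plane; and the tensor refit from couplings carrying 0.5 Hz of
noise recovers the generating alignment magnitude to better than 1%.

A `statescope` console script exposes the same machinery from the shell
(`statescope distances`, `superpose`, `pca`, `classify`, `rdc-fit`,
`survey`, `simulate ensemble|rdc`, `convert`); run `statescope --help`.

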