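# sigquant

Ordinal information-theory quantifiers for *quasi-offline* handwritten-signature
classification and verification.

A signature captured on a digitizing tablet is a pair of discrete-time
coordinate series (x_t, y_t).  `sigquant` characterizes each signature by six
numbers derived from the Bandt–Pompe ordinal symbolization of those two series,
and builds three analyses on top of them: a typology of signature styles
(dendrograms), per-writer stability indices, and one-class verification of
genuine vs. skilled-forgery signatures.  No pressure, pen-angle or image data
is used — only the time ordering of the coordinates.

## The method

Each trajectory is rescaled into the unit square and expanded to M = 5000
samples with a shape-preserving cubic Hermite interpolant.  Sliding windows of
D = 5 samples (lag τ = 1) are mapped to the permutation that sorts them
ascending; histogramming the D! = 120 patterns gives the ordinal distribution
P.  Three quantifiers summarize P (natural logs; N = D!):

- **Normalized permutation entropy** H[P] = −Σᵢ pᵢ ln pᵢ / ln N
- **MPR statistical complexity** C[P] = Q_J[P, P_e] · H[P], where
  Q_J = J[P, P_e]/J_max is the normalized Jensen–Shannon disequilibrium from
  the uniform distribution P_e
- **Fisher information measure** F[P] = F₀ Σᵢ (√pᵢ₊₁ − √pᵢ)², with F₀ = 1 for
  a delta on an extreme bin and 1/2 otherwise (bins in frozen lexicographic
  pattern order)

One value of each per coordinate yields the feature vector
(H_X, H_Y, C_X, C_Y, F_X, F_Y) ∈ [0,1]⁶.  Downstream:

- **Typology** — subjects are summarized by the mean and SD of their genuine
  features, clustered by hierarchical clustering and neighbor-joining
  (Euclidean/Manhattan/Chebyshev), and classifiable with a per-feature
  min–max box ("parallelepiped") rule.
- **Stability** — per writer, the global index η = √(S[P̄] − mean S[Pⱼ])
  (Jensen–Shannon) and the local index ξ = mean F[Pⱼ] − F[P̄] (Jensen–Fisher)
  over the genuine ensemble.
- **Verification** — a Gaussian-kernel one-class SVM
  (k(u,v) = exp(−‖u−v‖²/2σ²), σ² = 10) is trained on n genuine vectors per
  subject and scored on held-out genuine + all forgeries; performance is
  reported as ACC, AUC and EER over n = 5, 10, 14, 18, 22.

Licensed signature corpora cannot be redistributed, so the package ships a
synthetic cohort generator (`sigquant.synth`) that emulates the relevant
structure: per-subject stroke templates in three planted complexity classes,
genuine realizations with small reproduction jitter, and forgeries with larger
scatter, a smooth time warp and hand tremor.

## Worked example

```
$ python examples/ordinal_quantifiers.py
series: [4, 7, 9, 10, 6, 11, 3]
windows: 5, pattern bins: 6
pattern probabilities (lexicographic): [0.4 0.  0.2 0.  0.4 0. ]
H (normalized entropy)      = 0.5888
C (statistical complexity)  = 0.2900
F (Fisher information)      = 0.8000
```

The five length-3 windows of the series populate three of the six ordinal
patterns, giving entropy 1.0549/ln 6 ≈ 0.5888; the nonzero complexity marks
structure between perfect order and noise.

End to end on a 12-subject synthetic cohort:

```
$ python examples/verification_protocol.py
 n_train    acc    auc    eer  eer_pct
       5 0.6244 0.8417 0.2030  20.3000
      10 0.7500 0.8536 0.1893  18.9333
      14 0.7806 0.8565 0.1865  18.6485
      18 0.7672 0.8621 0.1764  17.6381
      22 0.7649 0.8793 0.1640  16.4000
```

AUC is high already with five training signatures and EER falls as the
training sample grows.  The other `examples/` scripts demonstrate feature
extraction, stability indices and the clustering typology; the `sigquant`
command-line tool exposes the same pipeline as subcommands
(`simulate`, `features`, `cluster`, `stability`, `verify`).

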