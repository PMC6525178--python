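# Methods

## Model and assumptions

Nuclei are spheres of fixed diameter *d* (μm); the microtome slab
occupies depths [0, *t*]; the depth *x* of a nucleus's lowest point
(measured downward from the slab's top face) is uniform on [0, *t* + *d*],
the full range over which a sphere intersects the slab. FISH signals are
independent points uniform in the nuclear volume. A nucleus is
enumerated when its largest in-slab cross-section (its microscopic image)
has diameter ≥ *c·d*. These assumptions idealise real tissue: nuclei are
often ellipsoidal with a spread of diameters, chromatin is organised
non-randomly (heterochromatin at the periphery), and nuclei can overlap
in thick sections; none of that is modelled in the closed forms.

Retained volume is the sphere minus the cap above the top face and the
cap below the bottom face,

    V(x) = cap(min(x, d)) − cap(clamp(x − t, 0, d)),
    cap(h) = π(d h²/2 − h³/3),

a single expression covering both thickness regimes (t ≥ d and t < d).
It is continuous, symmetric about (t + d)/2, and equals V₀ = πd³/6 only
for x ∈ [d, t]. The enumeration window [x₁, x₂] follows from chord
geometry: the image diameter equals *c·d* exactly at both window edges.

The mean retained volume V̄ is the integral of V(x) over the window
divided by the window width, evaluated with exact piecewise-quartic
antiderivatives (no numeric quadrature in the library; adaptive
quadrature is retained in the test suite as an independent oracle at
1e-10 relative tolerance). The signal-retention probability is
p = V̄/V₀.

## Count laws: mean-field binomial vs exact depth mixture

Two observed-count distributions are exposed, and the distinction
matters:

- `observed_pmf` — the **mean-field binomial** Binomial(N, p̄) with p̄
  averaged over the window. This is the convention behind all reference
  outputs this package reproduces (probability curves, the category
  grid, the correction table), and it is exact for the *mean* count.
- `depth_mixture_pmf` — the **exact marginal** under the stated physical
  assumptions: conditional on depth x the count is Binomial(N, V(x)/V₀),
  and the marginal mixes these over the uniform depth. Same mean N·p̄,
  but overdispersed: on a 2 μm section with N = 8 the mixture puts
  ≈ 33% of mass at n ≥ 6 where the mean-field binomial puts ≈ 17%
  (total-variation distance ≈ 0.33). The two converge as t ≫ d, where
  partial nuclei become an O(d/t) minority.

The Monte Carlo simulator follows the physical process and therefore
reproduces the mixture (TV ≈ 0.002 at 10⁵ nuclei), not the mean-field
binomial. Category probabilities and corrections in this package use the
mean-field binomial convention of the reference results; users studying
per-nucleus count *dispersion* (rather than means or slide-level
averages) should prefer the mixture, and should expect the mean-field
category probabilities to overstate certainty on thin sections.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| t (μm) | section thickness | — (required) | the variable under study; guidelines recommend 4–6 |
| d (μm) | nuclear diameter | 3.0 | reference value used by all headline tables; DAPI measurements of FFPE nuclei cluster near 3–3.4 |
| c | enumeration threshold | 0.8 | an image ≥ 80% of full diameter (≥ 64% of full area) is what scorers accept in practice |
| m | nuclei per slide | 20 | common scoring practice counts 20–60 nuclei; intervals scale as 1/√m |
| equivocal_low / positive_low | category cutoffs | 4.0 / 6.0 | guideline bins: n ≥ 6 positive, 4 ≤ n < 6 equivocal |
| ratio_positive | target/control cutoff | 2.0 | guideline ratio criterion |

Category cutoffs are applied to integer single-nucleus counts when
computing probabilities (positive ⇔ n ∈ {6, …, N}, equivocal ⇔
n ∈ {4, 5}); `mean_sampling_distribution` provides the slide-mean
alternative (exact m-fold convolution for m ≤ 30, normal approximation
above — exactness where cheap, stability where large). Deterministic
slide-level labels (`classify_observed`) additionally honour the ratio
criterion; the probability grid uses copy number alone, since the ratio
is thickness-invariant.

## Correction and intervals

The point correction is the exact ratio p(t_to)/p(t_from): linear in the
observed value, reciprocal and transitive by construction. The reference
correction grid is empirically linear with a constant per-column ratio,
confirming this construction; two cells of the printed grid differ from
the exact integral at the second decimal (e.g. 2.0 corrected 2→6 μm:
2.97 exact vs 2.95 printed), consistent with a coarser numeric grid in
the original computation. Serialized tables are rounded to 2 decimals
(round-half-to-even) at output only.

The 95% interval construction for corrected values is not uniquely
determined by the reference tables; this package uses the normal
approximation to the m-nucleus mean at the target thickness with
N̂ = n_obs/p(t_from): mean N̂·p(t_to), variance N̂·p(t_to)(1 − p(t_to))/m,
clipped at zero, default m = 20. An effective m ≈ 13 approximately
reproduces the printed reference intervals; that observation is recorded
here, not asserted anywhere.

## Monte Carlo simulator

Geometry: depths uniform on [0, t + d_i]; per-nucleus volume and image
fractions evaluated from the same closed forms the analytic model uses
(the randomness being validated is in the depths and signal placement).
Signals: radial position via the exact inverse CDF r = R·U^{1/3} and a
depth-direction cosine uniform on [−1, 1] — fixed draw-count transforms,
so streams stay aligned across configurations; a signal is counted iff
its depth lies in [0, t]. One `default_rng` stream per run with a
documented draw order (depths, diameters, target signals, control
signals); identical configs yield byte-identical TSV.

Diameter heterogeneity (truncated-normal diameters, resampling at ≤ 0)
is an exploratory sensitivity probe. Two honest caveats: intersecting
nuclei are sampled by drawing d_i first and then depth on [0, t + d_i],
without the size-biased intersection weight ∝ (t + d_i); and enumeration
compares each nucleus's image to its *own* diameter. Empirically, count
dispersion is essentially flat in the diameter sd at t = 4 μm (the extra
geometric variance is offset by small nuclei being retained more
completely), while the *mean* retention rises monotonically with the sd
at fixed mean diameter (a Jensen-type effect — p(t, d) is decreasing and
convex in d over this range); the test suite asserts the latter.

## Problem sizes and numerical choices

Validation simulations use 10⁵ nuclei (3σ gates on enumerated fraction
and retention; TV < 0.01 against the exact mixture), chosen so the whole
suite runs in seconds while keeping Monte Carlo error well below the
tested tolerances. Root finds (cap-height inversion, retained-volume
level sets) use bracketed Brent iteration at 1e-10; the
volume-at-least fraction uses the cap-height closed form for t ≥ d and a
symmetric level-set root-find for t < d, where no simple cap formula
holds, clipping the qualifying depth interval to the enumeration window.
Degenerate inputs: d = 0 gives zero volumes; c = 1 collapses the window
to [d/2, t + d/2]; p → 1 and all distributions degenerate as t → ∞.

## Known limitations

- Uniform-diameter spheres; no ellipsoids (heterogeneity only via the
  simulator's diameter distribution).
- No model of probe hybridisation efficiency, signal splitting or
  colocalised/overlapping signals; truncation is the only loss channel.
- The mean-field binomial convention understates per-nucleus count
  dispersion on thin sections (see above); slide-mean inference via
  `mean_sampling_distribution` inherits the same convention.
- Corrections assume the thin-section measurement is itself unbiased
  apart from truncation (no over-digestion or scoring drift).
- Passing the simulator-based tests shows internal consistency of the
  model, not fidelity to real tissue; the assumptions above are the
  boundary of what the validation can claim.
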