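# Methods

## Model and conventions

Complex permittivity is carried as `eps* = eps' − i eps''` with the loss
`eps''` stored positive everywhere.  Complex powers use the principal
branch, so `(i x)^a = x^a e^{i a π/2}` for `x > 0`; with `a = b = 1` the
Havriliak–Negami (HN) term reduces to the Debye form `Δeps/(1 + i f/f0)` to
machine precision.  The conductivity term `sigma0 / (eps0 (i 2πf)^n)` uses
the vacuum permittivity `eps0 = 8.8541878128e−12 F/m` as a global constant;
`sigma0` is carried in S/m, which makes `sigma0/eps0` dimensionally an
`(rad/s)^n` rate — the customary convention for the fractional-exponent
conductivity of disordered solids.  Frequencies are Hz throughout (never
rad/s); temperatures are kelvin internally, degrees Celsius at the I/O
boundary with offset 273.15.

Useful closed forms implemented and tested:

* loss-peak frequency of an isolated HN term,
  `f_max = f0 [sin(aπ/(2+2b)) / sin(abπ/(2+2b))]^{1/a}`;
* low-frequency tan δ plateau of a conductivity-dominated spectrum,
  `tan(nπ/2)` for `0 < n < 1` (divergent for ohmic `n = 1`);
* glass transition and fragility from VFT parameters (below).

The factor printed as "2.3" in the usual presentation of these formulas is
implemented as `ln 10 = 2.302585…`: recomputing a tabulated fragility of
235.7 from its own `(f_inf, B, T0)` triple only reproduces the printed value
with `ln 10` (2.3 gives 235.5).

## Two-stage isotherm fitting

The staged protocol mirrors how these measurements are analysed in
practice:

1. `eps_inf` is read off the coldest spectrum at the highest frequency
   (1 MHz), where all relaxations have decayed.
2. Spectra are fitted coldest-first.  In the cold window only the fastest
   process lives; as slower processes enter the 0.1 Hz–1 MHz window on
   heating they are added to the model per a user-supplied plan (process
   counts are inspection choices, never automated model selection).
3. When a fast process's peak leaves the window its relaxation frequency is
   pinned, isotherm by isotherm, to the extrapolation of a temperature law
   (Arrhenius or VFT, per configuration) fitted to its own
   lower-temperature free results; the provenance (`fixed:arrhenius`,
   `fixed:vft`) is recorded on every parameter, and pinned entries are
   excluded from later map-level law fits so no circularity can arise.

Optimization is bounded trust-region least squares (lmfit/`least_squares`),
with strengths, frequencies and conductivity on a log10 scale.  Default
bounds: `Δeps ∈ (1e−4, 1e4)`, `f0 ∈ (1e−6, 1e9) Hz`, `a, b ∈ (0.05, 1]`,
`n ∈ (0.05, 1]`, `log10 sigma0 ∈ (−20, 2)`.  Residuals are evaluated at the
measured frequencies in the linear scale of the fitted quantity (tan δ or
eps''), unweighted by default; a `relative` weighting (residual divided by
the datum) is available and is what the shipped preset plans use, since it
is the near-maximum-likelihood choice under multiplicative measurement
noise.

Initialization is by peak picking on the lightly smoothed fitted quantity:
detected maxima are handed, most prominent first, to the free-frequency
processes in their configured (fastest-first) order; the low-frequency
plateau gives the conductivity exponent via `n = (2/π) arctan(tan δ_lo)`
and the lowest-frequency loss gives `sigma0`.  Several start families are
tried — the previous isotherm's parameters (temperature continuation), the
pure data-driven guess, a "stacked" variant that places undetected
processes just below their faster neighbour (for merged peaks), and a
hybrid that keeps the slowest process below the window — plus seeded
jittered restarts.  The best residual norm wins, with two refinements:
a later start must improve the norm by >1% to displace an earlier one
(earlier families encode continuity, and near-ties are noise), and the
multi-start loop stops once the residual reaches the configured noise
floor.  All randomness flows from the configuration seed; identical inputs
and seed give identical results.

Because the tan δ residual is label-blind, shape-identical overlapping
processes can trade identities between isotherms.  An optional (default-on)
speed-ordering constraint parametrizes each next process's `log10 f0` as
the previous one minus a non-negative gap, freezing the configured order
within an isotherm.  Where two processes genuinely cross in temperature,
the plan switches their order at a window boundary.

Processes whose fitted strength falls below 1e−3 or whose frequency leaves
the measured window by more than two decades are flagged `unresolved`
rather than deleted — mirroring the genuine ambiguity of near-coincident
structural and interfacial processes in these materials — and unresolved
entries never enter the relaxation map.

## Temperature laws, Tg, fragility

Arrhenius groups are fitted by ordinary least squares of `log10 f0` on
`1/T` (`Ea = −slope·ln10·R`, `R = 8.314462618 J/(mol K)`), unweighted.  VFT
fitting profiles the Vogel temperature on a grid — for fixed `T0` the
remaining two parameters are an exact linear subproblem — and then polishes
all free parameters with bounded trust-region least squares; the fixed-
`f_inf` mode (merging of structural and secondary relaxations) only frees
`(B, T0)`.  A fit whose Vogel temperature lands within 0.5 K of the coldest
point is flagged: the asymptote is effectively inside the data.  Map-level
summary fits apply one robustness device each — a 0.5-decade gross-outlier
trim for Arrhenius, a soft-L1 loss (scale 0.1 decade) for VFT — which leave
exact data untouched but keep a single derailed isotherm from corrupting an
activation energy or a glass transition.

The dielectric glass transition is the temperature where the VFT law
reaches `f = 1/(2π·100 s)`;
`Tg = T0 + B/(ln10 (2 + log10 2π f_inf))` equals the numeric root of the
law to 1e−9 K.  The fragility
`m = C (1 + ln10 C T0/B)` with `C = 2 + log10(2π f_inf)` agrees with its
algebraic twin `B Tg / (ln10 (Tg − T0)^2)` to 1e−9 relative; both identities
are enforced by tests over random parameter triples.  A map group can also
be read directly at the rounded level `log10 f0 = −2.8`: bracketed crossings
are interpolated linearly in `1/T`, otherwise a VFT extrapolation is used,
guarded to `(T0 + 1 K, max(T) + 100 K)` and to at most 150 K below the
coldest point — wilder extrapolations are refused rather than reported.

## Interfacial polarization and conductivity

`tau_MWS` is evaluated directly from the two-phase mixture formula with the
primes of the phase permittivities interpreted as real (relaxed) values at
the interfacial frequency.  The dc-conductivity series extracted from the
tan δ fits is analysed with a plain two-segment Arrhenius scan over grid
midpoints (at least three points per side, lowest total squared residual
wins); the σ0–slow-frequency correlation is an ordinary log–log regression
with a t-based confidence interval, where proportionality (slope one) is
the `sigma1 ≪ sigma2` signature of interfacial polarization.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of isothermal BDS campaigns on
solution-cast polysaccharide films: 0.1 Hz–1 MHz sweeps at 10 points per
decade (71 points), 5 or 10 K steps from −100 °C upward, up to five
simultaneous processes with Arrhenius or VFT laws, a two-regime
conductivity (activation energies stepping ~20 → ~70 kJ/mol with the
exponent stepping ~0.35 → ~0.9 across the break), multiplicative lognormal
noise (default sd 1%, independent per point), and a thickness-drift factor
`g(T)` that multiplies `eps'` and `eps''` jointly — the default drift
magnitude option corresponds to a film thinning from 51 to 32 μm.  VFT
processes are dropped from an isotherm below `T0 + 1 K` or once their
frequency falls below 10^−20 Hz (frozen out), and a process whose strength
law has decayed to zero is omitted.

Preset temperature-law parameters are the published relaxation-map fits for
the neutralized (A90) and non-neutralized (A0) films at each annealing
temperature.  Everything else is a package choice, documented here because
no strengths or shapes are published:

* width exponents follow field systematics — secondary relaxations broad
  (`a ≈ 0.45–0.5`), the structural process broad (`a ≈ 0.55`), interfacial
  and electrode polarization near-Debye (`a ≈ 0.9–0.95`); `b = 1`
  throughout, matching how such spectra are routinely fitted;
* strengths are order-unity for the secondary process, ~10 for the
  structural process and ~4 for the interfacial one.  An information
  analysis at the generating parameters (Fisher information of the tan δ
  curve under 1% multiplicative noise) showed that a structural process
  much weaker than its interfacial neighbour is not localizable to the
  ~0.1-decade level at any estimator — inconsistent with the precision the
  emulated study reports for its structural-relaxation fits — so the
  structural process carries the dominant strength;
* electrode polarization has an apparent strength orders of magnitude above
  the molecular processes (a charge layer spanning the whole sample) and is
  emulated with a linear-in-T strength that switches on near room
  temperature, reaching ~1.7×10^3 at the top of the ramp: electrode charge
  build-up requires active dc conduction, so EP vanishes from cold spectra;
* conductivity magnitudes put the dc plateau near 10^−7 S/m at the hottest
  isotherm, low enough for the relaxations to stay visible in tan δ.

Passing the recovery tests therefore demonstrates that the estimator is
unbiased and precise *within this model class* — spectra that are exactly a
finite HN sum plus a power-law conductivity, with independent multiplicative
noise.  Real films add baseline artifacts, correlated noise, temperature
gradients, irreversible annealing during the ramp (the slow process's
plateaus), and shape parameters that drift with temperature; none of these
are emulated, and recovery on synthetic data does not certify performance
against them.

## Problem sizes

The shipped validation runs use the 10 K-step grid (25 isotherms × 71
frequencies) and ten noise realizations for the recovery study; the
brute-force loss-peak oracle uses a 2×10^5-point grid over 18 decades; the
identity checks use 10^3 random parameter triples.

## Known limitations

* No Cole–Davidson/KWW interconversions, no temperature-dependent shape
  laws in the fitter, no automatic selection of the number of processes.
* Electrode polarization is modelled as one more HN term (`b = 1`), not as
  a blocking-electrode circuit element.
* The two-regime conductivity split assumes a single breakpoint.
* Fits of heavily overlapped processes (closer than ~half a decade with
  comparable strengths) are near-degenerate; the package flags rather than
  resolves them, and reported uncertainties there are unreliable
  (covariances are close to singular).
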