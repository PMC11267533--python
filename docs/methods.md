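# Methods

## Observable and CSP definition

The per-residue observable is the position of a backbone amide
cross-peak in a ¹⁵N-HSQC. The perturbation between a reference state and
an observed state is the weighted Euclidean combined shift
Δδ = sqrt(Δ¹H² + (α·Δ¹⁵N)²) in ppm, with the standard amide ¹⁵N
weighting α = 0.14 by default. A popular variant divides the sum of
squares by two before the square root; the two differ by a constant
factor, which cancels in σ-based top-shifter selection and is absorbed
into the fitted amplitude Δδ_max during K_d fitting, so the choice does
not move any downstream decision made in ppm-free terms. α is
configurable everywhere the formula enters. Peaks are matched across
conditions by residue number parsed from the assignment label; the
pipeline assumes curated, transferred assignments and performs no
nearest-neighbour peak tracking.

## Top-shifter selection

A residue is a top shifter when its CSP is at least k standard
deviations above the profile mean (k = 1 by default). σ is the
population standard deviation over the residues present in the profile,
and the comparison is inclusive (≥). When all CSPs are equal, σ = 0 and
every residue meets the inclusive threshold; this degenerate but
well-defined case is logged as a warning rather than raised.

## Mixture triage and deconvolution hit calling

Screening mixtures are triaged by counting residues of interest — the
membrane interface plus the observable functional set — whose CSP
exceeds a threshold (0.01 ppm, strict inequality). Tier boundaries are
≥ 5 shifted resonances → high, 3–4 → medium, 1–2 → low, 0 → none. This
is a deliberate quantitative surrogate for prioritization that is
usually done by eye; the boundaries are configurable, and by default
only high and medium tiers advance to deconvolution.

A deconvoluted (singly retested) fragment is a hit when at least
`min_count` residues of the observable functional set — cationic patch
and catalytic site resonances minus anything unassigned, 15 for the
target that motivated the defaults — shift by strictly more than the
CSP threshold. Defaults are 7 of 15 and 0.01 ppm. The denominator comes
from the annotation table, not a hard-coded constant, so the rule reuses
across targets. The hit rate is 100 × validated hits / library size,
reported to two decimals.

## Ligand-depletion isotherm

With total protein P, total ligand L and apparent dissociation constant
K_d (all μM), 1:1 binding with ligand depletion has the closed-form
bound-protein fraction

f = ((P + L + K_d) − sqrt((P + L + K_d)² − 4PL)) / (2P),

the unique root of the equilibrium quadratic lying in [0, 1]. Under fast
exchange the observed CSP is Δδ_max · f. Concentrations are totals over
the whole sample; no correction for compartmental partitioning of the
fragment is applied, so fitted constants are apparent K_d values. The
implementation clips the discriminant at zero and the result to [0, 1]
to absorb floating-point round-off near the stoichiometric corner; tests
verify |Δ| < 1e−9 against an independent root-finding equilibrium solver
over a 10×10×10 grid spanning 1–1000 μM, and convergence to the
hyperbolic limit L/(L+K_d) at P/K_d = 1e−5.

## Per-residue and global fitting

Each candidate residue is first fit individually by bounded nonlinear
least squares (Levenberg–Marquardt via lmfit, relative ftol = xtol =
1e−10) with K_d ∈ (0, 10·L_max] and Δδ_max ∈ (0, 10·max observed CSP].
Three log-spaced K_d starting values spanning L_max/50 to 10·L_max guard
against local minima; the lowest-χ² start wins. R² = 1 − SS_res/SS_tot
with SS_tot taken about the mean observed CSP of that residue. Residues
whose CSPs are identically zero are rejected outright (the Δδ_max → 0
boundary carries no K_d information), as are residues observable at
fewer than three titration points.

Fits with R² strictly below the cutoff (0.85 by default; the boundary
value itself is retained) are excluded, and the survivors enter one
joint least-squares problem with a single shared K_d and per-residue
Δδ_max — a full joint refit rather than reuse of the individual-fit
amplitudes, the statistically standard choice. The reported K_d standard
error is the square root of the K_d diagonal of the covariance estimate
at the joint optimum; when the solver cannot supply it (e.g. a parameter
pinned at a bound) a finite-difference Gauss–Newton estimate is
substituted.

Fragments are classified from the global fit plus the
highest-concentration CSP profile: hit if K_d < 1 mM and at least half
of the top shifters lie in the membrane interface or functional region
(both cutoffs configurable); weak if localized but K_d at or above the
cutoff; nonspecific otherwise. The locality fraction quantifies the
otherwise qualitative notion of structurally localized, saturating
binding.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the physics of the spectrometer. Reference amide positions are drawn
once per simulation (¹H ∈ [7.0, 9.5] ppm, ¹⁵N ∈ [106, 128] ppm,
uniformly) and constitute the noise-free baseline; a screen shares one
protein, so all fragments simulated within a screen share the reference
positions through a common reference seed. Each responsive residue is
assigned a saturation shift Δδ_max drawn from [0.02, 0.10] ppm and a
fixed displacement direction — a random angle θ applied as
(Δ¹H, Δ¹⁵N) = (d·cosθ, d·sinθ/α), so the weighted CSP equals the model
value d exactly. At each ligand concentration, d = Δδ_max · f(P, L, K_d)
and independent Gaussian noise (σ_H = 0.002 ppm, σ_N = 0.01 ppm by
default) is added to every peak. Defaults mirror the screening design
the package targets: P = 100 μM, L ∈ {0, 50, 100, 250, 400} μM (400 μM
being the 4:1 screening ratio), a 15-residue functional set, planted
K_d = 105 μM, and binders responsive at 8 functional residues so that a
planted binder passes the 7-of-15 rule.

Scenarios: `binder` and `weak_binder` follow the depletion isotherm
(weak binders simply carry a large K_d); `nonbinder` displaces nothing;
`nonspecific_drift` moves all residues along random directions linearly
in L (non-saturating, delocalized), the signature the classifier labels
nonspecific. Mixtures take their observed profile from the strongest
planted binder they contain: with one protein observable, co-screened
non-binders contribute nothing, and competition between co-binders in
one mixture is not modeled — the deconvolution stage retests fragments
singly, which the simulator mirrors. Libraries are partitioned into
ceil(library/mixture_size) consecutive mixtures, so a 1911-member
library in mixtures of ten yields 192 mixtures with the last holding a
single fragment.

What the generator does not emulate: line broadening and intermediate
exchange, resonance overlap and peak-picking errors, fragment
partitioning thermodynamics in the membrane mimic, solvent/DMSO effects,
and inter-fragment competition. Passing tests therefore demonstrate the
correctness of the analysis under the fast-exchange two-state model with
Gaussian position noise — not robustness to those real-data pathologies.

## Numerical and design choices

- All randomness flows from one seeded NumPy generator per simulation;
  identical config and seed give byte-identical peak lists (4 decimal
  places ppm on disk).
- Peak-list files are Sparky-style whitespace tables, w1 = ¹⁵N,
  w2 = ¹H, with a config switch for swapped exports.
- Residues missing at some titration points are retained and flagged,
  then excluded per-fit rather than dropped globally.
- Insoluble-aggregate mixtures are screened, not skipped; the flag is
  carried on the mixture record.
- PDB annotation rewrites only columns 61–66 of ATOM/HETATM records
  (B = CSP × 1000, capped at 999.99; unmapped residues zeroed) so the
  output is byte-identical to the input outside the temperature-factor
  column. Residue-numbering offsets between assignment and structure are
  a config option, never inferred.
- Problem sizes in the test and acceptance runs (100-seed recovery
  studies, 200-fragment screens, 25-seed dispersion curves) were chosen
  as the smallest sizes at which the statistical contracts are stable;
  the generator scales to full library sizes (1911 fragments) directly.

## Known limitations

- The joint fit assumes independent homoscedastic CSP errors; CSP noise
  is mildly non-Gaussian (magnitude of a noisy 2-vector), which biases
  very small CSPs upward. At the default noise this effect is well below
  the fitted-parameter uncertainty.
- One shared K_d per fragment presumes a single binding mode across the
  selected residues; multi-site or cooperative binding is out of scope.
- Classification thresholds (1 mM, locality 0.5) are screening
  heuristics, not mechanistic statements.
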