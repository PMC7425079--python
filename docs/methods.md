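# Methods

## The model

sielkit quantifies the *directionality* of electronic excitations in
multichromophoric systems — typically polypyridyl transition-metal
photosensitizers — using only fragment-resolved populations of the excited
electron, never molecular orbitals. The molecule is partitioned into
fragments (the metal centre and its ligands); every descriptor is a
function of the per-fragment excited-electron populations e_i of one
excited state, or of their statistics over a geometry ensemble.

**Participation ratio.** For a population vector e over n fragments,

    PR_f = (Σ_i e_i)² / Σ_i e_i²

is an inverse-participation-ratio-style count of how many fragments
effectively share the excited electron. It is invariant under uniform
rescaling, equals 1 iff exactly one fragment carries population, and equals
n iff the populations are uniform.

**Delocalization-length histogram.** Over an ensemble of N excited states,

    EEDL_n = N(n − 0.5 < PR_f < n + 0.5) / N × 100 %

is the percentage of states whose PR_f falls in the unit bin around the
integer n. Bins above n structurally receive zero (PR_f ≤ n) and are
reported as exact zeros. The open intervals leave exact half-integers
undefined (a measure-zero set); we assign n = floor(PR_f + 0.5), i.e.
half-integers go to the upper bin. Σ_n EEDL_n = 100 % exactly for any
ensemble, by construction.

**Substituent-induced exciton localization.** With the metal fragment
dropped and the m ligand populations renormalized to ê (Σ ê_i = 1), and R
the ligand carrying the substituent,

    SIEL = (1/(m−1)) Σ_{i≠R} ê_i − ê_R .

The prefactor makes the evenly delocalized state give SIEL = 0; the range
is [−1, 1/(m−1)], with −1 attained only at ê_R = 1 (the substituent pulls
the whole excited electron onto its ligand; electron-withdrawing behaviour)
and the upper bound only at ê_R = 0 (complete repulsion;
electron-donating). For three ligands the range is [−1, 0.5]. The upper
bound is 1/(m−1); a typeset variant "1/(m⁻¹)" that circulates in the
literature is a typographical error, since 1/(m⁻¹) = m would exceed the
value Σ_{i≠R} ê_i/(m−1) ≤ 1/(m−1) attainable when ê_R = 0. Schemes with
m = 2 are allowed (range [−1, 1]); m = 1 is rejected as degenerate.

These two closed forms are the unique expressions consistent with all the
boundary values the descriptors are defined by (PR of a localized state
= 1, uniform state = n; SIEL = 0 when even, bounds 0.5/−1 for m = 3,
general upper bound 1/(m−1)); both are verified in the tests by brute-force
enumeration on 0.01-step population simplexes.

**Ensemble statistics.** The natural unit of analysis is a *band*: the
lowest ~25 singlet states at each of ~100 thermally sampled geometries for
absorption (≈2500 states), or the lowest triplet per geometry for emission
(≈100 states). The default ensemble average is uniform over all states of
the band. Two opt-in weightings exist: Boltzmann weights
w_i ∝ exp(−(E_i − E_min)/k_B T) with k_B = 8.617333×10⁻⁵ eV/K (appropriate
for a near-degenerate triplet manifold; shift-invariant by construction),
and oscillator-strength weights (bright states count more). Weighted
standard deviations use the plain weighted second central moment.

Because SIEL is linear in ê, the uniform-weight ensemble mean of SIEL
equals SIEL of the mean population vector — *provided* the per-state ligand
renormalization is trivial, i.e. for ligand-only schemes or a constant
metal fraction. With a state-varying metal population the renormalization
is nonlinear and the identity is only approximate; the tests check it on
ligand-only bands, where it holds to 1e−9.

**Direction classification.** A SIEL value is labelled *attract* below
−0.02, *repel* above +0.02, *neutral* between. The dead band exists because
the ensemble-mean SIEL of an unsubstituted parent complex is close to, but
never exactly, zero over a finite ensemble; 0.02 is roughly the magnitude
of that finite-sampling residue and an order of magnitude below the
smallest substituent effects worth reporting (~0.2). It is a keyword
argument everywhere it matters.

## From transition density matrices to populations

When fragment populations are not supplied directly, they are computed from
the one-electron transition density matrix D (row = hole AO, column =
electron AO) and the AO overlap S. The fragment × fragment charge-transfer
numbers are aggregated over AO pairs a∈A, b∈B in one of two conventions:

* Mulliken-style (default): Ω_ab = ½[(DS)_ab (SD)_ab + D_ab (SDS)_ab];
* Löwdin-style: Ω_ab = (S^{1/2} D S^{1/2})_ab².

Both reduce to D_ab² at S = I and share the sum rule
Σ_AB Ω_AB = ‖S^{1/2} D S^{1/2}‖²_F. Which convention a given upstream code
used is rarely documented, so the choice is an explicit argument. Electron
and hole fragment populations are the column and row sums of Ω/Ω_total; the
MLCT/LLCT/MC/LC character fractions are the corresponding Ω blocks, plus an
explicit LMCT (ligand→metal) fraction so the five-way partition sums to
unity exactly — the LMCT block is usually negligible in MLCT-dominated
excitations but is not identically zero for a generic Ω. NTO weights are
the normalized squared singular values of S^{1/2} D S^{1/2}.

Numerical choices: S^{1/2} is built from the eigendecomposition of S, and a
minimum eigenvalue ≤ 1e−10 raises an invalid-overlap error. Mulliken-style
partitioning can produce small negative fragment blocks even for exact
inputs; Ω is stored exactly as the formula gives it (so it satisfies its
defining identities to machine precision), a negative entry beyond
1e−3·Ω_total raises as unphysical, and smaller negatives are clamped to
zero (with renormalization and a logged warning) only when Ω is converted
to population vectors, which must be nonnegative for the descriptors.

Fragment merging (e.g. folding a triazole linker into the bipyridine it
decorates) sums the corresponding Ω rows/columns, or the corresponding
population entries; the total Ω and all unmerged marginals are invariant —
this sum rule is what lets a 5-fragment analysis be collapsed onto a
4-fragment one exactly.

## The additivity design rule

Per-substituent SIEL contributions, tabulated on the reference scaffold
(one substituent on one bipyridine of the tris-bipyridine complex), are
summed per ligand: net SIEL of a ligand = Σ of its substituents' entries;
unsubstituted ligands get 0. Ligands ranked by ascending net SIEL give the
predicted excitation destination (most attracting first; ties break
alphabetically). The bundled table carries the five triplet-state
contributions reported in the primary literature source's main text (CH3
+0.26, COOH −0.71, NHCOCH3 +0.41, CONHCH3 −0.69, CH2SCH3 +0.28); fuller
tables can be loaded from YAML. Caveats, by design: the summation has no
saturation (net values may leave the single-state SIEL range — they rank
ligands, they are not populations), the rule has been validated against
explicit calculation only for the dmb/dcb dye case, and cross-ligand
interactions are outside the predictor (the full descriptor pipeline, not
the additivity rule, captures them). Triplet contributions are the default
because the relaxed triplet charge-transfer state drives the subsequent
photochemistry; singlet tables are accepted via the same interface.

`correlate_constants` is a thin ordinary-least-squares wrapper (slope,
intercept, R²) for comparing SIEL against empirical substituent scales such
as the Hammett σp constants; constant-y input reports R² = 0 (zero
explained variance).

## Synthetic data

The generator emulates the *shape* of ensemble TD-DFT population data, not
its physics: per-state electron populations are drawn from a Dirichlet(α)
on the fragment simplex, state energies from a normal law (default centre
2.9 eV, spread 0.15 eV — a typical visible MLCT band), oscillator strengths
from a folded normal (scale 0.05, typical of weak MLCT transitions). The
single dial is α: a spiked α localizes states on one fragment, a large
uniform α delocalizes them. `localization_concentration` inverts the
Dirichlet mean so an ensemble can be tuned to a target mean population p*
on the substituted ligand, for which the analytic expectation
SIEL* = (1/(m−1))(1−p*) − p* follows from linearity; statistical tests
recover it within three standard errors at 2500 states. Default ensemble
sizes mirror the real protocol (25 states × 100 geometries). What the
generator does **not** model: energy–population correlations, vibronic
structure, state crossings, or any relation between oscillator strength and
localization — so passing tests demonstrate the correctness of the
descriptor arithmetic and statistics, not the photophysics of any real
complex. All generators take an explicit integer seed; there is no global
random state.

Toy transition density matrices are built analogously: a random D with
extra weight in the columns of a chosen target fragment, and a diagonally
dominant (hence SPD) overlap S = I + small symmetric noise. AOs are dealt
round-robin to fragments so every fragment owns at least one AO.

## File formats and conventions

Population tables are CSV/TSV with header
`geometry_id,state_index,multiplicity,energy_eV,osc_strength,e_<frag>,...`
(optional `h_<frag>` hole columns), fragment columns ordered as in the
fragment config. The reader sniffs comma vs tab from the header and rejects
malformed rows with the 1-based row and column named; the writer always
emits comma-separated values at 12 significant digits, so a write→read
round trip preserves populations to that precision. Raw per-state
populations are renormalized to unit sum on construction; a sum deviating
from 1 by more than 0.05 (truncated state expansions) logs a warning.
Energies are eV throughout; hartree and cm⁻¹ inputs are converted at the
boundary. Atom indices in fragment configs are 1-based and inclusive
(`"2-20"`), the convention of quantum-chemistry outputs. Dense matrix files
for D and S are whitespace-delimited text; D is stored row = hole AO, with
a transpose flag for files in the opposite convention.

## Known limitations

* No electronic-structure computation, geometry sampling, or spectral
  simulation: the package starts from populations or TDMs someone else
  computed.
* Singlet and triplet TDMs are treated identically (spatial part only); no
  spin–orbit coupling.
* The additivity predictor ignores cross-ligand substituent interactions
  and saturation by construction.
* Ensemble-scale reference values from the literature (delocalization
  histograms of full derivative series, descriptor–σp regressions over ~20
  compounds) require the original deposited quantum-chemistry ensembles and
  are not reproduced here; the pipeline is validated on exact worked
  examples, brute-force oracles, and synthetic ensembles instead.
* Problem sizes used in the test suite and acceptance script — 0.01-step
  simplex enumeration (~5×10³ points), ≤ 8-AO toy TDMs, 2500-state
  synthetic bands — are the package's chosen validation scale; all
  descriptor code is vectorized and handles larger inputs.
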