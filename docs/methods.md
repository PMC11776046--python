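# Methods

## Model

A protein sequence with N ionizable sites (D, E, C, Y, H, K; optionally the
free N-/C-termini) populates 2^N charge microstates. The model assigns each
microstate a standard-state free energy relative to the fully protonated
reference (G_ref ≡ 0) as a sum of per-site deprotonation free energies taken
along a fixed thermodynamic path: sites release their protons in N-to-C
order, and each site's contribution

    ΔG(site) = ΔG°_intr(type) + Σ_{neighbors j, 1 ≤ |d_j| ≤ w} δg(type, res_j, d_j, state_j)

depends additively on the residues within a window of w sequence positions on
either side and, for left-side ionizable neighbors, on their protonation
state. Right-side neighbors are protonated by the path convention, so the
database never stores a deprotonated right-neighbor term. The intrinsic term
is ΔG°_intr = RT·ln(10)·pKa_model; model-compound pKa values are
configuration data (`src/qtitrate/data/model_pkas.yaml`), not code.

The ensemble is organized q-canonically: mesostate n pools the microstates
with n released protons; its net charge is q = q_max − n exactly (releasing a
proton lowers the charge by one for acids and bases alike). Standard-state
mesostate free energies G_n° are pH independent, and

    G_n(pH) = G_n° − n·RT·ln(10)·pH

recovers the full pH dependence analytically. The sign is fixed by the
decoupled limit, which must reduce each site to Henderson–Hasselbalch
(bound fraction 1/(1 + 10^(pH − pKa))).

**Assumptions.** Additivity of neighbor contributions; no influence from
residues outside the window (realistic for expanded, disordered chains); no
conformational coupling — the model estimates sequence-context effects only,
and compact or structured ensembles will deviate.

## Dynamic programs

`global_dp` propagates, site by site, the pooled free energy of every
(mesostate n, context c) cell, where c is the release pattern of the last L
processed sites. The released branch adds the context-dependent ΔG of the
current site and advances n; the retained branch adds nothing; branches
landing in one cell are merged with the overflow-safe log-sum-exp
combination. After N steps, marginalizing contexts gives G_n°. `site_dp`
carries, alongside, one ledger per (site, bound/released state): tracked
sites update through the identical branching, and each newly considered site
initializes its two ledgers from the retained/released branches of the global
table. Combining a site's two ledgers recovers G_n° exactly, for every site —
a structural invariant the observables layer verifies.

**Exactness.** A site's ΔG reads only the states of sites within its left
window; in N-to-C order those are always among the most recently processed.
The default context depth is therefore the per-sequence maximum span of any
left window (`exact_context_depth`), which makes both programs exact: on
randomized instances they agree with brute-force enumeration to ~1e−13
kcal/mol, far inside the 1e−9 kcal/mol contract used by the tests. A fixed
smaller depth may be requested (`allow_approx=True`); untracked neighbors are
then taken as protonated, and results are approximate. The depth is capped
(default 12) because cell count scales as 2^L.

**Numerics.** Cells hold Boltzmann weights scaled by a per-mesostate
free-energy offset; each step renormalizes every mesostate row by its
maximum weight and absorbs the factor into the offset, so no exponential
over- or underflows regardless of sequence length or energy scale. A newly
populated mesostate inherits its source row's offset (transfer factors stay
O(1)). Empty ensembles — e.g. "site r released in mesostate 0" — are +inf
sentinels carrying zero weight, never large finite floats. The oracle
tolerance 1e−9 kcal/mol covers double-precision log-sum-exp reordering up to
N = 12.

**Cost.** Instrumented operation counts grow as ~N² (global) and ~N³
(site-specific) at fixed window, versus 2^N for enumeration; measured log–log
fit exponents over N ∈ {8…128} are 1.96 and 2.94. The large-sequence
condition exercised by the tests is a 2,000-residue chain of repeating EGKG
(1,000 ionizable sites, left-context depth 2 at window 5), which completes in
about a minute on one CPU. The prefix-sharing enumerator (`dynamic_build`)
needs 2^N − 1 additions versus the naive N·2^(N−1).

## Synthetic database

`synthesize_db` emulates the *structure* of a context database without any
external fit: neighbor terms follow a screened-Coulomb form. Releasing a
proton changes the center's charge by exactly −1 (acids 0→−1, bases +1→0), so
the term for a neighbor of formal charge z at distance d is

    δg = −A · z(state) / |d|^p        (kcal/mol)

with coupling strength A (default 1.0 kcal/mol — at that scale nearest
neighbors shift pKa values by ~0.7 units, the magnitude of typical measured
context shifts) and decay exponent p (default 1, unscreened Coulomb in a
uniform dielectric). A protonated lysine neighbor thus lowers a glutamate's
pKa; a deprotonated glutamate raises it — and, symmetrically, raises a
lysine's. Non-ionizable neighbors receive seeded zero-mean perturbations
(|δg| ≤ 0.05·A) so distinct contexts remain distinguishable; with A = 0 the
database is exactly decoupled and every site titrates at its model pKa. The
generator is deterministic per seed.

What it does **not** emulate: chemically specific (non-Coulombic) neighbor
effects, conformational averaging, salt screening, temperature dependence of
the parameters. Tests passing under this generator demonstrate the
correctness of the partition-function machinery for *any* additive database,
not the accuracy of predictions for real proteins — that accuracy is a
property of the database supplied.

`apply_rescaling` implements per-type recalibration: an additive offset on
the intrinsic term and a multiplier on contributions whose neighbor is
charged in its stated state (the electrostatic part); uncharged-neighbor
terms are untouched. It is defined for implicit-mode databases only, since an
explicit keyed table does not separate the two parts.

## Observables and conventions

* `f_tot` is the fraction of ionizable protons *released* (0 at low pH);
  per-site curves report the fraction proton-*bound*, matching site-specific
  NMR titrations. Output headers state both conventions.
* pKa is the pH where a site's bound fraction crosses 0.5; the grid
  (default 0–14, step 0.05) only brackets the crossing, which is refined on
  the analytic curve to 1e−6 pH. Multi-crossing (non-sigmoidal) curves report
  the first crossing with flag "multi"; curves that never cross are "none"
  with a missing value. Intrinsic shifts propagate exactly: adding
  δ·RT·ln 10 to every intrinsic term moves every pKa by δ.
* `cooperativity_metric` is the central-difference slope of the mean
  net-charge curve where it crosses (q_max + q_min)/2. Note a caveat for
  sequences with both acids and bases: that crossing sits on the neutral
  plateau *between* the acid and base branches, so for strongly coupled
  alternating-charge sequences (whose branches are pushed away from
  neutrality) the metric reports the plateau flatness rather than branch
  steepness. `type_titration_slope` — the midpoint slope of one residue
  type's mean bound-fraction curve — is the per-branch cooperativity readout
  and is what the patterning tests use: like-charge blocks deprotonate
  anti-cooperatively (each release makes the next harder), broadening the
  branch, so its magnitude falls monotonically from the alternating (EK)₂₅
  variant (0.336/pH) to the fully blocked (E)₂₅(K)₂₅ variant (0.182/pH)
  under the default synthetic database.

## Design choices

* **Display alphabet.** The internal state bit is always "proton released";
  the string form capitalizes the *charged* state (released acids, protonated
  bases), with termini as `+`/`n` and `-`/`c` marker characters. Rendering is
  presentation only; round-trips are exact.
* **Termini** are off by default and, when enabled, titrate as ordinary sites
  (NTERM basic, site 0; CTERM acidic, last site) and act as neighbors at
  their sequence distance. A terminus and the residue carrying it are at
  distance 0 and exchange no database term (the schema starts at |d| = 1).
* **Lenient parsing** keeps a non-standard residue's *position* (as a
  non-titratable placeholder) rather than deleting it, since deletion would
  silently change every window distance; a warning is logged. Strict mode
  (default) raises, naming the position.
* **Missing implicit contributions** resolve to 0.0 with a once-per-key
  warning (absence of an effect is null under additivity); `strict` upgrades
  this to an error. Explicit-mode lookup misses are always hard errors.
* **His, Cys, Tyr** titrate by default; each type can be disabled
  (e.g. disulfide-bonded cysteines).
* Database JSON serializes numbers as full-precision reprs, so a save/load
  round trip is bit exact.

## Limitations

* Accuracy is bounded by the additive window model: long-range and
  conformation-mediated interactions are absent by construction.
* Site-specific cost is ~N³ with a 2^L context factor; very dense ionizable
  stretches under large windows raise L and memory ((N²·2^L) cells).
* The pKa of a strongly coupled site is a summary of a possibly
  non-sigmoidal curve; consult the flag and the full curve.
* The shipped model pKa values are conventional reference numbers; any
  application to real data should supply its own calibrated database.
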