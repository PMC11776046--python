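# qtitrate

Exact charge-state partition functions, titration curves and site-specific
pKa values for protein sequences — at polynomial cost.

## The problem

Every aspartate, glutamate, cysteine, tyrosine, histidine and lysine in a
protein (arginine excepted — its guanidinium group does not titrate in any
relevant pH range) can gain or lose a proton, and the free energy of doing so
depends on the residue's sequence neighborhood: a nearby opposite charge
favors ionization, a like charge opposes it (*charge regulation*). A sequence
with N ionizable residues therefore populates 2^N **charge microstates**, and
for intrinsically disordered regions — which are enriched in charged residues
— N easily reaches the hundreds, putting brute-force evaluation of the charge
landscape out of reach.

qtitrate organizes the ensemble q-canonically. Microstates with the same
number of released protons n form a **mesostate** (there are only N + 1), and
the net charge is the exact bijection q = q_max − n. Standard-state free
energies are pH independent; pH enters analytically:

    G_n(pH) = G_n° − n·RT·ln(10)·pH,     p_n(pH) ∝ exp(−G_n(pH)/RT)

so one computation of the standard-state spectrum yields every observable at
every pH: mesostate populations, the global degree of protonation
f_tot(pH) = Σ_n (n/N)·p_n, the mean net charge, and per-residue bound
fractions f_r(pH) = Σ_n f_{n,r,bound}·p_n from which pKa values are read off
at the half-titration point.

## The algorithm

Microstate free energies are sums of context-dependent deprotonation free
energies ΔG(site | neighbors, their protonation states), taken from a
database (intrinsic term per residue type plus additive neighbor terms keyed
by residue type, signed sequence distance and protonation state). Protons
are released along a fixed N-to-C thermodynamic path, so a site's ΔG is
always evaluated with its right-side neighbors protonated — halving the
contexts a database must cover.

Instead of enumerating microstates, qtitrate propagates **pooled** free
energies G = −RT·ln Σ exp(−G_i/RT), one per (mesostate, context of the last L
processed sites): at each site the released branch adds ΔG for the current
context and advances the mesostate, the retained branch adds nothing, and
branches meeting in the same cell are log-sum-exp merged. Because a site's ΔG
depends only on the states of the sites inside its left window — which in
N-to-C order are always among the most recently processed — a context depth
covering the densest left window makes the recurrence *exact*: it reproduces
brute-force enumeration to floating-point accuracy (≲1e−13 kcal/mol in
practice) while its operation count grows as ~N² (global) and ~N³
(site-specific) instead of 2^N. A sequence of 2,000 residues with 1,000
ionizable sites runs in about a minute on one CPU.

A brute-force enumerator (`enumerate_microstates`) and a prefix-sharing
variant (`dynamic_build`) are included as oracles for small N, and a
synthetic database generator (`synthesize_db`) produces physically
structured, seeded stand-in parameters (screened-Coulomb neighbor terms,
distance-decaying, charge-sign dependent) so the entire stack runs
self-contained.

## Worked example

```sh
printf ">protA example\nAEDGKEHAKAEY\n" > ex.fasta
qtitrate predict --fasta ex.fasta --out exout --seed 0
cat exout/protA.pka.tsv
```

```
position  residue  pKa           flag     model_pKa  shift
1         E        4.772204888   sigmoid  4.34        0.4322048875
2         D        3.60619178    sigmoid  3.86       -0.2538082198
4         K        11.56804483   sigmoid  10.34       1.228044833
5         E        2.679394956   sigmoid  4.34       -1.660605044
6         H        6.965137883   sigmoid  6.54        0.4251378827
8         K        10.95085035   sigmoid  10.34       0.610850348
10        E        3.950766261   sigmoid  4.34       -0.3892337386
```

Each row is one titratable site: its extracted pKa, a flag describing the
curve shape ("multi" marks non-sigmoidal titration, where one number cannot
summarize the curve), the model-compound pKa implied by the database's
intrinsic term, and the context-induced shift. Here E5, flanked by two
protonated lysines, is pushed 1.66 pH units more acidic, while K4 — in a
negatively charged neighborhood — holds its proton 1.23 units longer.
`exout/protA.global.tsv` carries f_tot and the mean net charge per pH (e.g.
net charge −1.508 at pH 7 for this peptide), `*.mesostates.tsv` the mesostate
populations, and `*.sites.tsv` the per-site bound fractions.

The other subcommands: `qtitrate oracle` prints full microstate tables and a
DP-vs-brute-force comparison for small sequences, `qtitrate synth-db` writes
a synthetic database to JSON, and `qtitrate fixtures` generates benchmark
FASTA sets (E/K charge-patterning variants, poly-acids, random sequences).

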