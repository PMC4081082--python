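# Methods

`triplexkit` models cooperative repression of one mRNA by two miRNAs bound at
neighboring 3′ UTR sites. This note records the models, the parameters that
matter, the numerical choices, and what the bundled synthetic data does and
does not emulate.

## Candidate definition

A triplex candidate is an ordered pair of predicted target sites on one
transcript whose seed matches are 13–35 nt apart (both bounds inclusive).
The default distance metric is the **gap**: the count of nucleotides
strictly between the two seed-match intervals. Because "distance between
seed sites" is ambiguous in common usage, a `start_to_start` metric is
selectable in configuration. Homotypic pairs (the same miRNA bound at both
sites) are retained: tandem sites for one miRNA are a documented biological
case. Site-level filtering keeps sites with mirSVR ≤ −0.1 (boundary
inclusive) from conserved miRNAs. The folded substrate is the UTR
subsequence that exactly encloses both site intervals (`flank = 0` by
default; positive flank is clipped at the UTR ends).

## Folding engine

Structures are non-pseudoknotted matchings over the concatenation of 1–3
strands (mRNA window first, then the miRNAs), with pairs allowed within and
between strands. The energy model is a reduced nearest-neighbor scheme:

- **Pair set** — Watson–Crick plus G·U wobble.
- **Stacks** — a packaged table (`data/stack_energies.tsv`) of helix
  stacking energies in kcal/mol. Watson–Crick entries follow the standard
  nearest-neighbor values; G·U entries are a reduced set chosen to keep
  wobble stacking weaker than Watson–Crick stacking, with the tandem
  5′GU/UG3′ motif mildly destabilizing. The table is symmetrized on load
  (`stack(xy, wz) = stack(zw, yx)`), and conflicts raise an error.
- **Loops** — affine + logarithmic penalties
  (`data/loop_params.tsv`): hairpin `5.40 + 1.08·ln(n/3)` (minimum size 3),
  bulge `3.80 + 1.08·ln n`, internal
  `4.00 + 1.08·ln((n1+n2)/2) + min(3.0, 0.5·|n1−n2|)`, multiloop
  `3.40 + 0.40·branches + 0.10·unpaired`. Internal/bulge loops larger than
  30 nt are disallowed outright; this cap is part of the energy definition,
  so the dynamic program and the enumeration oracle agree exactly.
- **Nick rules** — a loop that contains a strand nick is exterior-like: it
  carries no penalty, no stack bonus across the nick, and is exempt from the
  minimum hairpin size. This is what lets two strands form a blunt duplex
  whose "hairpin" across the nick costs nothing.
- **Zero point** — unstructured single strands have energy 0 and there is no
  per-strand association penalty. Consequently ΔG ≤ 0 for every complex,
  adding a strand can never raise the MFE
  (ΔG_triplex ≤ min ΔG_duplex), and ΔΔG ≤ 0 whenever the triplex search
  space contains each duplex structure with the third strand unpaired.

The MFE is computed by a Zuker-style dynamic program with four tables
(paired, exterior-like, multiloop ≥0 and ≥1 branches) extended with the nick
cases; complexity is O(n³) plus O(n²·L²) for interior loops capped at
L = 30. Absolute ΔG values from this reduced model are **not** comparable
to full Turner/partition-function implementations; every downstream filter
is threshold-relative, so only orderings matter.

**Verification** is dual-route: `enumerate_structures` lists every valid
matching (feasible to total length ~30) and scores each with
`score_structure`, an independent loop-decomposition implementation of the
same energy definition; the DP must reproduce the enumeration minimum
exactly. The test suite checks 200+ random 1–3 strand instances.

**Tie-breaking** among co-optimal structures is by a fixed traceback
preference order (unpaired-first, then smallest split index), which makes
the reported structure deterministic. No claim is made that it is the
lexicographically smallest co-optimal pair map.

**Strand order**: for three strands both distinct orders
(window, miR1, miR2) and (window, miR2, miR1) are folded and the minimum
taken, since non-pseudoknotted structure space depends on concatenation
order.

## Conformation classes and seed preservation

On the winning triplex structure (strand 0 = mRNA window):

- `duplex_plus_free_mirna` — a miRNA strand has no inter-strand pairs;
- `mirna_mirna_hybrid` — the miRNA strands pair with each other;
- `canonical_triplex` — both miRNAs pair exclusively with the mRNA, each at
  least once (a miRNA self-hairpin demotes the structure to `other`).

The first two classes are discarded by default: an isolated miRNA is a
duplex in disguise, and miRNA–miRNA hybridization is typically bought at
the cost of seed pairing. Seed preservation requires all 7 of miRNA
nucleotides 2–8 (configurable window and count) to pair with positions
inside that miRNA's **designated** seed-match interval on the window —
pairing with the other site's interval does not count.

## Population free-energy cutoff

The TFE cutoff is `mean(ΔG) − Z·sd(ΔG)` (sample standard deviation,
Z = 3 by default) over the folded candidate population, keeping records with
ΔG_triplex ≤ cutoff. A Z-score from a handful of values is statistically
meaningless, so the pipeline skips this stage (cutoff = +∞, logged) when the
population is smaller than `min_population_for_cutoff` (default 10).

## Stability-time decision rule

Molecular dynamics itself is out of scope; the pipeline ingests stability
times (ps for which a strand stayed hydrogen-bonded during a production
run). A record passes when

1. `min(t1, t2) ≥ 100 ps` (inclusive — decisive for a record with a joint
   time of exactly 100), and
2. some miRNA is held longer in the triplex than in its own duplex
   (`t1 > d1 or t2 > d2`).

The per-miRNA comparison in (2) is the default (`caption` rule) because it
is the variant consistent with the published pass/fail outcomes on the
bundled reference table; a stricter variant comparing the joint triplex
time against the smaller duplex time (`equation`) is selectable for audit.
The bundled table (13 records: 12 extreme-energy candidates plus the
experimentally validated CDKN1A control) classifies as: low-TFE group 3/3
pass, high-gain group 3/3, high-TFE group 0/3, low-gain group 1/3 (KAT2B
only), control passes.

## Equilibrium concentrations

For the declared complex set (default {M, A, B, MA, MB, AB, MAB};
homodimers excluded but accepted via configuration) in dilute solution,

    [c] = ρ₀ · exp(−ΔG_c / RT) · Π_s λ_s^{n_sc},   ρ₀ = 1 M, monomer ΔG = 0,

with per-strand activities λ_s fixed by strand conservation
(Σ_c n_sc[c] = total_s, default 100 nM each, T = 310.15 K,
R = 1.9872×10⁻³ kcal/(mol·K)). Conservation is the stationarity condition
of the convex potential Φ(x) = Σ_c [c](e^x) − Σ_s t_s x_s in log-activities,
solved by damped Newton with Levenberg regularization (the Hessian is
rank-deficient when a single complex dominates), a residual-norm line
search near the solution, and bounded per-coordinate bisection as a
fallback. The system is nondimensionalized by the geometric-mean total so
the line search stays above machine precision. Convergence demands strand
conservation to 10⁻¹⁰ relative; every solve re-asserts conservation to
10⁻⁶ before returning. Complexes with ΔG = +∞ are excluded (binding
disabled), and the solution is invariant to declaring such a complex.

The complex energies handed to the solver are MFE values, a proxy for the
ensemble free energies a partition function would supply; this
underestimates the stability of complexes with many near-optimal
structures. The TEC filter keeps triplexes with [MAB] strictly greater
than 50 nM — at 100 nM totals, the point where the majority of mRNA is
triplex-bound.

## Kinetic model

Species (nM): free mRNA `m`, free miRNAs `R1, R2`, duplexes `C1, C2`,
triplex `T`, protein `P`. Processes: mRNA synthesis `k_m`; miRNA synthesis
`TFᵢ·kᵢ`; reversible duplex assembly (`aᵢ`, `dᵢ`) and triplex assembly from
either duplex (`a₁₂, a₂₁`, `d₁₂, d₂₁`); degradations δ_m < δ_C < δ_T
(complexed mRNA decays faster, the triplex fastest), δ_R, δ_P; translation
`k_p·m`. When a complex degrades the mRNA is destroyed and the miRNAs are
recycled (catalytic miRNA action; config switch `recycle_mirna`).

Rates derive from the folding energies by detailed balance at fixed
association rate `k_on`:

    dᵢ  = k_on · ρ₀ · exp(ΔG_duplexᵢ / RT)
    d₁₂ = k_on · ρ₀ · exp((ΔG_triplex − ΔG_duplex₂) / RT)   (miR2 stays bound)
    d₂₁ = k_on · ρ₀ · exp((ΔG_triplex − ΔG_duplex₁) / RT)

with ΔG/RT clamped at ±60 to keep rates finite (a warning is emitted).

Defaults (package configuration, with units):
`k_on = 10⁻³ nM⁻¹s⁻¹`, `k_m = 10⁻³ nM/s` (free-mRNA baseline 10 nM),
`k₁ = k₂ = 10⁻⁵ nM/s`, `δ_m = 10⁻⁴`, `δ_R = 10⁻⁵`, `δ_C = 2×10⁻⁴`,
`δ_T = 4×10⁻⁴`, `k_p = 10⁻³`, `δ_P = 10⁻⁴ s⁻¹`. With recycling, free miRNA
settles at `TFᵢ·kᵢ/δ_R ≈ TFᵢ nM`, placing the physiological expression range
TF ∈ [0.1, 100] squarely in the dynamic range of duplex dissociation
constants of a few to a few thousand nM. This is the regime where the
energy dependence of cooperativity is expressed: a triplex assembled from
individually weak duplexes but with a large |ΔΔG| represses
disproportionately when both miRNAs are modestly up-regulated
(RG₃ > max(RG₁, RG₂)), while energetically shallow triplexes show only
additive behavior. At the opposite extreme — duplex dissociation constants
many orders of magnitude below free-miRNA levels — every channel saturates
and single miRNAs already silence the target, so no synergy can be
expressed regardless of the triplex energy; the toy pipeline's perfectly
complementary plants land in this regime and are reported `additive`.

Steady states are normalized by the miRNA-free model (TF₁ = TF₂ = 0), so
SS ∈ [0, 1] with SS = 1 meaning no repression. Two independent solvers are
implemented and cross-checked to 10⁻⁶ relative: a Newton root-solve of the
algebraic system (`scipy.optimize.root`, warm-started, residual verified
against the synthesis scale) and stiff ODE integration (`solve_ivp`/BDF to
50 times the slowest decay time, then a Newton polish). Repression gains
are reported in the positive-gain convention RG = SS(1,1) − SS(point), so
larger gains mean stronger repression; the literal sign convention
(SS(point) − SS(1,1)) is available behind a flag.

## Synthetic data

`generate_toy_dataset` plants triplexes with known ground truth: two pool
miRNAs whose seed complements (reverse complement of nucleotides 2–8) are
embedded in a uniform-random UTR at an exact seed distance, with
`complementarity_level` scaling how many 3′ nucleotides beyond the seed are
also complementary (up to 12; the downstream site's 3′ extension is capped
by the inter-site gap so plants never overlap). Planted sites carry
mirSVR = −0.5 and PhastCons = 0.9, passing default filters. Background
sequence is rejection-sampled so no accidental 7-mer seed complement of a
planted miRNA occurs within the pairing window (±25 nt); identical seeds
give byte-identical outputs.

What the generator does **not** emulate: realistic UTR base composition and
length distributions, imperfect seed matches (G·U seeds, bulged seeds),
overlapping or nested site annotations from real predictors, conservation
structure, and competing miRNAs at distant sites. Passing the recovery
tests therefore demonstrates the pipeline's bookkeeping and boundary
behavior — not predictive accuracy on real transcriptomes, which is bounded
by the upstream site predictor and by the reduced energy model.

## Numerical conventions and degenerate inputs

- On-disk coordinates 1-based inclusive; in-memory 0-based half-open.
- DNA input is tolerated everywhere (T→U on read); non-ACGU symbols are
  errors naming the offending character.
- Empty strands, >3 strands, or total length > 2000 nt are folding errors;
  enumeration refuses totals > 30.
- `tfe_cutoff` requires ≥ 2 values for Z > 0; equal values give sd = 0 and
  the common value as cutoff.
- Degradation-free kinetic models are rejected (all rate constants must be
  positive at construction; zero association rates are permitted to express
  "no binding" models).
- Equilibrium non-convergence after Newton + bisection raises a numerical
  error carrying the residuals; this is unreachable for the declared
  heterotrimer set in double precision as far as testing shows.

## Known limitations

- Absolute free energies are not comparable to full thermodynamic engines;
  only threshold-relative decisions are meaningful.
- MFE energies stand in for partition-function ensemble energies in the
  equilibrium step.
- Site accessibility in the full-length UTR is ignored (only the enclosing
  window is folded).
- The kinetic rate mapping compresses all binding kinetics into a single
  `k_on`; AGO loading, RISC concentration and transcript competition are
  not modeled.
- The stability-time rule consumes externally produced summaries; nothing
  validates how those times were measured.
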