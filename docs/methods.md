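# Methods

## Ensemble definition

A structure is a set of base pairs (i, j), drawn from the canonical
alphabet AU, UA, GC, CG, GU, UG, subject to:

* at most one partner per position;
* hairpin loops of at least 3 unpaired nucleotides;
* every pair belongs to a maximal run ("helix") of at least 2 stacked
  pairs. An isolated canonical pair carries no stack term in a purely
  nearest-neighbor energy, so lonely pairs are excluded from structures
  and instead re-enter the model as intra-loop mismatches (below);
* pairs either nest, or — in the pseudoknot modes — form exactly one
  H-type pseudoknot: two crossing helices with three connecting loops,
  with any further structure strictly 5' or 3' of the pseudoknotted
  span. Recursive and multiple pseudoknots are out of scope. The
  `junction1` mode restricts the inter-helix junction to ≤ 1 nt; the
  `any` mode allows any junction length and is capped at N ≤ 60 by
  default because the two-stem geometry enumeration grows steeply.

The partition function is relative to the open chain (weight 1), so
Q ≥ 1 and all probabilities are equilibrium populations.

## Energy model

**Stacks.** Two embedded nearest-neighbor dialects supply ΔH and ΔS per
stack of two adjacent pairs; ΔG(T) = ΔH − T·ΔS with R = 1.987×10⁻³
kcal/(mol·K) and T in kelvin (°C + 273.15 exactly). ΔS values are
derived once from published (ΔH, ΔG37) pairs via ΔS = (ΔH − ΔG37)/310.15,
which makes the 37 °C reconstruction exact by construction. A stack key
and its strand-rotated reading are the same physical stack and share one
table entry; both dialects cover all 21 rotation-distinct canonical
stacks. ΔH and ΔS are treated as temperature-independent (no ΔCp), and
dangling ends and coaxial stacking are not modelled.

**Loop entropies.** The backbone is coarse-grained to two virtual bonds
per nucleotide and embedded on the diamond lattice (coordination 4,
109.5° bond angles, matching the P–C4'–P virtual-bond geometry of
A-form RNA). A base pair occupies two vertices separated by a fixed
pair vector; successive pairs of a helix translate by a fixed axis
vector; one extra stacked pair of each closing helix is kept as excluded
volume. A strand of k unpaired nucleotides between two anchors is a
self-avoiding walk of 2(k+1) bonds. Then

    ΔS_loop / R = ln(Ω_closed / Ω_open),

where Ω_closed counts the walks satisfying the closure (joint
enumeration with mutual avoidance for two-strand loops) and Ω_open the
free chains of equal length (product over strands). Entropies are
stored in units of R and converted to kcal/(mol·K) only inside free
energies. These closure templates are a declared canonical stand-in for
full helix geometry: the counts are exact for the stated model, and all
downstream contracts depend only on counts → entropies.

The shipped table (`data/loop_entropy.tsv`, regenerated byte-identically
by `scripts/build_loop_table.py`) enumerates hairpins to L = 10,
internal/bulge loops to total size 8, and pseudoknot strands (length l
bridging a helix of `span` pairs, the helix's vertices excluded) for
spans 1–4, l ≤ 8. The cap of 10 nt reflects the exponential cost of
exact enumeration on this lattice (L = 12 would need ~10¹¹-node
searches); it is configurable. Beyond the cap, the Jacobson–Stockmayer
closure form ΔS = a − c·ln L is fitted per loop family (the pseudoknot
family uses a surface in ln(l+1) and span); extrapolated entries are
marked as such in the table. The fitted hairpin closure exponent is
c ≈ 1.53, consistent with self-avoiding-walk closure scaling
(c = 3ν − h corrections ~ 1.5–2). A pseudoknot strand shorter than the
helix it must bridge is geometrically unformable and receives zero
weight (ΔG = +∞); this reproduces the steric loop-span constraints of
H-type pseudoknots without ad hoc rules.

**Intra-loop mismatches.** Every hairpin and internal/bulge loop is
summed over its conformational substates: the plain loop plus every
admissible placement of one intra-loop pair ("mismatch") drawn from the
canonical alphabet. A mismatch pinned to the pair template splits the
loop into two sub-loops whose entropies add (cross-sub-loop excluded
volume neglected — loop additivity at the constraint); a mismatch
stacked directly on a closing pair also gains that stack's ΔG. A
substate whose mismatch would simply extend a closing helix on both
sides is excluded — that state already exists in the ensemble as the
longer helix. Mismatch-closed sub-loops observe the minimum hairpin
size. Effective loop free energy: ΔG_loop = −RT·ln Σ_substates
exp(−ΔG_substate/RT). Mismatches are not applied inside multiloops or
pseudoknot loops.

**Multiloops.** Junction loops are scored with the extrapolated closure
form applied to the total unpaired length (floored at 1 for the
logarithm) plus a branch penalty of 0.1 kcal/mol per participating helix
— an acknowledged approximation, since no exact multiloop enumeration is
tabulated.

**Pseudoknots.** An H-type configuration's weight is the product of its
two stems' stack weights and exp(ΔS₁ + ΔS₂ + ΔS₃), the entropies of:
loop 1 bridging stem 2, loop 3 bridging stem 1 (each from the
span-closure table), and the junction (span-1 template). Treating the
three strands as independently closed is itself an approximation; loop
entropies of interlocked motifs are not strictly additive, and requests
beyond the enumerated spans are logged as such.

## Algorithms

**Production.** The nested ensemble is computed by an interval dynamic
program over candidate helices (all maximal-run prefixes of length ≥ 2):
closed-helix weights combine stacks with the enclosed region's weight
(hairpin, internal/bulge to one inner helix, or a multiloop filling
tracked by branch count and unpaired count, so the non-local multiloop
entropy is exact within the stated form). Zero-gap "internal loops" are
excluded everywhere, which makes each pair set correspond to exactly one
decomposition (helix runs are maximal). Pseudoknots are added by direct
enumeration over crossing helix pairs times the nested weights of the
flanking regions.

Base-pair probabilities come from the same recursion run over
first-order jet (value, gradient) weights: Q is a polynomial in one
formal weight x_h per candidate helix, and x_h·∂Q/∂x_h at x = 1 is the
total weight of structures containing h. This replaces a separate
outside recursion and is exact to floating-point rounding. Melting
scans reuse the scalar (value-only) recursion per grid temperature.

**Oracle.** `exhaustive_oracle` (N ≤ 25) generates every admissible
structure by explicit recursion, scores each with
`structure_free_energy` — an independent decomposition of the pair set
into runs and loops — and sums weights directly. The production DP
matches it to < 10⁻⁹ relative error in Q and < 10⁻⁹ absolute in every
P_ij over 200 random sequences across both dialects and all three
pseudoknot modes (machine precision in practice).

**Heat capacity.** C(T) = R·(2·T_k·g₁ + T_k²·g₂) with g₁, g₂ the central
first and second differences of lnQ on the uniform grid; one point is
lost at each boundary. C is the excess heat capacity per mole of strand,
open chain as baseline. Peaks are strict local maxima with prominence
≥ 5 % of max C (scipy peak finding). On a synthetic two-state system the
peak sits within one 0.5 °C step of the closed-form Tm = ΔH/ΔS and the
integrated C over the transition recovers |ΔH| within 5 %.

**Structure calls.** The dominant structure is the set of pairs with
P_ij > 0.5 (strict). Helices are reported as maximal runs of
non-negligible pairs with probability = mean P_ij over the run.
Alternatives group mutually compatible helices whose probabilities agree
within a level tolerance (default 0.15), on the premise that pairs of
one structure share a common formation probability; sets already inside
the dominant call are not re-reported.

## Motif decomposition

A 2D structure decomposes uniquely into helices, hairpin loops,
internal/bulge loops, N-way junctions (branch count = helices meeting
the loop), one pseudoknot motif for a crossing stem pair, and open
motifs: 5'/3' single-stranded tails and strands connecting helices that
share no closing pair (including the zero-length strand between tandem
helices — coaxial stacking is not inferred, as that requires 3D
knowledge). Template-based 3D assembly supports all closed motif kinds
and junctions with 3–7 branches; open motifs have no templates, so any
structure containing one is reported ineligible, with the recommendation
to trim single-stranded tails first.

## Synthetic fixtures and what they show

The generators are deterministic (sizes, and a seed for random
sequences, fully determine the output):

* **hairpin** — a GC stem-loop; used for single-transition melting and
  high-temperature limits.
* **bistable (symmetric)** — `G⁴ A³ C⁴ A³ G⁴`, a literal palindrome whose
  two mutually exclusive helices are exactly equivalent; the ensemble
  must assign them equal probabilities (observed equal to ~10⁻¹²).
* **bistable (melting study)** — a 41-nt sequence with a 5-bp GC-rich
  anchor hairpin and two mutually exclusive 6-bp AU-rich helices sharing
  one block, biased by asymmetric loop sizes (3 vs 5 nt). The AU arms
  were chosen so both transitions fall inside the standard 0–100 °C
  window — long enough (|ΔH| ≈ 35 kcal/mol) to give a sharp,
  resolvable low-temperature peak, AU-rich so that peak sits well below
  the anchor's. At 37 °C it yields a dominant structure at level ≈ 0.78
  and one alternative at ≈ 0.31, and exactly two heat-capacity peaks
  (≈ 58 °C and ≈ 88 °C) ordered by helix stability.
* **pseudoknot** — a toy H-type with two crossing GC stems sized to be
  lattice-formable.
* **random** — seeded uniform sequences for ensemble stress tests.

These fixtures exercise the model's bookkeeping and thermodynamic laws;
they do not establish accuracy on natural RNAs, whose loops carry
non-canonical pairs, modified bases and tertiary contacts outside this
model, and whose stack parameters carry experimental uncertainty.

## Numerical notes and limitations

* Determinism throughout: no randomness outside the seeded fixture
  generator; iteration orders are index-fixed; writers emit fixed
  formats (probabilities to 4 decimals, energies to 2), so identical
  inputs give byte-identical outputs.
* Boltzmann weights are computed unscaled in double precision; very
  long, very stable GC-rich chains (|ΔG| ≳ 400 kcal/mol) would overflow
  before the 140-nt input limit matters in practice.
* The gradient DP costs O(H) memory per cell (H = candidate helices);
  pair probabilities are practical to N ≈ 60–80, melting scans (scalar)
  well beyond.
* The GU-wobble and older-dialect stack literals are embedded
  best-effort values of the standard compilations; the package's
  invariants (rotation symmetry, 37 °C self-consistency, dialect
  distinctness) are tested, individual literal accuracy is not
  load-bearing for any test.
* C(T) is reported per mole of strand; no absolute heat-capacity
  baseline, no ionic-strength dependence, no UV-absorbance simulation.
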