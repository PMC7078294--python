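# Methods

## The Protein Blocks model

Protein Blocks (PBs) are a structural alphabet of 16 local backbone
prototypes, letters *a*–*p*. Each prototype is an 8-vector of dihedral
angles over five consecutive residues, in the column order
ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2), in degrees.
*m* is the central α-helix prototype and *d* the central β-strand; *a*–*c*
cap strand N-termini, *e*–*f* strand C-termini, *g*–*j* are coil-like,
*k*–*l* helix N-caps and *n*–*p* helix C-caps. The canonical 16×8 table is
embedded in `pb_assignment` and validated at load time by the
self-assignment identity: assigning each prototype's own vector must
return that prototype's letter, 16 distinct letters in total.

A position *i* is assigned the letter whose prototype minimizes

RMSDA(v, w) = sqrt( (1/8) Σₖ d(vₖ, wₖ)² ),

where d wraps the angular difference into (−180°, 180°]. Ties (measure
zero on real data) resolve to the alphabetically first letter, making
assignment deterministic. Positions without a complete window — the first
two and last two residues of every continuous segment, and any window
containing an undefined angle — are labelled `Z`. Z-padding is applied
per segment, not per chain: a chain break makes windows spanning it
geometrically meaningless, so each continuous segment contributes its own
two leading and two trailing `Z`, and segments shorter than five residues
are entirely `Z`. There is no "too many incomplete residues" heuristic:
the deterministic window rule (any undefined component ⇒ `Z`) reproduces
the degeneration of heavily incomplete models into `Z` stretches as an
emergent consequence.

## Dihedral geometry

φ(i) = torsion(C(i−1), N(i), CA(i), C(i)) and
ψ(i) = torsion(N(i), CA(i), C(i), N(i+1)), IUPAC sign convention
(cis = 0°), degrees on (−180°, 180°]. Undefined values are represented as
NaN and never raise: missing atoms, segment termini and residues adjacent
to breaks all propagate NaN into the affected angles. A chain break is
declared when the C(i)–N(i+1) distance exceeds 2.5 Å (a formed peptide
bond is ≈1.33 Å; 2.5 Å tolerates poorly refined models while rejecting
real gaps) or when author numbering jumps with no insertion codes.

## Neq

With per-position PB frequencies fₓ = countₓ / n_assigned (x over the 16
letters; `Z` observations are "not assigned" and excluded from both
numerator and denominator, never a 17th state),

Neq = exp(−Σₓ fₓ ln fₓ),  1 ≤ Neq ≤ 16,

with natural logarithm and the explicit convention 0·ln 0 = 0
(implemented by masking zero frequencies, not by floating-point
accident), so the degenerate distribution gives exactly 1 and the uniform
distribution exactly 16. Positions never assigned in any model have
undefined Neq, are labelled `unassigned`, and are excluded from the
ensemble mean.

Continuum labels are a thresholding of Neq: rigid below `t_rigid`,
disordered at or above `t_disorder`, flexible between. The cut-offs are
deliberately configuration, not library constants; the shipped template
documents defaults t_rigid = 1.5 and t_disorder = 5.0. The rigid cut sits
halfway between one and two equivalent states so that a genuine
two-conformation position — whose finite-sample Neq estimate is slightly
*below* 2 (see the bias note below) — is never mislabelled rigid.

## Ensemble cleaning

Deposited ensembles are normalized before any geometry: alternate
locations resolve to the highest-occupancy atom (ties to the
alphabetically first altloc), residues are re-sorted by (author number,
insertion code), breaks are annotated, and models whose residue key
sequence or chain set disagrees with the majority of models are dropped
(or, optionally, rejected with an error). If no majority exists the
ensemble is unrecoverable. Every action is recorded in a report written
as a plain-text log plus a TSV table, so offline cleaning becomes
auditable; model count is conserved (kept + dropped = input) and cleaning
is idempotent. Waters and HETATM records are discarded except
selenomethionine (MSE), which is analysed as MET; unrecognized ATOM
residue names are kept with identity `UNK` so tagged constructs stay
parseable. Parsing and writing go through gemmi; a fixed-column validator
runs first so that malformed coordinate records fail loudly with their
line number instead of being silently zeroed.

## Synthetic ensemble generator

The generator emulates the one feature the pipeline measures — controlled
per-position conformational heterogeneity — and nothing else. A chain is
tiled by regions; each region lists conformational basins (PB letters)
with mixture weights and a von Mises noise concentration κ per angle
(default κ = 1600, i.e. ≈1.4° angular spread; κ = ∞ disables noise).
Backbones are built from internal coordinates (NeRF) with fixed standard
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, bond angles
111.2°/116.2°/121.7°, ω fixed trans at 180°), and the construction is
exact: recomputing φ/ψ from the built coordinates reproduces the sampled
values to floating-point precision. A single seeded random stream makes
every fixture byte-reproducible.

Two design points deserve explanation:

**Stretch centres, not prototype centres.** A basin must be a (φ, ψ)
pair such that a *homogeneous* stretch built at that pair assigns to the
intended letter. The prototype table's own central columns do not have
this property: most PBs describe locally non-repetitive conformations,
and repeating their central pair collapses onto only 4 distinct letters.
Basins therefore use per-letter "stretch centres", found by scanning the
(φ, ψ) torus for the point whose repeated window maximizes the RMSDA
margin between the intended letter and the runner-up. Thirteen letters
are stretch-realizable at all; the eight with margin ≥ 4°
(a, c, d, e, g, m, n, o) are exposed, which is exactly what a disordered
region needs to present eight distinguishable states. At the default κ
the measured misassignment rate at every centre is below 10⁻⁴.

**Region-coherent basin draws.** By default each model draws one basin
per region and holds it across the region (noise stays independent per
angle). Per-position independent draws are available
(`sampling="position"`) but are not the default because assignment
windows overlap five residues: with independent draws the letter observed
at a position is a convolution over the basins of its neighbours, not the
specified mixture. Region-coherent draws realize the specified
per-position letter *marginals* exactly, at the cost of perfect
correlation along the region within one model. Neq is a per-position
functional of the marginals, so this is the faithful construction for
testing it.

What the generator does **not** emulate: side chains, sterics, excluded
volume, radius-of-gyration or scattering restraints, cis-prolines,
realistic along-chain decorrelation of real IDP ensembles. Passing tests
therefore demonstrate the correctness of the measurement pipeline on
ensembles with known letter statistics, not the physical realism of
those ensembles.

## Statistical validation of Neq recovery

The end-to-end test generates a 2,000-model ensemble with a rigid region
(1 basin), a flexible region (2 equal basins) and a disordered region
(8 equal basins), runs the full file-level pipeline (write PDB → read →
clean → assign → profile) and compares per-region mean Neq against 1, 2
and 8 over the region interiors (positions whose full window lies inside
the region; boundary windows mix neighbouring regions and carry no
clean expectation). The comparison uses bootstrap inference over models:
the plug-in estimator exp(Ĥ) is biased downward by a factor
≈ exp(−(k−1)/2n) for k occupied states and n models, which at a uniform
mixture is the *same order* as its sampling error, so the test compares
the bootstrap bias-corrected estimate (2·θ̂ − mean of bootstrap
replicates, 200 replicates) within three bootstrap standard errors.
`ensemble_profile.bootstrap_mean_neq` exposes estimate, corrected value
and standard error for this purpose.

Problem sizes used by the test suite: 2,000 models × 30 residues for the
statistical recovery test, 50 × 30 for pipeline unit tests, a 20°-step
(φ, ψ) grid (324 pairs) for the dihedral round-trip, and 1,000 random
inputs for each brute-force oracle comparison.

## Numerical conventions

- Angles in degrees everywhere; wrap into (−180°, 180]° with −180° mapped
  to +180°.
- Torsion computation rejects coincident consecutive points and collinear
  triples (GeometryError) rather than returning garbage; inside
  `compute_phi_psi` such degeneracies become NaN.
- Frequency vectors passed to `neq` must sum to 1 within 1e−9.
- Internal indexing is 0-based half-open; emitted tables use 1-based
  sequential positions alongside author residue numbers.
- File formats: `.PB.fasta` (one record per model, header
  `>{entry} | model {n} | chain {c}`), `.PB.count` (whitespace-delimited,
  header `position a b c … p n_assigned`; `Z` is not a column —
  `n_assigned` carries that information), `.PB.Neq` (header
  `position Neq`, 4 decimals, `NA` when unassigned). Multi-chain entries
  insert `-chain{C}` before the extension.

## Known limitations

- No mmCIF input; no reconstruction of missing atoms; hydrogens ignored.
- ω is never validated; cis-peptides are assigned like any other window.
- The PB logo uses glyph heights proportional to frequency (not
  information content); its exact styling is semantic, not a pixel-level
  reproduction of any particular figure set.
- Disorder/rigidity labels depend entirely on the user-supplied
  thresholds; the defaults are documented choices, not community
  standards.
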