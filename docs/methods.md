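# Methods

This note records the models, conventions, numerical choices and known
limitations behind `pepfunnel`, in the order the pipeline runs.

## Template and numbering

Sequences use the GLP-1 convention in which the mature peptide spans
positions 7–37: residue *i* of a record sits at template position
`numbering_start + i`, with `numbering_start` defaulting to 7 (a FASTA
header key `start=` overrides it).  The bundled design template is the
Semaglutide peptide backbone: GLP-1(7–37), 31 residues, with Aib at
position 8 and Arg at position 34.  The fatty-acid conjugation at Lys26
is carried as an annotation string only; its chemistry is out of scope.

Thirteen template positions are anchored (7H, 8Aib, 9E, 10G, 11T, 12F,
13T, 14S, 15D, 17S, 26K, 34R, 37G): nine are highly conserved across
GLP-1 analogs, and 8Aib, 26K and 34R are Semaglutide-specific choices.
The design mask is the exact partition of the 31 positions into these 13
fixed and the remaining 18 designable positions.

**Token matching policy.**  Aib is a registered extended token serialized
as `[Aib]` in FASTA.  For sequence recovery and alignment identity it
matches both Aib and Ala: design tools emit canonical residues and
biosynthesized constructs substitute Ala at position 8, yet both are
scored against the Aib-containing template, and the template scored
against itself must give exactly 1.  Recovery uses the template length
(31) as denominator and is reported rounded half-up to two decimals
(e.g. 25 matches / 31 → 0.81).

**Conservation.**  Per-column conservation of an input alignment is the
majority fraction by default (gaps excluded from counts), with Shannon
entropy in bits as an alternative for sensitivity analysis.  No single
conservation threshold reproduces a given anchor set exactly — anchor
lists legitimately mix conservation evidence with template-specific
choices — so thresholds are configurable and anchors are always unioned
into the selected set.

## Stability gate

**Cleavage scanning.**  The six NEP-24.11 scissile dipeptides of
GLP-1(7–37) are template-numbered P1–P1′ rules (15/16, 18/19, 19/20,
27/28, 28/29, 31/32).  The default scan mode checks each rule only at
its template position, matching the enzyme-mapping convention in which
the sites are named by residue numbers; `motif_scan` additionally flags
the dipeptide anywhere in the sequence and is documented as stricter
(designed sequences can relocate motifs).  The default cap is zero
sites — the one stability cutoff that is categorical rather than
tunable.

**Physicochemical descriptors.**  Net charge is the Henderson–
Hasselbalch sum (basic groups `1/(1+10^(pH−pKa))`, acidic groups
`−1/(1+10^(pKa−pH))`, free termini included) with EMBOSS-style pKa
values (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
C 8.5, Y 10.1), evaluated at pH 7.4 by default.  Any fixed published set
keeps the computation deterministic; the table is injectable.  The
isoelectric point is the bisection root of the strictly decreasing
charge curve on (0, 14), iterated to 1e-4 pH so the charge residual
stays small even for steep multi-group curves; peptides lacking a sign
change (e.g. with a blocked terminus modeled through the pKa table)
have no pI and report it as missing.  Hydropathy is the Kyte–Doolittle
mean per residue; helix propensity is the negated per-residue
helix-formation free energy (kcal/mol, Ala = 0 at the top, Pro
strongly negative), so a *minimum* bound is natural.  Aib maps to Ala's
value on both scales.  Numeric bounds for charge, hydropathy, helicity
and the pI window default to report-only: no published cutoffs exist
for them, so rejecting on library defaults would be arbitrary.

## Efficacy gate

**Superposition.**  Kabsch superposition via SVD with the reflection
correction (determinant forced to +1); the RMSD it minimizes is
cross-checked in the tests against an independent quaternion-eigenvalue
implementation at 1e-8.

**TM-score.**  `(1/L) Σ 1/(1+(d_i/d0)²)` with
`d0 = 1.24·(L−15)^(1/3) − 1.8`, clamped below at 0.5 Å for short
peptides (at L = 31, d0 ≈ 1.325 Å, so the clamp is inactive for the
default template).  The superposition is optimized by iterative Kabsch
reweighting — start from the all-pair superposition, repeatedly
re-superpose on the pairs closer than d0, keep the best score, stop at
a fixed point or 20 rounds.  A fragment-search alignment (TM-align
style) is unnecessary here because candidate and reference residues are
in fixed one-to-one correspondence through template numbering; this is
a deliberate deviation from the reference TM-score implementation and
is exact whenever the correspondence is known.

**Pairing convention.**  TM-score and RMSD are computed on the agonist
chain.  When the receptor chain is present in both models, its frame
anchors the RMSD superposition (shared-receptor convention: the metric
then reflects agonist placement in the binding site); otherwise the
agonist pairs themselves are superposed.

**SASA.**  Shrake–Rupley sphere sampling with a deterministic
golden-spiral point set (256 points per atom by default, no RNG, so
results are bit-reproducible), probe radius 1.4 Å, element van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20; unknown elements
fall back to 1.8 Å).  Neighbor search is restricted to atoms within
`r_i + r_j + 2·probe`.  Tests pin the isolated-atom area to the
closed-form sphere within 2% and the 256→960-point refinement to under
3% per atom.

**SAP.**  Per residue r, SAP sums over every side-chain atom j of the
structure within 5.0 Å of any atom of r the atom's exposure fraction
(SASA_j over the fully exposed side-chain reference of its residue
type, Gly-X-Gly context) times the residue-type hydrophobicity
(Black–Mould-style, normalized and shifted so Gly = 0, hydrophilic
residues negative).  The aggregate is `Σ_r max(SAP_r, 0)`: only
aggregation-prone patches accumulate.  Because spatial neighborhoods
overlap, an exposed atom can contribute to several residues'
neighborhood sums — that is the intended reading of a spatial
smoothing, not double counting of area.  Radius, scales and reference
areas are all injectable.

**Confidence metrics.**  Per-residue pLDDT is read from the Cα B-factor
column (the structure-predictor convention); chain mean pLDDT averages
residues with a value.  Interface pAE is the plain mean over both
inter-chain blocks of the predicted-aligned-error matrix, each entry
weighted equally; both the bare-object and list-wrapped PAE JSON
dialects are accepted, with the chain index map supplied by the caller
(chain lengths), since PAE files do not carry it.

**Thresholds.**  Derived from the reference complex scored against
itself: lower bounds scale by (1 − slack), upper bounds by (1 + slack),
slack defaulting to 0.1.  The RMSD bound is floored at 0.5 Å before
applying slack because the reference's self-RMSD is zero and a pure
ratio bound would collapse.  Binding affinity enters only as an
ingested external score with an optional cap.

## Diversity gate

Distances are `1 − identity` from pairwise Needleman–Wunsch global
alignments (linear gap penalty, match 1 / mismatch 0 under the token
policy; identity = identical aligned columns over alignment length).
Traceback ties break deterministically diagonal → up → left.  A Poisson
multiple-hit correction (`−ln(1−p)`) is available but off by default:
at these identity ranges the correction changes rankings, not clusters.

The tree is built by neighbor joining with two determinism guarantees:
Q-matrix ties select the lexicographically lowest pair of cluster
labels, and negative branch lengths are clamped to zero with the
deficit moved to the sibling branch (preserving the pair's path-length
sum).  The final three clusters join at a trifurcating root by the
three-point formulas.  NJ replaces maximum-likelihood tree inference
deliberately: the tree's only role here is clustering and
representative selection, NJ is exactly reproducible, and it recovers
any additive metric without error (property-tested at 1e-9).  Published
leaf-to-leaf distances obtained with ML trees are therefore not
comparable numbers and are not reproduced.

Cluster cutting removes edges greedily in order of decreasing branch
length (ties by canonical preorder), skipping removals that do not
separate leaf components, until exactly *k* leaf clusters exist.  This
greedy-effective reading — rather than "remove the k−1 longest internal
edges" literally — is required for the boundary case *k = n*
(singletons), which leaf-edge-excluding removals can never reach, and
it makes cuts nested in *k*.  One representative is kept per cluster:
highest template recovery by default (ties to the lexicographically
smallest id), with medoid and first-id rules as alternatives.  The
patent gate fails a candidate when its alignment identity to the
reference drug *reaches* the cap (`identity ≥ cap`, so the reference
itself fails even at cap 1.0); the default cap of 0.90 is a
placeholder — real patent thresholds are jurisdiction-specific and
should be configured explicitly.

## Funnel accounting

Stages run in the order dedupe → stability → efficacy → diversity by
default (configurable).  Deduplication keeps the first occurrence of
each distinct token sequence.  Every stage satisfies
`entering = passing + failing` with per-candidate failure reasons, and
the report serializes deterministically (sorted keys, stable column
order), so a seeded campaign is byte-reproducible end to end.  Missing
structural scores in a configured efficacy stage raise in strict mode
(default); lenient mode tags the candidates `not_evaluated` and passes
them through with the annotation, which inflates downstream
denominators and is therefore opt-in.

The in-vitro bookkeeping treats assay outcomes as data, never
recomputing them: relative expression is the band-density ratio of a
fusion peptide to the reference (values above 1 are legitimate); the
expression filter applies strictly-less-than at the threshold, so a
candidate sitting exactly at 0.70 proceeds — the boundary policy is
pinned by the bundled campaign table, where the at-threshold candidate
is retained and exactly five fall below.

## Synthetic data

The generator emulates the *shape* of real campaign inputs, not their
statistics.  Candidate sequences are position-independent draws at the
designable positions (anchored positions always carry template
residues), with an exact duplicate fraction realized by resampling
earlier outputs and optional installation of scissile dipeptides at
their template positions.  `MOTIF_FREE_ALPHABET` excludes every P1′
residue (V, Y, L, F, I), guaranteeing zero cleavage hits for unspiked
candidates — useful for constructing campaigns with known pass counts.
A real design model's outputs are position-dependent and
structure-conditioned; passing tests on synthetic campaigns therefore
demonstrates pipeline correctness (counting, gating, determinism), not
biological realism of the gate thresholds.

Ideal α-helices are built by sequential internal-coordinate (NeRF)
construction with canonical stereochemistry (φ = −57°, ψ = −47°,
ω = 180°; N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å), backbone N/Cα/C/O
plus Cβ for non-Gly residues, pLDDT initialized to 100.  The synthetic
"receptor" is a second helix offset by 9 Å — enough for a defined
interface, with no pretense of receptor realism.  Gaussian coordinate
perturbation (seeded) provides RMSD/TM test pairs; mock confidence
files carry separable intra-/inter-chain PAE levels and per-chain pLDDT
means, exact when noise is zero.

## Problem sizes and determinism

All randomness flows through explicitly seeded NumPy generators; no
global RNG state is touched.  Test campaigns use 30–500 candidates and
end-to-end byte-identity runs at 120 candidates — sizes at which the
pure-Python pairwise alignment stage (O(n²) alignments of O(L²) each)
completes in seconds while still exercising every stage transition.
The full suite targets well under five minutes on one CPU.

## Known limitations

* No structure prediction, MD or affinity computation: predicted
  complexes, PAE files and affinity scores are inputs.
* Pairwise global alignment only; multiple alignments are inputs, and
  the star-alignment route through the template is the supported way to
  compare unequal-length references.
* NJ clustering is not ML phylogenetics; branch supports and
  model-based distances are out of scope.
* The SAP reference areas and hydrophobicity scale are one published
  convention among several; absolute SAP values are convention-dependent
  and should be compared only within a fixed parameter set.
* Kinetic proteolysis, AGADIR-style helicity and solubility prediction
  beyond the shipped descriptors are out of scope.
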