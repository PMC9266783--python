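# Methods

`confswitch` reconstructs, at desk scale, a mutation-based strategy for
steering a structure predictor toward alternative conformations of
rocker-switch membrane transporters (the MFS fold: 12 TM helices in two
six-helix bundles, N- and C-terminal domains, joined by an intracellular
linker). This note records the models, the parameters that matter, the
numerical choices, and what the synthetic fixtures do and do not show.

## The design model

Alternating access means the two domains pivot around the substrate site:
the inward-facing state opens a cytoplasmic cavity and seals the
periplasmic gate; the outward-facing state is the mirror image; the
occluded state seals both. The design rule exploits this symmetry: to bias
prediction toward the **inward** state, small-side-chain residues
(G, A, S, C, V, T — side chains of ≤ 3 heavy atoms; proline excluded) at
the **periplasmic** end of the N/C interface are substituted with
tryptophan; for the **outward** state the cytoplasmic end is used.
Replacing the smallest side chains with the bulkiest one maximises the
steric perturbation per site while leaving the backbone untouched.

Candidates come from inter-domain contacts (minimum heavy-atom distance,
default cutoff 4.5 Å; the contact's side label is taken from the midpoint
of its closest atom pair against the membrane frame). One practical
subtlety: the side being mutated is typically the *open* mouth of the
starting model — that is exactly why the other conformation is being
sought — so no 4.5 Å cross-domain contacts exist there. The candidate pool
therefore widens the contact cutoff stepwise (4.5 → 6 → 8 → 12 → 16 Å)
until enough small candidates line the target mouth, and as a last resort
widens the small-residue set to ≤ 4 heavy atoms (N, D, I, L). Every
escalation is logged. Ranking is fully deterministic: coevolution support
first, then contact count, then contact distance, then residue number.

Redesign rounds mirror practice with real predictors: a round that yields
no obvious conformational change adds one site (keeping the previous
ones); when the pool is exhausted the coevolution threshold is relaxed
once from 0.8 to 0.6 before the design fails. The initial plan has three
sites — the modal number at which transporters switch — and the pipeline
caps escalation at 8 rounds.

## Covariation scoring

Residue–residue coupling is scored by weighted mutual information with the
average product correction, a deliberate stand-in for a Potts-model
(GREMLIN-style) fit: it is dependency-free, fast at alignment sizes of a
few hundred rows, and sufficient for the qualitative claim the design
needs (coevolving pairs concentrate at the domain interface). A
pre-computed external pair table (TSV `i j prob`) can be imported
wherever the internal scorer would run.

Pipeline: rows with coverage < 70% or gaps > 75% are removed (the query is
always kept); surviving rows are down-weighted by redundancy
(w = 1/#{rows ≥ 80% identical}); joint 21-state (20 AA + gap) frequency
tables receive a uniform pseudocount (default 1.0 spread over the 441
cells) so marginals stay consistent; columns with > 75% gaps are masked
out of pair scoring; MI is computed in nats for pairs separated by ≥ 6
positions (closer pairs are trivially coupled through the helix); APC
subtracts the product of positional means over the mean coupling. The
reported `prob` is the logistic transform of the APC z-score — a rank-
preserving map onto [0, 1]. It is **not** a calibrated probability;
thresholds such as 0.8/0.9 refer to this scale.

## Topology annotation

The membrane normal is estimated from chain geometry, not from an external
membrane-positioning service. A plain principal component of the Cα cloud
fails on this fold — the two bundles make it wider than it is tall, so the
largest-variance axis lies in the membrane plane. Instead the normal is
the principal eigenvector of the orientation tensor of local segment
vectors Cα(i)→Cα(i+6), which align with the TM helices whatever the
aspect ratio; one refinement pass restricts the tensor and the slab centre
to hydrophobic residues inside the provisional slab (half-thickness
default 15 Å, the standard bilayer half-width; valid range 10–25 Å). The
frame can be overridden or flipped from the CLI for difficult cases.

TM helices are maximal runs of ≥ 15 consecutive in-slab residues whose
Cα(i)→Cα(i+3) distances are helical (within [4.5, 6.0] Å, ideal ≈ 5.1 Å,
for ≥ 70% of the run) and which cross the membrane midplane. The first
half of the TM segments in sequence order is the N domain, the second half
the C domain; an explicit `--domain-split` residue overrides the automatic
halving (needed for odd TM counts). The frame sign is set so the
inter-domain linker — intracellular in this fold — projects to negative z;
aqueous side labels use a boundary at 0.5 × half-thickness, leaving an
explicit "membrane" band in between.

## State classification

Gate distances operationalise what is usually judged by eye: for each
aqueous side, the minimum inter-domain Cα distance among residues in the
outer third of the slab (|z| ∈ [ht/3, ht]). A mouth is *closed* at ≤ 8 Å
and *open* at ≥ 11 Å; inward-open = periplasmic closed + cytoplasmic
open, outward-open the mirror image, anything else occluded. The two
thresholds are configuration keys calibrated on the synthetic generator,
where closed mouths sit near 6–7 Å and open mouths above 13 Å; they are
not derived from experimental structures. Models arriving from a predictor
are first superposed globally onto the annotated reference so the gate
regions are evaluated in a well-defined membrane frame.

## Change verdict

Two models of the same protein show an *obvious conformational change*
when their global Cα RMSD is ≥ 2 Å while each domain superimposes to
< 1 Å — i.e. the domains move as rigid bodies and only their relative
arrangement differs. Superposition is closed-form least squares (SVD with
the proper-rotation sign correction); residues are paired by global
sequence alignment rather than author numbering, with a 70% identity floor
for cross-entry comparisons, and all matched Cα are used untrimmed.

## Reversion and side-chain rebuilding

Predicted mutant models are converted back to the wild-type sequence
geometrically: at each mutated position the side chain beyond CB is
discarded and the wild-type side chain is rebuilt from ideal internal
coordinates (standard bond lengths/angles, natural-extension frame
placement), leaving backbone and CB coordinates bit-for-bit unchanged.
Glycine targets drop CB; a missing CB is placed from the backbone improper
(N-C-CA-CB ≈ 122.6°). The rebuilt chain is optimised by exhaustive search
over its chi angles on a 30° grid (configurable; no off-grid refinement),
minimising a soft-sphere clash score Σ max(0, r_vdw,i + r_vdw,j − d)² over
environment atoms within 5 Å (per-element vdW radii: C 1.70, N 1.55,
O 1.52, S 1.80 Å); ties keep the first grid point, so the procedure is
deterministic and exactly equals its own brute-force enumeration. Only
mutated positions are rebuilt — neighbours are not repacked — because the
downstream metric (Cα RMSD) never sees side chains; backbone fidelity is
what matters.

## The predictor adapter

The structure predictor is a black box behind a small contract: sequence
in, `n_models` (default 5) ranked structures out, per-residue pLDDT in the
B-factor column, model sequence required to equal the input exactly. The
`max_template_date` knob (default 2000-01-01, predating deposited
transporter structures so templates cannot leak the answer) is recorded
verbatim in the run manifest. The shipped implementation is a
deterministic mock — a lookup of registered fixture structures by
sequence, padded to `n_models` with seeded rigid perturbations — which
keeps the full pipeline runnable and bit-reproducible with no weights or
GPU. All models are evaluated, since a conformational change may appear in
only a subset of them. Model quality is summarised by mean pLDDT
(unweighted mean of Cα B-factors; above 70 is conventionally an accurate
backbone).

## Synthetic fixtures

`synthetic.make_bundle` builds a two-domain bundle of ideal poly-helices
(rise 1.5 Å/residue, 100°/residue, Cα radius 2.3 Å): per domain, an
interface column and an outer column of helix axes on a 10 Å grid, the
interface axes 10.5 Å apart across the midline; short surface loops and an
8-residue intracellular linker connect the helices; helix residues draw
from bulky hydrophobics (F/M/Y), loops from E/K/Q/R, and designated small
residues (A/S/V cycling) are planted at the interface positions nearest
each mouth (three periplasmic sites on the N domain, three cytoplasmic on
the C domain). Conformational states rotate each domain rigidly by half
the rocker angle (default 24° total) about an axis through the *closing*
mouth (z = ±0.8·ht): that mouth stays sealed while the opposite mouth
opens with the full ~27 Å lever arm. A midplane pivot cannot separate the
8 Å/11 Å gate thresholds at any rocker angle ≤ 30°, because the minimum
gate pair sits only 5 Å from the midplane; the mouth pivot is the
geometrically consistent way to realise the rocker picture at toy scale.
With the default geometry the inward/outward pair differs by ≈ 5.3 Å
global Cα RMSD with exactly 0 per-domain RMSD.

Fixtures carry N, CA, C and CB atoms only (side-chain rebuild tests add
full side chains on demand); B-factors are set to 90 to emulate confident
pLDDT. What passing on these fixtures shows: the geometry, bookkeeping and
decision rules of every stage are correct under exactly known truth. What
it does not show: that a real predictor responds to tryptophan wedges by
switching states, that MI+APC matches Potts-model contact precision on
real families, or that the gate thresholds transfer to experimental
structures — those depend on running the real predictor and are outside
this package's scope.

`synthetic.make_msa` samples rows column-independently from seeded
3-letter Dirichlet backgrounds, except planted pairs: each is a two-state
system ((a₁,b₁) vs (a₂,b₂), 50/50) followed with probability `coupling`
(default 0.9, 5 pairs, 500 rows × 120 columns) and broken otherwise;
gap-heavy rows can be injected to exercise the filters. The planted-pair
MI has the closed form ((1+c)/2)·ln(1+c) + ((1−c)/2)·ln(1−c) nats
(ln 2 at c = 1), which the generator's output matches empirically and the
tests assert.

## Problem sizes and determinism

Default problem sizes — 312-residue bundles, 500 × 120 alignments, 30
classification fixtures, a 6°-coarse/1°-fine exhaustive rotation-grid
oracle on 4–8-point sets — were chosen so the whole suite and the
acceptance script each run in seconds on one CPU while still exercising
every code path at realistic fold dimensions. Every stochastic component
takes an explicit seed (fixture generators, the mock predictor, noise
helpers); identical seeds give bit-identical structures, alignments and
manifests.

## Known limitations

- The prob scale is a rank transform of MI+APC, not GREMLIN's score;
  absolute thresholds do not transfer between the two.
- Membrane placement is geometric; strongly tilted or distorted real
  structures may need the frame override.
- Reversion optimises clash only (no energy function) and does not repack
  neighbours.
- The mock predictor cannot generate a conformational change by itself; it
  replays fixtures. Real-predictor behaviour is represented only through
  the adapter contract.
- Single chain per comparison; no nucleic acids, ligands, waters or
  multi-conformer ensembles.
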