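# confswitch

Mutation-driven conformational sampling for MFS-fold membrane
transporters.

Secondary transporters of the major facilitator superfamily (MFS) move
substrates by alternating access: two six-helix bundles (the N- and
C-terminal domains) rock around the substrate site, alternately opening an
inward-facing (cytoplasmic) or outward-facing (periplasmic) cavity, with
an occluded state in between. Deposited structures and standard predicted
models usually capture only one of these states. `confswitch` implements
the design loop that drives a structure predictor toward the *other*
state:

1. **Score covariation** — weighted mutual information with the average
   product correction (APC) over a filtered MSA (coverage ≥ 70%, row gaps
   ≤ 75%), normalised to a [0, 1] `prob` score; external pair tables can
   be imported instead.
2. **Annotate topology** — membrane frame from chain geometry, TM-helix
   detection, 6+6 N/C-domain split, cytoplasmic/periplasmic side labels.
3. **Design trp mutants** — small-side-chain residues (G/A/S/C/V/T) at the
   N/C interface on one membrane side are substituted with tryptophan:
   periplasmic side to target the inward state, cytoplasmic side to target
   the outward state. Rounds escalate (one extra site per round) until the
   conformation switches.
4. **Predict** — an adapter contract to an external predictor
   (`max_template_date`, `n_models`, pLDDT in the B-factor column), with a
   deterministic mock for weight-free testing.
5. **Revert** — predicted mutant models are converted back to the
   wild-type sequence with ideal-geometry side-chain rebuilding and
   exhaustive chi-grid clash minimisation; the backbone is untouched.
6. **Compare** — Kabsch Cα superposition; *changed* means global
   RMSD ≥ 2 Å with both per-domain RMSDs < 1 Å (rigid domains, new
   arrangement); states are called from gate distances (minimum
   inter-domain Cα distance in each outer third of the membrane slab,
   closed ≤ 8 Å / open ≥ 11 Å).

A synthetic module generates ground-truth rocker-switch bundles and MSAs
with planted covarying pairs, so the entire loop is testable offline. See
`docs/methods.md` for the models, parameters and their rationale.

## Worked example

Generate a transporter fixture in the outward state, design a three-site
tryptophan plan targeting the inward state, and compare the two states:

```sh
$ confswitch simulate bundle --state outward --seed 7 --out outward.pdb
outward bundle (312 residues) -> outward.pdb
$ confswitch simulate bundle --state inward --seed 7 --out inward.pdb
inward bundle (312 residues) -> inward.pdb

$ confswitch design --structure outward.pdb --target inward \
      --n-sites 3 --out plan.tsv --fasta-out mutant.fasta
plan V122W_S82W_A20W -> plan.tsv
$ cat plan.tsv
pos     wt      mut     side    coevolving      round
122     V       W       periplasmic     0       1
82      S       W       periplasmic     0       1
20      A       W       periplasmic     0       1

$ confswitch compare --wt outward.pdb --mut inward.pdb --out report.json
rmsd_global=5.26 Å (N=0.00, C=0.00) changed=True state=inward-open
```

Reading the output: the design picked exactly the three small periplasmic
interface residues (A20, S82, V122) for tryptophan substitution — the
periplasmic side is the one that must seal for the inward state. The
comparison between the two conformations shows a 5.26 Å global Cα RMSD
while each domain superimposes at 0.00 Å: the domains are rigid and only
their rocker arrangement changed, so the verdict is `changed=True` and the
mutant-side model is classified `inward-open`.

The full escalating loop (design → predict → revert → compare, mock
predictor) is available as `confswitch run`; `simulate msa` produces
alignments with planted covarying pairs for the coevolution stage.

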