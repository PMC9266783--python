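"""End-to-end workflow: coevolution → topology → design → predict →
revert → compare, with the redesign/escalation loop.

Each round designs a tryptophan plan, predicts the mutant structure (mock
or external adapter), reverts it to the wild-type sequence and renders the
change verdict; rounds escalate (one extra site per round, coevolution
threshold relaxed once) until an obvious conformational change appears or
the design pool is exhausted.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import compare, coevolution, design, msa as msa_mod, predict, revert
from . import structio, topology
from .errors import ConfigError, DesignError
from .predict import MockPredictor, PredictorConfig
from .structio import SequenceRecord, Structure

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (CLI flags override file
    keys; unknown keys are rejected)."""

    structure: str = ""
    msa: str = ""
    fasta: str = ""
    chain: str = ""
    target_state: str = "inward"
    n_sites: int = 3
    min_coverage: float = 0.70
    max_row_gap: float = 0.75
    min_separation: int = 6
    pseudocount: float = 1.0
    prob_min: float = 0.8
    contact_cutoff: float = 4.5
    chi_step: float = 30.0
    change_min: float = 2.0
    domain_max: float = 1.0
    closed_max: float = 8.0
    open_min: float = 11.0
    half_thickness: float = 15.0
    domain_split: int = 0
    flip_frame: bool = False
    max_template_date: str = "2000-01-01"
    n_models: int = 5
    max_rounds: int = 8
    seed: int = 0
    mock_dir: str = ""
    outdir: str = "confswitch_out"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            typ = known[key].type
            try:
                if typ == "bool":
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif typ == "int":
                    values[key] = int(raw)
                elif typ == "float":
                    values[key] = float(raw)
                else:
                    values[key] = raw
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


@dataclass
class RoundResult:
    round: int
    plan: design.MutationPlan
    reports: list[compare.ConformationReport]
    changed: bool


@dataclass
class PipelineResult:
    rounds: list[RoundResult] = field(default_factory=list)
    changed: bool = False

    @property
    def final_report(self) -> compare.ConformationReport | None:
        for rnd in reversed(self.rounds):
            for rep in rnd.reports:
                if rep.changed:
                    return rep
        return self.rounds[-1].reports[0] if self.rounds else None


def seq_structure_map(
    seq: SequenceRecord, s: Structure, chain: str | None = None
) -> dict[int, int]:
    """res_seq → 1-based sequence position (identity when sequences agree)."""
    from Bio import Align

    extracted = structio.extract_sequence(s, chain)
    nums = structio.numbering_map(s, chain)
    if extracted.seq == seq.seq:
        return {num: k + 1 for k, num in enumerate(nums)}
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-0.5,
    )
    aln = aligner.align(extracted.seq, seq.seq)[0]
    mapping = {}
    for (ms, me), (rs, _) in zip(*aln.aligned):
        for k in range(me - ms):
            mapping[nums[ms + k]] = rs + k + 1
    return mapping


def run_pipeline(
    cfg: RunConfig,
    predictor: MockPredictor | None = None,
    wt_structure: Structure | None = None,
    wt_sequence: SequenceRecord | None = None,
    topo: topology.TopologyAnnotation | None = None,
    alignment: msa_mod.MsaAlignment | None = None,
) -> PipelineResult:
    """Run the full workflow; inputs may be passed in memory or as paths.

    Artifacts (plan TSV, mutant FASTA, reverted model, per-round report
    JSON, run manifest) are written under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chain = cfg.chain or None

    if wt_structure is None:
        if not cfg.structure:
            raise ConfigError("no wild-type structure given")
        wt_structure = structio.read_structure(cfg.structure)
    if wt_sequence is None:
        wt_sequence = (
            structio.read_fasta(cfg.fasta)[0] if cfg.fasta
            else structio.extract_sequence(wt_structure, chain)
        )
    if topo is None:
        topo = topology.annotate(
            wt_structure, chain, cfg.half_thickness,
            cfg.domain_split or None, cfg.flip_frame,
        )
    seq_map = seq_structure_map(wt_sequence, wt_structure, topo.chain_id)

    pairs = None
    if alignment is None and cfg.msa:
        alignment = msa_mod.read_msa(cfg.msa)
    if alignment is not None:
        alignment = msa_mod.filter_msa(
            alignment, cfg.min_coverage, cfg.max_row_gap
        )
        alignment.weights = msa_mod.sequence_weights(alignment)
        pairs = coevolution.score_pairs(
            alignment, cfg.min_separation, cfg.pseudocount
        )
        coevolution.write_pairs(pairs, outdir / "pairs.tsv")

    if predictor is None:
        if not cfg.mock_dir:
            raise ConfigError(
                "no predictor configured (mock_dir required in mock mode)"
            )
        predictor = MockPredictor.from_directory(cfg.mock_dir, seed=cfg.seed)
    pcfg = PredictorConfig(
        max_template_date=cfg.max_template_date, n_models=cfg.n_models
    )
    contacts = design.find_interface(wt_structure, topo, cfg.contact_cutoff)

    result = PipelineResult()
    plan: design.MutationPlan | None = None
    for rnd in range(1, cfg.max_rounds + 1):
        if plan is None:
            plan = design.select_mutation_sites(
                wt_structure, topo, contacts, cfg.target_state,
                n_sites=cfg.n_sites, pairs=pairs, prob_min=cfg.prob_min,
                seq_of_res=seq_map,
            )
            plan.round = rnd
        else:
            plan = design.escalate_plan(
                plan, wt_structure, topo, contacts, pairs, seq_map
            )
        log.info("round %d: plan %s [stage=design round=%d seed=%d]",
                 rnd, plan.mutation_string(), rnd, cfg.seed)
        design.write_plan(plan, outdir / f"plan_round{rnd}.tsv")
        mut_seq = design.apply_mutations(wt_sequence, plan)
        structio.write_fasta([mut_seq], outdir / f"mutant_round{rnd}.fasta")

        models = predict.run_predictor(mut_seq, pcfg, predictor)
        predict.write_manifest(
            predict.make_manifest(mut_seq, pcfg, models),
            outdir / f"manifest_round{rnd}.json",
        )
        reports = []
        changed = False
        for k, model in enumerate(models, start=1):
            reverted = revert.revert_to_wildtype(
                model, plan, wt_sequence, chi_step=cfg.chi_step,
            )
            report = compare.change_verdict(
                wt_structure, reverted, topo,
                cfg.change_min, cfg.domain_max, cfg.closed_max, cfg.open_min,
            )
            reports.append(report)
            report.to_json(outdir / f"report_round{rnd}_model{k}.json")
            if report.changed and not changed:
                changed = True
                structio.write_structure(
                    reverted, outdir / f"reverted_round{rnd}_model{k}.pdb"
                )
        result.rounds.append(
            RoundResult(round=rnd, plan=plan, reports=reports,
                        changed=changed)
        )
        log.info(
            "round %d verdict: changed=%s (rmsd_global=%.2f) "
            "[stage=compare round=%d seed=%d]",
            rnd, changed, reports[0].rmsd_global, rnd, cfg.seed,
        )
        if changed:
            result.changed = True
            break
    summary = {
        "changed": result.changed,
        "rounds": len(result.rounds),
        "final_mutations": (
            result.rounds[-1].plan.mutation_string() if result.rounds else ""
        ),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    if not result.changed and result.rounds and len(result.rounds) == cfg.max_rounds:
        log.warning("no obvious conformational change after %d rounds",
                    cfg.max_rounds)
    return result
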