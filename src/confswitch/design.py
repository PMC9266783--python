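"""Tryptophan mutant design at the N/C-domain interface.

The design rule mirrors rocker-switch steric logic: to bias prediction
toward the *inward* state, small-side-chain residues at the periplasmic end
of the domain interface are mutated to tryptophan; for the *outward* state
the cytoplasmic end is used.  Candidate residues are drawn from
cross-domain contacts; on a structure whose target side is an open mouth
(no 4.5 Å contacts exist there) the contact cutoff auto-widens so the
mouth-lining residues are still reachable.  Coevolution support, contact
count, contact distance and residue number form a full deterministic
tie-break.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import SMALL_AA, SMALL_AA_WIDE
from .coevolution import CoevolutionPair
from .errors import DesignError, MappingError
from .structio import SequenceRecord, Structure
from .topology import TopologyAnnotation, side_label

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.5
WIDEN_CUTOFFS = (4.5, 6.0, 8.0, 12.0, 16.0)


@dataclass
class InterfaceContact:
    res_n: int          # res_seq in N domain
    res_c: int          # res_seq in C domain
    min_dist: float     # minimum heavy-atom distance, Å
    side: str           # side label of the closest atom-pair midpoint
    prob: float = 0.0   # best covariation prob linking the two residues
    coevolving: bool = False


@dataclass
class MutationSite:
    pos: int     # 1-based position in the reference sequence
    wt_aa: str
    mut_aa: str = "W"


@dataclass
class MutationPlan:
    target_state: str   # "inward" | "outward"
    sites: list[MutationSite] = field(default_factory=list)
    round: int = 1
    prob_min: float = 0.8

    def positions(self) -> list[int]:
        return [s.pos for s in self.sites]

    def mutation_string(self) -> str:
        return "_".join(f"{s.wt_aa}{s.pos}{s.mut_aa}" for s in self.sites)


def required_side(target_state: str) -> str:
    if target_state == "inward":
        return "periplasmic"
    if target_state == "outward":
        return "cytoplasmic"
    raise DesignError(f"unknown target state: {target_state!r}")


def find_interface(
    s: Structure,
    topo: TopologyAnnotation,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[InterfaceContact]:
    """All (N-domain, C-domain) residue pairs within a heavy-atom cutoff.

    The contact's side label comes from the midpoint of the closest atom
    pair, judged against the membrane frame — a contact may therefore be
    periplasmic even though both residues are TM-labelled.
    """
    def domain_atoms(domain: str):
        res, coords = [], []
        for r in s.chain(topo.chain_id):
            if topo.domain_of.get(r.res_seq) != domain:
                continue
            for a in r.atoms.values():
                if a.element != "H":
                    res.append(r.res_seq)
                    coords.append(a.coord)
        return np.array(res), np.array(coords).reshape(len(res), 3)

    res_n, xyz_n = domain_atoms("N")
    res_c, xyz_c = domain_atoms("C")
    if len(res_n) == 0 or len(res_c) == 0:
        log.warning("%s: a domain has no heavy atoms", s.id)
        return []
    pairs = cKDTree(xyz_n).query_ball_tree(cKDTree(xyz_c), r=cutoff)
    best: dict[tuple[int, int], tuple[float, np.ndarray]] = {}
    for a_idx, matches in enumerate(pairs):
        for b_idx in matches:
            d = float(np.linalg.norm(xyz_n[a_idx] - xyz_c[b_idx]))
            key = (int(res_n[a_idx]), int(res_c[b_idx]))
            if key not in best or d < best[key][0]:
                best[key] = (d, 0.5 * (xyz_n[a_idx] + xyz_c[b_idx]))
    contacts = [
        InterfaceContact(
            res_n=rn, res_c=rc, min_dist=d,
            side=side_label(topo.frame, mid),
        )
        for (rn, rc), (d, mid) in sorted(best.items())
    ]
    if not contacts:
        log.warning("%s: no inter-domain contacts at %.1f Å", s.id, cutoff)
    return contacts


def map_coevolution_to_interface(
    contacts: list[InterfaceContact],
    pairs: list[CoevolutionPair],
    prob_min: float = 0.8,
    seq_of_res: dict[int, int] | None = None,
) -> list[InterfaceContact]:
    """Annotate each contact with the best covariation prob linking it.

    ``seq_of_res`` maps structure res_seq to 1-based sequence position
    (identity when omitted).  Contacts at or above ``prob_min`` are flagged
    coevolving.
    """
    by_pair: dict[tuple[int, int], float] = {}
    for p in pairs:
        if p.prob is None:
            continue
        key = (min(p.i, p.j), max(p.i, p.j))
        by_pair[key] = max(by_pair.get(key, 0.0), p.prob)
    for c in contacts:
        if seq_of_res is None:
            pos_n, pos_c = c.res_n, c.res_c
        else:
            try:
                pos_n, pos_c = seq_of_res[c.res_n], seq_of_res[c.res_c]
            except KeyError as exc:
                raise MappingError(
                    f"residue {exc.args[0]} has no sequence position"
                ) from exc
        c.prob = by_pair.get((min(pos_n, pos_c), max(pos_n, pos_c)), 0.0)
        c.coevolving = c.prob >= prob_min
    return contacts


def _candidate_table(
    s: Structure,
    topo: TopologyAnnotation,
    contacts: list[InterfaceContact],
    side: str,
    small_set: frozenset[str],
    seq_of_res: dict[int, int] | None,
) -> list[tuple]:
    """Ranked candidate rows: (coevolving, n_contacts, min_dist, pos, wt)."""
    stats: dict[int, dict] = {}
    for c in contacts:
        if c.side != side:
            continue
        for res_seq in (c.res_n, c.res_c):
            st = stats.setdefault(
                res_seq, {"n": 0, "d": np.inf, "coev": False}
            )
            st["n"] += 1
            st["d"] = min(st["d"], c.min_dist)
            st["coev"] = st["coev"] or c.coevolving
    rows = []
    for res_seq, st in stats.items():
        wt = s.residue(res_seq, topo.chain_id).one_letter
        if wt not in small_set or wt == "P":
            continue
        pos = res_seq if seq_of_res is None else seq_of_res.get(res_seq)
        if pos is None:
            raise MappingError(f"residue {res_seq} has no sequence position")
        rows.append((st["coev"], st["n"], st["d"], pos, wt))
    # coevolving desc, contact count desc, min_dist asc, position asc
    rows.sort(key=lambda r: (not r[0], -r[1], r[2], r[3]))
    return rows


def select_mutation_sites(
    s: Structure,
    topo: TopologyAnnotation,
    contacts: list[InterfaceContact],
    target_state: str,
    n_sites: int = 3,
    pairs: list[CoevolutionPair] | None = None,
    prob_min: float = 0.8,
    seq_of_res: dict[int, int] | None = None,
    widen_cutoffs: tuple[float, ...] = WIDEN_CUTOFFS,
) -> MutationPlan:
    """Pick the top-ranked small residues on the target side for W mutation.

    The pool starts from the supplied contacts; if too few small residues
    sit on the required side (typically because that mouth is open in the
    starting model) the contact cutoff widens stepwise, and as a last
    resort the small-residue set widens to <= 4 heavy atoms — each
    escalation is logged.  An empty pool after all widening raises
    :class:`DesignError` suggesting manual sites.
    """
    side = required_side(target_state)
    if n_sites == 0:
        return MutationPlan(target_state=target_state, prob_min=prob_min)

    def pool_at(contact_set, small):
        if pairs is not None:
            map_coevolution_to_interface(contact_set, pairs, prob_min,
                                         seq_of_res)
        return _candidate_table(s, topo, contact_set, side, small, seq_of_res)

    rows: list[tuple] = []
    for small in (SMALL_AA, SMALL_AA_WIDE):
        contact_set = contacts
        for cutoff in widen_cutoffs:
            if cutoff != widen_cutoffs[0]:
                log.info(
                    "select_mutation_sites: widening contact cutoff to "
                    "%.1f Å on the %s side", cutoff, side,
                )
                contact_set = find_interface(s, topo, cutoff)
            rows = pool_at(contact_set, small)
            if len(rows) >= n_sites:
                break
        if len(rows) >= n_sites:
            break
        if small is SMALL_AA:
            log.warning(
                "select_mutation_sites: widening small-residue set to "
                "<= 4 heavy atoms"
            )
    if not rows:
        raise DesignError(
            f"no small-side-chain interface residues on the {side} side; "
            "supply mutation sites manually"
        )
    if len(rows) < n_sites:
        log.warning(
            "select_mutation_sites: only %d of %d requested sites available",
            len(rows), n_sites,
        )
    sites = [MutationSite(pos=r[3], wt_aa=r[4]) for r in rows[:n_sites]]
    return MutationPlan(
        target_state=target_state, sites=sites, prob_min=prob_min
    )


def apply_mutations(seq: SequenceRecord, plan: MutationPlan) -> SequenceRecord:
    """Substitute W at the plan's positions; id gains the mutation string."""
    chars = list(seq.seq)
    for site in plan.sites:
        if not 1 <= site.pos <= len(chars):
            raise DesignError(f"position {site.pos} outside 1..{len(chars)}")
        if chars[site.pos - 1] != site.wt_aa:
            raise DesignError(
                f"wild-type mismatch at {site.pos}: sequence has "
                f"{chars[site.pos - 1]}, plan expects {site.wt_aa}"
            )
        chars[site.pos - 1] = site.mut_aa
    new_id = seq.id if not plan.sites else f"{seq.id}_{plan.mutation_string()}"
    return SequenceRecord(id=new_id, seq="".join(chars))


def escalate_plan(
    previous: MutationPlan,
    s: Structure,
    topo: TopologyAnnotation,
    contacts: list[InterfaceContact],
    pairs: list[CoevolutionPair] | None = None,
    seq_of_res: dict[int, int] | None = None,
) -> MutationPlan:
    """Round n+1: keep the previous sites and add the next-ranked candidate.

    When the candidate pool is exhausted, the coevolution threshold is
    relaxed once from 0.8 to 0.6 (re-ranking the pool) before failing.
    """
    want = len(previous.sites) + 1
    prob_min = previous.prob_min
    while True:
        plan = select_mutation_sites(
            s, topo, contacts, previous.target_state,
            n_sites=max(want, 1) * 4,  # over-fetch the ranked pool
            pairs=pairs, prob_min=prob_min, seq_of_res=seq_of_res,
        )
        kept = {site.pos: site for site in previous.sites}
        new_sites = list(previous.sites)
        for site in plan.sites:
            if site.pos not in kept:
                new_sites.append(site)
            if len(new_sites) == want:
                return MutationPlan(
                    target_state=previous.target_state,
                    sites=new_sites,
                    round=previous.round + 1,
                    prob_min=prob_min,
                )
        if prob_min > 0.6:
            log.warning(
                "escalate_plan: pool exhausted; relaxing coevolution "
                "threshold 0.8 -> 0.6"
            )
            prob_min = 0.6
            continue
        raise DesignError("mutation-site pool exhausted after relaxation")


def write_plan(plan: MutationPlan, path: str | Path,
               side_of_pos: dict[int, str] | None = None,
               coevolving: dict[int, bool] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("pos\twt\tmut\tside\tcoevolving\tround\n")
        for site in plan.sites:
            fh.write(
                f"{site.pos}\t{site.wt_aa}\t{site.mut_aa}\t"
                f"{(side_of_pos or {}).get(site.pos, required_side(plan.target_state))}\t"
                f"{int((coevolving or {}).get(site.pos, False))}\t"
                f"{plan.round}\n"
            )


def read_plan(path: str | Path, target_state: str = "inward") -> MutationPlan:
    sites, rnd = [], 1
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or not parts[0].isdigit():
            continue
        sites.append(MutationSite(int(parts[0]), parts[1], parts[2]))
        if len(parts) >= 6:
            rnd = int(parts[5])
    return MutationPlan(target_state=target_state, sites=sites, round=rnd)
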