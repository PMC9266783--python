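"""Superposition, domain-resolved RMSD and conformational-state calls.

The change verdict reproduces the criterion used to score mutant
predictions: an obvious conformational change means a global Cα RMSD of at
least 2 Å between wild-type and reverted mutant models while each domain
superimposes to under 1 Å (the domains move as rigid bodies; only their
relative arrangement changes).  States are called from gate distances: the
minimum inter-domain Cα distance within the cytoplasmic or periplasmic
third of the membrane slab, with 8 Å closed / 11 Å open thresholds
calibrated on the synthetic rocker-switch fixtures.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, ClassificationError
from .structio import Structure, extract_sequence, numbering_map
from .topology import TopologyAnnotation

log = logging.getLogger(__name__)

INWARD_OPEN = "inward-open"
OUTWARD_OPEN = "outward-open"
OCCLUDED = "occluded"


@dataclass
class ConformationReport:
    rmsd_global: float
    rmsd_N: float
    rmsd_C: float
    gate_cyto: float
    gate_peri: float
    state: str            # state call of the mutant/mobile model
    state_reference: str  # state call of the reference (wild-type) model
    changed: bool
    n_common_residues: int
    mean_plddt: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q (row-paired points).

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1) via the SVD sign correction.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise AlignmentError("need >= 3 paired 3-D points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def match_residues(
    mobile: Structure,
    reference: Structure,
    mobile_chain: str | None = None,
    reference_chain: str | None = None,
) -> tuple[list[tuple[int, int]], float]:
    """Pair residues of two chains by global sequence alignment.

    Returns (res_seq pairs, identity over aligned columns).  Alignment by
    sequence rather than raw numbering survives author-numbering drift
    between PDB entries.
    """
    from Bio import Align

    seq_m = extract_sequence(mobile, mobile_chain).seq
    seq_r = extract_sequence(reference, reference_chain).seq
    num_m = numbering_map(mobile, mobile_chain)
    num_r = numbering_map(reference, reference_chain)
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-0.5,
    )
    aln = aligner.align(seq_m, seq_r)[0]
    pairs, matches, aligned_cols = [], 0, 0
    for (ms, me), (rs, re) in zip(*aln.aligned):
        for k in range(me - ms):
            aligned_cols += 1
            if seq_m[ms + k] == seq_r[rs + k]:
                matches += 1
            pairs.append((num_m[ms + k], num_r[rs + k]))
    if not pairs:
        raise AlignmentError("sequences share no alignable residues")
    return pairs, matches / aligned_cols


def _paired_ca(
    mobile: Structure,
    reference: Structure,
    pairs: Iterable[tuple[int, int]],
    selection: set[int] | None,
    mobile_chain: str | None = None,
    reference_chain: str | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    ca_m = dict(zip(*mobile.ca_coords(mobile_chain)))
    ca_r = dict(zip(*reference.ca_coords(reference_chain)))
    P, Q = [], []
    for rm, rr in pairs:
        if selection is not None and rr not in selection:
            continue
        if rm in ca_m and rr in ca_r:
            P.append(ca_m[rm])
            Q.append(ca_r[rr])
    return np.array(P), np.array(Q), len(P)


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: set[int] | None = None,
    mobile_chain: str | None = None,
    reference_chain: str | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal Cα superposition over sequence-matched residues.

    ``selection`` restricts to a set of reference res_seq numbers.
    """
    pairs, _ = match_residues(mobile, reference, mobile_chain,
                              reference_chain)
    P, Q, n = _paired_ca(mobile, reference, pairs, selection,
                         mobile_chain, reference_chain)
    if n < 3:
        raise AlignmentError(f"only {n} common Cα atoms in selection")
    return kabsch(P, Q)


def domain_rmsd(
    mobile: Structure,
    reference: Structure,
    topo: TopologyAnnotation,
    mobile_chain: str | None = None,
) -> tuple[float, float]:
    """Independent Cα superposition of the N and C domains (reference's
    annotation)."""
    out = []
    for domain in ("N", "C"):
        sel = set(topo.domain_residues(domain))
        _, _, rmsd = kabsch_superpose(
            mobile, reference, selection=sel,
            mobile_chain=mobile_chain, reference_chain=topo.chain_id,
        )
        out.append(rmsd)
    return out[0], out[1]


def gate_distances(
    s: Structure,
    topo: TopologyAnnotation,
) -> tuple[float, float]:
    """(gate_cyto, gate_peri): min inter-domain Cα distance in each outer
    third of the membrane slab (|z| in [ht/3, ht])."""
    ht = topo.frame.half_thickness
    nums, coords = s.ca_coords(topo.chain_id)
    z = topo.frame.z(coords).ravel()
    gates = []
    for sign, name in ((-1, "cytoplasmic"), (+1, "periplasmic")):
        lo, hi = (ht / 3.0, ht)
        in_region = (sign * z >= lo) & (sign * z <= hi)
        pts = {"N": [], "C": []}
        for k, res_seq in enumerate(nums):
            if in_region[k] and topo.domain_of.get(res_seq) in pts:
                pts[topo.domain_of[res_seq]].append(coords[k])
        if not pts["N"] or not pts["C"]:
            raise ClassificationError(
                f"empty {name} gate region "
                f"(N: {len(pts['N'])}, C: {len(pts['C'])} Cα)"
            )
        gates.append(float(cdist(np.array(pts["N"]),
                                 np.array(pts["C"])).min()))
    return gates[0], gates[1]


def classify_state(
    s: Structure,
    topo: TopologyAnnotation,
    closed_max: float = 8.0,
    open_min: float = 11.0,
) -> tuple[str, float, float]:
    """Call inward-open / outward-open / occluded from gate distances."""
    gate_cyto, gate_peri = gate_distances(s, topo)
    if gate_peri <= closed_max and gate_cyto >= open_min:
        state = INWARD_OPEN
    elif gate_cyto <= closed_max and gate_peri >= open_min:
        state = OUTWARD_OPEN
    else:
        state = OCCLUDED
    return state, gate_cyto, gate_peri


def change_verdict(
    wt_model: Structure,
    mut_model: Structure,
    topo: TopologyAnnotation,
    change_min: float = 2.0,
    domain_max: float = 1.0,
    closed_max: float = 8.0,
    open_min: float = 11.0,
    mut_chain: str | None = None,
) -> ConformationReport:
    """Full comparison report between wild-type and reverted mutant models.

    ``changed`` is true iff the global Cα RMSD is at least ``change_min``
    while both per-domain RMSDs stay below ``domain_max`` — a relative
    domain rearrangement rather than internal distortion.
    """
    from .predict import mean_plddt

    pairs, _ = match_residues(mut_model, wt_model, mut_chain, topo.chain_id)
    P, Q, n_common = _paired_ca(mut_model, wt_model, pairs, None,
                                mut_chain, topo.chain_id)
    if n_common < 3:
        raise AlignmentError(f"only {n_common} common Cα atoms")
    R, t, rmsd_global = kabsch(P, Q)
    rmsd_n, rmsd_c = domain_rmsd(mut_model, wt_model, topo, mut_chain)

    state_ref, _, _ = classify_state(wt_model, topo, closed_max, open_min)
    # classify the mutant model in the reference membrane frame: superpose
    # it globally onto the reference first (predictors return models in an
    # arbitrary frame), then transfer the reference annotation through the
    # residue matching (identity for identical numbering)
    aligned = mut_model.copy()
    aligned.transform(R, t)
    mut_state, gate_cyto, gate_peri = classify_state(
        aligned, _transfer_annotation(topo, pairs), closed_max, open_min
    )
    return ConformationReport(
        rmsd_global=rmsd_global,
        rmsd_N=rmsd_n,
        rmsd_C=rmsd_c,
        gate_cyto=gate_cyto,
        gate_peri=gate_peri,
        state=mut_state,
        state_reference=state_ref,
        changed=bool(rmsd_global >= change_min
                     and rmsd_n < domain_max and rmsd_c < domain_max),
        n_common_residues=n_common,
        mean_plddt=mean_plddt(mut_model),
    )


def _transfer_annotation(
    topo: TopologyAnnotation, pairs: list[tuple[int, int]]
) -> TopologyAnnotation:
    """Re-key a reference annotation onto the mobile structure's numbering.

    The membrane frame is re-used as-is: gate regions are defined in the
    reference frame, which is shared when both models describe the same
    protein placed in the same membrane.  For mock-predicted models this
    holds by construction; real predictor output should be annotated
    directly instead.
    """
    domain_of = {}
    side_of = {}
    for rm, rr in pairs:
        if rr in topo.domain_of:
            domain_of[rm] = topo.domain_of[rr]
            side_of[rm] = topo.side_of.get(rr, "membrane")
    return TopologyAnnotation(
        tm_segments=topo.tm_segments,
        domain_of=domain_of,
        side_of=side_of,
        frame=topo.frame,
        chain_id=None,
    )


def compare_to_experiment(
    predicted: Structure,
    experimental: Structure,
    min_identity: float = 0.70,
    predicted_chain: str | None = None,
    experimental_chain: str | None = None,
) -> tuple[float, int]:
    """Global Cα RMSD against an experimental structure.

    Residues are matched by sequence alignment (>= 70% identity over the
    matched region required); returns (rmsd, matched residue count).
    """
    pairs, identity = match_residues(predicted, experimental,
                                     predicted_chain, experimental_chain)
    if identity < min_identity:
        raise AlignmentError(
            f"sequence identity {identity:.2f} below {min_identity:.2f}"
        )
    P, Q, n = _paired_ca(predicted, experimental, pairs, None,
                         predicted_chain, experimental_chain)
    if n < 3:
        raise AlignmentError(f"only {n} common Cα atoms")
    _, _, rmsd = kabsch(P, Q)
    return rmsd, n
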