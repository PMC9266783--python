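"""Ground-truth synthetic fixtures: rocker-switch helix bundles and MSAs.

The bundle generator emulates the MFS fold at toy scale: two rigid
six-helix bundles (N and C domains) of ideal α-helices (1.5 Å rise,
100°/residue) flank a central substrate pathway, joined by an intracellular
linker.  Conformational states are made by rigidly rotating each domain
about an axis near the *closing* mouth, which keeps that mouth sealed while
the opposite aqueous mouth swings open — so inward/outward/occluded truth
labels are exact by construction, domains superimpose at 0 RMSD across
states, and designated small residues (Ala/Ser/Val) sit at interface
positions near each mouth with bulky residues everywhere else.

The MSA generator plants covarying column pairs: each planted pair is a
two-state system ((a1,b1) vs (a2,b2), 50/50) that the row follows with
probability ``coupling`` and breaks (independent draws) otherwise; all
other columns are sampled independently from seeded per-column
backgrounds.  The expected mutual information of a planted pair has the
closed form ((1+c)/2)·ln(1+c) + ((1−c)/2)·ln(1−c) nats.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfswitchError
from .msa import MsaAlignment
from .structio import Atom, Residue, SequenceRecord, Structure
from .topology import MembraneFrame, TmSegment, TopologyAnnotation

log = logging.getLogger(__name__)

STATES = ("inward", "outward", "occluded")
_SMALL_CYCLE = ("ALA", "SER", "VAL")
_HELIX_POOL = ("PHE", "MET", "TYR")   # bulky, hydrophobic (belt-visible)
_LOOP_POOL = ("GLU", "LYS", "GLN", "ARG")

RISE = 1.5          # Å per residue along the helix axis
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3     # Å, Cα distance from the helix axis


@dataclass
class BundleSpec:
    n_helices_per_domain: int = 6
    helix_length: int = 22
    state: str = "occluded"
    rocker_angle: float = 24.0   # total inter-domain rotation, degrees
    seed: int = 0
    planted_per_side: int = 3
    loop_length: int = 4
    linker_length: int = 8
    interface_half_gap: float = 5.25  # Å, half the interface axis gap
    packing: float = 10.0             # Å between neighbouring helix axes
    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ConfswitchError(f"unknown bundle state: {self.state!r}")
        if not 0.0 <= self.rocker_angle <= 30.0:
            raise ConfswitchError("rocker_angle outside [0, 30] degrees")


@dataclass
class MsaSpec:
    n_rows: int = 500
    length: int = 120
    planted_pairs: list[tuple[int, int, float]] | None = None
    n_planted: int = 5
    coupling: float = 0.9
    min_separation: int = 6
    gap_row_rate: float = 0.0
    seed: int = 0


@dataclass
class BundleFixture:
    structure: Structure
    topology: TopologyAnnotation
    state: str
    sequence: SequenceRecord
    planted_periplasmic: list[int] = field(default_factory=list)
    planted_cytoplasmic: list[int] = field(default_factory=list)
    spec: BundleSpec | None = None


def _rotation_y(angle_deg: float, pivot_z: float) -> tuple[np.ndarray, np.ndarray]:
    a = np.deg2rad(angle_deg)
    R = np.array([
        [math.cos(a), 0.0, math.sin(a)],
        [0.0, 1.0, 0.0],
        [-math.sin(a), 0.0, math.cos(a)],
    ])
    pivot = np.array([0.0, 0.0, pivot_z])
    return R, pivot - R @ pivot


def make_bundle(spec: BundleSpec) -> BundleFixture:
    """Build a two-domain helix bundle in a named conformational state."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_helices_per_domain
    hl = spec.helix_length
    g, pk = spec.interface_half_gap, spec.packing
    half_span = RISE * (hl - 1) / 2.0

    # helix slots per domain: column (iface/outer) pattern and row index
    slots = []
    for k in range(n):
        iface = k % 4 in (0, 3)
        row = k // 2 - (math.ceil(n / 2) - 1) / 2.0
        direction = 1 if k % 2 == 0 else -1
        slots.append((iface, row * pk, direction))

    phases = rng.uniform(0.0, 360.0, size=2 * n)

    # --- lay out Cα positions (occluded placement), sequence order ---
    ca: list[np.ndarray] = []
    res_names: list[str] = []
    helix_ranges: list[tuple[int, int]] = []   # 0-based [start, end] indices
    domain_of_idx: list[str] = []              # "N"/"C"/"linker" per residue
    planted = {"periplasmic": [], "cytoplasmic": []}

    def helix_points(domain_sign: int, helix_k: int):
        iface, y0, direction = slots[helix_k]
        x0 = domain_sign * (g if iface else g + pk)
        phase = phases[helix_k if domain_sign < 0 else n + helix_k]
        pts, phis = [], []
        for t in range(hl):
            phi = math.radians(phase + TWIST * t)
            z = direction * (RISE * t - half_span)
            pts.append(np.array([
                x0 + CA_RADIUS * math.cos(phi),
                y0 + CA_RADIUS * math.sin(phi),
                z,
            ]))
            phis.append(phi)
        return pts, phis

    def add_loop(p_from: np.ndarray, p_to: np.ndarray, n_res: int,
                 domain: str) -> None:
        sign = 1.0 if (p_from[2] + p_to[2]) > 0 else -1.0
        for m in range(n_res):
            u = (m + 1) / (n_res + 1)
            pos = (1 - u) * p_from + u * p_to
            pos[2] += sign * (2.0 + 2.0 * math.sin(math.pi * u))
            ca.append(pos)
            res_names.append(str(rng.choice(_LOOP_POOL)))
            domain_of_idx.append(domain)

    small_cycle = {"periplasmic": 0, "cytoplasmic": 0}
    for domain_sign, domain in ((-1, "N"), (+1, "C")):
        # periplasmic plants go on N-domain interface helices, cytoplasmic
        # plants on C-domain ones — each mouth gets its own small residues
        plant_side = "periplasmic" if domain == "N" else "cytoplasmic"
        z_band = (8.5, 13.5) if plant_side == "periplasmic" else (-13.5, -8.5)
        face = 0.0 if domain_sign < 0 else math.pi  # toward the other domain
        iface_helices = [k for k in range(n) if slots[k][0]]
        to_plant = set(iface_helices[: spec.planted_per_side])

        prev_end: np.ndarray | None = None
        for k in range(n):
            pts, phis = helix_points(domain_sign, k)
            if prev_end is not None:
                add_loop(prev_end, pts[0], spec.loop_length, domain)
            start = len(ca)
            plant_t = None
            if k in to_plant:
                zs = [p[2] for p in pts]
                candidates = [
                    t for t in range(hl) if z_band[0] <= zs[t] <= z_band[1]
                ]
                if candidates:
                    plant_t = max(
                        candidates,
                        key=lambda t: math.cos(phis[t] - face),
                    )
            for t, p in enumerate(pts):
                ca.append(p)
                if t == plant_t:
                    name = _SMALL_CYCLE[small_cycle[plant_side]
                                        % len(_SMALL_CYCLE)]
                    small_cycle[plant_side] += 1
                    planted[plant_side].append(len(ca))  # 1-based res_seq
                else:
                    name = str(rng.choice(_HELIX_POOL))
                res_names.append(name)
                domain_of_idx.append(domain)
            helix_ranges.append((start, len(ca) - 1))
            prev_end = pts[-1]
        if domain == "N":
            # intracellular linker down to the C domain's first helix
            first_c_pts, _ = helix_points(+1, 0)
            add_loop(prev_end, first_c_pts[0], spec.linker_length, "linker")

    coords = np.array(ca)

    # --- rigid rocker motion ---
    theta = spec.rocker_angle / 2.0
    if spec.state == "inward":       # cytoplasmic mouth opens
        pivot_z = 0.8 * spec.half_thickness
        angles = {"N": +theta, "C": -theta}
    elif spec.state == "outward":    # periplasmic mouth opens
        pivot_z = -0.8 * spec.half_thickness
        angles = {"N": -theta, "C": +theta}
    else:
        pivot_z, angles = 0.0, {"N": 0.0, "C": 0.0}
    if spec.rocker_angle > 0 and spec.state != "occluded":
        transforms = {d: _rotation_y(a, pivot_z) for d, a in angles.items()}
        linker_idx = [i for i, d in enumerate(domain_of_idx)
                      if d == "linker"]
        half = len(linker_idx) // 2
        side_of_linker = {i: ("N" if pos < half else "C")
                          for pos, i in enumerate(linker_idx)}
        for i in range(len(coords)):
            d = domain_of_idx[i]
            d = side_of_linker[i] if d == "linker" else d
            R, t = transforms[d]
            coords[i] = R @ coords[i] + t

    # --- assemble Structure with N/CA/C/CB atoms ---
    s = Structure(id=f"bundle_{spec.state}_seed{spec.seed}")
    n_res = len(coords)
    helix_members = set()
    for a, b in helix_ranges:
        helix_members.update(range(a, b + 1))
    for i in range(n_res):
        prev_ca = coords[i - 1] if i > 0 else None
        next_ca = coords[i + 1] if i < n_res - 1 else None
        u_prev = (prev_ca - coords[i]) if prev_ca is not None \
            else (coords[i] - next_ca)
        u_next = (next_ca - coords[i]) if next_ca is not None \
            else (coords[i] - prev_ca)
        u_prev = u_prev / np.linalg.norm(u_prev)
        u_next = u_next / np.linalg.norm(u_next)
        res = Residue("A", i + 1, res_names[i])
        res.add(Atom("N", coords[i] + 1.45 * u_prev, bfactor=90.0))
        res.add(Atom("CA", coords[i], bfactor=90.0))
        res.add(Atom("C", coords[i] + 1.52 * u_next, bfactor=90.0))
        if res_names[i] != "GLY":
            lateral = np.cross(u_prev, u_next)
            if np.linalg.norm(lateral) < 1e-6:
                lateral = np.cross(u_next, np.array([0.0, 0.0, 1.0]))
            side_dir = -(u_prev + u_next)
            if np.linalg.norm(side_dir) < 1e-6:
                side_dir = lateral
            side_dir = side_dir / np.linalg.norm(side_dir)
            res.add(Atom("CB", coords[i] + 1.53 * side_dir, bfactor=90.0))
        s.residues.append(res)

    # --- ground-truth annotation ---
    frame = MembraneFrame(center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
                          half_thickness=spec.half_thickness)
    tms = [
        TmSegment(a + 1, b + 1, idx + 1)
        for idx, (a, b) in enumerate(helix_ranges)
    ]
    domain_of, side_of = {}, {}
    boundary = 0.5 * spec.half_thickness
    for i in range(n_res):
        res_seq = i + 1
        domain_of[res_seq] = domain_of_idx[i]
        if i in helix_members:
            side_of[res_seq] = "membrane"
        else:
            z = coords[i][2]
            side_of[res_seq] = (
                "cytoplasmic" if z < -boundary
                else "periplasmic" if z > boundary
                else "membrane"
            )
    topo = TopologyAnnotation(
        tm_segments=tms, domain_of=domain_of, side_of=side_of,
        frame=frame, chain_id="A",
    )
    from .structio import extract_sequence

    return BundleFixture(
        structure=s,
        topology=topo,
        state=spec.state,
        sequence=extract_sequence(s, "A"),
        planted_periplasmic=planted["periplasmic"],
        planted_cytoplasmic=planted["cytoplasmic"],
        spec=spec,
    )


def mutant_structure(fixture: BundleFixture, positions: list[int]) -> Structure:
    """The fixture structure with the given residues renamed to TRP.

    Models what the predictor returns for the mutant sequence: same
    backbone, tryptophan at the mutated sites (side chains beyond CB are
    not modelled in the fixtures).
    """
    s = fixture.structure.copy()
    for pos in positions:
        s.residue(pos, "A").name = "TRP"
    return s


def add_noise(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Gaussian coordinate noise with per-axis std ``sigma/sqrt(3)`` so the
    expected per-atom displacement RMS equals ``sigma``."""
    out = s.copy()
    rng = np.random.default_rng(seed)
    per_axis = sigma / math.sqrt(3.0)
    for r in out.residues:
        for a in r.atoms.values():
            a.coord = a.coord + rng.normal(0.0, per_axis, size=3)
    return out


def make_globule(n_residues: int = 120, center_z: float = 45.0,
                 seed: int = 0) -> Structure:
    """Compact soluble decoy sitting entirely above the membrane slab."""
    rng = np.random.default_rng(seed)
    s = Structure(id=f"globule_seed{seed}")
    pos = np.array([0.0, 0.0, center_z])
    for i in range(n_residues):
        step = rng.normal(0.0, 1.0, size=3)
        step = 3.8 * step / np.linalg.norm(step)
        cand = pos + step
        offset = cand - np.array([0.0, 0.0, center_z])
        radius = np.linalg.norm(offset)
        if radius > 12.0:  # reflect back into the blob
            cand = cand - 2 * step
        pos = cand
        res = Residue("A", i + 1, "ALA")
        res.add(Atom("N", pos + np.array([1.2, 0.0, 0.0]), bfactor=50.0))
        res.add(Atom("CA", pos.copy(), bfactor=50.0))
        res.add(Atom("C", pos + np.array([0.0, 1.2, 0.0]), bfactor=50.0))
        s.residues.append(res)
    return s


def make_single_helix(length: int = 30, res_name: str = "LEU") -> Structure:
    """One ideal TM helix along +z, centred on the membrane midplane."""
    s = Structure(id="single_helix")
    half_span = RISE * (length - 1) / 2.0
    for t in range(length):
        phi = math.radians(TWIST * t)
        pos = np.array([
            CA_RADIUS * math.cos(phi),
            CA_RADIUS * math.sin(phi),
            RISE * t - half_span,
        ])
        res = Residue("A", t + 1, res_name)
        res.add(Atom("N", pos + np.array([0.4, 0.4, -1.2]), bfactor=90.0))
        res.add(Atom("CA", pos, bfactor=90.0))
        res.add(Atom("C", pos + np.array([-0.4, 0.4, 1.2]), bfactor=90.0))
        s.residues.append(res)
    return s


# ---------------------------------------------------------------- MSA ----

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def planted_pair_mi(coupling: float) -> float:
    """Closed-form MI (nats) of a planted two-state pair at the given
    coupling; ln 2 at coupling 1."""
    c = float(coupling)
    if not 0.0 <= c <= 1.0:
        raise ConfswitchError("coupling outside [0, 1]")
    mi = 0.0
    if 1 + c > 0:
        mi += ((1 + c) / 2.0) * math.log(1 + c)
    if 1 - c > 0:
        mi += ((1 - c) / 2.0) * math.log(1 - c)
    return mi


def _default_planted(rng: np.random.Generator, length: int, k: int,
                     min_separation: int, coupling: float):
    positions = rng.permutation(length) + 1
    pairs, used = [], set()
    idx = 0
    while len(pairs) < k and idx < length:
        i = int(positions[idx]); idx += 1
        if i in used:
            continue
        for jdx in range(idx, length):
            j = int(positions[jdx])
            if j in used or abs(j - i) < min_separation:
                continue
            pairs.append((min(i, j), max(i, j), coupling))
            used.update((i, j))
            break
    if len(pairs) < k:
        raise ConfswitchError("could not place the requested planted pairs")
    return pairs


def make_msa(spec: MsaSpec) -> tuple[MsaAlignment, list[tuple[int, int, float]]]:
    """Sample an alignment with planted covarying pairs; returns truth."""
    rng = np.random.default_rng(spec.seed)
    L, n = spec.length, spec.n_rows
    planted = spec.planted_pairs
    if planted is None:
        planted = _default_planted(rng, L, spec.n_planted,
                                   spec.min_separation, spec.coupling)
    for i, j, c in planted:
        if abs(j - i) < spec.min_separation:
            raise ConfswitchError(
                f"planted pair ({i}, {j}) violates min separation"
            )

    planted_cols = {p for pair in planted for p in pair[:2]}
    # per-column background: 3 letters with a seeded Dirichlet composition
    backgrounds = {}
    for col in range(1, L + 1):
        letters = rng.choice(list(_AA20), size=3, replace=False)
        probs = rng.dirichlet([2.0, 2.0, 2.0])
        backgrounds[col] = (letters, probs)
    pair_states = {}
    for i, j, c in planted:
        ai = rng.choice(list(_AA20), size=2, replace=False)
        bj = rng.choice(list(_AA20), size=2, replace=False)
        pair_states[(i, j)] = (ai, bj, c)

    matrix = np.empty((n, L), dtype="<U1")
    for col, (letters, probs) in backgrounds.items():
        matrix[:, col - 1] = rng.choice(letters, size=n, p=probs)
    for (i, j), (ai, bj, c) in pair_states.items():
        follow = rng.random(n) < c
        state = rng.integers(0, 2, size=n)
        state_j = np.where(follow, state, rng.integers(0, 2, size=n))
        matrix[:, i - 1] = ai[state]
        matrix[:, j - 1] = bj[state_j]
    # gap-heavy rows to exercise coverage filtering (never the query)
    if spec.gap_row_rate > 0:
        gappy = rng.random(n) < spec.gap_row_rate
        gappy[0] = False
        for r in np.nonzero(gappy)[0]:
            cols = rng.random(L) < 0.85
            matrix[r, cols] = "-"

    query = SequenceRecord(f"synthetic_query_seed{spec.seed}",
                           "".join(matrix[0]))
    m = MsaAlignment(
        query=query,
        ids=[query.id] + [f"row{k}" for k in range(1, n)],
        rows=matrix,
    )
    return m, planted
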