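"""Membrane frame, TM-helix detection and N/C-domain annotation.

The MFS fold is 12 TM helices in two six-helix bundles (N- and C-terminal
domains) joined by a long intracellular loop.  This module reconstructs
that vocabulary geometrically: the membrane normal is the principal axis of
the hydrophobic-belt Cα cloud, TM segments are helical runs crossing the
slab, the first half of the TM segments is the N domain, and the frame sign
is fixed so the inter-domain linker sits on the cytoplasmic (negative-z)
side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import HYDROPHOBIC_AA3
from .errors import TopologyError
from .structio import Structure

log = logging.getLogger(__name__)

CYTOPLASMIC = "cytoplasmic"
PERIPLASMIC = "periplasmic"
MEMBRANE = "membrane"


@dataclass
class MembraneFrame:
    center: np.ndarray
    normal: np.ndarray
    half_thickness: float = 15.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise TopologyError("zero membrane normal")
        self.normal = self.normal / n
        if not 10.0 <= self.half_thickness <= 25.0:
            raise TopologyError(
                f"half_thickness {self.half_thickness} outside [10, 25] Å"
            )

    def z(self, coords: np.ndarray) -> np.ndarray:
        """Signed distance of points from the membrane midplane."""
        return (np.atleast_2d(coords) - self.center) @ self.normal

    def flipped(self) -> "MembraneFrame":
        return replace(self, normal=-self.normal)


@dataclass
class TmSegment:
    start: int  # res_seq, inclusive
    end: int    # res_seq, inclusive
    index: int  # helix number, 1-based in sequence order


@dataclass
class TopologyAnnotation:
    tm_segments: list[TmSegment]
    domain_of: dict[int, str]  # res_seq -> {"N", "C", "linker"}
    side_of: dict[int, str]    # res_seq -> side label
    frame: MembraneFrame
    chain_id: str | None = field(default=None)

    def domain_residues(self, domain: str) -> list[int]:
        return [r for r, d in self.domain_of.items() if d == domain]

    def helix_domain(self, seg: TmSegment) -> str:
        half = len(self.tm_segments) // 2
        return "N" if seg.index <= half else "C"


def fit_membrane_frame(
    s: Structure,
    chain: str | None = None,
    half_thickness: float = 15.0,
) -> MembraneFrame:
    """Chain-direction membrane frame with one hydrophobic-belt refinement.

    The normal is the principal eigenvector of the orientation tensor of
    local chain segment vectors Cα(i)→Cα(i+6), which point along TM
    helices regardless of how wide the two-bundle fold is (a plain Cα
    covariance axis picks the inter-bundle width instead on squat folds).
    Pass 2 recomputes the tensor and centre from hydrophobic residues
    inside the provisional slab.  The sign of the normal is provisional —
    :func:`assign_domains` fixes it so the linker is cytoplasmic.
    """
    residues = [r for r in s.chain(chain) if "CA" in r.atoms]
    if len(residues) < 100:
        raise TopologyError(
            f"{s.id}: {len(residues)} Cα atoms; need >= 100 to place a membrane"
        )
    coords = np.array([r.coord("CA") for r in residues])
    span = 6

    def direction(select: np.ndarray) -> np.ndarray:
        M = np.zeros((3, 3))
        for k in range(len(residues) - span):
            if not (select[k] and select[k + span]):
                continue
            if residues[k + span].res_seq - residues[k].res_seq != span:
                continue  # chain break
            v = coords[k + span] - coords[k]
            norm = np.linalg.norm(v)
            if norm > 0:
                v = v / norm
                M += np.outer(v, v)
        if not np.all(np.isfinite(M)) or np.allclose(M, 0):
            raise TopologyError("degenerate chain-direction tensor")
        evals, evecs = np.linalg.eigh(M)
        return evecs[:, np.argmax(evals)]

    everything = np.ones(len(residues), dtype=bool)
    axis = direction(everything)
    center = coords.mean(axis=0)
    z = (coords - center) @ axis
    z = z - np.median(z)
    belt = np.array(
        [
            abs(zi) <= half_thickness and r.name in HYDROPHOBIC_AA3
            for zi, r in zip(z, residues)
        ]
    )
    if belt.sum() >= 10:
        axis = direction(belt)
        center = coords[belt].mean(axis=0)
    else:
        log.warning("%s: hydrophobic belt too sparse; using all Cα", s.id)
    return MembraneFrame(center=center, normal=axis,
                         half_thickness=half_thickness)


def detect_tm_helices(
    s: Structure,
    frame: MembraneFrame,
    chain: str | None = None,
    min_length: int = 15,
    helical_fraction: float = 0.70,
    min_segments: int = 2,
) -> list[TmSegment]:
    """Maximal in-slab helical runs that cross the membrane midplane.

    A run is helical when >= 70% of its Cα(i)→Cα(i+3) distances fall in
    [4.5, 6.0] Å (the ideal α-helix value is ≈5.1 Å); it is transmembrane
    when it spans both signs of z.
    """
    residues = [r for r in s.chain(chain) if "CA" in r.atoms]
    coords = np.array([r.coord("CA") for r in residues])
    z = frame.z(coords).ravel()
    in_slab = np.abs(z) <= frame.half_thickness

    segments: list[TmSegment] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if len(run) < min_length:
            return
        pts = coords[run]
        d3 = np.linalg.norm(pts[3:] - pts[:-3], axis=1)
        if ((4.5 <= d3) & (d3 <= 6.0)).mean() < helical_fraction:
            return
        zr = z[run]
        if zr.min() >= 0 or zr.max() <= 0:  # does not cross the midplane
            return
        segments.append(
            TmSegment(residues[run[0]].res_seq, residues[run[-1]].res_seq, 0)
        )

    for k, r in enumerate(residues):
        contiguous = bool(run) and r.res_seq == residues[run[-1]].res_seq + 1
        if in_slab[k] and (not run or contiguous):
            run.append(k)
        else:
            flush(run)
            run = [k] if in_slab[k] else []
    flush(run)

    for idx, seg in enumerate(segments, start=1):
        seg.index = idx
    if len(segments) < min_segments:
        raise TopologyError(
            f"{s.id}: only {len(segments)} TM segments detected"
        )
    return segments


def assign_domains(
    s: Structure,
    tms: list[TmSegment],
    frame: MembraneFrame,
    chain: str | None = None,
    domain_split: int | None = None,
) -> TopologyAnnotation:
    """Split TM helices into N/C six-helix bundles and label sides.

    The first half of the TM segments (in sequence order) forms the N
    domain, the second half the C domain; residues between the two halves
    are the linker.  ``domain_split`` overrides the automatic split with an
    explicit residue number: helices starting before it are N.  The frame
    sign is fixed so the linker midpoint projects to negative z
    (cytoplasmic), matching the intracellular inter-domain loop of the
    fold.
    """
    n = len(tms)
    if domain_split is None:
        if n % 2 != 0 or n < 4:
            raise TopologyError(
                f"{n} TM segments; expected an even count >= 4 "
                "(override with an explicit domain split)"
            )
        n_count = n // 2
    else:
        n_count = sum(1 for seg in tms if seg.start < domain_split)
        if not 1 <= n_count < n:
            raise TopologyError(
                f"domain split {domain_split} leaves an empty domain"
            )
    linker_lo = tms[n_count - 1].end
    linker_hi = tms[n_count].start

    residues = s.chain(chain)
    chain_id = residues[0].chain_id

    def seg_of(res_seq: int) -> TmSegment | None:
        for seg in tms:
            if seg.start <= res_seq <= seg.end:
                return seg
        return None

    # fix frame sign on the linker midpoint
    linker_res = [r for r in residues
                  if linker_lo < r.res_seq < linker_hi and "CA" in r.atoms]
    if linker_res:
        mid_z = float(
            np.mean(frame.z(np.array([r.coord("CA") for r in linker_res])))
        )
    else:
        ends = [r for r in residues
                if r.res_seq in (linker_lo, linker_hi) and "CA" in r.atoms]
        mid_z = float(
            np.mean(frame.z(np.array([r.coord("CA") for r in ends])))
        ) if ends else 0.0
    if mid_z > 0:
        frame = frame.flipped()
        log.info("%s: frame flipped so linker is cytoplasmic", s.id)

    boundary = 0.5 * frame.half_thickness
    domain_of: dict[int, str] = {}
    side_of: dict[int, str] = {}
    for r in residues:
        seg = seg_of(r.res_seq)
        if seg is not None:
            domain_of[r.res_seq] = "N" if seg.index <= n_count else "C"
            side_of[r.res_seq] = MEMBRANE
            continue
        if linker_lo < r.res_seq < linker_hi:
            domain_of[r.res_seq] = "linker"
        elif r.res_seq <= linker_lo:
            domain_of[r.res_seq] = "N"
        else:
            domain_of[r.res_seq] = "C"
        if "CA" in r.atoms:
            zi = float(frame.z(r.coord("CA"))[0])
            if zi < -boundary:
                side_of[r.res_seq] = CYTOPLASMIC
            elif zi > boundary:
                side_of[r.res_seq] = PERIPLASMIC
            else:
                side_of[r.res_seq] = MEMBRANE
        else:
            side_of[r.res_seq] = MEMBRANE
    return TopologyAnnotation(
        tm_segments=tms,
        domain_of=domain_of,
        side_of=side_of,
        frame=frame,
        chain_id=chain_id,
    )


def annotate(
    s: Structure,
    chain: str | None = None,
    half_thickness: float = 15.0,
    domain_split: int | None = None,
    flip_frame: bool = False,
) -> TopologyAnnotation:
    """fit_membrane_frame → detect_tm_helices → assign_domains."""
    frame = fit_membrane_frame(s, chain, half_thickness)
    if flip_frame:
        frame = frame.flipped()
    tms = detect_tm_helices(s, frame, chain)
    return assign_domains(s, tms, frame, chain, domain_split)


def side_label(frame: MembraneFrame, point: np.ndarray) -> str:
    """Side of an arbitrary point under the 0.5·half-thickness boundary."""
    zi = float(frame.z(point)[0])
    boundary = 0.5 * frame.half_thickness
    if zi < -boundary:
        return CYTOPLASMIC
    if zi > boundary:
        return PERIPLASMIC
    return MEMBRANE


def write_topology(topo: TopologyAnnotation, path: str | Path) -> None:
    helix_of = {}
    for seg in topo.tm_segments:
        for r in range(seg.start, seg.end + 1):
            helix_of[r] = seg.index
    with open(path, "w") as fh:
        fh.write("res_seq\tdomain\tside\thelix_index\n")
        for res_seq in sorted(topo.domain_of):
            fh.write(
                f"{res_seq}\t{topo.domain_of[res_seq]}\t"
                f"{topo.side_of[res_seq]}\t{helix_of.get(res_seq, 0)}\n"
            )
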