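"""Adapter contract to the external structure predictor, plus a mock.

The pipeline treats the predictor as a black box: a sequence goes in,
``n_models`` ranked structures with per-residue pLDDT in the B-factor
column come out.  Swapping the deterministic mock (a lookup of registered
fixtures by sequence, with an optional seeded rigid perturbation) for a
real AlphaFold2 endpoint changes no downstream code path.  The
``max_template_date`` knob (default 2000-01-01, predating deposited
transporter conformations) is recorded verbatim in the run manifest.
"""
from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, PredictorError
from .structio import SequenceRecord, Structure, extract_sequence

log = logging.getLogger(__name__)


@dataclass
class PredictorConfig:
    max_template_date: str = "2000-01-01"
    n_models: int = 5
    locator: str | None = None  # executable path / endpoint / mock tag

    def __post_init__(self) -> None:
        try:
            datetime.date.fromisoformat(self.max_template_date)
        except ValueError as exc:
            raise ConfigError(
                f"max_template_date {self.max_template_date!r} is not ISO-8601"
            ) from exc
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")


class MockPredictor:
    """Deterministic stand-in predictor keyed on the input sequence.

    Registered fixture structures are returned as deep copies; if fewer
    fixtures than ``n_models`` are registered for a sequence, extra models
    are generated by applying a seeded rigid-body perturbation (which
    leaves every superposition-based metric unchanged).
    """

    def __init__(self, seed: int = 0, jitter: bool = True) -> None:
        self._registry: dict[str, list[Structure]] = {}
        self.seed = seed
        self.jitter = jitter

    def register(self, seq: str, *structures: Structure) -> None:
        self._registry.setdefault(seq, []).extend(
            s.copy() for s in structures
        )

    @classmethod
    def from_directory(cls, path: str | Path, seed: int = 0,
                       jitter: bool = True) -> "MockPredictor":
        """Register every PDB file in a directory under its own sequence."""
        from .structio import read_structure

        mock = cls(seed=seed, jitter=jitter)
        files = sorted(Path(path).glob("*.pdb"))
        if not files:
            raise ConfigError(f"mock fixture directory {path} has no PDBs")
        for f in files:
            s = read_structure(f)
            mock.register(extract_sequence(s).seq, s)
        return mock

    def predict(self, seq: SequenceRecord, n_models: int) -> list[Structure]:
        if seq.seq not in self._registry:
            raise PredictorError(
                f"mock predictor has no fixture for sequence {seq.id}"
            )
        fixtures = self._registry[seq.seq]
        models = []
        rng = np.random.default_rng(
            [self.seed, int(hashlib.sha256(seq.seq.encode()).hexdigest(), 16)
             % (2**31)]
        )
        for k in range(n_models):
            model = fixtures[k % len(fixtures)].copy()
            model.id = f"{seq.id}_model{k + 1}"
            if self.jitter and k >= len(fixtures):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0, np.pi)
                K = np.array([
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ])
                R = (np.eye(3) + np.sin(angle) * K
                     + (1 - np.cos(angle)) * K @ K)
                model.transform(R, rng.uniform(-5, 5, size=3))
            models.append(model)
        return models


def run_predictor(
    seq: SequenceRecord,
    cfg: PredictorConfig,
    predictor: MockPredictor,
) -> list[Structure]:
    """Run the (mock) predictor; validate and rank the returned models.

    Every output model must carry exactly the input sequence (tryptophan
    substitutions included); models are ranked by mean pLDDT descending.
    """
    models = predictor.predict(seq, cfg.n_models)
    for model in models:
        got = extract_sequence(model).seq
        if got != seq.seq:
            raise PredictorError(
                f"{model.id}: predicted sequence differs from input"
            )
    models.sort(key=mean_plddt, reverse=True)
    return models


def mean_plddt(s: Structure) -> float:
    """Unweighted mean of per-residue pLDDT (the Cα B-factor)."""
    values = []
    for r in s.residues:
        if "CA" not in r.atoms:
            log.warning("%s: residue %d lacks Cα; skipped in mean pLDDT",
                        s.id, r.res_seq)
            continue
        values.append(r.atoms["CA"].bfactor)
    if not values:
        raise PredictorError(f"{s.id}: no Cα atoms for pLDDT")
    return float(np.mean(values))


def make_manifest(
    seq: SequenceRecord,
    cfg: PredictorConfig,
    models: list[Structure],
) -> dict:
    return {
        "sequence_id": seq.id,
        "sequence_sha256": hashlib.sha256(seq.seq.encode()).hexdigest(),
        "max_template_date": cfg.max_template_date,
        "n_models": cfg.n_models,
        "locator": cfg.locator,
        "models": [
            {"id": m.id, "rank": k + 1, "mean_plddt": round(mean_plddt(m), 3)}
            for k, m in enumerate(models)
        ],
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
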