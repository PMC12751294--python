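"""Lossless genome serialization (JSON, with provenance)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .evolution import GENOME_LENGTH, _check_genes

__all__ = ["save_genome", "load_genome", "FORMAT"]

FORMAT = "forager-genome/1"


def save_genome(genes: np.ndarray, path: str | Path, *,
                condition: str = "RI", seed: int | None = None,
                generation: int | None = None,
                fitness: float | None = None) -> None:
    """Write a genome with its provenance (seed, generation, measured
    fitness) to a JSON file; round-trips losslessly via repr-exact floats."""
    genes = _check_genes(np.asarray(genes, dtype=float))
    doc = {
        "format": FORMAT,
        "condition": condition,
        "genes": [float(g) for g in genes],
        "provenance": {"seed": seed, "generation": generation,
                       "fitness": fitness},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_genome(path: str | Path):
    """Read a genome file; returns ``(genes, metadata)``.

    Rejects unknown format versions, wrong gene counts, and malformed
    JSON (with the parser's position diagnostic)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed genome file {path}: {err}") from err
    if not isinstance(doc, dict) or doc.get("format") != FORMAT:
        raise ValueError(f"{path}: expected format {FORMAT!r}, "
                         f"got {doc.get('format')!r}"
                         if isinstance(doc, dict)
                         else f"{path}: not a genome document")
    genes = np.asarray(doc.get("genes", []), dtype=float)
    if genes.shape != (GENOME_LENGTH,):
        raise ValueError(f"{path}: expected {GENOME_LENGTH} genes, "
                         f"got {genes.shape}")
    _check_genes(genes)
    meta = {"condition": doc.get("condition"),
            **(doc.get("provenance") or {})}
    return genes, meta
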