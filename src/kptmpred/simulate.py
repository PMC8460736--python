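"""Synthetic proteins with planted, recoverable K-PTM structure.

The generator emulates the statistics of a curated lysine-modification
corpus without any download: proteins are drawn from realistic background
residue frequencies; a small fraction of lysine sites (default 1/17,
i.e. a ≈1:16 modified:unmodified imbalance) are declared modified; each
modified site draws a label-multiplicity from a heavy-tailed histogram
(most sites carry one modification, a few carry up to five) and that
many distinct PTM types; and each assigned PTM stamps its own positional
residue preferences — a set of (offset, residue, enrichment) triples —
into the flanking sequence.  The motifs live inside the ±ζ window, so
the sequence-coupling encoder is the intended dominant signal.

A ground-truth manifest records every planted site, its labels, and
which feature columns the motifs make informative, letting downstream
tests close the loop against the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET, PTM_TYPES
from .dataset import (Annotation, Protein, write_annotations, write_fasta)
from .errors import ConfigError

#: Approximate UniProt/Swiss-Prot residue frequencies (fractions).
BACKGROUND_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: Label-multiplicity distribution for modified sites: P(1..5 labels),
#: shaped like a curated corpus where single modifications dominate.
DEFAULT_MULTIPLICITY = (4089 / 5059, 861 / 5059, 77 / 5059,
                        26 / 5059, 6 / 5059)

#: Per-PTM positional preferences: (offset from K, residue, enrichment).
#: Offsets are disjoint across PTM types so co-occurring labels compose.
DEFAULT_MOTIFS = {
    "acetylation": ((-1, "G", 0.9), (1, "H", 0.9), (-3, "R", 0.9), (3, "F", 0.9)),
    "crotonylation": ((-2, "E", 0.9), (2, "D", 0.9), (-5, "P", 0.9), (5, "W", 0.9)),
    "methylation": ((-4, "S", 0.9), (4, "T", 0.9), (-7, "A", 0.9), (7, "V", 0.9)),
    "succinylation": ((-6, "L", 0.9), (6, "I", 0.9), (-9, "N", 0.9), (9, "Q", 0.9)),
    "glutarylation": ((-8, "Y", 0.9), (8, "C", 0.9), (-11, "M", 0.9), (11, "D", 0.9)),
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults mirror the emulated study.

    ``positive_fraction`` defaults to 1/17 so modified:unmodified sites
    land near 1:16; ``multiplicity_probs`` is P(a modified site carries
    1..5 labels); ``motifs`` maps each PTM type to its planted
    (offset, residue, enrichment-probability) triples.
    """

    n_proteins: int = 120
    length_mean: float = 420.0
    length_sd: float = 120.0
    length_min: int = 80
    background: dict[str, float] = field(
        default_factory=lambda: dict(BACKGROUND_FREQUENCIES))
    positive_fraction: float = 1.0 / 17.0
    multiplicity_probs: tuple[float, ...] = DEFAULT_MULTIPLICITY
    motifs: dict[str, tuple[tuple[int, str, float], ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MOTIFS.items()})
    zeta: int = 24
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not 0 < self.positive_fraction < 1:
            raise ConfigError("positive_fraction must lie in (0, 1)")
        if len(self.multiplicity_probs) != len(PTM_TYPES):
            raise ConfigError(
                f"multiplicity_probs needs {len(PTM_TYPES)} entries "
                "(P(1 label) .. P(5 labels))")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ConfigError("multiplicity_probs must sum to 1")
        if any(p < 0 for p in self.multiplicity_probs):
            raise ConfigError("multiplicity_probs must be non-negative")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-2:  # renormalized exactly at draw time
            raise ConfigError("background frequencies must sum to ~1")
        for ptm, triples in self.motifs.items():
            if ptm not in PTM_TYPES:
                raise ConfigError(f"motif for unknown PTM type {ptm!r}")
            for off, res, w in triples:
                if off == 0 or abs(off) > self.zeta:
                    raise ConfigError(
                        f"{ptm}: motif offset {off} outside ±ζ (ζ={self.zeta})")
                if res not in ALPHABET[:-1]:
                    raise ConfigError(f"{ptm}: motif residue {res!r} invalid")
                if not 0 <= w <= 1:
                    raise ConfigError(f"{ptm}: enrichment {w} outside [0, 1]")


@dataclass
class SyntheticData:
    """Generated corpus plus its ground-truth manifest."""

    proteins: list[Protein]
    annotations: list[Annotation]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        write_annotations(self.annotations, outdir / "annotations.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def informative_columns(motifs, ptm_type: str | None = None) -> list[str]:
    """Feature columns a motif set makes informative.

    Each (offset, residue) preference shifts the residue distribution at
    that offset, which moves the coupling feature for the offset and the
    one-hot column for the (offset, residue) pair.
    """
    kinds = [ptm_type] if ptm_type else list(motifs)
    cols: list[str] = []
    for ptm in kinds:
        for off, res, _w in motifs[ptm]:
            cols.append(f"coupling:{off:+d}")
            cols.append(f"be:{off:+d}:{res}")
    return sorted(set(cols))


def generate(config: GeneratorConfig | None = None) -> SyntheticData:
    """Draw a synthetic corpus; byte-identical for a fixed seed."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    residues = sorted(config.background)
    probs = np.array([config.background[r] for r in residues])
    probs = probs / probs.sum()

    proteins: list[Protein] = []
    annotations: list[Annotation] = []
    sites = []
    for p in range(config.n_proteins):
        length = max(config.length_min,
                     int(round(rng.normal(config.length_mean, config.length_sd))))
        seq = list(rng.choice(residues, size=length, p=probs))
        k_pos = [i for i, c in enumerate(seq) if c == "K"]  # 0-based
        pos_flags = rng.random(len(k_pos)) < config.positive_fraction
        chosen = [i for i, f in zip(k_pos, pos_flags) if f]
        centers = set(chosen)
        pid = f"SYN{p:04d}"
        for i in chosen:
            mult = 1 + int(rng.choice(len(PTM_TYPES),
                                      p=config.multiplicity_probs))
            labels = sorted(rng.choice(PTM_TYPES, size=mult, replace=False))
            for lab in labels:
                for off, res, w in config.motifs.get(lab, ()):
                    j = i + off
                    # never overwrite a modified center: its K must survive
                    if 0 <= j < length and j not in centers:
                        if rng.random() < w:
                            seq[j] = res
                annotations.append(Annotation(pid, i + 1, lab))
            sites.append({"protein_id": pid, "position": i + 1,
                          "labels": labels})
        proteins.append(Protein(pid, "".join(seq)))

    manifest = {
        "seed": config.seed,
        "n_proteins": config.n_proteins,
        "positive_fraction": config.positive_fraction,
        "zeta": config.zeta,
        "n_planted_sites": len(sites),
        "sites": sites,
        "motifs": {k: [list(t) for t in v] for k, v in config.motifs.items()},
        "informative_columns": {
            ptm: informative_columns(config.motifs, ptm)
            for ptm in config.motifs},
        "informative_columns_all": informative_columns(config.motifs),
    }
    return SyntheticData(proteins, annotations, manifest)
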