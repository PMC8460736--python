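"""Peptide-window dataset construction.

Turns annotated proteins into equal-length windows of 2ζ+1 residues
centered on lysine (K), each carrying a label *set* drawn from the five
K-PTM types; an empty set means the site carries no known modification
(the negative, "non-K-PTM" class).  When a window overruns a protein
terminus the missing flank is filled by repeating the terminal residue
on that side.  Exact-duplicate windows are collapsed to one sample whose
label set is the union of the duplicates' labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import PTM_TYPES, sanitize_sequence
from .errors import CenterResidueError, EmptyInputError

logger = logging.getLogger(__name__)

#: Default half-window; windows are 2ζ+1 = 49 residues wide.
DEFAULT_ZETA = 24


@dataclass(frozen=True)
class Protein:
    """A protein sequence keyed by accession.

    The sequence is sanitized on construction: uppercased, with
    nonstandard letters mapped to the wildcard 'Z'.
    """

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise EmptyInputError(f"protein {self.id}: empty sequence")
        object.__setattr__(
            self, "sequence", sanitize_sequence(self.sequence, context=self.id))

    def k_positions(self) -> list[int]:
        """1-based positions of every lysine residue."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == "K"]


@dataclass(frozen=True)
class Annotation:
    """One experimentally observed modification at a lysine residue."""

    protein_id: str
    position: int  # 1-based
    ptm_type: str

    def __post_init__(self):
        if self.ptm_type not in PTM_TYPES:
            raise KeyError(
                f"unknown PTM type {self.ptm_type!r}; expected one of {PTM_TYPES}")


@dataclass(frozen=True)
class PeptideSample:
    """A fixed-length K-centered window with its modification label set."""

    window: str
    labels: frozenset[str]
    origin: tuple[str, int]  # (protein_id, 1-based position)

    @property
    def is_positive(self) -> bool:
        return bool(self.labels)


@dataclass
class BenchmarkDataset:
    """An ordered, deduplicated collection of peptide samples."""

    samples: list[PeptideSample]
    zeta: int

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def windows(self) -> list[str]:
        return [s.window for s in self.samples]

    @property
    def label_sets(self) -> list[frozenset[str]]:
        return [s.labels for s in self.samples]

    def multiplicity_histogram(self) -> dict[int, int]:
        """Sample counts keyed by label-set size 0..5."""
        hist = {m: 0 for m in range(6)}
        for s in self.samples:
            hist[len(s.labels)] += 1
        return hist

    def positives(self) -> list[PeptideSample]:
        return [s for s in self.samples if s.labels]

    def negatives(self) -> list[PeptideSample]:
        return [s for s in self.samples if not s.labels]


def extract_window(protein: Protein, position: int, zeta: int = DEFAULT_ZETA) -> str:
    """Extract the 2ζ+1 window centered on the K at ``position`` (1-based).

    Flanks that overrun a terminus are filled by repeating the terminal
    residue of the protein on that side, so the output length is always
    2ζ+1 regardless of where the site sits.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise IndexError(
            f"position {position} outside protein {protein.id} "
            f"(length {len(seq)})")
    if seq[position - 1] != "K":
        raise CenterResidueError(
            f"{protein.id}:{position} is {seq[position - 1]!r}, not 'K'")
    if zeta < 1:
        raise ValueError("zeta must be >= 1")
    i = position - 1
    left = seq[max(0, i - zeta): i]
    right = seq[i + 1: i + 1 + zeta]
    left = seq[0] * (zeta - len(left)) + left
    right = right + seq[-1] * (zeta - len(right))
    return left + "K" + right


def build_benchmark(
    proteins: Iterable[Protein],
    annotations: Iterable[Annotation],
    zeta: int = DEFAULT_ZETA,
) -> BenchmarkDataset:
    """Window every K residue of every protein and attach label sets.

    Every lysine yields one candidate sample; its label set is the union
    of PTM types annotated at that (protein, position).  Samples with
    identical window strings are collapsed to the first occurrence, the
    union of their labels (an observed modification anywhere outweighs
    its absence elsewhere).  Annotations at non-K residues or out-of-range
    positions are rejected with a logged reason.
    """
    proteins = list(proteins)
    if not proteins:
        raise EmptyInputError("no proteins supplied")
    by_id = {p.id: p for p in proteins}

    site_labels: dict[tuple[str, int], set[str]] = {}
    for ann in annotations:
        prot = by_id.get(ann.protein_id)
        if prot is None:
            logger.warning("annotation %s:%d dropped: unknown protein",
                           ann.protein_id, ann.position)
            continue
        if not 1 <= ann.position <= len(prot.sequence):
            logger.warning("annotation %s:%d dropped: position out of range",
                           ann.protein_id, ann.position)
            continue
        if prot.sequence[ann.position - 1] != "K":
            logger.warning("annotation %s:%d dropped: residue is %r, not K",
                           ann.protein_id, ann.position,
                           prot.sequence[ann.position - 1])
            continue
        site_labels.setdefault((prot.id, ann.position), set()).add(ann.ptm_type)

    by_window: dict[str, int] = {}
    samples: list[PeptideSample] = []
    for prot in proteins:
        for pos in prot.k_positions():
            window = extract_window(prot, pos, zeta)
            labels = frozenset(site_labels.get((prot.id, pos), ()))
            if window in by_window:
                i = by_window[window]
                prev = samples[i]
                samples[i] = PeptideSample(
                    window, prev.labels | labels, prev.origin)
            else:
                by_window[window] = len(samples)
                samples.append(PeptideSample(window, labels, (prot.id, pos)))

    ds = BenchmarkDataset(samples, zeta)
    hist = ds.multiplicity_histogram()
    logger.info("benchmark: %d samples (%d positive); multiplicity %s",
                len(ds), sum(1 for s in samples if s.labels), hist)
    return ds


def per_ptm_view(
    dataset: BenchmarkDataset, ptm_type: str
) -> tuple[list[PeptideSample], list[PeptideSample]]:
    """Partition the dataset into (positives, negatives) for one PTM type.

    A sample is positive iff its label set contains ``ptm_type``; samples
    carrying several labels are positive in several views.
    """
    if ptm_type not in PTM_TYPES:
        raise KeyError(
            f"unknown PTM type {ptm_type!r}; expected one of {PTM_TYPES}")
    pos = [s for s in dataset.samples if ptm_type in s.labels]
    neg = [s for s in dataset.samples if ptm_type not in s.labels]
    return pos, neg


# ---------------------------------------------------------------------------
# File formats

def read_fasta(path: str | Path) -> list[Protein]:
    """Load proteins from a multi-record FASTA file."""
    proteins = [Protein(rec.id, str(rec.seq))
                for rec in SeqIO.parse(str(path), "fasta")]
    if not proteins:
        raise EmptyInputError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Sequence[Protein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    """Load the modification table: TSV with protein_id, position, ptm_type.

    Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"protein_id": str, "position": int, "ptm_type": str})
    required = {"protein_id", "position", "ptm_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns {sorted(missing)}")
    return [Annotation(r.protein_id, int(r.position), r.ptm_type)
            for r in df.itertuples(index=False)]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.protein_id, a.position, a.ptm_type) for a in annotations],
        columns=["protein_id", "position", "ptm_type"],
    ).to_csv(path, sep="\t", index=False)


def write_dataset_tsv(dataset: BenchmarkDataset, path: str | Path) -> None:
    """Persist a dataset: window, comma-joined labels, provenance."""
    rows = [(s.window, ",".join(sorted(s.labels)), s.origin[0], s.origin[1])
            for s in dataset.samples]
    pd.DataFrame(rows, columns=["window", "labels", "protein_id", "position"]
                 ).to_csv(path, sep="\t", index=False)


def read_dataset_tsv(path: str | Path) -> BenchmarkDataset:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"window": str, "labels": str,
                            "protein_id": str, "position": int})
    samples = []
    for r in df.itertuples(index=False):
        labels = frozenset(x for x in r.labels.split(",") if x)
        samples.append(PeptideSample(r.window, labels, (r.protein_id, int(r.position))))
    if not samples:
        raise EmptyInputError(f"no samples in {path}")
    zeta = (len(samples[0].window) - 1) // 2
    return BenchmarkDataset(samples, zeta)
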