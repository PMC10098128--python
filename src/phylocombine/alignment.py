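"""Nucleotide alignment container, FASTA I/O, and supermatrix concatenation.

Sequences are stored as upper-case strings over the IUPAC nucleotide
alphabet.  Ambiguity codes are kept as read and interpreted downstream as
subsets of {A, C, G, T}; the gap character ``-`` (and ``?``) is treated as
the full state set, i.e. it carries no information about the site.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "NucAlignment",
    "parse_fasta",
    "write_fasta",
    "concatenate_supermatrix",
    "occupancy_table",
    "CHAR_TO_CODE",
    "CODE_TO_STATES",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Malformed alignment input (shape, identity or alphabet problems)."""


# Bitmask encoding: A=1, C=2, G=4, T=8.  Ambiguity codes are unions; the
# gap and '?' map to the full set (uninformative).
CHAR_TO_CODE: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8, "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15, "-": 15, "?": 15,
}

#: code -> tuple of allowed state indices (A=0, C=1, G=2, T=3)
CODE_TO_STATES: dict[int, tuple[int, ...]] = {
    code: tuple(i for i in range(4) if code & (1 << i))
    for code in range(1, 16)
}

_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _code in CHAR_TO_CODE.items():
    _CODE_LUT[ord(_ch)] = _code
    _CODE_LUT[ord(_ch.lower())] = _code


def normalize_taxon(label: str) -> str:
    """Strip surrounding whitespace and replace internal spaces with '_'."""
    return "_".join(label.strip().split())


@dataclass
class NucAlignment:
    """A taxa-by-sites nucleotide matrix.

    Parameters
    ----------
    taxon_labels:
        Ordered unique taxon identifiers (normalized: no surrounding
        whitespace, internal spaces replaced by underscores).
    sequences:
        One upper-case sequence string per taxon, all of equal length.
    """

    taxon_labels: list[str]
    sequences: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxon_labels) != len(self.sequences):
            raise AlignmentError("label/sequence count mismatch")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        labels = [normalize_taxon(t) for t in self.taxon_labels]
        if any(not t for t in labels):
            raise AlignmentError("empty taxon label")
        if len(set(labels)) != len(labels):
            dup = sorted({t for t in labels if labels.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels after normalization: {dup}")
        self.taxon_labels = labels
        seqs = [s.upper() for s in self.sequences]
        n = len(seqs[0])
        if n < 1:
            raise AlignmentError("alignment has zero sites")
        for t, s in zip(labels, seqs):
            if len(s) != n:
                raise AlignmentError(
                    f"sequence length mismatch for {t!r}: {len(s)} != {n}"
                )
            for pos, ch in enumerate(s):
                if ch not in CHAR_TO_CODE:
                    raise AlignmentError(
                        f"illegal character {ch!r} in taxon {t!r} at site {pos}"
                    )
        self.sequences = seqs

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 bitmask matrix (A=1, C=2, G=4, T=8)."""
        if self._codes is None:
            rows = [
                _CODE_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
                for s in self.sequences
            ]
            self._codes = np.vstack(rows)
        return self._codes

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxon_labels.index(taxon)]

    def subset_sites(self, indices: Sequence[int] | np.ndarray) -> "NucAlignment":
        idx = np.asarray(indices, dtype=np.intp)
        codes = self.codes()[:, idx]
        seqs = ["".join(seq[i] for i in idx) for seq in self.sequences]
        return NucAlignment(list(self.taxon_labels), seqs)

    def subset_taxa(self, taxa: Iterable[str]) -> "NucAlignment":
        wanted = [normalize_taxon(t) for t in taxa]
        missing = [t for t in wanted if t not in self.taxon_labels]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        return NucAlignment(
            wanted, [self.sequence(t) for t in wanted]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucAlignment):
            return NotImplemented
        return (
            self.taxon_labels == other.taxon_labels
            and self.sequences == other.sequences
        )


def parse_fasta(source) -> NucAlignment:
    """Parse a multi-FASTA stream/str/path into an aligned matrix.

    Records must begin with ``>``; sequences are upper-cased and must all
    have the same length.  Record order is preserved.
    """
    if isinstance(source, (str, Path)):
        text = str(source)
        if isinstance(source, Path) or (
            "\n" not in text and ">" not in text and Path(text).exists()
        ):
            handle: io.TextIOBase = open(source)
        else:
            handle = io.StringIO(text)
    else:
        handle = source
    labels: list[str] = []
    seqs: list[str] = []
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            labels.append(rec.description)
            seqs.append(str(rec.seq))
    if not labels:
        raise AlignmentError("no FASTA records found")
    return NucAlignment(labels, seqs)


def write_fasta(aln: NucAlignment, dest=None, wrap: int = 60) -> str:
    """Serialize deterministically (wrapped at ``wrap`` columns)."""
    lines: list[str] = []
    for t, s in zip(aln.taxon_labels, aln.sequences):
        lines.append(f">{t}")
        if wrap:
            lines.extend(s[i : i + wrap] for i in range(0, len(s), wrap))
        else:
            lines.append(s)
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def concatenate_supermatrix(
    alignments: Sequence[NucAlignment],
    names: Sequence[str] | None = None,
):
    """Concatenate per-gene alignments into a supermatrix.

    The taxon set is the union of the inputs in first-seen order; taxa
    missing from a gene are filled with gaps for that gene's columns.
    Returns ``(supermatrix, scheme)`` where the scheme has one partition
    per input gene, in input order.
    """
    from .partitions import Partition, PartitionScheme

    if not alignments:
        raise ValueError("need at least one alignment to concatenate")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(names) != len(alignments):
        raise ValueError("names/alignments length mismatch")
    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxon_labels:
            if t not in taxa:
                taxa.append(t)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    parts = []
    offset = 0
    for name, aln in zip(names, alignments):
        present = set(aln.taxon_labels)
        for t in taxa:
            pieces[t].append(aln.sequence(t) if t in present else "-" * aln.n_sites)
        parts.append(Partition(name, [(offset, offset + aln.n_sites)]))
        offset += aln.n_sites
    super_aln = NucAlignment(taxa, ["".join(pieces[t]) for t in taxa])
    return super_aln, PartitionScheme(parts)


def occupancy_table(
    alignments: Sequence[NucAlignment], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene taxon occupancy: taxa present, total taxa, fraction."""
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(alignments))]
    all_taxa: set[str] = set()
    for aln in alignments:
        all_taxa.update(aln.taxon_labels)
    total = len(all_taxa)
    rows = [
        {
            "gene": name,
            "n_present": aln.n_taxa,
            "n_total": total,
            "fraction": aln.n_taxa / total,
        }
        for name, aln in zip(names, alignments)
    ]
    return pd.DataFrame(rows)
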