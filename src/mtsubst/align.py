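"""Protein multiple sequence alignments with site-pattern compression.

Reading and writing goes through Biopython (FASTA and relaxed PHYLIP);
the container itself keeps the rows as plain strings and lazily compresses
the columns into unique site patterns with multiplicities, which is what
the likelihood engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet

__all__ = ["Alignment", "read_alignment", "write_alignment"]


@dataclass
class Alignment:
    """Aligned amino-acid sequences (equal-length rows)."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        self._patterns = None

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset(self, names: list[str]) -> "Alignment":
        """Rows for the given names, keeping all columns."""
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"sequences not in alignment: {missing[:5]}")
        return Alignment(list(names), [self.rows[index[n]] for n in names])

    # -- site patterns -------------------------------------------------

    def patterns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique columns, their multiplicities, and the site->pattern map.

        Returns ``(columns, weights, site_index)`` where ``columns`` is a
        (n_patterns, n_sequences) array of single characters, ``weights``
        the multiplicity of each pattern, and ``site_index[i]`` the
        pattern of alignment column i.  Pattern compression never changes
        a likelihood; it only avoids recomputing identical columns.
        """
        if self._patterns is None:
            mat = np.array([list(r) for r in self.rows]).T  # sites x seqs
            cols, site_index, weights = np.unique(
                mat, axis=0, return_inverse=True, return_counts=True
            )
            self._patterns = (cols, weights, site_index.ravel())
        return self._patterns

    def tip_indicators(self) -> np.ndarray:
        """(n_sequences, n_patterns, 20) indicator array over patterns."""
        cols, _, _ = self.patterns()
        out = np.empty((self.n_sequences, cols.shape[0], alphabet.N_STATES))
        for s in range(self.n_sequences):
            for p, symbol in enumerate(cols[:, s]):
                out[s, p] = alphabet.indicator(symbol)
        return out

    def residue_counts(self) -> np.ndarray:
        """Counts of the 20 canonical residues (ambiguity codes skipped)."""
        counts = np.zeros(alphabet.N_STATES)
        for row in self.rows:
            for ch in row:
                idx = alphabet.INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        return counts

    # -- I/O -----------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "Alignment":
        return read_alignment(path, fmt=fmt)

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        write_alignment(self, path, fmt=fmt)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".phy", ".phylip"}:
        return "phylip-relaxed"
    if suffix in {".fa", ".fasta", ".faa", ".fas"}:
        return "fasta"
    with open(path) as fh:
        first = fh.readline()
    return "fasta" if first.startswith(">") else "phylip-relaxed"


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or (relaxed) PHYLIP protein alignment."""
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
    else:
        records = list(AlignIO.read(path, fmt))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(alignment: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(alignment.names, alignment.rows)
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    else:
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)
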