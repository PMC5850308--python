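"""Named reference sequence collections with a molecular-class label.

A :class:`ReferenceSet` is the unit the matcher, the classifier and the
synthetic generator exchange: an ordered mapping ``name -> sequence`` tagged
with one molecular class (``mirna``, ``rrna``, ``trna``, ``mrna``,
``retro``, ``pri_mirna``, ``genome``).  FASTA round-tripping goes through
Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Molecular classes, ordered specific-to-generic.  This ordering is the
#: default priority used when a read hits references of several classes.
CLASS_PRIORITY: tuple[str, ...] = (
    "mirna",
    "rrna",
    "trna",
    "mrna",
    "retro",
    "pri_mirna",
    "genome",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSet:
    """A FASTA-writable set of reference sequences of one molecular class.

    Parameters
    ----------
    class_label:
        One of :data:`CLASS_PRIORITY`.
    sequences:
        Ordered mapping of reference name to uppercase DNA sequence.
    """

    class_label: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_PRIORITY:
            raise ValueError(
                f"unknown molecular class {self.class_label!r}; "
                f"expected one of {CLASS_PRIORITY}"
            )
        self.sequences = {n: s.upper() for n, s in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences.items())

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        records = [
            SeqRecord(Seq(seq), id=name, description=self.class_label)
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")
        return path

    @classmethod
    def read_fasta(cls, path: str | Path, class_label: str) -> "ReferenceSet":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(class_label=class_label, sequences=sequences)
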