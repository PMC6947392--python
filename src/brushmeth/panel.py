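"""Amplicon panel model and on-disk formats.

A panel is a set of locus-specific amplicon reference sequences together
with the 0-based offsets of the cytosines of their CpG dinucleotides.
On disk a panel is a FASTA file of amplicon sequences plus a tab-separated
sidecar with columns ``gene``, ``offset`` (0-based, half-open w.r.t. the
CpG dinucleotide [offset, offset+2)) and ``cpg_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"

#: Default gene labels for the 13-gene promoter panel.
DEFAULT_GENES = (
    "ZAP70", "ITGA4", "KIF1A", "PARP15", "EPHX3", "NTM", "LRRTM1",
    "FLI1", "MIR193", "LINC00599", "MIR296", "TERT", "GP1BB",
)


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class Amplicon:
    """One amplicon reference with its declared CpG positions."""

    gene_name: str
    sequence: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set(DNA_ALPHABET):
            raise PanelError(
                f"{self.gene_name}: sequence contains non-ACGT characters"
            )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "cpg_positions", tuple(sorted(self.cpg_positions)))
        for p in self.cpg_positions:
            if not (0 <= p < len(seq) - 1):
                raise PanelError(f"{self.gene_name}: CpG offset {p} out of range")
            if seq[p] != "C" or seq[p + 1] != "G":
                raise PanelError(
                    f"{self.gene_name}: position {p} is not a CpG "
                    f"({seq[p:p + 2]!r})"
                )

    @property
    def cpg_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.gene_name}:{p}" for p in self.cpg_positions)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconPanel:
    """An ordered collection of amplicons with globally unique CpG ids."""

    amplicons: tuple[Amplicon, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        names = [a.gene_name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise PanelError("duplicate amplicon gene names")
        ids = self.cpg_ids
        if len(set(ids)) != len(ids):
            raise PanelError("CpG ids are not unique across the panel")

    @property
    def cpg_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for amp in self.amplicons:
            out.extend(amp.cpg_ids)
        return tuple(out)

    @property
    def n_cpgs(self) -> int:
        return sum(len(a.cpg_positions) for a in self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def get(self, gene_name: str) -> Amplicon:
        for amp in self.amplicons:
            if amp.gene_name == gene_name:
                return amp
        raise KeyError(gene_name)

    # -- on-disk representation -------------------------------------------

    def write(self, fasta_path: str | Path, sidecar_path: str | Path) -> None:
        """Write sequences as FASTA plus a ``gene\\toffset\\tcpg_id`` sidecar."""
        records = [
            SeqRecord(Seq(a.sequence), id=a.gene_name, description="")
            for a in self.amplicons
        ]
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        with open(sidecar_path, "w") as fh:
            fh.write("gene\toffset\tcpg_id\n")
            for amp in self.amplicons:
                for p, cid in zip(amp.cpg_positions, amp.cpg_ids):
                    fh.write(f"{amp.gene_name}\t{p}\t{cid}\n")

    @classmethod
    def read(cls, fasta_path: str | Path, sidecar_path: str | Path) -> "AmpliconPanel":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        positions: dict[str, list[int]] = {name: [] for name in seqs}
        with open(sidecar_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["gene", "offset"]:
                raise PanelError(f"unexpected sidecar header: {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                gene, offset, _cpg_id = line.rstrip("\n").split("\t")
                if gene not in positions:
                    raise PanelError(f"sidecar gene {gene!r} missing from FASTA")
                positions[gene].append(int(offset))
        amplicons = tuple(
            Amplicon(name, seqs[name], tuple(positions[name])) for name in seqs
        )
        return cls(amplicons)


def scan_cpg_positions(sequence: str) -> tuple[int, ...]:
    """All offsets ``p`` with ``sequence[p:p+2] == 'CG'`` (plain string scan)."""
    seq = sequence.upper()
    return tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
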