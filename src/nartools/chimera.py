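"""Transmembrane-domain (TMD) chimera construction for rhodopsin apoproteins.

Each Na+-pump rhodopsin apoprotein is partitioned into seven contiguous TMD
segments, each containing one transmembrane helix.  Chimeras swap the
N-terminal ``k`` TMDs of one parent onto the C-terminal ``7-k`` TMDs of the
other.  Junctions follow the published residue ranges literally: the
N-terminal part runs through the last residue of the donor's TMD ``k`` and
the C-terminal part resumes at the acceptor's stated resumption residue, so
one acceptor residue is skipped at each join (a numbering-offset artifact of
the two parents' alignment).  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DomainBoundaries",
    "ChimeraSpec",
    "IANAR_BOUNDARIES",
    "KR2_BOUNDARIES",
    "split_domains",
    "build_chimera",
    "chimera_record",
]

N_SEGMENTS = 7


@dataclass(frozen=True)
class DomainBoundaries:
    """1-based start residues of TMD2..TMD7 (TMD1 starts at residue 1).

    ``junction_end(k)`` is the last residue of TMD ``k`` (the residue before
    the start of TMD ``k+1``), i.e. the residue at which an N-terminal donor
    segment ends.
    """

    segment_starts: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        starts = tuple(int(s) for s in self.segment_starts)
        if len(starts) != N_SEGMENTS - 1:
            raise ValueError("exactly six segment starts (TMD2..TMD7) required")
        if any(b <= a for a, b in zip(starts, starts[1:])) or starts[0] <= 1:
            raise ValueError("segment starts must be strictly increasing and > 1")
        object.__setattr__(self, "segment_starts", starts)

    def junction_end(self, k: int) -> int:
        if not 1 <= k <= N_SEGMENTS - 1:
            raise ValueError("junction index must be in 1..6")
        return self.segment_starts[k - 1] - 1

    def resumption_start(self, k: int) -> int:
        if not 1 <= k <= N_SEGMENTS - 1:
            raise ValueError("junction index must be in 1..6")
        return self.segment_starts[k - 1]


# Published junctions: IaNaR N-terminal segments end at these residues
# (Val52, Asn100, Val127, Val160, Lys192, Phe234) and KR2 C-terminal
# segments resume at Asp54, Asp102, Ser129, Ser162, Glu194, Ser236.
IANAR_BOUNDARIES = DomainBoundaries((53, 101, 128, 161, 193, 235))
KR2_BOUNDARIES = DomainBoundaries((54, 102, 129, 162, 194, 236))


@dataclass(frozen=True)
class ChimeraSpec:
    """N-terminal parent, C-terminal parent, and the junction index (1..6).

    ``junction_index`` is the number of TMDs contributed by the N-terminal
    parent.
    """

    n_terminal_parent: str
    c_terminal_parent: str
    junction_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.junction_index <= N_SEGMENTS - 1:
            raise ValueError("junction_index must be in 1..6")


def _as_str(sequence) -> str:
    if isinstance(sequence, SeqRecord):
        return str(sequence.seq)
    return str(sequence)


def split_domains(sequence, boundaries: DomainBoundaries) -> list[str]:
    """Partition a sequence into its seven TMD segments.

    The segments are contiguous and their concatenation equals the input
    exactly.
    """
    seq = _as_str(sequence)
    starts = (1,) + boundaries.segment_starts
    if boundaries.segment_starts[-1] > len(seq):
        raise ValueError("segment start beyond sequence length")
    ends = boundaries.segment_starts + (len(seq) + 1,)
    return [seq[s - 1 : e - 1] for s, e in zip(starts, ends)]


def build_chimera(
    parent_n,
    parent_c,
    spec: ChimeraSpec,
    boundaries_n: DomainBoundaries = IANAR_BOUNDARIES,
    boundaries_c: DomainBoundaries = KR2_BOUNDARIES,
) -> str:
    """Assemble a chimera at the given TMD junction.

    Takes residues 1..junction_end(k) of the N-terminal parent (its own
    boundary set) and residues resumption_start(k)..end of the C-terminal
    parent (its boundary set).
    """
    k = spec.junction_index
    n_seq = _as_str(parent_n)
    c_seq = _as_str(parent_c)
    n_end = boundaries_n.junction_end(k)
    c_start = boundaries_c.resumption_start(k)
    if n_end > len(n_seq):
        raise ValueError("N-terminal parent shorter than its junction end")
    if c_start > len(c_seq):
        raise ValueError("C-terminal parent shorter than its resumption start")
    return n_seq[:n_end] + c_seq[c_start - 1 :]


def chimera_record(
    parent_n: SeqRecord,
    parent_c: SeqRecord,
    spec: ChimeraSpec,
    boundaries_n: DomainBoundaries = IANAR_BOUNDARIES,
    boundaries_c: DomainBoundaries = KR2_BOUNDARIES,
) -> SeqRecord:
    """FASTA-ready record for a chimera, named after parents and junction."""
    seq = build_chimera(parent_n, parent_c, spec, boundaries_n, boundaries_c)
    k = spec.junction_index
    name = f"{spec.n_terminal_parent}{k}_{spec.c_terminal_parent}{N_SEGMENTS - k}_chimera"
    return SeqRecord(
        Seq(seq), id=name,
        description=(
            f"TMD1-{k} of {spec.n_terminal_parent} + TMD{k + 1}-7 of "
            f"{spec.c_terminal_parent}; length {len(seq)}"
        ),
    )
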