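"""Sequence records for membrane-anchored chain simulations.

A :class:`SequenceRecord` couples a one-letter amino-acid sequence with the
span of N-terminal residues that is held helical (the transmembrane anchor)
and an offset translating local 1-based numbering into global
(UniProt-style) numbering.

The module also provides the constructors used throughout the test
experiments: the proline/serine control sequence, generalized P/S-repeat
chains, and the centered-peptide sequence used by the kinase
docking-availability screen.
"""

from __future__ import annotations

from dataclasses import dataclass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Transmembrane span of human LRP6 (T1371-I1393), 23 residues.
LRP6_TM_ANCHOR = "TNTVGSVIGVIVTIFVSGTVYFI"

# Control chain: the LRP6 transmembrane helix followed by a proline/serine
# repeat of the same overall length as the LRP6 membrane+intracellular
# segment.  Stored verbatim (line breaks stripped); the occasional double
# letter in the repeat is kept as-is.
_CONTROL = (
    "TNTVGSVIGVIVTIFVSGTVYFIPSPSPSPSPSPSPSPSPSPSPSPSSPSPSPSPSPSPSPS"
    "PSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPS"
    "PSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPS"
    "PSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPSPS"
)


@dataclass(frozen=True)
class SequenceRecord:
    """One-letter sequence with a designated helical anchor span.

    Parameters
    ----------
    id : str
        Record identifier (FASTA description line for file input).
    residues : str
        One-letter amino-acid string (standard 20 codes only).
    anchor_span : tuple of int
        Inclusive local residue interval ``(1, k)`` constrained to helix.
    numbering_offset : int
        Added to the local index to obtain the global residue number
        (1370 for the LRP6 intracellular segment).
    """

    id: str
    residues: str
    anchor_span: tuple[int, int]
    numbering_offset: int = 0

    def __post_init__(self):
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")
        lo, hi = self.anchor_span
        if lo != 1:
            raise ValueError("anchor_span must start at local residue 1")
        if hi < lo:
            raise ValueError("anchor_span must be non-empty")
        if hi - lo + 1 >= len(self.residues):
            raise ValueError("anchor_span must be shorter than the chain")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def anchor_length(self) -> int:
        return self.anchor_span[1] - self.anchor_span[0] + 1

    def global_number(self, local_index: int) -> int:
        """Global (UniProt-style) residue number for a 1-based local index."""
        return local_index + self.numbering_offset

    def is_anchor(self, local_index: int) -> bool:
        return self.anchor_span[0] <= local_index <= self.anchor_span[1]


def control_sequence() -> SequenceRecord:
    """The proline/serine control chain with the LRP6 transmembrane anchor.

    The sequence is a fixed constant: the 23-residue transmembrane helix
    followed by alternating P/S covering the remaining length of the LRP6
    membrane-plus-intracellular segment.
    """
    return SequenceRecord(
        id="control_ps_repeat",
        residues=_CONTROL,
        anchor_span=(1, 23),
        numbering_offset=0,
    )


def make_ps_repeat_sequence(anchor: str, total_length: int,
                            record_id: str = "ps_repeat") -> SequenceRecord:
    """Anchor followed by an alternating P/S repeat truncated to
    ``total_length`` residues."""
    if len(anchor) < 3:
        raise ValueError("anchor must have at least 3 residues")
    if total_length <= len(anchor):
        raise ValueError("total_length must exceed the anchor length")
    n_tail = total_length - len(anchor)
    tail = ("PS" * (n_tail // 2 + 1))[:n_tail]
    return SequenceRecord(
        id=record_id,
        residues=anchor + tail,
        anchor_span=(1, len(anchor)),
    )


def make_docking_test_sequence(peptide: str, total_length: int = 100,
                               record_id: str = "docking_test"
                               ) -> tuple[SequenceRecord, tuple[int, int]]:
    """Embed ``peptide`` at the center of a P/S-repeat chain.

    Returns the record and the inclusive local interval occupied by the
    peptide (the binding region used for superposition downstream).  The
    peptide starts at ``floor((total_length - len) / 2) + 1``.  The record's
    anchor span is the minimal ``(1, 1)``: the chain has no transmembrane
    helix and is never plane-filtered.
    """
    if len(peptide) < 1:
        raise ValueError("peptide must be non-empty")
    if total_length < len(peptide):
        raise ValueError("total_length must be at least the peptide length")
    start = (total_length - len(peptide)) // 2 + 1
    end = start + len(peptide) - 1
    left = start - 1
    right = total_length - end
    left_flank = ("PS" * (left // 2 + 1))[:left]
    right_flank = ("PS" * (right // 2 + 1))[:right]
    residues = left_flank + peptide + right_flank
    if total_length == len(peptide):
        # degenerate: no flanks; SequenceRecord still needs a valid anchor
        # shorter than the chain
        if total_length < 2:
            raise ValueError("degenerate docking sequence needs >= 2 residues")
    record = SequenceRecord(
        id=record_id,
        residues=residues,
        anchor_span=(1, 1),
    )
    return record, (start, end)


def read_fasta(path) -> SequenceRecord:
    """Read the first record of a FASTA file as a SequenceRecord.

    The anchor span defaults to the first 23 residues (the LRP6
    transmembrane helix convention); callers with a different anchor
    construct the record directly.
    """
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return SequenceRecord(
        id=rec.description,
        residues=str(rec.seq).upper(),
        anchor_span=(1, 23),
    )
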