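"""Class I PDZ-binding motif scanning of protein C-termini.

Class I PDZ-binding motifs (consensus S/T-x-Phi at the extreme
C-terminus, typically preceded by an acidic residue) anchor Shaker-type
channels to MAGUK scaffolds at synapses and axons.  The scanner calls
the final four residues (positions -3..0) against a configurable
consensus, and reports near-consensus motifs that deviate at exactly
one constrained position by an allowed conservative substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO

__all__ = ["MotifCall", "PdzConsensus", "pdz_scan", "scan_fasta"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PdzConsensus:
    """Consensus residue sets per constrained position and the allowed
    single conservative substitutions.

    Positions are numbered from the C-terminus: 0 is the final residue,
    -2 the canonical S/T, -3 the acidic position; -1 is unconstrained.
    The default substitution table is built from observed near-consensus
    motifs rather than a substitution matrix, and is fully overridable.
    """

    consensus: dict = field(
        default_factory=lambda: {-3: {"E", "D"}, -2: {"S", "T"}, 0: {"V", "L", "I"}}
    )
    substitutions: dict = field(
        default_factory=lambda: {-3: {"H", "Q"}, -2: {"F", "G"}, 0: {"F"}}
    )


@dataclass(frozen=True)
class MotifCall:
    sequence_id: str
    c_terminal_4mer: str
    call: str  # "consensus" | "near_consensus" | "none"
    substitution_position: Optional[int] = None  # -3..0

    def __post_init__(self) -> None:
        if self.call == "near_consensus" and self.substitution_position is None:
            raise ValueError("near-consensus call requires the deviating position")


def pdz_scan(
    sequence: str,
    sequence_id: str = "",
    consensus: Optional[PdzConsensus] = None,
) -> MotifCall:
    """Call the C-terminal Class I PDZ-binding motif of one protein.

    The call is a pure function of the final four residues: consensus
    when all constrained positions match; near-consensus when exactly
    one constrained position deviates and the deviation is in the
    allowed-substitution set; none otherwise.
    """
    cfg = consensus or PdzConsensus()
    seq = str(sequence).strip().upper().rstrip("*")
    if len(seq) < 4:
        raise ValueError("sequence must be at least 4 residues long")
    tail = seq[-4:]
    if not set(tail) <= _AA:
        bad = sorted(set(tail) - _AA)
        raise ValueError(f"non-standard residues in C-terminal 4-mer: {bad}")

    deviations = []
    allowed = True
    for pos, residues in cfg.consensus.items():
        aa = tail[pos + 3]  # pos -3 -> index 0 ... pos 0 -> index 3
        if aa not in residues:
            deviations.append(pos)
            if aa not in cfg.substitutions.get(pos, set()):
                allowed = False

    if not deviations:
        call, sub = "consensus", None
    elif len(deviations) == 1 and allowed:
        call, sub = "near_consensus", deviations[0]
    else:
        call, sub = "none", None
    return MotifCall(
        sequence_id=sequence_id,
        c_terminal_4mer=tail,
        call=call,
        substitution_position=sub,
    )


def scan_fasta(path, consensus: Optional[PdzConsensus] = None) -> list[MotifCall]:
    """Scan every protein in a FASTA file."""
    return [
        pdz_scan(str(rec.seq), sequence_id=rec.id, consensus=consensus)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
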