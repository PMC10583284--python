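"""Placement of protein-level substitutions into signal-peptide coordinates.

A signal peptide is stored together with its first mature residue (the
"+1" position) because the cleavage-site rule evaluates it.  Coordinates
are 1-based protein positions; cleavage-relative coordinates count from
the signal-peptidase cut, with −1 the last signal-peptide residue, +1 the
first mature residue, and no zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import AnnotationError, SequenceError
from .scales import validate_sequence


class Region(str, enum.Enum):
    """Signal-peptide region of a substituted position."""

    N = "N"
    H = "H"
    C = "C"
    PLUS1 = "PLUS1"
    OUTSIDE = "OUTSIDE"

    def __str__(self) -> str:  # for TSV/report serialization
        return self.value


@dataclass(frozen=True)
class SignalPeptide:
    """An annotated signal peptide plus the +1 mature residue.

    ``sequence`` has length ``sp_len + 1``.  Regions tile positions
    1..sp_len: N = 1..n_end, H = n_end+1..h_end, C = h_end+1..sp_len.
    The cleavage site sits between positions ``sp_len`` (−1) and
    ``sp_len + 1`` (+1).
    """

    protein_id: str
    gene: str
    sequence: str
    n_end: int
    h_end: int
    sp_len: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not (1 <= self.n_end < self.h_end < self.sp_len):
            raise AnnotationError(
                f"{self.protein_id}: region boundaries must satisfy "
                f"1 <= n_end < h_end < sp_len, got "
                f"({self.n_end}, {self.h_end}, {self.sp_len})"
            )
        if self.sp_len != len(self.sequence) - 1:
            raise AnnotationError(
                f"{self.protein_id}: sp_len={self.sp_len} conflicts with "
                f"sequence of {len(self.sequence)} residues "
                f"(expected sp_len + 1 including the +1 residue)"
            )

    @property
    def n_region(self) -> str:
        return self.sequence[: self.n_end]

    @property
    def h_region(self) -> str:
        return self.sequence[self.n_end : self.h_end]

    @property
    def c_region(self) -> str:
        return self.sequence[self.h_end : self.sp_len]

    @property
    def plus1(self) -> str:
        """The first residue of the mature protein."""
        return self.sequence[self.sp_len]

    def residue(self, position: int) -> str:
        """Residue at 1-based ``position`` within the stored sequence."""
        if not 1 <= position <= len(self.sequence):
            raise AnnotationError(
                f"{self.protein_id}: position {position} outside stored "
                f"sequence (1..{len(self.sequence)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MissenseVariant:
    """A single amino-acid substitution in protein coordinates."""

    variant_id: str
    protein_id: str
    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", validate_sequence(self.wt))
        object.__setattr__(self, "mut", validate_sequence(self.mut))
        if len(self.wt) != 1 or len(self.mut) != 1:
            raise SequenceError("wt and mut must be single residues")
        if self.wt == self.mut:
            raise SequenceError(
                f"{self.variant_id}: wt and mut are both {self.wt!r}; "
                "identity substitutions are not variants"
            )
        if self.position < 1:
            raise AnnotationError(f"{self.variant_id}: position must be >= 1")


@dataclass(frozen=True)
class MappedVariant:
    """A variant placed into signal-peptide coordinates."""

    variant: MissenseVariant
    region: Region
    cleavage_relative: int


def locate_substitution(wt_seq: str, mut_seq: str) -> tuple[int, str, str]:
    """Find the unique substitution between a WT/mutant sequence pair.

    Returns ``(position, wt, mut)`` with a 1-based position.  Zero or more
    than one mismatch, or a length mismatch, is an error.
    """
    wt_norm = validate_sequence(wt_seq)
    mut_norm = validate_sequence(mut_seq)
    if len(wt_norm) != len(mut_norm):
        raise SequenceError(
            f"length mismatch: {len(wt_norm)} vs {len(mut_norm)} residues"
        )
    diffs = [i for i, (a, b) in enumerate(zip(wt_norm, mut_norm)) if a != b]
    if not diffs:
        raise SequenceError("sequences are identical: no substitution found")
    if len(diffs) > 1:
        raise SequenceError(
            f"{len(diffs)} substitutions found at positions "
            f"{[i + 1 for i in diffs]}; exactly one expected"
        )
    i = diffs[0]
    return i + 1, wt_norm[i], mut_norm[i]


def cleavage_relative_position(sp: SignalPeptide, position: int) -> int:
    """Convert a 1-based protein position to a cleavage-relative coordinate.

    Positions inside the signal peptide map to −sp_len..−1; the first
    mature residue maps to +1.  There is no position 0.  Positions beyond
    the stored sequence are an error.
    """
    if not 1 <= position <= len(sp.sequence):
        raise AnnotationError(
            f"{sp.protein_id}: position {position} outside stored sequence "
            f"(1..{len(sp.sequence)})"
        )
    if position <= sp.sp_len:
        return position - sp.sp_len - 1
    return position - sp.sp_len


def assign_region(sp: SignalPeptide, position: int) -> Region:
    """Region label of a 1-based protein position (total over positions ≥ 1)."""
    if position < 1:
        raise AnnotationError(f"position must be >= 1, got {position}")
    if position <= sp.n_end:
        return Region.N
    if position <= sp.h_end:
        return Region.H
    if position <= sp.sp_len:
        return Region.C
    if position == sp.sp_len + 1:
        return Region.PLUS1
    return Region.OUTSIDE


def apply_variant(sp: SignalPeptide, v: MissenseVariant) -> str:
    """Build the mutant stored sequence by substituting ``v`` into ``sp``.

    The stored reference residue must agree with ``v.wt``; a mismatch
    signals stale annotation and is a hard error.
    """
    stored = sp.residue(v.position)
    if stored != v.wt:
        raise AnnotationError(
            f"{v.variant_id}: reference mismatch at {sp.protein_id} position "
            f"{v.position}: annotation has {stored!r}, variant claims {v.wt!r}"
        )
    seq = sp.sequence
    return seq[: v.position - 1] + v.mut + seq[v.position :]


def map_variant(sp: SignalPeptide, v: MissenseVariant) -> MappedVariant:
    """Attach region label and cleavage-relative coordinate to a variant.

    Variants strictly beyond the +1 position are labeled OUTSIDE (their
    cleavage-relative coordinate continues +2, +3, …) so whole-protein
    variant tables can be fed in and filtered rather than erroring.
    """
    region = assign_region(sp, v.position)
    if region is Region.OUTSIDE:
        rel = v.position - sp.sp_len
    else:
        rel = cleavage_relative_position(sp, v.position)
    return MappedVariant(variant=v, region=region, cleavage_relative=rel)
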