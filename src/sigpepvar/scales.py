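"""Residue scales and the elementary scoring arithmetic.

Two scales drive the H-region rule:

* **Kyte–Doolittle hydropathy** — positive values are hydrophobic.  The
  hydrophobicity change of a substitution is ``KD(mut) − KD(wt)``; a
  negative delta means the variant makes the signal peptide less
  hydrophobic and therefore a weaker SRP client.
* **Boman (protein-binding potential)** — per-residue solubility values
  derived from side-chain water/cyclohexane transfer free energies
  (kcal/mol), signed so that hydrophilic residues contribute positively.
  The Boman index of a sequence is the mean per-residue value; a high
  index indicates high protein-binding (hydrophilic) potential and hence
  poor engagement of the hydrophobic SRP54 groove.  Proline has no
  measured transfer free energy in the source data and is assigned 0.0.

Both tables ship as plain-text data assets (``data/*.tsv``) and can be
overridden by loading a custom table with :func:`load_scale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import InvalidResidueError, SequenceError

#: The 20 standard one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)


def _check_residue(residue: str) -> str:
    """Normalize case and reject anything that is not a standard residue.

    Ambiguity codes (B, Z, X) and selenocysteine (U) are rejected rather
    than imputed.
    """
    if not isinstance(residue, str) or len(residue) != 1:
        raise InvalidResidueError(f"expected a single residue letter, got {residue!r}")
    upper = residue.upper()
    if upper not in _AA_SET:
        raise InvalidResidueError(f"{residue!r} is not a standard amino-acid code")
    return upper


def validate_sequence(sequence: str) -> str:
    """Upper-case ``sequence`` and verify every residue is standard."""
    if not sequence:
        raise SequenceError("empty sequence")
    upper = sequence.upper()
    bad = set(upper) - _AA_SET
    if bad:
        raise InvalidResidueError(
            f"non-standard residue(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return upper


@dataclass(frozen=True)
class ResidueScale:
    """A residue → value lookup table covering the 20 standard residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != _AA_SET:
            missing = sorted(_AA_SET - keys)
            extra = sorted(keys - _AA_SET)
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing {missing}, extra {extra})"
            )
        for res, val in self.values.items():
            if not math.isfinite(val):
                raise ValueError(f"scale {self.name!r}: non-finite value for {res}")

    def __getitem__(self, residue: str) -> float:
        return self.values[_check_residue(residue)]


def load_scale(path: str | Path, name: str | None = None) -> ResidueScale:
    """Load a residue scale from a two-column TSV (``residue<TAB>value``)."""
    path = Path(path)
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("residue"):
            raise ValueError(f"{path}: expected header 'residue\\tvalue'")
        for line in handle:
            line = line.strip()
            if not line:
                continue
            res, val = line.split("\t")
            values[_check_residue(res)] = float(val)
    return ResidueScale(name or path.stem, values)


def _load_bundled(asset: str, name: str) -> ResidueScale:
    with resources.as_file(resources.files("sigpepvar.data") / asset) as p:
        return load_scale(p, name)


#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: ResidueScale = _load_bundled("kyte_doolittle.tsv", "kyte-doolittle")

#: Boman per-residue solubility / binding-potential values.
BOMAN: ResidueScale = _load_bundled("boman.tsv", "boman")


@dataclass(frozen=True)
class ScoreComponents:
    """Score components attached to a classified substitution.

    ``delta_kd`` and ``scaled_boman_change`` both follow the mut − wt
    convention: negative ``delta_kd`` is a hydrophobicity decrease and
    positive ``scaled_boman_change`` an increase in binding potential.
    """

    delta_kd: float
    scaled_boman_change: float
    sequence_length: int = field(default=0)


def scale_value(scale: ResidueScale, residue: str) -> float:
    """Tabulated value of ``residue`` under ``scale`` (pure lookup)."""
    return scale[residue]


def delta_hydrophobicity(
    wt: str, mut: str, scale: ResidueScale = KYTE_DOOLITTLE
) -> float:
    """Hydrophobicity change of a substitution, ``scale(mut) − scale(wt)``.

    Antisymmetric under WT/mutant swap; exactly 0 for identity substitutions.
    """
    return scale[mut] - scale[wt]


def boman_index(sequence: str, scale: ResidueScale = BOMAN) -> float:
    """Boman index: mean per-residue solubility value of ``sequence``."""
    seq = validate_sequence(sequence)
    return sum(scale[res] for res in seq) / len(seq)


def scaled_boman_change(
    wt_seq: str, mut_seq: str, scale: ResidueScale = BOMAN
) -> float:
    """Boman-index difference of a single-substitution pair, × 100.

    Computed as ``(boman_index(mut_seq) − boman_index(wt_seq)) × 100`` over
    the full stored sequences (signal peptide plus the +1 residue), which
    algebraically equals ``(scale(mut) − scale(wt)) / len × 100`` for the
    single substituted residue.  Positive values mean the variant raised
    the peptide's protein-binding potential, i.e. weakened the hydrophobic
    signal the SRP54 M-domain recognizes.
    """
    wt_norm = validate_sequence(wt_seq)
    mut_norm = validate_sequence(mut_seq)
    if len(wt_norm) != len(mut_norm):
        raise SequenceError(
            f"length mismatch: {len(wt_norm)} vs {len(mut_norm)} residues"
        )
    n_diff = sum(a != b for a, b in zip(wt_norm, mut_norm))
    if n_diff == 0:
        raise SequenceError("sequences are identical: no substitution to score")
    if n_diff > 1:
        raise SequenceError(f"{n_diff} substitutions found; exactly one expected")
    return (boman_index(mut_norm, scale) - boman_index(wt_norm, scale)) * 100.0
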