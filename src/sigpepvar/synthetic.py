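"""Synthetic signal peptides and planted variants with known ground truth.

The generator emulates the architecture of human signal peptides: a short
positively charged N-region, a leucine-dominated hydrophobic H-region and
a short C-region with alanine/glycine/serine-rich cleavage-site
positions, at median region lengths of 3/14/5 residues (22 overall, +1
mature residue appended).  Per-region residue profiles are a data asset
seeded from published human proteome composition (e.g. ~16.5% K/R in the
N-region with ~3:1 R:K, 36.93% leucine in the H-region, 20.14% alanine in
the C-region); residue 1 is always the initiator methionine.

Planted variants are constructed to satisfy — or, for the NONE label,
verifiably violate — one classification rule, with the decisive score's
distance from its threshold recorded as ``rule_margin`` (positive margin
⇔ flagged).  Because the rules are deterministic, classification must
recover planted labels exactly; recovery failures indicate wiring or
coordinate bugs, not statistical noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .classify import (
    ACIDIC,
    ClassificationConfig,
    DEFAULT_CONFIG,
    Mechanism,
)
from .compstats import PositionFrequencyTable, position_frequency_table
from .errors import ConfigError, DesignError
from .mapping import MissenseVariant, Region, SignalPeptide, assign_region
from .scales import AMINO_ACIDS, BOMAN, KYTE_DOOLITTLE


def load_region_profiles(path=None) -> dict[str, dict[str, float]]:
    """Load per-region residue probability profiles from a TSV data asset.

    Columns: region, residue, fraction.  Fractions are renormalized per
    region to absorb rounding in the asset.
    """
    profiles: dict[str, dict[str, float]] = {}
    if path is None:
        ctx = resources.as_file(
            resources.files("sigpepvar.data") / "region_profiles.tsv"
        )
    else:
        from contextlib import nullcontext

        ctx = nullcontext(path)
    with ctx as p, open(p, encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            profiles.setdefault(row["region"], {})[row["residue"]] = float(
                row["fraction"]
            )
    for region, prof in profiles.items():
        total = sum(prof.values())
        if not np.isclose(total, 1.0, atol=0.01):
            raise ConfigError(f"profile for region {region} sums to {total}")
        profiles[region] = {r: v / total for r, v in prof.items()}
    return profiles


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the signal-peptide generator.

    Region lengths are drawn uniformly from ``median ± jitter`` (clipped
    at 1), a bounded discrete distribution whose median equals the
    configured value; profiles default to the bundled composition asset.
    """

    n_peptides: int = 100
    region_length_medians: tuple[int, int, int] = (3, 14, 5)
    length_jitter: tuple[int, int, int] = (1, 3, 1)
    region_residue_profiles: Optional[Mapping[str, Mapping[str, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ConfigError("n_peptides must be >= 1")
        for m, j in zip(self.region_length_medians, self.length_jitter):
            if m - j < 1:
                raise ConfigError(
                    "length_jitter would allow region lengths below 1"
                )

    def profiles(self) -> dict[str, dict[str, float]]:
        if self.region_residue_profiles is not None:
            out = {k: dict(v) for k, v in self.region_residue_profiles.items()}
        else:
            out = load_region_profiles()
        for region in ("N", "H", "C", "PLUS1"):
            if region not in out:
                raise ConfigError(f"missing residue profile for region {region}")
            total = sum(out[region].values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError(
                    f"profile for region {region} sums to {total}, expected 1"
                )
        return out


@dataclass(frozen=True)
class PlantedVariant:
    """A planted substitution with its ground-truth label and margin."""

    variant: MissenseVariant
    truth_label: Mechanism
    rule_margin: float


def _sample_region(rng, profile: Mapping[str, float], length: int) -> str:
    residues = sorted(profile)
    p = np.array([profile[r] for r in residues])
    p = p / p.sum()
    return "".join(rng.choice(residues, size=length, p=p))


def generate_signal_peptides(params: GeneratorParams) -> list[SignalPeptide]:
    """Generate a reproducible collection of annotated signal peptides."""
    rng = np.random.default_rng(params.seed)
    profiles = params.profiles()
    peptides: list[SignalPeptide] = []
    for i in range(params.n_peptides):
        lengths = [
            int(m + rng.integers(-j, j + 1))
            for m, j in zip(params.region_length_medians, params.length_jitter)
        ]
        n_len, h_len, c_len = (max(1, l) for l in lengths)
        n_seq = "M" + _sample_region(rng, profiles["N"], n_len - 1)
        h_seq = _sample_region(rng, profiles["H"], h_len)
        c_seq = _sample_region(rng, profiles["C"], c_len)
        plus1 = _sample_region(rng, profiles["PLUS1"], 1)
        peptides.append(
            SignalPeptide(
                protein_id=f"SYNP{i:05d}",
                gene=f"SYNG{i:05d}",
                sequence=n_seq + h_seq + c_seq + plus1,
                n_end=n_len,
                h_end=n_len + h_len,
                sp_len=n_len + h_len + c_len,
            )
        )
    return peptides


def _h_margin(wt: str, mut: str, length: int, cfg: ClassificationConfig) -> float:
    """Decision margin of the H-rule (positive ⇔ flagged)."""
    delta_kd = KYTE_DOOLITTLE[mut] - KYTE_DOOLITTLE[wt]
    boman = (BOMAN[mut] - BOMAN[wt]) / length * 100.0
    return min(cfg.kd_decrease_threshold - delta_kd, boman - cfg.boman_cutoff)


def _plant_rapp(sp, pos, wt, cfg) -> Optional[tuple[str, float]]:
    best = None
    for mut in "RDEKNQ":  # strongly hydrophilic candidates
        if mut == wt:
            continue
        margin = _h_margin(wt, mut, len(sp.sequence), cfg)
        if margin > 0 and (best is None or margin > best[1]):
            best = (mut, margin)
    return best


def _plant_none_h(sp, pos, wt, cfg) -> Optional[tuple[str, float]]:
    # prefer hydrophobicity-increasing swaps; fall back to small decreases
    # whose Boman change stays under the cutoff
    best = None
    for mut in AMINO_ACIDS:
        if mut == wt:
            continue
        margin = _h_margin(wt, mut, len(sp.sequence), cfg)
        if margin < 0 and (best is None or margin < best[1]):
            best = (mut, margin)
    return best


def plant_variants(
    peptides: Sequence[SignalPeptide],
    design: Mapping[Mechanism, int],
    cfg: ClassificationConfig = DEFAULT_CONFIG,
    seed: int = 0,
    freq_table: Optional[PositionFrequencyTable] = None,
) -> list[PlantedVariant]:
    """Construct variants whose classification under ``cfg`` is known.

    ``design`` maps each truth label to a requested count.  Planting is
    deterministic for a fixed seed; an unsatisfiable request raises
    :class:`DesignError` naming the label.  NONE variants are planted in
    the H-region with substitutions that fail the decay rule.
    """
    rng = np.random.default_rng(seed)
    if freq_table is None:
        freq_table = position_frequency_table(peptides)
    planted: list[PlantedVariant] = []
    order = rng.permutation(len(peptides))
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"synv{counter:05d}"

    for label, count in design.items():
        made = 0
        for idx in np.tile(order, 1 + count // max(len(peptides), 1) * 2 + 2):
            if made >= count:
                break
            sp = peptides[int(idx)]
            cand = _plant_for_label(sp, label, cfg, freq_table, rng)
            if cand is None:
                continue
            pos, wt, mut, margin = cand
            planted.append(
                PlantedVariant(
                    variant=MissenseVariant(
                        variant_id=next_id(),
                        protein_id=sp.protein_id,
                        position=pos,
                        wt=wt,
                        mut=mut,
                    ),
                    truth_label=label,
                    rule_margin=margin,
                )
            )
            made += 1
        if made < count:
            raise DesignError(
                f"could only plant {made}/{count} variants for label "
                f"{label.value}: peptide set too small or rule unsatisfiable"
            )
    return planted


def _plant_for_label(sp, label, cfg, freq_table, rng):
    if label is Mechanism.RAPP_MRNA_DECAY or label is Mechanism.NONE:
        h_positions = list(range(sp.n_end + 1, sp.h_end + 1))
        rng.shuffle(h_positions)
        for pos in h_positions:
            wt = sp.residue(pos)
            picker = _plant_rapp if label is Mechanism.RAPP_MRNA_DECAY else _plant_none_h
            got = picker(sp, pos, wt, cfg)
            if got is not None:
                mut, margin = got
                return pos, wt, mut, margin
        return None
    if label is Mechanism.PROCESSING_FAILURE:
        for rel in sorted(cfg.c_positions, key=lambda r: rng.random()):
            pos = sp.sp_len + 1 + rel if rel < 0 else sp.sp_len + rel
            if not 1 <= pos <= len(sp.sequence):
                continue
            if assign_region(sp, pos) not in (Region.C, Region.PLUS1):
                continue
            wt = sp.residue(pos)
            rare = [
                (r, freq_table.frequency(rel, r))
                for r in AMINO_ACIDS
                if r != wt and freq_table.frequency(rel, r) < cfg.c_rarity_threshold
            ]
            if rare:
                mut, freq = min(rare, key=lambda t: t[1])
                return pos, wt, mut, cfg.c_rarity_threshold - freq
        return None
    if label is Mechanism.TRANSLOCATION_DEFECT:
        n_positions = [p for p in range(2, sp.n_end + 1)] or [1]
        rng.shuffle(n_positions)
        for pos in n_positions:
            wt = sp.residue(pos)
            if wt in ACIDIC:
                continue
            mut = "D" if wt != "D" else "E"
            return pos, wt, mut, 1.0
        return None
    raise DesignError(f"unknown truth label {label!r}")
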