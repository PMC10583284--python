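"""The three region-specific pathogenicity rules and their orchestrator.

A missense variant in a signal peptide is flagged as a predicted
pathogenic variant (PPV) by exactly one rule, dispatched on the region it
hits:

* **H-region** — a substitution that decreases Kyte–Doolittle
  hydrophobicity (ΔKD = KD(mut) − KD(wt) < 0) *and* raises the
  peptide-level Boman binding potential by at least the cutoff
  (scaled ΔBoman = (Boman(mut seq) − Boman(wt seq)) × 100 ≥ 20 by
  default) is predicted to escape SRP recognition, triggering RAPP
  quality control and decay of the protein's mRNA.
* **C-region / +1** — a substitution at the signal-peptidase-critical
  positions (−3, −1, +1 by default) that introduces a residue rarely
  observed there in wild-type peptides (< 2.5% by default) is predicted
  to impair cleavage (processing failure).
* **N-region** — a substitution introducing an acidic residue (D or E)
  where the wild type is not acidic is predicted to disturb the
  N-terminal positive charge required for correct orientation in the
  SEC61 translocon (translocation defect).

The scaled Boman change is stored in the mut − wt convention throughout;
a value ≥ +20 here is the same rule as a WT-minus-variant value ≤ −20.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .compstats import PositionFrequencyTable, position_frequency_table
from .errors import AnnotationError, ConfigError, SigPepVarError
from .mapping import (
    MappedVariant,
    MissenseVariant,
    Region,
    SignalPeptide,
    apply_variant,
    map_variant,
)
from .scales import ScoreComponents, delta_hydrophobicity, scaled_boman_change

#: Acidic residues whose introduction the N-region rule flags.
ACIDIC = frozenset("DE")


class Mechanism(str, enum.Enum):
    """Predicted molecular mechanism of a flagged variant."""

    RAPP_MRNA_DECAY = "RAPP_MRNA_DECAY"
    PROCESSING_FAILURE = "PROCESSING_FAILURE"
    TRANSLOCATION_DEFECT = "TRANSLOCATION_DEFECT"
    NONE = "NONE"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ClassificationConfig:
    """Tunable thresholds of the three rules.

    ``boman_cutoff`` is the minimum scaled Boman increase (mut − wt) for
    the H-rule; ``kd_decrease_threshold`` the ΔKD below which a
    substitution counts as a hydrophobicity decrease (0 = any strict
    decrease); ``c_rarity_threshold`` the wild-type frequency below which
    an incoming residue is "rare" at a cleavage-site position;
    ``c_positions`` the cleavage-relative positions the C-rule evaluates.
    Set ``c_all_positions`` to evaluate every C-region position present in
    the frequency table instead of only ``c_positions``.
    """

    boman_cutoff: float = 20.0
    kd_decrease_threshold: float = 0.0
    c_rarity_threshold: float = 0.025
    c_positions: frozenset[int] = frozenset({-3, -1, 1})
    c_all_positions: bool = False

    def __post_init__(self) -> None:
        if self.boman_cutoff <= 0:
            raise ConfigError("boman_cutoff must be positive")
        if not 0 < self.c_rarity_threshold < 1:
            raise ConfigError("c_rarity_threshold must be a fraction in (0, 1)")
        object.__setattr__(self, "c_positions", frozenset(self.c_positions))
        if 0 in self.c_positions:
            raise ConfigError("c_positions must not contain 0 (no such position)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassificationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "c_positions" in kwargs:
            kwargs["c_positions"] = frozenset(int(p) for p in kwargs["c_positions"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "boman_cutoff": self.boman_cutoff,
            "kd_decrease_threshold": self.kd_decrease_threshold,
            "c_rarity_threshold": self.c_rarity_threshold,
            "c_positions": sorted(self.c_positions),
            "c_all_positions": self.c_all_positions,
        }


DEFAULT_CONFIG = ClassificationConfig()


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the rules for one mapped variant."""

    mapped: MappedVariant
    is_ppv: bool
    mechanism: Mechanism
    scores: ScoreComponents
    gene: str = ""
    protein_id: str = ""
    mut_position_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.is_ppv != (self.mechanism is not Mechanism.NONE):
            raise SigPepVarError("mechanism NONE must coincide with is_ppv False")


def _scores(sp: SignalPeptide, v: MissenseVariant) -> ScoreComponents:
    mut_seq = apply_variant(sp, v)
    return ScoreComponents(
        delta_kd=delta_hydrophobicity(v.wt, v.mut),
        scaled_boman_change=scaled_boman_change(sp.sequence, mut_seq),
        sequence_length=len(sp.sequence),
    )


def classify_h(
    sp: SignalPeptide,
    v: MissenseVariant,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """H-region rule: hydrophobicity decrease plus Boman increase ≥ cutoff."""
    mapped = map_variant(sp, v)
    if mapped.region is not Region.H:
        raise AnnotationError(
            f"{v.variant_id}: classify_h requires an H-region variant, "
            f"got {mapped.region}"
        )
    scores = _scores(sp, v)
    flagged = (
        scores.delta_kd < cfg.kd_decrease_threshold
        and scores.scaled_boman_change >= cfg.boman_cutoff
    )
    return ClassificationResult(
        mapped=mapped,
        is_ppv=flagged,
        mechanism=Mechanism.RAPP_MRNA_DECAY if flagged else Mechanism.NONE,
        scores=scores,
        gene=sp.gene,
        protein_id=sp.protein_id,
    )


def classify_c(
    sp: SignalPeptide,
    v: MissenseVariant,
    freq_table: PositionFrequencyTable,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Cleavage-site rule: rare incoming residue at a peptidase-critical position."""
    mapped = map_variant(sp, v)
    if mapped.region not in (Region.C, Region.PLUS1):
        raise AnnotationError(
            f"{v.variant_id}: classify_c requires a C-region or +1 variant, "
            f"got {mapped.region}"
        )
    if freq_table is None:
        raise SigPepVarError("the cleavage-site rule needs a wild-type frequency table")
    scores = _scores(sp, v)
    evaluated = cfg.c_all_positions or mapped.cleavage_relative in cfg.c_positions
    freq: Optional[float] = None
    flagged = False
    if evaluated:
        freq = freq_table.frequency(mapped.cleavage_relative, v.mut)
        flagged = freq < cfg.c_rarity_threshold
    return ClassificationResult(
        mapped=mapped,
        is_ppv=flagged,
        mechanism=Mechanism.PROCESSING_FAILURE if flagged else Mechanism.NONE,
        scores=scores,
        gene=sp.gene,
        protein_id=sp.protein_id,
        mut_position_frequency=freq,
    )


def classify_n(
    sp: SignalPeptide,
    v: MissenseVariant,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """N-region rule: introduction of an acidic residue (D/E) into a
    non-acidic wild-type position."""
    mapped = map_variant(sp, v)
    if mapped.region is not Region.N:
        raise AnnotationError(
            f"{v.variant_id}: classify_n requires an N-region variant, "
            f"got {mapped.region}"
        )
    scores = _scores(sp, v)
    flagged = v.mut in ACIDIC and v.wt not in ACIDIC
    return ClassificationResult(
        mapped=mapped,
        is_ppv=flagged,
        mechanism=Mechanism.TRANSLOCATION_DEFECT if flagged else Mechanism.NONE,
        scores=scores,
        gene=sp.gene,
        protein_id=sp.protein_id,
    )


def classify_variant(
    sp: SignalPeptide,
    v: MissenseVariant,
    freq_table: Optional[PositionFrequencyTable] = None,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Dispatch a variant to the rule of its region.

    OUTSIDE variants pass through unclassified (``is_ppv`` False,
    mechanism NONE) so whole-protein variant tables can be processed.
    """
    region = map_variant(sp, v).region
    if region is Region.N:
        return classify_n(sp, v, cfg)
    if region is Region.H:
        return classify_h(sp, v, cfg)
    if region in (Region.C, Region.PLUS1):
        return classify_c(sp, v, freq_table, cfg)
    # OUTSIDE: keep scores where computable for reporting
    mapped = map_variant(sp, v)
    scores = _scores(sp, v) if v.position <= len(sp.sequence) else ScoreComponents(
        delta_kd=delta_hydrophobicity(v.wt, v.mut),
        scaled_boman_change=0.0,
        sequence_length=len(sp.sequence),
    )
    return ClassificationResult(
        mapped=mapped,
        is_ppv=False,
        mechanism=Mechanism.NONE,
        scores=scores,
        gene=sp.gene,
        protein_id=sp.protein_id,
    )


def classify_pair(
    wt_seq: str,
    mut_seq: str,
    cfg: ClassificationConfig = DEFAULT_CONFIG,
    variant_id: str = "pair",
    gene: str = "",
) -> ClassificationResult:
    """mRNA-decay prediction for a WT/mutant sequence pair.

    Sequence-pair input carries no region annotation, so this applies the
    decay (H-rule) arithmetic directly: ΔKD of the substituted residue and
    the scaled Boman change over the full stored sequences (signal peptide
    plus the +1 residue).  This is the mode in which literature
    validation sets of WT/mutant signal-peptide pairs are scored.
    """
    from .mapping import locate_substitution  # local to avoid cycle noise

    position, wt, mut = locate_substitution(wt_seq, mut_seq)
    scores = ScoreComponents(
        delta_kd=delta_hydrophobicity(wt, mut),
        scaled_boman_change=scaled_boman_change(wt_seq, mut_seq),
        sequence_length=len(wt_seq),
    )
    flagged = (
        scores.delta_kd < cfg.kd_decrease_threshold
        and scores.scaled_boman_change >= cfg.boman_cutoff
    )
    variant = MissenseVariant(
        variant_id=variant_id, protein_id=gene or variant_id,
        position=position, wt=wt, mut=mut,
    )
    mapped = MappedVariant(
        variant=variant,
        region=Region.H,
        cleavage_relative=position - len(wt_seq) + 1
        if position == len(wt_seq)
        else position - len(wt_seq),
    )
    return ClassificationResult(
        mapped=mapped,
        is_ppv=flagged,
        mechanism=Mechanism.RAPP_MRNA_DECAY if flagged else Mechanism.NONE,
        scores=scores,
        gene=gene,
        protein_id=gene,
    )


@dataclass
class BatchSummary:
    """Accounting of a classification run."""

    n_peptides: int = 0
    n_variants: int = 0
    n_mapped: int = 0
    n_outside: int = 0
    n_ppv: int = 0
    variants_per_region: dict = field(default_factory=dict)
    ppv_per_region: dict = field(default_factory=dict)
    ppv_per_mechanism: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_peptides": self.n_peptides,
            "n_variants": self.n_variants,
            "n_mapped": self.n_mapped,
            "n_outside": self.n_outside,
            "n_ppv": self.n_ppv,
            "variants_per_region": dict(self.variants_per_region),
            "ppv_per_region": dict(self.ppv_per_region),
            "ppv_per_mechanism": dict(self.ppv_per_mechanism),
        }


@dataclass
class BatchResult:
    """Per-variant results, run summary, and rejected inputs with reasons."""

    results: list[ClassificationResult]
    summary: BatchSummary
    rejects: list[tuple[str, str]]


def classify_batch(
    peptides: Sequence[SignalPeptide],
    variants: Iterable[MissenseVariant],
    cfg: ClassificationConfig = DEFAULT_CONFIG,
    freq_table: Optional[PositionFrequencyTable] = None,
) -> BatchResult:
    """Classify every variant against its peptide; unresolvable or
    inconsistent variants are collected in a rejects report, never
    silently dropped.

    The wild-type frequency table for the cleavage-site rule is built
    from ``peptides`` when not supplied.
    """
    by_id = {sp.protein_id: sp for sp in peptides}
    if freq_table is None and peptides:
        freq_table = position_frequency_table(peptides)
    results: list[ClassificationResult] = []
    rejects: list[tuple[str, str]] = []
    summary = BatchSummary(n_peptides=len(peptides))
    for v in variants:
        summary.n_variants += 1
        sp = by_id.get(v.protein_id)
        if sp is None:
            rejects.append((v.variant_id, f"unknown protein_id {v.protein_id!r}"))
            continue
        try:
            res = classify_variant(sp, v, freq_table, cfg)
        except SigPepVarError as exc:
            rejects.append((v.variant_id, str(exc)))
            continue
        results.append(res)
        region = res.mapped.region.value
        if res.mapped.region is Region.OUTSIDE:
            summary.n_outside += 1
        else:
            summary.n_mapped += 1
        summary.variants_per_region[region] = (
            summary.variants_per_region.get(region, 0) + 1
        )
        if res.is_ppv:
            summary.n_ppv += 1
            summary.ppv_per_region[region] = summary.ppv_per_region.get(region, 0) + 1
            mech = res.mechanism.value
            summary.ppv_per_mechanism[mech] = (
                summary.ppv_per_mechanism.get(mech, 0) + 1
            )
    return BatchResult(results=results, summary=summary, rejects=rejects)
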