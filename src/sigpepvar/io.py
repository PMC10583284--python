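"""Tabular input/output, configuration and the run report.

Canonical tables are UTF-8 TSV with documented headers; '.' marks a
missing value.  Sequences may alternatively arrive as FASTA, in which
case they are cross-checked against the annotation table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .classify import (
    BatchResult,
    ClassificationConfig,
    ClassificationResult,
)
from .compstats import gene_region_overlap
from .errors import ConfigError, SigPepVarError
from .mapping import MissenseVariant, SignalPeptide

PEPTIDE_COLUMNS = ["protein_id", "gene", "sequence", "n_end", "h_end", "sp_len"]
VARIANT_COLUMNS = ["variant_id", "protein_id", "position", "wt", "mut"]
RESULT_COLUMNS = [
    "variant_id", "protein_id", "gene", "position", "cleavage_relative",
    "region", "wt", "mut", "delta_kd", "scaled_boman_change",
    "mut_position_frequency", "is_ppv", "mechanism",
]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SigPepVarError(f"{path}: missing required column(s) {missing}")


def read_signal_peptides(
    path, fasta: Optional[str] = None
) -> tuple[list[SignalPeptide], list[tuple[int, str]]]:
    """Read and validate a peptide annotation TSV.

    Returns ``(records, rejects)`` where each reject is ``(line_number,
    reason)``; line numbers count the header as line 1.  An optional
    companion FASTA is cross-checked: a sequence mismatch rejects the
    row.  If every row fails, the run aborts with an error.
    """
    df = _read_tsv(path)
    _require_columns(df, PEPTIDE_COLUMNS, path)
    fasta_seqs: dict[str, str] = {}
    if fasta is not None:
        from Bio import SeqIO

        fasta_seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta, "fasta")
        }
    peptides: list[SignalPeptide] = []
    rejects: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            sp = SignalPeptide(
                protein_id=row["protein_id"],
                gene=row["gene"],
                sequence=row["sequence"],
                n_end=int(row["n_end"]),
                h_end=int(row["h_end"]),
                sp_len=int(row["sp_len"]),
            )
            if fasta_seqs:
                ref = fasta_seqs.get(sp.protein_id)
                if ref is not None and ref != sp.sequence:
                    raise SigPepVarError(
                        f"{sp.protein_id}: FASTA sequence disagrees with TSV"
                    )
        except (SigPepVarError, ValueError) as exc:
            rejects.append((line, str(exc)))
            continue
        peptides.append(sp)
    if len(df) > 0 and not peptides:
        raise SigPepVarError(f"{path}: all {len(df)} rows failed validation")
    return peptides, rejects


def write_signal_peptides(peptides: Sequence[SignalPeptide], path) -> None:
    df = pd.DataFrame(
        [
            (sp.protein_id, sp.gene, sp.sequence, sp.n_end, sp.h_end, sp.sp_len)
            for sp in peptides
        ],
        columns=PEPTIDE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_variants(path) -> tuple[list[MissenseVariant], list[tuple[int, str]]]:
    """Read a variant TSV; malformed rows are returned as rejects."""
    df = _read_tsv(path)
    _require_columns(df, VARIANT_COLUMNS, path)
    variants: list[MissenseVariant] = []
    rejects: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2
        try:
            variants.append(
                MissenseVariant(
                    variant_id=row["variant_id"],
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    wt=row["wt"],
                    mut=row["mut"],
                )
            )
        except (SigPepVarError, ValueError) as exc:
            rejects.append((line, str(exc)))
    if len(df) > 0 and not variants:
        raise SigPepVarError(f"{path}: all {len(df)} rows failed validation")
    return variants, rejects


def write_variants(variants: Sequence[MissenseVariant], path) -> None:
    df = pd.DataFrame(
        [
            (v.variant_id, v.protein_id, v.position, v.wt, v.mut)
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sequence_pairs(path) -> pd.DataFrame:
    """Read WT/mutant sequence pairs (columns ``wt_seq`` and ``mut_seq``;
    optional ``gene`` and ``variant_id``)."""
    df = _read_tsv(path)
    _require_columns(df, ["wt_seq", "mut_seq"], path)
    return df


def table1_fixture() -> pd.DataFrame:
    """The bundled 15-variant literature validation set.

    WT/mutant signal-peptide sequence pairs (including the +1 residue)
    with rsIDs and the experimentally established decay outcome
    (``decay`` / ``no_decay``).
    """
    with resources.as_file(
        resources.files("sigpepvar.data") / "table1_variants.tsv"
    ) as p:
        return _read_tsv(p)


def load_config(path) -> ClassificationConfig:
    """Load a YAML config file mirroring :class:`ClassificationConfig`."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return ClassificationConfig.from_dict(raw)


def results_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    """Long-format results table (one row per classified variant)."""
    rows = []
    for r in results:
        v = r.mapped.variant
        rows.append(
            {
                "variant_id": v.variant_id,
                "protein_id": r.protein_id or v.protein_id,
                "gene": r.gene or ".",
                "position": v.position,
                "cleavage_relative": r.mapped.cleavage_relative,
                "region": str(r.mapped.region),
                "wt": v.wt,
                "mut": v.mut,
                "delta_kd": f"{r.scores.delta_kd:.4f}",
                "scaled_boman_change": f"{r.scores.scaled_boman_change:.4f}",
                "mut_position_frequency": (
                    f"{r.mut_position_frequency:.6f}"
                    if r.mut_position_frequency is not None
                    else "."
                ),
                "is_ppv": str(r.is_ppv),
                "mechanism": str(r.mechanism),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


@dataclass
class RunReport:
    """Machine- and human-readable accounting of a classification run."""

    n_peptides: int = 0
    n_variants: int = 0
    n_rejects: int = 0
    rejects: list = field(default_factory=list)
    variants_per_region: dict = field(default_factory=dict)
    ppv_per_region: dict = field(default_factory=dict)
    ppv_per_mechanism: dict = field(default_factory=dict)
    n_ppv: int = 0
    gene_venn: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    input_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_peptides": self.n_peptides,
            "n_variants": self.n_variants,
            "n_rejects": self.n_rejects,
            "rejects": [list(r) for r in self.rejects],
            "variants_per_region": self.variants_per_region,
            "ppv_per_region": self.ppv_per_region,
            "ppv_per_mechanism": self.ppv_per_mechanism,
            "n_ppv": self.n_ppv,
            "gene_venn": self.gene_venn,
            "config": self.config,
            "seed": self.seed,
            "input_digests": self.input_digests,
        }

    def to_text(self) -> str:
        lines = [
            "sigpepvar run report",
            f"  peptides:            {self.n_peptides}",
            f"  variants:            {self.n_variants}",
            f"  rejected:            {self.n_rejects}",
            f"  PPVs:                {self.n_ppv}",
            "  variants per region: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.variants_per_region.items())),
            "  PPVs per region:     "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.ppv_per_region.items())),
            "  PPVs per mechanism:  "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.ppv_per_mechanism.items())),
            "  gene-level regions:  "
            + ", ".join(f"{k or '-'}={v}" for k, v in sorted(self.gene_venn.items())),
        ]
        return "\n".join(lines) + "\n"


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def build_report(
    batch: BatchResult,
    cfg: ClassificationConfig,
    seed: Optional[int] = None,
    input_digests: Optional[dict] = None,
) -> RunReport:
    """Assemble the run report from a batch result; report totals
    reconcile with the result rows by construction."""
    s = batch.summary
    return RunReport(
        n_peptides=s.n_peptides,
        n_variants=s.n_variants,
        n_rejects=len(batch.rejects),
        rejects=list(batch.rejects),
        variants_per_region=dict(s.variants_per_region),
        ppv_per_region=dict(s.ppv_per_region),
        ppv_per_mechanism=dict(s.ppv_per_mechanism),
        n_ppv=s.n_ppv,
        gene_venn=gene_region_overlap(batch.results),
        config=cfg.to_dict(),
        seed=seed,
        input_digests=input_digests or {},
    )


def write_results(
    results: Iterable[ClassificationResult], report: RunReport, out_prefix
) -> dict[str, Path]:
    """Write the results TSV plus JSON and text reports.

    Output is byte-stable for identical inputs and configuration.
    Returns the written paths keyed by kind.
    """
    prefix = str(out_prefix)
    if not prefix.endswith(("/", ".", "_", "-")):
        prefix += "."
    Path(prefix + "results.tsv").parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": Path(prefix + "results.tsv"),
        "report_json": Path(prefix + "report.json"),
        "report_txt": Path(prefix + "report.txt"),
    }
    results_frame(results).to_csv(paths["results"], sep="\t", index=False)
    paths["report_json"].write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    paths["report_txt"].write_text(report.to_text(), encoding="utf-8")
    return paths
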