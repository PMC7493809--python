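"""Readers and writers for the package's tab-separated file dialects.

Coordinates are 1-based, inclusive protein positions throughout.

* Track file: one row per track with columns ``isoform_id``, ``track_id``,
  ``group``, ``ligand`` (``.`` when absent), ``family_id`` (``.`` when
  absent), ``protein_length`` and semicolon-joined ``position:weight`` pairs
  (``11:0.9;12:0.3``).
* Mutation file: a documented subset of MAF column semantics with required
  columns ``gene``, ``isoform``, ``protein_position``, ``class``, ``sample``
  and optional ``f``, ``cancer_type``, ``codon``. Class names are matched
  case-insensitively through an alias table so MAF-derived tables load
  directly. Malformed rows are collected into an error report, never
  silently dropped.
* Expression file: a ``#unit=TPM`` or ``#unit=FPKM`` declaration line
  followed by a gene x sample TSV matrix (FPKM is converted to TPM on load).
* Variant-count file: individuals x genes TSV of nonnegative integers.
* Gold-standard list: one gene symbol per line.

Readers stream row by row and never require whole-cohort memory residence
beyond the parsed records themselves.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .background import cds_lambdas
from .engine import MutationRecord
from .exceptions import InputError
from .tracks import FunctionalTrack

logger = logging.getLogger(__name__)

#: Case-insensitive aliases for mutation classes (MAF variant classifications).
CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "missense_variant": "missense",
    "silent": "silent",
    "synonymous": "silent",
    "synonymous_variant": "silent",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
}

_MUTATION_REQUIRED = ("gene", "isoform", "protein_position", "class", "sample")


# ---------------------------------------------------------------------------
# tracks


def read_tracks(path: str) -> List[FunctionalTrack]:
    """Read a track annotation file."""
    tracks: List[FunctionalTrack] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise InputError(f"{path}: empty track file")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 7:
                raise InputError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
            iso, track_id, group, ligand, family, length, pairs = row[:7]
            positions: List[int] = []
            weights: List[float] = []
            for pair in pairs.split(";"):
                if not pair:
                    continue
                p, w = pair.split(":")
                positions.append(int(p))
                weights.append(float(w))
            tracks.append(
                FunctionalTrack(
                    track_id=track_id,
                    isoform_id=iso,
                    group=group,
                    positions=np.asarray(positions, dtype=np.int64),
                    weights=np.asarray(weights, dtype=float),
                    protein_length=int(length),
                    ligand=None if ligand == "." else ligand,
                    family_id=None if family == "." else family,
                )
            )
    return tracks


def write_tracks(tracks: Sequence[FunctionalTrack], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["isoform_id", "track_id", "group", "ligand", "family_id",
             "protein_length", "position_weights"]
        )
        for t in tracks:
            pairs = ";".join(
                f"{p}:{w:.6g}" for p, w in zip(t.positions.tolist(), t.weights.tolist())
            )
            writer.writerow(
                [t.isoform_id, t.track_id, t.group, t.ligand or ".",
                 t.family_id or ".", t.protein_length, pairs]
            )


# ---------------------------------------------------------------------------
# mutations


@dataclass
class MutationReadReport:
    """Validated mutation records plus per-row rejection reasons."""

    records: List[MutationRecord]
    rejected: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_mutations(path: str) -> MutationReadReport:
    """Read a mutation table; malformed rows are reported, not fatal."""
    records: List[MutationRecord] = []
    rejected: List[Tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty mutation file")
        missing = [c for c in _MUTATION_REQUIRED if c not in reader.fieldnames]
        if missing:
            raise InputError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_mutation_row(row))
            except (InputError, ValueError) as exc:
                rejected.append((lineno, str(exc)))
    if rejected:
        logger.warning("%s: rejected %d malformed rows", path, len(rejected))
    return MutationReadReport(records=records, rejected=rejected)


def _parse_mutation_row(row: Dict[str, str]) -> MutationRecord:
    cls_raw = (row["class"] or "").strip().lower()
    if cls_raw not in CLASS_ALIASES:
        raise InputError(f"unknown mutation class {row['class']!r}")
    position = int(row["protein_position"])
    if position < 1:
        raise InputError("protein positions are 1-based")
    f_raw = (row.get("f") or "").strip()
    f = float(f_raw) if f_raw else 1.0  # missing subclonal fraction defaults to 1
    if not (0.0 < f <= 1.0):
        raise InputError(f"subclonal fraction {f} outside (0, 1]")
    codon = (row.get("codon") or "").strip() or None
    return MutationRecord(
        gene=row["gene"].strip(),
        isoform=row["isoform"].strip(),
        protein_position=position,
        mutation_class=CLASS_ALIASES[cls_raw],
        f=f,
        sample_id=(row.get("sample") or "").strip(),
        cancer_type=(row.get("cancer_type") or "").strip(),
        codon=codon,
    )


def write_mutations(records: Sequence[MutationRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "isoform", "protein_position", "class", "sample", "f",
             "cancer_type", "codon"]
        )
        for m in records:
            writer.writerow(
                [m.gene, m.isoform, m.protein_position, m.mutation_class,
                 m.sample_id, f"{m.f:.6g}", m.cancer_type, m.codon or ""]
            )


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix in TPM."""

    values: pd.DataFrame  # genes as index, samples as columns
    unit: str = "TPM"

    def tpm(self, gene: str, sample: str) -> Optional[float]:
        if gene not in self.values.index or sample not in self.values.columns:
            return None
        return float(self.values.at[gene, sample])


def fpkm_to_tpm(values: pd.DataFrame) -> pd.DataFrame:
    """Convert per-sample FPKM columns to TPM: TPM_g = FPKM_g / sum FPKM * 1e6."""
    values = values.astype(float)
    if (values < 0).any().any():
        raise InputError("negative expression values")
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise InputError(f"all-zero expression in samples {bad}")
    return values.div(sums, axis=1) * 1e6


def read_expression(path: str) -> ExpressionTable:
    """Read an expression matrix with a leading ``#unit=`` declaration."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#unit="):
            raise InputError(f"{path}: missing '#unit=' declaration line")
        unit = first.split("=", 1)[1].upper()
        if unit not in ("TPM", "FPKM"):
            raise InputError(f"{path}: unknown expression unit {unit!r}")
        values = pd.read_csv(fh, sep="\t", index_col=0)
    if unit == "FPKM":
        values = fpkm_to_tpm(values)
    return ExpressionTable(values=values, unit="TPM")


@dataclass
class ExpressionFilterReport:
    """Outcome of the expression filter with per-reason counts."""

    kept: List[MutationRecord]
    n_input: int
    n_removed_low_expression: int
    n_kept_missing_gene: int
    n_kept_tissue_fallback: int

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def expression_filter(
    mutations: Sequence[MutationRecord],
    expression: ExpressionTable,
    threshold: float = 0.1,
) -> ExpressionFilterReport:
    """Drop mutations in genes expressed below ``threshold`` TPM in their sample.

    For samples absent from the table, the gene's mean TPM across other
    samples of the same cancer type decides; genes absent from the table pass
    (permissive default, logged).
    """
    values = expression.values
    sample_types: Dict[str, str] = {}
    for m in mutations:
        if m.sample_id and m.cancer_type:
            sample_types.setdefault(m.sample_id, m.cancer_type)
    type_samples: Dict[str, List[str]] = {}
    for s, t in sample_types.items():
        if s in values.columns:
            type_samples.setdefault(t, []).append(s)

    kept: List[MutationRecord] = []
    n_low = n_missing_gene = n_fallback = 0
    tissue_means: Dict[Tuple[str, str], float] = {}
    for m in mutations:
        if m.gene not in values.index:
            n_missing_gene += 1
            kept.append(m)
            continue
        if m.sample_id in values.columns:
            tpm = float(values.at[m.gene, m.sample_id])
        else:
            key = (m.gene, m.cancer_type)
            if key not in tissue_means:
                samples = type_samples.get(m.cancer_type, [])
                tissue_means[key] = (
                    float(values.loc[m.gene, samples].mean()) if samples else np.nan
                )
            tpm = tissue_means[key]
            if np.isnan(tpm):
                kept.append(m)  # no evidence either way; permissive
                continue
            n_fallback += 1
        if tpm < threshold:
            n_low += 1
        else:
            kept.append(m)
    if n_missing_gene:
        logger.info(
            "expression filter: %d mutations kept for genes absent from the "
            "expression table", n_missing_gene,
        )
    return ExpressionFilterReport(
        kept=kept,
        n_input=len(mutations),
        n_removed_low_expression=n_low,
        n_kept_missing_gene=n_missing_gene,
        n_kept_tissue_fallback=n_fallback,
    )


# ---------------------------------------------------------------------------
# other inputs


def read_variant_counts(path: str) -> pd.DataFrame:
    """Individuals x genes variant-count table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise InputError(f"{path}: negative variant counts")
    return df


def read_gene_list(path: str) -> Set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def read_cds_lambdas(path: str, b: float) -> Dict[str, np.ndarray]:
    """Per-isoform position rates from a FASTA of coding sequences."""
    out: Dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = cds_lambdas(str(rec.seq), b)
    return out


# ---------------------------------------------------------------------------
# results


def write_results(results, path: str) -> None:
    """Serialize gene results: one row per gene with a per-track breakdown.

    Breakdown entries are '|'-joined strings
    ``group:ligand:track_id=Z;n`` (``Z`` is ``NA`` for undefined scores).
    """
    rows = []
    for gene in sorted(results.gene_results):
        gr = results.gene_results[gene]
        entries = []
        for b in gr.breakdown:
            z = "NA" if b.zscore is None else f"{b.zscore:.4f}"
            entries.append(f"{b.group}:{b.ligand or '.'}:{b.track_id}={z};{b.n}")
        rows.append(
            [gene, gr.best_isoform or ".",
             "NA" if gr.combined_z is None else f"{gr.combined_z:.4f}",
             "|".join(entries)]
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "best_isoform", "combined_Z", "tracks"])
        writer.writerows(rows)


def read_results_table(path: str) -> pd.DataFrame:
    """Read a results table back, expanding the track breakdown."""
    df = pd.read_csv(path, sep="\t")
    parsed = []
    for entry in df["tracks"].fillna(""):
        items = []
        for piece in entry.split("|"):
            if not piece:
                continue
            head, tail = piece.split("=", 1)
            group, ligand, track_id = head.split(":", 2)
            z_str, n_str = tail.split(";")
            items.append(
                {
                    "group": group,
                    "ligand": None if ligand == "." else ligand,
                    "track_id": track_id,
                    "zscore": None if z_str == "NA" else float(z_str),
                    "n": int(n_str),
                }
            )
        parsed.append(items)
    df = df.copy()
    df["track_breakdown"] = parsed
    df["combined_Z"] = pd.to_numeric(df["combined_Z"], errors="coerce")
    return df
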