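"""Extract per-read aligned lengths from transcriptome alignments and filter them.

Reads are expected to be aligned in *transcript space* (one reference
sequence per transcript), as produced by minimap2 against a
transcriptome FASTA. The aligned span on the reference — not the
basecalled query length — is taken as the molecule's templated length,
so soft-clipped adapter and poly(A) bases never inflate it.

Filters implemented here mirror a typical nanopore dRNA QC chain:

* restriction to reads whose poly(A) tail estimate passed QC,
* restriction to reads carrying the 5' adapter (molecules sequenced to
  their true 5' end),
* a minimum per-condition read count per feature, default 5, below
  which a feature is untestable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .tables import DesignTable, LengthTable, SchemaError, ValidationError

__all__ = [
    "extract_read_lengths",
    "load_length_table",
    "write_length_table",
    "load_adapter_ids",
    "join_polya_pass",
    "filter_by_adapter",
    "filter_min_reads",
]

log = logging.getLogger(__name__)


def extract_read_lengths(
    alignments: str | Path,
    adapter_ids: set[str] | None = None,
    library_id: str | None = None,
) -> LengthTable:
    """Convert a transcriptome BAM/SAM into a per-read length table.

    Only primary, mapped alignments are retained; secondary and
    supplementary records are dropped so each molecule contributes a
    single span. ``five_p``/``three_p`` are the reference alignment
    start/end (0-based, half-open).

    Parameters
    ----------
    alignments
        Path to a BAM or SAM file with transcript-space alignments.
    adapter_ids
        Read IDs with a ligated 5' adapter. Membership sets the
        ``adapter`` flag; if ``None`` all flags are False.
    library_id
        Library label for every record. Defaults to the read group, or
        the file stem when no read groups are present.

    Raises
    ------
    OSError
        If the file is unreadable or truncated.
    """
    path = Path(alignments)
    mode = "rb" if path.suffix == ".bam" else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignment file {path}: {exc}") from exc

    default_lib = library_id or path.stem
    rows = []
    n_skipped_span = 0
    n_dropped_nonprimary = 0
    with af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_dropped_nonprimary += 1
                continue
            start = aln.reference_start
            end = aln.reference_end
            if end is None or end - start <= 0:
                n_skipped_span += 1
                continue
            lib = default_lib
            if library_id is None and aln.has_tag("RG"):
                lib = str(aln.get_tag("RG"))
            rows.append(
                {
                    "read_id": aln.query_name,
                    "library_id": lib,
                    "feature_id": aln.reference_name,
                    "five_p": int(start),
                    "three_p": int(end),
                    "length": int(end - start),
                    "adapter": bool(adapter_ids and aln.query_name in adapter_ids),
                    "polya_pass": "unknown",
                }
            )
    if n_skipped_span:
        log.warning("%d alignments with non-positive reference span skipped", n_skipped_span)
    log.info(
        "extracted %d primary alignments from %s (%d non-primary/unmapped dropped)",
        len(rows), path.name, n_dropped_nonprimary,
    )
    note = f"extracted from {path} ({len(rows)} primary alignments)"
    return LengthTable.from_records(rows, [note])


def load_length_table(path: str | Path) -> LengthTable:
    """Load the canonical length-table TSV (schema- and invariant-checked)."""
    return LengthTable.read(path)


def write_length_table(table: LengthTable, path: str | Path) -> None:
    """Write the canonical length-table TSV."""
    table.write(path)


def load_adapter_ids(path: str | Path) -> set[str]:
    """Read a one-ID-per-line adapter-positive read list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def join_polya_pass(table: LengthTable, polya_table: str | Path | pd.DataFrame) -> LengthTable:
    """Keep only reads whose poly(A) tail estimate is tagged PASS.

    ``polya_table`` follows the nanopolish ``polya`` output dialect: a
    TSV with a read-ID column (``readname`` or ``read_id``) and a
    ``qc_tag`` column. Reads absent from the table are dropped —
    an unknown QC state is not treated as a pass.

    Raises
    ------
    ValidationError
        If a read ID appears with conflicting QC tags.
    """
    if isinstance(polya_table, pd.DataFrame):
        pdf = polya_table.copy()
    else:
        pdf = pd.read_csv(polya_table, sep="\t", comment="#")
    id_col = "readname" if "readname" in pdf.columns else "read_id"
    if id_col not in pdf.columns or "qc_tag" not in pdf.columns:
        raise SchemaError("poly(A) table needs a 'readname'/'read_id' column and a 'qc_tag' column")
    pdf = pdf[[id_col, "qc_tag"]].rename(columns={id_col: "read_id"})
    pdf["read_id"] = pdf["read_id"].astype(str)

    conflict = pdf.groupby("read_id")["qc_tag"].nunique()
    conflicted = conflict[conflict > 1]
    if not conflicted.empty:
        raise ValidationError(
            f"conflicting qc_tag values for read_id {conflicted.index[0]!r} in poly(A) table"
        )
    pdf = pdf.drop_duplicates("read_id")

    passing = set(pdf.loc[pdf["qc_tag"] == "PASS", "read_id"])
    df = table.df[table.df["read_id"].isin(passing)].copy()
    df["polya_pass"] = "pass"
    n_drop = len(table) - len(df)
    log.info("poly(A) PASS filter: kept %d of %d reads", len(df), len(table))
    return LengthTable(df, table.provenance + [f"poly(A) PASS filter: dropped {n_drop} reads"])


def filter_by_adapter(table: LengthTable) -> LengthTable:
    """Keep only reads carrying the ligated 5' adapter."""
    df = table.df[table.df["adapter"]].copy()
    log.info("adapter filter: kept %d of %d reads", len(df), len(table))
    return LengthTable(df, table.provenance + [f"adapter filter: dropped {len(table) - len(df)} reads"])


def filter_min_reads(
    table: LengthTable,
    design: DesignTable,
    min_reads: int = 5,
) -> LengthTable:
    """Drop features lacking ``min_reads`` aligned reads in each condition.

    A differential test needs observations on both sides, so the
    threshold applies per condition: a feature is retained iff it has
    at least ``min_reads`` records in the control libraries *and* at
    least ``min_reads`` in the treated libraries.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if len(table) == 0:
        return table.with_note(f"min-reads filter (>= {min_reads}/condition): empty input")

    known = set(design.df["library_id"])
    present = set(table.df["library_id"])
    missing = sorted(present - known)
    if missing:
        raise ValidationError(f"library {missing[0]!r} in length table but not in design table")

    cond = table.df["library_id"].map(
        dict(zip(design.df["library_id"], design.df["condition"]))
    )
    ref, alt = design.levels
    counts = (
        pd.DataFrame({"feature_id": table.df["feature_id"], "condition": cond})
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[ref, alt], fill_value=0)
    )
    keep = counts.index[(counts[ref] >= min_reads) & (counts[alt] >= min_reads)]
    df = table.df[table.df["feature_id"].isin(set(keep))].copy()
    n_features_dropped = table.df["feature_id"].nunique() - df["feature_id"].nunique()
    log.info(
        "min-reads filter (>=%d per condition): dropped %d features (%d reads)",
        min_reads, n_features_dropped, len(table) - len(df),
    )
    return LengthTable(
        df,
        table.provenance + [f"min-reads filter (>= {min_reads}/condition): dropped {n_features_dropped} features"],
    )
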