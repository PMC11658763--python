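"""Transcript-anatomy computations in transcript space.

Three views of where reads sit on their transcripts:

* **meta-length** — each transcript is divided into 20 equal bins
  (0..19) and a read's ends are mapped to bins; the read's
  meta-length is the number of bins it covers, expressed as a
  percentage of full length. This normalizes away transcript length so
  5'-truncation is comparable across transcripts.
* **TSS calling** — the transcription start site of a transcript is
  taken as the position inside the annotated 5' UTR where most read
  5' ends pile up, pooled across replicates, requiring a minimum
  number of supporting reads (default 5).
* **5'-end nucleotide composition** — base frequencies of the
  reference transcript sequence at fixed offsets around read 5' ends,
  which exposes sequence preferences of the upstream degradation or
  ligation chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .tables import DesignTable, LengthTable

__all__ = [
    "TranscriptAnnotation",
    "MetaCoordinates",
    "TSSCall",
    "CompositionMatrix",
    "load_annotations",
    "assign_meta_coordinates",
    "add_meta_coordinates",
    "summarize_metalength",
    "identify_tss",
    "call_tss_table",
    "nucleotide_composition",
]

log = logging.getLogger(__name__)

N_BINS_DEFAULT = 20


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Annotated transcript length and (optionally) where its CDS starts."""

    feature_id: str
    length: int
    five_utr_end: int | None = None  # transcript coordinate where the CDS begins

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.feature_id}: transcript length must be >= 1")
        if self.five_utr_end is not None and not 0 <= self.five_utr_end < self.length:
            raise ValueError(f"{self.feature_id}: five_utr_end must lie in [0, length)")


def load_annotations(path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Read a transcript annotation TSV.

    Requires columns ``feature_id`` and ``length``; an optional
    ``cds_start`` column provides the 5' UTR boundary.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "feature_id" not in df.columns or "length" not in df.columns:
        raise ValueError("annotation TSV needs 'feature_id' and 'length' columns")
    out = {}
    for _, row in df.iterrows():
        utr = None
        if "cds_start" in df.columns and pd.notna(row["cds_start"]):
            utr = int(row["cds_start"])
        out[str(row["feature_id"])] = TranscriptAnnotation(
            str(row["feature_id"]), int(row["length"]), utr
        )
    return out


@dataclass(frozen=True)
class MetaCoordinates:
    """A read's ends in the 20-bin normalized transcript space."""

    bin5: int
    bin3: int
    meta_length_pct: float


def assign_meta_coordinates(
    five_p: int,
    three_p: int,
    transcript_length: int,
    n_bins: int = N_BINS_DEFAULT,
) -> MetaCoordinates:
    """Map a read's templated ends to transcript bins.

    The (inclusive) 5' end maps to bin ``floor(five_p * n_bins / L)``;
    the half-open 3' end to the bin containing its exclusive endpoint,
    ``ceil(three_p * n_bins / L) - 1``. Both are pure functions of the
    position/length ratio, so meta-coordinates are exactly invariant
    under joint scaling of read coordinates and transcript length. The
    meta-length is the covered bin count as a percentage, so a
    full-length read is exactly 100% and a single-bin read 100/n_bins %.
    """
    if not 0 <= five_p < three_p:
        raise ValueError(f"require 0 <= five_p < three_p, got ({five_p}, {three_p})")
    if three_p > transcript_length:
        raise ValueError(
            f"read end {three_p} beyond annotated transcript length {transcript_length}"
        )

    b5 = five_p * n_bins // transcript_length
    b3 = (three_p * n_bins - 1) // transcript_length  # == ceil(three_p*n/L) - 1
    pct = (b3 - b5 + 1) * 100.0 / n_bins
    return MetaCoordinates(b5, b3, pct)


def add_meta_coordinates(
    table: LengthTable,
    annotations: Mapping[str, TranscriptAnnotation],
    n_bins: int = N_BINS_DEFAULT,
) -> pd.DataFrame:
    """Vectorized meta-coordinates for every read in a length table."""
    missing = sorted(set(table.df["feature_id"]) - set(annotations))
    if missing:
        raise ValueError(f"features missing from annotations: {missing[:10]}")
    L = table.df["feature_id"].map({k: a.length for k, a in annotations.items()}).to_numpy()
    five = table.df["five_p"].to_numpy()
    three = table.df["three_p"].to_numpy()
    if (three > L).any():
        bad = table.df.loc[three > L, "feature_id"].iloc[0]
        raise ValueError(f"read end beyond annotated length for feature {bad!r}")
    b5 = five * n_bins // L
    b3 = (three * n_bins - 1) // L
    out = table.df[["read_id", "library_id", "feature_id"]].copy()
    out["bin5"] = b5.astype(int)
    out["bin3"] = b3.astype(int)
    out["meta_length_pct"] = (b3 - b5 + 1) * 100.0 / n_bins
    return out


def summarize_metalength(
    table: LengthTable,
    annotations: Mapping[str, TranscriptAnnotation],
    design: DesignTable | None = None,
    min_reads: int = 1,
    n_bins: int = N_BINS_DEFAULT,
) -> pd.DataFrame:
    """Mean meta-length per feature (per condition when a design is given).

    Returns a tidy frame with columns ``feature_id, condition,
    n_reads, mean_meta_length_pct``; condition is ``"all"`` without a
    design. Feature/condition groups with fewer than ``min_reads``
    reads are omitted.
    """
    meta = add_meta_coordinates(table, annotations, n_bins)
    if design is not None:
        cond_map = dict(zip(design.df["library_id"], design.df["condition"]))
        missing = set(meta["library_id"]) - set(cond_map)
        if missing:
            raise ValueError(f"library {sorted(missing)[0]!r} not in design table")
        meta["condition"] = meta["library_id"].map(cond_map)
    else:
        meta["condition"] = "all"
    grouped = (
        meta.groupby(["feature_id", "condition"], sort=True)["meta_length_pct"]
        .agg(n_reads="size", mean_meta_length_pct="mean")
        .reset_index()
    )
    return grouped[grouped["n_reads"] >= min_reads].reset_index(drop=True)


@dataclass(frozen=True)
class TSSCall:
    """A called transcription start site and its read support."""

    feature_id: str
    tss_position: int
    support: int


def identify_tss(
    five_p_positions: Sequence[int],
    annotation: TranscriptAnnotation,
    min_reads: int = 5,
) -> TSSCall | None:
    """Call the TSS of one transcript from pooled read 5' ends.

    The TSS is the 5' UTR position (coordinate < ``five_utr_end``)
    with the highest 5'-end count, provided that count reaches
    ``min_reads``; ties break toward the 5'-most position. Returns
    ``None`` when no position qualifies; transcripts without a 5' UTR
    annotation are skipped with a log entry.
    """
    if annotation.five_utr_end is None:
        log.info("feature %s lacks a 5'UTR annotation; TSS not called", annotation.feature_id)
        return None
    pos = np.asarray(five_p_positions, dtype=int)
    pos = pos[(pos >= 0) & (pos < annotation.five_utr_end)]
    if pos.size == 0:
        return None
    values, counts = np.unique(pos, return_counts=True)
    best = int(np.argmax(counts))  # np.unique sorts ascending: first argmax is 5'-most
    if counts[best] < min_reads:
        return None
    return TSSCall(annotation.feature_id, int(values[best]), int(counts[best]))


def call_tss_table(
    table: LengthTable,
    annotations: Mapping[str, TranscriptAnnotation],
    min_reads: int = 5,
) -> pd.DataFrame:
    """Call TSSs for every feature in a length table (replicates pooled)."""
    rows = []
    for fid, sub in table.df.groupby("feature_id", sort=True):
        ann = annotations.get(str(fid))
        if ann is None:
            raise ValueError(f"feature {fid!r} missing from annotations")
        call = identify_tss(sub["five_p"].to_numpy(), ann, min_reads)
        if call is not None:
            rows.append({"feature_id": call.feature_id, "tss_position": call.tss_position, "support": call.support})
    return pd.DataFrame(rows, columns=["feature_id", "tss_position", "support"])


BASES = ("A", "C", "G", "T")


@dataclass
class CompositionMatrix:
    """Base frequencies around read 5' ends.

    ``freq`` has one row per offset and one column per base; rows with
    at least one counted base sum to 1. ``totals`` counts the bases
    contributing at each offset (ends near transcript boundaries
    contribute to fewer offsets).
    """

    offsets: np.ndarray
    freq: pd.DataFrame  # index: offsets, columns: BASES
    totals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.freq.copy()
        out.insert(0, "offset", self.offsets)
        out["total"] = self.totals
        return out


def nucleotide_composition(
    table: LengthTable,
    sequences: str | Path | Mapping[str, str],
    window: tuple[int, int] = (-10, 10),
) -> CompositionMatrix:
    """Reference-base composition at offsets around read 5' ends.

    For each read with 5' end at position p, the transcript base at
    ``p + offset`` is counted for every offset in ``window``
    (inclusive); offsets outside the transcript are skipped, not
    padded. U is counted as T. Frequencies are normalized per offset
    over the counted bases.
    """
    if isinstance(sequences, (str, Path)):
        fa = Fasta(str(sequences))
        seqs: Mapping[str, str] = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = sequences
    missing = sorted(set(table.df["feature_id"]) - set(seqs))
    if missing:
        raise ValueError(f"feature {missing[0]!r} not found in FASTA")

    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros((len(offsets), len(BASES)), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    base_idx["U"] = base_idx["T"]
    for fid, sub in table.df.groupby("feature_id", sort=False):
        seq = seqs[str(fid)].upper()
        L = len(seq)
        for p in sub["five_p"].to_numpy():
            for k, off in enumerate(offsets):
                q = p + off
                if 0 <= q < L:
                    i = base_idx.get(seq[q])
                    if i is not None:
                        counts[k, i] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals[:, None] > 0, counts / np.maximum(totals[:, None], 1), np.nan)
    return CompositionMatrix(
        offsets=offsets,
        freq=pd.DataFrame(freq, index=offsets, columns=list(BASES)),
        totals=totals,
    )
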