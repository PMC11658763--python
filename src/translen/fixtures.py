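"""Synthetic alignment fixtures with known ground truth.

Generates a miniature but fully valid transcriptome experiment — a
coordinate-sorted, indexed BAM of primary alignments, the transcript
FASTA it aligns to, an annotation TSV, a library design TSV and a
truth TSV recording every read's intended span — so the whole
ingest -> filter -> test chain can be exercised end-to-end without any
external data. Treated libraries can be given a 5'-truncation
distribution, emulating 5'->3' decay intermediates: their reads start
downstream of the cap while keeping the annotated 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .tables import DesignTable

__all__ = ["FeatureSpec", "FixtureSpec", "generate_fixtures"]


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic transcript.

    ``truncation_frac`` is the mean fraction of the transcript removed
    from the 5' end in *treated* libraries (0 = no shortening);
    control libraries always sample near-full-length reads.
    """

    feature_id: str
    length: int
    reads_per_library: int = 10
    truncation_frac: float = 0.0
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("transcript length must be >= 20 nt")
        if not 0.0 <= self.truncation_frac < 1.0:
            raise ValueError("truncation_frac must lie in [0, 1)")


@dataclass(frozen=True)
class FixtureSpec:
    """The whole synthetic experiment."""

    features: tuple[FeatureSpec, ...]
    n_control_libs: int = 2
    n_treated_libs: int = 2
    start_jitter_frac: float = 0.02  # SD of 5'-end jitter, fraction of length

    def library_conditions(self) -> list[tuple[str, str]]:
        libs = [(f"ctrl_{i + 1}", "control") for i in range(self.n_control_libs)]
        libs += [(f"treat_{i + 1}", "treated") for i in range(self.n_treated_libs)]
        return libs


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_fixtures(spec: FixtureSpec, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write BAM/BAI, FASTA/FAI, annotation, metadata and truth TSVs.

    Every read's intended (five_p, three_p) span is drawn here and
    recorded in ``truth.tsv``; the BAM encodes exactly those spans as
    ungapped full-match alignments, so extraction must reproduce the
    truth table record-for-record.

    Returns a dict of output paths keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    fasta_path = out / "transcripts.fa"
    with open(fasta_path, "w") as fh:
        seqs = {}
        for f in spec.features:
            seqs[f.feature_id] = _random_seq(rng, f.length)
            fh.write(f">{f.feature_id}\n{seqs[f.feature_id]}\n")
    pysam.faidx(str(fasta_path))

    ann_path = out / "annotation.tsv"
    pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in spec.features],
            "length": [f.length for f in spec.features],
            "cds_start": [f.cds_start for f in spec.features],
        }
    ).to_csv(ann_path, sep="\t", index=False)

    libs = spec.library_conditions()
    meta_path = out / "metadata.tsv"
    DesignTable(
        pd.DataFrame(libs, columns=["library_id", "condition"]), "control"
    ).write(meta_path)

    truth_rows = []
    for f in spec.features:
        for lib, cond in libs:
            for i in range(f.reads_per_library):
                if cond == "treated" and f.truncation_frac > 0:
                    cut = rng.normal(f.truncation_frac, spec.start_jitter_frac)
                else:
                    cut = abs(rng.normal(0.0, spec.start_jitter_frac))
                five_p = int(np.clip(round(cut * f.length), 0, f.length - 2))
                three_p = f.length
                truth_rows.append(
                    {
                        "read_id": f"{f.feature_id}:{lib}:r{i}",
                        "library_id": lib,
                        "feature_id": f.feature_id,
                        "five_p": five_p,
                        "three_p": three_p,
                        "length": three_p - five_p,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": f.feature_id, "LN": f.length} for f in spec.features],
        "RG": [{"ID": lib, "SM": lib} for lib, _ in libs],
    }
    tid = {f.feature_id: i for i, f in enumerate(spec.features)}
    bam_path = out / "alignments.bam"
    records = truth.assign(_tid=truth["feature_id"].map(tid)).sort_values(
        ["_tid", "five_p", "read_id"], kind="stable"
    )
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for _, row in records.iterrows():
            a = pysam.AlignedSegment(bam.header)
            a.query_name = row["read_id"]
            a.reference_id = tid[row["feature_id"]]
            a.reference_start = int(row["five_p"])
            span = int(row["length"])
            seq = seqs[row["feature_id"]][row["five_p"] : row["three_p"]]
            a.query_sequence = seq
            a.cigarstring = f"{span}M"
            a.mapping_quality = 60
            a.flag = 0
            a.set_tag("RG", row["library_id"])
            bam.write(a)
    pysam.index(str(bam_path))

    return {
        "bam": bam_path,
        "fasta": fasta_path,
        "annotation": ann_path,
        "metadata": meta_path,
        "truth": truth_path,
    }
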