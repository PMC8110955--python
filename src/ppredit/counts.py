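"""Strand-specific per-position nucleotide counts.

Counts are stored in *transcript sense*: observations assigned to the minus
strand are complemented before tallying, so a C-to-U editing event is always
an excess of T over C in the stored counts, on either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = {0: 3, 1: 2, 2: 1, 3: 0}  # A<->T, C<->G
STRANDS = ("+", "-")


@dataclass
class BaseCountTable:
    """Per-position, per-strand A/C/G/T counts for one sample.

    ``counts[sequence][strand]`` is an ``(L, 4)`` integer array in transcript
    sense with columns ordered A, C, G, T.  Absent positions mean zero
    coverage.
    """

    sample_name: str
    counts: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def zeros(cls, sample_name: str, lengths: Mapping[str, int]) -> "BaseCountTable":
        return cls(
            sample_name,
            {
                name: {s: np.zeros((length, 4), dtype=np.int64) for s in STRANDS}
                for name, length in lengths.items()
            },
        )

    def lengths(self) -> dict[str, int]:
        return {name: arrs["+"].shape[0] for name, arrs in self.counts.items()}

    def coverage(self, sequence: str, strand: str) -> np.ndarray:
        return self.counts[sequence][strand].sum(axis=1)

    # -- tab-separated interchange format ---------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Sparse long-format frame (rows with any coverage only)."""
        rows = []
        for name in sorted(self.counts):
            for strand in STRANDS:
                arr = self.counts[name][strand]
                covered = np.flatnonzero(arr.sum(axis=1) > 0)
                for pos in covered:
                    rows.append(
                        (name, int(pos) + 1, strand, *arr[pos].tolist(), self.sample_name)
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "sequence", "position_1based", "strand",
                "n_A", "n_C", "n_G", "n_T", "sample",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, lengths: Mapping[str, int], sample_name: Optional[str] = None
    ) -> "BaseCountTable":
        if sample_name is None:
            sample_name = str(frame["sample"].iloc[0]) if len(frame) else "sample"
        table = cls.zeros(sample_name, lengths)
        for row in frame.itertuples(index=False):
            arr = table.counts[row.sequence][row.strand]
            arr[row.position_1based - 1] = (row.n_A, row.n_C, row.n_G, row.n_T)
        return table

    @classmethod
    def read_tsv(
        cls, path: str | Path, lengths: Mapping[str, int], sample_name: Optional[str] = None
    ) -> "BaseCountTable":
        frame = pd.read_csv(path, sep="\t")
        return cls.from_frame(frame, lengths, sample_name)


def count_bases(
    alignments: str | Path | pysam.AlignmentFile,
    sample_name: Optional[str] = None,
    min_base_quality: int = 0,
    strandedness: str = "forward",
    reference_names: Optional[Mapping[str, int]] = None,
) -> BaseCountTable:
    """Tally strand-specific base counts from SAM/BAM alignments.

    The transcript strand of a read defaults to its mapping orientation
    (``strandedness='forward'``); dUTP-type stranded libraries, where read 1
    is antisense to the transcript, use ``strandedness='reverse'``.  Mate 2
    of a pair is always flipped relative to mate 1.  Unmapped, secondary and
    supplementary records are skipped; positions spanned by indels contribute
    nothing (only aligned match columns are counted).  Malformed records are
    skipped with a logged warning count.
    """
    if strandedness not in ("forward", "reverse"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    own_handle = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_handle = True
    try:
        header_lengths = {
            name: length
            for name, length in zip(alignments.references, alignments.lengths)
        }
        if reference_names is not None:
            missing = set(reference_names) - set(header_lengths)
            if missing:
                raise ValueError(
                    f"reference name(s) absent from SAM header: {sorted(missing)}"
                )
            header_lengths = {n: header_lengths[n] for n in reference_names}
        if sample_name is None:
            sample_name = Path(str(getattr(alignments, "filename", b"sample"), "utf-8")).stem
        table = BaseCountTable.zeros(sample_name, header_lengths)
        n_malformed = 0
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name not in header_lengths:
                continue
            try:
                seq = read.query_sequence
                if seq is None:
                    raise ValueError("record lacks a query sequence")
                quals = read.query_qualities
                strand = "-" if read.is_reverse else "+"
                if read.is_paired and read.is_read2:
                    strand = "+" if strand == "-" else "-"
                if strandedness == "reverse":
                    strand = "+" if strand == "-" else "-"
                arr = table.counts[read.reference_name][strand]
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    base = seq[qpos].upper()
                    if base not in _BASE_INDEX:
                        continue
                    idx = _BASE_INDEX[base]
                    if strand == "-":
                        idx = _COMPLEMENT_INDEX[idx]
                    arr[rpos, idx] += 1
            except (ValueError, IndexError, KeyError):
                n_malformed += 1
        if n_malformed:
            logger.warning("skipped %d malformed alignment record(s)", n_malformed)
    finally:
        if own_handle:
            alignments.close()
    return table
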