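"""C-to-U editing detection and coding-consequence annotation.

Candidate sites are all positions whose transcript-sense reference base is C
(forward-strand C, or forward-strand G read on the minus strand).  At each
candidate the edited (T) and unedited (C) counts in treatment and control
form a 2x2 table analysed with a two-sided Fisher exact test; p-values are
corrected across the whole candidate family with the Simes-Hochberg step-up
procedure, and effect sizes are pseudocounted odds ratios.  A site is called
significant when the adjusted p falls below alpha AND the log odds ratio
exceeds the configured threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .counts import BASES, BaseCountTable
from .motifs import PPRFactor
from .scoring import ScoringTable, score_site_table
from .stats import fisher_exact, hochberg_adjust, pseudo_odds_ratio

logger = logging.getLogger(__name__)

_T = BASES.index("T")
_C = BASES.index("C")


@dataclass
class Contrast:
    """Parameters of a treatment-vs-control editing comparison."""

    treatment_sample: str = "treatment"
    control_sample: str = "control"
    alpha: float = 0.05
    lor_threshold: float = 2.0
    pseudocount: float = 0.5
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class EditingCall:
    """A candidate C-to-U event with its contingency counts and statistics."""

    sequence_name: str
    position_1based: int
    strand: str
    edited_treat: int
    unedited_treat: int
    edited_ctrl: int
    unedited_ctrl: int
    p_raw: float
    p_adj: float
    odds_ratio: float
    log_odds_ratio: float
    percent_edited_treat: float  # NaN when the treatment site has no C/T coverage
    significant: bool
    binding_score: Optional[float] = None

    @property
    def position(self) -> int:
        return self.position_1based - 1


def candidate_positions(reference: str) -> dict[str, np.ndarray]:
    """0-based candidate coordinates per strand for one reference sequence."""
    ref = np.frombuffer(reference.upper().replace("U", "T").encode(), dtype="S1")
    return {
        "+": np.flatnonzero(ref == b"C"),
        "-": np.flatnonzero(ref == b"G"),
    }


def detect_editing(
    treat: BaseCountTable,
    ctrl: BaseCountTable,
    contrast: Contrast,
    reference: Mapping[str, str],
    factor: Optional[PPRFactor] = None,
    scoring_table: Optional[ScoringTable] = None,
    min_coverage: int = 1,
    circular: bool = False,
) -> list[EditingCall]:
    """Detect differential C-to-U editing between two count tables.

    Every candidate C with combined C+T coverage >= ``min_coverage`` across
    the two samples enters the multiple-testing family.  Returns calls in
    reference order; the ``significant`` flag combines the adjusted p and
    the log-odds-ratio threshold from ``contrast``.
    """
    if set(treat.counts) != set(ctrl.counts):
        raise ValueError("treatment and control tables cover different references")
    missing = set(treat.counts) - set(reference)
    if missing:
        raise ValueError(f"reference sequence(s) missing: {sorted(missing)}")

    sites: list[tuple[str, int, str, int, int, int, int]] = []
    for name in sorted(treat.counts):
        cands = candidate_positions(reference[name])
        for strand in ("+", "-"):
            pos = cands[strand]
            t_arr = treat.counts[name][strand]
            c_arr = ctrl.counts[name][strand]
            a = t_arr[pos, _T]
            b = t_arr[pos, _C]
            c = c_arr[pos, _T]
            d = c_arr[pos, _C]
            keep = (a + b + c + d) >= max(min_coverage, 1)
            for p, aa, bb, cc, dd in zip(
                pos[keep], a[keep], b[keep], c[keep], d[keep]
            ):
                sites.append((name, int(p), strand, int(aa), int(bb), int(cc), int(dd)))

    if not sites:
        return []

    p_raw = np.array([fisher_exact(a, b, c, d) for _, _, _, a, b, c, d in sites])
    p_adj = hochberg_adjust(p_raw)

    calls: list[EditingCall] = []
    for (name, pos, strand, a, b, c, d), pr, pa in zip(sites, p_raw, p_adj):
        odds, lor = pseudo_odds_ratio(
            a, b, c, d, pseudocount=contrast.pseudocount, log_base=contrast.log_base
        )
        pct = 100.0 * a / (a + b) if (a + b) > 0 else float("nan")
        calls.append(
            EditingCall(
                sequence_name=name,
                position_1based=pos + 1,
                strand=strand,
                edited_treat=a,
                unedited_treat=b,
                edited_ctrl=c,
                unedited_ctrl=d,
                p_raw=float(pr),
                p_adj=float(pa),
                odds_ratio=odds,
                log_odds_ratio=lor,
                percent_edited_treat=pct,
                significant=bool(pa < contrast.alpha and lor > contrast.lor_threshold),
            )
        )

    if factor is not None and scoring_table is not None:
        locs = [(call.sequence_name, call.position, call.strand) for call in calls]
        alignments = score_site_table(factor, locs, reference, scoring_table, circular=circular)
        for call, aln in zip(calls, alignments):
            call.binding_score = aln.total_score if aln is not None else None
    return calls


CALL_COLUMNS = [
    "sequence_name", "position_1based", "strand",
    "edited_treat", "unedited_treat", "edited_ctrl", "unedited_ctrl",
    "p_raw", "p_adj", "odds_ratio", "log_odds_ratio",
    "percent_edited_treat", "significant", "binding_score",
]


def calls_to_frame(calls: Sequence[EditingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(c, col) for col in CALL_COLUMNS] for c in calls], columns=CALL_COLUMNS
    )


def write_calls_tsv(calls: Sequence[EditingCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coding-consequence annotation
# ---------------------------------------------------------------------------

@dataclass
class EffectRecord:
    """Predicted consequence of a C-to-U event on the coding sequence."""

    category: str  # synonymous | nonsynonymous | intron | UTR/intergenic
    codon_before: Optional[str] = None
    codon_after: Optional[str] = None
    aa_before: Optional[str] = None
    aa_after: Optional[str] = None
    codon_position: Optional[int] = None  # 1-based position within the codon
    gene: Optional[str] = None


def _load_gff(annotations) -> "gffutils.FeatureDB":
    import gffutils

    if isinstance(annotations, (str, Path)):
        return gffutils.create_db(
            str(annotations),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    return annotations


def annotate_effect(
    call: EditingCall | tuple[str, int, str],
    annotations,
    reference: Mapping[str, str],
) -> EffectRecord:
    """Project an edited C into its codon and classify the consequence.

    ``annotations`` is a GFF3 path or an open ``gffutils`` database with CDS
    features carrying strand and phase.  The standard genetic code is used
    (plastid CDS translate with the standard table).  Sites outside any
    same-strand CDS are classified by feature context: within a same-strand
    gene but between its CDS segments -> intron, otherwise UTR/intergenic.
    CDS groups with an invalid phase or a non-codon length are skipped with
    a warning.
    """
    if isinstance(call, EditingCall):
        seq_name, pos, strand = call.sequence_name, call.position, call.strand
    else:
        seq_name, pos, strand = call
    db = _load_gff(annotations)
    ref = reference[seq_name].upper().replace("U", "T")

    overlapping = list(db.region(seqid=seq_name, start=pos + 1, end=pos + 1))
    cds_hit = next(
        (f for f in overlapping if f.featuretype == "CDS" and f.strand == strand), None
    )
    if cds_hit is None:
        genes = [
            f
            for f in overlapping
            if f.featuretype in ("gene", "mRNA") and f.strand == strand
        ]
        for gene in genes:
            segments = list(
                db.children(gene, featuretype="CDS")
            ) or list(db.region(seqid=seq_name, start=gene.start, end=gene.end, featuretype="CDS"))
            segments = [s for s in segments if s.strand == strand]
            if len(segments) >= 2:
                span = (min(s.start for s in segments), max(s.end for s in segments))
                if span[0] <= pos + 1 <= span[1]:
                    return EffectRecord(category="intron", gene=gene.id)
        return EffectRecord(category="UTR/intergenic")

    # assemble the spliced CDS this segment belongs to
    parents = list(db.parents(cds_hit, level=1))
    if parents:
        segments = [
            s
            for s in db.children(parents[0], featuretype="CDS")
            if s.strand == strand
        ]
        gene_id = parents[0].id
    else:
        segments = [cds_hit]
        gene_id = cds_hit.id
    segments.sort(key=lambda s: s.start, reverse=(strand == "-"))

    spliced = []
    offset = None
    for seg in segments:
        part = ref[seg.start - 1 : seg.end]
        if strand == "-":
            part = str(Seq(part).reverse_complement())
            if seg.start - 1 <= pos <= seg.end - 1:
                offset = sum(len(s) for s in spliced) + (seg.end - 1 - pos)
        else:
            if seg.start - 1 <= pos <= seg.end - 1:
                offset = sum(len(s) for s in spliced) + (pos - (seg.start - 1))
        spliced.append(part)
    cds_seq = "".join(spliced)
    phase = int(segments[0].frame) if str(segments[0].frame) in "012" else 0
    if offset is None or offset < phase:
        return EffectRecord(category="UTR/intergenic", gene=gene_id)

    codon_index = (offset - phase) // 3
    codon_start = phase + 3 * codon_index
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        logger.warning("CDS %s has an incomplete terminal codon; skipped", gene_id)
        return EffectRecord(category="UTR/intergenic", gene=gene_id)
    codon_position = offset - codon_start  # 0-based within codon
    if codon[codon_position] != "C":
        logger.warning(
            "site %s:%d is not a C in the annotated CDS frame", seq_name, pos + 1
        )
    edited = codon[:codon_position] + "T" + codon[codon_position + 1 :]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(edited).translate())
    return EffectRecord(
        category="synonymous" if aa_before == aa_after else "nonsynonymous",
        codon_before=codon,
        codon_after=edited,
        aa_before=aa_before,
        aa_after=aa_after,
        codon_position=codon_position + 1,
        gene=gene_id,
    )
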