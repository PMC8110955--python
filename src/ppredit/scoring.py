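"""PPR-code binding scores and genome scanning.

Each nucleotide-contacting motif of a factor is scored against its aligned
RNA base with a lookup table keyed on the motif's (5th, last) residue pair
and the base; the alignment score is the exact sum over motifs.  The edited
C is predicted 4 nt 3' of the base aligned with the S2 motif (or with the
last contacting motif for factors lacking S2), so a scan window spans the
contacting bases plus that offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .motifs import NUCLEOTIDES, PPRFactor, WILDCARD

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalise_rna(seq: str) -> str:
    """Uppercase and map T->U; DNA input is accepted as RNA sense."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return normalise_rna(seq).translate(_COMPLEMENT)[::-1]


class ScoringTable:
    """Map (5th residue, last residue, base) -> dimensionless score.

    Unseen (fifth, last) pairs score ``default_score`` (neutral 0 by
    default) rather than raising.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str, str], float],
        default_score: float = 0.0,
    ):
        self.default_score = float(default_score)
        self.entries: dict[tuple[str, str, str], float] = {}
        for (fifth, last, base), score in entries.items():
            base = normalise_rna(base)
            if base not in NUCLEOTIDES:
                raise ValueError(f"invalid base {base!r} in scoring table")
            score = float(score)
            if score != score or score in (float("inf"), float("-inf")):
                raise ValueError("scores must be finite")
            self.entries[(fifth.upper(), last.upper(), base)] = score

    def score(self, fifth: str, last: str, base: str) -> float:
        return self.entries.get((fifth, last, normalise_rna(base)), self.default_score)

    @classmethod
    def read(cls, path: str | Path, default_score: float = 0.0) -> "ScoringTable":
        """Read a delimited table with columns fifth, last, A, C, G, U."""
        entries: dict[tuple[str, str, str], float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if fields[0].lower() == "fifth":
                continue
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fifth, last = fields[0], fields[1]
            for base, value in zip(NUCLEOTIDES, fields[2:]):
                entries[(fifth, last, base)] = float(value)
        return cls(entries, default_score=default_score)

    def write(self, path: str | Path) -> None:
        pairs = sorted({(f, l) for f, l, _ in self.entries})
        lines = ["fifth\tlast\tA\tC\tG\tU"]
        for f, l in pairs:
            scores = "\t".join(repr(self.entries.get((f, l, b), self.default_score)) for b in NUCLEOTIDES)
            lines.append(f"{f}\t{l}\t{scores}")
        Path(path).write_text("\n".join(lines) + "\n")


#: Offset (nt) of the edited C 3' of the S2-aligned base.
EDIT_OFFSET = 4


@dataclass(frozen=True)
class SiteAlignment:
    """One factor/RNA alignment with per-motif and total scores.

    ``window_start`` is the 0-based forward-strand coordinate of the leftmost
    genome base covered by the alignment window (contacting bases plus the
    +4 offset to the predicted edit site); ``edit_position`` is the 0-based
    forward-strand coordinate of the predicted edited C.
    """

    factor_name: str
    sequence_name: str
    strand: str
    window_start: int
    per_motif_scores: tuple[float, ...]
    total_score: float
    edit_position: int

    @property
    def edit_position_1based(self) -> int:
        return self.edit_position + 1

    @property
    def window_start_1based(self) -> int:
        return self.window_start + 1


def edit_offset_in_window(factor: PPRFactor) -> int:
    """Offset of the predicted edit site from the first aligned base."""
    return factor.s2_index() + EDIT_OFFSET


def window_span(factor: PPRFactor) -> int:
    """Total genomic span of a scan window (contacting bases + edit offset)."""
    return max(factor.n_contacting, edit_offset_in_window(factor) + 1)


def score_alignment(
    factor: PPRFactor,
    rna_window: str,
    table: ScoringTable,
    sequence_name: str = "",
    strand: str = "+",
    window_start: int = 0,
    edit_position: int = -1,
) -> SiteAlignment:
    """Score the factor's contacting motifs against ``rna_window``.

    The window must have exactly one base per contacting motif, aligned
    one-to-one 5'→3'.  Coordinates default to window-relative; genome
    context may be supplied by the caller.
    """
    window = normalise_rna(rna_window)
    contacts = factor.contacting_motifs
    if len(window) != len(contacts):
        raise ValueError(
            f"window length {len(window)} != {len(contacts)} contacting motifs"
        )
    for b in window:
        if b not in NUCLEOTIDES:
            raise ValueError(f"invalid base {b!r} in window")
    scores = tuple(table.score(m.fifth, m.last, b) for m, b in zip(contacts, window))
    if edit_position < 0:
        edit_position = window_start + edit_offset_in_window(factor)
    return SiteAlignment(
        factor_name=factor.name,
        sequence_name=sequence_name,
        strand=strand,
        window_start=window_start,
        per_motif_scores=scores,
        total_score=sum(scores),
        edit_position=edit_position,
    )


def _scan_one_orientation(
    factor: PPRFactor,
    seq: str,
    seq_name: str,
    strand: str,
    table: ScoringTable,
    anchor: str,
    length: int,
    circular: bool,
) -> list[SiteAlignment]:
    n = factor.n_contacting
    off = edit_offset_in_window(factor)
    span = window_span(factor)
    hits = []
    limit = length if circular else len(seq) - span + 1
    for w in range(max(limit, 0)):
        edit_base = seq[w + off]
        if anchor == "edited_C_only" and edit_base != "C":
            continue
        window = seq[w : w + n]
        if strand == "+":
            window_start = w % length
            edit_position = (w + off) % length
        else:
            # coordinates on the reverse strand map back through L-1-i
            window_start = (length - 1 - (w + span - 1)) % length
            edit_position = (length - 1 - (w + off)) % length
        aln = score_alignment(
            factor,
            window,
            table,
            sequence_name=seq_name,
            strand=strand,
            window_start=window_start,
            edit_position=edit_position,
        )
        hits.append(aln)
    return hits


def scan_sequence(
    factor: PPRFactor,
    genome: Mapping[str, str],
    table: ScoringTable,
    strands: str = "both",
    anchor: str = "edited_C_only",
    circular: bool = False,
    min_score: Optional[float] = None,
) -> list[SiteAlignment]:
    """Scan named sequences for candidate binding/editing sites.

    Returns one :class:`SiteAlignment` per eligible window per strand,
    sorted by total score descending (ties: sequence name, coordinate,
    strand).  With ``anchor='edited_C_only'`` only windows whose predicted
    edit position carries a C in the scanned orientation are emitted; on the
    reverse strand this corresponds to a forward-strand G.  With
    ``circular=True`` the sequence is extended by one window span before
    scanning and output coordinates are folded modulo the length.
    """
    if strands not in ("both", "forward", "reverse"):
        raise ValueError(f"unknown strand selector {strands!r}")
    if anchor not in ("all_positions", "edited_C_only"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    span = window_span(factor)
    hits: list[SiteAlignment] = []
    for name in sorted(genome):
        seq = normalise_rna(str(genome[name]))
        length = len(seq)
        if length < span:
            continue
        fwd = seq + seq[: span - 1] if circular else seq
        if strands in ("both", "forward"):
            hits += _scan_one_orientation(
                factor, fwd, name, "+", table, anchor, length, circular
            )
        if strands in ("both", "reverse"):
            rev = reverse_complement(seq)
            rev = rev + rev[: span - 1] if circular else rev
            hits += _scan_one_orientation(
                factor, rev, name, "-", table, anchor, length, circular
            )
    if min_score is not None:
        hits = [h for h in hits if h.total_score >= min_score]
    hits.sort(
        key=lambda h: (-h.total_score, h.sequence_name, h.window_start, h.strand)
    )
    return hits


def score_site_table(
    factor: PPRFactor,
    sites: Sequence[tuple[str, int, str]],
    genome: Mapping[str, str],
    table: ScoringTable,
    circular: bool = False,
) -> list[Optional[SiteAlignment]]:
    """Score the binding window upstream of each edit site.

    ``sites`` lists ``(sequence_name, edit_position_0based, strand)`` with
    the edit position given on the forward strand.  The scored window ends
    4 nt 5' of the edited C in transcript orientation.  Sites whose window
    overruns the sequence are flagged with ``None`` rather than scored
    (unless the sequence is circular).
    """
    n = factor.n_contacting
    off = edit_offset_in_window(factor)
    results: list[Optional[SiteAlignment]] = []
    for seq_name, edit_pos, strand in sites:
        seq = normalise_rna(str(genome[seq_name]))
        length = len(seq)
        if strand == "+":
            oriented, pos = seq, edit_pos
        elif strand == "-":
            oriented, pos = reverse_complement(seq), length - 1 - edit_pos
        else:
            raise ValueError(f"invalid strand {strand!r}")
        w = pos - off
        if circular:
            oriented = oriented + oriented
            w %= length
        elif w < 0 or pos >= length:
            results.append(None)
            continue
        window = oriented[w : w + n]
        if strand == "+":
            window_start = w % length
        else:
            window_start = (length - 1 - (w + window_span(factor) - 1)) % length
        results.append(
            score_alignment(
                factor,
                window,
                table,
                sequence_name=seq_name,
                strand=strand,
                window_start=window_start,
                edit_position=edit_pos,
            )
        )
    return results


def preferred_target(factor: PPRFactor, code=None, table: Optional[ScoringTable] = None) -> str:
    """The RNA window this factor is predicted to bind best, one base per
    contacting motif.

    Uses the inverse code table where it identifies a unique base for the
    motif's residue pair, falling back to the scoring-table argmax
    (alphabetical tie-break).
    """
    bases = []
    for m in factor.contacting_motifs:
        base = None
        if code is not None:
            preferred = code.preferred_bases(m)
            if len(preferred) == 1:
                base = preferred[0]
        if base is None and table is not None:
            base = max(NUCLEOTIDES, key=lambda b: (table.score(m.fifth, m.last, b), b))
        if base is None:
            raise ValueError(
                f"cannot infer a preferred base for motif {m.motif_type.value} "
                f"({m.fifth}/{m.last}) without a code or scoring table"
            )
        bases.append(base)
    return "".join(bases)


def write_scan_tsv(hits: Iterable[SiteAlignment], path: str | Path) -> None:
    """Write scan results as the tab-separated report format (1-based)."""
    lines = [
        "factor\tsequence\tstrand\twindow_start_1based\tedit_position_1based\t"
        "per_motif_scores\ttotal_score"
    ]
    for h in hits:
        scores = ",".join(repr(s) for s in h.per_motif_scores)
        lines.append(
            f"{h.factor_name}\t{h.sequence_name}\t{h.strand}\t"
            f"{h.window_start_1based}\t{h.edit_position_1based}\t{scores}\t{h.total_score!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
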