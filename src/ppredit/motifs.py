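"""PPR motif model: motifs, factors, consensus scaffolds and the PPR code.

PLS-class RNA-editing factors are tandem arrays of ~35-aa pentatricopeptide
repeat (PPR) motifs.  The array follows the canonical arrangement
``(P1-L1-S1)+ [P2-L2-S2] [E1 [E2 [DYW]]]``; each P/L/S motif contacts one RNA
base, with specificity determined largely by the amino acids at the 5th and
last positions of the motif ("5/35 combination").  This module represents
factors, builds position-specific consensus scaffolds from motif alignments,
and programs new factors against a target RNA using a nucleotide→residue
code table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
WILDCARD = "-"
NUCLEOTIDES = ("A", "C", "G", "U")


class MotifType(str, Enum):
    """The nine valid PPR motif type labels."""

    P1 = "P1"
    L1 = "L1"
    S1 = "S1"
    P2 = "P2"
    L2 = "L2"
    S2 = "S2"
    E1 = "E1"
    E2 = "E2"
    DYW = "DYW"

    @classmethod
    def parse(cls, label: str) -> "MotifType":
        try:
            return cls(label.strip().upper())
        except ValueError:
            raise ValueError(f"unknown motif type {label!r}") from None


#: Motif types that contact exactly one RNA base.
CONTACTING_TYPES = frozenset(
    {MotifType.P1, MotifType.L1, MotifType.S1, MotifType.P2, MotifType.L2, MotifType.S2}
)

# Valid motif arrangements: P1-L1-S1 triplets (the last may be truncated, so
# minimal single-motif factors are representable), optionally a P2-L2-S2
# module, then optional E1, E2, DYW (each requiring its predecessor).
_ORDER_RE = re.compile(
    r"^(P1 L1 S1 )*(P1 (L1 )?)?(P2 L2 S2 )?(E1 (E2 (DYW )?)?)?$"
)


def _check_residue(res: str, context: str) -> str:
    res = res.strip().upper()
    if len(res) != 1 or (res not in AA_ALPHABET and res != WILDCARD):
        raise ValueError(f"invalid residue letter {res!r} in {context}")
    return res


@dataclass(frozen=True)
class Motif:
    """One PPR motif with its specificity-determining residues.

    ``fifth``/``last`` use the one-letter amino-acid code, with ``-`` meaning
    unspecified.  DYW motifs carry no contact residues (wildcards only).
    ``sequence`` optionally holds the full amino-acid string of the motif.
    """

    motif_type: MotifType
    fifth: str = WILDCARD
    last: str = WILDCARD
    triplet_index: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fifth", _check_residue(self.fifth, str(self.motif_type.value)))
        object.__setattr__(self, "last", _check_residue(self.last, str(self.motif_type.value)))
        if self.motif_type is MotifType.DYW and (self.fifth != WILDCARD or self.last != WILDCARD):
            raise ValueError("DYW motifs carry no 5th/last contact residues")
        if self.triplet_index is not None and self.triplet_index < 1:
            raise ValueError("triplet_index must be >= 1")

    @property
    def contacts_rna(self) -> bool:
        return self.motif_type in CONTACTING_TYPES


@dataclass(frozen=True)
class PPRFactor:
    """An ordered array of PPR motifs plus an N-terminal cap peptide."""

    name: str
    motifs: tuple[Motif, ...]
    cap: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        labels = " ".join(m.motif_type.value for m in self.motifs) + " "
        if not _ORDER_RE.match(labels):
            raise ValueError(
                f"invalid motif arrangement for factor {self.name!r}: {labels.strip()}"
            )
        if not self.contacting_motifs:
            raise ValueError("factor must contain at least one nucleotide-contacting motif")
        for aa in self.cap:
            _check_residue(aa, "cap")

    @property
    def contacting_motifs(self) -> tuple[Motif, ...]:
        return tuple(m for m in self.motifs if m.contacts_rna)

    @property
    def n_contacting(self) -> int:
        return len(self.contacting_motifs)

    def s2_index(self) -> int:
        """Index (among contacting motifs) of the S2 motif.

        Falls back to the last contacting motif when no S2 is present; the
        edited C is predicted 4 nt 3' of the base aligned with this motif.
        """
        for i, m in enumerate(self.contacting_motifs):
            if m.motif_type is MotifType.S2:
                return i
        return self.n_contacting - 1


class CodeTable:
    """Inverse PPR code: (motif type, RNA base) -> (5th, last) residue pair.

    Missing keys raise ``KeyError`` on lookup — designing against a base the
    table does not cover is an error, never a silent default.
    """

    def __init__(self, entries: Mapping[tuple[MotifType, str], tuple[str, str]]):
        self.entries: dict[tuple[MotifType, str], tuple[str, str]] = {}
        for (mt, base), (fifth, last) in entries.items():
            mt = MotifType.parse(mt if isinstance(mt, str) else mt.value)
            base = _normalise_base(base)
            self.entries[(mt, base)] = (
                _check_residue(fifth, "code table"),
                _check_residue(last, "code table"),
            )

    def __getitem__(self, key: tuple[MotifType, str]) -> tuple[str, str]:
        mt, base = key
        base = _normalise_base(base)
        try:
            return self.entries[(mt, base)]
        except KeyError:
            raise KeyError(
                f"no code-table entry for motif type {mt.value}, base {base}"
            ) from None

    def __contains__(self, key: tuple[MotifType, str]) -> bool:
        mt, base = key
        return (mt, _normalise_base(base)) in self.entries

    def preferred_bases(self, motif: Motif) -> list[str]:
        """Bases whose code entry for this motif type equals the motif's pair."""
        return [
            base
            for (mt, base), pair in sorted(self.entries.items(), key=lambda kv: kv[0][1])
            if mt is motif.motif_type and pair == (motif.fifth, motif.last)
        ]

    @classmethod
    def read(cls, path: str | Path) -> "CodeTable":
        """Read a delimited table with columns motif_type, nucleotide, fifth, last."""
        entries = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if fields[0].lower() == "motif_type":  # header
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            mt, base, fifth, last = fields
            entries[(MotifType.parse(mt), base)] = (fifth, last)
        return cls(entries)

    def write(self, path: str | Path) -> None:
        lines = ["motif_type\tnucleotide\tfifth\tlast"]
        for (mt, base), (fifth, last) in sorted(
            self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            lines.append(f"{mt.value}\t{base}\t{fifth}\t{last}")
        Path(path).write_text("\n".join(lines) + "\n")


def _normalise_base(base: str) -> str:
    base = base.strip().upper().replace("T", "U")
    if base not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide {base!r}")
    return base


# ---------------------------------------------------------------------------
# Factor definition files
# ---------------------------------------------------------------------------

def parse_factor(text: str, name: str = "factor") -> PPRFactor:
    """Parse a factor-definition document into a :class:`PPRFactor`.

    The format is plain text, one motif per line as ``TYPE<TAB>FIFTH<TAB>LAST``
    (any whitespace accepted), ``#`` comments, and optional ``name=`` and
    ``cap=`` header lines.  Motif order is validated against the canonical
    PLS arrangement.
    """
    cap = ""
    motifs: list[Motif] = []
    triplet = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line and line.split("=", 1)[0].strip().lower() in ("name", "cap"):
            key, value = (s.strip() for s in line.split("=", 1))
            if key.lower() == "name":
                name = value
            else:
                cap = value
            continue
        fields = line.split()
        if len(fields) not in (1, 2, 3):
            raise ValueError(f"line {lineno}: expected 'TYPE FIFTH LAST', got {raw!r}")
        try:
            mt = MotifType.parse(fields[0])
            if mt is MotifType.P1:
                triplet += 1
            fifth = fields[1] if len(fields) > 1 else WILDCARD
            last = fields[2] if len(fields) > 2 else WILDCARD
            if mt is MotifType.DYW:
                fifth = last = WILDCARD
            motifs.append(
                Motif(
                    mt,
                    fifth,
                    last,
                    triplet_index=triplet
                    if (triplet > 0 and mt in (MotifType.P1, MotifType.L1, MotifType.S1))
                    else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    try:
        return PPRFactor(name=name, motifs=tuple(motifs), cap=cap)
    except ValueError as exc:
        raise ValueError(str(exc)) from None


def read_factor(path: str | Path) -> PPRFactor:
    return parse_factor(Path(path).read_text(), name=Path(path).stem)


def write_factor(factor: PPRFactor, path: str | Path) -> None:
    lines = [f"name={factor.name}"]
    if factor.cap:
        lines.append(f"cap={factor.cap}")
    for m in factor.motifs:
        lines.append(f"{m.motif_type.value}\t{m.fifth}\t{m.last}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """Per-column residue counts for one motif category of an alignment."""

    motif_type: MotifType
    triplet_index: Optional[int]
    columns: list[Counter] = field(default_factory=list)

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        motif_type: MotifType,
        triplet_index: Optional[int] = None,
    ) -> "ConsensusProfile":
        if not sequences:
            raise ValueError("cannot build a profile from an empty alignment")
        length = len(sequences[0])
        if any(len(s) != length for s in sequences):
            raise ValueError("aligned sequences must all have the same length")
        columns = [Counter() for _ in range(length)]
        for seq in sequences:
            for i, aa in enumerate(seq.upper()):
                if aa != WILDCARD:
                    _check_residue(aa, f"alignment column {i + 1}")
                columns[i][aa] += 1
        return cls(motif_type, triplet_index, columns)

    def consensus(self) -> str:
        """Plurality consensus with no minimum threshold ("plurality 0").

        Gaps are excluded from the counts so a gap never wins a column; a
        column that is all-gap is dropped from the output.  Ties are broken
        by the fixed canonical one-letter amino-acid order (alphabetical).
        """
        out = []
        for col in self.columns:
            residues = {aa: n for aa, n in col.items() if aa != WILDCARD}
            if not residues:
                continue  # all-gap column: dropped
            best = min(residues, key=lambda aa: (-residues[aa], aa))
            out.append(best)
        return "".join(out)


def build_consensus(
    aligned_motifs: Sequence[str],
    motif_type: MotifType = MotifType.P1,
    triplet_index: Optional[int] = None,
) -> str:
    """Plurality consensus of equal-length aligned amino-acid strings."""
    return ConsensusProfile.from_sequences(aligned_motifs, motif_type, triplet_index).consensus()


def read_motif_collection(path: str | Path) -> dict[tuple[MotifType, Optional[int]], list[str]]:
    """Read an aligned-FASTA motif collection grouped by (type, triplet index).

    Motif type and triplet index are encoded in the record description as
    ``type=P1 triplet=2`` (triplet optional).
    """
    groups: dict[tuple[MotifType, Optional[int]], list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        if "type" not in fields:
            raise ValueError(f"record {rec.id!r} lacks a type= tag in its description")
        key = (
            MotifType.parse(fields["type"]),
            int(fields["triplet"]) if "triplet" in fields else None,
        )
        groups.setdefault(key, []).append(str(rec.seq).upper())
    return groups


# ---------------------------------------------------------------------------
# Factor design
# ---------------------------------------------------------------------------

def _program_sequence(consensus: str, fifth: str, last: str) -> str:
    """Substitute the specificity residues into a motif consensus string.

    The 5th residue replaces position 5 (1-based) and the "last" residue the
    final position, the two RNA-contacting positions of the motif.
    """
    if len(consensus) < 5:
        raise ValueError("motif consensus shorter than 5 residues cannot be programmed")
    seq = list(consensus)
    if fifth != WILDCARD:
        seq[4] = fifth
    if last != WILDCARD:
        seq[-1] = last
    return "".join(seq)


def design_factor(
    target_rna: str,
    scaffold: Sequence[tuple[MotifType, Optional[int], str]],
    code: CodeTable,
    fixed_tail: Optional[Mapping[MotifType, tuple[str, str]]] = None,
    name: str = "designed",
    cap: str = "MGNS",
) -> PPRFactor:
    """Program a consensus scaffold to bind ``target_rna``.

    ``scaffold`` lists, in order, ``(motif_type, triplet_index, consensus)``
    for every motif of the factor.  Contacting motifs whose type appears in
    ``fixed_tail`` keep the supplied residue pair (the natural-factor tail);
    every other contacting motif is programmed from the code table against
    successive bases of ``target_rna`` (5'→3', first programmed motif to the
    first base).  E1/E2 take fixed_tail residues when given; DYW stays
    wildcard.  The cap peptide is prepended unchanged.
    """
    fixed_tail = dict(fixed_tail or {})
    target = [_normalise_base(b) for b in target_rna]
    motifs: list[Motif] = []
    programmed = [
        (mt, tri, cons)
        for mt, tri, cons in scaffold
        if mt in CONTACTING_TYPES and mt not in fixed_tail
    ]
    if len(target) != len(programmed):
        raise ValueError(
            f"target length {len(target)} does not match the "
            f"{len(programmed)} motifs to be programmed"
        )
    it = iter(target)
    for mt, tri, cons in scaffold:
        mt = MotifType.parse(mt if isinstance(mt, str) else mt.value)
        if mt is MotifType.DYW:
            motifs.append(Motif(mt, triplet_index=tri, sequence=cons or None))
            continue
        if mt in fixed_tail:
            fifth, last = fixed_tail[mt]
        elif mt in CONTACTING_TYPES:
            fifth, last = code[(mt, next(it))]
        else:  # E1/E2 without fixed residues stay wildcard
            fifth, last = WILDCARD, WILDCARD
        sequence = _program_sequence(cons, fifth, last) if cons else None
        motifs.append(Motif(mt, fifth, last, triplet_index=tri, sequence=sequence))
    return PPRFactor(name=name, motifs=tuple(motifs), cap=cap)


def scaffold_from_collections(
    groups: Mapping[tuple[MotifType, Optional[int]], Sequence[str]],
    arrangement: Sequence[tuple[MotifType, Optional[int]]],
) -> list[tuple[MotifType, Optional[int], str]]:
    """Build a position-specific consensus scaffold for a motif arrangement."""
    scaffold = []
    for mt, tri in arrangement:
        key = (mt, tri) if (mt, tri) in groups else (mt, None)
        if key not in groups:
            raise KeyError(f"no aligned motifs for type {mt.value}, triplet {tri}")
        scaffold.append((mt, tri, build_consensus(groups[key], mt, tri)))
    return scaffold


def canonical_arrangement(n_triplets: int = 3, with_tail: bool = True) -> list[tuple[MotifType, Optional[int]]]:
    """The (P1-L1-S1)_n [-P2-L2-S2-E1-E2-DYW] motif arrangement."""
    arr: list[tuple[MotifType, Optional[int]]] = []
    for t in range(1, n_triplets + 1):
        arr += [(MotifType.P1, t), (MotifType.L1, t), (MotifType.S1, t)]
    if with_tail:
        arr += [
            (MotifType.P2, None),
            (MotifType.L2, None),
            (MotifType.S2, None),
            (MotifType.E1, None),
            (MotifType.E2, None),
            (MotifType.DYW, None),
        ]
    return arr
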