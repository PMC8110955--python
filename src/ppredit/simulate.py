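"""Synthetic data with recorded ground truth.

Generates every input the pipeline consumes: a small circular
chloroplast-like genome with an optional planted binding site for a designed
factor (the edited C placed 4 nt 3' of the S2-aligned base), strand-specific
base-count tables with planted C-to-U editing sampled binomially at Poisson
coverage with a uniform sequencing-error rate, SAM read sets consistent with
those counts, and aligned motif collections for consensus building.  All
draws come from seeded NumPy generators so every artefact is reproducible
byte-for-byte from the recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .counts import BASES, BaseCountTable, STRANDS
from .motifs import PPRFactor, CodeTable
from .scoring import (
    EDIT_OFFSET,
    ScoringTable,
    edit_offset_in_window,
    preferred_target,
    reverse_complement,
    window_span,
)

_ROLE_STREAM = {"treatment": 1, "control": 2}
_PURINES = {"A", "G"}


@dataclass
class PlantedBindingSite:
    sequence_name: str
    window_start: int  # 0-based forward-strand coordinate of the leftmost base
    strand: str
    target_window: str  # bases aligned to the contacting motifs, 5'->3'


@dataclass
class PlantedEditingSite:
    sequence_name: str
    position: int  # 0-based forward-strand coordinate of the edited C
    strand: str
    efficiency_treat: float
    efficiency_ctrl: float


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a simulated dataset exactly."""

    seed: int
    sequences: dict[str, str]
    circular: bool = True
    planted_binding_sites: list[PlantedBindingSite] = field(default_factory=list)
    planted_editing_sites: list[PlantedEditingSite] = field(default_factory=list)
    mean_depth: float = 200.0
    error_rate: float = 0.001
    minus_one_purine_penalty: Optional[float] = None

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["planted_binding_sites"] = [
            PlantedBindingSite(**d) for d in payload["planted_binding_sites"]
        ]
        payload["planted_editing_sites"] = [
            PlantedEditingSite(**d) for d in payload["planted_editing_sites"]
        ]
        return cls(**payload)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def simulate_genome(
    length: int,
    gc_fraction: float = 0.36,
    seed: int = 0,
    name: str = "synth_plastid",
    circular: bool = True,
    plant_factor: Optional[PPRFactor] = None,
    code: Optional[CodeTable] = None,
    scoring_table: Optional[ScoringTable] = None,
    plant_position: Optional[int] = None,
    plant_strand: str = "+",
    mean_depth: float = 200.0,
    error_rate: float = 0.001,
    efficiency_treat: float = 0.4,
    efficiency_ctrl: float = 0.0,
    minus_one_purine_penalty: Optional[float] = None,
) -> SyntheticTruth:
    """Simulate an i.i.d. random genome, optionally with a planted target.

    Bases are drawn independently at the requested GC content (GC split
    evenly between G and C, AT between A and T).  When ``plant_factor`` is
    given, its preferred target window (from the code table and/or scoring
    table) replaces the background at a recorded coordinate, with a C placed
    at the predicted edit position 4 nt 3' of the S2-aligned base and a
    pyrimidine at -1 so the optional purine penalty never silently applies
    to the intended target.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = _rng(seed, 0)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    genome = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    truth = SyntheticTruth(
        seed=int(seed),
        sequences={},
        circular=circular,
        mean_depth=float(mean_depth),
        error_rate=float(error_rate),
        minus_one_purine_penalty=minus_one_purine_penalty,
    )
    if plant_factor is not None:
        span = window_span(plant_factor)
        if length < span:
            raise ValueError("genome shorter than the factor's window span")
        target = preferred_target(plant_factor, code=code, table=scoring_table)
        off = edit_offset_in_window(plant_factor)
        insert = list(target.replace("U", "T"))
        insert += ["T"] * (off + 1 - len(insert))  # pyrimidine filler incl. -1 base
        insert[off] = "C"
        if plant_position is None:
            plant_position = int(rng.integers(0, length - span + 1))
        elif plant_position + span > length:
            raise ValueError("planting collides with the sequence end")
        window = np.frombuffer("".join(insert).encode(), dtype="S1")
        if plant_strand == "+":
            genome[plant_position : plant_position + len(insert)] = window
            edit_pos = plant_position + off
        else:
            rc = np.frombuffer(
                reverse_complement("".join(insert)).replace("U", "T").encode(), dtype="S1"
            )
            genome[plant_position : plant_position + len(insert)] = rc
            edit_pos = plant_position + len(insert) - 1 - off
        truth.planted_binding_sites.append(
            PlantedBindingSite(
                sequence_name=name,
                window_start=plant_position,
                strand=plant_strand,
                target_window=target,
            )
        )
        truth.planted_editing_sites.append(
            PlantedEditingSite(
                sequence_name=name,
                position=edit_pos,
                strand=plant_strand,
                efficiency_treat=float(efficiency_treat),
                efficiency_ctrl=float(efficiency_ctrl),
            )
        )
    truth.sequences[name] = genome.tobytes().decode()
    return truth


def add_editing_site(
    truth: SyntheticTruth,
    sequence_name: str,
    position: int,
    strand: str,
    efficiency_treat: float,
    efficiency_ctrl: float = 0.0,
) -> PlantedEditingSite:
    """Register an editing site at an existing reference-sense C."""
    seq = truth.sequences[sequence_name]
    base = seq[position]
    expected = "C" if strand == "+" else "G"
    if base != expected:
        raise ValueError(
            f"position {position} ({strand}) is {base}, not a transcript-sense C"
        )
    site = PlantedEditingSite(
        sequence_name, int(position), strand, float(efficiency_treat), float(efficiency_ctrl)
    )
    truth.planted_editing_sites.append(site)
    return site


def _effective_efficiency(truth: SyntheticTruth, site: PlantedEditingSite, role: str) -> float:
    eff = site.efficiency_treat if role == "treatment" else site.efficiency_ctrl
    if truth.minus_one_purine_penalty is not None:
        seq = truth.sequences[site.sequence_name]
        length = len(seq)
        if site.strand == "+":
            i = site.position - 1
            minus_one = seq[i % length] if (truth.circular or i >= 0) else None
        else:
            i = site.position + 1
            minus_one = (
                reverse_complement(seq[i % length]).replace("U", "T")
                if (truth.circular or i < length)
                else None
            )
        if minus_one in _PURINES:
            eff *= truth.minus_one_purine_penalty
    return eff


def simulate_counts(truth: SyntheticTruth, sample_role: str = "treatment") -> BaseCountTable:
    """Draw a strand-specific base-count table from the truth model.

    Per position and strand, depth ~ Poisson(mean_depth).  Each read base is
    the transcript-sense reference base, edited C->T with the site's
    (penalised) efficiency at planted sites, then miscalled uniformly to one
    of the other three bases with probability ``error_rate``.  The
    treatment and control draws use disjoint substreams of the truth seed.
    """
    if sample_role not in _ROLE_STREAM:
        raise ValueError(f"sample_role must be one of {sorted(_ROLE_STREAM)}")
    rng = _rng(truth.seed, _ROLE_STREAM[sample_role])
    table = BaseCountTable.zeros(sample_role, truth.lengths())
    err = truth.error_rate
    for name in sorted(truth.sequences):
        seq = truth.sequences[name].upper()
        length = len(seq)
        edited = {
            (s.position, s.strand): _effective_efficiency(truth, s, sample_role)
            for s in truth.planted_editing_sites
            if s.sequence_name == name
        }
        for strand in STRANDS:
            depth = rng.poisson(truth.mean_depth, size=length)
            arr = table.counts[name][strand]
            # transcript-sense base at each forward coordinate
            base_idx = np.frombuffer(
                (seq if strand == "+" else reverse_complement(seq).replace("U", "T")[::-1]).encode(),
                dtype="S1",
            )
            # tally errors in bulk, then overwrite planted sites exactly
            idx_map = {b.encode(): i for i, b in enumerate(BASES)}
            ref_idx = np.array([idx_map.get(b.tobytes(), -1) for b in base_idx])
            n_err = rng.binomial(depth, err)
            e1 = rng.binomial(n_err, 1 / 3)
            e2 = rng.binomial(n_err - e1, 1 / 2)
            e3 = n_err - e1 - e2
            errs = np.stack([e1, e2, e3], axis=1)
            for i in range(length):
                r = ref_idx[i]
                if r < 0:
                    continue
                others = [j for j in range(4) if j != r]
                arr[i, r] += depth[i] - n_err[i]
                for j, k in zip(others, range(3)):
                    arr[i, j] += errs[i, k]
            for (pos, s), eff in edited.items():
                if s != strand:
                    continue
                d = depth[pos]
                # per-read: edit C->T with prob eff, then uniform miscall
                p_t = eff * (1 - err) + (1 - eff) * err / 3
                p_c = (1 - eff) * (1 - err) + eff * err / 3
                p_other = err / 3
                draw = rng.multinomial(d, [p_other, p_c, p_other, p_t])
                arr[pos] = draw
    return table


def simulate_sam(
    truth: SyntheticTruth,
    path: str | Path,
    n_reads: int,
    read_length: int = 100,
    sample_role: str = "treatment",
    seed: Optional[int] = None,
) -> None:
    """Write a SAM file of uniformly placed stranded reads.

    Read strand encodes the transcript strand directly (the ``forward``
    strandedness convention of :func:`ppredit.counts.count_bases`): a read
    with the reverse flag carries the reverse complement of the
    transcript-sense bases.  Editing and sequencing errors are drawn
    per-read from the same model as :func:`simulate_counts`.
    """
    if sample_role not in _ROLE_STREAM:
        raise ValueError(f"sample_role must be one of {sorted(_ROLE_STREAM)}")
    rng = _rng(truth.seed if seed is None else seed, _ROLE_STREAM[sample_role], 7)
    names = sorted(truth.sequences)
    lengths = truth.lengths()
    if any(read_length > lengths[n] for n in names):
        raise ValueError("read_length exceeds a reference length")
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
    }
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    err = truth.error_rate
    other = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(int(n_reads)):
            name = names[rng.choice(len(names), p=weights)]
            seq = truth.sequences[name]
            length = lengths[name]
            start = int(rng.integers(0, length - read_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            window = seq[start : start + read_length]
            sense = window if strand == "+" else reverse_complement(window).replace("U", "T")
            bases = list(sense)
            for site in truth.planted_editing_sites:
                if site.sequence_name != name or site.strand != strand:
                    continue
                if not start <= site.position < start + read_length:
                    continue
                j = (
                    site.position - start
                    if strand == "+"
                    else (read_length - 1 - (site.position - start))
                )
                eff = _effective_efficiency(truth, site, sample_role)
                if bases[j] == "C" and rng.random() < eff:
                    bases[j] = "T"
            for j in range(read_length):
                if rng.random() < err:
                    bases[j] = other[bases[j]][int(rng.integers(0, 3))]
            read_sense = "".join(bases)
            rec = pysam.AlignedSegment()
            rec.query_name = f"read{i}"
            rec.reference_id = names.index(name)
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigarstring = f"{read_length}M"
            rec.flag = 0 if strand == "+" else 16
            rec.query_sequence = (
                read_sense if strand == "+" else reverse_complement(read_sense).replace("U", "T")
            )
            rec.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            out.write(rec)


def simulate_motif_collection(
    n_sequences: int,
    consensus: str,
    divergence: float,
    seed: int = 0,
    motif_type: str = "P1",
    triplet_index: Optional[int] = None,
    path: Optional[str | Path] = None,
) -> list[str]:
    """Simulate an aligned motif collection around a consensus.

    Each column of each sequence is substituted with probability
    ``divergence`` by a uniformly chosen different residue, so for
    divergence < 0.5 the plurality consensus of a large collection recovers
    the input.  When ``path`` is given the collection is written as aligned
    FASTA with ``type=`` / ``triplet=`` description tags.
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = _rng(seed, 9)
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    sequences = []
    for _ in range(int(n_sequences)):
        chars = []
        for aa in consensus.upper():
            if rng.random() < divergence:
                choices = [x for x in alphabet if x != aa]
                chars.append(choices[int(rng.integers(0, len(choices)))])
            else:
                chars.append(aa)
        sequences.append("".join(chars))
    if path is not None:
        tag = f"type={motif_type}" + (
            f" triplet={triplet_index}" if triplet_index is not None else ""
        )
        records = [
            SeqRecord(Seq(s), id=f"motif{i}", description=tag)
            for i, s in enumerate(sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
    return sequences
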