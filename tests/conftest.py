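import pytest

from ppredit import (
    CodeTable,
    MotifType,
    ScoringTable,
    canonical_arrangement,
    design_factor,
)

# Fixture PPR code: one residue pair per base, used uniformly for every
# contacting motif type.  No literature value is treated as ground truth.
PAIR_FOR_BASE = {"A": ("T", "N"), "C": ("N", "S"), "G": ("T", "D"), "U": ("N", "D")}

CONTACTING = [
    MotifType.P1, MotifType.L1, MotifType.S1,
    MotifType.P2, MotifType.L2, MotifType.S2,
]

#: 12-nt design target used across scoring/scanning tests.
TARGET = "GAUUACAGGAUC"


@pytest.fixture(scope="session")
def code_table() -> CodeTable:
    return CodeTable(
        {(mt, b): pair for mt in CONTACTING for b, pair in PAIR_FOR_BASE.items()}
    )


@pytest.fixture(scope="session")
def match_table() -> ScoringTable:
    """Matched base scores 1.0, everything else 0.0 (strictly monotone)."""
    entries = {}
    for base, (fifth, last) in PAIR_FOR_BASE.items():
        for b in "ACGU":
            entries[(fifth, last, b)] = 1.0 if b == base else 0.0
    return ScoringTable(entries)


@pytest.fixture(scope="session")
def scaffold():
    consensus = "VVTYNTLIDGLCKAGKVDEALELFEEMKEKGIKPD"  # 35 aa, P-motif-like
    return [(mt, tri, consensus) for mt, tri in canonical_arrangement()]


@pytest.fixture(scope="session")
def designed_factor(scaffold, code_table):
    return design_factor(TARGET, scaffold, code_table, name="dsn3PLS-DYW", cap="MGNS")
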