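"""Access to the editable default code and scoring tables shipped with the
package.  These are documented defaults, not empirical ground truth; real
analyses should supply their own tables."""

from __future__ import annotations

from importlib import resources

from .motifs import CodeTable
from .scoring import ScoringTable


def _data_path(name: str):
    return resources.files("ppredit").joinpath("data", name)


def default_code_table() -> CodeTable:
    with resources.as_file(_data_path("ppr_code.tsv")) as path:
        return CodeTable.read(path)


def default_scoring_table(default_score: float = 0.0) -> ScoringTable:
    with resources.as_file(_data_path("scoring_table.tsv")) as path:
        return ScoringTable.read(path, default_score=default_score)
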