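"""Orchestrated off-target analysis runs.

A run loads a factor, its code/scoring tables, a reference genome and
treatment/control count tables, detects differential editing across the
full candidate family, annotates each candidate with its predicted binding
score, and writes a machine-readable report bundle: the per-candidate
table, the highlighted subset (significant AND log odds ratio above the
threshold), scatter data (binding score vs log OR), and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .counts import BaseCountTable
from .detect import Contrast, calls_to_frame, detect_editing
from .motifs import CodeTable, read_factor
from .scoring import ScoringTable
from .seqio import read_fasta

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one off-target analysis run."""

    factor_path: str
    scoring_table_path: str
    genome_path: str
    treatment_counts_path: str
    control_counts_path: str
    output_dir: str
    code_table_path: Optional[str] = None
    annotation_path: Optional[str] = None
    treatment_sample: str = "treatment"
    control_sample: str = "control"
    alpha: float = 0.05
    lor_threshold: float = 2.0
    pseudocount: float = 0.5
    log_base: str = "natural"
    min_coverage: int = 1
    circular: bool = False
    seed: int = 0
    verbosity: str = "info"
    schema_version: int = SCHEMA_VERSION

    def contrast(self) -> Contrast:
        return Contrast(
            treatment_sample=self.treatment_sample,
            control_sample=self.control_sample,
            alpha=self.alpha,
            lor_threshold=self.lor_threshold,
            pseudocount=self.pseudocount,
            log_base=self.log_base,
        )

    def validate(self) -> None:
        for attr in (
            "factor_path", "scoring_table_path", "genome_path",
            "treatment_counts_path", "control_counts_path",
        ):
            path = getattr(self, attr)
            if not Path(path).exists():
                raise PipelineError("config", f"{attr} does not exist: {path}")
        for attr in ("code_table_path", "annotation_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"{attr} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        version = payload.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise PipelineError("config", f"unsupported schema version {version}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def run_offtarget_analysis(config: RunConfig) -> dict[str, Path]:
    """Execute design-agnostic off-target detection and write the bundle.

    Returns the paths of the written report files.  Any stage failure
    aborts with a :class:`PipelineError` naming the stage, and partial
    outputs are removed.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "candidates": outdir / "candidates.tsv",
        "highlighted": outdir / "highlighted.tsv",
        "scatter": outdir / "scatter.tsv",
        "run_log": outdir / "run_log.json",
    }
    written: list[Path] = []
    try:
        try:
            factor = read_factor(config.factor_path)
            table = ScoringTable.read(config.scoring_table_path)
            genome = read_fasta(config.genome_path)
            lengths = {name: len(seq) for name, seq in genome.items()}
            treat = BaseCountTable.read_tsv(
                config.treatment_counts_path, lengths, config.treatment_sample
            )
            ctrl = BaseCountTable.read_tsv(
                config.control_counts_path, lengths, config.control_sample
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc

        try:
            calls = detect_editing(
                treat,
                ctrl,
                config.contrast(),
                genome,
                factor=factor,
                scoring_table=table,
                min_coverage=config.min_coverage,
                circular=config.circular,
            )
        except Exception as exc:
            raise PipelineError("detect", str(exc)) from exc

        try:
            frame = calls_to_frame(calls)
            frame.to_csv(outputs["candidates"], sep="\t", index=False)
            written.append(outputs["candidates"])
            highlighted = frame[frame["significant"]].sort_values(
                "log_odds_ratio", ascending=False
            )
            highlighted.to_csv(outputs["highlighted"], sep="\t", index=False)
            written.append(outputs["highlighted"])
            scatter = frame[
                ["sequence_name", "position_1based", "strand",
                 "binding_score", "log_odds_ratio", "significant"]
            ]
            scatter.to_csv(outputs["scatter"], sep="\t", index=False)
            written.append(outputs["scatter"])
            log = {
                "ppredit_version": __version__,
                "schema_version": SCHEMA_VERSION,
                "seed": config.seed,
                "parameters": dataclasses.asdict(config),
                "n_candidates": int(len(frame)),
                "n_highlighted": int(len(highlighted)),
            }
            outputs["run_log"].write_text(json.dumps(log, indent=2) + "\n")
            written.append(outputs["run_log"])
        except Exception as exc:
            raise PipelineError("report", str(exc)) from exc
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    logger.info(
        "off-target analysis: %d candidates, %d highlighted",
        len(calls),
        int(calls_to_frame(calls)["significant"].sum()),
    )
    return outputs
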