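"""Pipeline configuration: a JSON document validated up front, with every
error collected and reported at once."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError, model_validator


class TriggerConstraintsModel(BaseModel):
    len_min: int = 200
    len_max: int = 500
    gc_min: float = 40.0
    gc_max: float = 60.0
    orf_margin: int = 70
    offtarget_k: int = 21

    @model_validator(mode="after")
    def _ordered(self) -> "TriggerConstraintsModel":
        if self.len_min > self.len_max:
            raise ValueError("len_min must not exceed len_max")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must not exceed gc_max")
        if self.orf_margin < 0:
            raise ValueError("orf_margin must be >= 0")
        return self


class OrthologFiltersModel(BaseModel):
    e_value_max: float = 0.01
    identity_min: float = 50.0
    coverage_min: float = 75.0
    coverage_max: float = 125.0
    db_kind: str = "proteins"

    @model_validator(mode="after")
    def _ordered(self) -> "OrthologFiltersModel":
        if not (0 < self.identity_min <= 100):
            raise ValueError("identity_min must lie in (0, 100]")
        if self.coverage_min >= self.coverage_max:
            raise ValueError("coverage_min must be below coverage_max")
        if self.db_kind not in ("proteins", "contigs", "reads"):
            raise ValueError("db_kind must be proteins, contigs or reads")
        return self


class PipelineConfig(BaseModel):
    """Paths and thresholds for one end-to-end design run."""

    queries: Path | None = None  # FASTA of query proteins (optional stage)
    transcriptome: Path  # FASTA, target species transcripts
    orfs_bed: Path | None = None  # precomputed ORFs; found de novo otherwise
    offtarget_sets: dict[str, Path] = Field(default_factory=dict)
    motif_list: Path | None = None  # one IUPAC motif per line
    conservation_sets: dict[str, Path] = Field(default_factory=dict)
    constraints: TriggerConstraintsModel = Field(default_factory=TriggerConstraintsModel)
    filters: OrthologFiltersModel = Field(default_factory=OrthologFiltersModel)
    k: int = 21
    strands: str = "both"
    step: int = 10
    min_orf_nt: int = 342  # smallest interior admitting a 200-nt window
    seed: int = 0
    out_dir: Path = Path("trigger_forge_out")

    @model_validator(mode="after")
    def _strands_valid(self) -> "PipelineConfig":
        if self.strands not in ("sense_only", "both"):
            raise ValueError("strands must be sense_only or both")
        return self

    def missing_paths(self) -> list[str]:
        missing = []
        for label, p in [("queries", self.queries), ("transcriptome", self.transcriptome),
                         ("orfs_bed", self.orfs_bed), ("motif_list", self.motif_list)]:
            if p is not None and not Path(p).exists():
                missing.append(f"{label}: {p} does not exist")
        for label, p in {**self.offtarget_sets, **self.conservation_sets}.items():
            if not Path(p).exists():
                missing.append(f"{label}: {p} does not exist")
        return missing


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a JSON config; all constraint violations and
    missing paths are reported together in one error."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: "
                         f"{exc.msg}") from None
    errors: list[str] = []
    cfg: PipelineConfig | None = None
    try:
        cfg = PipelineConfig.model_validate(doc)
    except ValidationError as exc:
        errors.extend(
            f"{'.'.join(str(x) for x in e['loc']) or '<root>'}: {e['msg']}"
            for e in exc.errors()
        )
    if cfg is not None:
        errors.extend(cfg.missing_paths())
    if errors:
        raise ValueError(f"{path}: {len(errors)} config error(s):\n  " + "\n  ".join(errors))
    assert cfg is not None
    return cfg
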