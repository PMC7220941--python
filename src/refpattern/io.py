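"""Readers, writers and pipeline configuration.

All artifacts are plain TSV (diff-able, desk-scale data): expression
(probe-sets x samples), sample metadata, selection tables, score tables,
curve tables, plus GMT gene sets and a YAML pipeline config. Every writer
round-trips through the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compendium import ClusteringParams
from .pairwise import SelectionCriteria
from .types import ConfigurationError, ExpressionMatrix, GeneSet, PipelineError

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_metadata",
    "write_metadata",
    "read_gene_map",
    "read_gmt",
    "write_gmt",
    "load_expression",
    "PipelineConfig",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger("refpattern")

FLOAT_FORMAT = "%.10g"


def setup_logging(level: str = "INFO") -> None:
    """Log to stderr; stdout stays clean for data."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression table: first column probe-set ID, header samples.

    Rejects duplicate probe-set or sample IDs and reports the coordinates
    of any non-numeric cell. Decimal-point dialect only.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise PipelineError(f"{path.name}: duplicate probe-set ID(s): {list(dup[:5])}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique()
        raise PipelineError(f"{path.name}: duplicate sample ID(s): {list(dup[:5])}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise PipelineError(
                f"{path.name}: non-numeric value {df.at[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise PipelineError(f"{path.name}: missing value at row {row!r}, column {col!r}")
        out[col] = converted
    return out


def write_expression_table(values: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    values.to_csv(path, sep="\t", index_label="probe_set", float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV; requires sample_id and group columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise PipelineError(f"metadata lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise PipelineError(f"duplicate sample_id(s) in metadata: {dup[:5]}")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> pd.Series:
    """Two-column TSV probe_set -> gene symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise PipelineError("gene map needs two columns: probe_set, gene")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def load_expression(
    expr_path: str | Path,
    meta_path: str | Path,
    gene_map_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from its TSV parts."""
    values = read_expression_table(expr_path)
    meta = read_metadata(meta_path)
    groups = meta.set_index("sample_id")["group"]
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise PipelineError(f"samples missing from metadata: {missing[:5]}")
    gene_map = read_gene_map(gene_map_path) if gene_map_path else None
    return ExpressionMatrix(values, groups, gene_map)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> member symbols."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise PipelineError(f"GMT line {lineno}: needs name, description, >=1 member")
        name, description, *members = fields
        sets.append(GeneSet(name, description, frozenset(m for m in members if m.strip())))
    if not sets:
        raise PipelineError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.description, *sorted(gs.members)]) for gs in sets
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {
    "paths",
    "contrast",
    "selection",
    "clustering",
    "scoring",
    "simulation",
    "log_level",
    "seed",
}


@dataclass
class ContrastConfig:
    """Names of the target contrast's sample groups."""

    experimental: str = "disease"
    baseline: str = "control"

    def __post_init__(self) -> None:
        if self.experimental == self.baseline:
            raise ConfigurationError("experimental and baseline groups must differ")


@dataclass
class ScoringConfig:
    top_n: int = 100
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.top_n <= 0:
            raise ConfigurationError("scoring.top_n must be positive")


@dataclass
class SimulationConfig:
    """Knobs of the canonical synthetic study (see synthetic module)."""

    n_cell_types: int = 3
    markers_per_type: int = 40
    n_background: int = 80
    genes_per_stimulus: int = 30
    n_per_group: int = 10
    n_replicates: int = 3
    noise_sd: float | None = None  # None -> synthetic.DEFAULT_NOISE_SD
    embedded_stimulus: str | None = None  # None -> first cell type's stimulus


@dataclass
class PipelineConfig:
    paths: dict[str, str] = field(default_factory=dict)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    log_level: str = "INFO"
    seed: int | None = None

    def digest(self) -> str:
        payload = {
            "paths": self.paths,
            "contrast": asdict(self.contrast),
            "selection": asdict(self.selection),
            "clustering": asdict(self.clustering),
            "scoring": asdict(self.scoring),
            "simulation": asdict(self.simulation),
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _build_section(cls, data: dict, section: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    paths = raw.get("paths", {}) or {}
    if not isinstance(paths, dict):
        raise ConfigurationError("paths must be a mapping")
    for name, p in paths.items():
        if name != "out" and not Path(p).exists():
            raise ConfigurationError(f"configured path {name!r} does not exist: {p}")
    return PipelineConfig(
        paths={k: str(v) for k, v in paths.items()},
        contrast=_build_section(ContrastConfig, raw.get("contrast", {}) or {}, "contrast"),
        selection=_build_section(SelectionCriteria, raw.get("selection", {}) or {}, "selection"),
        clustering=_build_section(ClusteringParams, raw.get("clustering", {}) or {}, "clustering"),
        scoring=_build_section(ScoringConfig, raw.get("scoring", {}) or {}, "scoring"),
        simulation=_build_section(SimulationConfig, raw.get("simulation", {}) or {}, "simulation"),
        log_level=str(raw.get("log_level", "INFO")),
        seed=raw.get("seed"),
    )


def write_provenance(out_dir: str | Path, config: PipelineConfig, seed: int | None) -> None:
    """Record config hash, seed and versions next to the outputs."""
    import refpattern

    record = {
        "config_sha256": config.digest(),
        "seed": seed,
        "refpattern": refpattern.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(record, indent=2) + "\n")
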