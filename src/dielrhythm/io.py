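"""Table readers/writers and run-configuration loading.

All tables are plain TSV (UTF-8, '.' decimal): expression values and the
0/1 detection mask share a layout (rows = transcript ids, columns = ZT
labels); truth, annotation, module and call tables are tidy tables with
a header row.  The run configuration is a YAML document; absent keys
fall back to the study defaults and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .design import DielDesign, generate_design
from .jtk import JtkConfig
from .network import NetworkConfig
from .pipeline import PipelineConfig
from .preprocessing import ExpressionCallConfig, ExpressionMatrix
from .synthetic import OrganSpec, SharingSpec

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class TableError(ValueError):
    pass


def write_expression_tsv(
    matrix: ExpressionMatrix, values_path: Path, mask_path: Path | None = None
) -> None:
    matrix.values.rename_axis("transcript_id").to_csv(values_path, sep="\t")
    if mask_path is not None:
        matrix.detected.astype(int).rename_axis("transcript_id").to_csv(
            mask_path, sep="\t"
        )


def read_expression_tsv(
    values_path: Path,
    mask_path: Path | None,
    organ: str,
    design: DielDesign,
) -> ExpressionMatrix:
    """Read a values table and its detection mask.

    A missing mask yields an all-detected mask with a warning.  Errors
    on duplicate ids, non-numeric cells and column/design mismatches.
    """
    values = pd.read_csv(
        values_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    values.index.name = None
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise TableError(f"duplicate transcript id {dup!r} in {values_path}")
    if list(values.columns) != design.time_labels():
        raise TableError(
            f"columns of {values_path} do not match the design's ZT labels"
        )
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        raise TableError(f"non-numeric cells in column {non_numeric[0]!r}")
    if mask_path is None:
        log.warning("no detection mask for %s; assuming all detected", values_path)
        detected = pd.DataFrame(1, index=values.index, columns=values.columns)
    else:
        detected = pd.read_csv(mask_path, sep="\t", index_col=0)
        detected.index.name = None
    return ExpressionMatrix(
        organ=organ, values=values, detected=detected.astype(int), design=design
    )


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path: Path) -> None:
    truth.reset_index().to_csv(path, sep="\t", index=False)


def read_truth(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic-dataset block of the run configuration."""

    organs: tuple[str, ...] = ("L1", "I1", "I5")
    organ_spec: OrganSpec = field(default_factory=OrganSpec)
    sharing: SharingSpec = field(default_factory=SharingSpec)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a whole run."""

    rng_seed: int = 0
    design: DielDesign = field(default_factory=generate_design)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def config_hash(self) -> str:
        """Short provenance hash of the effective configuration."""
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _build(cls, data: Mapping, where: str):
    """Construct a (frozen) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in _NESTED:
            value = _build(_NESTED[f.name], value, f"{where}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_NESTED = {
    "expression": ExpressionCallConfig,
    "network": NetworkConfig,
    "jtk": JtkConfig,
    "organ_spec": OrganSpec,
}


def load_config(path: Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration; absent keys get study defaults.

    An empty (or missing) document therefore yields beta=18, merge
    dissimilarity 0.25, adjacency threshold 0.175, adjusted P < 0.75,
    Spearman >= 0.3, 8-of-14 expression call and the 5:45/19:00 dawn/dusk
    clock.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **dict(overrides)}
    known = {"rng_seed", "design", "pipeline", "synthetic"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    design_block = dict(data.get("design", {}))
    design_known = {
        "n_timepoints", "interval_h", "start_offset_h",
        "dawn_clock", "dusk_clock", "period_h",
    }
    bad = set(design_block) - design_known
    if bad:
        raise ConfigError(f"design: unknown key(s) {sorted(bad)}")
    try:
        design = generate_design(**design_block)
    except ValueError as exc:
        raise ConfigError(f"design: {exc}") from exc
    pipeline = _build(PipelineConfig, data.get("pipeline", {}), "pipeline")
    synth_block = dict(data.get("synthetic", {}))
    if "sharing" in synth_block:
        synth_block["sharing"] = _build(
            SharingSpec, synth_block["sharing"], "synthetic.sharing"
        )
    synthetic = _build(SyntheticConfig, synth_block, "synthetic")
    cfg = RunConfig(
        rng_seed=int(data.get("rng_seed", 0)),
        design=design,
        pipeline=pipeline,
        synthetic=synthetic,
    )
    log.info("effective config %s (hash %s)", _to_jsonable(cfg), cfg.config_hash())
    return cfg
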