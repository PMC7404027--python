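"""TSV readers/writers and pipeline configuration.

All tabular interchange is plain TSV. The expression matrix format is
gene ids in the first column, a header row of sample ids, numeric body;
floats are written in canonical ``%.6g`` so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import SampleDesign

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "read_traits_tsv",
    "PipelineConfig",
]

FLOAT_FORMAT = "%.6g"


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Parse a gene x sample expression TSV with line-level diagnostics."""
    path = Path(path)
    with open(path) as fh:
        header = None
        rows = []
        width = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                width = len(parts)
                continue
            if len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})")
            gene = parts[0]
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({err})") from None
            rows.append((gene, lineno, values))
    if header is None or not rows:
        raise ValueError(f"{path}: empty expression file")
    seen: dict[str, int] = {}
    for gene, lineno, _ in rows:
        if gene in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate gene id {gene!r} (first at line {seen[gene]})")
        seen[gene] = lineno
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids in header")
    return pd.DataFrame(
        [v for _, _, v in rows],
        index=[g for g, _, _ in rows],
        columns=samples,
    ).rename_axis("gene")


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_design_tsv(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", comment="#"))


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    """Trait table: first column sample_id, remaining columns traits."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])


@dataclass
class PipelineConfig:
    """Flat parameter set for the end-to-end run; YAML round-trippable."""

    # stage parameters (the analysis defaults of the study design)
    expression_threshold: float = 1.0
    de_alpha: float = 0.05
    fold_change: float = 2.0
    power: float = 12.0
    signed: bool = False
    min_module_size: int = 50
    merge_cut_height: float = 0.75
    kme_min: float = 0.8
    ssc_min: float = 0.5
    weight_min: float = 0.45
    top_n: int = 100
    enrich_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"
    # input paths (optional; the orchestrator can run on in-memory data)
    expression: str | None = None
    samples: str | None = None
    traits: str | None = None
    annotation: str | None = None
    grades: str | None = None
    ct: str | None = None
    qpcr_control: str | None = None
    outdir: str = "chillnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
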