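"""Sample design sheet: genotype x timepoint x replicate layout.

A *stage* is one genotype x timepoint cell of the design (e.g. the
tolerant genotype at 3 h of 4 degC stress). All group-level operations in
the pipeline — per-stage expressed sets, differential-expression
contrasts, module-sample correlation, stage Z-scores — are defined over
stages, so the design sheet is the single source of truth for them.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

__all__ = ["SampleDesign"]


class SampleDesign:
    """Maps sample ids to (genotype, timepoint, replicate).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sample_id``, ``genotype``, ``timepoint``, ``replicate``.
        Sample ids must be unique.
    """

    COLUMNS = ("sample_id", "genotype", "timepoint", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"design sheet missing columns: {missing}")
        if table["sample_id"].duplicated().any():
            dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        self.table = table.reset_index(drop=True).copy()
        self.table["stage"] = (
            self.table["genotype"].astype(str) + "." + self.table["timepoint"].astype(str)
        )

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def stages(self) -> list[str]:
        """Stage labels in design order (genotype-major)."""
        return list(dict.fromkeys(self.table["stage"]))

    def stage_of(self) -> pd.Series:
        """sample_id -> stage label."""
        return self.table.set_index("sample_id")["stage"]

    def samples_in_stage(self, stage: str) -> list[str]:
        hit = self.table.loc[self.table["stage"] == stage, "sample_id"]
        if hit.empty:
            raise KeyError(f"unknown stage {stage!r}; known: {self.stages}")
        return hit.tolist()

    def stage_indicator(self, stage: str) -> pd.Series:
        """One-hot membership vector over samples for one stage."""
        members = set(self.samples_in_stage(stage))
        return pd.Series(
            [1.0 if s in members else 0.0 for s in self.sample_ids],
            index=self.sample_ids,
            name=stage,
        )

    # -- validation ------------------------------------------------------

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        """Raise if any expression-matrix column lacks a design row."""
        known = set(self.sample_ids)
        orphans = [s for s in sample_ids if s not in known]
        if orphans:
            raise ValueError(f"samples absent from design sheet: {orphans}")

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SampleDesign({len(self)} samples, "
            f"{self.table['genotype'].nunique()} genotypes, "
            f"{len(self.stages)} stages)"
        )

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_layout(
        cls,
        genotypes: Iterable[str],
        timepoints: Iterable[str],
        n_replicates: int,
    ) -> "SampleDesign":
        """Full-factorial design with ``n_replicates`` per stage."""
        rows = [
            {
                "sample_id": f"{g}.{t}.R{r}",
                "genotype": g,
                "timepoint": t,
                "replicate": r,
            }
            for g in genotypes
            for t in timepoints
            for r in range(1, n_replicates + 1)
        ]
        if not rows:
            raise ValueError("empty design")
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, str, int]]) -> "SampleDesign":
        rows = [
            {"sample_id": s, "genotype": g, "timepoint": t, "replicate": r}
            for s, (g, t, r) in mapping.items()
        ]
        return cls(pd.DataFrame(rows))
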