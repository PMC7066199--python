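"""Core in-memory containers and their plain-text serialisations.

Two matrices drive the pipeline: a samples x compounds log-abundance table
(metabolites + lipids, the ``Pr`` matrix of the transcript-metabolite
objective) and a samples x genes normalised-expression table (``Expr``).
Both share the same experimental design rows: accession x treatment x
replicate. Pathways are named compound sets stored in small JSON databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("accession", "treatment", "replicate")


def _check_design(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks design columns: {missing}")
    if samples.index.has_duplicates:
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    return samples.loc[:, list(DESIGN_COLUMNS)]


@dataclass
class CompoundMatrix:
    """Samples x compounds abundance table with design labels.

    ``values`` holds one row per sample (index = sample id) and one column
    per compound; missing measurements are ``NaN``. ``samples`` carries the
    accession / treatment / replicate design aligned to ``values.index``.
    ``compound_classes`` annotates each compound with its chemical class
    (a metabolite class or a lipid class); the annotation never enters any
    computation, only grouping and reports.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    compound_classes: pd.Series

    def __post_init__(self) -> None:
        self.samples = _check_design(self.samples)
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values rows and sample table rows differ")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate compound ids")
        self.compound_classes = self.compound_classes.reindex(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def compounds(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def groups(self) -> pd.Series:
        """Design cell of each sample, ``accession:treatment``."""
        return self.samples["accession"].astype(str) + ":" + self.samples[
            "treatment"
        ].astype(str)

    def subset_samples(self, mask: Sequence[bool] | pd.Series) -> "CompoundMatrix":
        return CompoundMatrix(
            self.values.loc[mask].copy(),
            self.samples.loc[mask].copy(),
            self.compound_classes.copy(),
        )

    def copy_with(self, values: pd.DataFrame) -> "CompoundMatrix":
        return CompoundMatrix(values, self.samples.copy(), self.compound_classes.copy())

    # -- TSV round-trip: design columns first, then one column per compound,
    #    missing encoded as an empty field.
    def to_tsv(self, path: str | Path) -> None:
        table = pd.concat([self.samples, self.values], axis=1)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            table.to_csv(fh, sep="\t", index_label="sample", na_rep="")
        class_path = _class_sidecar(path)
        self.compound_classes.rename("class").to_csv(
            class_path, sep="\t", index_label="compound"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompoundMatrix":
        table = pd.read_csv(path, sep="\t", index_col="sample")
        samples = table[list(DESIGN_COLUMNS)]
        values = table.drop(columns=list(DESIGN_COLUMNS)).astype(float)
        class_path = _class_sidecar(path)
        if Path(class_path).exists():
            classes = pd.read_csv(class_path, sep="\t", index_col="compound")["class"]
        else:
            classes = pd.Series("unknown", index=values.columns)
        return cls(values, samples, classes)


def _class_sidecar(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".classes.tsv")


@dataclass
class ExpressionMatrix:
    """Samples x genes normalised expression (nonnegative, unitless).

    Rows align one-to-one with the CompoundMatrix rows of the same study.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = _check_design(self.samples)
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values rows and sample table rows differ")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        table = pd.concat([self.samples, self.values], axis=1)
        table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        table = pd.read_csv(path, sep="\t", index_col="sample")
        samples = table[list(DESIGN_COLUMNS)]
        values = table.drop(columns=list(DESIGN_COLUMNS)).astype(float)
        return cls(values, samples)


@dataclass(frozen=True)
class PathwayDefinition:
    """A metabolic pathway as a named set of compound ids."""

    id: str
    name: str
    members: frozenset[str]
    label: str | None = None  # "positive" / "negative" for training databases

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")


def write_pathway_db(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    records = [
        {
            "id": pw.id,
            "name": pw.name,
            "members": sorted(pw.members),
            **({"label": pw.label} if pw.label is not None else {}),
        }
        for pw in pathways
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n", encoding="utf-8")


def read_pathway_db(path: str | Path) -> list[PathwayDefinition]:
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        PathwayDefinition(
            id=r["id"],
            name=r.get("name", r["id"]),
            members=frozenset(r["members"]),
            label=r.get("label"),
        )
        for r in records
    ]
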