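"""Core containers and plain-text I/O.

Expression matrices travel as TSV (first column = feature id, remaining
columns = samples) with a two-column sample annotation (sample, group).
Gene sets use the standard GMT layout: name, description, then one gene per
tab-separated field. All tables are written with a fixed float format so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.10g"


class MirnetproxError(Exception):
    """Base class for package errors."""


class ConfigurationError(MirnetproxError):
    pass


class InputError(MirnetproxError):
    pass


@dataclass
class ExpressionMatrix:
    """A log2 feature-by-sample expression matrix with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples, entries are log2 expression.
    groups : pandas.Series
        Group label per sample, indexed by sample id.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise InputError(f"duplicate feature ids: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InputError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    def subset_groups(self, labels: list[str]) -> "ExpressionMatrix":
        keep = self.groups.index[self.groups.isin(labels)]
        return ExpressionMatrix(self.values[keep], self.groups.loc[keep])

    def relabel_groups(self, mapping: dict[str, str]) -> "ExpressionMatrix":
        """Return a copy whose group labels are mapped (e.g. pooling)."""
        new = self.groups.map(lambda g: mapping.get(g, g))
        return ExpressionMatrix(self.values.copy(), new)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    if ann.shape[1] < 2:
        raise InputError(f"{groups_path}: expected columns (sample, group)")
    groups = pd.Series(ann.iloc[:, 1].values, index=ann.iloc[:, 0].astype(str))
    return ExpressionMatrix(values, groups)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature"
    df.to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
    ann = pd.DataFrame({"sample": matrix.sample_ids, "group": matrix.groups.values})
    ann.to_csv(groups_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise InputError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_pair_table(path: str | Path, columns: tuple[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns {columns}")
    df = df.iloc[:, :2]
    df.columns = list(columns)
    return df


def read_target_pairs(path: str | Path) -> pd.DataFrame:
    """miRNA->target table, columns (mirna, gene)."""
    return read_pair_table(path, ("mirna", "gene"))


def read_drug_targets(path: str | Path) -> dict[str, list[str]]:
    """Drug->target table (drug_id, gene), one row per pair."""
    df = read_pair_table(path, ("drug_id", "gene"))
    out: dict[str, list[str]] = {}
    for drug, sub in df.groupby("drug_id", sort=True):
        out[str(drug)] = sorted(set(sub["gene"]))
    return out


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
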