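"""Plain-text (TSV/CSV) readers and writers.

Abundance matrices are TSV with metabolite IDs in the first column and
subject IDs as the header row; missing cells are empty fields.  A study is
written as ``specimen_A.tsv``, ``specimen_B.tsv``, ``groups.tsv`` and,
when generator truth is present, ``truth.tsv`` (true_r, true_de).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import PairedStudy

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_study",
    "read_study",
    "write_mask",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "metabolite_id"
    df.columns.name = "subject_id"
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", na_rep="")


def write_mask(mask: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mask).astype(int).to_csv(path, sep="\t")


def write_study(study: PairedStudy, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(study.specimen_a, directory / "specimen_A.tsv")
    write_matrix(study.specimen_b, directory / "specimen_B.tsv")
    study.groups.rename("group").to_csv(directory / "groups.tsv", sep="\t")
    if study.true_r is not None or study.true_de is not None:
        truth = pd.DataFrame(index=study.specimen_a.index)
        if study.true_r is not None:
            truth["true_r"] = study.true_r
        if study.true_de is not None:
            truth["true_de"] = study.true_de.astype(int)
        truth.to_csv(directory / "truth.tsv", sep="\t")


def read_study(
    path_a: str | Path,
    path_b: str | Path,
    groups_path: str | Path,
    scale: str = "raw",
) -> PairedStudy:
    """Load a user-supplied paired study from two matrix TSVs and a label TSV."""
    a = read_matrix(path_a)
    b = read_matrix(path_b)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    groups = groups.reindex(a.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some subjects")
    return PairedStudy(a, b, groups, scale=scale)
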