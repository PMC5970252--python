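"""Reading expression-style matrices and writing result tables.

Input is a delimited numeric table (TSV or CSV, sniffed from the
extension) with a header row and an index column.  Samples are in rows by
default; a transposed layout (variables in rows, one column per sample)
is handled via the orientation flag.  Group membership comes from a
two-column sample-to-group file with exactly two distinct labels and at
least two samples each.  Missing or non-numeric cells fail loudly with
row/column context — no silent imputation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TwoSampleMatrix

__all__ = [
    "read_matrix",
    "read_labels",
    "build_two_sample",
    "write_report",
    "write_study_tables",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, samples_in_rows: bool = True) -> pd.DataFrame:
    """Load the numeric matrix as a samples-by-variables DataFrame."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if not samples_in_rows:
        df = df.T
    bad = df.columns[~df.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all()
    )]
    if len(bad):
        rows = df[bad[0]][pd.to_numeric(df[bad[0]], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric or missing cells in column {bad[0]!r} "
            f"(e.g. sample {rows.index[0]!r}); clean the input explicitly"
        )
    return df.astype(float)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column sample-to-group mapping (header optional, TSV/CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     comment="#")
    # tolerate a header line
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns "
                         "(sample, group)")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("sample", "id", "name"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                     name="group")


def build_two_sample(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[TwoSampleMatrix, tuple[str, str]]:
    """Split the matrix into the two groups named by the label map.

    Groups are ordered by sorted label name; the first becomes X1.
    """
    missing = [s for s in matrix.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    lab = labels.loc[matrix.index]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError(
            f"need exactly two groups, found {len(groups)}: {groups[:5]}"
        )
    x1 = matrix.loc[lab == groups[0]].to_numpy()
    x2 = matrix.loc[lab == groups[1]].to_numpy()
    if min(len(x1), len(x2)) < 2:
        raise ValueError("each group needs at least two samples")
    return TwoSampleMatrix(x1, x2), (groups[0], groups[1])


def write_report(result, variables, groups, path: str | Path, extra=None) -> None:
    """JSON report: global p-value, AGCP0, argmax pair, marginal p-values."""
    report = {
        "pvalue": result.pvalue,
        "agcp0": result.agcp0,
        "argmax_thresholds": list(result.argmax_pair),
        "B": result.B,
        "groups": list(groups),
        "gcp_by_pair": {
            f"({lo:g}, {hi:g})": float(v)
            for (lo, hi), v in zip(result.pair_thresholds, result.gcp_by_pair)
        },
        "marginal_pvalues": {
            str(v): float(p)
            for v, p in zip(variables, result.marginal_pvalues)
        },
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_study_tables(results, out_dir: str | Path) -> Path:
    """Concatenate study tables into one tidy TSV (full float precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.concat([r.table for r in results], ignore_index=True)
    out = out_dir / "study_results.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.17g")
    return out
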