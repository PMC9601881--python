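"""Heatmap matrices, position summaries and motif annotations.

Residue-level scores arrive per pool; residues measured by two overlapping
amplicon pools are reconciled here (default: mean across pools).  The final
matrix has one row per mutagenized residue (publication numbering) and one
column per amino acid plus stop; missing cells (variant absent from the
library or under the input-count filter) stay missing all the way to the
rendered heatmap, where they are gray.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .enrichment import AA_COLUMNS, classify

__all__ = [
    "MotifAnnotation",
    "load_annotations",
    "build_matrix",
    "summarize_positions",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "render_heatmap",
]


class ReportingError(ValueError):
    pass


@dataclass(frozen=True)
class MotifAnnotation:
    """A named residue range in publication numbering."""

    name: str
    start_residue: int
    end_residue: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ReportingError(f"annotation {self.name!r}: start > end")

    def __contains__(self, residue: int) -> bool:
        return self.start_residue <= residue <= self.end_residue


def load_annotations(path: str | Path) -> list[MotifAnnotation]:
    """Read an annotation TSV (name, start_residue, end_residue, note)."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifAnnotation(
            name=str(r["name"]),
            start_residue=int(r["start_residue"]),
            end_residue=int(r["end_residue"]),
            note=str(r.get("note", "")),
        )
        for _, r in df.iterrows()
    ]


def build_matrix(
    residue_values: pd.DataFrame,
    rule: str = "mean",
    designated_pool: Optional[str] = None,
) -> pd.DataFrame:
    """Reconcile per-pool residue-level scores into one matrix.

    ``residue_values`` is the tidy output of synonymous aggregation
    (columns pool_id, residue_number, aa_class, value).  Under the ``mean``
    rule a residue covered by two pools gets the mean of the pools' values;
    under ``designated`` only ``designated_pool`` contributes where it
    covers a residue, other pools fill the rest.
    """
    required = {"pool_id", "residue_number", "aa_class", "value"}
    if not required <= set(residue_values.columns):
        raise ReportingError(f"residue_values needs columns {sorted(required)}")
    df = residue_values.dropna(subset=["value"])
    if rule == "mean":
        merged = df.groupby(["residue_number", "aa_class"], as_index=False)["value"].mean()
    elif rule == "designated":
        if designated_pool is None:
            raise ReportingError("the 'designated' rule needs designated_pool")
        primary = df[df["pool_id"] == designated_pool]
        covered = set(primary["residue_number"])
        rest = df[(df["pool_id"] != designated_pool) & ~df["residue_number"].isin(covered)]
        merged = (
            pd.concat([primary, rest])
            .groupby(["residue_number", "aa_class"], as_index=False)["value"]
            .mean()
        )
    else:
        raise ReportingError(f"unknown reconciliation rule {rule!r}")
    wide = merged.pivot(index="residue_number", columns="aa_class", values="value")
    wide = wide.reindex(columns=list(AA_COLUMNS)).sort_index()
    wide.index.name = "residue_number"
    wide.columns.name = "aa_class"
    return wide


def summarize_positions(
    matrix: pd.DataFrame,
    annotations: list[MotifAnnotation] | None = None,
    neutral_band: float = 0.2,
    intolerant_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Per-residue summary over non-missing cells.

    ``fraction_loss`` / ``fraction_gain`` are the fractions of non-missing
    cells classified loss / gain at ``neutral_band``; residues whose
    fraction_loss reaches ``intolerant_cutoff`` are flagged intolerant
    (positions where almost any substitution kills activity).
    """
    annotations = annotations or []
    rows = []
    for residue, cells in matrix.iterrows():
        present = cells.dropna()
        n = len(present)
        calls = classify(present, neutral_band) if n else pd.Series(dtype=object)
        frac_loss = float((calls == "loss").sum() / n) if n else np.nan
        frac_gain = float((calls == "gain").sum() / n) if n else np.nan
        rows.append(
            {
                "residue_number": int(residue),
                "mean": float(present.mean()) if n else np.nan,
                "min": float(present.min()) if n else np.nan,
                "max": float(present.max()) if n else np.nan,
                "fraction_loss": frac_loss,
                "fraction_gain": frac_gain,
                "n_cells": n,
                "intolerant": bool(n and frac_loss >= intolerant_cutoff),
                "motifs": ";".join(a.name for a in annotations if int(residue) in a),
            }
        )
    return pd.DataFrame(rows)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialize a residue matrix losslessly (full float precision, NA for
    missing cells)."""
    matrix.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="residue_number", na_values=["NA"])
    matrix.columns.name = "aa_class"
    return matrix


def render_heatmap(
    matrix: pd.DataFrame,
    tsv_path: str | Path,
    image_path: Optional[str | Path] = None,
    vlim: Optional[float] = None,
) -> None:
    """Write the matrix TSV and optionally a diverging heatmap image.

    The palette is centered at 0 (gain red, loss blue), symmetric to
    ``vlim`` (default: max |value| in the matrix); missing cells render
    gray.
    """
    write_matrix_tsv(matrix, tsv_path)
    if image_path is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.ma.masked_invalid(matrix.to_numpy(dtype=float).T)
    if vlim is None:
        vlim = float(np.nanmax(np.abs(matrix.to_numpy(dtype=float)))) if data.count() else 1.0
        vlim = vlim or 1.0
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.09 * len(matrix.index)), 5.0), constrained_layout=True
    )
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.75")
    mesh = ax.pcolormesh(data, cmap=cmap, vmin=-vlim, vmax=vlim)
    ax.set_yticks(np.arange(len(matrix.columns)) + 0.5, list(matrix.columns))
    step = max(1, len(matrix.index) // 25)
    ax.set_xticks(
        np.arange(0, len(matrix.index), step) + 0.5,
        [str(r) for r in matrix.index[::step]],
        rotation=90,
        fontsize=6,
    )
    ax.set_xlabel("residue")
    ax.set_ylabel("substitution")
    fig.colorbar(mesh, ax=ax, label="enrichment score (log10)")
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
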