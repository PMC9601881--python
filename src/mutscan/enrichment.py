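"""Log-ratio enrichment scoring of a growth selection.

For each variant *m* the enrichment score compares its count change between
the selected and the reference (by default unselected) population with that
of the wild-type sequence::

    dE = log10(N_sel^m / N_ref^m) - log10(N_sel^wt / N_ref^wt)

Negative values mean the variant supported growth under selection worse
than wild type (loss of function); positive values mean better (gain).
The unselected endpoint is used as the reference rather than the input
library so that variants depleted in *both* flasks (e.g. by toxicity of an
over-active kinase) are not misread as loss-of-function.

Scores are computed per codon and replicate, filtered on input-library
counts, averaged over replicates, and finally averaged over synonymous
codons into a residue x amino-acid matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon_counting import CountTable, SampleManifest
from .library_spec import MutagenesisDesign, variants_for_pool

__all__ = [
    "AA_COLUMNS",
    "ScoringConfig",
    "UndefinedScoreError",
    "delta_e",
    "score_replicate",
    "score_experiment",
    "apply_input_filter",
    "average_replicates",
    "aggregate_synonymous",
    "residue_matrix",
    "replicate_correlation",
    "classify",
]

#: Column order of residue-level matrices: the 20 amino acids, then stop.
AA_COLUMNS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

SCORE_COLUMNS = [
    "pool_id",
    "replicate",
    "codon_index",
    "residue_number",
    "codon",
    "aa_class",
    "is_wt_synonymous",
    "n_input",
    "n_sel",
    "n_ref",
    "value",
    "status",
]


class UndefinedScoreError(ValueError):
    """A zero count makes the log-ratio undefined at pseudocount 0."""


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs of the scoring stage.

    pseudocount
        Added to all four counts symmetrically. 0.5 by default; 0 reproduces
        the bare log-ratio, which is undefined when any count is zero.
    min_input_count
        Variants with fewer input-library reads are masked (strict ``<``).
    input_condition / reference_condition
        Which sample plays the input-filter role (default t0) and which is
        the denominator of the ratios (default unselected).
    neutral_band
        Half-width of the |dE| band called neutral by :func:`classify`.
    """

    pseudocount: float = 0.5
    min_input_count: int = 25
    input_condition: str = "t0"
    reference_condition: str = "unselected"
    neutral_band: float = 0.2

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.min_input_count < 0:
            raise ValueError("min_input_count must be >= 0")
        if self.neutral_band < 0:
            raise ValueError("neutral_band must be >= 0")
        for cond in (self.input_condition, self.reference_condition):
            if cond not in ("t0", "unselected"):
                raise ValueError(f"unknown condition {cond!r}")


def delta_e(
    n_m_sel: float,
    n_m_ref: float,
    n_wt_sel: float,
    n_wt_ref: float,
    pseudocount: float = 0.0,
) -> float:
    """The enrichment score in log10 units (see module docstring).

    With ``pseudocount == 0`` all four counts must be positive; a zero count
    raises :class:`UndefinedScoreError` rather than silently returning
    +/-inf.
    """
    counts = (n_m_sel, n_m_ref, n_wt_sel, n_wt_ref)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and any(c == 0 for c in counts):
        raise UndefinedScoreError(
            f"zero count with pseudocount 0 leaves the score undefined: {counts}"
        )
    pc = pseudocount
    return math.log10((n_m_sel + pc) / (n_m_ref + pc)) - math.log10(
        (n_wt_sel + pc) / (n_wt_ref + pc)
    )


TableMap = dict[tuple[str, str, int], CountTable]
"""(pool_id, condition, replicate) -> CountTable"""


def score_replicate(
    tables: TableMap,
    pool_id: str,
    replicate: int,
    design: MutagenesisDesign,
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Codon-level scores for one pool x replicate.

    Every non-wild-type-codon variant of the pool gets a row with a status:
    ``ok`` (scored), ``insufficient_input`` (input-count filter or a count
    configuration that leaves the score undefined), or ``absent`` (never
    observed in any condition of this replicate).
    """
    sel = tables[(pool_id, "selected", replicate)]
    ref = tables[(pool_id, config.reference_condition, replicate)]
    inp = tables[(pool_id, config.input_condition, replicate)]
    rows = []
    for v in variants_for_pool(design, pool_id):
        if v.is_wt_codon:
            continue  # indistinguishable from wild type; its reads sit in wt_count
        key = (v.codon_index, v.codon)
        n_sel = sel.variant_count(*key)
        n_ref = ref.variant_count(*key)
        n_inp = inp.variant_count(*key)
        value = np.nan
        if n_sel == 0 and n_ref == 0 and n_inp == 0:
            status = "absent"
        elif n_inp < config.min_input_count:
            status = "insufficient_input"
        else:
            try:
                value = delta_e(n_sel, n_ref, sel.wt_count, ref.wt_count, config.pseudocount)
                status = "ok"
            except UndefinedScoreError:
                status = "insufficient_input"
        rows.append(
            {
                "pool_id": pool_id,
                "replicate": replicate,
                "codon_index": v.codon_index,
                "residue_number": v.codon_index + design.numbering_offset,
                "codon": v.codon,
                "aa_class": v.aa_class,
                "is_wt_synonymous": v.is_wt_synonymous,
                "n_input": float(n_inp),
                "n_sel": float(n_sel),
                "n_ref": float(n_ref),
                "value": value,
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def score_experiment(
    tables: TableMap,
    design: MutagenesisDesign,
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Codon-level scores for every (pool, replicate) present in ``tables``."""
    keys = sorted({(p, r) for (p, c, r) in tables})
    frames = [score_replicate(tables, p, r, design, config) for p, r in keys]
    return pd.concat(frames, ignore_index=True)


def apply_input_filter(
    scores: pd.DataFrame,
    tables: TableMap,
    threshold: int,
    input_condition: str = "t0",
) -> pd.DataFrame:
    """Re-apply the input-library count filter to an existing score frame.

    Variants whose count in the input condition is strictly below
    ``threshold`` get status ``insufficient_input`` (value masked); variants
    never observed anywhere keep/get ``absent``.
    """
    if input_condition not in ("t0", "unselected"):
        raise ValueError(f"unknown input_condition {input_condition!r}")
    out = scores.copy()
    n_inp = np.empty(len(out))
    for i, row in enumerate(out.itertuples()):
        table = tables[(row.pool_id, input_condition, row.replicate)]
        n_inp[i] = table.variant_count(row.codon_index, row.codon)
    out["n_input"] = n_inp
    low = (n_inp < threshold) & (out["status"] != "absent")
    out.loc[low, "status"] = "insufficient_input"
    out.loc[low, "value"] = np.nan
    # scores masked for other reasons (undefined at pc=0) stay masked; this
    # filter only ever tightens, it never recomputes
    return out


def average_replicates(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean score over replicates per (pool, codon), counting contributing
    replicates; codons with no ok replicate stay as missing rows (NaN)."""
    ok = scores[scores["status"] == "ok"]
    grouped = (
        ok.groupby(["pool_id", "codon_index", "codon"], as_index=False)
        .agg(value=("value", "mean"), n_replicates=("value", "size"))
    )
    meta = scores.drop_duplicates(["pool_id", "codon_index", "codon"])[
        ["pool_id", "codon_index", "residue_number", "codon", "aa_class", "is_wt_synonymous"]
    ]
    out = meta.merge(grouped, on=["pool_id", "codon_index", "codon"], how="left")
    out["n_replicates"] = out["n_replicates"].fillna(0).astype(int)
    return out


def aggregate_synonymous(codon_values: pd.DataFrame) -> pd.DataFrame:
    """Average synonymous codons into residue x amino-acid cells.

    Input is a codon-level frame with a ``value`` column (NaN = missing);
    output has one row per (pool, residue, aa) with the mean over
    contributing codons and ``n_codons`` recorded.  Cells with no
    contributing codon are absent from the output (missing).
    """
    ok = codon_values.dropna(subset=["value"])
    return (
        ok.groupby(["pool_id", "residue_number", "aa_class"], as_index=False)
        .agg(value=("value", "mean"), n_codons=("value", "size"))
    )


def residue_matrix(residue_values: pd.DataFrame, pool_id: str | None = None) -> pd.DataFrame:
    """Pivot residue-level values into a residues x (20 aa + stop) matrix.

    Missing cells are NaN.  If ``pool_id`` is given, only that pool's rows
    are used; otherwise the input must already be reconciled to one value
    per (residue, aa).
    """
    df = residue_values
    if pool_id is not None:
        df = df[df["pool_id"] == pool_id]
    wide = df.pivot_table(index="residue_number", columns="aa_class", values="value", aggfunc="mean")
    wide = wide.reindex(columns=list(AA_COLUMNS))
    wide.index.name = "residue_number"
    return wide


def replicate_correlation(scores: pd.DataFrame, pool_id: str) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-replicate residue-level scores.

    Synonymous codons are averaged within each replicate first; each
    replicate pair is correlated over the cells that are ok in both.  Pairs
    with fewer than 2 overlapping cells get ``r = NaN``.
    """
    pool_scores = scores[scores["pool_id"] == pool_id]
    per_rep: dict[int, pd.Series] = {}
    for rep, grp in pool_scores.groupby("replicate"):
        agg = aggregate_synonymous(grp.rename(columns={"value": "value"}))
        per_rep[int(rep)] = agg.set_index(["residue_number", "aa_class"])["value"]
    rows = []
    for a, b in itertools.combinations(sorted(per_rep), 2):
        joined = pd.concat([per_rep[a], per_rep[b]], axis=1, join="inner", keys=["a", "b"]).dropna()
        n = len(joined)
        if n < 2:
            r = np.nan
        else:
            r = float(np.corrcoef(joined["a"], joined["b"])[0, 1])
        rows.append({"pool_id": pool_id, "replicate_a": a, "replicate_b": b, "pearson_r": r, "n_cells": n})
    return pd.DataFrame(rows)


def classify(value, neutral_band: float = 0.2):
    """Map scores to gain / loss / neutral / missing.

    Accepts a scalar or an array-like; NaN propagates to ``missing``.
    """
    if neutral_band < 0:
        raise ValueError("neutral_band must be >= 0")

    def one(v: float) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "missing"
        if v > neutral_band:
            return "gain"
        if v < -neutral_band:
            return "loss"
        return "neutral"

    if np.isscalar(value) or value is None:
        return one(value)  # type: ignore[arg-type]
    arr = pd.Series(value, dtype=float)
    return arr.map(one)
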