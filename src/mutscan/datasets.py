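"""Bundled reference tables and the synthetic study-shaped design.

The deposited study provides no raw-sequencing accession, so the packaged
default design uses a synthetic 278-codon coding sequence with the real
experiment's geometry: NNS codons, three overlapping ~100-codon amplicon
pools (2-100, 90-189, 178-278) and a +338 offset from library codon index to
publication residue numbering.  The sequence itself is a deterministic random
CDS (synthetic; it is not the kinase's real gene) — every analysis stage is
sequence-agnostic, so the geometry, not the letters, is what matters.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .library_spec import (
    DegenerateCodonPattern,
    MutagenesisDesign,
    PoolRegion,
    translate_codon,
)

__all__ = [
    "load_ortholog_set_sizes",
    "total_ortholog_sequences",
    "load_default_annotations",
    "synthetic_reference_cds",
    "default_design",
]

#: Seed fixing the packaged synthetic reference CDS.
_CDS_SEED = 20220278

#: Library codon index -> publication residue number (residue = index + offset).
DEFAULT_NUMBERING_OFFSET = 338

#: The three amplicon pools of the kinase-domain scan (1-based, inclusive).
DEFAULT_POOLS = (
    PoolRegion("pool1", 2, 100),
    PoolRegion("pool2", 90, 189),
    PoolRegion("pool3", 178, 278),
)


def _data_path(name: str):
    return resources.files("mutscan.data").joinpath(name)


def load_ortholog_set_sizes() -> pd.DataFrame:
    """Sizes of the Syk-family ortholog sequence sets used for the ancestral
    reconstruction (fixture metadata; the reconstruction itself is out of
    scope here)."""
    with resources.as_file(_data_path("syk_ortholog_sets.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def total_ortholog_sequences() -> int:
    """Total number of ortholog sequences across all three sets."""
    return int(load_ortholog_set_sizes()["n_sequences"].sum())


def load_default_annotations() -> pd.DataFrame:
    """Bundled motif annotations of the kinase domain in publication numbering."""
    with resources.as_file(_data_path("motif_annotations.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def synthetic_reference_cds(n_codons: int = 278, seed: int = _CDS_SEED) -> str:
    """Deterministic random CDS without internal stop codons (synthetic).

    Starts with ATG; every subsequent codon is drawn uniformly from the 61
    sense codons.  Used as the stand-in reference for simulated experiments.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    sense = [
        a + b + c
        for a in bases
        for b in bases
        for c in bases
        if translate_codon(a + b + c) != "*"
    ]
    codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), size=n_codons - 1)]
    return "".join(codons)


def default_design(n_codons: int = 278) -> MutagenesisDesign:
    """Study-shaped NNS design over the synthetic reference CDS."""
    pools = tuple(p for p in DEFAULT_POOLS if p.first_codon <= n_codons)
    pools = tuple(
        PoolRegion(p.pool_id, p.first_codon, min(p.last_codon, n_codons)) for p in pools
    )
    return MutagenesisDesign(
        reference_cds=synthetic_reference_cds(n_codons),
        pattern=DegenerateCodonPattern.from_string("NNS"),
        pools=pools,
        numbering_offset=DEFAULT_NUMBERING_OFFSET,
    )
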