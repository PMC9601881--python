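"""Single-site degenerate-codon saturation library design.

A saturation mutagenesis library replaces each codon of a reference coding
sequence, one position at a time, with a degenerate codon (typically NNS:
N = A/C/G/T at the first two positions, S = C/G at the third).  The NNS set
contains 32 codons covering all 20 amino acids plus the amber stop codon
(TAG), and is the variant universe everything downstream scores against.

Coordinates are 1-based codon indices, inclusive on both ends, matching the
"residues 2-100" convention of mutagenesis pool descriptions.  A constant
``numbering_offset`` converts a library codon index into the residue
numbering used in publications about the full-length protein.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "STOP",
    "DegenerateCodonPattern",
    "PoolRegion",
    "MutagenesisDesign",
    "VariantId",
    "expand_degenerate",
    "translate_codon",
    "enumerate_variants",
    "variants_for_pool",
    "map_position",
    "mutagenized_indices",
    "load_reference_cds",
    "variant_universe_frame",
]

#: Amino-acid class used for the three stop codons.
STOP = "*"

# The 15 IUPAC nucleotide codes, e.g. "N" -> "ACGT", "S" -> "CG".  Biopython's
# table adds a non-standard "X" alias for N, which is not accepted here.
_IUPAC: dict[str, str] = {
    code.upper(): "".join(sorted(bases.upper()))
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code.upper() != "X"
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class DesignError(ValueError):
    """Raised when a library design violates its invariants."""


@dataclass(frozen=True)
class DegenerateCodonPattern:
    """An ordered triple of IUPAC nucleotide codes, e.g. ``("N", "N", "S")``."""

    symbols: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.symbols) != 3:
            raise DesignError(f"a codon pattern has 3 symbols, got {self.symbols!r}")
        for sym in self.symbols:
            if sym.upper() not in _IUPAC:
                raise DesignError(f"invalid IUPAC nucleotide code: {sym!r}")
        object.__setattr__(self, "symbols", tuple(s.upper() for s in self.symbols))

    @classmethod
    def from_string(cls, pattern: str) -> "DegenerateCodonPattern":
        return cls(tuple(pattern))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(self.symbols)

    @property
    def degeneracy(self) -> int:
        """Number of distinct codons the pattern expands to."""
        n = 1
        for sym in self.symbols:
            n *= len(_IUPAC[sym])
        return n


@dataclass(frozen=True)
class PoolRegion:
    """A contiguous stretch of mutagenized codons amplified as one amplicon.

    ``first_codon`` and ``last_codon`` are 1-based and inclusive.  Regions of
    distinct pools may overlap; overlapping positions are measured
    independently in each pool.
    """

    pool_id: str
    first_codon: int
    last_codon: int

    def __post_init__(self) -> None:
        if not 1 <= self.first_codon <= self.last_codon:
            raise DesignError(
                f"pool {self.pool_id!r}: need 1 <= first ({self.first_codon}) "
                f"<= last ({self.last_codon})"
            )

    @property
    def codon_indices(self) -> range:
        return range(self.first_codon, self.last_codon + 1)

    def __contains__(self, codon_index: int) -> bool:
        return self.first_codon <= codon_index <= self.last_codon


@dataclass(frozen=True)
class VariantId:
    """One codon substitution at one position of the reference CDS.

    ``is_wt_codon`` marks the codon identical to the reference codon (reads
    carrying it are indistinguishable from wild type and are tallied as such);
    ``is_wt_synonymous`` marks a different codon encoding the reference amino
    acid (a synonymous variant, scored like any mutant and expected neutral).
    """

    codon_index: int
    codon: str
    aa_class: str
    is_wt_codon: bool
    is_wt_synonymous: bool

    def __post_init__(self) -> None:
        if self.is_wt_codon and self.is_wt_synonymous:
            raise DesignError("a codon cannot be both wild-type and synonymous")

    @property
    def key(self) -> tuple[int, str]:
        return (self.codon_index, self.codon)


@dataclass(frozen=True)
class MutagenesisDesign:
    """Reference CDS + degenerate pattern + amplicon pools + numbering offset.

    ``numbering_offset`` is added to a 1-based library codon index to obtain
    the publication residue number (e.g. offset 338 maps library codon 88 to
    residue 426).
    """

    reference_cds: str
    pattern: DegenerateCodonPattern
    pools: tuple[PoolRegion, ...]
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        cds = self.reference_cds.upper()
        object.__setattr__(self, "reference_cds", cds)
        if len(cds) == 0 or len(cds) % 3 != 0:
            raise DesignError(
                f"reference CDS length {len(cds)} is not a positive multiple of 3"
            )
        bad = set(cds) - set("ACGT")
        if bad:
            raise DesignError(f"reference CDS contains non-ACGT characters: {sorted(bad)}")
        object.__setattr__(self, "pools", tuple(self.pools))
        n_codons = len(cds) // 3
        for pool in self.pools:
            if pool.last_codon > n_codons:
                raise DesignError(
                    f"pool {pool.pool_id!r} extends past the CDS "
                    f"({pool.last_codon} > {n_codons} codons)"
                )
        ids = [p.pool_id for p in self.pools]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate pool ids: {ids}")

    @property
    def n_codons(self) -> int:
        return len(self.reference_cds) // 3

    def reference_codon(self, codon_index: int) -> str:
        if not 1 <= codon_index <= self.n_codons:
            raise DesignError(f"codon index {codon_index} outside CDS (1..{self.n_codons})")
        return self.reference_cds[3 * (codon_index - 1) : 3 * codon_index]

    def pool(self, pool_id: str) -> PoolRegion:
        for p in self.pools:
            if p.pool_id == pool_id:
                return p
        raise DesignError(f"unknown pool id {pool_id!r}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference_cds": self.reference_cds,
            "pattern": str(self.pattern),
            "pools": [
                {"pool_id": p.pool_id, "first_codon": p.first_codon, "last_codon": p.last_codon}
                for p in self.pools
            ],
            "numbering_offset": self.numbering_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MutagenesisDesign":
        return cls(
            reference_cds=d["reference_cds"],
            pattern=DegenerateCodonPattern.from_string(d["pattern"]),
            pools=tuple(
                PoolRegion(p["pool_id"], int(p["first_codon"]), int(p["last_codon"]))
                for p in d["pools"]
            ),
            numbering_offset=int(d.get("numbering_offset", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "MutagenesisDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def expand_degenerate(pattern: DegenerateCodonPattern | str) -> frozenset[str]:
    """Expand a degenerate codon pattern to its full codon set.

    The result size equals the product of the per-symbol degeneracies
    (NNS -> 4*4*2 = 32 codons).
    """
    if isinstance(pattern, str):
        pattern = DegenerateCodonPattern.from_string(pattern)
    choices = [_IUPAC[sym] for sym in pattern.symbols]
    return frozenset("".join(c) for c in itertools.product(*choices))


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation; TAA/TAG/TGA return ``"*"``."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise DesignError(f"not an unambiguous codon: {codon!r}")
    if codon in _STANDARD_TABLE.stop_codons:
        return STOP
    return _STANDARD_TABLE.forward_table[codon]


def mutagenized_indices(design: MutagenesisDesign) -> list[int]:
    """Sorted union of all codon indices covered by any pool."""
    idx: set[int] = set()
    for pool in design.pools:
        idx.update(pool.codon_indices)
    return sorted(idx)


def _variants_at(design: MutagenesisDesign, codon_index: int) -> list[VariantId]:
    ref_codon = design.reference_codon(codon_index)
    ref_aa = translate_codon(ref_codon)
    out = []
    for codon in sorted(expand_degenerate(design.pattern)):
        aa = translate_codon(codon)
        is_wt = codon == ref_codon
        out.append(
            VariantId(
                codon_index=codon_index,
                codon=codon,
                aa_class=aa,
                is_wt_codon=is_wt,
                is_wt_synonymous=(not is_wt) and aa == ref_aa,
            )
        )
    return out


def enumerate_variants(design: MutagenesisDesign) -> list[VariantId]:
    """All library variants, ordered by (codon_index, codon); duplicate-free.

    Positions covered by two overlapping pools appear once here; per-pool
    enumeration is :func:`variants_for_pool`.
    """
    out: list[VariantId] = []
    for idx in mutagenized_indices(design):
        out.extend(_variants_at(design, idx))
    return out


def variants_for_pool(design: MutagenesisDesign, pool_id: str) -> list[VariantId]:
    """Variants of one amplicon pool, ordered by (codon_index, codon)."""
    pool = design.pool(pool_id)
    out: list[VariantId] = []
    for idx in pool.codon_indices:
        out.extend(_variants_at(design, idx))
    return out


def map_position(design: MutagenesisDesign, codon_index: int) -> int:
    """Publication residue number for a mutagenized library codon index."""
    if not any(codon_index in pool for pool in design.pools):
        raise DesignError(f"codon index {codon_index} is not covered by any pool")
    return codon_index + design.numbering_offset


def load_reference_cds(path: str | Path) -> str:
    """Read a single-record FASTA and return its sequence as a string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DesignError(f"expected exactly one FASTA record in {path}, got {len(records)}")
    return str(records[0].seq).upper()


def variant_universe_frame(design: MutagenesisDesign) -> pd.DataFrame:
    """Tidy per-pool export of the variant universe.

    Columns: pool_id, codon_index, residue_number, codon, aa_class,
    is_wt_codon, is_wt_synonymous.  Overlapping-pool positions appear once
    per pool, since each pool measures them independently.
    """
    rows = []
    for pool in design.pools:
        for v in variants_for_pool(design, pool.pool_id):
            rows.append(
                {
                    "pool_id": pool.pool_id,
                    "codon_index": v.codon_index,
                    "residue_number": v.codon_index + design.numbering_offset,
                    "codon": v.codon,
                    "aa_class": v.aa_class,
                    "is_wt_codon": v.is_wt_codon,
                    "is_wt_synonymous": v.is_wt_synonymous,
                }
            )
    return pd.DataFrame(rows)
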