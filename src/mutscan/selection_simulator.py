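"""Growth-selection simulator with known per-variant selection coefficients.

Models the two-hybrid growth selection as pure exponential competition: a
variant with selection coefficient ``s`` (per-hour growth-rate difference
vs wild type) changes abundance as ``N0 * exp((r_wt + s) * t)`` during the
selection window.  The whole reporter cascade (kinase -> phospho-bait ->
SH2 -> polymerase -> resistance enzyme) is collapsed into ``s``; the assay
reads out growth, nothing else.

The simulated workflow mirrors the experiment: cells carrying the library
grow for a 3 h induction (neutral), the population is sampled for the input
library (T0), diluted through a bottleneck into a selected and an
unselected flask, grown 7 h (the unselected flask saturating logistically,
the selected one staying in exponential phase), and each endpoint is
sequenced by a multinomial draw of fixed depth, so per-sample counts are
exactly conserved.  In the deterministic limit (bottlenecks and sampling
disabled) the pipeline's enrichment score equals ``s * t / ln(10)``
exactly, which anchors the correctness tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .amplicon_counting import CountTable, ManifestEntry, SampleManifest, pool_amplicon
from .library_spec import MutagenesisDesign, VariantId, variants_for_pool

__all__ = [
    "EffectModel",
    "FitnessMap",
    "SimulationConfig",
    "SimulatedExperiment",
    "assign_fitness",
    "simulate_counts",
    "expected_delta_e",
    "emit_fastq",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EffectModel:
    """Mixture model for ground-truth mutational effects.

    Positions are drawn loss / neutral / gain with the given fractions
    (most positions of a protein are mutation-tolerant, so neutral carries
    the majority).  At a loss (gain) position each non-synonymous variant
    draws its own negative (positive) effect magnitude from a folded
    normal; synonymous variants are neutral everywhere and stop codons get
    ``s_min`` at every position.  Units: per-hour growth-rate difference.
    """

    frac_loss: float = 0.3
    frac_neutral: float = 0.6
    frac_gain: float = 0.1
    loss_mean: float = 0.4
    loss_sd: float = 0.15
    gain_mean: float = 0.25
    gain_sd: float = 0.1
    s_min: float = -1.0

    def __post_init__(self) -> None:
        total = self.frac_loss + self.frac_neutral + self.frac_gain
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimulationError(f"class fractions must sum to 1, got {total}")
        if min(self.frac_loss, self.frac_neutral, self.frac_gain) < 0:
            raise SimulationError("class fractions must be non-negative")


@dataclass
class FitnessMap:
    """Ground-truth selection coefficients per variant.

    ``s`` maps (codon_index, codon) to the coefficient under selection;
    unlisted variants (including the wild-type codon and, by default, all
    synonymous variants) are 0.  ``toxicity`` is an optional additional
    growth-rate term applied in the *unselected* flask (e.g. kinase
    over-activity harming the host independently of the reporter).
    """

    s: dict[tuple[int, str], float] = field(default_factory=dict)
    toxicity: dict[tuple[int, str], float] = field(default_factory=dict)
    position_class: dict[int, str] = field(default_factory=dict)

    def s_of(self, codon_index: int, codon: str) -> float:
        return self.s.get((codon_index, codon), 0.0)

    def toxicity_of(self, codon_index: int, codon: str) -> float:
        return self.toxicity.get((codon_index, codon), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon_index": idx,
                "codon": codon,
                "s": s,
                "toxicity": self.toxicity.get((idx, codon), 0.0),
                "position_class": self.position_class.get(idx, "neutral"),
            }
            for (idx, codon), s in sorted(self.s.items())
        ]
        return pd.DataFrame(rows, columns=["codon_index", "codon", "s", "toxicity", "position_class"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def assign_fitness(
    design: MutagenesisDesign,
    model: EffectModel = EffectModel(),
    seed: int = 0,
) -> FitnessMap:
    """Draw a reproducible ground-truth fitness map for a design."""
    rng = np.random.default_rng(seed)
    fmap = FitnessMap()
    by_index: dict[int, list[VariantId]] = {}
    for pool in design.pools:
        for v in variants_for_pool(design, pool.pool_id):
            by_index.setdefault(v.codon_index, []).append(v)
    for idx in sorted(by_index):
        cls = rng.choice(
            ["loss", "neutral", "gain"],
            p=[model.frac_loss, model.frac_neutral, model.frac_gain],
        )
        fmap.position_class[idx] = str(cls)
        seen: set[str] = set()
        for v in by_index[idx]:
            if v.codon in seen:
                continue  # overlapping pools list a position twice
            seen.add(v.codon)
            if v.aa_class == "*":
                fmap.s[(idx, v.codon)] = model.s_min
            elif v.is_wt_codon or v.is_wt_synonymous:
                fmap.s[(idx, v.codon)] = 0.0
            elif cls == "loss":
                fmap.s[(idx, v.codon)] = -abs(rng.normal(model.loss_mean, model.loss_sd))
            elif cls == "gain":
                fmap.s[(idx, v.codon)] = abs(rng.normal(model.gain_mean, model.gain_sd))
            else:
                fmap.s[(idx, v.codon)] = 0.0
    return fmap


def benchmark_fitness(
    design: MutagenesisDesign,
    s_low: float = -0.6,
    s_high: float = 0.3,
    s_min: float = -1.0,
    seed: int = 0,
) -> FitnessMap:
    """Continuous-effects ground truth for rank-recovery benchmarking.

    Every non-synonymous variant draws an iid uniform effect in
    ``[s_low, s_high]``; stops get ``s_min`` and synonymous variants 0.
    Unlike the study-like mixture of :func:`assign_fitness`, this map has
    essentially no tied true values, so a rank correlation between true and
    recovered effects actually measures recovery error instead of being
    capped by the neutral tie group.
    """
    rng = np.random.default_rng(seed)
    fmap = FitnessMap()
    seen: set[tuple[int, str]] = set()
    for pool in design.pools:
        for v in variants_for_pool(design, pool.pool_id):
            key = (v.codon_index, v.codon)
            if key in seen:
                continue
            seen.add(key)
            if v.aa_class == "*":
                fmap.s[key] = s_min
            elif v.is_wt_codon or v.is_wt_synonymous:
                fmap.s[key] = 0.0
            else:
                fmap.s[key] = float(rng.uniform(s_low, s_high))
    return fmap


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment geometry and sampling layers.

    Defaults follow the study's schedule: 3 h neutral induction, dilution
    through a bottleneck into two flasks, 7 h selection, sequencing of T0
    and both endpoints at fixed depth for 3 replicates.  ``sampling`` and
    ``bottlenecks`` can be switched off to obtain the deterministic
    (infinite-depth) limit, in which counts are expected values (floats).
    """

    random_seed: int
    induction_hours: float = 3.0
    selection_hours: float = 7.0
    wt_growth_rate: float = 1.0
    wt_fraction: float = 0.05
    bottleneck_cells: int = 2_000_000
    carrying_capacity: float = 2e9
    sequencing_depth: int = 1_000_000
    base_error_rate: float = 0.0
    n_replicates: int = 3
    sampling: bool = True
    bottlenecks: bool = True
    saturate_unselected: bool = True
    saturate_selected: bool = False

    def __post_init__(self) -> None:
        if self.random_seed is None:
            raise SimulationError("a random seed is mandatory for reproducibility")
        for name in (
            "induction_hours",
            "selection_hours",
            "wt_growth_rate",
            "bottleneck_cells",
            "carrying_capacity",
            "sequencing_depth",
            "base_error_rate",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not 0 <= self.wt_fraction < 1:
            raise SimulationError("wt_fraction must be in [0, 1)")
        if self.n_replicates < 1:
            raise SimulationError("need at least one replicate")


@dataclass
class SimulatedExperiment:
    """Ground truth plus generated counts for every manifest sample."""

    design: MutagenesisDesign
    fitness: FitnessMap
    config: SimulationConfig
    manifest: SampleManifest
    tables: dict[tuple[str, str, int], CountTable]

    def table(self, pool_id: str, condition: str, replicate: int) -> CountTable:
        return self.tables[(pool_id, condition, replicate)]

    def write_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for table in self.tables.values():
            table.write_tsv(
                outdir / f"{table.sample_id}.counts.tsv",
                outdir / f"{table.sample_id}.summary.tsv",
                self.design,
            )
        self.fitness.write_tsv(outdir / "ground_truth.tsv")
        self.manifest.save(outdir / "manifest.yaml")


def _grow(n: np.ndarray, rates: np.ndarray, hours: float, cap: Optional[float]) -> np.ndarray:
    """Exponential growth, optionally capped by a shared logistic resource.

    With a cap, all lineages grow for a common effective time tau <= hours
    chosen so the total just reaches the carrying capacity — this preserves
    the exponential form per lineage while compressing fold-changes.
    """
    total0 = n.sum()
    if total0 == 0 or hours == 0:
        return n.astype(float)

    def total_at(tau: float) -> float:
        return float(np.sum(n * np.exp(rates * tau)))

    if cap is None or total_at(hours) <= cap:
        return n * np.exp(rates * hours)
    if total0 >= cap:
        return n.astype(float)
    tau = brentq(lambda t: total_at(t) - cap, 0.0, hours, xtol=1e-12)
    return n * np.exp(rates * tau)


def simulate_counts(
    design: MutagenesisDesign,
    fitness: FitnessMap,
    config: SimulationConfig,
) -> SimulatedExperiment:
    """Run the full selection for every pool and replicate.

    Each pool is an independent experiment over its own variants plus a
    wild-type background (``wt_fraction`` of molecules, plus the library
    molecules whose degenerate draw equals the reference codon, which read
    as wild type).  Every sequenced sample's counts sum exactly to
    ``sequencing_depth``.
    """
    ss = np.random.SeedSequence(config.random_seed)
    entries: list[ManifestEntry] = []
    tables: dict[tuple[str, str, int], CountTable] = {}

    for pool in design.pools:
        variants = [v for v in variants_for_pool(design, pool.pool_id)]
        non_wt = [v for v in variants if not v.is_wt_codon]
        n_molecule_types = len(variants)  # incl. wt-codon draws
        # slot 0 = wild type; slots 1.. = non-wt variants
        per_molecule = (1.0 - config.wt_fraction) / n_molecule_types
        x0 = np.empty(len(non_wt) + 1)
        x0[0] = config.wt_fraction + per_molecule * (n_molecule_types - len(non_wt))
        x0[1:] = per_molecule
        x0 /= x0.sum()

        s_sel = np.zeros(len(non_wt) + 1)
        s_tox = np.zeros(len(non_wt) + 1)
        for i, v in enumerate(non_wt, start=1):
            s_sel[i] = fitness.s_of(v.codon_index, v.codon)
            s_tox[i] = fitness.toxicity_of(v.codon_index, v.codon)
        r_sel = config.wt_growth_rate + s_sel
        r_unsel = config.wt_growth_rate + s_tox

        for rep in range(1, config.n_replicates + 1):
            rng = np.random.default_rng(ss.spawn(1)[0])

            def sequence(freqs: np.ndarray) -> np.ndarray:
                freqs = freqs / freqs.sum()
                if config.sampling:
                    return rng.multinomial(config.sequencing_depth, freqs).astype(float)
                return config.sequencing_depth * freqs

            def bottleneck(freqs: np.ndarray) -> np.ndarray:
                freqs = freqs / freqs.sum()
                if config.bottlenecks:
                    return rng.multinomial(config.bottleneck_cells, freqs).astype(float)
                return config.bottleneck_cells * freqs

            # induction is neutral: T0 frequencies equal the inoculum mix
            t0_counts = sequence(x0)

            results: dict[str, np.ndarray] = {"t0": t0_counts}
            for condition, rates, saturate in (
                ("selected", r_sel, config.saturate_selected),
                ("unselected", r_unsel, config.saturate_unselected),
            ):
                n_start = bottleneck(x0)
                cap = config.carrying_capacity if saturate else None
                n_end = _grow(n_start, rates, config.selection_hours, cap)
                results[condition] = sequence(n_end)

            for condition, vec in results.items():
                sample_id = f"{pool.pool_id}_{condition}_r{rep}"
                entry = ManifestEntry(sample_id, pool.pool_id, condition, rep)
                entries.append(entry)
                counts = {
                    (v.codon_index, v.codon): float(c)
                    for v, c in zip(non_wt, vec[1:])
                    if c > 0
                }
                table = CountTable(
                    pool_id=pool.pool_id,
                    sample_id=sample_id,
                    counts=counts,
                    wt_count=float(vec[0]),
                    total_reads=float(vec.sum()),
                )
                table.validate()
                tables[(pool.pool_id, condition, rep)] = table

    return SimulatedExperiment(
        design=design,
        fitness=fitness,
        config=config,
        manifest=SampleManifest(entries),
        tables=tables,
    )


def expected_delta_e(s: float, t_sel: float) -> float:
    """Enrichment score implied by pure exponential growth: s*t/ln(10)."""
    return s * t_sel / math.log(10)


def emit_fastq(
    experiment: SimulatedExperiment,
    outdir: str | Path,
    paired: bool = False,
    read_length: int = 250,
    base_error_rate: Optional[float] = None,
    seed: Optional[int] = None,
    flank: int = 18,
    min_overlap: int = 20,
) -> SampleManifest:
    """Write the experiment's reads as FASTQ, one (or one pair of) file(s)
    per sample, and return a manifest whose sources point at them.

    Each read is the pool amplicon with the variant codon substituted.  In
    paired mode R1/R2 are the two amplicon ends; the pair must overlap by
    at least ``min_overlap``.  Substitution errors are injected per base at
    ``base_error_rate`` (defaults to the simulation config's rate); the
    pre-error count ledger is the experiment's count tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    err = experiment.config.base_error_rate if base_error_rate is None else base_error_rate
    ss = np.random.SeedSequence(
        experiment.config.random_seed if seed is None else seed
    )
    rng = np.random.default_rng(ss)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    new_entries: list[ManifestEntry] = []
    for entry in experiment.manifest:
        table = experiment.tables[(entry.pool_id, entry.condition, entry.replicate)]
        amplicon = pool_amplicon(experiment.design, entry.pool_id, flank=flank)
        if paired:
            if read_length > len(amplicon.seq):
                raise SimulationError("read_length exceeds the amplicon length")
            if 2 * read_length - len(amplicon.seq) < min_overlap:
                raise SimulationError(
                    f"amplicon of {len(amplicon.seq)} nt cannot be covered by "
                    f"{read_length} nt pairs with a {min_overlap} nt overlap"
                )

        def reads_for_sample():
            items = [(None, table.wt_count)] + [
                (key, c) for key, c in sorted(table.counts.items())
            ]
            for key, count in items:
                if count != int(count):
                    raise SimulationError(
                        "FASTQ emission needs integer counts; run with sampling enabled"
                    )
                if key is None:
                    seq = amplicon.seq
                else:
                    idx, codon = key
                    off = amplicon.region_start + 3 * (idx - amplicon.first_codon)
                    seq = amplicon.seq[:off] + codon + amplicon.seq[off + 3 :]
                for _ in range(int(count)):
                    yield _inject_errors(seq, err, rng, bases)

        qual_char = "F"  # Q37
        if paired:
            p1 = outdir / f"{entry.sample_id}_R1.fastq"
            p2 = outdir / f"{entry.sample_id}_R2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for i, seq in enumerate(reads_for_sample()):
                    r1 = seq[:read_length]
                    r2 = _revcomp(seq[-read_length:])
                    f1.write(f"@{entry.sample_id}:{i}/1\n{r1}\n+\n{qual_char * len(r1)}\n")
                    f2.write(f"@{entry.sample_id}:{i}/2\n{r2}\n+\n{qual_char * len(r2)}\n")
            sources: tuple[str, ...] = (str(p1), str(p2))
        else:
            p = outdir / f"{entry.sample_id}.fastq"
            with open(p, "w") as fh:
                for i, seq in enumerate(reads_for_sample()):
                    fh.write(f"@{entry.sample_id}:{i}\n{seq}\n+\n{qual_char * len(seq)}\n")
            sources = (str(p),)
        new_entries.append(replace(entry, sources=sources))
    return SampleManifest(new_entries)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _inject_errors(seq: str, rate: float, rng: np.random.Generator, bases: np.ndarray) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    for p in pos:
        choices = bases[bases != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()
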