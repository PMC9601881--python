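"""Ground-truth assignment, growth simulation and FASTQ emission."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from mutscan.amplicon_counting import load_count_tables, tally_fastq
from mutscan.enrichment import ScoringConfig, score_experiment
from mutscan.library_spec import (
    DegenerateCodonPattern,
    MutagenesisDesign,
    PoolRegion,
    mutagenized_indices,
    variants_for_pool,
)
from mutscan import datasets
from mutscan.selection_simulator import (
    EffectModel,
    SimulationConfig,
    SimulationError,
    assign_fitness,
    benchmark_fitness,
    emit_fastq,
    expected_delta_e,
    simulate_counts,
)


class TestAssignFitness:
    def test_all_neutral_model_gives_zero_everywhere(self, small_design):
        model = EffectModel(frac_loss=0, frac_neutral=1, frac_gain=0, s_min=0.0)
        fmap = assign_fitness(small_design, model, seed=1)
        assert all(s == 0.0 for s in fmap.s.values())

    def test_stop_only_effects(self, small_design):
        model = EffectModel(frac_loss=0, frac_neutral=1, frac_gain=0, s_min=-1.0)
        fmap = assign_fitness(small_design, model, seed=1)
        stops = {k: s for k, s in fmap.s.items() if k[1] == "TAG"}
        # exactly the one NNS stop codon per position, forced to s_min
        assert len(stops) == len(mutagenized_indices(small_design))
        assert all(s == -1.0 for s in stops.values())
        assert all(s == 0.0 for k, s in fmap.s.items() if k[1] != "TAG")

    def test_class_proportions_within_binomial_noise(self):
        design = datasets.default_design(120)
        model = EffectModel()
        fmap = assign_fitness(design, model, seed=7)
        classes = pd.Series(fmap.position_class)
        n = len(classes)
        for cls, frac in [("loss", 0.3), ("neutral", 0.6), ("gain", 0.1)]:
            k = int((classes == cls).sum())
            assert binomtest(k, n, frac).pvalue > 1e-4

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SimulationError):
            EffectModel(frac_loss=0.5, frac_neutral=0.6, frac_gain=0.1)

    def test_synonymous_variants_neutral_under_default_model(self, small_design):
        fmap = assign_fitness(small_design, EffectModel(), seed=3)
        for pool in small_design.pools:
            for v in variants_for_pool(small_design, pool.pool_id):
                if v.is_wt_codon or v.is_wt_synonymous:
                    assert fmap.s_of(v.codon_index, v.codon) == 0.0


class TestExpectedDeltaE:
    def test_exponential_growth_algebra(self):
        assert expected_delta_e(0.0, 7.0) == 0.0
        assert expected_delta_e(math.log(10) / 7, 7.0) == pytest.approx(1.0, abs=1e-12)
        assert expected_delta_e(-math.log(10) / 7, 7.0) == pytest.approx(-1.0, abs=1e-12)


def _grid_fitness(design, grid):
    """Place a grid of s values on distinct non-synonymous variants."""
    fmap = assign_fitness(
        design, EffectModel(frac_loss=0, frac_neutral=1, frac_gain=0, s_min=0.0), seed=0
    )
    targets = [
        v
        for pool in design.pools
        for v in variants_for_pool(design, pool.pool_id)
        if not (v.is_wt_codon or v.is_wt_synonymous or v.aa_class == "*")
    ]
    chosen = []
    step = max(1, len(targets) // len(grid))
    for v, s in zip(targets[::step], grid):
        fmap.s[(v.codon_index, v.codon)] = float(s)
        chosen.append(v)
    assert len(chosen) == len(grid)
    return fmap, chosen


class TestSimulateCounts:
    def test_neutral_selection_gives_zero_scores_in_the_deterministic_limit(
        self, single_pool_design
    ):
        model = EffectModel(frac_loss=0, frac_neutral=1, frac_gain=0, s_min=0.0)
        fmap = assign_fitness(single_pool_design, model, seed=1)
        config = SimulationConfig(random_seed=1, sampling=False, bottlenecks=False, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        scores = score_experiment(
            exp.tables, single_pool_design, ScoringConfig(pseudocount=0.0, min_input_count=0)
        )
        assert np.allclose(scores["value"].dropna(), 0.0, atol=1e-12)

    def test_deterministic_limit_matches_closed_form_on_s_grid(self, single_pool_design):
        grid = np.linspace(-1.0, 1.0, 21)
        fmap, chosen = _grid_fitness(single_pool_design, grid)
        config = SimulationConfig(random_seed=1, sampling=False, bottlenecks=False, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        scores = score_experiment(
            exp.tables, single_pool_design, ScoringConfig(pseudocount=0.0, min_input_count=0)
        ).set_index(["codon_index", "codon"])
        for v, s in zip(chosen, grid):
            got = scores.loc[v.key, "value"]
            assert abs(got - expected_delta_e(s, config.selection_hours)) <= 1e-9

    def test_unselected_saturation_cancels_in_the_score(self, single_pool_design):
        grid = np.linspace(-0.5, 0.5, 5)
        fmap, chosen = _grid_fitness(single_pool_design, grid)
        base = SimulationConfig(random_seed=1, sampling=False, bottlenecks=False, n_replicates=1)
        tight_cap = SimulationConfig(
            random_seed=1,
            sampling=False,
            bottlenecks=False,
            n_replicates=1,
            carrying_capacity=1e7,  # forces the unselected flask deep into saturation
        )
        def values(cfg):
            exp = simulate_counts(single_pool_design, fmap, cfg)
            scores = score_experiment(
                exp.tables, single_pool_design, ScoringConfig(pseudocount=0.0, min_input_count=0)
            ).set_index(["codon_index", "codon"])
            return np.array([scores.loc[v.key, "value"] for v in chosen])

        assert np.allclose(values(base), values(tight_cap), atol=1e-9)

    def test_counts_conserved_at_sequencing_depth(self, small_design):
        fmap = assign_fitness(small_design, EffectModel(), seed=2)
        config = SimulationConfig(random_seed=2, sequencing_depth=5000, n_replicates=2)
        exp = simulate_counts(small_design, fmap, config)
        assert len(exp.tables) == len(small_design.pools) * 3 * 2
        for table in exp.tables.values():
            assert table.total_reads == 5000
            table.validate()

    def test_seed_determinism(self, small_design):
        fmap = assign_fitness(small_design, EffectModel(), seed=2)
        config = SimulationConfig(random_seed=5, sequencing_depth=2000)
        a = simulate_counts(small_design, fmap, config)
        b = simulate_counts(small_design, fmap, config)
        assert a.tables.keys() == b.tables.keys()
        for key in a.tables:
            assert a.tables[key].counts == b.tables[key].counts
            assert a.tables[key].wt_count == b.tables[key].wt_count

    def test_table_tsv_round_trip_through_manifest(self, small_design, tmp_path):
        fmap = assign_fitness(small_design, EffectModel(), seed=2)
        config = SimulationConfig(random_seed=3, sequencing_depth=1000, n_replicates=1)
        exp = simulate_counts(small_design, fmap, config)
        exp.write_tables(tmp_path)
        loaded = load_count_tables(tmp_path, exp.manifest)
        assert loaded.keys() == exp.tables.keys()
        for key in loaded:
            assert loaded[key].counts == exp.tables[key].counts


class TestParameterRecovery:
    def test_rank_recovery_under_continuous_effects(self):
        from scipy.stats import spearmanr
        from mutscan.enrichment import average_replicates

        design = MutagenesisDesign(
            reference_cds=datasets.synthetic_reference_cds(21, seed=11),
            pattern=DegenerateCodonPattern.from_string("NNS"),
            pools=(PoolRegion("p1", 2, 21),),
        )
        fmap = benchmark_fitness(design, seed=42)
        config = SimulationConfig(random_seed=42, sequencing_depth=400_000)
        exp = simulate_counts(design, fmap, config)
        per_codon = average_replicates(score_experiment(exp.tables, design))
        merged = per_codon.dropna(subset=["value"]).copy()
        merged["s_true"] = [
            fmap.s_of(i, c) for i, c in zip(merged.codon_index, merged.codon)
        ]
        rho = spearmanr(merged["s_true"], merged["value"]).statistic
        assert rho >= 0.9


class TestEmitFastq:
    def test_zero_error_round_trip_reproduces_ledger(self, single_pool_design, tmp_path):
        fmap = assign_fitness(single_pool_design, EffectModel(), seed=4)
        config = SimulationConfig(random_seed=4, sequencing_depth=400, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        manifest = emit_fastq(exp, tmp_path, base_error_rate=0.0)
        for entry in manifest:
            table = tally_fastq(entry, single_pool_design)
            ledger = exp.tables[(entry.pool_id, entry.condition, entry.replicate)]
            assert table.counts == {k: v for k, v in ledger.counts.items()}
            assert table.wt_count == ledger.wt_count
            assert table.total_reads == ledger.total_reads
            assert sum(table.rejected.values()) == 0

    def test_paired_end_round_trip(self, single_pool_design, tmp_path):
        fmap = assign_fitness(single_pool_design, EffectModel(), seed=4)
        config = SimulationConfig(random_seed=4, sequencing_depth=200, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        # the tiny amplicon is 24 nt (3 nt flanks survive at the CDS ends),
        # so 18 nt pairs overlap by 12
        manifest = emit_fastq(exp, tmp_path, paired=True, read_length=18, min_overlap=10)
        entry = manifest.entries[0]
        assert len(entry.sources) == 2
        table = tally_fastq(entry, single_pool_design, min_overlap=10)
        ledger = exp.tables[(entry.pool_id, entry.condition, entry.replicate)]
        assert table.counts == ledger.counts
        assert table.wt_count == ledger.wt_count

    def test_base_errors_produce_rejects_within_poisson_bounds(
        self, single_pool_design, tmp_path
    ):
        fmap = assign_fitness(
            single_pool_design,
            EffectModel(frac_loss=0, frac_neutral=1, frac_gain=0, s_min=0.0),
            seed=4,
        )
        depth = 2000
        config = SimulationConfig(random_seed=4, sequencing_depth=depth, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        rate = 0.002
        manifest = emit_fastq(exp, tmp_path, base_error_rate=rate, seed=99)
        entry = manifest.get("p1", "t0", 1)
        table = tally_fastq(entry, single_pool_design)
        # analytic oracle: each error-carrying read leaves the exact-ledger
        # classes; expected number of hit reads is depth * (1-(1-e)^L)
        amplicon_nt = len(
            __import__("mutscan.amplicon_counting", fromlist=["pool_amplicon"]).pool_amplicon(
                single_pool_design, "p1"
            ).seq
        )
        p_hit = 1 - (1 - rate) ** amplicon_nt
        expected = depth * p_hit
        ledger = exp.tables[("p1", "t0", 1)]
        perturbed = (
            table.off_design
            + sum(table.rejected.values())
            + abs(table.wt_count - ledger.wt_count)
        )
        sd = math.sqrt(depth * p_hit * (1 - p_hit))
        assert perturbed <= expected + 6 * sd
        assert perturbed >= max(0.0, expected - 6 * sd) * 0.2  # loose lower bound

    def test_zero_depth_gives_empty_files(self, single_pool_design, tmp_path):
        fmap = assign_fitness(single_pool_design, EffectModel(), seed=4)
        config = SimulationConfig(random_seed=4, sequencing_depth=0, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        manifest = emit_fastq(exp, tmp_path)
        for entry in manifest:
            assert (tmp_path / f"{entry.sample_id}.fastq").stat().st_size == 0

    def test_unachievable_merged_length_rejected(self, single_pool_design, tmp_path):
        fmap = assign_fitness(single_pool_design, EffectModel(), seed=4)
        config = SimulationConfig(random_seed=4, sequencing_depth=10, n_replicates=1)
        exp = simulate_counts(single_pool_design, fmap, config)
        with pytest.raises(SimulationError):
            emit_fastq(exp, tmp_path, paired=True, read_length=20)


class TestPipelineEquivalence:
    def test_scores_identical_from_tables_and_refastqed_counts(
        self, single_pool_design, tmp_path
    ):
        fmap = assign_fitness(single_pool_design, EffectModel(), seed=8)
        config = SimulationConfig(random_seed=8, sequencing_depth=300)
        exp = simulate_counts(single_pool_design, fmap, config)
        manifest = emit_fastq(exp, tmp_path, base_error_rate=0.0)
        retallied = {
            (e.pool_id, e.condition, e.replicate): tally_fastq(e, single_pool_design)
            for e in manifest
        }
        direct = score_experiment(exp.tables, single_pool_design)
        indirect = score_experiment(retallied, single_pool_design)
        pd.testing.assert_frame_equal(direct, indirect)
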