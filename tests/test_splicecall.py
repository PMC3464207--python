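import itertools

import numpy as np
import pandas as pd
import pytest

from spliceindex import simdata, splicecall
from spliceindex.preprocess import gene_expression_signal, summarize_probe_sets
from spliceindex.splicecall import (
    TIER1,
    TIER2,
    NO_TIER,
    apply_filters,
    call_events,
    compute_inorm,
    cross_tissue_concordance,
    ttest_two_tailed,
)


def toy_annotation():
    rows = [
        dict(probe_set_id="ps.exon", gene_id="g", event_id="ev", role="exon",
             flag_constitutive=0, flag_multi_gene=0, flag_alt_promoter=0,
             flag_conserved=1, flag_neuron_specific=1),
        dict(probe_set_id="ps.skip", gene_id="g", event_id="ev", role="skipping_junction",
             flag_constitutive=0, flag_multi_gene=0, flag_alt_promoter=0,
             flag_conserved=1, flag_neuron_specific=1),
        dict(probe_set_id="ps.up", gene_id="g", event_id="ev", role="inclusion_junction_up",
             flag_constitutive=0, flag_multi_gene=0, flag_alt_promoter=0,
             flag_conserved=1, flag_neuron_specific=1),
        dict(probe_set_id="ps.const", gene_id="g", event_id="", role="constitutive",
             flag_constitutive=1, flag_multi_gene=0, flag_alt_promoter=0,
             flag_conserved=0, flag_neuron_specific=0),
        dict(probe_set_id="ps.multi", gene_id="g", event_id="", role="exon",
             flag_constitutive=0, flag_multi_gene=1, flag_alt_promoter=0,
             flag_conserved=0, flag_neuron_specific=0),
        dict(probe_set_id="ps.altp", gene_id="g", event_id="", role="exon",
             flag_constitutive=0, flag_multi_gene=0, flag_alt_promoter=1,
             flag_conserved=0, flag_neuron_specific=0),
    ]
    return pd.DataFrame(rows)


def record(ps, role, p, mean_control, mean_mutant, event="ev"):
    return dict(
        probe_set_id=ps, event_id=event, role=role, mean_control=mean_control,
        mean_mutant=mean_mutant, t=0.0, p=p,
    )


class TestComputeInorm:
    def test_signal_over_gene_ratio(self):
        ps = pd.DataFrame({"s1": [4.0, 8.0]}, index=["ps.exon", "ps.skip"])
        gene = pd.DataFrame({"s1": [4.0]}, index=["g"])
        out = compute_inorm(ps, gene, toy_annotation())
        assert out.at["ps.exon", "s1"] == 1.0
        assert out.at["ps.skip", "s1"] == 2.0

    def test_nonpositive_gene_signal_excluded_with_warning(self):
        ps = pd.DataFrame({"s1": [4.0]}, index=["ps.exon"])
        gene = pd.DataFrame({"s1": [0.0]}, index=["g"])
        with pytest.warns(UserWarning):
            out = compute_inorm(ps, gene, toy_annotation())
        assert out.empty

    def test_constitutive_inorm_genotype_ratio_is_one_without_noise(self):
        config = simdata.SimConfig(
            n_genes=4, n_cassette_events=2, replicates_per_genotype=3,
            psi_by_genotype=simdata.make_psi_map(2, 1),
            noise_sd_log2=0.0, background_mean=0.0, affinity_sd_log2=0.0, seed=9,
        )
        sim = simdata.simulate_array(config)
        ps = 2.0 ** summarize_probe_sets(np.log2(sim.intensities))
        gene = gene_expression_signal(ps, sim.annotation)
        inorm = compute_inorm(ps, gene, sim.annotation)
        const = inorm.loc["gene_0000.const_0"]
        ctrl = const[sim.genotypes == "control"].mean()
        mut = const[sim.genotypes == "mutant"].mean()
        assert abs(ctrl / mut - 1.0) < 1e-6


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_closed_form_example(self):
        t, p = ttest_two_tailed([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_swapping_groups_flips_sign_only(self):
        t1, p1 = ttest_two_tailed([1, 2, 3], [4, 5, 7])
        t2, p2 = ttest_two_tailed([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, p = ttest_two_tailed([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and t < 0
        assert 0 < p <= np.finfo(float).tiny

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            ttest_two_tailed([1.0], [2.0, 3.0])

    def test_agrees_with_exhaustive_permutation_test(self):
        # 4+4 design: the 70 relabelings (35 distinct splits) give the exact
        # permutation null; Student-t P should track it closely on normal data
        rng = np.random.default_rng(12)
        diffs = []
        for _ in range(20):
            values = rng.normal(0, 1, size=8) + np.array([0.0] * 4 + [rng.uniform(0, 2)] * 4)
            t_obs, p_obs = ttest_two_tailed(values[:4], values[4:])
            stats = []
            for idx in itertools.combinations(range(8), 4):
                mask = np.zeros(8, dtype=bool)
                mask[list(idx)] = True
                t_perm, _ = ttest_two_tailed(values[mask], values[~mask])
                stats.append(abs(t_perm))
            p_perm = np.mean(np.asarray(stats) >= abs(t_obs) - 1e-12)
            diffs.append(abs(p_obs - p_perm))
        assert max(diffs) < 0.2
        assert np.mean(diffs) < 0.1


class TestFilters:
    def test_flagged_probe_sets_removed(self):
        out = apply_filters(toy_annotation())
        kept = set(out["probe_set_id"])
        assert kept == {"ps.exon", "ps.skip", "ps.up"}

    def test_unknown_role_rejected(self):
        ann = toy_annotation()
        ann.loc[0, "role"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            apply_filters(ann)


class TestCallEvents:
    def test_concordant_exon_and_skipping_votes_make_tier1(self):
        records = pd.DataFrame([
            record("ps.exon", "exon", 0.01, mean_control=1.0, mean_mutant=0.6),
            record("ps.skip", "skipping_junction", 0.02, mean_control=0.4, mean_mutant=0.9),
        ])
        calls = call_events(records, toy_annotation())
        assert calls.loc[0, "tier"] == TIER1
        assert calls.loc[0, "direction"] == "inclusion_down"
        assert calls.loc[0, "n_significant_probe_sets"] == 2

    def test_opposite_inclusion_votes_are_ambiguous(self):
        records = pd.DataFrame([
            record("ps.exon", "exon", 0.01, mean_control=1.0, mean_mutant=0.6),
            record("ps.up", "inclusion_junction_up", 0.02, mean_control=0.6, mean_mutant=1.0),
        ])
        calls = call_events(records, toy_annotation())
        assert calls.loc[0, "tier"] == NO_TIER
        assert calls.loc[0, "direction"] == "ambiguous"

    def test_single_vote_with_flags_is_tier2_candidate(self):
        records = pd.DataFrame([
            record("ps.exon", "exon", 0.01, mean_control=1.0, mean_mutant=0.6),
            record("ps.skip", "skipping_junction", 0.5, mean_control=0.5, mean_mutant=0.5),
        ])
        calls = call_events(records, toy_annotation())
        assert calls.loc[0, "tier"] == TIER2

    def test_single_vote_without_flags_is_not_called(self):
        ann = toy_annotation()
        ann["flag_conserved"] = 0
        records = pd.DataFrame([
            record("ps.exon", "exon", 0.01, mean_control=1.0, mean_mutant=0.6),
        ])
        calls = call_events(records, ann)
        assert calls.loc[0, "tier"] == NO_TIER

    def test_nonsignificant_probe_sets_do_not_veto(self):
        records = pd.DataFrame([
            record("ps.exon", "exon", 0.01, mean_control=1.0, mean_mutant=0.6),
            record("ps.skip", "skipping_junction", 0.02, mean_control=0.4, mean_mutant=0.9),
            record("ps.up", "inclusion_junction_up", 0.9, mean_control=0.6, mean_mutant=0.8),
        ])
        calls = call_events(records, toy_annotation())
        assert calls.loc[0, "tier"] == TIER1


class TestConcordance:
    def test_identical_vectors(self):
        r, _ = cross_tissue_concordance([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_exact_negation(self):
        r, _ = cross_tissue_concordance([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_hand_example(self):
        r, _ = cross_tissue_concordance([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_tissue_concordance([1, 1, 1], [1, 2, 3])


class TestMonotonicity:
    def test_mean_inorm_monotone_in_psi_without_noise(self):
        incl_means, skip_means = [], []
        for psi in (0.2, 0.4, 0.6, 0.8):
            config = simdata.SimConfig(
                n_genes=2, n_cassette_events=1, replicates_per_genotype=2,
                psi_by_genotype={"event_0000": (psi, psi)},
                noise_sd_log2=0.0, background_mean=0.0, affinity_sd_log2=0.0, seed=2,
            )
            sim = simdata.simulate_array(config)
            ps = 2.0 ** summarize_probe_sets(np.log2(sim.intensities))
            gene = gene_expression_signal(ps, sim.annotation)
            inorm = compute_inorm(ps, gene, sim.annotation)
            incl_means.append(inorm.loc["gene_0000.event_0000.exon"].mean())
            skip_means.append(inorm.loc["gene_0000.event_0000.skipping_junction"].mean())
        assert (np.diff(incl_means) > 0).all()
        assert (np.diff(skip_means) < 0).all()


class TestRecoveryBenchmark:
    def test_tier1_recall_and_precision(self, recovery_sim, recovery_result):
        metrics = recovery_result.metrics
        assert metrics["recall"] >= 0.8
        assert metrics["precision"] >= 0.9
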