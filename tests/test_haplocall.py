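import numpy as np
import pytest

from osteotrace.haplocall import (
    EmptyCohortError,
    NoEvaluablePositionsError,
    SampleGenotypes,
    call_cohort,
    call_haplogroup,
    read_genotype_csv,
    read_genotype_vcf,
    score_haplogroup,
    write_calls_csv,
)
from osteotrace.haplotree import expected_profile
from osteotrace.synthesize import CohortSpec, simulate_cohort_genotypes

from _oracles import brute_force_best_haplogroup


def perfect_sample(tree, panel, label, sample_id="s"):
    """Noise-free genotypes for one haplogroup over all panel sites."""
    reference = tree.reference_alleles()
    states = expected_profile(tree, label).states
    calls = {p: states.get(p, reference[p]) for p in panel.positions}
    return SampleGenotypes(sample_id, calls)


class TestScoreHaplogroup:
    def test_perfect_match_scores_one(self, default_tree, default_panel):
        sample = perfect_sample(default_tree, default_panel, "M39")
        assert score_haplogroup(sample, "M39", default_tree, default_panel) == 1.0

    def test_partial_match_with_extra_derived_call(self, fixture_tree):
        # M39 expects 489C and 12361T; carry only 489C plus one extra
        # derived call at R's site -> recall 1/2, precision 1/2 -> 0.5
        from osteotrace.haplotree import PanelDefinition

        panel = PanelDefinition(sites=((489, 1), (12361, 1), (16189, 1)))
        sample = SampleGenotypes("s", {489: "C", 12361: "C", 16189: "C"})
        assert score_haplogroup(sample, "M39", fixture_tree, panel) == 0.5

    def test_all_reference_sample_scores_one_against_root(
        self, default_tree, default_panel, default_reference
    ):
        sample = SampleGenotypes(
            "s", {p: default_reference[p] for p in default_panel.positions}
        )
        assert score_haplogroup(sample, "rCRS", default_tree, default_panel) == 1.0

    def test_all_missing_sample_is_an_error(self, default_tree, default_panel):
        sample = SampleGenotypes("s", {p: None for p in default_panel.positions})
        with pytest.raises(NoEvaluablePositionsError):
            score_haplogroup(sample, "M39", default_tree, default_panel)

    def test_adding_a_matching_derived_call_never_decreases_score(
        self, default_tree, default_panel, default_reference
    ):
        states = expected_profile(default_tree, "R32").states
        derived_sites = [p for p in default_panel.positions
                         if states.get(p, default_reference[p]) != default_reference[p]]
        calls = {p: default_reference[p] for p in default_panel.positions}
        previous = score_haplogroup(
            SampleGenotypes("s", dict(calls)), "R32", default_tree, default_panel
        )
        for site in derived_sites:
            calls[site] = states[site]
            current = score_haplogroup(
                SampleGenotypes("s", dict(calls)), "R32", default_tree, default_panel
            )
            assert current >= previous
            previous = current


class TestCallHaplogroup:
    @pytest.mark.parametrize("label", ["R32", "M39", "HV0e", "U2a", "K", "N5"])
    def test_noise_free_generative_recovery(self, default_tree, default_panel, label):
        call = call_haplogroup(
            perfect_sample(default_tree, default_panel, label),
            default_tree, default_panel,
        )
        assert call.best == label
        assert call.score == 1.0

    def test_equals_brute_force_oracle_on_noisy_cohort(
        self, default_tree, default_panel, default_reference
    ):
        spec = CohortSpec(n_samples=40, missing_rate=0.2, error_rate=0.05, seed=11)
        samples, _ = simulate_cohort_genotypes(spec, default_tree, default_panel)
        for sample in samples:
            call = call_haplogroup(sample, default_tree, default_panel)
            oracle_label, oracle_score = brute_force_best_haplogroup(
                sample.calls, default_tree.root,
                default_panel.positions, default_reference,
            )
            assert call.best == oracle_label
            assert call.score == pytest.approx(oracle_score, abs=1e-12)

    def test_parent_child_tie_resolves_to_deeper_child(self, fixture_tree):
        # All of M39's defining sites missing: M and M39 both score 1.0;
        # the depth tie-break must return the more specific M39.
        from osteotrace.haplotree import PanelDefinition

        panel = PanelDefinition(sites=((489, 1), (12361, 1)))
        sample = SampleGenotypes("s", {489: "C", 12361: None})
        call = call_haplogroup(sample, fixture_tree, panel)
        assert call.best == "M39"
        assert ("M", 1.0) in call.alternatives

    def test_alternatives_are_ranked_below_best(self, default_tree, default_panel):
        call = call_haplogroup(
            perfect_sample(default_tree, default_panel, "U2a"),
            default_tree, default_panel,
        )
        assert all(call.score >= s for _, s in call.alternatives)
        assert call.n_matched <= min(call.n_expected, call.n_observed_derived) or (
            call.n_expected == 0
        )


class TestCallCohort:
    def test_counts_to_frequencies(self, default_tree, default_panel):
        # 50 samples with fixed haplogroup counts mirroring a small cohort
        composition = {"M39": 12, "R32": 7, "HV0e": 3, "M2": 20, "M3": 3, "N5": 5}
        samples = [
            perfect_sample(default_tree, default_panel, lab, f"{lab}-{i}")
            for lab, count in composition.items()
            for i in range(count)
        ]
        _, freqs, macro = call_cohort(samples, default_tree, default_panel)
        assert freqs["M39"] == pytest.approx(0.24)
        assert freqs["R32"] == pytest.approx(0.14)
        assert freqs["HV0e"] == pytest.approx(0.06)
        assert macro["M"] == pytest.approx(0.70)
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert sum(macro.values()) == pytest.approx(1.0)

    def test_single_sample_has_frequency_one(self, default_tree, default_panel):
        _, freqs, _ = call_cohort(
            [perfect_sample(default_tree, default_panel, "J")],
            default_tree, default_panel,
        )
        assert freqs == {"J": 1.0}

    def test_empty_cohort_rejected(self, default_tree, default_panel):
        with pytest.raises(EmptyCohortError):
            call_cohort([], default_tree, default_panel)


class TestGenotypeIO:
    def test_csv_round_trip_with_missing_tokens(self, tmp_path):
        path = tmp_path / "geno.csv"
        path.write_text(
            "sample_id,position,allele\n"
            "s1,489,C\n"
            "s1,12361,\n"
            "s1,8701,N\n"
            "s2,489,T\n"
        )
        samples = {s.sample_id: s for s in read_genotype_csv(str(path))}
        assert samples["s1"].calls == {489: "C", 12361: None, 8701: None}
        assert samples["s2"].calls == {489: "T"}

    def test_invalid_allele_rejected(self, tmp_path):
        path = tmp_path / "geno.csv"
        path.write_text("sample_id,position,allele\ns1,489,Z\n")
        with pytest.raises(ValueError, match="allele"):
            read_genotype_csv(str(path))

    def test_vcf_diploid_majority_collapse(self, tmp_path, default_panel):
        positions = sorted(default_panel.positions)[:2]
        vcf = tmp_path / "calls.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chrM,length=16569>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            f"chrM\t{positions[0]}\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\n"
            f"chrM\t{positions[1]}\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t1/1\n"
            "chrM\t1\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\n"
        )
        samples = {s.sample_id: s for s in read_genotype_vcf(str(vcf), default_panel)}
        assert samples["s1"].calls[positions[0]] == "G"
        # heterozygous tie collapses to REF
        assert samples["s2"].calls[positions[0]] == "A"
        assert samples["s1"].calls[positions[1]] is None
        # off-panel site ignored
        assert 1 not in samples["s1"].calls

    def test_calls_csv_written_with_documented_columns(
        self, tmp_path, default_tree, default_panel
    ):
        calls, _, _ = call_cohort(
            [perfect_sample(default_tree, default_panel, "M39")],
            default_tree, default_panel,
        )
        out = tmp_path / "calls.csv"
        write_calls_csv(calls, str(out))
        header, row = out.read_text().strip().splitlines()
        assert header == "sample_id,haplogroup,score,n_expected,n_matched"
        assert row.split(",")[1] == "M39"
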