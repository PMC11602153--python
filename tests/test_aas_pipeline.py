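"""Mapping, tallies, stop ratios, D-site calls and condition comparisons."""

import numpy as np
import pandas as pd
import pytest

from duskit import aas
from duskit.core import (
    DSiteAnnotation,
    ModificationProfile,
    ReferenceBundle,
    TRNAReference,
    effective_occupancy,
    strain_config,
)
from duskit.simulate import AASLibraryParams, simulate_aas_library

from conftest import score_library, zero_profile


# ---------------------------------------------------------------------------
# independent brute-force mapping oracle
# ---------------------------------------------------------------------------


def brute_force_map(seq, bundle, max_mismatch=2):
    """All-offsets Hamming scan written independently of the mapper."""
    seq = seq.upper().replace("T", "U")
    hits = []
    for ref in bundle.references:
        for offset in range(len(ref.sequence) - len(seq) + 1):
            window = ref.sequence[offset : offset + len(seq)]
            mm = sum(1 for a, b in zip(seq, window) if a != b or a == "N")
            hits.append((mm, ref.id, offset + 1))
    if not hits:
        return None
    best = min(h[0] for h in hits)
    best_hits = [h for h in hits if h[0] == best]
    if best > max_mismatch:
        return None
    if len(best_hits) > 1:
        return "multimapped"
    _, trna_id, start = best_hits[0]
    return (trna_id, start, best)


class TestMapReads:
    def test_exact_substring_maps_at_its_offset(self, bundle5):
        ref = bundle5.references[0]
        query = ref.sequence[20:50]  # 30-mer starting at 1-based position 21
        aligned, report = aas.map_reads([("r1", query)], bundle5)
        assert report.mapped == 1
        assert aligned[0].trna_id == ref.id
        assert aligned[0].start_index == 21
        assert aligned[0].end_index == 50
        assert aligned[0].mismatches == 0

    def test_read_shared_by_two_references_is_discarded(self):
        stem = "ACGUACGGUCAGUCAGGCAUCGAUCGGAUC"
        r1 = TRNAReference("t1", stem + "AAAAAAAAAAAAAAAAAAAA")
        r2 = TRNAReference("t2", "GGGGGGGGGGGGGGGGGGGG" + stem)
        bundle = ReferenceBundle(references=[r1, r2], annotations=[])
        aligned, report = aas.map_reads([("r1", stem)], bundle)
        assert report.multimapped == 1 and aligned == []

    def test_random_read_is_unmapped(self, bundle5):
        rng = np.random.default_rng(123)
        query = "".join(rng.choice(list("ACGU"), size=30))
        assert brute_force_map(query, bundle5) is None  # oracle agrees it cannot place
        _, report = aas.map_reads([("r1", query)], bundle5)
        assert report.unmapped == 1

    def test_read_longer_than_references_is_unmapped(self, bundle5):
        _, report = aas.map_reads([("r1", "A" * 200)], bundle5)
        assert report.unmapped == 1

    def test_mapper_equals_brute_force_oracle(self, bundle5):
        """On <=200 reads the mapper is identical to the exhaustive oracle,
        including tie discards and mismatch tolerance."""
        rng = np.random.default_rng(7)
        reads = []
        params = AASLibraryParams(molecules_per_trna=60, seed=5)
        sim_reads, _ = simulate_aas_library(bundle5, bundle5.baseline_profile(), params)
        for read in sim_reads[:120]:
            reads.append((read.read_id, read.sequence))
        # mutated and random reads exercise the mismatch and unmapped paths
        for i in range(60):
            ref = bundle5.references[rng.integers(len(bundle5.references))]
            start = int(rng.integers(0, len(ref.sequence) - 30))
            seq = list(ref.sequence[start : start + 30])
            for _ in range(rng.integers(0, 4)):
                pos = int(rng.integers(len(seq)))
                seq[pos] = str(rng.choice(list("ACGU")))
            reads.append((f"mut{i}", "".join(seq)))
        for i in range(20):
            reads.append((f"rand{i}", "".join(rng.choice(list("ACGU"), size=30))))
        assert len(reads) <= 200
        aligned, _ = aas.map_reads(reads, bundle5)
        by_id = {a.read_id: a for a in aligned}
        for read_id, seq in reads:
            expected = brute_force_map(seq, bundle5)
            if expected is None or expected == "multimapped":
                assert read_id not in by_id
            else:
                got = by_id[read_id]
                assert (got.trna_id, got.start_index, got.mismatches) == expected


class TestTallyAndStopRatio:
    def _toy_bundle(self):
        return ReferenceBundle(
            references=[TRNAReference("t1", "ACGUACGUAC")], annotations=[]
        )

    def test_single_read_counts(self):
        bundle = self._toy_bundle()
        aligned = [aas.AlignedRead("r1", "t1", 3, 7, 0)]
        counts = aas.tally(aligned, bundle)
        assert counts.get_n5("t1", 3) == 1
        assert [counts.get_cov("t1", p) for p in range(1, 11)] == [0, 0, 1, 1, 1, 1, 1, 0, 0, 0]

    def test_counts_are_additive(self):
        bundle = self._toy_bundle()
        aligned = [aas.AlignedRead("r1", "t1", 3, 7, 0)] * 2
        counts = aas.tally(aligned, bundle)
        assert counts.get_n5("t1", 3) == 2 and counts.get_cov("t1", 5) == 2

    def test_empty_alignment_gives_zero_counts(self):
        counts = aas.tally([], self._toy_bundle())
        assert counts.n5["t1"].sum() == 0 and counts.cov["t1"].sum() == 0

    def test_coverage_mass_equals_read_lengths(self, bundle5):
        params = AASLibraryParams(molecules_per_trna=100, seed=6)
        reads, _ = simulate_aas_library(bundle5, bundle5.baseline_profile(), params)
        aligned, _ = aas.map_reads([(r.read_id, r.sequence) for r in reads], bundle5)
        counts = aas.tally(aligned, bundle5)
        total_cov = sum(int(c.sum()) for c in counts.cov.values())
        assert total_cov == sum(a.end_index - a.start_index + 1 for a in aligned)

    @pytest.mark.parametrize(
        "n5,cov,expected,flagged",
        [(25, 100, 0.25, False), (0, 50, 0.0, False), (4, 4, 0.0, True)],
    )
    def test_stop_ratio_arithmetic_and_min_cov(self, n5, cov, expected, flagged):
        counts = aas.SiteCounts(
            n5={"t1": np.array([n5] + [0] * 9)},
            cov={"t1": np.array([cov] + [0] * 9)},
        )
        profile = aas.stop_ratio(counts, min_cov=10)
        assert profile.get_ratio("t1", 1) == pytest.approx(expected)
        assert profile.is_flagged("t1", 1) is flagged

    def test_ratios_bounded_and_n5_within_coverage(self, bundle5):
        params = AASLibraryParams(molecules_per_trna=300, seed=8)
        reads, _ = simulate_aas_library(bundle5, bundle5.baseline_profile(), params)
        profile, _ = score_library(reads, bundle5)
        for trna_id in profile.ratio:
            assert ((profile.ratio[trna_id] >= 0) & (profile.ratio[trna_id] <= 1)).all()
            assert (profile.n5[trna_id] <= np.maximum(profile.cov[trna_id], 1)).all()


class TestDSiteCalls:
    def test_wild_type_calls_all_annotated_positions(self, bundle20, baseline20):
        reads, _ = simulate_aas_library(bundle20, baseline20, AASLibraryParams(seed=11))
        profile, _ = score_library(reads, bundle20)
        calls = aas.infer_d_positions(profile, bundle20, mode="annotated")
        assert {(c.trna_id, c.d_index) for c in calls} == {
            (a.trna_id, a.seq_index) for a in bundle20.annotations
        }
        assert {c.canonical_label for c in calls} == {"16", "17", "20", "20a"}

    def test_dusA_knockout_calls_only_16_and_17(self, bundle20, baseline20):
        """The DusA knockout retains signals only at 16 and 17, silencing
        every 20/20a site while leaving the other calls intact."""
        profile_ko = effective_occupancy(baseline20, strain_config("dusA"))
        reads, _ = simulate_aas_library(bundle20, profile_ko, AASLibraryParams(seed=12))
        stop, _ = score_library(reads, bundle20)
        calls = aas.infer_d_positions(stop, bundle20, mode="annotated")
        assert {c.canonical_label for c in calls} == {"16", "17"}
        expected = {
            (a.trna_id, a.seq_index)
            for a in bundle20.annotations
            if a.canonical_label in ("16", "17")
        }
        assert {(c.trna_id, c.d_index) for c in calls} == expected

    def test_all_zero_profile_yields_no_calls(self, bundle20):
        counts = aas.SiteCounts(
            n5={r.id: np.zeros(len(r), dtype=int) for r in bundle20.references},
            cov={r.id: np.full(len(r), 100) for r in bundle20.references},
        )
        profile = aas.stop_ratio(counts)
        assert aas.infer_d_positions(profile, bundle20, mode="annotated") == []
        assert aas.infer_d_positions(profile, bundle20, mode="discovery") == []

    def test_discovery_mode_requires_uridine_at_back_shifted_index(self, bundle5):
        reads, _ = simulate_aas_library(
            bundle5, bundle5.baseline_profile(), AASLibraryParams(seed=13)
        )
        profile, _ = score_library(reads, bundle5)
        for call in aas.infer_d_positions(profile, bundle5, mode="discovery"):
            ref = bundle5.reference(call.trna_id)
            assert ref.sequence[call.d_index - 1] == "U"

    def test_stop_ratio_tracks_molecule_break_fraction(self):
        """With full terminal ligation and no background, the stop ratio at
        N+1 estimates the molecule-level break fraction p x c."""
        from test_synthetic_data import _single_site_bundle, _profile

        n, p, c = 10_000, 0.6, 0.5
        bundle = _single_site_bundle(site_index=20)
        params = AASLibraryParams(
            molecules_per_trna=n, alk_cleavage_prob=c,
            background_break_rate=0.0, terminal_ligatable_rate=1.0, seed=21,
        )
        reads, _ = simulate_aas_library(bundle, _profile(bundle, p), params)
        profile, _ = score_library(reads, bundle)
        se = np.sqrt(p * c * (1 - p * c) / n)
        assert abs(profile.get_ratio("tRNA-single", 21) - p * c) <= 3 * se


class TestComparisons:
    def _profile_from_ratio(self, ratios, cov=100):
        n = len(ratios)
        counts = aas.SiteCounts(
            n5={"t1": np.array([int(r * cov) for r in ratios])},
            cov={"t1": np.full(n, cov)},
        )
        return aas.stop_ratio(counts)

    def test_percent_of_control_arithmetic(self):
        treated = self._profile_from_ratio([0.2, 0.1])
        control = self._profile_from_ratio([0.4, 0.1])
        table = aas.compare_conditions(treated, control)
        assert table.loc[table["position"] == 1, "percent_of_control"].iloc[0] == pytest.approx(50.0)
        assert table.loc[table["position"] == 2, "percent_of_control"].iloc[0] == pytest.approx(100.0)

    def test_identical_profiles_give_100_everywhere_defined(self):
        profile = self._profile_from_ratio([0.3, 0.2, 0.5])
        table = aas.compare_conditions(profile, profile)
        defined = table[table["status"] == "ok"]
        assert len(defined) > 0
        assert np.allclose(defined["percent_of_control"], 100.0)

    def test_zero_control_is_undefined_not_infinite(self):
        treated = self._profile_from_ratio([0.2])
        control = self._profile_from_ratio([0.0])
        table = aas.compare_conditions(treated, control)
        row = table.iloc[0]
        assert row["status"] == "undefined_control" and np.isnan(row["percent_of_control"])

    def test_enzyme_summary_counts_decreases(self, bundle5):
        rows = []
        for ann in bundle5.annotations:
            rows.append({
                "trna_id": ann.trna_id, "position": ann.seq_index + 1,
                "d_index": ann.seq_index, "ratio_treated": 0.1, "ratio_control": 0.2,
                "percent_of_control": 60.0 if ann.enzyme == "DusC" else 110.0,
                "status": "ok",
            })
        summary = aas.enzyme_level_summary(pd.DataFrame(rows), bundle5.annotations)
        dusc = summary[summary["enzyme"] == "DusC"].iloc[0]
        assert dusc["fraction_decreased"] == 1.0
        assert dusc["mean_percent_of_control"] == pytest.approx(60.0)
        dusa = summary[summary["enzyme"] == "DusA"]
        if len(dusa):
            assert dusa.iloc[0]["fraction_decreased"] == 0.0

    def test_empty_comparison_gives_empty_summary(self, bundle5):
        summary = aas.enzyme_level_summary(pd.DataFrame(), bundle5.annotations)
        assert summary.empty

    def test_paraquat_summary_orders_enzymes_by_sensitivity(self, bundle20, baseline20):
        """Aerobic paraquat with the default retention factors ranks the mean
        percent-of-control DusA > DusB > DusC."""
        treated_profile = effective_occupancy(
            baseline20, strain_config("WT", paraquat_mM=0.3, aerobic=True)
        )
        reads_t, _ = simulate_aas_library(bundle20, treated_profile, AASLibraryParams(seed=31))
        reads_c, _ = simulate_aas_library(bundle20, baseline20, AASLibraryParams(seed=32))
        prof_t, _ = score_library(reads_t, bundle20)
        prof_c, _ = score_library(reads_c, bundle20)
        summary = aas.enzyme_level_summary(
            aas.compare_conditions(prof_t, prof_c), bundle20.annotations
        )
        means = dict(zip(summary["enzyme"], summary["mean_percent_of_control"]))
        assert means["DusA"] > means["DusB"] > means["DusC"]
        assert summary.set_index("enzyme").loc["DusC", "fraction_decreased"] == 1.0

    def test_pipeline_is_deterministic_downstream_of_reads(self, bundle5):
        reads, _ = simulate_aas_library(
            bundle5, bundle5.baseline_profile(), AASLibraryParams(molecules_per_trna=200, seed=14)
        )
        p1, _ = score_library(reads, bundle5)
        p2, _ = score_library(reads, bundle5)
        for trna_id in p1.ratio:
            assert (p1.ratio[trna_id] == p2.ratio[trna_id]).all()
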