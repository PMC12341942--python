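import numpy as np
import pandas as pd
import pytest

from phasebench import (
    DiploidAncestryCalls,
    PhasedAncestryCalls,
    collapse_to_diploid,
    oracle_lai,
    pearson_r,
    read_anc_vcf,
    read_calls_tsv,
    read_msp,
    write_calls_tsv,
    write_msp,
)
from phasebench.calls import write_anc_vcf


def _calls_from_tracks(tracks, chrom="1"):
    tracks = np.asarray(tracks, dtype=np.int8)
    m = tracks.shape[2]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, m + 1) * 1000, "id": ".", "ref": "A", "alt": "G"}
    )
    return PhasedAncestryCalls(markers, [f"s{i}" for i in range(tracks.shape[0])], tracks)


class TestCollapse:
    @pytest.mark.parametrize(
        "h0,h1,expected", [(1, 1, 2), (0, 1, 1), (1, 0, 1), (0, 0, 0)]
    )
    def test_dosage_definition(self, h0, h1, expected):
        calls = _calls_from_tracks([[[h0], [h1]]])
        assert collapse_to_diploid(calls).dosage[0, 0] == expected

    def test_invariant_to_track_relabeling(self):
        rng = np.random.default_rng(0)
        tracks = rng.integers(0, 2, size=(4, 2, 50))
        calls = _calls_from_tracks(tracks)
        swapped = _calls_from_tracks(tracks[:, ::-1, :])
        np.testing.assert_array_equal(
            collapse_to_diploid(calls).dosage, collapse_to_diploid(swapped).dosage
        )

    def test_dosage_histogram_matches_direct_count(self):
        rng = np.random.default_rng(1)
        tracks = rng.integers(0, 2, size=(3, 2, 200))
        dosage = collapse_to_diploid(_calls_from_tracks(tracks)).dosage
        brute = np.array([[int(tracks[i, 0, j] == 1) + int(tracks[i, 1, j] == 1)
                           for j in range(200)] for i in range(3)])
        np.testing.assert_array_equal(dosage, brute)
        np.testing.assert_array_equal(
            np.bincount(dosage.ravel(), minlength=3), np.bincount(brute.ravel(), minlength=3)
        )


class TestOracleLai:
    def test_perfect_mode_matches_truth_exactly(self, small_map, cohort):
        acc = pearson_r(
            collapse_to_diploid(cohort["truth_calls"]),
            collapse_to_diploid(cohort["truth_calls"]),
        )
        assert acc.r == pytest.approx(1.0)

    def test_switch_only_corruption_preserves_dosage(self, small_map, small_panels, cohort):
        corrupted = oracle_lai(
            cohort["pairs"], small_map, small_panels[0].markers,
            mode="corrupted", switch_rate=0.05, seed=7,
        )
        np.testing.assert_array_equal(
            collapse_to_diploid(corrupted).dosage,
            collapse_to_diploid(cohort["truth_calls"]).dosage,
        )

    def test_heavy_miscalls_destroy_correlation(self, small_map, small_panels, cohort):
        corrupted = oracle_lai(
            cohort["pairs"], small_map, small_panels[0].markers,
            mode="corrupted", miscall_prob=0.5, seed=8,
        )
        acc = pearson_r(
            collapse_to_diploid(corrupted), collapse_to_diploid(cohort["truth_calls"])
        )
        assert abs(acc.r) < 0.25

    def test_rejects_negative_corruption_params(self, small_map, small_panels, cohort):
        with pytest.raises(ValueError, match="nonnegative"):
            oracle_lai(
                cohort["pairs"], small_map, small_panels[0].markers,
                mode="corrupted", jitter_cm=-1.0,
            )


class TestMsp:
    def test_single_window_expands_to_constant_tracks(self, tmp_path):
        path = tmp_path / "one.msp.tsv"
        path.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t1\t99999\t0.0\t1.0\t5\t1\t1\n"
        )
        markers = pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 3000]})
        calls = read_msp(path, markers)
        assert (calls.tracks == 1).all()
        assert calls.codes == {0: "AFR", 1: "EUR"}

    def test_adjacent_windows_half_open_boundary(self, tmp_path):
        path = tmp_path / "two.msp.tsv"
        path.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t1\t2000\t0.0\t0.5\t1\t0\t0\n"
            "1\t2000\t5000\t0.5\t1.0\t2\t1\t1\n"
        )
        markers = pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 3000]})
        calls = read_msp(path, markers)
        np.testing.assert_array_equal(calls.tracks[0, 0], [0, 1, 1])

    def test_round_trip_identity(self, tmp_path, small_map, cohort):
        path = tmp_path / "rt.msp.tsv"
        write_msp(cohort["truth_calls"], path, small_map)
        back = read_msp(path, cohort["truth_calls"].markers)
        np.testing.assert_array_equal(back.tracks, cohort["truth_calls"].tracks)
        assert back.samples == cohort["truth_calls"].samples

    def test_uncovered_marker_is_an_error(self, tmp_path):
        path = tmp_path / "gap.msp.tsv"
        path.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t1\t1500\t0.0\t0.5\t1\t0\t0\n"
        )
        markers = pd.DataFrame({"chrom": "1", "pos": [1000, 2000]})
        with pytest.raises(ValueError, match="not covered"):
            read_msp(path, markers)

    def test_overlapping_windows_rejected(self, tmp_path):
        path = tmp_path / "overlap.msp.tsv"
        path.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t1\t3000\t0.0\t0.5\t2\t0\t0\n"
            "1\t2000\t5000\t0.5\t1.0\t2\t1\t1\n"
        )
        markers = pd.DataFrame({"chrom": "1", "pos": [1000, 2000, 3000]})
        with pytest.raises(ValueError, match="overlap"):
            read_msp(path, markers)

    def test_unknown_ancestry_code_rejected(self, tmp_path):
        path = tmp_path / "badcode.msp.tsv"
        path.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t1\t9000\t0.0\t0.5\t2\t0\t7\n"
        )
        markers = pd.DataFrame({"chrom": "1", "pos": [1000]})
        with pytest.raises(ValueError, match="unknown ancestry code"):
            read_msp(path, markers)


class TestAncVcf:
    def test_round_trip_with_default_fields(self, tmp_path, cohort):
        path = tmp_path / "anc.vcf"
        write_anc_vcf(cohort["truth_calls"], path, genotypes=cohort["genotypes"])
        back = read_anc_vcf(path)
        np.testing.assert_array_equal(back.tracks, cohort["truth_calls"].tracks)

    def test_configurable_field_names(self, tmp_path, cohort):
        path = tmp_path / "anc2.vcf"
        write_anc_vcf(cohort["truth_calls"], path, fields=("LA0", "LA1"))
        back = read_anc_vcf(path, fields=("LA0", "LA1"))
        np.testing.assert_array_equal(back.tracks, cohort["truth_calls"].tracks)
        with pytest.raises(ValueError, match="AN1"):
            read_anc_vcf(path)  # default field names absent


def test_calls_tsv_round_trip(tmp_path, cohort):
    path = tmp_path / "calls.tsv"
    write_calls_tsv(cohort["truth_calls"], path)
    back = read_calls_tsv(path)
    np.testing.assert_array_equal(back.tracks, cohort["truth_calls"].tracks)
    assert back.codes == cohort["truth_calls"].codes


def test_diploid_container_validation():
    markers = pd.DataFrame({"chrom": ["1"], "pos": [1]})
    with pytest.raises(ValueError, match="exactly one"):
        DiploidAncestryCalls(markers, ["s"], dosage=None, posterior=None)
    with pytest.raises(ValueError, match="sum to 1"):
        DiploidAncestryCalls(markers, ["s"], posterior=np.array([[[0.5, 0.1, 0.1]]]))
    with pytest.raises(ValueError, match="{0, 1, 2}"):
        DiploidAncestryCalls(markers, ["s"], dosage=np.array([[3]]))
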