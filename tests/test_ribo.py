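import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribotail import (
    assign_a_site,
    assign_a_sites,
    call_differential_te,
    codon_occupancy,
    compute_te,
    filter_rpfs,
    metagene_profile,
)
from ribotail.io import CountTable, RpfAlignment, design_from_library_ids
from ribotail.ribo import rpf_cds_counts

from conftest import make_transcript


@pytest.fixture
def transcript():
    # 20 nt UTRs, 30-codon CDS
    return make_transcript("t1", ["ATG"] + ["GCT"] * 28 + ["TAA"], utr5=20, utr3=20)


def aln(fp, length=30, unique=True, rid="r", tid="t1"):
    return RpfAlignment(rid, tid, fp, length, unique)


class TestFilterRpfs:
    def test_length_window_is_28_to_31(self, transcript):
        reads = [aln(20 - 15, L, rid=f"r{L}") for L in (27, 28, 31, 32)]
        result = filter_rpfs(reads, [transcript])
        assert set(result.alignments["read_id"]) == {"r28", "r31"}
        assert result.report["bad_length"] == 2

    def test_a_site_at_cds_start_boundary_retained(self, transcript):
        result = filter_rpfs([aln(transcript.cds_start - 15)], [transcript])
        assert result.report["kept"] == 1

    def test_off_frame_a_site_rejected(self, transcript):
        result = filter_rpfs([aln(transcript.cds_start - 15 + 1)], [transcript])
        assert result.report == pytest.approx({**result.report, "out_of_frame": 1, "kept": 0})

    def test_multimappers_rejected(self, transcript):
        result = filter_rpfs([aln(5, unique=False)], [transcript])
        assert result.report["not_unique"] == 1

    def test_unknown_transcript_counted_not_fatal(self, transcript):
        result = filter_rpfs([aln(5, tid="ghost"), aln(transcript.cds_start - 15)], [transcript])
        assert result.report["unknown_transcript"] == 1
        assert result.report["kept"] == 1

    def test_a_site_past_cds_end_rejected(self, transcript):
        fp = transcript.cds_end - 15  # A site exactly at cds_end (exclusive)
        result = filter_rpfs([aln(fp)], [transcript])
        assert result.report["a_site_outside_cds"] == 1

    def test_filter_is_idempotent(self, transcript):
        reads = [aln(fp, L, u, rid=f"r{fp}.{L}.{u}")
                 for fp in range(0, 40) for L in (27, 30) for u in (True, False)]
        once = filter_rpfs(reads, [transcript])
        twice = filter_rpfs(once.alignments, [transcript])
        pd.testing.assert_frame_equal(once.alignments, twice.alignments)
        assert twice.report["kept"] == len(twice.alignments) == once.report["kept"]


class TestAssignASite:
    def test_five_prime_at_cds_start_decodes_codon_five(self, transcript):
        a = assign_a_site(aln(transcript.cds_start), transcript)
        assert a.codon_index == 5

    def test_offset_thirty_decodes_codon_fifteen(self, transcript):
        a = assign_a_site(aln(transcript.cds_start + 30), transcript)
        assert a.codon_index == 15

    def test_last_codon_valid_and_flagged_near_stop(self, transcript):
        fp = transcript.cds_start + 3 * (transcript.n_codons - 1) - 15
        a = assign_a_site(aln(fp), transcript)
        assert a.codon_index == transcript.n_codons - 1
        assert a.codon == "TAA"
        assert a.near_stop

    def test_contract_violation_raises(self, transcript):
        with pytest.raises(ValueError, match="not in frame"):
            assign_a_site(aln(transcript.cds_start + 1), transcript)

    def test_vectorised_assignment_matches_scalar(self, transcript):
        reads = [aln(transcript.cds_start - 15 + 3 * i, rid=f"r{i}")
                 for i in range(transcript.n_codons)]
        df = assign_a_sites(filter_rpfs(reads, [transcript]).alignments, [transcript])
        for row in df.itertuples(index=False):
            scalar = assign_a_site(aln(int(row.codon_index * 3 + transcript.cds_start - 15)),
                                   transcript)
            assert (row.codon_index, row.codon, row.near_stop) == (
                scalar.codon_index, scalar.codon, scalar.near_stop)


def _occupancy_oracle(assignments, transcripts):
    """Brute-force positional arithmetic, independent of the library code."""
    from ribotail.io import SENSE_CODONS

    num, den, raw = {}, {}, {}
    for t in transcripts:
        sub = assignments[assignments["transcript_id"] == t.transcript_id]
        counts = [0] * t.n_codons
        for i in sub["codon_index"]:
            counts[i] += 1
        for i, evt in enumerate(counts):
            if evt == 0:
                continue
            codon = t.codons()[i]
            if codon not in SENSE_CODONS:
                continue  # stop codons stay out of the 61-entry table
            raw[codon] = raw.get(codon, 0) + evt
            if i > t.n_codons - 4:
                continue
            basal = (counts[i + 1] + counts[i + 2] + counts[i + 3]) / 3
            if basal == 0:
                continue
            num[codon] = num.get(codon, 0.0) + evt * (evt / basal)
            den[codon] = den.get(codon, 0.0) + evt
    return {c: num[c] / den[c] for c in num}, raw


class TestCodonOccupancy:
    def test_uniform_coverage_self_normalises_to_one(self):
        transcripts = [
            make_transcript("t1", ["ATG"] + ["GCT", "GAA", "TTT"] * 9 + ["TAA"]),
            make_transcript("t2", ["ATG"] + ["CCC", "AAA"] * 10 + ["TGA"]),
        ]
        rows = []
        for t in transcripts:
            for i in range(t.n_codons):
                rows.append((f"{t.transcript_id}:{i}", t.transcript_id, i, t.codons()[i], False))
        assignments = pd.DataFrame(
            rows, columns=["read_id", "transcript_id", "codon_index", "codon", "near_stop"]
        )
        occ = codon_occupancy(assignments, transcripts)
        observed = occ["occupancy"].dropna()
        assert len(observed) > 0
        assert np.allclose(observed, 1.0, atol=1e-12)

    def test_doubled_a_site_density_doubles_occupancy(self):
        # GAA A sites carry twice the reads of their downstream codons
        codons = ["ATG"] + ["GCT", "GAA", "TTT", "CCC", "AAA"] * 6 + ["TAA"]
        t = make_transcript("t1", codons)
        rows = []
        for i, c in enumerate(t.codons()):
            n = 2 if c == "GAA" else 1
            rows += [(f"r{i}.{j}", "t1", i, c, False) for j in range(n)]
        assignments = pd.DataFrame(
            rows, columns=["read_id", "transcript_id", "codon_index", "codon", "near_stop"]
        )
        occ = codon_occupancy(assignments, [t])
        assert occ.loc["GAA", "occupancy"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_random_fixture(self, small_experiment):
        tidx = small_experiment["tidx"]
        transcripts = small_experiment["transcripts"][:3]
        filtered = filter_rpfs(small_experiment["rpf"]["rpf_CTRL_rep1"], tidx)
        asites = assign_a_sites(filtered.alignments, tidx)
        asites = asites[asites["transcript_id"].isin([t.transcript_id for t in transcripts])]
        occ = codon_occupancy(asites, transcripts)
        oracle, raw = _occupancy_oracle(asites, transcripts)
        for codon, value in oracle.items():
            assert occ.loc[codon, "occupancy"] == pytest.approx(value, abs=1e-12)
        for codon, value in raw.items():
            assert occ.loc[codon, "raw_count"] == value

    def test_near_stop_events_excluded_and_counted(self):
        t = make_transcript("t1", ["ATG"] + ["GCT"] * 8 + ["TAA"])
        near = t.n_codons - 2  # fewer than 3 codons downstream
        assignments = pd.DataFrame(
            {
                "read_id": ["r1", "r2"],
                "transcript_id": ["t1", "t1"],
                "codon_index": [2, near],
                "codon": [t.codons()[2], t.codons()[near]],
                "near_stop": [False, True],
            }
        )
        occ = codon_occupancy(assignments, [t])
        assert occ.attrs["n_excluded_near_stop"] == 1
        assert occ.loc["GCT", "raw_count"] == 2  # raw keeps both events
        # r1's basal window (codons 3-5) holds no reads -> zero basal
        assert occ.attrs["n_excluded_zero_basal"] == 1
        assert np.isnan(occ.loc["GCT", "occupancy"])  # no eligible events


class TestMetagene:
    def test_uniform_coverage_gives_flat_fiftieths(self):
        t = make_transcript("t1", ["ATG"] + ["GCT"] * 98 + ["TAA"])  # 100 codons
        assignments = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(100)],
                "transcript_id": "t1",
                "codon_index": np.arange(100),
            }
        )
        profile = metagene_profile(assignments, [t], {"t1"}, min_rpf=32)
        assert np.allclose(profile.values, 0.02, atol=1e-12)
        assert profile.n_genes == 1

    def test_all_reads_in_first_codon(self):
        t = make_transcript("t1", ["ATG"] + ["GCT"] * 58 + ["TAA"])
        assignments = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(40)], "transcript_id": "t1", "codon_index": 0}
        )
        profile = metagene_profile(assignments, [t], {"t1"})
        assert profile.values[0] == 1.0
        assert profile.values[1:].sum() == 0.0

    def test_profile_is_mean_of_unit_sum_gene_profiles(self, small_experiment):
        tidx = small_experiment["tidx"]
        filtered = filter_rpfs(small_experiment["rpf"]["rpf_KO_rep1"], tidx)
        asites = assign_a_sites(filtered.alignments, tidx)
        genes = set(asites["transcript_id"].value_counts().head(20).index)
        profile = metagene_profile(asites, tidx, genes, min_rpf=32)
        assert profile.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_short_genes_flagged_not_dropped(self):
        t = make_transcript("t1", ["ATG"] + ["GCT"] * 28 + ["TAA"])  # 30 codons < 50 bins
        assignments = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(64)], "transcript_id": "t1",
             "codon_index": np.tile(np.arange(16), 4)}
        )
        profile = metagene_profile(assignments, [t], {"t1"})
        assert profile.n_short_genes == 1

    def test_empty_set_after_filtering_is_an_error(self):
        t = make_transcript("t1", ["ATG"] + ["GCT"] * 58 + ["TAA"])
        assignments = pd.DataFrame(
            {"read_id": ["r0"], "transcript_id": "t1", "codon_index": [0]}
        )
        with pytest.raises(ValueError, match="metagene"):
            metagene_profile(assignments, [t], {"t1"}, min_rpf=32)


def _counts(**columns):
    genes = [f"g{i}" for i in range(len(next(iter(columns.values()))))]
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="transcript_id"))
    return CountTable(counts=counts, design=design_from_library_ids(counts.columns))


class TestComputeTe:
    def test_te_is_rpf_cpm_over_mrna_cpm(self):
        table = _counts(
            rpf_KO_rep1=[1000, 1000], rpf_CTRL_rep1=[1000, 1000],
            mrna_KO_rep1=[500, 1500], mrna_CTRL_rep1=[500, 1500],
        )
        te = compute_te(table)
        # g0: rpf share 1/2, mrna share 1/4 -> TE ~ 2 (pseudocount negligible)
        assert te.loc[te.gene == "g0", "te_KO"].item() == pytest.approx(2.0, rel=1e-3)
        assert te.loc[te.gene == "g0", "log2_te_ratio"].item() == pytest.approx(0.0, abs=1e-9)

    def test_identical_conditions_give_zero_log_ratio(self, small_experiment):
        tidx = small_experiment["tidx"]
        transcripts = small_experiment["transcripts"]
        filtered = filter_rpfs(small_experiment["rpf"]["rpf_CTRL_rep1"], tidx).alignments
        counts = rpf_cds_counts(filtered, transcripts)
        mrna = small_experiment["mrna"]["mrna_CTRL_rep1"]
        table = _counts(
            rpf_KO_rep1=list(counts), rpf_CTRL_rep1=list(counts),
            mrna_KO_rep1=list(mrna), mrna_CTRL_rep1=list(mrna),
        )
        te = compute_te(table)
        assert np.allclose(te.loc[te.testable, "log2_te_ratio"], 0.0, atol=1e-12)

    def test_halved_te_gives_minus_one_log2(self):
        table = _counts(
            rpf_KO_rep1=[500, 1000], rpf_CTRL_rep1=[1000, 1000],
            mrna_KO_rep1=[1000, 1000], mrna_CTRL_rep1=[1000, 1000],
        )
        te = compute_te(table, pseudocount=0.0)
        # g0 RPF share drops from 1/2 to 1/3; mRNA unchanged:
        # te_KO/te_CTRL = (1/3)/(1/2) = 2/3
        assert te.loc[te.gene == "g0", "log2_te_ratio"].item() == pytest.approx(
            np.log2(2 / 3), abs=1e-9
        )

    def test_low_count_genes_not_testable(self):
        table = _counts(
            rpf_KO_rep1=[5, 1000], rpf_CTRL_rep1=[5, 1000],
            mrna_KO_rep1=[3, 1000], mrna_CTRL_rep1=[50, 1000],
        )
        te = compute_te(table)
        assert not te.loc[te.gene == "g0", "testable"].item()
        assert np.isnan(te.loc[te.gene == "g0", "te_KO"].item())

    def test_missing_condition_is_an_error(self):
        table = _counts(rpf_KO_rep1=[10], mrna_KO_rep1=[10])
        with pytest.raises(ValueError, match="CTRL"):
            compute_te(table)

    def test_mismatched_replicates_are_an_error(self):
        table = _counts(
            rpf_KO_rep1=[10], rpf_CTRL_rep1=[10],
            mrna_KO_rep2=[10], mrna_CTRL_rep1=[10],
        )
        with pytest.raises(ValueError, match="replicates"):
            compute_te(table)


class TestCallDifferentialTe:
    @pytest.mark.parametrize(
        "log2_ratio,expected",
        [(-1.0, "down"), (-0.99, "unchanged"), (1.0, "up"), (0.99, "unchanged")],
    )
    def test_two_fold_threshold_is_inclusive(self, log2_ratio, expected):
        records = pd.DataFrame(
            {"gene": ["g"], "log2_te_ratio": [log2_ratio], "testable": [True]}
        )
        assert call_differential_te(records)["call"].item() == expected

    def test_not_testable_propagates(self):
        records = pd.DataFrame(
            {"gene": ["g"], "log2_te_ratio": [np.nan], "testable": [False]}
        )
        assert call_differential_te(records)["call"].item() == "not_testable"

    def test_threshold_at_or_below_one_rejected(self):
        records = pd.DataFrame({"gene": [], "log2_te_ratio": [], "testable": []})
        with pytest.raises(ValueError, match="threshold"):
            call_differential_te(records, threshold=1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    fps=st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=30),
    lengths=st.lists(st.integers(min_value=25, max_value=34), min_size=1, max_size=30),
)
def test_filter_idempotence_property(fps, lengths):
    """Filtering an already-filtered library changes nothing."""
    t = make_transcript("t1", ["ATG"] + ["GCT"] * 18 + ["TAA"], utr5=20, utr3=20)
    n = min(len(fps), len(lengths))
    reads = [RpfAlignment(f"r{i}", "t1", fps[i], lengths[i], True) for i in range(n)
             if fps[i] + lengths[i] <= t.length]
    once = filter_rpfs(reads, [t])
    twice = filter_rpfs(once.alignments, [t])
    pd.testing.assert_frame_equal(once.alignments, twice.alignments)
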