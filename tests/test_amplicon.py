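"""Unit and property tests for the deep bisulfite amplicon analyzer."""

import math
import re

import numpy as np
import pandas as pd
import pytest

from epimut.amplicon import (
    AmpliconConfigError,
    ReadMethCall,
    assign_alleles,
    bisulfite_align,
    build_pattern_matrix,
    call_read,
    correct_allelic_imbalance,
    demultiplex,
    filter_reads,
    load_amplicon_spec,
    make_amplicon_spec,
    read_pattern_table,
    read_sequences,
    revcomp,
    run_pipeline,
    write_outputs,
)
from epimut.simulate import ReadSimConfig, random_amplicon_spec, simulate_amplicon_reads


def bisulfite_convert(reference: str, methylated: set[int] = frozenset()) -> str:
    """Fully converted read: every C becomes T except methylated CpG Cs."""
    return "".join(
        "C" if (b == "C" and i in methylated) else ("T" if b == "C" else b)
        for i, b in enumerate(reference)
    )


# ---------------------------------------------------------------------------
# Spec loading


class TestAmpliconSpec:
    def test_cpg_scan(self):
        spec = make_amplicon_spec("t", "ACGTACGT")
        assert spec.cpg_positions == (1, 5)

    def test_snp_at_cpg_cytosine_flagged_as_disrupting(self):
        # SNP C>T at the CpG's C destroys the dinucleotide on the T allele
        spec = make_amplicon_spec(
            "t", "AACGTT", snp={"position": 2, "alleles": ["C", "T"]}
        )
        assert spec.snp.disrupts_cpg_index == 0
        assert spec.disrupting_alleles() == ("T",)

    def test_snp_at_cpg_guanine_flagged_as_disrupting(self):
        spec = make_amplicon_spec(
            "t", "AACGTT", snp={"position": 3, "alleles": ["G", "C"]}
        )
        assert spec.snp.disrupts_cpg_index == 0
        assert spec.disrupting_alleles() == ("C",)

    def test_cpg_count_matches_regex_oracle(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        spec = make_amplicon_spec("t", seq)
        assert len(spec.cpg_positions) == len(re.findall("(?=CG)", seq))

    def test_snp_outside_reference_rejected(self):
        with pytest.raises(AmpliconConfigError, match="outside"):
            make_amplicon_spec("t", "ACGT", snp={"position": 9, "alleles": ["A", "G"]})

    def test_non_acgt_reference_rejected(self):
        with pytest.raises(AmpliconConfigError, match="non-ACGT"):
            make_amplicon_spec("t", "ACGN")

    def test_prefix_mid_rejected(self):
        with pytest.raises(AmpliconConfigError, match="prefix"):
            make_amplicon_spec(
                "t", "ACGT", barcodes={"ACGT": "a", "ACGTAA": "b"}
            )

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text(
            "name: amp\n"
            "reference: AACGTTACGTT\n"
            "snp: {position: 6, alleles: [A, G]}\n"
            "barcodes: {ACGAGTGCGT: s1}\n"
        )
        spec = load_amplicon_spec(path)
        assert spec.name == "amp"
        assert spec.cpg_positions == (2, 7)
        assert spec.snp.alleles == ("A", "G")
        assert spec.barcodes == {"ACGAGTGCGT": "s1"}


# ---------------------------------------------------------------------------
# Demultiplexing


class TestDemultiplex:
    def test_prefix_assignment_and_trim(self, small_spec):
        mid = next(iter(small_spec.barcodes))
        reads = [("r1", mid + "ACGTACGT" * 6)]
        out = demultiplex(reads, small_spec)
        assert out["sample_1"] == [("r1", "ACGTACGT" * 6)]

    def test_unmatched_read_goes_to_unassigned(self, small_spec):
        reads = [("r1", "TTTT" + "A" * 50)]
        out = demultiplex(reads, small_spec)
        assert out["unassigned"] == reads

    def test_reverse_complement_orientation_match(self, small_spec):
        mid = next(iter(small_spec.barcodes))
        insert = "ACGTACGT" * 6
        reads = [("r1", revcomp(mid + insert))]
        out = demultiplex(reads, small_spec)
        assert out["sample_1"] == [("r1", insert)]

    def test_one_mismatch_mode(self, small_spec):
        mid = next(iter(small_spec.barcodes))
        damaged = "T" + mid[1:] if mid[0] != "T" else "A" + mid[1:]
        reads = [("r1", damaged + "ACGTACGT" * 6)]
        assert demultiplex(reads, small_spec)["unassigned"] == reads
        out = demultiplex(reads, small_spec, max_mismatches=1)
        assert out["sample_1"] == [("r1", "ACGTACGT" * 6)]

    def test_planted_counts_recovered(self):
        barcodes = {"ACGAGTGCGT": "s1", "ACGCTCGACA": "s2", "AGACGCACTC": "s3"}
        spec = make_amplicon_spec("t", "ATGATTGGA", barcodes=barcodes)
        rng = np.random.default_rng(30)
        truth = {"s1": 0, "s2": 0, "s3": 0}
        reads = []
        mids = {v: k for k, v in barcodes.items()}
        for i in range(1000):
            sample = f"s{rng.integers(1, 4)}"
            truth[sample] += 1
            insert = "".join(rng.choice(list("ACGT"), size=60))
            reads.append((f"r{i}", mids[sample] + insert))
        out = demultiplex(reads, spec)
        assert {s: len(v) for s, v in out.items() if s != "unassigned"} == truth
        assert out["unassigned"] == []


# ---------------------------------------------------------------------------
# Alignment


class TestBisulfiteAlign:
    def test_fully_converted_read_aligns_forward(self, small_spec):
        read = bisulfite_convert(small_spec.reference)
        aln = bisulfite_align(read, small_spec)
        assert aln.ok and aln.orientation == "+"
        assert aln.identity == 1.0
        assert aln.ref_to_read == {i: i for i in range(len(read))}

    def test_reverse_complement_gives_same_mapping(self, small_spec):
        read = bisulfite_convert(small_spec.reference)
        aln = bisulfite_align(revcomp(read), small_spec)
        assert aln.ok and aln.orientation == "-"
        assert aln.ref_to_read == {i: i for i in range(len(read))}

    def test_short_read_flagged(self, small_spec):
        aln = bisulfite_align("ACGT", small_spec)
        assert not aln.ok and aln.flag == "too_short"

    def test_unrelated_sequence_flagged_low_identity(self, small_spec):
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("AG"), size=120))
        aln = bisulfite_align(junk, small_spec, identity_floor=0.9)
        assert not aln.ok

    def test_noisy_reads_align_with_correct_offsets(self):
        spec = random_amplicon_spec(n_cpgs=4, n_spacer_tokens=130, seed=40)
        rng = np.random.default_rng(41)
        n_ok = 0
        for _ in range(60):
            read = list(bisulfite_convert(spec.reference))
            for j in np.nonzero(rng.random(len(read)) < 0.01)[0]:
                read[j] = rng.choice([b for b in "ACGT" if b != read[j]])
            aln = bisulfite_align("".join(read), spec)
            if aln.ok and all(aln.ref_to_read.get(i) == i for i in spec.cpg_positions):
                n_ok += 1
        assert n_ok >= 59  # >= 99 % with correct CpG offsets


# ---------------------------------------------------------------------------
# Per-read calling


class TestCallRead:
    def _call(self, spec, read):
        aln = bisulfite_align(read, spec)
        return call_read("r", "s", aln, spec)

    def test_fully_methylated_read(self, small_spec):
        read = bisulfite_convert(
            small_spec.reference, methylated=set(small_spec.cpg_positions)
        )
        call = self._call(small_spec, read)
        assert np.all(call.states == 1.0)
        assert call.conversion_rate == 1.0

    def test_fully_unmethylated_read(self, small_spec):
        call = self._call(small_spec, bisulfite_convert(small_spec.reference))
        assert np.all(call.states == 0.0)
        assert call.conversion_rate == 1.0

    def test_one_conversion_failure_among_fifty(self):
        # reference with exactly 50 non-CpG cytosines and one CpG
        reference = "CA" * 50 + "CGAT"
        spec = make_amplicon_spec("t", reference)
        assert len(spec.non_cpg_c_positions()) == 50
        read = list(bisulfite_convert(reference, methylated={100}))
        read[0] = "C"  # one unconverted non-CpG cytosine
        call = self._call(spec, "".join(read))
        assert call.conversion_rate == pytest.approx(49 / 50)

    def test_states_match_generator_truth(self, small_spec, small_read_sim):
        cfg, sim = small_read_sim
        clean = ReadSimConfig(
            spec=cfg.spec,
            per_allele_meth=cfg.per_allele_meth,
            allele_read_counts=cfg.allele_read_counts,
            conversion_failure_rate=0.0,
            error_rate=0.0,
            seed=13,
        )
        sim = simulate_amplicon_reads(clean)
        demux = demultiplex(sim.reads, small_spec)
        truth = sim.truth.set_index("read_id")
        for read_id, seq in demux["sample_1"]:
            aln = bisulfite_align(seq, small_spec)
            call = call_read(read_id, "sample_1", aln, small_spec)
            expected = truth.loc[read_id, [f"CpG_{i+1}" for i in range(5)]]
            np.testing.assert_array_equal(
                call.states, expected.to_numpy(dtype=float)
            )
            assert call.conversion_rate == 1.0

    def test_snp_base_read_from_alignment(self, small_spec):
        seq = list(small_spec.reference)
        seq[small_spec.snp.position] = "A"  # the non-reference allele
        call = self._call(small_spec, bisulfite_convert("".join(seq)))
        assert call.snp_base == "A"


@pytest.fixture(scope="module")
def disrupted_spec():
    # CpG 2 (index 1) carries a G>C SNP at its guanine: the C allele
    # destroys the dinucleotide
    reference = "ATTCATTACGTTACGTTATTCATT" * 3
    spec = make_amplicon_spec(
        "t",
        reference,
        snp={"position": 14, "alleles": ["G", "C"]},
    )
    assert spec.snp.disrupts_cpg_index == 1
    return spec


class TestDisruptedCpG:
    """SNP destroying a CpG on one allele (white squares on that allele)."""

    @pytest.fixture
    def spec(self, disrupted_spec):
        return disrupted_spec

    def test_intact_allele_keeps_state(self, spec):
        read = bisulfite_convert(spec.reference, methylated=set(spec.cpg_positions))
        aln = bisulfite_align(read, spec)
        call = call_read("r", "s", aln, spec)
        assert call.states[1] == 1.0

    def test_disrupting_allele_state_missing(self, spec):
        seq = list(spec.reference)
        seq[14] = "C"  # C allele: position 13 is now a non-CpG C
        read = bisulfite_convert("".join(seq))
        aln = bisulfite_align(read, spec)
        call = call_read("r", "s", aln, spec)
        assert math.isnan(call.states[1])
        # observed T at the SNP can only come from the converted C allele
        assert call.snp_base == "T"

    def test_per_cpg_mean_uses_intact_allele_only(self, spec):
        calls = []
        for i, allele_base in enumerate(["G", "G", "C", "C"]):
            seq = list(spec.reference)
            seq[14] = allele_base
            meth = set(spec.cpg_positions) if allele_base == "G" else set()
            read = bisulfite_convert("".join(seq), methylated=meth)
            aln = bisulfite_align(read, spec)
            calls.append(call_read(f"r{i}", "s", aln, spec))
        calls = assign_alleles(calls, spec)
        matrix = build_pattern_matrix(calls, "s")
        # disrupted CpG: only the two methylated G-allele reads contribute
        assert matrix.per_cpg_mean["CpG_2"] == 1.0


# ---------------------------------------------------------------------------
# Conversion filter


def _mock_call(read_id, rate, n_cpgs=3):
    return ReadMethCall(
        read_id=read_id,
        sample="s",
        orientation="+",
        states=np.zeros(n_cpgs),
        conversion_rate=rate,
        snp_base=None,
    )


class TestFilterReads:
    def test_boundary_rate_rejected(self):
        kept, _ = filter_reads([_mock_call("r", 0.98)], "s", 1)
        assert kept == []

    def test_above_boundary_kept(self):
        kept, qc = filter_reads([_mock_call("r", 49 / 50 + 1e-9)], "s", 1)
        assert len(kept) == 1

    def test_all_clean_reads_kept_with_min_reads_flag(self):
        calls = [_mock_call(f"r{i}", 1.0) for i in range(200)]
        kept, qc = filter_reads(calls, "s", 200)
        assert len(kept) == 200
        assert qc.min_reads_ok

    def test_below_min_reads_flags_but_keeps(self):
        calls = [_mock_call(f"r{i}", 1.0) for i in range(5)]
        kept, qc = filter_reads(calls, "s", 5)
        assert len(kept) == 5
        assert not qc.min_reads_ok

    def test_planted_rates_match_enumeration(self):
        rates = [0.95, 0.97, 0.98, 0.9799, 0.981, 0.99, 1.0, None]
        calls = [_mock_call(f"r{i}", r) for i, r in enumerate(rates)]
        kept, qc = filter_reads(calls, "s", len(calls), min_conversion=0.98)
        expected = {f"r{i}" for i, r in enumerate(rates) if r is not None and r > 0.98}
        assert {c.read_id for c in kept} == expected
        assert qc.n_aligned == len(calls)
        assert qc.n_pass_conversion == len(expected)


# ---------------------------------------------------------------------------
# Allele assignment


class TestAssignAlleles:
    def test_matching_base_assigned(self, small_spec):
        call = _mock_call("r", 1.0)
        call.snp_base = small_spec.snp.alleles[0]
        (out,) = assign_alleles([call], small_spec)
        assert out.allele == small_spec.snp.alleles[0]

    def test_gap_at_snp_unassigned(self, small_spec):
        call = _mock_call("r", 1.0)
        call.snp_base = None
        (out,) = assign_alleles([call], small_spec)
        assert out.allele is None

    def test_third_base_unassigned(self, small_spec):
        call = _mock_call("r", 1.0)
        call.snp_base = "C"
        (out,) = assign_alleles([call], small_spec)
        assert out.allele is None

    def test_no_snp_spec_is_error(self):
        spec = make_amplicon_spec("t", "ACGTACGT")
        with pytest.raises(AmpliconConfigError, match="allele separation"):
            assign_alleles([], spec)

    def test_bisulfite_ambiguous_t_unassigned(self):
        # C/T SNP on the analyzed strand: an observed T could be the T allele
        # or the converted C allele, so it must stay unassigned
        spec = make_amplicon_spec(
            "t", "AATCATTACGTT", snp={"position": 3, "alleles": ["C", "T"]}
        )
        t_call = _mock_call("r1", 1.0)
        t_call.snp_base = "T"
        c_call = _mock_call("r2", 1.0)
        c_call.snp_base = "C"
        out = assign_alleles([t_call, c_call], spec)
        assert out[0].allele is None
        assert out[1].allele == "C"

    def test_planted_mixture_counts_exact(self, small_spec):
        cfg = ReadSimConfig(
            spec=small_spec,
            per_allele_meth={"G": [0.5] * 5, "A": [0.5] * 5},
            allele_read_counts={"G": 60, "A": 40},
            conversion_failure_rate=0.0,
            error_rate=0.0,
            seed=50,
        )
        sim = simulate_amplicon_reads(cfg)
        results = run_pipeline(sim.reads, small_spec, by_allele=True, min_reads=10)
        qc = results["sample_1"].qc
        assert qc.n_assigned == {"G": 60, "A": 40}
        assert qc.n_unassigned == 0


# ---------------------------------------------------------------------------
# Pattern matrix and summaries


class TestPatternMatrix:
    def test_all_methylated(self):
        calls = [_mock_call(f"r{i}", 1.0) for i in range(2)]
        for c in calls:
            c.states = np.ones(3)
        m = build_pattern_matrix(calls, "s")
        assert m.overall_mean == 1.0

    def test_half_methylated_symmetry(self):
        a = _mock_call("r1", 1.0)
        a.states = np.ones(3)
        b = _mock_call("r2", 1.0)
        b.states = np.zeros(3)
        m = build_pattern_matrix([a, b], "s")
        assert m.overall_mean == 0.5
        assert (m.per_cpg_mean == 0.5).all()
        assert m.n_reads == 2

    def test_overall_mean_matches_cell_count_oracle(self):
        rng = np.random.default_rng(60)
        calls = []
        for i in range(30):
            c = _mock_call(f"r{i:02d}", 1.0, n_cpgs=6)
            states = rng.choice([0.0, 1.0, np.nan], size=6, p=[0.4, 0.4, 0.2])
            c.states = states
            calls.append(c)
        m = build_pattern_matrix(calls, "s")
        cells = np.vstack([c.states for c in calls])
        n_meth = np.nansum(cells)
        n_obs = np.count_nonzero(~np.isnan(cells))
        assert m.overall_mean == pytest.approx(n_meth / n_obs)

    def test_empty_scope_is_error(self):
        with pytest.raises(AmpliconConfigError, match="no reads"):
            build_pattern_matrix([], "s")


class TestAllelicImbalance:
    def test_skewed_allele_means_average_unweighted(self):
        assert correct_allelic_imbalance(87.1, 11.6) == pytest.approx(49.35, abs=0.01)

    def test_equal_means_identity(self):
        assert correct_allelic_imbalance(0.42, 0.42) == pytest.approx(0.42)

    def test_nan_mean_rejected(self):
        with pytest.raises(ValueError):
            correct_allelic_imbalance(float("nan"), 0.5)

    def test_removes_read_count_imbalance(self, small_spec):
        cfg = ReadSimConfig(
            spec=small_spec,
            per_allele_meth={"G": [0.9] * 5, "A": [0.1] * 5},
            allele_read_counts={"G": 160, "A": 40},  # 80:20 imbalance
            conversion_failure_rate=0.0,
            error_rate=0.0,
            seed=61,
        )
        sim = simulate_amplicon_reads(cfg)
        results = run_pipeline(sim.reads, small_spec, by_allele=True, min_reads=10)
        res = results["sample_1"]
        n = 5 * 200  # cells per scope
        se_corr = 3 * math.sqrt(0.9 * 0.1 / (5 * 40))
        assert res.corrected_mean == pytest.approx(0.5, abs=se_corr)
        # the pooled mean is dominated by the over-amplified allele
        assert res.pooled.overall_mean > 0.65


# ---------------------------------------------------------------------------
# Invariants


class TestInvariants:
    def test_pooled_equals_read_weighted_allele_means(self, small_spec):
        cfg = ReadSimConfig(
            spec=small_spec,
            per_allele_meth={"G": [0.8] * 5, "A": [0.2] * 5},
            allele_read_counts={"G": 50, "A": 30},
            conversion_failure_rate=0.0,
            error_rate=0.0,
            seed=70,
        )
        sim = simulate_amplicon_reads(cfg)
        results = run_pipeline(sim.reads, small_spec, by_allele=True, min_reads=10)
        res = results["sample_1"]
        assert res.qc.n_unassigned == 0
        weights = {a: m.n_reads for a, m in res.by_allele.items()}
        weighted = sum(
            m.overall_mean * weights[a] for a, m in res.by_allele.items()
        ) / sum(weights.values())
        assert res.pooled.overall_mean == pytest.approx(weighted, abs=1e-9)

    def test_allele_count_conservation(self, small_results):
        qc = small_results["sample_1"].qc
        assert (
            sum(qc.n_assigned.values()) + qc.n_unassigned == qc.n_pass_conversion
        )

    def test_orientation_invariance(self, small_spec, small_read_sim):
        _, sim = small_read_sim
        flipped = [(rid, revcomp(seq)) for rid, seq in sim.reads]
        res_a = run_pipeline(sim.reads, small_spec, by_allele=True, min_reads=10)
        res_b = run_pipeline(flipped, small_spec, by_allele=True, min_reads=10)
        a, b = res_a["sample_1"], res_b["sample_1"]
        assert a.pooled.overall_mean == b.pooled.overall_mean
        pd.testing.assert_frame_equal(a.pooled.states, b.pooled.states)
        for allele in a.by_allele:
            assert (
                a.by_allele[allele].overall_mean == b.by_allele[allele].overall_mean
            )

    def test_conversion_failure_monotonicity(self, small_spec):
        passes = []
        for rate in (0.0, 0.02, 0.06):
            total = 0
            for seed in range(20):
                cfg = ReadSimConfig(
                    spec=small_spec,
                    per_allele_meth={"G": [0.5] * 5, "A": [0.5] * 5},
                    allele_read_counts={"G": 5, "A": 5},
                    conversion_failure_rate=rate,
                    error_rate=0.0,
                    seed=100 + seed,
                )
                sim = simulate_amplicon_reads(cfg)
                results = run_pipeline(sim.reads, small_spec, min_reads=1)
                total += results["sample_1"].qc.n_pass_conversion
            passes.append(total)
        assert passes[0] >= passes[1] >= passes[2]


# ---------------------------------------------------------------------------
# Outputs


class TestWriteOutputs:
    def test_pattern_round_trip(self, tmp_path, small_results):
        paths = write_outputs(small_results, tmp_path)
        pattern = read_pattern_table(paths["pattern"])
        res = small_results["sample_1"]
        assert len(pattern) == len(res.calls)
        by_id = pattern.set_index("read_id")
        for c in res.calls:
            row = by_id.loc[c.read_id, [f"CpG_{i+1}" for i in range(5)]]
            np.testing.assert_array_equal(row.to_numpy(dtype=float), c.states)

    def test_summary_consistent_with_pattern(self, tmp_path, small_results):
        paths = write_outputs(small_results, tmp_path)
        pattern = read_pattern_table(paths["pattern"])
        summary = pd.read_csv(paths["summary"], sep="\t")
        cells = pattern[[f"CpG_{i+1}" for i in range(5)]].to_numpy()
        recomputed = np.nansum(cells) / np.count_nonzero(~np.isnan(cells))
        pooled = summary[summary["scope"] == "all"].iloc[0]
        assert pooled["overall_mean"] == pytest.approx(recomputed, abs=1e-6)

    def test_qc_table_counts(self, tmp_path, small_results):
        paths = write_outputs(small_results, tmp_path)
        qc = pd.read_csv(paths["qc"], sep="\t").iloc[0]
        report = small_results["sample_1"].qc
        assert qc["n_raw"] == report.n_raw
        assert qc["n_pass_conversion"] == report.n_pass_conversion


def test_read_sequences_fasta_and_fastq(tmp_path):
    fa = tmp_path / "r.fasta"
    fa.write_text(">r1\nACGT\n>r2\nTTTT\n")
    fq = tmp_path / "r.fastq"
    fq.write_text("@r1\nACGT\n+\nIIII\n")
    assert read_sequences(fa) == [("r1", "ACGT"), ("r2", "TTTT")]
    assert read_sequences(fq) == [("r1", "ACGT")]
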