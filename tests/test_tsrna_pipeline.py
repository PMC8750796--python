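import itertools
import math

import numpy as np
import pandas as pd
import pytest

from srnaland.core_io import FeatureRecord, GenomicInterval, Sample, SampleTable, reverse_complement
from srnaland.locus_profiler import ExpressionTable
from srnaland.tsrna_pipeline import (
    TRNAReference,
    build_trna_reference,
    classify_tsrna_read,
    kendall_correlation,
    positional_profiles,
    select_reference_loci,
    tsrna_abundance,
)


def _random_genome(rng, length=2000, name="c1"):
    return {name: "".join(rng.choice(list("ACGT"), size=length))}


def _trna_feature(start=500, length=73, strand="+", fid="t1"):
    return FeatureRecord(fid, "tRNA", GenomicInterval("c1", start, start + length, strand))


class TestBuildReference:
    def test_lengths(self):
        rng = np.random.default_rng(0)
        genome = _random_genome(rng)
        (ref,) = build_trna_reference(genome, [_trna_feature(length=73)])
        assert len(ref.mature_seq) == 76  # 73 + CCA
        assert len(ref.primary_seq) == 153  # 73 + 40 + 40
        assert ref.mature_offset == 40
        assert len(ref.trailer_seq) == 40

    def test_mature_ends_with_cca(self):
        rng = np.random.default_rng(1)
        genome = _random_genome(rng)
        (ref,) = build_trna_reference(genome, [_trna_feature()])
        assert ref.mature_seq.endswith("CCA")

    def test_primary_contains_span_not_cca(self):
        rng = np.random.default_rng(2)
        genome = _random_genome(rng)
        (ref,) = build_trna_reference(genome, [_trna_feature()])
        span = ref.mature_seq[:-3]
        assert ref.primary_seq[40 : 40 + len(span)] == span

    def test_minus_strand_reverse_complemented(self):
        rng = np.random.default_rng(3)
        genome = _random_genome(rng)
        feat = _trna_feature(strand="-")
        (ref,) = build_trna_reference(genome, [feat])
        iv = feat.interval
        genomic = genome["c1"][iv.start : iv.end]
        assert ref.mature_seq == reverse_complement(genomic) + "CCA"

    def test_insufficient_flank_error(self):
        rng = np.random.default_rng(4)
        genome = _random_genome(rng, length=200)
        with pytest.raises(ValueError, match="t1"):
            build_trna_reference(genome, [_trna_feature(start=10)])


@pytest.fixture(scope="module")
def refs():
    rng = np.random.default_rng(11)
    genome = _random_genome(rng, length=4000)
    feats = [
        _trna_feature(start=500, length=73, fid="t1"),
        _trna_feature(start=1500, length=80, strand="-", fid="t2"),
    ]
    return build_trna_reference(genome, feats)


class TestClassifyRead:
    def test_trf5(self, refs):
        hit = classify_tsrna_read(refs[0].mature_seq[0:20], refs)
        assert hit.ts_class == "tRF-5"
        assert hit.match_start == 0

    def test_5tir(self, refs):
        hit = classify_tsrna_read(refs[0].mature_seq[0:33], refs)
        assert hit.ts_class == "5tiR"

    def test_trf3_ends_at_final_cca_base(self, refs):
        mature = refs[0].mature_seq  # length 76
        hit = classify_tsrna_read(mature[51:76], refs)
        assert hit.ts_class == "tRF-3"
        assert hit.match_end == len(mature)

    def test_3tir(self, refs):
        mature = refs[0].mature_seq
        hit = classify_tsrna_read(mature[len(mature) - 35 :], refs)
        assert hit.ts_class == "3tiR"

    def test_trf1_in_trailer(self, refs):
        trailer = refs[0].trailer_seq
        hit = classify_tsrna_read(trailer[5:25], refs)
        assert hit.ts_class == "tRF-1"
        assert hit.reference_space == "primary"

    def test_internal_fragment_is_no_hit(self, refs):
        hit = classify_tsrna_read(refs[0].mature_seq[10:34], refs)
        assert hit is None

    def test_length_41_rejected(self, refs):
        assert classify_tsrna_read(refs[0].mature_seq[0:41], refs) is None

    def test_length_13_rejected(self, refs):
        assert classify_tsrna_read(refs[0].mature_seq[0:13], refs) is None

    def test_trailer_31nt_discarded(self, refs):
        # tiR lengths are anchored classes only; a 31-40 nt trailer read is no hit
        ref = refs[0]
        seq = ref.primary_seq[ref.trailer_start : ref.trailer_start + 35]
        hit = classify_tsrna_read(seq, refs)
        assert hit is None or hit.ts_class != "tRF-1"

    def test_five_prime_precedence_full_trna(self):
        # a read equal to an entire short mature(+CCA) matches both anchors
        rng = np.random.default_rng(5)
        genome = _random_genome(rng)
        feat = _trna_feature(length=35)  # mature length 38, inside tiR range
        (ref,) = build_trna_reference(genome, [feat])
        hit = classify_tsrna_read(ref.mature_seq, [ref])
        assert hit.ts_class == "5tiR"

    def test_multi_trna_hit_counts_once(self):
        rng = np.random.default_rng(6)
        genome = _random_genome(rng)
        f1 = _trna_feature(start=500, fid="t1")
        # identical tRNA sequence elsewhere
        genome["c1"] = (
            genome["c1"][:1000]
            + genome["c1"][500:573]
            + genome["c1"][1073:]
        )
        f2 = _trna_feature(start=1000, fid="t2")
        r = build_trna_reference(genome, [f1, f2])
        hit = classify_tsrna_read(r[0].mature_seq[:20], r)
        assert set(hit.all_trna_ids) == {"t1", "t2"}


def brute_force_classify(seq, refs, trf=(14, 30), tir=(31, 40)):
    """Independent oracle: direct string-equality checks at the defining
    positions, 5' anchor > 3' anchor > trailer precedence."""
    L = len(seq)
    if not 14 <= L <= 40:
        return None
    by_priority = {0: None, 1: None, 2: None}
    for ref in refs:
        mature, primary = ref.mature_seq, ref.primary_seq
        if seq == mature[:L]:
            by_priority[0] = "tRF-5" if L <= trf[1] else "5tiR"
        if seq == mature[len(mature) - L :]:
            by_priority[1] = by_priority[1] or ("tRF-3" if L <= trf[1] else "3tiR")
        if trf[0] <= L <= trf[1]:
            trailer = ref.trailer_seq
            for s in range(0, len(trailer) - L + 1):
                if seq == trailer[s : s + L]:
                    by_priority[2] = "tRF-1"
                    break
    for pri in (0, 1, 2):
        if by_priority[pri]:
            return by_priority[pri]
    return None


class TestOracleEquivalence:
    def test_all_substrings_of_three_random_trnas(self):
        rng = np.random.default_rng(21)
        genome = _random_genome(rng, length=3000)
        feats = [
            _trna_feature(start=300 + 400 * i, length=int(rng.integers(70, 81)),
                          strand="+-"[i % 2], fid=f"t{i}")
            for i in range(3)
        ]
        refs = build_trna_reference(genome, feats)
        for ref in refs:
            for source in (ref.mature_seq, ref.primary_seq):
                for L in range(14, 41):
                    for s in range(0, len(source) - L + 1, 3):
                        seq = source[s : s + L]
                        hit = classify_tsrna_read(seq, refs)
                        got = hit.ts_class if hit else None
                        assert got == brute_force_classify(seq, refs), (seq, got)


class TestPositionalProfiles:
    def test_planted_trf5_start_mass_at_one(self, refs):
        hits = [classify_tsrna_read(refs[0].mature_seq[:l], refs) for l in range(14, 24)]
        starts, _ = positional_profiles(hits, refs)
        assert starts == {1: 10}

    def test_end_peak_counts_3prime_classes(self, refs):
        mature = refs[0].mature_seq
        hits = [
            classify_tsrna_read(mature[:20], refs),  # tRF-5
            classify_tsrna_read(mature[len(mature) - 20 :], refs),  # tRF-3
            classify_tsrna_read(mature[len(mature) - 33 :], refs),  # 3tiR
        ]
        _, ends = positional_profiles(hits, refs)
        assert ends[0] == 2

    def test_empty(self, refs):
        assert positional_profiles([], refs) == ({}, {})

    def test_counts_conserved(self, refs):
        mature = refs[0].mature_seq
        hits = [classify_tsrna_read(mature[:l], refs) for l in (14, 20, 33)]
        hits.append(classify_tsrna_read(refs[0].trailer_seq[2:20], refs))
        starts, ends = positional_profiles(hits, refs)
        assert sum(starts.values()) == sum(ends.values()) == 4


def _expr_table(fpkm):
    return ExpressionTable(
        counts=(fpkm > 0).astype(int),
        fpkm=fpkm,
        locus_lengths=pd.Series({i: 100 for i in fpkm.index}),
        library_sizes=pd.Series({c: 10**6 for c in fpkm.columns}),
    )


class TestSelectReferenceLoci:
    def test_constant_locus_selected_first(self):
        fpkm = pd.DataFrame(
            {"s1": [10.0, 5.0, 8.0, 9.0, 3.0], "s2": [10.0, 9.0, 4.0, 11.0, 5.0],
             "s3": [10.0, 7.0, 6.0, 10.0, 4.0]},
            index=["const", "b", "c", "d", "e"],
        )
        chosen = select_reference_loci(_expr_table(fpkm), k=1)
        assert chosen == ["const"]

    def test_low_replicate_ineligible(self):
        fpkm = pd.DataFrame(
            {"s1": [1.9, 10.0, 10.0, 10.0, 10.0], "s2": [50.0, 9.0, 11.0, 10.0, 12.0]},
            index=["bad", "a", "b", "c", "d"],
        )
        chosen = select_reference_loci(_expr_table(fpkm), k=4)
        assert "bad" not in chosen

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(8)
        fpkm = pd.DataFrame(
            rng.uniform(2.5, 50, size=(6, 4)),
            index=[f"l{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(4)],
        )
        chosen = select_reference_loci(_expr_table(fpkm), k=4)
        # independent CV computation
        cvs = {}
        for lid in fpkm.index:
            vals = fpkm.loc[lid].to_numpy()
            mean = vals.mean()
            sd = math.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
            cvs[lid] = sd / mean
        expected = sorted(fpkm.index, key=lambda l: (cvs[l], l))[:4]
        assert chosen == expected

    def test_too_few_eligible_error(self):
        fpkm = pd.DataFrame({"s1": [1.0, 3.0], "s2": [1.0, 3.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            select_reference_loci(_expr_table(fpkm), k=4)


class TestAbundance:
    @pytest.fixture
    def samples(self):
        return SampleTable(
            [
                Sample("root_r1", "veg_root", 1, 10**6),
                Sample("root_r2", "veg_root", 2, 10**6),
                Sample("emb_r1", "embryo", 1, 10**6),
            ]
        )

    def test_normalized_closed_form(self, samples):
        out = tsrna_abundance(
            {"root_r1": 200, "root_r2": 200, "emb_r1": 200},
            {"root_r1": 10_000, "root_r2": 10_000, "emb_r1": 10_000},
            {sid: [0.01, 0.01, 0.01, 0.01] for sid in
             ("root_r1", "root_r2", "emb_r1")},
            samples,
            baseline_tissue="veg_root",
        )
        assert out["root_r1"].normalized == pytest.approx(2.0)
        assert out["root_r1"].log2fc == pytest.approx(0.0)

    def test_log2fc_minus_two(self, samples):
        out = tsrna_abundance(
            {"root_r1": 200, "root_r2": 200, "emb_r1": 50},
            {"root_r1": 10_000, "root_r2": 10_000, "emb_r1": 10_000},
            {sid: [0.01] * 4 for sid in ("root_r1", "root_r2", "emb_r1")},
            samples,
            baseline_tissue="veg_root",
        )
        assert out["emb_r1"].log2fc == pytest.approx(-2.0)

    def test_zero_window_total_error(self, samples):
        with pytest.raises(ValueError):
            tsrna_abundance(
                {"root_r1": 1, "root_r2": 1, "emb_r1": 1},
                {"root_r1": 0, "root_r2": 10, "emb_r1": 10},
                {sid: [0.01] for sid in ("root_r1", "root_r2", "emb_r1")},
                samples, "veg_root",
            )

    def test_zero_reference_fraction_error(self, samples):
        with pytest.raises(ValueError):
            tsrna_abundance(
                {"root_r1": 1, "root_r2": 1, "emb_r1": 1},
                {"root_r1": 10, "root_r2": 10, "emb_r1": 10},
                {"root_r1": [0.0], "root_r2": [0.01], "emb_r1": [0.01]},
                samples, "veg_root",
            )

    def test_monotone_in_tsrna_count(self, samples):
        def fc(count):
            out = tsrna_abundance(
                {"root_r1": 100, "root_r2": 100, "emb_r1": count},
                {s: 10_000 for s in ("root_r1", "root_r2", "emb_r1")},
                {s: [0.01] * 4 for s in ("root_r1", "root_r2", "emb_r1")},
                samples, "veg_root",
            )
            return out["emb_r1"].log2fc

        values = [fc(c) for c in (10, 50, 100, 400)]
        assert values == sorted(values)


class TestKendall:
    def test_perfect_anticoncordance(self):
        tau, _ = kendall_correlation([1, 2, 3], [3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_perfect_concordance(self):
        tau, _ = kendall_correlation([1, 2, 3], [1, 2, 3])
        assert tau == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_correlation([1, 2, 3], [1, 2])

    @staticmethod
    def pair_counting_tau_b(x, y):
        n = len(x)
        concordant = discordant = tx = ty = 0
        for i, j in itertools.combinations(range(n), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
        n0 = n * (n - 1) / 2
        denom = math.sqrt((n0 - tx) * (n0 - ty))
        return (concordant - discordant) / denom

    def test_ties_match_pair_counting(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 4, size=n).tolist()
            y = rng.integers(0, 4, size=n).tolist()
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            tau, _ = kendall_correlation(x, y)
            assert tau == pytest.approx(self.pair_counting_tau_b(x, y), abs=1e-12)
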