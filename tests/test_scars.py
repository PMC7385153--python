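"""Scar counters (LOH/TAI/LST) against direct rule application and an
independent brute-force enumerator; RPS identities and linearity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdpipe.errors import ConfigurationError, DataError
from hrdpipe.genome import MB, ChromosomeMeta, GenomeMeta
from hrdpipe.scars import (
    RPS_BETA_WEIGHTS, count_loh, count_lst, count_tai, hrd_score_table,
    hrd_sum, import_hrd_scores, rps, rps_beta, rps_table, validate_segments,
)

GENOME = GenomeMeta((ChromosomeMeta("1", 100 * MB, 48 * MB, 52 * MB),))


def seg_table(rows, sample="S1"):
    return pd.DataFrame(
        [
            dict(sample=sample, chrom=c, start=s, end=e, major_cn=M, minor_cn=m)
            for c, s, e, M, m in rows
        ],
        columns=["sample", "chrom", "start", "end", "major_cn", "minor_cn"],
    )


# ---------------------------------------------------------------------------
# brute-force enumerators (naive, loop-based re-statements of the rules)
# ---------------------------------------------------------------------------


def brute_loh(segs, genome, min_len=15 * MB):
    n = 0
    for _, r in segs.iterrows():
        length = r.end - r.start + 1
        chrom = genome[str(r.chrom)]
        whole = r.start == 1 and r.end == chrom.length
        if r.minor_cn == 0 and length > min_len and not whole:
            n += 1
    return n


def brute_tai(segs, genome, min_len=11 * MB):
    n = 0
    for _, r in segs.iterrows():
        chrom = genome[str(r.chrom)]
        length = r.end - r.start + 1
        at_end = r.start == 1 or r.end == chrom.length
        crosses = r.start < chrom.centro_start and r.end > chrom.centro_end
        if r.major_cn != r.minor_cn and length > min_len and at_end and not crosses:
            n += 1
    return n


def brute_lst(segs, genome, min_seg=10 * MB, max_gap=3 * MB, smooth_below=3 * MB):
    total = 0
    for chrom_name in sorted(set(segs["chrom"].astype(str))):
        chrom = genome[chrom_name]
        mid = chrom.centromere_mid
        sub = segs[segs["chrom"].astype(str) == chrom_name].sort_values("start")
        arms = {"p": [], "q": []}
        for _, r in sub.iterrows():
            state = (r.major_cn, r.minor_cn)
            if r.end <= mid:
                arms["p"].append([r.start, r.end, state])
            elif r.start > mid:
                arms["q"].append([r.start, r.end, state])
            else:
                arms["p"].append([r.start, mid, state])
                arms["q"].append([mid + 1, r.end, state])
        for arm in arms.values():
            arm = [a for a in arm if a[1] - a[0] + 1 >= smooth_below]
            merged = []
            for a in arm:
                if merged and merged[-1][2] == a[2] and a[0] - merged[-1][1] - 1 <= max_gap:
                    merged[-1][1] = a[1]
                else:
                    merged.append(list(a))
            for left, right in zip(merged, merged[1:]):
                if (
                    left[2] != right[2]
                    and left[1] - left[0] + 1 >= min_seg
                    and right[1] - right[0] + 1 >= min_seg
                    and right[0] - left[1] - 1 <= max_gap
                ):
                    total += 1
    return total


def random_segment_table(rng, genome, max_segs=50):
    rows = []
    for chrom in genome.chromosomes:
        n = int(rng.integers(0, max_segs // len(genome.chromosomes) + 1))
        cuts = np.sort(rng.choice(chrom.length, size=2 * n, replace=False)) + 1
        for i in range(n):
            s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if rng.random() < 0.3:  # sometimes anchor at a telomere
                if rng.random() < 0.5:
                    s = 1
                else:
                    e = chrom.length
            minor = int(rng.integers(0, 3))
            major = int(rng.integers(minor, 4))
            rows.append(("%s" % chrom.name, s, e, major, minor))
    # drop overlaps introduced by telomere anchoring
    df = seg_table(rows)
    df = df.sort_values(["chrom", "start"])
    keep = []
    last_end = {}
    for idx, r in df.iterrows():
        if r.start > last_end.get(r.chrom, 0):
            keep.append(idx)
            last_end[r.chrom] = r.end
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# direct rule-application examples
# ---------------------------------------------------------------------------


class TestCountLoh:
    def test_qualifying_segment(self):
        segs = seg_table([("1", 10 * MB, 30 * MB - 1, 2, 0)])
        assert count_loh(segs, GENOME) == 1

    def test_whole_chromosome_excluded(self):
        segs = seg_table([("1", 1, 100 * MB, 2, 0)])
        assert count_loh(segs, GENOME) == 0

    def test_below_length_floor(self):
        segs = seg_table([("1", 10 * MB, 20 * MB, 2, 0)])
        assert count_loh(segs, GENOME) == 0

    def test_balanced_segment_not_loh(self):
        segs = seg_table([("1", 10 * MB, 40 * MB, 1, 1)])
        assert count_loh(segs, GENOME) == 0


class TestCountTai:
    def test_telomeric_imbalance(self):
        segs = seg_table([("1", 1, 30 * MB, 2, 1)])
        assert count_tai(segs, GENOME) == 1

    def test_interstitial_not_counted(self):
        segs = seg_table([("1", 5 * MB, 35 * MB, 2, 1)])
        assert count_tai(segs, GENOME) == 0

    def test_centromere_crossing_excluded(self):
        segs = seg_table([("1", 30 * MB, 100 * MB, 2, 1)])
        assert count_tai(segs, GENOME) == 0

    def test_missing_centromere_data_raises(self):
        segs = seg_table([("9", 1, 30 * MB, 2, 1)])
        with pytest.raises(ConfigurationError):
            count_tai(segs, GENOME)


class TestCountLst:
    def test_adjacent_state_change(self):
        segs = seg_table([
            ("1", 1 * MB, 13 * MB - 1, 2, 1),
            ("1", 13 * MB, 25 * MB - 1, 1, 1),
        ])
        assert count_lst(segs, GENOME) == 1

    def test_short_partner_not_counted(self):
        segs = seg_table([
            ("1", 1 * MB, 13 * MB - 1, 2, 1),
            ("1", 13 * MB, 21 * MB - 1, 1, 1),
        ])
        assert count_lst(segs, GENOME) == 0

    def test_alternating_three_segments_two_transitions(self):
        segs = seg_table([
            ("1", 1 * MB, 12 * MB - 1, 2, 2),
            ("1", 12 * MB, 23 * MB - 1, 1, 1),
            ("1", 23 * MB, 34 * MB - 1, 2, 2),
        ])
        assert count_lst(segs, GENOME) == 2

    def test_small_segment_smoothed_into_neighbors(self):
        # a 2 Mb blip inside an otherwise continuous state is removed and
        # the flanks merge: no transition
        segs = seg_table([
            ("1", 1 * MB, 12 * MB - 1, 2, 2),
            ("1", 12 * MB, 14 * MB - 1, 3, 1),
            ("1", 14 * MB, 26 * MB - 1, 2, 2),
        ])
        assert count_lst(segs, GENOME) == 0

    def test_gap_above_max_not_counted(self):
        segs = seg_table([
            ("1", 1 * MB, 12 * MB, 2, 2),
            ("1", 16 * MB + 2, 28 * MB, 1, 1),  # gap > 3 Mb
        ])
        assert count_lst(segs, GENOME) == 0


class TestBruteForceEquivalence:
    def test_counters_match_enumerator_on_random_tables(self, genome):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            segs = random_segment_table(rng, genome)
            assert count_loh(segs, genome) == brute_loh(segs, genome)
            assert count_tai(segs, genome) == brute_tai(segs, genome)
            assert count_lst(segs, genome) == brute_lst(segs, genome)

    def test_syndata_deterministic_truth(self, genome):
        from hrdpipe.syndata import SimConfig, simulate_cohort

        cfg = SimConfig(
            group_labels={"S1": "BRCA1mut", "S2": "nonHRD"},
            scar_mode="deterministic",
            seed=4,
        )
        coh = simulate_cohort(cfg)
        tab = hrd_score_table(coh.segments, coh.genome).set_index("sample")
        for s in coh.samples:
            truth = tuple(coh.truth["scar_counts"][s])
            got = tuple(tab.loc[s, ["loh_count", "tai_count", "lst_count"]])
            assert got == truth


class TestHrdSum:
    def test_components_add(self):
        segs = seg_table(
            [
                ("1", 5 * MB, 21 * MB, 1, 0),        # LOH
                ("1", 60 * MB, 100 * MB, 2, 1),      # TAI (q-telomere)
            ]
        )
        rec = hrd_sum("S1", segments=segs, genome=GENOME)
        assert rec.hrd_sum == rec.loh_count + rec.tai_count + rec.lst_count == 2
        assert rec.source == "computed"

    def test_imported_score_passthrough(self):
        rec = hrd_sum("S1", imported_score=57)
        assert rec.hrd_sum == 57
        assert rec.source == "imported"

    def test_empty_segments_zero(self):
        rec = hrd_sum("S1", segments=seg_table([]), genome=GENOME)
        assert (rec.loh_count, rec.tai_count, rec.lst_count) == (0, 0, 0)

    def test_conflicting_sources_raise(self):
        segs = seg_table([("1", 5 * MB, 21 * MB, 1, 0)])
        with pytest.raises(DataError):
            hrd_sum("S1", segments=segs, genome=GENOME, imported_score=57)

    def test_permutation_invariance(self, genome):
        rng = np.random.default_rng(7)
        segs = random_segment_table(rng, genome)
        shuffled = segs.sample(frac=1.0, random_state=1)
        a = hrd_score_table(segs, genome)
        b = hrd_score_table(shuffled, genome)
        assert a.set_index("sample").equals(b.set_index("sample"))

    def test_import_table_flags_source(self):
        out = import_hrd_scores(pd.DataFrame({"sample": ["A"], "hrd_score": [57]}))
        assert out.loc[0, "source"] == "imported"
        assert out.loc[0, "hrd_sum"] == 57


class TestSegmentValidation:
    def test_overlap_rejected(self):
        segs = seg_table([("1", 10, 100, 1, 1), ("1", 50, 200, 2, 1)])
        with pytest.raises(DataError):
            validate_segments(segs)

    def test_minor_above_major_rejected(self):
        segs = seg_table([("1", 10, 100, 1, 2)])
        with pytest.raises(DataError):
            validate_segments(segs)


class TestRps:
    def test_unweighted_sum(self):
        assert rps({"RIF1": 2, "PARPBP": 3, "RAD51": 4, "XRCC5": 1}) == -10.0

    def test_all_zero(self):
        assert rps(dict.fromkeys(RPS_BETA_WEIGHTS, 0.0)) == 0.0

    def test_beta_weights_sum_to_one(self):
        assert sum(RPS_BETA_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-7)
        assert rps_beta(dict.fromkeys(RPS_BETA_WEIGHTS, 1.0)) == pytest.approx(-1.0)

    def test_beta_single_gene_coefficient(self):
        vals = dict.fromkeys(RPS_BETA_WEIGHTS, 0.0)
        vals["RIF1"] = 1.0
        assert rps_beta(vals) == pytest.approx(-0.2171423)

    def test_missing_gene_named_in_error(self):
        with pytest.raises(DataError, match="RAD51"):
            rps({"RIF1": 1, "PARPBP": 1, "XRCC5": 1})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e4), min_size=4, max_size=4),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_linearity_and_sign(self, vals, scale):
        genes = list(RPS_BETA_WEIGHTS)
        inputs = dict(zip(genes, vals))
        scaled = {g: v * scale for g, v in inputs.items()}
        assert rps(inputs) <= 0
        assert rps_beta(inputs) <= 0
        assert rps(scaled) == pytest.approx(scale * rps(inputs), rel=1e-9, abs=1e-9)
        assert rps_beta(scaled) == pytest.approx(scale * rps_beta(inputs), rel=1e-9, abs=1e-9)

    def test_table_matches_scalar_functions(self, small_cohort):
        tab = rps_table(small_cohort.fpkm)
        s = small_cohort.samples[0]
        inputs = {g: small_cohort.fpkm.loc[g, s] for g in RPS_BETA_WEIGHTS}
        assert tab.loc[s, "rps"] == pytest.approx(rps(inputs))
        assert tab.loc[s, "rps_beta"] == pytest.approx(rps_beta(inputs))
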