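import numpy as np
import pandas as pd
import pytest

from sncrna import isomir, synthetic
from sncrna.isomir import (
    LABEL_3P, LABEL_5P, LABEL_CANONICAL, LABEL_INTERNAL, LABEL_MIXED,
    apply_retention_filter, canonical_percentage, classify_species,
    full_profile_counts, map_read, profile_reads, top_isomirs,
)
from tests.conftest import MIR146A, MIR211, MIR375


def brute_force_best(read, refs, max_mm=2, max_shift=4):
    """Independent scan over all ungapped placements (test oracle)."""
    best = None
    for idx, ref in enumerate(refs):
        c = ref.canonical_seq
        for s in range(-max_shift, max_shift + 1):
            e = s + len(read) - len(c)
            if abs(e) > max_shift:
                continue
            overlap = range(max(0, s), min(len(c), s + len(read)))
            if not overlap:
                continue
            mm = sum(1 for p in overlap if read[p - s] != c[p])
            if mm > max_mm:
                continue
            key = (mm, abs(s) + abs(e), idx, s, e)
            if best is None or key[:3] < best[:3]:
                best = key
    return best


class TestMapRead:
    def test_canonical_read_maps_with_zero_shifts(self, mirna_refs):
        m = map_read("TGAGAACTGAATTCCATGGGTT", mirna_refs)
        assert (m.mirna, m.start_shift, m.end_shift, m.internal_edits) == \
            ("miR-146a-5p", 0, 0, ())

    @pytest.mark.parametrize("read,ref,end_shift", [
        ("TGAGAACTGAATTCCATGGGTTT", "miR-146a-5p", +1),   # 3' addition of T
        ("TGAGAACTGAATTCCATGGGT", "miR-146a-5p", -1),     # 3' deletion
        ("TTCCCTTTGTCATCCTTTGCCTT", "miR-211-5p", +1),    # 3' addition
    ])
    def test_printed_3p_variants_map_with_expected_end_shift(
            self, mirna_refs, read, ref, end_shift):
        m = map_read(read, mirna_refs)
        assert m.mirna == ref
        assert m.start_shift == 0
        assert m.end_shift == end_shift
        assert m.internal_edits == ()

    def test_dissimilar_read_is_unmapped(self, mirna_refs):
        assert map_read("C" * 22, mirna_refs) is None
        assert brute_force_best("C" * 22, mirna_refs) is None

    def test_agrees_with_brute_force_scan_on_random_reads(self, mirna_refs):
        rng = np.random.default_rng(4)
        base = MIR375.canonical_seq
        for _ in range(50):
            # random perturbation of a real canonical sequence
            read = list(base)
            for _ in range(rng.integers(0, 4)):
                read[rng.integers(len(read))] = "ACGT"[rng.integers(4)]
            read = "".join(read)[rng.integers(0, 3):]
            expected = brute_force_best(read, mirna_refs)
            got = map_read(read, mirna_refs)
            if expected is None:
                assert got is None
            else:
                mm, shift_sum, idx, s, e = expected
                assert got.mirna == mirna_refs[idx].name
                assert len(got.internal_edits) == mm
                assert abs(got.start_shift) + abs(got.end_shift) == shift_sum

    def test_empty_read_rejected(self, mirna_refs):
        with pytest.raises(ValueError, match="empty read"):
            map_read("", mirna_refs)


class TestClassify:
    @pytest.mark.parametrize("s,e,edits,label", [
        (0, 0, (), LABEL_CANONICAL),
        (0, -1, (), LABEL_3P),
        (0, +1, (), LABEL_3P),
        (-1, 0, (), LABEL_5P),
        (+1, +1, (), LABEL_MIXED),
        (0, 0, ((10, "G", "A"),), LABEL_INTERNAL),
    ])
    def test_label_from_shifts_and_edits(self, s, e, edits, label):
        mapping = isomir.ReadMapping("m", s, e, edits)
        assert classify_species("ACGT", mapping).label == label


def _profile(rows):
    return pd.DataFrame(rows, columns=["mirna", "sequence", "label",
                                       "start_shift", "end_shift", "n_edits",
                                       "sample", "count"])


class TestRetentionFilter:
    def test_boundary_is_inclusive_at_five_percent(self):
        prof = _profile([
            ("m", "AAA", LABEL_CANONICAL, 0, 0, 0, "s1", 95),
            ("m", "AAT", LABEL_3P, 0, 1, 0, "s1", 5),
        ])
        out = apply_retention_filter(prof, 0.05)
        assert out.loc[out["sequence"] == "AAT", "retained"].all()

    def test_below_threshold_everywhere_is_dropped(self):
        prof = _profile([
            ("m", "AAA", LABEL_CANONICAL, 0, 0, 0, s, 96) for s in ("s1", "s2")
        ] + [
            ("m", "AAT", LABEL_3P, 0, 1, 0, s, 4) for s in ("s1", "s2")
        ])
        out = apply_retention_filter(prof, 0.05)
        assert not out.loc[out["sequence"] == "AAT", "retained"].any()

    def test_union_rule_keeps_species_in_all_samples(self):
        # 6% in s1 only, ~1% in s2/s3: retained everywhere
        rows = [("m", "AAA", LABEL_CANONICAL, 0, 0, 0, "s1", 94),
                ("m", "AAT", LABEL_3P, 0, 1, 0, "s1", 6)]
        for s in ("s2", "s3"):
            rows += [("m", "AAA", LABEL_CANONICAL, 0, 0, 0, s, 99),
                     ("m", "AAT", LABEL_3P, 0, 1, 0, s, 1)]
        out = apply_retention_filter(_profile(rows), 0.05)
        kept = out[out["sequence"] == "AAT"]
        assert kept["retained"].all() and len(kept) == 3

    def test_raising_fraction_never_adds_species(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in ("s1", "s2"):
            for i in range(10):
                rows.append(("m", f"SEQ{i}", LABEL_3P, 0, 1, 0, s,
                             int(rng.integers(1, 50))))
        prof = _profile(rows)
        kept_sets = []
        for frac in (0.01, 0.05, 0.1, 0.3):
            out = apply_retention_filter(prof, frac)
            kept_sets.append(set(out.loc[out["retained"], "sequence"]))
        for a, b in zip(kept_sets, kept_sets[1:]):
            assert b <= a


class TestStatistics:
    def test_all_canonical_is_100_percent(self):
        prof = _profile([("m", "AAA", LABEL_CANONICAL, 0, 0, 0, "s1", 50)])
        out = canonical_percentage(prof, "m")
        assert out["percent"].tolist() == [100.0]

    def test_hand_computed_percentage(self):
        prof = _profile([
            ("m", "AAA", LABEL_CANONICAL, 0, 0, 0, "s1", 32),
            ("m", "AAT", LABEL_3P, 0, 1, 0, "s1", 68),
        ])
        out = canonical_percentage(prof, "m")
        assert out["percent"].tolist() == [32.0]

    def test_top_isomirs_single_candidate(self):
        prof = _profile([
            ("m", "AAT", LABEL_3P, 0, 1, 0, s, 10) for s in ("t1", "t2")
        ])
        short = top_isomirs(prof, "m", ["t1", "t2"])
        assert short["sequence"].tolist() == ["AAT"]

    def test_top_isomirs_requires_presence_in_all_tbi(self):
        rows = []
        # 6 species; only 3 present in both TBI samples, in count order
        for i in range(6):
            rows.append(("m", f"S{i}", LABEL_3P, 0, 1, 0, "t1", 100 - i))
            if i < 3:
                rows.append(("m", f"S{i}", LABEL_3P, 0, 1, 0, "t2", 50))
        short = top_isomirs(_profile(rows), "m", ["t1", "t2"])
        assert short["sequence"].tolist() == ["S0", "S1", "S2"]

    def test_top_isomirs_empty_when_none_shared(self):
        prof = _profile([("m", "AAT", LABEL_3P, 0, 1, 0, "t1", 10)])
        short = top_isomirs(prof, "m", ["t1", "t2"])
        assert short.empty

    def test_full_profile_counts_sums_canonical_and_retained(self):
        prof = _profile([
            ("m", "AAA", LABEL_CANONICAL, 0, 0, 0, "s1", 60),
            ("m", "AAT", LABEL_3P, 0, 1, 0, "s1", 30),
            ("m", "AATT", LABEL_3P, 0, 2, 0, "s1", 10),
        ])
        prof = apply_retention_filter(prof, 0.05)
        totals = full_profile_counts(prof, "m")
        assert totals["s1"] == 100
        # dropping a species below threshold excludes it from the total
        prof2 = apply_retention_filter(prof.drop(columns="retained"), 0.2)
        assert full_profile_counts(prof2, "m")["s1"] == 90


class TestGeneratorRoundTrip:
    def test_count_conservation_and_involutive_classification(self, mirna_refs):
        mix = synthetic.canonical_isomir_mix(MIR375, 0.4)
        reads = synthetic.gen_isomir_reads(MIR375, mix, 20_000, 12)
        prof = profile_reads(reads, mirna_refs)
        # conservation: every generated read is mapped, counts preserved
        assert prof["count"].sum() == 20_000
        # generated 3' species classify as 3' isomiRs with the right shift
        for seq, shift in ((MIR375.canonical_seq + "T", 1),
                           (MIR375.canonical_seq[:-1], -1)):
            row = prof[prof["sequence"] == seq]
            assert (row["label"] == LABEL_3P).all()
            assert (row["end_shift"] == shift).all()
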