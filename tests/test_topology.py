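"""Channel-topology classification, group assignment, signal peptides."""

import numpy as np
import pytest

from gluscreen.metrics import group_accuracy
from gluscreen.records import ProteinRecord
from gluscreen.screen import predict_tm_segments
from gluscreen.synthetic import SyntheticSpec, generate_protein
from gluscreen.topology import (
    GROUP1_ANNOTATION,
    GROUP2_ANNOTATION,
    TopologyProfile,
    assign_groups,
    classify_screen_survivors,
    classify_topology,
    detect_k_filter,
    detect_pore_loop,
    detect_signal_peptide,
)


def make_channel(seed, group="channel-g1", signal=True, rate=0.05):
    spec = SyntheticSpec(
        substitution_rate=rate, include_signal_peptide=signal, rng_seed=seed
    )
    return generate_protein(
        spec, group, np.random.default_rng(seed), f"CH{seed:03d}"
    )


class TestKFilter:
    def test_canonical_filter_detected(self):
        assert detect_k_filter("AATVGYGAA")

    def test_plain_sequence_not_detected(self):
        assert not detect_k_filter("AAAAA")

    def test_fallback_accepts_bare_gyg_core(self):
        assert detect_k_filter("AAGYGAA")

    def test_pattern_is_configurable(self):
        assert not detect_k_filter("AAGYGAA", pattern="TVGYG", fallback="")


class TestPoreLoop:
    def test_planted_pore_recovered(self):
        record, truth = make_channel(21, signal=False)
        segments = predict_tm_segments(record.sequence)
        s1, s2 = truth.region("S1"), truth.region("S2")
        inner = [
            s for s in segments
            if s.passes_test and s.start >= s1.end and s.end <= s2.start
        ] + [s for s in segments if not s.passes_test]
        pore = detect_pore_loop(record.sequence, inner)
        assert pore is not None
        truth_pore = truth.region("P")
        overlap = min(pore.end, truth_pore.end) - max(
            pore.start, truth_pore.start
        )
        assert overlap >= len(truth_pore) // 2

    def test_requires_two_passing_helices(self):
        segments = predict_tm_segments("L" * 30)
        with pytest.raises(ValueError):
            detect_pore_loop("L" * 30, segments)

    def test_hydrophilic_linker_yields_no_pore(self):
        seq = "L" * 25 + "D" * 40 + "L" * 25
        segments = predict_tm_segments(seq)
        assert len([s for s in segments if s.passes_test]) == 2
        assert detect_pore_loop(seq, segments) is None


class TestClassifyTopology:
    def screen_one(self, record):
        from gluscreen.align import smith_waterman
        from gluscreen.fixtures import load_probes

        probes = load_probes()
        hits = {}
        for label, probe in (
            ("S1", probes.s1_sequence), ("S2", probes.s2_sequence)
        ):
            hits[label] = smith_waterman(
                probe, record.sequence, protein_id=record.protein_id,
                probe_label=label,
            )
        return hits, predict_tm_segments(record.sequence)

    def test_planted_channel_classified(self):
        record, _ = make_channel(31)
        hits, segments = self.screen_one(record)
        profile = classify_topology(record, hits["S1"], hits["S2"], segments)
        assert profile.is_channel
        types = [r.region_type for r in profile.regions]
        for t in ("S1", "M1", "P", "M2", "S2"):
            assert t in types

    def test_extra_nterminal_helix_does_not_break_classification(self):
        # the signal peptide often reads as an additional hydrophobic helix;
        # M1/M2 selection must ignore helices outside the S1..S2 span
        record, _ = make_channel(32, signal=True)
        hits, segments = self.screen_one(record)
        profile = classify_topology(record, hits["S1"], hits["S2"], segments)
        assert profile.is_channel

    def test_soluble_binder_is_not_a_channel(self):
        spec = SyntheticSpec(rng_seed=33)
        record, _ = generate_protein(
            spec, "soluble-binder", np.random.default_rng(33), "SOL001"
        )
        hits, segments = self.screen_one(record)
        profile = classify_topology(record, hits["S1"], hits["S2"], segments)
        assert not profile.is_channel
        assert profile.group is None

    def test_swapped_binding_domains_rejected(self, probes):
        # S2 before S1 in sequence order: the ordering predicate must fail
        record, truth = make_channel(34, signal=False, rate=0.0)
        s1 = truth.region("S1")
        s2 = truth.region("S2")
        seq = record.sequence
        swapped = (
            seq[:s1.start] + probes.s2_sequence[:s1.end - s1.start].ljust(
                s1.end - s1.start, "G")
            + seq[s1.end:s2.start]
            + probes.s1_sequence.ljust(s2.end - s2.start, "G")
            + seq[s2.end:]
        )
        rec2 = ProteinRecord("SWAP", swapped)
        hits, segments = self.screen_one(rec2)
        s1_iv, s2_iv = hits["S1"].subject_interval, hits["S2"].subject_interval
        if max(s1_iv[0], s2_iv[0]) < min(s1_iv[1], s2_iv[1]):
            with pytest.raises(ValueError):
                classify_topology(rec2, hits["S1"], hits["S2"], segments)
        else:
            profile = classify_topology(
                rec2, hits["S1"], hits["S2"], segments
            )
            assert not profile.is_channel

    def test_overlapping_hits_rejected(self):
        record, _ = make_channel(35)
        hits, segments = self.screen_one(record)
        with pytest.raises(ValueError):
            classify_topology(record, hits["S1"], hits["S1"], segments)


class TestSignalPeptide:
    def test_generated_signal_detected(self):
        record, _ = make_channel(41, signal=True)
        assert detect_signal_peptide(record.sequence)

    def test_signal_free_channel_not_detected(self):
        record, _ = make_channel(42, signal=False)
        assert not detect_signal_peptide(record.sequence)

    def test_poly_aspartate_n_terminus_rejected(self):
        assert not detect_signal_peptide("D" * 60)

    def test_short_sequence_warns_and_returns_false(self):
        with pytest.warns(UserWarning):
            assert not detect_signal_peptide("MKLLLLLLLLA")

    def test_two_signal_free_members_per_group_reported(self):
        # mirrors the observation that two members of each group lack the
        # signal peptide that orients the channel in the membrane
        records = []
        for seed, group in enumerate(
            ["channel-g1"] * 4 + ["channel-g2"] * 4, start=100
        ):
            signal = seed % 4 < 2  # exactly 2 with / 2 without per group
            rec, _ = make_channel(seed, group=group, signal=signal)
            records.append((group, rec))
        for group in ("channel-g1", "channel-g2"):
            flags = [
                detect_signal_peptide(rec.sequence)
                for g, rec in records if g == group
            ]
            assert flags.count(False) == 2


class TestAssignGroups:
    def test_group_recovery_on_small_dataset(self, small_benchmark):
        _, records, truths, _, result = small_benchmark
        profiles = classify_screen_survivors(records, result)
        assert group_accuracy(profiles, truths) == 1.0
        assert sum(p.group == 1 for p in profiles) == 5
        assert sum(p.group == 2 for p in profiles) == 5

    def test_annotation_strings_follow_group(self, small_benchmark):
        _, records, _, _, result = small_benchmark
        profiles = classify_screen_survivors(records, result)
        for p in profiles:
            if p.group == 1:
                assert p.suggested_annotation == GROUP1_ANNOTATION
            elif p.group == 2:
                assert p.suggested_annotation == GROUP2_ANNOTATION

    def test_non_channel_gets_no_group(self):
        profile = TopologyProfile("X", (), is_channel=False)
        (out,) = assign_groups([profile], {"X": "A" * 50})
        assert out.group is None

    def test_group_implies_channel_invariant(self):
        with pytest.raises(ValueError):
            TopologyProfile("X", (), is_channel=False, group=1)
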