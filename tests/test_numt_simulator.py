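import numpy as np
import pytest

import numt_sieve as ns
from numt_sieve.errors import SimulationError
from numt_sieve.genetic_codes import INVERTEBRATE_MITO, translate


class TestGenerate:
    def test_geometry_and_reading_frame(self, community):
        for rec in community:
            assert len(rec.seq) == 658  # 1 pad + 219 codons
            aa = translate(rec.seq, INVERTEBRATE_MITO, frame=1)
            assert "*" not in aa
            best = ns.longest_orf(ns.find_orfs(rec, INVERTEBRATE_MITO))
            assert best.length_nt == 657

    def test_gc_within_band(self, community):
        for rec in community:
            assert abs(ns.gc_fraction(rec) - 0.40) <= 0.05

    def test_same_seed_is_byte_identical(self):
        a = ns.generate_synthetic_community(20, seed=99)
        b = ns.generate_synthetic_community(20, seed=99)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]
        c = ns.generate_synthetic_community(20, seed=100)
        assert [r.seq for r in a] != [r.seq for r in c]

    def test_empty_and_bad_args(self):
        assert ns.generate_synthetic_community(0) == []
        with pytest.raises(ValueError):
            ns.generate_synthetic_community(5, length=30)
        with pytest.raises(SimulationError):
            ns.generate_synthetic_community(5, gc_target=0.999)

    def test_length_adjusted_to_1_mod_3(self):
        recs = ns.generate_synthetic_community(3, length=660, seed=1)
        assert all(len(r.seq) == 658 for r in recs)


class TestGcToAt:
    def test_exact_edit_count_and_gc_drop(self):
        rng = np.random.default_rng(0)
        src = ns.generate_synthetic_community(1, length=1000, seed=4)[0].seq
        assert len(src) == 1000
        out, edits = ns.apply_gc_to_at(src, 0.025, rng)
        assert len(edits) == 25 and len(out) == len(src)
        gc_drop = (src.count("G") + src.count("C")
                   - out.count("G") - out.count("C")) / len(src)
        assert gc_drop == pytest.approx(0.025)

    def test_edits_are_gc_to_at_transitions(self):
        rng = np.random.default_rng(1)
        src = ns.generate_synthetic_community(1, seed=5)[0].seq
        out, edits = ns.apply_gc_to_at(src, 0.025, rng)
        for e in edits:
            assert src[e.position] in "GC"
            assert out[e.position] in "AT"
            assert (src[e.position], e.base) in (("G", "A"), ("C", "T"))

    def test_rate_rounding_to_zero_edits_is_identity(self):
        src = "ACGT" * 50
        out, edits = ns.apply_gc_to_at(src, 0.001, np.random.default_rng(0))
        assert out == src and edits == []

    def test_too_few_gc_sites_rejected(self):
        with pytest.raises(SimulationError, match="G/C"):
            ns.apply_gc_to_at("AT" * 30, 0.2, np.random.default_rng(0))


class TestFrameshifts:
    def test_exact_event_count(self):
        rng = np.random.default_rng(2)
        src = ns.generate_synthetic_community(1, length=1000, seed=6)[0].seq
        out, edits = ns.apply_frameshifts(src, 0.025, rng)
        assert len(edits) == 25
        n_ins = sum(e.op == "ins" for e in edits)
        n_del = sum(e.op == "del" for e in edits)
        assert len(out) == len(src) + n_ins - n_del

    def test_provenance_replay_round_trip(self):
        rng = np.random.default_rng(3)
        src = ns.generate_synthetic_community(1, seed=7)[0].seq
        out, edits = ns.apply_frameshifts(src, 0.025, rng)
        assert ns.replay_edits(src, edits) == out

    def test_frameshifts_shorten_the_longest_orf(self):
        """~16 indels on a 658-nt codon-clean source essentially always
        break the full-length reading frame."""
        shorter = 0
        n_reps = 200
        for i in range(n_reps):
            src = ns.generate_synthetic_community(1, seed=1000 + i)[0]
            base = ns.longest_orf(ns.find_orfs(src, INVERTEBRATE_MITO, min_length=3))
            out, _ = ns.apply_frameshifts(src.seq, 0.025,
                                          np.random.default_rng(i))
            rec = ns.SequenceRecord(src.id, out)
            after = ns.longest_orf(ns.find_orfs(rec, INVERTEBRATE_MITO, min_length=3))
            if after is None or after.length_nt < base.length_nt:
                shorter += 1
        assert shorter / n_reps > 0.99


class TestSplitHalf:
    @pytest.mark.parametrize("L,expected", [(658, (329, 329)), (659, (329, 330))])
    def test_floor_rule(self, L, expected):
        five, three = ns.split_half("A" * L)
        assert (len(five), len(three)) == expected

    def test_concatenation_conserves(self):
        seq = "ACGTACGTT"
        five, three = ns.split_half(seq)
        assert five + three == seq


class TestPerturbCommunity:
    @pytest.mark.parametrize("fraction,n,expected", [
        (0.19, 100, 19),
        (0.38, 100, 38),
        (0.095, 200, 19),
    ])
    def test_numt_proportions(self, fraction, n, expected):
        recs = ns.generate_synthetic_community(n, seed=12)
        ds = ns.perturb_community(
            recs, ns.PerturbationConfig(numt_fraction=fraction, seed=1))
        assert ds.n_numts == expected
        assert set(ds.labels.values()) <= {"gene", "simulated_numt"}
        assert len(ds.records) == n

    def test_gc_mode_preserves_length(self, community):
        ds = ns.perturb_community(
            community, ns.PerturbationConfig(mode="gc_to_at", seed=2))
        src = {r.id: r for r in community}
        for rec in ds.records:
            assert len(rec.seq) == len(src[rec.id].seq)

    def test_fragments_truncate_genes_and_numts(self, community):
        ds5 = ns.perturb_community(
            community, ns.PerturbationConfig(mode="gc_to_at", fragment="half5", seed=2))
        assert all(len(r.seq) == 329 for r in ds5.records)
        h5, h3 = ns.perturb_community(
            community, ns.PerturbationConfig(mode="gc_to_at", fragment="both_halves", seed=2))
        assert h5.fragment == "half5" and h3.fragment == "half3"
        full = ns.perturb_community(
            community, ns.PerturbationConfig(mode="gc_to_at", fragment="full", seed=2))
        by_id = {r.id: r for r in full.records}
        for a, b in zip(h5.records, h3.records):
            assert a.seq + b.seq == by_id[a.id].seq

    def test_single_seed_determinism(self, community):
        cfg = ns.PerturbationConfig(mode="frameshift", seed=42)
        d1 = ns.perturb_community(community, cfg)
        d2 = ns.perturb_community(community, cfg)
        assert [(r.id, r.seq) for r in d1.records] == [(r.id, r.seq) for r in d2.records]
        assert d1.edits == d2.edits

    def test_mean_gc_drop_matches_edit_rate(self):
        recs = ns.generate_synthetic_community(100, seed=21)
        ds = ns.perturb_community(
            recs, ns.PerturbationConfig(mode="gc_to_at", seed=3))
        src = {r.id: r for r in recs}
        drops = [ns.gc_fraction(src[r.id]) - ns.gc_fraction(r)
                 for r in ds.records if ds.labels[r.id] == "simulated_numt"]
        # fixed-length 658-nt inputs: each drop is round(0.025*658)/658
        assert np.mean(drops) == pytest.approx(round(0.025 * 658) / 658, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ns.PerturbationConfig(numt_fraction=0.0)
        with pytest.raises(ValueError):
            ns.PerturbationConfig(mode="reverse")
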