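import numpy as np
import pytest

from memsa.seqio import Alignment, SequenceRecord
from memsa.synthetic import (
    FamilySimulationParams,
    SimulatedFamily,
    measure_identity,
    simulate_family,
)
from memsa.topology import TMHELIX


class TestSimulateFamily:
    def test_same_seed_gives_identical_families(self):
        p = FamilySimulationParams(rng_seed=7)
        a, b = simulate_family(p), simulate_family(p)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]
        assert a.true_alignment.rows == b.true_alignment.rows

    def test_zero_rates_give_identical_gapless_family(self):
        p = FamilySimulationParams(
            n_sequences=4, substitution_rate=0.0, loop_indel_rate=0.0, rng_seed=1
        )
        fam = simulate_family(p)
        seqs = {r.residues for r in fam.records}
        assert len(seqs) == 1
        assert all("-" not in row for _, row in fam.true_alignment.rows)

    def test_truth_round_trips_to_records(self, default_family):
        default_family.true_alignment.check_roundtrip(default_family.records)

    def test_topology_covers_each_record(self, default_family):
        for rec in default_family.records:
            ann = default_family.true_topology[rec.id]
            assert ann.length == len(rec.residues)
            assert ann.tm_count == default_family.params.n_helices

    def test_tm_columns_of_truth_are_indel_free(self, default_family):
        """Indels are confined to loops: wherever any member has a helix
        residue, every member has a residue."""
        fam = default_family
        tm_ranges = {
            rid: ann.tm_segments() for rid, ann in fam.true_topology.items()
        }

        def is_tm(rid, ridx):
            return any(s.start <= ridx < s.end for s in tm_ranges[rid])

        counters = {rid: 0 for rid, _ in fam.true_alignment.rows}
        for j in range(fam.true_alignment.width):
            col = []
            for rid, row in fam.true_alignment.rows:
                if row[j] != "-":
                    col.append((rid, counters[rid]))
                    counters[rid] += 1
            if any(is_tm(rid, ridx) for rid, ridx in col):
                assert len(col) == len(fam.true_alignment.rows)

    def test_soluble_family_has_single_loop(self):
        fam = simulate_family(
            FamilySimulationParams(n_sequences=3, n_helices=0, rng_seed=3)
        )
        for ann in fam.true_topology.values():
            assert ann.tm_count == 0
            assert len(ann.segments) == 1

    def test_helix_lengths_shared_across_members(self, default_family):
        """No helix indels: the k-th helix has one family-wide length."""
        lens = [
            [s.length for s in ann.tm_segments()]
            for ann in default_family.true_topology.values()
        ]
        assert all(l == lens[0] for l in lens)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            FamilySimulationParams(substitution_rate=1.0)
        with pytest.raises(ValueError):
            FamilySimulationParams(loop_indel_rate=-0.1)

    def test_many_parameter_draws_keep_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = FamilySimulationParams(
                n_sequences=int(rng.integers(2, 6)),
                n_helices=int(rng.integers(0, 5)),
                substitution_rate=float(rng.uniform(0, 0.5)),
                loop_indel_rate=float(rng.uniform(0, 0.6)),
                rng_seed=int(rng.integers(0, 10_000)),
            )
            fam = simulate_family(p)
            fam.true_alignment.check_roundtrip(fam.records)
            for rec in fam.records:
                assert fam.true_topology[rec.id].length == len(rec.residues)


class TestMeasureIdentity:
    def test_zero_rate_family_is_100_percent(self):
        p = FamilySimulationParams(
            n_sequences=3, substitution_rate=0.0, loop_indel_rate=0.0, rng_seed=4
        )
        assert measure_identity(simulate_family(p)) == 100.0

    def test_hand_built_pair_with_one_difference(self):
        records = [SequenceRecord("a", "A" * 100), SequenceRecord("b", "A" * 99 + "C")]
        aln = Alignment([("a", "A" * 100), ("b", "A" * 99 + "C")])
        fam = SimulatedFamily(
            FamilySimulationParams(n_sequences=2), records, {}, aln
        )
        assert measure_identity(fam) == pytest.approx(99.0)

    def test_singleton_family_rejected(self):
        fam = simulate_family(FamilySimulationParams(n_sequences=1, rng_seed=5))
        with pytest.raises(ValueError):
            measure_identity(fam)

    def test_identity_decreases_with_substitution_rate(self):
        means = []
        for rate in (0.0, 0.2, 0.4):
            vals = [
                measure_identity(
                    simulate_family(
                        FamilySimulationParams(
                            n_sequences=4, substitution_rate=rate, rng_seed=s
                        )
                    )
                )
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_default_conditions_sit_near_half_identity(self):
        vals = [
            measure_identity(simulate_family(FamilySimulationParams(rng_seed=s)))
            for s in range(10)
        ]
        assert 45.0 <= np.mean(vals) <= 55.0
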