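"""Mutagenesis-simulator tests: spectrum, synonymous rule, competence, decay."""

import numpy as np
import pytest

from oracles import oracle_competence
from piwikit import mutsim, simulate
from piwikit.mutsim import (
    ConsensusSequence,
    GuideRepertoire,
    MutagenesisTrajectory,
    MutationSpectrum,
    count_competent,
    decay_rate,
    encode_sequence,
    decode_sequence,
    mutate_step,
    run_simulations,
    simulate_lineage,
    _orf_memberships,
)
from piwikit.pairing import reverse_complement


class TestMutationSpectrum:
    def test_default_normalized_with_ts_tv_ratio(self):
        s = MutationSpectrum.default(2.0)
        total = sum(w for _, _, w in s.weights)
        assert total == pytest.approx(1.0)
        w = dict(((a, b), v) for a, b, v in s.weights)
        assert w[("A", "G")] / w[("A", "C")] == pytest.approx(2.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MutationSpectrum.from_dict({("A", "A"): 1.0})
        with pytest.raises(ValueError):
            MutationSpectrum.from_dict({("A", "G"): -1.0})


class TestMutateStep:
    def test_non_orf_positions_always_accepted(self, rng):
        cons = ConsensusSequence(name="c", sequence="A" * 60)
        codes = encode_sequence(cons.sequence)
        pos = mutate_step(codes, MutationSpectrum.default(),
                          _orf_memberships(cons), rng)
        assert decode_sequence(codes)[pos] != "A"

    def test_synonymous_codon_rule(self, rng):
        # TTT(Phe): third-position T->C (TTC, Phe) is synonymous and allowed;
        # T->A (TTA, Leu) must always be rejected
        cons = ConsensusSequence(name="c", sequence="TTT" * 20,
                                 orf_intervals=((0, 60),))
        spectrum = MutationSpectrum.from_dict({("T", "A"): 1.0})
        codes = encode_sequence(cons.sequence)
        with pytest.raises(RuntimeError):
            mutate_step(codes, spectrum, _orf_memberships(cons), rng,
                        max_redraws=2000)
        spectrum = MutationSpectrum.from_dict({("T", "C"): 1.0})
        pos = mutate_step(codes, spectrum, _orf_memberships(cons), rng)
        assert pos % 3 == 2  # only third positions are synonymous here
        assert decode_sequence(codes)[pos] == "C"

    def test_degenerate_spectrum_only_a_to_g(self, rng):
        cons = ConsensusSequence(name="c", sequence="ACGT" * 25)
        spectrum = MutationSpectrum.from_dict({("A", "G"): 1.0})
        codes = encode_sequence(cons.sequence)
        for _ in range(20):
            before = decode_sequence(codes)
            pos = mutate_step(codes, spectrum, _orf_memberships(cons), rng)
            assert before[pos] == "A"
            assert decode_sequence(codes)[pos] == "G"

    def test_overlapping_orfs_both_constrain(self, rng):
        # the overlap region must be synonymous in both reading frames
        seq = "ATGGCTGCAGCTGCAGCTTAAATG" + "GCT" * 10 + "TAA"
        cons = ConsensusSequence(
            name="c", sequence=seq,
            orf_intervals=((0, 24), (21, len(seq))),
        )
        codes = encode_sequence(cons.sequence)
        members = _orf_memberships(cons)
        assert len(members[22]) == 2
        for _ in range(50):
            snap = codes.copy()
            mutate_step(codes, MutationSpectrum.default(), members, rng)
            changed = int(np.nonzero(codes != snap)[0][0])
            for start, end in cons.orf_intervals:
                if start <= changed < end:
                    cs = start + ((changed - start) // 3) * 3
                    old = decode_sequence(snap[cs:cs + 3])
                    new = decode_sequence(codes[cs:cs + 3])
                    assert mutsim._CODON_AA[old] == mutsim._CODON_AA[new]


class TestCompetence:
    def _repertoire_with_mismatches(self, rng, n_mm, positions=None):
        cons = simulate.gen_consensus(length=600, seed=3)
        rep = simulate.gen_repertoire(cons, n_guides=1, seed=4)
        seq = list(cons.sequence)
        anchor = int(rep.anchors[0])
        if positions is None:
            positions = list(range(1, n_mm + 1))
        for g_pos in positions:
            idx = anchor + 26 - g_pos
            seq[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[idx]]
        return "".join(seq), rep

    def test_pirna_boundary_6_vs_7_mismatches(self, rng):
        seq6, rep = self._repertoire_with_mismatches(rng, 6)
        assert count_competent(seq6, rep)[0] == 1
        seq7, rep = self._repertoire_with_mismatches(rng, 7)
        assert count_competent(seq7, rep)[0] == 0

    def test_sirna_single_mismatch_at_g10_disqualifies(self, rng):
        seq, rep = self._repertoire_with_mismatches(rng, 1, positions=[10])
        n_pi, n_si = count_competent(seq, rep)
        assert n_pi == 1 and n_si == 0

    def test_sirna_seed_allows_one_mismatch(self, rng):
        seq, rep = self._repertoire_with_mismatches(rng, 1, positions=[4])
        assert count_competent(seq, rep)[1] == 1
        seq, rep = self._repertoire_with_mismatches(rng, 2, positions=[4, 6])
        assert count_competent(seq, rep)[1] == 0

    def test_agrees_with_bruteforce_oracle(self, rng):
        cons = simulate.gen_consensus(length=2000, seed=5)
        rep = simulate.gen_repertoire(cons, n_guides=100, seed=6)
        codes = encode_sequence(cons.sequence)
        # mutate heavily so guides span the competence boundary
        members = _orf_memberships(cons)
        spectrum = MutationSpectrum.default()
        for _ in range(400):
            mutate_step(codes, spectrum, members, rng)
        seq = decode_sequence(codes)
        n_pi, n_si = count_competent(seq, rep)
        pi_o = si_o = 0
        for guide, anchor in zip(rep.guides, rep.anchors):
            window = seq[anchor : anchor + 26]
            ok_pi, ok_si = oracle_competence(guide, window)
            pi_o += ok_pi
            si_o += ok_si
        assert (n_pi, n_si) == (pi_o, si_o)

    def test_restricted_dominance_property(self, rng):
        # if all mismatches lie in the first 21 nt and total <= 5, a
        # siRNA-competent prefix implies the full piRNA is competent too
        for trial in range(200):
            r = np.random.default_rng(trial)
            mm = r.choice(np.arange(1, 22), size=int(r.integers(0, 6)),
                          replace=False)
            guide = "".join(r.choice(list("ACGU"), 26))
            window = list(reverse_complement(guide).replace("U", "T"))
            for g_pos in mm:
                i = 26 - g_pos
                window[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[i]]
            ok_pi, ok_si = oracle_competence(guide, "".join(window))
            if ok_si:
                assert ok_pi

    def test_unmutated_repertoire_fully_competent(self):
        cons = simulate.gen_consensus(length=1000, seed=7)
        rep = simulate.gen_repertoire(cons, n_guides=40, seed=8)
        assert count_competent(cons.sequence, rep) == (40, 40)


class TestTrajectories:
    def test_identical_seeds_identical_trajectories(self):
        cons = simulate.gen_consensus(length=1500, seed=9)
        rep = simulate.gen_repertoire(cons, n_guides=50, seed=10)
        a = simulate_lineage(cons, rep, steps=50, seed=11)
        b = simulate_lineage(cons, rep, steps=50, seed=11)
        assert np.array_equal(a.n_pirna, b.n_pirna)
        assert np.array_equal(a.n_sirna, b.n_sirna)

    def test_counts_bounded_by_repertoire(self):
        cons = simulate.gen_consensus(length=1500, seed=9)
        rep = simulate.gen_repertoire(cons, n_guides=50, seed=10)
        t = simulate_lineage(cons, rep, steps=100, seed=12)
        assert (t.n_pirna <= 50).all() and (t.n_pirna >= 0).all()
        assert (t.n_sirna <= t.n_pirna).all()  # stricter rule on same guides


class TestDecayRate:
    def test_constructed_linear_case(self):
        # losing exactly 1 of 1,000 guides per step is 0.1 %/substitution
        n = 1000 - np.arange(101)
        traj = MutagenesisTrajectory(n_pirna=n, n_sirna=n, seed=0)
        d = decay_rate([traj], repertoire_size=1000, guide_class="pirna")
        assert d.slope_of_means == pytest.approx(0.1)
        assert d.mean_of_slopes == pytest.approx(0.1)

    def test_sirna_decays_at_least_as_fast_as_pirna(self):
        cons = simulate.gen_consensus(length=3000, seed=13)
        rep = simulate.gen_repertoire(cons, n_guides=100, seed=14)
        trajs = run_simulations(cons, rep, steps=300, n_simulations=5, seed=15)
        d_pi = decay_rate(trajs, len(rep), "pirna")
        d_si = decay_rate(trajs, len(rep), "sirna")
        assert d_si.slope_of_means >= d_pi.slope_of_means

    def test_planted_loss_matches_analytic_expectation(self):
        # with per-step loss probability p per surviving guide, the expected
        # fraction competent decays as (1 - p)^s; for small p*s the linear
        # slope is ~ p, recovered within Monte-Carlo error
        rng = np.random.default_rng(16)
        p, steps, n_guides, n_sims = 0.002, 100, 400, 60
        trajs = []
        for s in range(n_sims):
            alive = np.ones(n_guides, bool)
            counts = [n_guides]
            for _ in range(steps):
                alive &= rng.random(n_guides) >= p
                counts.append(alive.sum())
            arr = np.array(counts)
            trajs.append(MutagenesisTrajectory(arr, arr, seed=s))
        d = decay_rate(trajs, n_guides, "pirna")
        expected = 100 * (1 - (1 - p) ** steps) / steps  # mean slope of decay
        assert d.slope_of_means == pytest.approx(expected, rel=0.15)
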