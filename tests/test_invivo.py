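"""Degradome analysis tests: filters, quantification, candidates, f_cleaved."""

import numpy as np
import pandas as pd
import pytest

from piwikit import invivo, simulate
from piwikit.invivo import (
    AVOGADRO,
    ConfigurationQuery,
    absolute_quantify,
    bin_by_concentration,
    find_candidates,
    fraction_cleaved,
    group_pirnas,
)
from piwikit.pairing import GuideRNA, complement, reverse_complement


def _pirna_row(prefix, ctrl=2.0, mut=0.01, unique=True,
               n_ctrl=12, n_mut=9):
    row = {"prefix25": prefix, "unique_mapping": unique}
    ctrl = np.broadcast_to(np.asarray(ctrl, float), (n_ctrl,))
    mut = np.broadcast_to(np.asarray(mut, float), (n_mut,))
    for i, v in enumerate(ctrl, 1):
        row[f"control_ppm_{i}"] = v
    for i, v in enumerate(mut, 1):
        row[f"mutant_ppm_{i}"] = v
    return row


class TestGroupPirnas:
    def test_boundary_1ppm_everywhere_retained(self):
        df = pd.DataFrame([_pirna_row("A" * 25, ctrl=1.0)])
        out = group_pirnas(df)
        assert len(out) == 1  # >= threshold is inclusive

    def test_one_low_replicate_drops_group(self):
        ctrl = np.full(12, 2.0)
        ctrl[5] = 0.5
        df = pd.DataFrame([_pirna_row("A" * 25, ctrl=ctrl)])
        assert len(group_pirnas(df)) == 0

    def test_targeted_partition_by_mutant_mean(self):
        df = pd.DataFrame([
            _pirna_row("A" * 25, mut=0.1),    # boundary: still eliminated
            _pirna_row("C" * 25, mut=2.0),    # present in mutant: control set
        ])
        out = group_pirnas(df)
        assert list(out["targeted"]) == [True, False]

    def test_nonunique_mapping_dropped(self):
        df = pd.DataFrame([_pirna_row("A" * 25, unique=False)])
        assert len(group_pirnas(df)) == 0

    def test_matches_literal_rule_application(self, rng):
        rows = []
        for i in range(300):
            ctrl = np.exp(rng.normal(0.3, 1.0, 12))
            mut = np.exp(rng.normal(-2.0, 1.5, 9))
            rows.append(_pirna_row(f"{'ACGU'[i % 4] * 25}"[:25],
                                   ctrl=ctrl, mut=mut,
                                   unique=bool(rng.random() < 0.8)))
        df = pd.DataFrame(rows)
        out = group_pirnas(df)
        ctrl_cols = [f"control_ppm_{i}" for i in range(1, 13)]
        mut_cols = [f"mutant_ppm_{i}" for i in range(1, 10)]
        expected = df[df["unique_mapping"]
                      & (df[ctrl_cols] >= 1.0).all(axis=1)]
        assert len(out) == len(expected)
        assert (out["targeted"].to_numpy()
                == (expected[mut_cols].mean(axis=1) <= 0.1).to_numpy()).all()


class TestAbsoluteQuantify:
    def test_linearity_in_sample_counts(self):
        spikes = pd.Series([100.0, 200.0])
        mol = pd.Series([1e6, 2e6])
        a = absolute_quantify(pd.Series([10.0]), spikes, mol, n_cells=1e3)
        b = absolute_quantify(pd.Series([20.0]), spikes, mol, n_cells=1e3)
        assert b.iloc[0] == pytest.approx(2 * a.iloc[0])

    def test_closed_form_10_molecules_in_1pL(self):
        # calibration: 1 read = 1 molecule; 10 molecules/cell in 1 pL
        out = absolute_quantify(
            pd.Series([10.0]), pd.Series([100.0]), pd.Series([100.0]),
            n_cells=1.0, cell_volume_pL=1.0,
        )
        expect = 10 / (AVOGADRO * 1e-12) * 1e12
        assert out.iloc[0] == pytest.approx(expect)
        assert out.iloc[0] == pytest.approx(16.6, rel=0.01)

    def test_spike_self_quantification_recovers_input(self, rng):
        molecules = pd.Series([1e5, 1e6, 1e7])
        reads_per_molecule = 3e-4
        counts = pd.Series(
            rng.poisson(molecules * reads_per_molecule).astype(float))
        est_molecules = counts * molecules.sum() / counts.sum()
        assert np.allclose(est_molecules, molecules, rtol=0.15)

    def test_zero_spike_recovery_fails(self):
        with pytest.raises(ValueError, match="calibration"):
            absolute_quantify(pd.Series([1.0]), pd.Series([0.0]),
                              pd.Series([100.0]), n_cells=1.0)


def _planted_case(g_end=20, extra_mismatch=()):
    """One transcript with a planted site for a 25-nt guide."""
    rng = np.random.default_rng(99)
    guide = "".join(rng.choice(list("ACGU"), size=25))
    query = ConfigurationQuery(2, g_end, tuple(extra_mismatch))
    window = simulate._plant_site(guide, query, rng)
    left = "".join(rng.choice(list("ACGU"), size=30))
    right = "".join(rng.choice(list("ACGU"), size=30))
    transcript = left + window + right
    coord = len(left) + 25 - 10
    return guide, transcript, coord, query


class TestFindCandidates:
    def _tables(self, guide, coord, targeted=True):
        groups = pd.DataFrame({
            "prefix25": [guide],
            "targeted": [targeted],
            "abundance_pM": [100.0],
        })
        species = pd.DataFrame({
            "species_id": ["sp1"], "transcript": ["tx1"],
            "coordinate": [coord],
            "control_ppm_1": [1.0], "mutant_ppm_1": [1.0],
        })
        return groups, species

    def test_planted_perfect_site_found(self):
        guide, transcript, coord, query = _planted_case(20)
        groups, species = self._tables(guide, coord)
        cands = find_candidates(species, groups, {"tx1": transcript}, [query])
        assert len(cands) == 1
        assert cands.iloc[0]["config_label"] == "g2-g20"
        assert cands.iloc[0]["cumulative_abundance_pM"] == 100.0

    def test_nonoverlap_rule_excludes_wider_query(self):
        # a planted g2-g20 site has g21 unpaired, so g2-g21 never matches
        guide, transcript, coord, _ = _planted_case(20)
        groups, species = self._tables(guide, coord)
        cands = find_candidates(species, groups, {"tx1": transcript},
                                [ConfigurationQuery(2, 21)])
        assert cands.empty

    def test_missing_transcript_skipped_with_log(self):
        guide, transcript, coord, query = _planted_case(18)
        groups, species = self._tables(guide, coord)
        cands = find_candidates(species, groups, {}, [query])
        assert cands.empty
        assert cands.attrs["skipped_species"] == ["sp1"]

    def test_planted_classes_recovered_by_brute_force(self, rng):
        # plant sites across several configuration classes; each must be
        # recovered as exactly its planted class
        queries = [ConfigurationQuery(2, e) for e in (16, 17, 18, 19, 20)]
        queries += [ConfigurationQuery(2, 18, (9,)),
                    ConfigurationQuery(2, 18, (5,))]
        cohort = simulate.gen_degradome(
            queries=tuple(queries), phi=0.5, sites_per_query=15, seed=21,
        )
        groups = group_pirnas(cohort.pirnas)
        cands = find_candidates(cohort.species, groups, cohort.transcripts,
                                queries)
        truth = cohort.truth.set_index("species_id")
        got = cands.groupby("species_id")["config_label"].apply(set)
        assert len(got) == len(truth)
        for sid, labels in got.items():
            assert labels == {truth.loc[sid, "config_label"]}


class TestFractionCleaved:
    def _manual_tables(self):
        """10 targeted sites (6 decreased), 20 control sites (2 decreased)."""
        rows, cands = [], []
        for i in range(10):
            dec = i < 6
            rows.append({
                "species_id": f"t{i}", "transcript": f"txt{i}", "coordinate": 50,
                **{f"control_ppm_{r}": 8.0 for r in range(1, 5)},
                **{f"mutant_ppm_{r}": (1.0 if dec else 8.0) for r in range(1, 5)},
            })
            cands.append({
                "species_id": f"t{i}", "transcript": f"txt{i}", "coordinate": 50,
                "config_label": "g2-g18", "explaining_pirnas": ("p1",),
                "cumulative_abundance_pM": 10.0,
                "explained_by_targeted": True, "explained_by_control": False,
            })
        for i in range(20):
            dec = i < 2
            rows.append({
                "species_id": f"c{i}", "transcript": f"txc{i}", "coordinate": 50,
                **{f"control_ppm_{r}": 8.0 for r in range(1, 5)},
                **{f"mutant_ppm_{r}": (1.0 if dec else 8.0) for r in range(1, 5)},
            })
            cands.append({
                "species_id": f"c{i}", "transcript": f"txc{i}", "coordinate": 50,
                "config_label": "g2-g18", "explaining_pirnas": ("q1",),
                "cumulative_abundance_pM": 10.0,
                "explained_by_targeted": False, "explained_by_control": True,
            })
        return pd.DataFrame(cands), pd.DataFrame(rows)

    def test_worked_arithmetic(self):
        cands, species = self._manual_tables()
        res = fraction_cleaved(cands, species, n_bootstrap=100, seed=0)
        r = res["g2-g18"]
        assert r.f_decreased_targeted == pytest.approx(0.6)
        assert r.f_decreased_control == pytest.approx(0.1)
        assert r.f_cleaved == pytest.approx(0.5)
        assert len(r.per_permutation) == 16

    def test_exactly_8fold_counts_as_decreased(self):
        cands, species = self._manual_tables()
        # set one non-decreased targeted site to exactly 8-fold
        species.loc[species["species_id"] == "t9",
                    [f"mutant_ppm_{r}" for r in range(1, 5)]] = 1.0
        res = fraction_cleaved(cands, species, n_bootstrap=100, seed=0)
        assert res["g2-g18"].f_decreased_targeted == pytest.approx(0.7)

    def test_duplicate_explaining_pirna_does_not_change_f(self):
        cands, species = self._manual_tables()
        dup = cands.iloc[[0]].copy()
        dup["explaining_pirnas"] = [("p1", "p2")]
        cands2 = pd.concat([cands, dup], ignore_index=True)
        a = fraction_cleaved(cands, species, n_bootstrap=100, seed=0)
        b = fraction_cleaved(cands2, species, n_bootstrap=100, seed=0)
        assert a["g2-g18"].f_cleaved == b["g2-g18"].f_cleaved

    def test_zero_mutant_always_decreased(self):
        cands, species = self._manual_tables()
        species.loc[species["species_id"] == "t9",
                    [f"mutant_ppm_{r}" for r in range(1, 5)]] = 0.0
        res = fraction_cleaved(cands, species, n_bootstrap=100, seed=0)
        assert res["g2-g18"].f_decreased_targeted == pytest.approx(0.7)

    def test_exchangeable_sets_give_null_median(self):
        cohort = simulate.gen_degradome(
            queries=(ConfigurationQuery(2, 18),), phi=0.05, background=0.05,
            seed=3,
        )
        groups = group_pirnas(cohort.pirnas)
        cands = find_candidates(cohort.species, groups, cohort.transcripts,
                                [ConfigurationQuery(2, 18)])
        res = fraction_cleaved(cands, cohort.species, n_bootstrap=2000, seed=4)
        r = res["g2-g18"]
        assert r.ci_low <= 0.0 <= r.ci_high


class TestConcentrationBins:
    def test_cumulative_abundance_binning(self):
        cands, species = TestFractionCleaved()._manual_tables()
        # move all targeted sites to 600 pM and controls to both bins
        cands.loc[cands["explained_by_targeted"],
                  "cumulative_abundance_pM"] = 600.0
        cands.loc[~cands["explained_by_targeted"],
                  "cumulative_abundance_pM"] = 600.0
        out = bin_by_concentration(cands, species, n_bootstrap=100, seed=0)
        assert list(out) == [">500"]

    def test_boundary_30pM_lower_inclusive(self):
        cands, species = TestFractionCleaved()._manual_tables()
        cands["cumulative_abundance_pM"] = 30.0
        out = bin_by_concentration(cands, species, n_bootstrap=100, seed=0)
        assert list(out) == ["30-50"]

    def test_abundance_dependent_cleavage_monotone(self):
        # planted cleavage probability rises with piRNA concentration
        def phi(ab_pM):
            return 0.1 if ab_pM < 100 else 0.7

        cohort = simulate.gen_degradome(
            queries=(ConfigurationQuery(2, 18),), phi=phi,
            sites_per_query=250, seed=8,
        )
        groups = group_pirnas(cohort.pirnas)
        cands = find_candidates(cohort.species, groups, cohort.transcripts,
                                [ConfigurationQuery(2, 18)])
        out = bin_by_concentration(cands, cohort.species,
                                   n_bootstrap=200, seed=9)
        f = {b: r["g2-g18"].f_cleaved for b, r in out.items()}
        low = [v for b, v in f.items() if b in ("<30", "30-50", "50-100")]
        high = [v for b, v in f.items() if b in ("100-500", ">500")]
        assert low and high
        assert max(low) < min(high)
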