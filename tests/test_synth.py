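"""Synthetic generators: determinism, planted truth, stage-by-stage recovery."""

import numpy as np
import pytest
from scipy import stats

from lpfoot.gel import estimate_mass, fit_standard_curve, ladder_from_table, mass_to_length
from lpfoot.inference import AnchorHypothesis, call_unmasked_sites, infer_site
from lpfoot.proteins import (
    EpitopeWindow,
    ProteinRecord,
    TaggedConstruct,
    TerminalTag,
    scan_protease_sites,
)
from lpfoot.synth import (
    ConfigurationError,
    make_microscopy_pair,
    make_protein,
    make_scenario,
    plant_sites,
    simulate_digestion,
    simulate_gel,
)


class TestMakeProtein:
    def test_deterministic_from_seed(self):
        a = make_protein(500, seed=42)
        b = make_protein(500, seed=42)
        assert a[0].sequence == b[0].sequence
        assert [iv.name for iv in a[1].intervals] == [iv.name for iv in b[1].intervals]

    def test_kr_density_within_binomial_bounds(self):
        protein, _ = make_protein(1000, kr_density=0.1, seed=7)
        count = sum(protein.sequence.count(c) for c in "KR")
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= count <= hi

    def test_annotation_tiles_sequence(self):
        protein, annotation = make_protein(777, n_domains=5, seed=1)
        assert annotation.length == protein.length
        kinds = [iv.kind for iv in annotation.intervals]
        assert "structured" in kinds and "linker" in kinds

    def test_forbid_kp_makes_every_internal_kr_a_motif(self):
        protein, _ = make_protein(800, kr_density=0.15, seed=3, forbid_kp=True)
        sites = set(scan_protease_sites(protein))
        internal_kr = {
            i + 1
            for i, aa in enumerate(protein.sequence[:-1])
            if aa in "KR"
        }
        assert internal_kr == sites

    def test_infeasible_parameters(self):
        with pytest.raises(ConfigurationError):
            make_protein(30)
        with pytest.raises(ConfigurationError):
            make_protein(500, kr_density=0.5)


class TestSimulateDigestion:
    @pytest.fixture()
    def construct(self):
        protein, _ = make_protein(300, kr_density=0.1, seed=9, forbid_kp=True)
        return TaggedConstruct(
            protein,
            n_tag=TerminalTag("GFP", "N", 27_000.0),
            c_tag=TerminalTag("myc", "C", 1_200.0),
        )

    def test_c_tag_single_site(self, construct):
        site = scan_protease_sites(construct.protein)[3]
        obs = simulate_digestion(
            construct, [site], "c_tag", {site: "membrane"}, timepoints=(15.0,)
        )
        membrane = [o for o in obs if o.condition == "membrane"]
        assert len(membrane) == 1
        L = construct.protein.length
        assert membrane[0].residue_length == L - site
        assert membrane[0].estimated_mass == pytest.approx((L - site) * 110.0 + 1_200.0)
        assert [o for o in obs if o.condition == "cytosol"] == []

    def test_internal_epitope_fragment_selection(self):
        protein = ProteinRecord("t", ("AG" * 49 + "K" + "AG" * 49 + "R" + "AG" * 50)[:300])
        sites = scan_protease_sites(protein)
        assert sites == [99, 198]
        construct = TaggedConstruct(protein)
        obs = simulate_digestion(
            construct, sites, "internal_epitope",
            {s: "membrane" for s in sites},
            epitope=EpitopeWindow(120, 180), timepoints=(15.0,),
        )
        membrane = [o for o in obs if o.condition == "membrane"]
        # only the 100..198 fragment overlaps the epitope
        assert [o.residue_length for o in membrane] == [99]

    def test_no_membrane_only_sites_gives_identical_lanes(self, construct):
        sites = scan_protease_sites(construct.protein)[:3]
        obs = simulate_digestion(
            construct, sites, "c_tag", {s: "both" for s in sites}, timepoints=(15.0,)
        )
        cyt = sorted(o.residue_length for o in obs if o.condition == "cytosol")
        mem = sorted(o.residue_length for o in obs if o.condition == "membrane")
        assert cyt == mem

    def test_non_motif_site_rejected(self, construct):
        non_motif = next(
            i for i in range(2, construct.protein.length)
            if i not in set(scan_protease_sites(construct.protein))
        )
        with pytest.raises(ConfigurationError):
            simulate_digestion(construct, [non_motif], "c_tag", {non_motif: "membrane"})


class TestSimulateGel:
    def test_zero_noise_round_trip(self):
        scenario = make_scenario(seed=4, length=600, site_targets=(100, 250, 400),
                                 detections=("c_tag",))
        ladder, bands = simulate_gel(scenario.observations, scenario.true_curve, 0.0, seed=4)
        curve = fit_standard_curve(ladder_from_table(ladder))
        by_key = {(r.gel_id, r.lane, r.band_id): r.migration for r in bands.itertuples()}
        for obs in scenario.observations:
            est = estimate_mass(curve, by_key[(obs.gel_id, obs.lane, obs.band_id)])
            assert est.mass == pytest.approx(obs.estimated_mass, rel=1e-9)

    def test_ladder_refit_r2_one(self):
        scenario = make_scenario(seed=4, length=600, site_targets=(100,),
                                 detections=("c_tag",))
        ladder, _ = simulate_gel(scenario.observations, scenario.true_curve, 0.02, seed=4)
        assert fit_standard_curve(ladder_from_table(ladder)).r_squared == pytest.approx(1.0)

    def test_one_percent_noise_masses_within_5pct(self):
        scenario = make_scenario(seed=8, length=900, site_targets=(200, 400, 700),
                                 detections=("c_tag",))
        ladder, bands = simulate_gel(scenario.observations, scenario.true_curve, 0.01, seed=8)
        curve = fit_standard_curve(ladder_from_table(ladder))
        by_key = {(r.gel_id, r.lane, r.band_id): r.migration for r in bands.itertuples()}
        for obs in scenario.observations:
            est = estimate_mass(curve, by_key[(obs.gel_id, obs.lane, obs.band_id)])
            assert est.mass == pytest.approx(obs.estimated_mass, rel=0.05)


class TestMicroscopyPair:
    def test_deterministic(self):
        a = make_microscopy_pair(seed=13)
        b = make_microscopy_pair(seed=13)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_golgi_outside_cell_rejected(self):
        with pytest.raises(ConfigurationError):
            make_microscopy_pair(cell_geometry=((64, 64), 20),
                                 golgi_geometry=((10, 10), 8))

    def test_infeasible_fraction(self):
        with pytest.raises(ConfigurationError):
            make_microscopy_pair(planted_fraction=120.0)


class TestEndToEndRecovery:
    def run_pipeline(self, seed, noise):
        scenario = make_scenario(seed=seed, detections=("c_tag",),
                                 migration_noise_sd=noise)
        ladder, bands = simulate_gel(
            scenario.observations, scenario.true_curve, noise, seed=scenario.seed
        )
        curve = fit_standard_curve(ladder_from_table(ladder))
        by_key = {(r.gel_id, r.lane, r.band_id): r.migration for r in bands.itertuples()}
        L = scenario.protein.length
        calls = []
        for obs in scenario.observations:
            if obs.condition != "membrane":
                continue
            est = estimate_mass(curve, by_key[(obs.gel_id, obs.lane, obs.band_id)])
            call = infer_site(
                type(obs)(obs.gel_id, obs.lane, obs.band_id, obs.condition,
                          obs.detection, obs.timepoint, estimated_mass=est.mass),
                AnchorHypothesis("C", L), scenario.construct,
            )
            calls.append(call.position)
        return scenario.planted_sites, calls

    def test_zero_noise_exact_recovery(self):
        planted, calls = self.run_pipeline(seed=21, noise=0.0)
        assert sorted(set(calls)) == planted
        result = call_unmasked_sites([], calls)
        assert [s.position for s in result.sites] == planted

    def test_band_mass_noise_recovery_within_derived_tolerance(self, rng):
        """±2% band-mass error displaces a call by at most the equivalent
        residue count (0.02·mass/110) plus the one-residue rounding quantum."""
        scenario = make_scenario(seed=22, detections=("c_tag",))
        L = scenario.protein.length
        for obs in scenario.observations:
            if obs.condition != "membrane":
                continue
            noisy = obs.estimated_mass * (1.0 + rng.uniform(-0.02, 0.02))
            n = mass_to_length(noisy, scenario.construct, retained_tags=("C",))
            true_site = L - obs.residue_length
            tolerance = 0.02 * noisy / 110.0 + 1.0
            assert abs((L - n) - true_site) <= tolerance

    def test_equal_condition_sets_give_no_unmasked(self):
        scenario = make_scenario(seed=23, detections=("c_tag",))
        for s in scenario.condition_map:
            scenario.condition_map[s] = "both"
        obs = simulate_digestion(
            scenario.construct, scenario.planted_sites, "c_tag",
            scenario.condition_map,
        )
        cyt = [o.residue_length for o in obs if o.condition == "cytosol"]
        mem = [o.residue_length for o in obs if o.condition == "membrane"]
        L = scenario.protein.length
        result = call_unmasked_sites([L - n for n in cyt], [L - n for n in mem])
        assert result.n_sites == 0
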