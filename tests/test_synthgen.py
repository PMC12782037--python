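"""Generator contracts: taxonomy shape, allometric masses, rendering, weighing, OTU tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import norm

from megamorph import synthgen as sg


class TestTaxonomy:
    def test_rank_counts_match_request(self, taxonomy14):
        assert len(taxonomy14) == 14
        assert len({t.genus for t in taxonomy14}) == 13
        assert len({t.family for t in taxonomy14}) == 7
        assert len({t.order for t in taxonomy14}) == 3

    def test_ancestry_is_a_function_of_species(self, taxonomy14):
        by_genus: dict = {}
        for t in taxonomy14:
            assert by_genus.setdefault(t.genus, (t.family, t.order)) == (t.family, t.order)

    def test_degenerate_single_species(self):
        (t,) = sg.generate_taxonomy(1, 1, 1, 1, seed=0)
        assert t.species and t.genus and t.family and t.order

    def test_deterministic_per_seed(self):
        a = sg.generate_taxonomy(3, 2, 2, 1, seed=5)
        b = sg.generate_taxonomy(3, 2, 2, 1, seed=5)
        assert a == b

    def test_invalid_count_ordering_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_taxonomy(3, 4, 2, 1, seed=0)


def _allometry(taxonomy, c=1.0, b=3.0, sigma=0.0, **kw):
    return sg.AllometryParams(
        coeff_mg={t.species: c for t in taxonomy},
        exponent={t.species: b for t in taxonomy},
        sigma_log=sigma,
        **kw,
    )


class TestSpecimens:
    def test_noiseless_power_law_is_exact(self, taxonomy8):
        allom = _allometry(taxonomy8, c=1.0, b=3.0, sigma=0.0)
        lengths = sg.LengthParams({t.species: 2.0 for t in taxonomy8}, sigma_log=0.0)
        sps = sg.generate_specimens(taxonomy8, 2, allom, lengths, seed=0)
        assert all(abs(s.mass_mg - 8.0) < 1e-12 for s in sps)

    def test_log_linear_regression_recovers_parameters(self, taxonomy8):
        # with sigma=0 the generated (L, m) pairs lie exactly on the power law
        allom = _allometry(taxonomy8, c=0.04, b=2.7, sigma=0.0)
        lengths = sg.LengthParams(sg.default_lengths(taxonomy8).median_mm, sigma_log=0.2)
        sps = sg.generate_specimens(taxonomy8, 50, allom, lengths, seed=1)
        one = [s for s in sps if s.taxon == taxonomy8[0]]
        slope, intercept = np.polyfit(
            np.log([s.length_mm for s in one]), np.log([s.mass_mg for s in one]), 1
        )
        assert abs(slope - 2.7) < 1e-9
        assert abs(intercept - np.log(0.04)) < 1e-9

    def test_lognormal_noise_moments(self, taxonomy8):
        sigma = 0.2
        allom = _allometry(taxonomy8, c=0.05, b=2.5, sigma=sigma)
        lengths = sg.LengthParams({t.species: 5.0 for t in taxonomy8}, sigma_log=0.0)
        sps = sg.generate_specimens(taxonomy8[:1], 10_000, allom, lengths, seed=2)
        eps = np.log([s.mass_mg for s in sps]) - (np.log(0.05) + 2.5 * np.log(5.0))
        se = sigma / np.sqrt(len(eps))
        assert abs(eps.mean()) < 3 * se
        assert abs(eps.std() - sigma) < 3 * sigma / np.sqrt(2 * len(eps))

    def test_seeds_differ(self, taxonomy8):
        allom = _allometry(taxonomy8, sigma=0.1)
        lengths = sg.default_lengths(taxonomy8)
        a = sg.generate_specimens(taxonomy8, 3, allom, lengths, seed=0)
        b = sg.generate_specimens(taxonomy8, 3, allom, lengths, seed=1)
        assert any(x.mass_mg != y.mass_mg for x, y in zip(a, b))

    def test_invalid_allometry_rejected(self, taxonomy8):
        with pytest.raises(ValueError):
            _allometry(taxonomy8, c=-1.0)
        with pytest.raises(ValueError):
            _allometry(taxonomy8, b=5.0)


def _specimen(taxon, length=5.0, shape=None, mass=1.0, sid="S0000"):
    shape = shape or sg.ShapeDescriptor(elongation=2.5)
    return sg.SpecimenTruth(sid, taxon, length, mass, shape, 1, "A1")


class TestRendering:
    def test_frame_count_and_camera_split(self, taxonomy8):
        frames = sg.render_frames(_specimen(taxonomy8[0]), 4, (128, 128), 7.0, 0.0, seed=0)
        assert len(frames) == 4
        assert sorted(f.camera_id for f in frames) == [0, 0, 1, 1]

    def test_circle_body_feret_matches_length(self, taxonomy8):
        sp = _specimen(taxonomy8[0], length=5.0, shape=sg.ShapeDescriptor(elongation=1.0))
        frames = sg.render_frames(sp, 2, (96, 96), 10.0, 0.0, seed=1)
        for f in frames:
            pts = np.argwhere(f.pixels < 128).astype(float)
            assert abs(pdist(pts).max() - 50.0) <= 2.0

    def test_elongated_feret_within_two_px_across_rotations(self, taxonomy8):
        shape = sg.ShapeDescriptor(elongation=3.4, n_leg_pairs=3, waist=True, n_cerci=2)
        sp = _specimen(taxonomy8[0], length=8.0, shape=shape)
        frames = sg.render_frames(sp, 10, (128, 128), 9.0, 0.0, seed=2)
        for f in frames:
            pts = np.argwhere(f.pixels < 128).astype(float)
            assert abs(pdist(pts).max() - 72.0) <= 2.0

    def test_single_connected_component(self, taxonomy8):
        from skimage.measure import label

        for i in range(8):
            shape = sg.default_shape_library(taxonomy8)[taxonomy8[i].species]
            sp = _specimen(taxonomy8[i], length=3.0, shape=shape, sid=f"S{i:04d}")
            for f in sg.render_frames(sp, 6, (128, 128), 9.0, 0.0, seed=3):
                lab = label(f.pixels < 128, connectivity=2)
                assert lab.max() == 1

    def test_junk_rate_one_flags_everything(self, taxonomy8):
        frames = sg.render_frames(_specimen(taxonomy8[0]), 6, (128, 128), 7.0, 1.0, seed=0)
        assert all(f.nontarget_truth for f in frames)

    def test_oversize_silhouette_raises_with_required_size(self, taxonomy8):
        with pytest.raises(ValueError, match="S0000.*need at least"):
            sg.render_frames(_specimen(taxonomy8[0], length=30.0), 2, (64, 64), 10.0, 0.0, seed=0)

    def test_render_deterministic(self, taxonomy8):
        sp = _specimen(taxonomy8[0])
        a = sg.render_frames(sp, 4, (128, 128), 7.0, 0.3, seed=9, noise_sd=2.0)
        b = sg.render_frames(sp, 4, (128, 128), 7.0, 0.3, seed=9, noise_sd=2.0)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


class TestWeighing:
    def test_noiseless_rounding(self, taxonomy8):
        allom = _allometry(taxonomy8, readability_mg=0.2, weigh_noise_sd_mg=0.0)
        m = sg.weigh(_specimen(taxonomy8[0], mass=10.0), allom, seed=0)
        assert m == pytest.approx(10.0, abs=1e-12)

    def test_quantized_to_readability(self, taxonomy8):
        allom = _allometry(taxonomy8, readability_mg=0.2, weigh_noise_sd_mg=0.1)
        for i in range(50):
            m = sg.weigh(_specimen(taxonomy8[0], mass=1.0, sid=f"S{i:04d}"), allom, seed=1)
            assert abs(m / 0.2 - round(m / 0.2)) < 1e-9

    def test_negative_readings_match_normal_tail(self, taxonomy8):
        # P(measured <= 0) for m=0.05, sd=0.2 is the Normal tail at -0.25 sd
        allom = _allometry(taxonomy8, readability_mg=0.01, weigh_noise_sd_mg=0.2)
        n = 4000
        neg = sum(
            sg.weigh(_specimen(taxonomy8[0], mass=0.05, sid=f"S{i:04d}"), allom, seed=7) <= 0
            for i in range(n)
        )
        p = norm.cdf((0.005 - 0.05) / 0.2)  # quantization shifts the cut to r/2
        assert abs(neg / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestOTUTable:
    def test_no_failures_means_dominant_matches_truth(self, taxonomy8):
        allom = _allometry(taxonomy8, sigma=0.1)
        sps = sg.generate_specimens(taxonomy8, 3, allom, sg.default_lengths(taxonomy8), seed=5)
        records, ledger = sg.generate_otu_table(
            sps, taxonomy8, sg.ReadParams(), sg.FailureRates(), seed=5
        )
        df = sg.otu_frame(records)
        for sp in sps:
            grp = df[(df.specimen_id == sp.specimen_id) & df.macroinvertebrate]
            top = grp.loc[grp.reads.idxmax()]
            assert top.species == sp.taxon.species
        assert (ledger.injected_status == "ok").all()

    def test_injected_rates_within_binomial_error(self, failure_injection_run):
        _, _, ledger, _ = failure_injection_run
        n = len(ledger)
        for status, p in [("noreads", 0.072), ("mismatch", 0.034), ("nospecies", 0.031)]:
            obs = (ledger.injected_status == status).mean()
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n), status

    def test_repeats_get_two_samples(self, failure_injection_run):
        _, records, ledger, _ = failure_injection_run
        df = sg.otu_frame(records)
        repeated = ledger[ledger.repeat]["specimen_id"]
        assert len(repeated) > 0
        for sid in repeated.head(20):
            assert df[df.specimen_id == sid]["sample_id"].nunique() == 2

    def test_rates_validation(self):
        with pytest.raises(ValueError):
            sg.FailureRates(p_noreads=0.6, p_mismatch=0.5)
        with pytest.raises(ValueError):
            sg.FailureRates(p_noreads=-0.1)

    def test_tables_deterministic(self, taxonomy8):
        allom = _allometry(taxonomy8, sigma=0.1)
        sps = sg.generate_specimens(taxonomy8, 2, allom, sg.default_lengths(taxonomy8), seed=5)
        r1, l1 = sg.generate_otu_table(sps, taxonomy8, sg.ReadParams(), sg.FailureRates(0.1, 0.1, 0.1), seed=4)
        r2, l2 = sg.generate_otu_table(sps, taxonomy8, sg.ReadParams(), sg.FailureRates(0.1, 0.1, 0.1), seed=4)
        assert sg.otu_frame(r1).equals(sg.otu_frame(r2))
        assert l1.equals(l2)
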