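"""Morphometric rules: spines, boutons, Sholl, puncta, densitometry,
stereology."""

import numpy as np
import pytest

from hippoquant import (
    IsotopeMeasurement,
    NeuronTree,
    PunctaImage,
    SpineRecord,
    cavalieri_volume,
    classify_spine,
    coexpression_percent,
    detect_boutons,
    ei_ratio,
    fractionator_count,
    generate_neuron_tree,
    generate_puncta_image,
    generate_spines,
    isotope_ratio,
    optical_density,
    perisomatic_density,
    puncta_count,
    read_swc,
    sholl,
    sholl_bruteforce,
    spine_density,
    write_swc,
)


class TestClassifySpine:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(length_um=0.8, neck_present=False), "stubby"),
            (dict(length_um=1.2, head_diam_um=0.6, neck_len_um=0.35,
                  head_discernible=True, neck_present=True), "mushroom"),
            (dict(length_um=1.7, neck_present=True), "thin"),
            (dict(length_um=1.2, head_discernible=False, neck_present=True), "thin"),
            # boundary conventions: 1.5 um goes to thin, ratio exactly 1.5x
            # satisfies the mushroom rule ("at least")
            (dict(length_um=1.5, neck_present=True), "thin"),
            (dict(length_um=1.2, head_diam_um=0.45, neck_len_um=0.30,
                  head_discernible=True, neck_present=True), "mushroom"),
        ],
    )
    def test_rule_table(self, kw, expected):
        assert classify_spine(SpineRecord(**kw)) == expected

    def test_unclassifiable_geometry(self):
        # short, necked, head too small for the mushroom ratio
        s = SpineRecord(length_um=0.5, head_diam_um=0.2, neck_len_um=0.3,
                        head_discernible=True, neck_present=True)
        assert classify_spine(s) == "unclassified"

    def test_generator_agreement_per_class(self):
        for mix in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            for s in generate_spines(100, mix, seed=3):
                assert classify_spine(s) == s.true_class


class TestSpineDensity:
    def test_uniform_placement(self):
        spines = [SpineRecord(length_um=1.0, position_um=p)
                  for p in np.arange(5.0, 150.0, 5.0)]
        df = spine_density(spines)
        total = df[df.segment == "total"].iloc[0]
        assert total.density_per_um == pytest.approx(29 / 150)

    def test_boundary_half_open(self):
        df = spine_density([SpineRecord(length_um=1.0, position_um=50.0)])
        assert df[df.segment == "50-100"].iloc[0]["count"] == 1
        assert df[df.segment == "0-50"].iloc[0]["count"] == 0

    def test_empty(self):
        df = spine_density([])
        assert (df["count"] == 0).all()

    def test_beyond_bounds_excluded(self):
        df = spine_density([SpineRecord(length_um=1.0, position_um=200.0)])
        assert df["count"].sum() == 0


class TestBoutons:
    def _profile(self, peak_brightness=25.0, peak_width=0.5):
        pos = np.linspace(0, 10, 101)
        bright = np.full(101, 10.0)
        width = np.full(101, 0.2)
        bright[50] = peak_brightness
        width[48:53] = peak_width
        return pos, bright, width

    def test_varicosity_passing_both_criteria(self):
        n, dens, idx = detect_boutons(*self._profile())
        assert n == 1
        assert dens == pytest.approx(0.1)
        assert idx.tolist() == [50]

    def test_dim_varicosity_rejected(self):
        n, _, _ = detect_boutons(*self._profile(peak_brightness=15.0))
        assert n == 0

    def test_narrow_varicosity_rejected(self):
        n, _, _ = detect_boutons(*self._profile(peak_width=0.3))
        assert n == 0

    def test_flat_profile(self):
        pos = np.linspace(0, 12, 50)
        n, dens, _ = detect_boutons(pos, np.full(50, 10.0), np.full(50, 0.2))
        assert (n, dens) == (0, 0.0)

    def test_manual_exclusion_flag(self):
        pos, b, w = self._profile()
        excl = np.zeros(101, dtype=bool)
        excl[50] = True
        n, _, _ = detect_boutons(pos, b, w, excluded=excl)
        assert n == 0

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            detect_boutons(np.linspace(0, 5, 20), np.ones(20), np.ones(20))


class TestSholl:
    def test_straight_cable(self):
        prof = sholl(generate_neuron_tree(0, seed=2), step_um=20)
        assert prof.intersections.tolist() == [1, 1, 1, 1, 1]
        assert prof.total == 5

    def test_bifurcation(self):
        # trunk to 30 um on +x, two branches diverging +-30 deg for 40 um
        rows = [(1, 1, 0, 0, 0, 2.0, -1)]
        rows += [(2, 3, 30.0, 0, 0, 0.5, 1)]
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        rows += [(3, 3, 30 + 40 * c, 40 * s, 0, 0.5, 2)]
        rows += [(4, 3, 30 + 40 * c, -40 * s, 0, 0.5, 2)]
        tree = NeuronTree.from_rows(rows)
        prof = sholl(tree, 20)
        assert prof.intersections.tolist() == [1, 2, 2]
        assert prof.total == 5

    def test_matches_bruteforce_oracle_on_random_trees(self):
        for seed in range(25):
            tree = generate_neuron_tree(
                n_branch_events=seed % 5, step_um=4.0, seed=seed,
                length_um=60 + 10 * (seed % 4),
                jitter_rad=0.35 if seed % 2 else 0.0,
            )
            step = 10.0 if seed % 2 else 20.0
            assert np.array_equal(
                sholl(tree, step).intersections,
                sholl_bruteforce(tree, step).intersections,
            ), f"seed {seed}"

    def test_swc_roundtrip(self, tmp_path):
        tree = generate_neuron_tree(3, seed=9, jitter_rad=0.2)
        path = tmp_path / "tree.swc"
        write_swc(tree, path)
        back = read_swc(path)
        assert np.array_equal(tree.xyz, back.xyz)
        assert np.array_equal(tree.parent, back.parent)
        assert np.array_equal(tree.radius, back.radius)


class TestPunctaCount:
    def test_noiseless_exact(self):
        img, truth = generate_puncta_image(n_puncta=10, noise_sd=0.0, seed=1)
        n, dens = puncta_count(img, threshold=100)
        assert n == 10
        assert dens == pytest.approx(10 / img.field_um2)

    def test_area_filter_excludes_all(self):
        img, truth = generate_puncta_image(n_puncta=5, noise_sd=0.0, seed=2)
        n, _ = puncta_count(img, threshold=100,
                            max_area_um2=truth.area_um2.min() / 10)
        assert n == 0

    def test_zero_puncta(self):
        img, _ = generate_puncta_image(n_puncta=0, seed=3)
        n, dens = puncta_count(img, threshold=100)
        assert (n, dens) == (0, 0.0)

    def test_threshold_monotonicity(self):
        img, _ = generate_puncta_image(n_puncta=8, noise_sd=10.0, seed=4)
        counts = [puncta_count(img, threshold=th, rolling_radius_px=0)[0]
                  for th in (60, 120, 180, 240)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recall_precision_under_noise(self):
        hits, total, found = 0, 0, 0
        for seed in range(5):
            img, truth = generate_puncta_image(n_puncta=10, noise_sd=8.0, seed=seed)
            n, _ = puncta_count(img, threshold=100)
            found += n
            total += len(truth)
            hits += min(n, len(truth))
        assert hits / total == 1.0   # recall
        assert hits / found == 1.0   # precision


class TestEiRatio:
    def test_quotients(self):
        assert ei_ratio(0.6, 0.3) == pytest.approx(2.0)
        assert ei_ratio(0.3, 0.3) == pytest.approx(1.0)
        assert ei_ratio(0.0, 0.3) == 0.0

    def test_zero_inhibitory_rejected(self):
        with pytest.raises(ValueError):
            ei_ratio(0.5, 0.0)


class TestPerisomatic:
    def _image_with_ring_puncta(self, n=8, area_um2=0.5, px_um=0.1):
        # 10x10 um square soma centered in a 20x20 um field; puncta placed
        # on the ring 0.6 um outside the soma edge
        w = int(20 / px_um)
        img = np.full((w, w), 20, dtype=np.uint8)
        soma = np.array([[5.0, 5.0], [15.0, 5.0], [15.0, 15.0], [5.0, 15.0]])
        r_px = int(round(np.sqrt(area_um2 / np.pi) / px_um))
        yy, xx = np.mgrid[0:w, 0:w]
        centers = [(10 + 5.6 * np.cos(a), 10 + 5.6 * np.sin(a))
                   for a in np.linspace(0, 2 * np.pi, n, endpoint=False)]
        # keep only centers within the square ring band
        for cx, cy in centers:
            cx_px, cy_px = cx / px_um, cy / px_um
            img[(yy - cy_px) ** 2 + (xx - cx_px) ** 2 <= r_px**2] = 200
        return PunctaImage(img, px_um), soma, centers

    def test_density_per_perimeter(self):
        img, soma, centers = self._image_with_ring_puncta(n=4)
        # place puncta only on the 4 edge-midpoints (inside the 1.25 um ring)
        dens, frac = perisomatic_density(img, soma, threshold=100)
        assert dens == pytest.approx(4 / 40.0, abs=0.02)
        assert 0 < frac < 0.5

    def test_small_puncta_excluded(self):
        img, soma, _ = self._image_with_ring_puncta(n=4, area_um2=0.05)
        dens, _ = perisomatic_density(img, soma, threshold=100)
        assert dens == 0.0

    def test_large_structure_excluded(self):
        # an elongated 8 x 0.5 um band inside the ring: 4 um^2 > 2.5 um^2
        px_um = 0.1
        w = int(20 / px_um)
        img = np.full((w, w), 20, dtype=np.uint8)
        soma = np.array([[5.0, 5.0], [15.0, 5.0], [15.0, 15.0], [5.0, 15.0]])
        img[int(15.2 / px_um):int(15.7 / px_um),
            int(6.0 / px_um):int(14.0 / px_um)] = 200
        dens, _ = perisomatic_density(PunctaImage(img, px_um), soma, threshold=100)
        assert dens == 0.0

    def test_ring_outside_image_rejected(self):
        img = PunctaImage(np.zeros((50, 50), dtype=np.uint8), 0.1)
        soma = np.array([[0.1, 0.1], [4.0, 0.1], [4.0, 4.0], [0.1, 4.0]])
        with pytest.raises(ValueError):
            perisomatic_density(img, soma, threshold=100)


class TestOpticalDensity:
    def test_closed_form(self):
        img = np.full((10, 10), 128, dtype=np.uint8)
        img[:, 5:] = 255
        roi = np.zeros_like(img, bool)
        roi[:, :5] = True
        od = optical_density(img, roi, ~roi)
        assert od == pytest.approx(np.log10(255 / 128), abs=1e-9)

    def test_equal_rois_zero(self):
        img = np.full((8, 8), 77, dtype=np.uint8)
        m = np.zeros_like(img, bool)
        m[:4] = True
        assert optical_density(img, m, ~m) == pytest.approx(0.0)

    def test_darker_is_denser(self):
        base = np.full((8, 8), 200, dtype=np.uint8)
        white = np.zeros_like(base, bool)
        white[:2] = True
        ods = []
        for grey in (150, 100, 50):
            img = base.copy()
            img[4:] = grey
            roi = np.zeros_like(base, bool)
            roi[4:] = True
            ods.append(optical_density(img, roi, white))
        assert ods[0] < ods[1] < ods[2]


class TestStereology:
    def test_cavalieri_example(self):
        v = cavalieri_volume([0.10, 0.12, 0.11], thickness_um=0.05, series_factor=6)
        assert v == pytest.approx(0.099, abs=1e-12)

    def test_cavalieri_empty_and_linear(self):
        assert cavalieri_volume([]) == 0.0
        v1 = cavalieri_volume([1.0, 2.0])
        assert cavalieri_volume([2.0, 4.0]) == pytest.approx(2 * v1)
        with pytest.raises(ValueError):
            cavalieri_volume([-1.0])

    def test_fractionator(self):
        cells = [{"PV"}] * 6 + [{"PNN"}] * 2 + [{"PV", "PNN"}] * 4
        out = fractionator_count(cells, ["PV", "PNN"], series_factor=6)
        assert out == {"PV": 60, "PNN": 36, "PV+PNN": 24}

    def test_fractionator_empty_and_subset_property(self):
        out = fractionator_count([], ["PV", "PNN"])
        assert out["PV"] == out["PNN"] == out["PV+PNN"] == 0
        cells = [{"PV"}, {"PV", "PNN"}, {"PNN"}]
        out = fractionator_count(cells, ["PV", "PNN"], series_factor=1)
        assert out["PV+PNN"] <= min(out["PV"], out["PNN"])
        with pytest.raises(ValueError):
            fractionator_count([{"GFAP"}], ["PV"])

    def test_isotope_ratio(self):
        ms = [IsotopeMeasurement(50, 10_000, "positive"),
              IsotopeMeasurement(40, 10_000, "negative")]
        assert isotope_ratio(ms) == pytest.approx(1.25)
        scaled = [IsotopeMeasurement(m.n15_counts * 7, m.n14_counts * 7, m.roi_label)
                  for m in ms]
        assert isotope_ratio(scaled) == pytest.approx(1.25)
        with pytest.raises(ValueError):
            isotope_ratio([IsotopeMeasurement(1, 1, "positive")])

    def test_coexpression(self):
        cells = [{"Gad1", "Epor"}] * 49 + [{"Gad1"}] * 21
        assert coexpression_percent(cells, "Gad1", "Epor") == pytest.approx(70.0)
        assert coexpression_percent(cells, "Gad1", "Pvalb") == 0.0
        assert coexpression_percent([{"Gad1", "Epor"}], "Gad1", "Epor") == 100.0
        with pytest.raises(ValueError):
            coexpression_percent(cells, "Sst", "Epor")
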