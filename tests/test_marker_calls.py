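"""Marker classification: cytoplasmic CC3, puncta, gammaH2AX, colocalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import blebquant as bq
from blebquant.marker_calls import (
    MarkerCallError,
    auto_threshold_gh2ax,
    count_puncta,
    ring_owner_map,
)
from blebquant.segmentation import CellGeometry, NucleusLabelMap

from conftest import disk_labels

MPP = 0.4622


def _one_cell_setup(shape=(64, 64), radius=8, width_um=5.0, mpp=MPP):
    labels = disk_labels(shape, [(shape[0] // 2, shape[1] // 2)], [radius])
    counts = np.bincount(labels.ravel())
    label_map = NucleusLabelMap(
        labels, mpp, {1: counts[1] * mpp**2}, {1: (shape[0] / 2, shape[1] / 2)}
    )
    cells = bq.make_cytoplasm_rings(label_map, width_um)
    return label_map, cells


def _add_disk(img, center, radius_px, value):
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2] = value


class TestCytoplasmicCC3:
    def test_threshold_extremes(self):
        _, cells = _one_cell_setup()
        cc3 = np.full((64, 64), 500.0)
        _, pos, _ = bq.classify_cytoplasmic_cc3(cells, cc3, 1e9)
        assert pos == {1: False}
        _, pos, _ = bq.classify_cytoplasmic_cc3(cells, cc3, 0.0)
        assert pos == {1: True}

    def test_empty_ring_flagged_unevaluable(self):
        _, cells = _one_cell_setup()
        empty = CellGeometry(
            label=9,
            nucleus_rc=cells[0].nucleus_rc,
            ring_rc=(np.array([], dtype=int), np.array([], dtype=int)),
            nuclear_area_um2=80.0,
            ring_width_um=3.0,
            centroid=(1.0, 1.0),
            shape=cells[0].shape,
        )
        means, pos, skipped = bq.classify_cytoplasmic_cc3(
            cells + [empty], np.full((64, 64), 500.0), 100.0
        )
        assert skipped == [9]
        assert set(means) == {1}

    def test_diffuse_positives_match_generator_truth_at_midgap_threshold(self):
        # 30% of cells carry diffuse CC3 at 20x background, no puncta
        cfg = bq.SyntheticConfig(
            n_cells=150,
            field_px=(640, 640),
            frac_gh2ax=0.0,
            frac_bleb=0.0,
            frac_coloc=0.0,
            frac_diffuse_cc3=0.3,
            frac_decoy=0.0,
            diffuse_cc3_snr=20.0,
            seed=21,
        )
        field, truth = bq.generate_field(cfg)
        label_map = bq.filter_nuclei_by_area(
            bq.segment_nuclei(field.channels["DAPI"], MPP)
        )
        cells = bq.make_cytoplasm_rings(label_map, 2.0)
        midgap = 0.5 * (cfg.cc3_background + 20.0 * cfg.cc3_background)
        _, pos, _ = bq.classify_cytoplasmic_cc3(cells, field.channels["CC3"], midgap)
        truth_by_seg = {
            lab: truth.diffuse_pos[int(truth.labels[tuple(map(round, label_map.centroids[lab]))])]
            for lab in label_map.label_ids
        }
        assert pos == truth_by_seg


class TestDetectPuncta:
    # a finer pixel pitch so the 0.1 um^2 decoy is super-pixel and the
    # area-filter behaviour is purely geometric
    FINE_MPP = 0.2

    def _setup(self):
        labels = disk_labels((64, 64), [(32, 32)], [8])
        counts = np.bincount(labels.ravel())
        label_map = NucleusLabelMap(
            labels, self.FINE_MPP, {1: counts[1] * self.FINE_MPP**2}, {1: (32.0, 32.0)}
        )
        cells = bq.make_cytoplasm_rings(label_map, 4.0)
        return cells

    def _detect(self, cc3, cells, **kw):
        params = bq.SpotParams(spot_intensity_threshold=4000.0, **kw)
        return bq.detect_cc3_puncta(cells, cc3, params, self.FINE_MPP)

    def test_small_spot_below_min_area_rejected(self):
        cells = self._setup()
        cc3 = np.full((64, 64), 500.0)
        r_small = np.sqrt(0.1 / np.pi) / self.FINE_MPP  # 0.1 um^2
        _add_disk(cc3, (32, 45), r_small, 8000.0)
        assert self._detect(cc3, cells) == []

    def test_large_blob_above_max_area_rejected(self):
        cells = self._setup()
        cc3 = np.full((64, 64), 500.0)
        r_large = np.sqrt(6.0 / np.pi) / self.FINE_MPP  # 6 um^2
        _add_disk(cc3, (32, 48), r_large, 8000.0)
        assert self._detect(cc3, cells) == []

    def test_five_disks_in_ring_all_detected_and_owned(self):
        cells = self._setup()
        cc3 = np.full((64, 64), 500.0)
        r_one = np.sqrt(1.0 / np.pi) / self.FINE_MPP  # ~1 um^2 each
        for ang in np.linspace(0, 2 * np.pi, 5, endpoint=False):
            center = (32 + 12 * np.sin(ang), 32 + 12 * np.cos(ang))
            _add_disk(cc3, center, r_one, 8000.0)
        puncta = self._detect(cc3, cells)
        assert len(puncta) == 5
        assert all(p.cell_label == 1 for p in puncta)
        assert all(0.2 <= p.area_um2 <= 5.0 for p in puncta)

    def test_puncta_outside_rings_ignored(self):
        cells = self._setup()
        cc3 = np.full((64, 64), 500.0)
        _add_disk(cc3, (5, 5), 2.5, 8000.0)  # far outside the ring
        assert self._detect(cc3, cells) == []

    def test_raising_threshold_never_increases_count(self):
        cells = self._setup()
        rng = np.random.default_rng(13)
        cc3 = np.full((64, 64), 500.0) + rng.normal(0, 50, (64, 64))
        for ang in np.linspace(0, 2 * np.pi, 4, endpoint=False):
            amp = rng.uniform(3000, 9000)
            _add_disk(cc3, (32 + 12 * np.sin(ang), 32 + 12 * np.cos(ang)), 2.0, amp)
        counts = []
        for thr in (1000.0, 2500.0, 4000.0, 6000.0, 9500.0):
            params = bq.SpotParams(spot_intensity_threshold=thr)
            counts.append(len(bq.detect_cc3_puncta(cells, cc3, params, self.FINE_MPP)))
        assert counts == sorted(counts, reverse=True)

    def test_invalid_spot_params_rejected(self):
        with pytest.raises(MarkerCallError):
            bq.SpotParams(min_spot_area_um2=5.0, max_spot_area_um2=0.2)
        with pytest.raises(MarkerCallError):
            bq.SpotParams(min_puncta_per_cell=0)


class TestBlebRule:
    @pytest.mark.parametrize("count,expected", [(0, False), (1, False), (2, True), (7, True)])
    def test_two_or_more_puncta_rule(self, count, expected):
        assert bq.classify_cc3_bleb({1: count})[1] is expected

    def test_negative_count_rejected(self):
        with pytest.raises(MarkerCallError):
            bq.classify_cc3_bleb({1: -1})

    @given(st.integers(min_value=0, max_value=12), st.integers(min_value=1, max_value=6))
    def test_raising_min_puncta_never_increases_positives(self, count, min_puncta):
        low = bq.classify_cc3_bleb({1: count}, min_puncta)[1]
        high = bq.classify_cc3_bleb({1: count}, min_puncta + 1)[1]
        assert (not high) or low


class TestGH2AXThreshold:
    def test_bimodal_split_lies_between_modes(self):
        rng = np.random.default_rng(14)
        background = rng.normal(1000, 120, 300)
        positive = rng.normal(20000, 1500, 60)
        thr = auto_threshold_gh2ax(np.concatenate([background, positive]))
        assert background.max() < thr < positive.min()
        calls = np.concatenate([background, positive]) > thr
        assert calls.sum() == 60 and calls[:300].sum() == 0

    def test_unimodal_background_yields_zero_positives(self):
        rng = np.random.default_rng(15)
        values = rng.normal(1000, 120, 400)
        thr = auto_threshold_gh2ax(values)
        assert (values > thr).sum() == 0

    def test_single_value_errors(self):
        with pytest.raises(MarkerCallError):
            auto_threshold_gh2ax([5.0])

    def test_identical_values_yield_zero_positives(self):
        values = np.full(50, 700.0)
        assert (values > auto_threshold_gh2ax(values)).sum() == 0


class TestClassifyGH2AX:
    def test_threshold_above_max_all_negative(self):
        label_map, _ = _one_cell_setup()
        gh2ax = np.full((64, 64), 900.0)
        _, pos = bq.classify_gh2ax(label_map, gh2ax, 1e9)
        assert pos == {1: False}

    def test_pan_nuclear_positives_match_truth(self, default_field):
        field, truth = default_field
        label_map = bq.filter_nuclei_by_area(
            bq.segment_nuclei(field.channels["DAPI"], MPP)
        )
        means, _ = bq.classify_gh2ax(label_map, field.channels["GH2AX"], 0.0)
        thr = auto_threshold_gh2ax(list(means.values()))
        _, pos = bq.classify_gh2ax(label_map, field.channels["GH2AX"], thr)
        mismatches = 0
        for lab in label_map.label_ids:
            true_lab = int(truth.labels[tuple(map(round, label_map.centroids[lab]))])
            if true_lab > 0 and pos[lab] != truth.gh2ax_pos[true_lab]:
                mismatches += 1
        assert mismatches == 0

    def test_raising_threshold_never_increases_positives(self):
        label_map, _ = _one_cell_setup()
        rng = np.random.default_rng(16)
        gh2ax = rng.uniform(0, 10000, (64, 64))
        counts = [
            sum(bq.classify_gh2ax(label_map, gh2ax, thr)[1].values())
            for thr in np.linspace(0, 12000, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestColocalization:
    @pytest.mark.parametrize(
        "gh,bleb,expected", [(True, True, True), (False, True, False), (True, False, False), (False, False, False)]
    )
    def test_truth_table(self, gh, bleb, expected):
        call = bq.CellCall(1, 80.0, 0.0, False, 2, bleb, 0.0, gh)
        (out,) = bq.classify_colocalization([call])
        assert out.coloc_pos is expected

    def test_gating_order_is_irrelevant(self, default_field):
        """Blebbing on all cells then intersecting with gammaH2AX+ equals
        gating gammaH2AX+ cells first and detecting blebbing only there."""
        field, _ = default_field
        label_map = bq.filter_nuclei_by_area(
            bq.segment_nuclei(field.channels["DAPI"], MPP)
        )
        cells = bq.make_cytoplasm_rings(label_map, 3.0)
        params = bq.SpotParams()
        cc3 = field.channels["CC3"]
        means, _ = bq.classify_gh2ax(label_map, field.channels["GH2AX"], 0.0)
        thr = auto_threshold_gh2ax(list(means.values()))
        _, gh_pos = bq.classify_gh2ax(label_map, field.channels["GH2AX"], thr)

        all_counts = count_puncta(bq.detect_cc3_puncta(cells, cc3, params, MPP), cells)
        bleb_all = bq.classify_cc3_bleb(all_counts)
        coloc_a = {lab for lab in bleb_all if bleb_all[lab] and gh_pos[lab]}

        gated_cells = [c for c in cells if gh_pos[c.label]]
        gated_counts = count_puncta(
            bq.detect_cc3_puncta(gated_cells, cc3, params, MPP), gated_cells
        )
        bleb_gated = bq.classify_cc3_bleb(gated_counts)
        coloc_b = {lab for lab in bleb_gated if bleb_gated[lab]}
        assert coloc_a == coloc_b


def test_ring_owner_map_requires_cells():
    with pytest.raises(MarkerCallError):
        ring_owner_map([])
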