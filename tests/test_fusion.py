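import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfuse.fusion import (BASE, NEW, SHARED, FusedWavelengthSet,
                             euclidean_update, fuse_wavelengths, recalibrate)
from specfuse.io import ReferenceTable, SpectraSet
from specfuse.metrics import evaluate
from specfuse.sampling import ks_split
from specfuse.synth import SyntheticConfig, generate_condition

OPEN_FIELD_LIST = [957, 1008, 2339, 920, 2248, 2394, 1137, 1976, 647, 602]
RAIN_SHELTER_LIST = [1257, 962, 905, 1137, 2337, 2300, 1541, 2378, 2386,
                     1947, 1907, 1480, 1058, 2128, 811, 693]
EXPECTED_FUSED = [602, 647, 693, 811, 920, 957, 1008, 1058, 1137, 1257,
                  1480, 1541, 1907, 1976, 2128, 2248, 2300, 2339, 2394]


def brute_force_fusion_oracle(base, new, offset):
    """Independent conflict-resolution oracle: explicit pairwise scan."""
    kept = sorted(set(float(b) for b in base))
    new_kept = []
    for v in map(float, new):
        if any(abs(v - b) < offset for b in kept):
            continue
        if any(abs(v - u) < offset for u in new_kept):
            continue
        new_kept.append(v)
    return sorted(kept + new_kept)


class TestFuseWavelengths:
    def test_reproduces_published_fused_list(self):
        fused = fuse_wavelengths(OPEN_FIELD_LIST, RAIN_SHELTER_LIST, 30)
        assert [int(v) for v in fused.values] == EXPECTED_FUSED

    def test_conflict_resolutions_of_published_lists(self):
        fused = fuse_wavelengths(OPEN_FIELD_LIST, RAIN_SHELTER_LIST, 30)
        removed = {int(v): int(a) for v, a in fused.removed}
        assert removed == {905: 920, 962: 957, 1947: 1976, 2337: 2339,
                           2378: 2394, 2386: 2394, 1137: 1137}

    def test_provenance_labels(self):
        fused = fuse_wavelengths(OPEN_FIELD_LIST, RAIN_SHELTER_LIST, 30)
        by_value = dict(zip(fused.values, fused.provenance))
        assert by_value[1137.0] == SHARED
        assert by_value[957.0] == BASE
        assert by_value[1257.0] == NEW

    def test_self_fusion_is_identity(self):
        fused = fuse_wavelengths(OPEN_FIELD_LIST, OPEN_FIELD_LIST, 30)
        assert list(fused.values) == sorted(set(OPEN_FIELD_LIST))
        assert all(p == SHARED for p in fused.provenance)

    def test_disjoint_lists_union(self):
        fused = fuse_wavelengths([500, 700], [600, 900], 30)
        assert list(fused.values) == [500, 600, 700, 900]
        assert fused.removed == ()

    def test_empty_new_list_idempotent(self):
        once = fuse_wavelengths(OPEN_FIELD_LIST, RAIN_SHELTER_LIST, 30)
        again = fuse_wavelengths(list(once.values), [], 30)
        assert again.values == once.values

    def test_strict_window_boundary(self):
        # exactly offset apart is NOT a repeat (open interval)
        fused = fuse_wavelengths([1000], [1030], 30)
        assert list(fused.values) == [1000, 1030]
        fused = fuse_wavelengths([1000], [1029], 30)
        assert list(fused.values) == [1000]

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        base = data.draw(st.lists(st.integers(400, 2400), min_size=1,
                                  max_size=12, unique=True))
        new = data.draw(st.lists(st.integers(400, 2400), min_size=0,
                                 max_size=12, unique=True))
        fused = fuse_wavelengths(base, new, 30)
        assert list(fused.values) == brute_force_fusion_oracle(base, new, 30)
        # every input is fused or removed-with-anchor
        accounted = set(fused.values) | {v for v, _ in fused.removed}
        assert set(map(float, base)) | set(map(float, new)) <= accounted
        # size bound; equality iff nothing was removed
        assert len(fused) <= len(set(base)) + len(set(new))

    def test_base_list_required(self):
        with pytest.raises(ValueError):
            fuse_wavelengths([], [500], 30)

    def test_json_roundtrip(self):
        fused = fuse_wavelengths(OPEN_FIELD_LIST, RAIN_SHELTER_LIST, 30)
        back = FusedWavelengthSet.from_dict(fused.to_dict())
        assert back == fused


def two_condition_study(seed, n=60, noise_sd=0.005):
    cfg = SyntheticConfig(n_samples=n, grid_step=10.0, noise_sd=noise_sd,
                          seed=seed)
    base_s, base_r = generate_condition(cfg, "open_field")
    new_s, new_r = generate_condition(cfg, "rain_shelter")
    return cfg, (base_s, base_r), (new_s, new_r)


def small_fused(base_s):
    # a handful of on-grid wavelengths spanning the absorption bands
    values = [650.0, 970.0, 1190.0, 1450.0, 1940.0, 2250.0]
    return fuse_wavelengths(values, [], 30)


class TestEuclideanUpdate:
    def test_trace_contract(self):
        _, (base_s, base_r), (new_s, new_r) = two_condition_study(1, n=25)
        fused = small_fused(base_s)
        aug_s, aug_r, trace = euclidean_update(
            base_s, base_r.values, new_s, new_r.values, fused, folds=5)
        assert trace.rmsecv.shape == (25,)
        assert trace.m_star == int(np.argmin(trace.rmsecv)) + 1
        # base samples always retained, in order
        assert aug_s.sample_ids[: base_s.n_samples] == base_s.sample_ids
        assert aug_s.n_samples == base_s.n_samples + trace.m_star

    def test_duplicate_new_samples_leave_trace_flat(self):
        """Exact copies of base samples bring no new information.  On
        noiseless spectra (which PLS fits exactly, so the RMSECV floor is
        numerical zero) the whole trace must stay at that floor."""
        cfg = SyntheticConfig(n_samples=20, grid_step=10.0, noise_sd=0.0,
                              seed=3)
        base_s, base_r = generate_condition(cfg, "open_field")
        copies = SpectraSet(
            tuple(f"copy-{i}" for i in range(20)),
            base_s.wavelengths, base_s.reflectance.copy(),
        )
        fused = small_fused(base_s)
        _, _, trace = euclidean_update(
            base_s, base_r.values, copies, base_r.values, fused, folds=5)
        assert trace.rmsecv.max() < 1e-8

    def test_force_m_zero_recovers_base_set(self):
        _, (base_s, base_r), (new_s, new_r) = two_condition_study(2, n=15)
        fused = small_fused(base_s)
        aug_s, aug_r, trace = euclidean_update(
            base_s, base_r.values, new_s, new_r.values, fused, folds=5,
            force_m=0)
        assert trace.m_star == 0
        assert aug_s.sample_ids == base_s.sample_ids
        assert trace.rmsecv_zero is not None

    def test_mismatched_grids_rejected(self):
        _, (base_s, base_r), (new_s, new_r) = two_condition_study(4, n=10)
        clipped = new_s.select_wavelengths(np.arange(new_s.n_wavelengths - 1))
        fused = small_fused(base_s)
        with pytest.raises(ValueError, match="grid"):
            euclidean_update(base_s, base_r.values, clipped,
                             new_r.values, fused, folds=5)

    def test_off_grid_fused_wavelength_rejected(self):
        _, (base_s, base_r), (new_s, new_r) = two_condition_study(5, n=10)
        fused = fuse_wavelengths([973.5], [], 30)  # not on the 10 nm grid
        with pytest.raises(ValueError, match="not on the grid"):
            euclidean_update(base_s, base_r.values, new_s, new_r.values,
                             fused, folds=5)


class TestRecalibrate:
    def test_zero_added_samples_equals_fusion_only_model(self):
        _, (base_s, base_r), (new_s, new_r) = two_condition_study(6, n=20)
        fused = small_fused(base_s)
        aug_s, aug_r, _ = euclidean_update(
            base_s, base_r.values, new_s, new_r.values, fused, folds=5,
            force_m=0)
        grid = dict(gammas=[100.0], sigma2s=[1.0], folds=5)
        updated = recalibrate(aug_s, aug_r, fused, **grid)
        fusion_only = recalibrate(base_s, base_r, fused, **grid)
        query = new_s.reflectance[:5, aug_s.wavelength_indices(fused.values)]
        np.testing.assert_allclose(updated.predict(query),
                                   fusion_only.predict(query), atol=1e-10)

    def test_updated_model_is_usable_on_both_conditions(self):
        """RPD above 1.4 on held-out samples of both conditions at the
        generator's default noise and shift settings."""
        cfg, (base_s, base_r), (new_s, new_r) = two_condition_study(7, n=80)
        (bc_s, bc_r), (bp_s, bp_r) = ks_split(base_s, base_r, 60)
        (nc_s, nc_r), (np_s, np_r) = ks_split(new_s, new_r, 60)
        fused = small_fused(base_s)
        aug_s, aug_r, trace = euclidean_update(
            bc_s, bc_r.values, nc_s, nc_r.values, fused, folds=5)
        model = recalibrate(aug_s, aug_r, fused, folds=5)
        cols = bp_s.wavelength_indices(fused.values)
        for pred_s, pred_r in ((bp_s, bp_r), (np_s, np_r)):
            report = evaluate(pred_r.values,
                              model.predict(pred_s.reflectance[:, cols]))
            assert report.rpd > 1.4
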