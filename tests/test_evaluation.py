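"""Dice/t-test/island oracles and the phenotype comparison pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from embryoseg import (
    KnockoutSpec,
    LabelVolume,
    PhantomConfig,
    default_phantom_labels,
    dice,
    dice_report,
    generate_cohort,
    group_ttest,
    phenotype_compare,
    remove_islands,
    volume_fraction,
)


def _lab(arr):
    return LabelVolume(np.asarray(arr, dtype=np.int32))


class TestDice:
    def test_closed_forms(self):
        a = np.zeros((4, 4, 4)); b = np.zeros((4, 4, 4))
        a[:1, :2, :2] = 1          # |A| = 4
        b[:2, :2, :2] = 1          # |B| = 8, A subset of B
        assert dice(_lab(a), _lab(b), 1) == pytest.approx(2 * 4 / (4 + 8))
        assert dice(_lab(a), _lab(a), 1) == 1.0
        c = np.zeros((4, 4, 4)); c[3, 3, 3] = 1
        assert dice(_lab(a), _lab(c), 1) == 0.0
        assert dice(_lab(a), _lab(b), 9) == 1.0  # both empty convention

    def test_symmetry_and_set_arithmetic_on_random_masks(self, rng):
        """Dice equals the brute-force set computation and is symmetric."""
        for _ in range(20):
            a = _lab(rng.integers(0, 3, size=(8, 8, 8)))
            b = _lab(rng.integers(0, 3, size=(8, 8, 8)))
            for lid in (1, 2):
                d_ab = dice(a, b, lid)
                d_ba = dice(b, a, lid)
                sa = {tuple(i) for i in np.argwhere(a.data == lid)}
                sb = {tuple(i) for i in np.argwhere(b.data == lid)}
                ref = 1.0 if not sa and not sb else 2 * len(sa & sb) / (len(sa) + len(sb))
                assert d_ab == d_ba
                assert d_ab == pytest.approx(ref, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(_lab(np.zeros((2, 2, 2))), _lab(np.zeros((3, 2, 2))), 1)


class TestDiceReport:
    def test_perfect_and_missing(self, rng):
        ref = _lab(rng.integers(0, 4, size=(8, 8, 8)))
        rep = dice_report(ref, ref, [1, 2, 3])
        assert rep.mean == 1.0
        pred = _lab(np.where(ref.data == 2, 0, ref.data))
        rep2 = dice_report(pred, ref, [1, 2, 3])
        assert rep2.per_label[2] == 0.0

    def test_mean_is_brute_force_mean(self, rng):
        pred = _lab(rng.integers(0, 5, size=(8, 8, 8)))
        ref = _lab(rng.integers(0, 5, size=(8, 8, 8)))
        rep = dice_report(pred, ref, range(1, 5))
        manual = np.mean([dice(pred, ref, l) for l in range(1, 5)])
        assert rep.mean == pytest.approx(manual, abs=1e-12)
        assert rep.n_above(0.8) == sum(v > 0.8 for v in rep.per_label.values())

    def test_exclude_absent_labels(self):
        ref = _lab(np.zeros((4, 4, 4)))
        ref.data[0, 0, 0] = 1
        rep = dice_report(ref, ref, [1, 2], exclude_absent=True)
        assert list(rep.per_label) == [1]
        rep2 = dice_report(ref, ref, [1, 2], exclude_absent=False)
        assert rep2.per_label[2] == 1.0 and rep2.both_empty == [2]


def _flood_fill_components(mask):
    """Independent 26-connected component oracle via BFS."""
    comps = []
    seen = np.zeros_like(mask, dtype=bool)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in offsets:
                q = tuple(np.add(p, off))
                if all(0 <= qi < si for qi, si in zip(q, mask.shape)) and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        comps.append(set(comp))
    return comps


class TestRemoveIslands:
    def test_single_component_unchanged(self):
        arr = np.zeros((6, 6, 6)); arr[2:4, 2:4, 2:4] = 1
        out = remove_islands(_lab(arr), "keep_largest")
        np.testing.assert_array_equal(out.data, arr)

    def test_keep_largest_drops_small(self):
        arr = np.zeros((10, 10, 10))
        arr[:5, :5, :4] = 1            # 100 voxels
        arr[8, 8, 6:9] = 1             # 3 voxels, disconnected
        out = remove_islands(_lab(arr), "keep_largest")
        assert (out.data == 1).sum() == 100
        assert out.data[8, 8, 7] == 0

    def test_min_size_against_flood_fill_oracle(self, rng):
        """min_size removal agrees with a BFS flood-fill oracle on 16^3 masks."""
        for trial in range(5):
            arr = (rng.random((16, 16, 16)) < 0.08).astype(np.int32)
            out = remove_islands(_lab(arr), "min_size", min_size=5)
            comps = _flood_fill_components(arr == 1)
            expected = np.zeros_like(arr)
            for comp in comps:
                if len(comp) >= 5:
                    for p in comp:
                        expected[p] = 1
            np.testing.assert_array_equal(out.data, expected)

    def test_never_increases_or_touches_other_labels(self, rng):
        arr = rng.integers(0, 4, size=(12, 12, 12))
        seg = _lab(arr)
        out = remove_islands(seg, "min_size", min_size=4)
        for lid in (1, 2, 3):
            assert (out.data == lid).sum() <= (arr == lid).sum()
            # removed voxels become background, never another label
            changed = (arr == lid) & (out.data != lid)
            assert np.all(out.data[changed] == 0)


class TestVolumeFraction:
    def test_closed_forms(self):
        arr = np.zeros((10, 10, 10))
        arr[:10, :10, :1] = 1
        assert volume_fraction(_lab(arr), 1) == 100.0
        assert volume_fraction(_lab(arr), 2) == 0.0
        arr2 = np.zeros((10, 10, 10))
        arr2.reshape(-1)[:1000] = 2
        arr2.reshape(-1)[:25] = 1
        assert volume_fraction(_lab(arr2), 1) == pytest.approx(2.5)

    def test_fractions_sum_to_100(self, rng):
        arr = rng.integers(0, 5, size=(8, 8, 8))
        arr[0, 0, 0] = 1  # ensure foreground
        seg = _lab(arr)
        total = sum(volume_fraction(seg, l) for l in range(1, 5))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_zero_foreground_error(self):
        with pytest.raises(ValueError):
            volume_fraction(_lab(np.zeros((4, 4, 4))), 1)


class TestGroupTTest:
    def test_identical_groups(self):
        t, p, sig = group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and not sig

    def test_hand_computed_pooled_formula(self):
        """Student's t from the pooled-variance formula to 1e-9."""
        x = np.array([1.0, 2.0, 3.0])
        y = x + 10.0
        nx = ny = 3
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t_ref = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        t, p, sig = group_ttest(x, y)
        assert abs(t - t_ref) < 1e-9
        assert sig

    def test_matches_t_table(self):
        """p-value consistent with tabulated t quantiles (df=10, t=2.228 -> p=0.05)."""
        from scipy import stats
        # construct two n=6 samples with a known t statistic
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = x + 2.0
        t, p, _ = group_ttest(x, y)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=10), abs=1e-12)

    def test_threshold_semantics_and_errors(self):
        x = [0.0, 0.1, -0.1, 0.05, 0.02, -0.03]
        y = [1.0, 1.1, 0.9, 1.05, 1.02, 0.97]
        _, p, sig = group_ttest(x, y, alpha=0.05)
        assert sig == (p < 0.05)
        with pytest.raises(ValueError):
            group_ttest([1.0], [1.0, 2.0])
        t, p, sig = group_ttest([2.0, 2.0], [2.0, 2.0])
        assert (t, p, sig) == (0.0, 1.0, False)


class TestPhenotypeCompare:
    def test_identical_groups_nothing_significant(self, rng):
        labs = [_lab(rng.integers(0, 4, size=(8, 8, 8))) for _ in range(3)]
        rep = phenotype_compare(labs, labs, [1, 2, 3])
        assert rep.significant_labels() == []

    def test_knockout_cohort_detected(self):
        """A 30% reduction of two small organs is detected on exact labels."""
        cfg = PhantomConfig(shape=(48, 48, 48), n_organs=6, seed=33)
        targets = [5, 6]
        ko = KnockoutSpec({t: 0.7 for t in targets})
        base = [lab for _, lab in generate_cohort(cfg, 8, base_seed=1000)]
        mut = [lab for _, lab in generate_cohort(cfg, 6, ko=ko, base_seed=2000)]
        rep = phenotype_compare(base, mut, default_phantom_labels(6), alpha=0.05)
        sig = set(rep.significant_labels())
        assert set(targets) <= sig
        # knocked-out organs have lower mean fraction in group B
        st = rep.stats.set_index("label")
        for t in targets:
            assert st.loc[t, "mean_b"] < st.loc[t, "mean_a"]

    def test_fraction_table_shape(self, rng):
        labs_a = [_lab(rng.integers(0, 3, size=(6, 6, 6))) for _ in range(2)]
        labs_b = [_lab(rng.integers(0, 3, size=(6, 6, 6))) for _ in range(3)]
        rep = phenotype_compare(labs_a, labs_b, [1, 2])
        assert len(rep.fractions) == (2 + 3) * 2
        per_spec = rep.fractions.groupby(["group", "specimen"])["fraction_pct"].sum()
        assert (per_spec <= 100.0 + 1e-9).all()
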