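"""DSSP class mapping, per-frame probabilities/fractions, boxplots, export."""

import numpy as np
import pandas as pd
import pytest

from mdspectra.fixtures import DSSP_CODES, gen_dssp_xpm
from mdspectra.gromacs_io import XpmMatrix, read_xpm
from mdspectra.secondary_structure import (
    CLASSES,
    ClassificationError,
    SsAssignments,
    boxplot_summary,
    classify_dssp,
    export_fraction_table,
    fraction_per_frame,
    probability_per_frame,
)

CODE_TO_CLASS = {
    "H": "alpha-helix",
    "E": "beta-sheet",
    "~": "coil/loop",
    "T": "turn",
    "S": "bend",
    "G": "3-helix",
}


def _dssp_xpm(rows, x_ticks=None, y_ticks=None):
    """Build a DSSP XpmMatrix from rows of single-char codes."""
    used = sorted({c for r in rows for c in r})
    legend = {c: (CODE_TO_CLASS.get(c, c), None) for c in used}
    return XpmMatrix(
        ncols=len(rows[0]),
        nrows=len(rows),
        chars_per_pixel=1,
        legend=legend,
        codes=[list(r) for r in rows],
        x_ticks=x_ticks,
        y_ticks=y_ticks,
    )


class TestClassifyDssp:
    def test_direct_mapping_one_frame(self):
        # residues on rows (y), one frame on x
        m = _dssp_xpm(["H", "H", "E", "C"])
        a = classify_dssp(m, frames_on_x=True)
        assert a.n_frames == 1 and a.n_residues == 4
        assert list(a.classes[0]) == [
            "alpha-helix",
            "alpha-helix",
            "beta-sheet",
            "coil/loop",
        ]

    def test_all_tilde_is_coil(self):
        a = classify_dssp(_dssp_xpm(["~~~", "~~~"]), frames_on_x=True)
        assert set(a.classes.ravel()) == {"coil/loop"}

    def test_bridge_and_pi_helix_folding(self):
        a = classify_dssp(_dssp_xpm(["B", "I"]), frames_on_x=True)
        assert list(a.classes[0]) == ["beta-sheet", "coil/loop"]

    def test_unmapped_code_lists_it(self):
        m = _dssp_xpm(["HX"])
        with pytest.raises(ClassificationError, match="X"):
            classify_dssp(m)

    def test_orientation_from_ticks(self):
        # 3 frames x 2 residues, frames on x: x ticks longer than y ticks
        m = _dssp_xpm(
            ["HHE", "EEE"],
            x_ticks=np.array([0.0, 1.0, 2.0]),
            y_ticks=np.array([1.0, 2.0]),
        )
        a = classify_dssp(m)
        assert a.n_frames == 3 and a.n_residues == 2
        assert list(a.classes[2]) == ["beta-sheet", "beta-sheet"]
        np.testing.assert_array_equal(a.frame_times, [0.0, 1.0, 2.0])

    def test_fixture_exact_recovery(self, tmp_path):
        truth = gen_dssp_xpm(tmp_path / "s.xpm", seed=5, n_frames=50, n_residues=25)
        a = classify_dssp(read_xpm(tmp_path / "s.xpm"))
        assert (a.n_frames, a.n_residues) == (50, 25)
        counts = np.stack(
            [
                (a.classes == CODE_TO_CLASS[c]).sum(axis=1)
                for c in DSSP_CODES
            ],
            axis=1,
        )
        np.testing.assert_array_equal(counts, truth.counts)


def _random_assignments(rng, n_frames=100, n_residues=30):
    labels = np.array(CLASSES, dtype=object)
    return SsAssignments(labels[rng.integers(0, 6, size=(n_frames, n_residues))])


class TestProbabilityAndFraction:
    def test_probability_arithmetic(self):
        grid = np.array(
            [["alpha-helix"] * 5 + ["coil/loop"] * 35], dtype=object
        )
        p = probability_per_frame(SsAssignments(grid))
        assert p.loc[0, "alpha-helix"] == pytest.approx(12.5)
        f = fraction_per_frame(SsAssignments(grid))
        assert f.loc[0, "alpha-helix"] == pytest.approx(0.125)

    def test_pure_coil_frame(self):
        grid = np.full((1, 7), "coil/loop", dtype=object)
        p = probability_per_frame(SsAssignments(grid))
        assert p.loc[0, "coil/loop"] == 100.0
        assert p.loc[0, [c for c in CLASSES if c != "coil/loop"]].sum() == 0.0

    def test_partition_of_unity(self, rng):
        a = _random_assignments(rng)
        p = probability_per_frame(a)
        f = fraction_per_frame(a)
        np.testing.assert_allclose(p.sum(axis=1), 100.0, atol=1e-9)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_bruteforce_counting(self, rng):
        a = _random_assignments(rng)
        p = probability_per_frame(a)
        for i in range(a.n_frames):
            for s in CLASSES:
                n_is = sum(1 for r in range(a.n_residues) if a.classes[i, r] == s)
                assert p.loc[i, s] == n_is / a.n_residues * 100.0

    def test_fraction_is_probability_over_100(self, rng):
        a = _random_assignments(rng)
        np.testing.assert_allclose(
            fraction_per_frame(a).to_numpy(),
            probability_per_frame(a).to_numpy() / 100.0,
            atol=1e-15,
        )

    def test_residue_permutation_invariance(self, rng):
        a = _random_assignments(rng, n_frames=20, n_residues=15)
        perm = rng.permutation(15)
        b = SsAssignments(a.classes[:, perm])
        pd.testing.assert_frame_equal(
            probability_per_frame(a), probability_per_frame(b)
        )


class TestBoxplotSummary:
    def test_odd_length_quartiles(self):
        st = boxplot_summary(np.array([10.0, 20, 30, 40, 50]))["values"]
        assert (st.median, st.q1, st.q3) == (30.0, 20.0, 40.0)

    def test_constant_series(self):
        st = boxplot_summary(np.full(10, 7.0))["values"]
        assert st.median == st.q1 == st.q3 == 7.0
        assert len(st.outliers) == 0

    def test_outliers_beyond_tukey_fences(self):
        v = np.array([1.0, 2, 3, 4, 5, 100.0])
        st = boxplot_summary(v)["values"]
        assert 100.0 in st.outliers
        assert st.whisker_hi <= 5.0

    def test_matches_sort_and_index_oracle(self, rng):
        v = rng.normal(50, 10, size=1000)
        st = boxplot_summary(v)["values"]
        s = np.sort(v)

        def q(p):  # type-7 linear interpolation
            h = p * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert st.q1 == pytest.approx(q(0.25), abs=1e-12)
        assert st.median == pytest.approx(q(0.5), abs=1e-12)
        assert st.q3 == pytest.approx(q(0.75), abs=1e-12)
        iqr = st.q3 - st.q1
        inside = s[(s >= st.q1 - 1.5 * iqr) & (s <= st.q3 + 1.5 * iqr)]
        assert st.whisker_lo == inside.min()
        assert st.whisker_hi == inside.max()
        assert st.median >= v.min() and st.median <= v.max()


class TestExportFractionTable:
    def test_shape_and_all_classes_present(self, tmp_path, rng):
        a = _random_assignments(rng, n_frames=3)
        xlsx, csv = export_fraction_table(
            {"sim1": fraction_per_frame(a)}, tmp_path / "out"
        )
        df = pd.read_csv(csv)
        assert df.shape == (3, 7)
        assert all(f"sim1: {c}" in df.columns for c in CLASSES)
        assert xlsx.exists()

    def test_csv_roundtrip_precision(self, tmp_path, rng):
        a = _random_assignments(rng, n_frames=30)
        frac = fraction_per_frame(a)
        _, csv = export_fraction_table({"g": frac}, tmp_path / "out")
        back = pd.read_csv(csv)
        for c in CLASSES:
            np.testing.assert_allclose(back[f"g: {c}"], frac[c], atol=1e-9)

    def test_empty_class_column_kept(self, tmp_path):
        grid = np.full((4, 5), "turn", dtype=object)
        frac = fraction_per_frame(SsAssignments(grid))
        _, csv = export_fraction_table({"g": frac}, tmp_path / "out")
        df = pd.read_csv(csv)
        assert (df["g: alpha-helix"] == 0).all()
        assert df.shape[1] == 7
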