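import numpy as np
import pandas as pd
import pytest

from tcburden import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    compute_tcb,
    directional_foldchange,
    generate_longitudinal_reversal,
    longitudinal_course,
    paired_tcb_shift,
    reflected_kde,
)
from tcburden.stratify import DEFAULT_BANDS, GROUP_ORDER


def brute_force_shift(tcb1, tcb2):
    """Direct cutoff lookup: upward band move with both timepoints in a band."""

    def band(x):
        for name in GROUP_ORDER:
            lo, hi = DEFAULT_BANDS[name]
            if lo <= x <= hi:
                return name
        return None

    b1, b2 = band(tcb1), band(tcb2)
    if b1 is None or b2 is None:
        return None  # indeterminate
    return GROUP_ORDER.index(b2) > GROUP_ORDER.index(b1)


def _shift_frame(pairs):
    rows = []
    for i, (t1, t2) in enumerate(pairs):
        rows.append({"sample_id": f"P{i}_a", "subject_id": f"P{i}", "timepoint": "initial"})
        rows.append({"sample_id": f"P{i}_b", "subject_id": f"P{i}", "timepoint": "relapse"})
    meta = SampleTable(table=pd.DataFrame(rows), timepoint_order=["initial", "relapse"])
    tcb = pd.DataFrame(
        {
            "sample_id": [r["sample_id"] for r in rows],
            "tcb": [v for pair in pairs for v in pair],
        }
    )
    return tcb, meta


class TestPairedShift:
    @pytest.mark.parametrize(
        "t1,t2,expected",
        [
            (0.1, 0.5, True),    # low -> mid
            (0.1, 0.9, True),    # low -> high
            (0.5, 0.9, True),    # mid -> high
            (0.1, 0.2, False),   # stays low
            (0.5, 0.1, False),   # downward never counts
            (0.9, 0.1, False),
        ],
    )
    def test_band_movement(self, t1, t2, expected):
        tcb, meta = _shift_frame([(t1, t2)])
        out = paired_tcb_shift(tcb, meta)
        assert bool(out.loc[0, "shifted"]) is expected
        assert out.loc[0, "delta_tcb"] == pytest.approx(t2 - t1)

    def test_excluded_timepoint_is_indeterminate(self):
        tcb, meta = _shift_frame([(0.30, 0.9), (0.1, 0.70)])
        out = paired_tcb_shift(tcb, meta)
        assert out["indeterminate"].all()
        assert not out["shifted"].any()

    def test_matches_brute_force_on_random_pairs(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.uniform(size=(200, 2))]
        tcb, meta = _shift_frame(pairs)
        out = paired_tcb_shift(tcb, meta).set_index("subject_id")
        for i, (t1, t2) in enumerate(pairs):
            expected = brute_force_shift(t1, t2)
            row = out.loc[f"P{i}"]
            if expected is None:
                assert row["indeterminate"] and not row["shifted"]
            else:
                assert bool(row["shifted"]) is expected

    def test_missing_timepoint_dropped_with_warning(self):
        tcb, meta = _shift_frame([(0.1, 0.5)])
        meta.table = meta.table.iloc[:1]  # drop the relapse sample
        with pytest.warns(UserWarning, match="P0"):
            out = paired_tcb_shift(tcb, meta)
        assert out.empty


class TestDirectionalFoldchange:
    def _design(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 2.0, 4.0, 6.0], [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
            index=["G1", "G2"],
            columns=["A_t1", "B_t1", "C_t1", "A_t2", "B_t2", "C_t2"],
        )
        m = ExpressionMatrix(values=values, scale="log2")
        meta = SampleTable(
            table=pd.DataFrame(
                {
                    "sample_id": values.columns,
                    "subject_id": ["A", "B", "C"] * 2,
                    "timepoint": ["t1"] * 3 + ["t2"] * 3,
                }
            ),
            timepoint_order=["t1", "t2"],
        )
        sets = GeneSetCollection(sets={"pw": ["G1", "G2"]}, category_map={"pw": "cat"})
        shifts = pd.DataFrame(
            {"subject_id": ["A", "B", "C"], "shifted": [True, True, True],
             "indeterminate": [False, False, False]}
        )
        return m, meta, sets, shifts

    def test_mean_over_subjects(self):
        m, meta, sets, shifts = self._design()
        fc = directional_foldchange(m, meta, shifts, sets)
        g1 = fc[(fc["gene_id"] == "G1") & (fc["subset"] == "shifted")].iloc[0]
        assert g1["log2fc"] == pytest.approx(2.0)  # deltas 1, 2, 3
        g2 = fc[(fc["gene_id"] == "G2") & (fc["subset"] == "all")].iloc[0]
        assert g2["log2fc"] == 0.0

    def test_empty_subset_omitted(self):
        m, meta, sets, shifts = self._design()
        fc = directional_foldchange(m, meta, shifts, sets)
        assert "not_shifted" not in set(fc["subset"])

    def test_dataset_against_itself_is_zero(self):
        m, meta, sets, shifts = self._design()
        same = m.values.copy()
        same[["A_t2", "B_t2", "C_t2"]] = same[["A_t1", "B_t1", "C_t1"]].to_numpy()
        fc = directional_foldchange(ExpressionMatrix(values=same, scale="log2"),
                                    meta, shifts, sets)
        assert np.allclose(fc["log2fc"], 0.0)


class TestKdeAndCourse:
    def test_reflected_kde_integrates_to_one(self, rng):
        grid, dens = reflected_kde(rng.beta(0.5, 0.5, size=500))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_boundary_mass_not_leaked(self, rng):
        # half the mass piled at 0: a plain Gaussian KDE would lose ~25%
        x = np.concatenate([np.zeros(300), rng.uniform(size=300)])
        grid, dens = reflected_kde(x)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_longitudinal_course_extracts_deltas(self):
        m, meta, truth, _ = generate_longitudinal_reversal(
            n_subjects=3, n_genes=50, noise_sd=0.0, seed=3
        )
        course, density = longitudinal_course(m, meta)
        assert set(course["subject_id"]) == {"SUBJ000", "SUBJ001", "SUBJ002"}
        deltas = course["delta_tcb"].dropna()
        assert (deltas <= 0).all()
        for _, sub in density.groupby("timepoint"):
            assert np.trapezoid(sub["density"], sub["grid"]) == pytest.approx(1.0, abs=1e-3)

    def test_single_timepoint_subject_excluded(self):
        m, meta, _, _ = generate_longitudinal_reversal(n_subjects=3, n_genes=50, seed=3)
        meta.table = meta.table[~((meta.table.subject_id == "SUBJ000")
                                  & (meta.table.timepoint != "day0"))]
        with pytest.warns(UserWarning, match="SUBJ000"):
            course, _ = longitudinal_course(m, meta)
        assert "SUBJ000" not in set(course["subject_id"])

    def test_identical_timepoints_give_zero_deltas(self):
        base = np.random.default_rng(0).normal(8, 1, size=(20, 3))
        values = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"G{i}" for i in range(20)],
            columns=[f"SUBJ{j}_t{t}" for t in (0, 1) for j in range(3)],
        )
        m = ExpressionMatrix(values=values, scale="log2")
        meta = SampleTable(
            table=pd.DataFrame(
                {
                    "sample_id": values.columns,
                    "subject_id": [f"SUBJ{j}" for j in range(3)] * 2,
                    "timepoint": ["t0"] * 3 + ["t1"] * 3,
                }
            ),
            timepoint_order=["t0", "t1"],
        )
        course, density = longitudinal_course(m, meta)
        assert np.allclose(course["delta_tcb"].dropna(), 0.0)
        d0 = density[density.timepoint == "t0"]["density"].to_numpy()
        d1 = density[density.timepoint == "t1"]["density"].to_numpy()
        assert np.allclose(d0, d1)
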