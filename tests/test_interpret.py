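"""Z-scores, heat-map assembly, t-test tables, differential reporting."""

import numpy as np
import pytest

from metadx import (
    FeatureTable,
    Group,
    SampleMeta,
    SimConfig,
    build_heatmap,
    fit_oplsda,
    generate_cohort,
    render_table1,
    select_identified,
    standard_scores,
    truncate_scores,
    ttest_table,
)
from metadx.datamodel import groups_for
from metadx.simulate import Contrast, Direction, default_effects

from _oracles import pooled_ttest, zscores_vs_reference


def _small_table():
    # controls at (1, 3), one RA sample at 4
    return (
        FeatureTable(["C1", "C2", "R1"], ["Met"], [[1.0], [3.0], [4.0]], [True], ["GC"]),
        [
            SampleMeta("C1", Group.CONTROL, "s"),
            SampleMeta("C2", Group.CONTROL, "s"),
            SampleMeta("R1", Group.RA, "s"),
        ],
    )


class TestStandardScores:
    def test_hand_arithmetic(self):
        table, meta = _small_table()
        z = standard_scores(table, meta, reference=Group.CONTROL)
        assert z[2, 0] == pytest.approx(2.0 / np.sqrt(2.0))
        assert z[0, 0] == pytest.approx(-1.0 / np.sqrt(2.0))

    def test_reference_mean_sample_scores_zero(self):
        table, meta = _small_table()
        z = standard_scores(table, meta, reference=Group.CONTROL)
        # mean of z over the reference samples is 0 by construction
        assert abs(z[:2, 0].mean()) < 1e-10

    def test_matches_naive_oracle_on_random_tables(self, rng):
        X = rng.lognormal(size=(12, 7))
        ids = [f"M{j}" for j in range(7)]
        table = FeatureTable([f"S{i}" for i in range(12)], ids, X, [True] * 7, ["GC"] * 7)
        meta = [SampleMeta(f"S{i}", Group.CONTROL if i < 5 else Group.RA, "s") for i in range(12)]
        z = standard_scores(table, meta, reference=Group.CONTROL)
        np.testing.assert_allclose(z, zscores_vs_reference(X, np.arange(5)), atol=1e-12)
        assert np.max(np.abs(z[:5].mean(axis=0))) < 1e-10

    def test_zero_reference_sd_warns(self):
        table = FeatureTable(["C1", "C2", "R1"], ["Met"], [[2.0], [2.0], [5.0]], [True], ["GC"])
        meta = _small_table()[1]
        with pytest.warns(UserWarning, match="zero reference SD"):
            z = standard_scores(table, meta, reference=Group.CONTROL)
        assert np.all(z == 0)


class TestTruncateScores:
    @pytest.mark.parametrize("value,expected", [(3.5, 2.0), (-2.7, -2.0), (1.3, 1.3), (-2.0, -2.0)])
    def test_clamping(self, value, expected):
        assert truncate_scores(np.array([value]), limit=2.0)[0] == expected

    def test_limit_must_be_positive(self):
        with pytest.raises(ValueError):
            truncate_scores(np.zeros(3), limit=0.0)


@pytest.fixture(scope="module")
def fitted():
    table, meta = generate_cohort(SimConfig(seed=8))
    keep = [m.sample_id for m in meta if m.group in (Group.RA, Group.CONTROL)]
    sub = select_identified(table.subset_samples(keep))
    sub_meta = [m for m in meta if m.sample_id in set(keep)]
    model = fit_oplsda(sub.intensities, groups_for(sub, sub_meta))
    return sub, sub_meta, model


class TestBuildHeatmap:
    def test_columns_sorted_by_pcorr(self, fitted):
        sub, sub_meta, model = fitted
        heat = build_heatmap(sub, sub_meta, model, reference=Group.CONTROL)
        assert np.all(np.diff(heat.pcorr) >= 0)
        by_id = dict(zip(sub.metabolite_ids, model.pcorr_))
        assert heat.metabolite_ids == sorted(sub.metabolite_ids, key=lambda m: by_id[m])

    def test_entries_within_limit_and_rows_grouped(self, fitted):
        sub, sub_meta, model = fitted
        heat = build_heatmap(sub, sub_meta, model, reference=Group.CONTROL, limit=2.0)
        assert np.all(np.abs(heat.z) <= 2.0)
        # reference block first, disease block after
        assert heat.sample_groups[:9] == ["control"] * 9
        assert heat.sample_groups[9:] == ["RA"] * 21

    def test_psoa_reference_convention(self):
        table, meta = generate_cohort(SimConfig(seed=8))
        keep = [m.sample_id for m in meta if m.group in (Group.RA, Group.PSOA)]
        sub = select_identified(table.subset_samples(keep))
        sub_meta = [m for m in meta if m.sample_id in set(keep)]
        model = fit_oplsda(sub.intensities, groups_for(sub, sub_meta))
        heat = build_heatmap(sub, sub_meta, model, reference=Group.PSOA)
        assert heat.sample_groups[:17] == ["PsoA"] * 17
        z = standard_scores(sub, sub_meta, reference=Group.PSOA)
        # PsoA rows average to zero against their own mean before truncation
        psoa_rows = [i for i, m in enumerate(sub.sample_ids) if m.startswith("P")]
        assert np.max(np.abs(z[psoa_rows].mean(axis=0))) < 1e-10


class TestTtestTable:
    def test_worked_example_against_oracle(self):
        table = FeatureTable(
            [f"S{i}" for i in range(6)], ["Met"],
            np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]]), [True], ["GC"],
        )
        meta = [SampleMeta(f"S{i}", Group.RA if i < 3 else Group.CONTROL, "s") for i in range(6)]
        (report,) = ttest_table(table, meta)
        assert report.t_stat == pytest.approx(-1.2247, abs=1e-4)
        assert report.p_value == pytest.approx(0.2879, abs=1e-4)
        assert report.direction == "decreased"
        t_ref, p_ref = pooled_ttest([1, 2, 3], [2, 3, 4])
        assert report.t_stat == pytest.approx(t_ref, abs=1e-12)
        assert report.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_null(self):
        table = FeatureTable(
            ["a", "b", "c", "d"], ["Met"], np.array([[1.0], [2.0], [1.0], [2.0]]), [True], ["GC"]
        )
        meta = [SampleMeta(s, Group.RA if s in "ab" else Group.CONTROL, "s") for s in "abcd"]
        (report,) = ttest_table(table, meta)
        assert report.t_stat == pytest.approx(0.0, abs=1e-12)
        assert report.p_value == pytest.approx(1.0)

    def test_random_groups_match_oracle(self, rng):
        for _ in range(200):
            na, nb = rng.integers(3, 9), rng.integers(3, 9)
            a, b = rng.normal(size=na), rng.normal(2, 1, size=nb) ** 2 + 0.01
            X = np.concatenate([a - a.min() + 0.01, b]).reshape(-1, 1)
            table = FeatureTable([f"S{i}" for i in range(na + nb)], ["M"], X, [True], ["GC"])
            meta = [SampleMeta(f"S{i}", Group.RA if i < na else Group.CONTROL, "s")
                    for i in range(na + nb)]
            (rep,) = ttest_table(table, meta)
            t_ref, p_ref = pooled_ttest(X[:na, 0], X[na:, 0])
            assert rep.t_stat == pytest.approx(t_ref, abs=1e-12)
            assert rep.p_value == pytest.approx(p_ref, abs=1e-12)
            assert np.sign(rep.t_stat) == np.sign(X[:na].mean() - X[na:].mean())

    def test_planted_marker_direction_recovered(self):
        hits = 0
        for seed in range(10):
            table, meta = generate_cohort(SimConfig(seed=300 + seed))
            keep = [m.sample_id for m in meta if m.group in (Group.RA, Group.CONTROL)]
            sub = table.subset_samples(keep)
            sub_meta = [m for m in meta if m.sample_id in set(keep)]
            reports = {r.metabolite_id: r for r in ttest_table(sub, sub_meta)}
            hits += reports["Histidine"].direction == "decreased"
        assert hits >= 9

    def test_zero_variance_metabolite_warns(self):
        table = FeatureTable(
            ["a", "b", "c", "d"], ["Met"], np.full((4, 1), 3.0), [True], ["GC"]
        )
        meta = [SampleMeta(s, Group.RA if s in "ab" else Group.CONTROL, "s") for s in "abcd"]
        with pytest.warns(UserWarning, match="zero pooled variance"):
            (rep,) = ttest_table(table, meta)
        assert (rep.t_stat, rep.p_value) == (0.0, 1.0)


class TestRenderTable1:
    def test_empty_report_renders(self):
        out = render_table1([], alpha=0.05)
        assert out["increased"] == [] and out["decreased"] == []

    def test_threshold_boundary(self):
        from metadx.interpret import MetaboliteReport

        r = MetaboliteReport("X", 5.0, 1.0, 3.0, 1.0, 2.2, 0.049, "increased", True)
        out = render_table1([r], alpha=0.05)
        assert [e["metabolite_id"] for e in out["increased"]] == ["X"]
        assert render_table1([r], alpha=0.04)["increased"] == []

    def test_planted_markers_recovered_with_direction(self):
        recovered = []
        panel = {e.metabolite_id: e.direction
                 for e in default_effects() if e.contrast is Contrast.RA_VS_CONTROL}
        for seed in range(9):
            table, meta = generate_cohort(SimConfig(seed=700 + seed))
            keep = [m.sample_id for m in meta if m.group in (Group.RA, Group.CONTROL)]
            sub = table.subset_samples(keep)
            sub_meta = [m for m in meta if m.sample_id in set(keep)]
            out = render_table1(ttest_table(sub, sub_meta))
            n_ok = 0
            for name, direction in panel.items():
                section = "increased" if direction is Direction.INCREASED else "decreased"
                n_ok += name in {e["metabolite_id"] for e in out[section]}
            recovered.append(n_ok)
        assert np.median(recovered) >= 7
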