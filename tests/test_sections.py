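"""Free-body section moments: decomposition arithmetic, printed-table
reproduction, equilibrium equivalence, isometric scaling."""

import numpy as np
import pandas as pd
import pytest

from mandiflex import fem, loads, sections
from mandiflex import geometry as geo


@pytest.fixture(scope="module")
def healthy_solution(healthy_mesh):
    sys_ = fem.assemble_system(healthy_mesh)
    lc = loads.build_load_case(chew_side="left")
    csys = fem.apply_constraints(sys_, lc)
    sol = fem.solve_static(csys, f=fem.build_load_vector(sys_, lc))
    return sol, lc


class TestMomentContribution:
    def test_single_cross_product_term(self):
        M, (fx_dz, fz_dx, my) = sections.moment_contribution(
            (10.0, 0, 0), (0, 0, 5.0), (0, 0, 0))
        assert my == pytest.approx(0.05)
        assert M[1] == pytest.approx(0.05)
        assert M[0] == pytest.approx(0.0) and M[2] == pytest.approx(0.0)

    def test_printed_decomposition_row(self):
        # Rt posterior temporalis: Fx*dz = -0.91, Fz*dx = -0.07 => My = -0.84
        assert -0.91 - (-0.07) == pytest.approx(-0.84)

    def test_matches_brute_force_cross_product(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            F = rng.normal(size=3) * 50
            pt = rng.normal(size=3) * 40
            c = rng.normal(size=3) * 40
            M, (fx_dz, fz_dx, my) = sections.moment_contribution(F, pt, c)
            r = pt - c
            brute = np.array([r[1] * F[2] - r[2] * F[1],
                              r[2] * F[0] - r[0] * F[2],
                              r[0] * F[1] - r[1] * F[0]]) / 1000.0
            assert np.allclose(M, brute)
            assert my == pytest.approx(fx_dz - fz_dx)
            assert my == pytest.approx(brute[1])


class TestPrintedMomentTable:
    """The packaged cross-species twisting-moment table is arithmetically
    self-consistent at printed precision."""

    def test_my_column_within_printed_rounding(self):
        t3 = loads.load_section_moment_table()
        body = t3[t3.load != "summed torques"]
        for sp in ("macaque", "human"):
            got = body[f"{sp}_fx_dz"] - body[f"{sp}_fz_dx"]
            assert np.all(np.abs(got - body[f"{sp}_my"]) <= 0.02 + 1e-12), sp

    def test_macaque_summed_row_exact_at_2dp(self):
        t3 = loads.load_section_moment_table()
        body = t3[t3.load != "summed torques"]
        summed = t3[t3.load == "summed torques"].iloc[0]
        for col in ("fx_dz", "fz_dx", "my"):
            assert round(body[f"macaque_{col}"].sum(), 2) == pytest.approx(
                summed[f"macaque_{col}"])

    def test_human_summed_row_within_rounding_propagation(self):
        # the printed human summed row was computed before rounding the
        # per-load cells; 7 cells rounded to +-0.005 bound the difference
        t3 = loads.load_section_moment_table()
        body = t3[t3.load != "summed torques"]
        summed = t3[t3.load == "summed torques"].iloc[0]
        for col in ("fx_dz", "fz_dx", "my"):
            got = body[f"human_{col}"].sum()
            assert abs(got - summed[f"human_{col}"]) <= 0.005 * len(body) + 1e-12

    def test_cited_ratio_cells(self):
        t3 = loads.load_section_moment_table().set_index("load")
        condyle = t3.loc["Rt condyle"]
        assert round(condyle.human_my / condyle.macaque_my, 2) == 3.61
        bite = t3.loc["Lt P3-M1 bite force"]
        assert abs(bite.human_my / bite.macaque_my - 1.10) <= 0.02
        summed = t3.loc["summed torques"]
        assert round(summed.human_my / summed.macaque_my, 2) == 2.47


class TestSections:
    def test_thirty_equidistant_monotone(self, healthy_mesh):
        secs = sections.make_sections(healthy_mesh, "left_hemimandible", 30)
        assert len(secs) == 30
        pos = [s.origin[1] for s in secs]
        assert np.all(np.diff(pos) > 0)
        gaps = np.diff(pos)
        assert np.allclose(gaps, gaps[0])
        for s in secs:
            assert s.centroid[1] == pytest.approx(s.origin[1])

    def test_single_section(self, healthy_mesh):
        secs = sections.make_sections(healthy_mesh, "symphysis", 1)
        assert len(secs) == 1

    def test_uniform_bar_centroids_on_axis(self):
        bar = geo.box_mesh(4.0, 30.0, 4.0, 1.0)
        bar.params = None
        secs = sections.make_sections(bar, "symphysis", 5)  # z-axis slicing
        for s in secs:
            assert s.centroid[0] == pytest.approx(2.0, abs=1e-6)
            assert s.centroid[1] == pytest.approx(15.0, abs=1e-6)

    def test_invalid_inputs(self, healthy_mesh):
        with pytest.raises(sections.SectionError):
            sections.make_sections(healthy_mesh, "left_hemimandible", 0)
        with pytest.raises(sections.SectionError):
            sections.make_sections(healthy_mesh, "maxilla", 3)


class TestSectionMoments:
    def test_summed_row_equals_column_sums_and_my_identity(
            self, healthy_mesh, healthy_solution):
        sol, lc = healthy_solution
        secs = sections.make_sections(healthy_mesh, "left_hemimandible", 10)
        tab = sections.section_moments(sol, lc, secs)
        df = tab.df
        for idx in df.section.unique():
            sub = df[(df.section == idx) & (df.load != "summed")]
            tot = df[(df.section == idx) & (df.load == "summed")].iloc[0]
            for col in ("Mx", "My", "Mz", "fx_dz", "fz_dx"):
                assert tot[col] == pytest.approx(sub[col].sum(), abs=1e-12)
            assert np.allclose(sub.My, sub.fx_dz - sub.fz_dx)

    def test_equilibrium_equivalence_anterior_vs_posterior(
            self, healthy_mesh, healthy_solution):
        """Moments of loads anterior to each plane equal minus the moments
        of the posterior loads (global equilibrium), within 1e-6 relative."""
        sol, lc = healthy_solution
        secs = sections.make_sections(healthy_mesh, "left_hemimandible", 8)
        ant = sections.section_moments(sol, lc, secs, side="anterior")
        post = sections.section_moments(sol, lc, secs, side="posterior")
        Ma = ant.summed()[["Mx", "My", "Mz"]].to_numpy()
        Mp = post.summed()[["Mx", "My", "Mz"]].to_numpy()
        scale = np.abs(Ma).max()
        assert np.abs(Ma + Mp).max() < 1e-6 * scale

    def test_left_section_excludes_left_posterior_loads(
            self, healthy_mesh, healthy_solution):
        """At a coronal section through the left M2, the free body contains
        the right-side muscles, the right condyle and the left bite
        reaction, but no left muscle or left condyle."""
        sol, lc = healthy_solution
        y_m2 = dict(healthy_mesh.params.tooth_landmarks)["M2"]
        sec = sections.SectionSpec("left_hemimandible", 1,
                                   (0.0, y_m2, 0.0), (0.0, 1.0, 0.0),
                                   (-50.0, y_m2, 45.0))
        tab = sections.section_moments(sol, lc, [sec])
        names = set(tab.df.load) - {"summed"}
        assert "condyle R" in names and "bite L" in names
        assert "condyle L" not in names
        assert not any(n.endswith(" L") and "bite" not in n for n in names)
        assert "anterior temporalis R" in names

    def test_section_anterior_to_all_loads_zero_moments(
            self, healthy_mesh, healthy_solution):
        sol, lc = healthy_solution
        sec = sections.SectionSpec("left_hemimandible", 1,
                                   (0.0, 500.0, 0.0), (0.0, 1.0, 0.0),
                                   (0.0, 500.0, 45.0))
        tab = sections.section_moments(sol, lc, [sec])
        tot = tab.summed()[["Mx", "My", "Mz"]].to_numpy()
        assert np.abs(tot).max() == 0.0


def test_scale_moments():
    df = pd.DataFrame(dict(section=[1], load=["summed"], Fx=[1.0], Fy=[0.0],
                           Fz=[0.0], dx=[0.0], dy=[0.0], dz=[0.0],
                           fx_dz=[2.0], fz_dx=[0.5], Mx=[1.0], My=[1.5],
                           Mz=[-2.0]))
    tab = sections.SectionMomentTable(df=df, sections=[])
    assert sections.scale_moments(tab, 1.0).df.My[0] == pytest.approx(1.5)
    assert sections.scale_moments(tab, 1.5).df.My[0] == pytest.approx(
        1.5 * 3.375)
    assert sections.scale_moments(tab, 2.0).df.Mz[0] == pytest.approx(-16.0)
    s = loads.isometric_scale_factors(1.0, 1.5)
    assert round(s.moment, 2) == 3.38


def test_compare_tables_ratios_and_nan():
    a = pd.DataFrame(dict(x=[3.62, -0.76, 0.0]))
    b = pd.DataFrame(dict(x=[13.08, -0.84, 1.0]))
    r = sections.compare_tables(a, b)
    assert round(r.x[0], 2) == 3.61
    assert round(r.x[1], 2) == pytest.approx(1.11, abs=0.01)
    assert np.isnan(r.x[2])
    same = sections.compare_tables(b, b)
    assert np.allclose(same.x[:2], 1.0)
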