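"""Phylomorphospace projection, minimum ellipse and disparity statistics."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import radnull as rn
from radnull.morphospace import DegenerateMorphospaceError

from conftest import dense_gls_ancestral_oracle


def _traits_for(tree, rng):
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return pd.DataFrame(rng.standard_normal((len(labels), 2)),
                        index=labels, columns=["shape", "size"])


class TestAncestralStates:
    def test_cherry_root_is_midpoint(self):
        t = rn.parse_tree("(A:1,B:1);")
        proj = rn.ancestral_states_bm(
            t, pd.DataFrame({"x": [0.0, 2.0], "y": [0.0, 2.0]},
                            index=["A", "B"]))
        root = proj.coords[0]
        assert root == pytest.approx([1.0, 1.0])

    def test_star_tree_root_is_mean(self):
        t = rn.parse_tree("(A:1,B:1,C:1,D:1,E:1);")
        y = np.array([0.5, 1.0, 2.0, 3.5, 8.0])
        proj = rn.ancestral_states_bm(
            t, pd.DataFrame({"x": y, "y": y},
                            index=["A", "B", "C", "D", "E"]))
        assert proj.coords[0, 0] == pytest.approx(y.mean())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rn.simulate_yule_tree(int(rng.integers(4, 9)), rng)
        traits = _traits_for(t, rng)
        proj = rn.ancestral_states_bm(t, traits)
        for j, col in enumerate(traits.columns):
            beta, states = dense_gls_ancestral_oracle(
                t, traits[col].to_dict())
            assert proj.coords[0, j] == pytest.approx(beta, abs=1e-8)
            for nd in t.preorder_node_iter():
                i = proj.context.node_index(nd)
                assert proj.coords[i, j] == pytest.approx(
                    states[id(nd)], abs=1e-8)

    def test_projection_branch_lengths_consistent(self, small_scenario):
        tree, _part, traits = small_scenario
        proj = rn.ancestral_states_bm(tree, traits)
        ctx = proj.context
        for i in range(1, ctx.n_nodes):
            d = np.linalg.norm(proj.coords[i] - proj.coords[ctx.parent[i]])
            assert proj.branch_lengths[i] == pytest.approx(d, abs=1e-9)

    def test_zero_length_branch_rejected(self):
        t = rn.parse_tree("((A:0,B:1):1,C:2);")
        with pytest.raises(ValueError, match="positive"):
            rn.ancestral_states_bm(
                t, pd.DataFrame({"x": [0, 1, 2], "y": [0, 1, 2.0]},
                                index=["A", "B", "C"]))


class TestMeanMorphBranchLength:
    def test_identical_traits_give_zero(self, three_tip_tree):
        traits = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [2.0, 2.0, 2.0]},
                              index=["A", "B", "C"])
        proj = rn.ancestral_states_bm(three_tip_tree, traits)
        M, sum_L, n = rn.mean_morph_branch_length(proj)
        assert M == 0.0 and sum_L == 0.0 and n == 4

    def test_scales_linearly_with_traits(self, small_scenario):
        tree, _part, traits = small_scenario
        M1, s1, _ = rn.mean_morph_branch_length(
            rn.ancestral_states_bm(tree, traits))
        M3, s3, _ = rn.mean_morph_branch_length(
            rn.ancestral_states_bm(tree, traits * 3.0))
        assert M3 == pytest.approx(3 * M1)
        assert s3 == pytest.approx(3 * s1)


class TestMinVolumeEllipse:
    def test_square_corners_give_circumcircle(self):
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        ell = rn.min_volume_ellipse(pts, tol=1e-9)
        assert ell.area == pytest.approx(2 * np.pi, abs=1e-4)
        assert ell.center == pytest.approx([0, 0], abs=1e-6)

    def test_recovers_known_ellipse_from_boundary_points(self):
        a, b = 3.0, 1.5
        th = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        ell = rn.min_volume_ellipse(pts, tol=1e-8)
        assert ell.area == pytest.approx(np.pi * a * b, rel=1e-6)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateMorphospaceError):
            rn.min_volume_ellipse(np.ones((3, 2)))

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(DegenerateMorphospaceError):
            rn.min_volume_ellipse(pts)

    @pytest.mark.parametrize("seed", range(8))
    def test_containment_and_support_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((10, 2))
        tol = 1e-7
        ell = rn.min_volume_ellipse(P, tol=tol)
        s = np.einsum("ij,jk,ik->i", P - ell.center, ell.shape,
                      P - ell.center)
        assert s.max() <= 1 + 10 * tol
        # removing any strictly interior point leaves the ellipse unchanged
        interior = np.flatnonzero(s < 0.98)
        for i in interior[:3]:
            e2 = rn.min_volume_ellipse(np.delete(P, i, axis=0), tol=tol)
            assert e2.area == pytest.approx(ell.area, rel=1e-4)

    def test_matches_r_cluster_ellipsoidhull(self, tmp_path):
        """Areas agree with the R routine the D1 statistic was defined with."""
        rng = np.random.default_rng(31)
        P = rng.standard_normal((12, 2))
        csv = tmp_path / "pts.csv"
        np.savetxt(csv, P, delimiter=",")
        script = tmp_path / "mve.R"
        script.write_text(
            'suppressMessages(library(cluster));'
            'x <- as.matrix(read.csv("%s", header=FALSE));'
            'e <- ellipsoidhull(x, tol=1e-10);'
            'cat(sprintf("%%.10f\\n", volume(e)))' % csv)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        r_area = float(out.stdout.strip())
        ell = rn.min_volume_ellipse(P, tol=1e-9)
        assert ell.area == pytest.approx(r_area, rel=1e-5)


class TestRatios:
    def test_lineage_density_arithmetic(self):
        assert rn.lineage_density_D1(10.0, 4.0) == 2.5
        with pytest.raises(DegenerateMorphospaceError):
            rn.lineage_density_D1(10.0, 0.0)

    def test_published_component_arithmetic(self):
        # ratios recomputed from the study's printed per-clade components
        assert 169.55 / 108.05 == pytest.approx(1.57, abs=0.005)
        assert 9.80 / 2.61 == pytest.approx(3.75, abs=0.005)
        assert 38.53 / 21.61 == pytest.approx(1.78, abs=0.005)

    def test_identity_ratios(self, small_scenario):
        tree, part, traits = small_scenario
        focal, ref, _ = rn.clade_disparity(tree, traits, part)
        r = rn.disparity_ratios(focal, focal)
        assert r.M_ratio == 1.0 and r.D_ratio == 1.0


class TestCladeDisparity:
    def test_translation_invariance(self, small_scenario):
        tree, part, traits = small_scenario
        f1, r1, q1 = rn.clade_disparity(tree, traits, part)
        f2, r2, q2 = rn.clade_disparity(tree, traits + 100.0, part)
        assert f2.M == pytest.approx(f1.M, abs=1e-9)
        assert f2.ellipse.area == pytest.approx(f1.ellipse.area, rel=1e-7)
        assert q2.M_ratio == pytest.approx(q1.M_ratio, abs=1e-9)
        assert q2.D_ratio == pytest.approx(q1.D_ratio, rel=1e-6)

    def test_scale_equivariance(self, small_scenario):
        tree, part, traits = small_scenario
        c = 2.5
        f1, r1, q1 = rn.clade_disparity(tree, traits, part)
        f2, r2, q2 = rn.clade_disparity(tree, traits * c, part)
        assert f2.M == pytest.approx(c * f1.M, rel=1e-9)
        assert f2.ellipse.area == pytest.approx(c**2 * f1.ellipse.area,
                                                rel=1e-6)
        assert f2.D1 == pytest.approx(f1.D1 / c, rel=1e-6)
        assert q2.M_ratio == pytest.approx(q1.M_ratio, rel=1e-9)
        assert q2.D_ratio == pytest.approx(q1.D_ratio, rel=1e-6)

    def test_mirrored_clades_give_unit_ratios(self):
        # two topologically identical clades carrying identical trait values
        nwk = ("((FA:1,(FB:0.5,FC:0.5):0.5):1,"
               "(RA:1,(RB:0.5,RC:0.5):0.5):1);")
        tree = rn.parse_tree(nwk)
        part = rn.CladePartition(focal=frozenset(["FA", "FB", "FC"]),
                                 reference=frozenset(["RA", "RB", "RC"]))
        vals = {"A": (0.0, 1.0), "B": (1.0, 0.0), "C": (2.0, 2.0)}
        rows = {f"{p}{s}": vals[s] for p in "FR" for s in "ABC"}
        traits = pd.DataFrame.from_dict(rows, orient="index",
                                        columns=["x", "y"])
        _f, _r, ratios = rn.clade_disparity(tree, traits, part)
        assert ratios.M_ratio == pytest.approx(1.0, abs=1e-9)
        assert ratios.D_ratio == pytest.approx(1.0, abs=1e-6)

    def test_log10_requires_positive_traits(self, small_scenario):
        tree, part, traits = small_scenario
        with pytest.raises(ValueError, match="positive"):
            rn.clade_disparity(tree, traits - traits.min().min() - 1, part,
                               transform="log10")

    def test_tips_only_ellipse_option(self, small_scenario):
        tree, part, traits = small_scenario
        f_all, _, _ = rn.clade_disparity(tree, traits, part,
                                         ellipse_points="all")
        f_tips, _, _ = rn.clade_disparity(tree, traits, part,
                                          ellipse_points="tips")
        # the all-nodes cloud contains the tip cloud
        assert f_all.ellipse.area >= f_tips.ellipse.area * (1 - 1e-6)
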