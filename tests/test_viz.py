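"""Profile geometry, SVG determinism, and figure structure checks."""

import math
import re

import numpy as np
import pytest

from toxpi.data import DataError
from toxpi.hier_cluster import auto_color, euclidean_distances, linkage
from toxpi.scoring import score
from toxpi.viz import (
    TAU,
    profile_geometry,
    render_dendrogram,
    render_pca_scatter,
    render_profiles,
    render_rank_plot,
)

ARC_RADIUS = re.compile(r'class="slice-arc"')


def extract_arc_radii(svg: str) -> list[float]:
    """Outer radii of slice arcs, read back from SVG path data."""
    radii = []
    for m in re.finditer(r'<path d="([^"]+)" fill="[^"]*"[^/]*class="slice-arc"', svg):
        arc = re.search(r"A ([0-9.]+) ", m.group(1))
        radii.append(float(arc.group(1)))
    return radii


@pytest.fixture
def scored(medium_table, medium_model):
    return score(medium_table, medium_model), medium_model


class TestProfileGeometry:
    def test_equal_weights_quarter_turns(self, scored):
        s, model = scored
        geom = profile_geometry(s, model, s.entity_ids[0])
        for g in geom.slices:
            assert g.end_angle - g.start_angle == pytest.approx(TAU / 4, abs=1e-12)

    def test_widths_proportional_to_weights(self, small_table, small_model):
        s = score(small_table, small_model)
        geom = profile_geometry(s, small_model, "e1")
        widths = [g.end_angle - g.start_angle for g in geom.slices]
        assert widths[0] == pytest.approx(3 * math.pi / 2, abs=1e-12)
        assert widths[1] == pytest.approx(math.pi / 2, abs=1e-12)

    def test_widths_sum_to_tau(self, scored):
        s, model = scored
        for e in s.entity_ids[:5]:
            geom = profile_geometry(s, model, e)
            total = sum(g.end_angle - g.start_angle for g in geom.slices)
            assert total == pytest.approx(TAU, abs=1e-9)

    def test_arc_radius_equals_score(self, scored):
        s, model = scored
        i = 3
        geom = profile_geometry(s, model, s.entity_ids[i])
        for k, g in enumerate(geom.slices):
            assert g.arc_radius == s.slice_scores[i, k]

    def test_starts_at_twelve_oclock(self, scored):
        s, model = scored
        geom = profile_geometry(s, model, s.entity_ids[0])
        assert geom.slices[0].start_angle == 0.0


class TestProfileRendering:
    def test_svg_bytes_deterministic(self, scored, tmp_path):
        s, model = scored
        fig1 = render_profiles(s.entity_ids[:4], s, model, None, n_cols=2)
        fig2 = render_profiles(s.entity_ids[:4], s, model, None, n_cols=2)
        assert fig1.to_svg() == fig2.to_svg()

    def test_grid_arithmetic(self, scored):
        s, model = scored
        fig = render_profiles(s.entity_ids[:6], s, model, None, n_cols=3)
        assert fig.width == 3 * 160.0
        assert fig.height == 2 * (160.0 + 18.0)

    def test_empty_entity_list_rejected(self, scored):
        s, model = scored
        with pytest.raises(DataError):
            render_profiles([], s, model, None)

    def test_arc_radii_read_back_match_scores(self, scored):
        s, model = scored
        e = s.entity_ids[0]
        fig = render_profiles([e], s, model, None, n_cols=1)
        svg = fig.to_svg()
        R = 160.0 * 0.42
        radii = sorted(extract_arc_radii(svg))
        i = s.row(e)
        expected = sorted(r * R for r in s.slice_scores[i] if r > 0)
        assert len(radii) == len(expected)
        for got, want in zip(radii, expected):
            assert got == pytest.approx(want, abs=1e-6 * R)

    def test_zero_score_slice_has_no_arc(self, small_table, small_model):
        s = score(small_table, small_model)
        # e4 has m1=0 and m2=1 -> S1 score may be > 0; craft directly instead
        s.slice_scores[0, 0] = 0.0
        fig = render_profiles(["e1"], s, small_model, None, n_cols=1)
        assert len(extract_arc_radii(fig.to_svg())) == sum(
            v > 0 for v in s.slice_scores[0]
        )

    def test_png_output_written(self, scored, tmp_path):
        s, model = scored
        p = tmp_path / "profiles.png"
        render_profiles(s.entity_ids[:2], s, model, p, format="png", dpi=72)
        assert p.stat().st_size > 0

    def test_ci_band_lighter_shade_present(self, medium_table, medium_model):
        from toxpi.uncertainty import bootstrap_ci

        s = score(medium_table, medium_model)
        ci = bootstrap_ci(medium_table, medium_model, n_boot=100, seed=1, point=s)
        fig = render_profiles(s.entity_ids[:2], s, medium_model, None, ci=ci)
        assert 'class="ci-band"' in fig.to_svg()


class TestRankPlot:
    def test_highlights_marked(self, scored):
        s, model = scored
        fig = render_rank_plot(s, None, highlight=s.entity_ids[:2])
        svg = fig.to_svg()
        assert svg.count('class="rank-point-highlight"') == 2
        assert svg.count('class="hist-highlight"') == 2

    def test_ci_toggle(self, medium_table, medium_model):
        from toxpi.uncertainty import bootstrap_ci

        s = score(medium_table, medium_model)
        ci = bootstrap_ci(medium_table, medium_model, n_boot=100, seed=2, point=s)
        with_ci = render_rank_plot(s, None, ci=ci).to_svg()
        without = render_rank_plot(s, None).to_svg()
        assert 'class="ci-whisker"' in with_ci
        assert 'class="ci-whisker"' not in without

    def test_unknown_highlight_rejected(self, scored):
        s, _ = scored
        with pytest.raises(DataError):
            render_rank_plot(s, None, highlight=["ghost"])

    def test_one_point_per_entity(self, scored):
        s, _ = scored
        svg = render_rank_plot(s, None).to_svg()
        assert svg.count('class="rank-point"') == len(s.entity_ids)


class TestDendrogramRendering:
    @pytest.fixture
    def dend3(self):
        from scipy.spatial.distance import pdist

        return linkage(pdist(np.array([[0.0], [1.0], [10.0]])), "single",
                       entity_ids=["a", "b", "c"])

    def test_hanging_has_one_junction_per_merge(self, dend3):
        svg = render_dendrogram(dend3, None, layout="hanging").to_svg()
        assert svg.count('class="junction"') == 2

    def test_circular_distribute_uniform_gaps(self, scored):
        s, model = scored
        dend = linkage(euclidean_distances(s.slice_scores), "average",
                       entity_ids=s.entity_ids)
        fig = render_dendrogram(dend, None, layout="circular", distribute=True)
        # leaf label positions must sit at uniform 2*pi/n angular spacing
        n = dend.n_leaves
        centers = fig.width / 2, fig.height / 2
        angles = []
        for e in fig.elements:
            if getattr(e, "cls", "") == "leaf-label":
                angles.append(math.atan2(e.x - centers[0], centers[1] - e.y) % TAU)
        angles = np.sort(np.array(angles))
        gaps = np.diff(np.concatenate([angles, [angles[0] + TAU]]))
        np.testing.assert_allclose(gaps, TAU / n, atol=1e-9)

    def test_auto_color_yields_distinct_edge_colors(self, scored):
        s, model = scored
        dend = linkage(euclidean_distances(s.slice_scores), "average",
                       entity_ids=s.entity_ids)
        cmap = auto_color(dend, depth=2)
        svg = render_dendrogram(dend, None, layout="hanging", color_map=cmap).to_svg()
        stem_colors = set(re.findall(r'stroke="(#[0-9A-F]{6})"[^/]*class="stem"', svg))
        assert len(stem_colors) >= 3

    def test_profile_leaves(self, scored):
        s, model = scored
        dend = linkage(euclidean_distances(s.slice_scores), "ward",
                       entity_ids=s.entity_ids)
        svg = render_dendrogram(dend, None, scores=s, model=model,
                                layout="circular", leaf_style="profile").to_svg()
        assert svg.count('class="missingness"') == len(s.entity_ids) * len(model.slices)

    def test_heights_to_scale(self, dend3):
        fig = render_dendrogram(dend3, None, layout="hanging")
        ys = sorted({e.y0 for e in fig.elements
                     if getattr(e, "cls", "") == "junction"})
        # junction heights 1 and 9 of max 9 -> y positions ordered root-up
        assert len(ys) == 2 and ys[0] < ys[1]


class TestPcaScatter:
    def test_points_and_determinism(self, scored):
        from toxpi.kmeans_cluster import kmeans, pca_project

        s, _ = scored
        km = kmeans(s.slice_scores, 3, n_start=5, seed=3)
        proj = pca_project(s.slice_scores)
        fig = render_pca_scatter(proj, None, labels=km.labels,
                                 entity_ids=s.entity_ids)
        svg = fig.to_svg()
        assert svg.count('class="pca-point"') == len(s.entity_ids)
        assert svg == render_pca_scatter(proj, None, labels=km.labels,
                                         entity_ids=s.entity_ids).to_svg()
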