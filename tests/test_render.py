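import io

import numpy as np
import pytest
from PIL import Image

from hicbox import GenomicLocus, decode_url, map_color, parse_bedpe, query_region
from hicbox.genome import bin_range
from hicbox.matrix import ContactMatrix
from hicbox.render import (
    ColorScale,
    FigureSpec,
    export_figure,
    render_heatmap,
    render_session,
    resolve_vmax,
)
from hicbox.session import AnnotationSource, MapSource, SessionState
from hicbox.testing import serve

WHITE_RED = ColorScale(v_max=5.0)


def _matrix(values, res=100, chrom="c", mask=None):
    values = np.asarray(values, float)
    n, m = values.shape
    return ContactMatrix(
        values=values,
        mask=np.zeros(values.shape, bool) if mask is None else mask,
        locus_x=GenomicLocus(chrom, 0, n * res),
        locus_y=GenomicLocus(chrom, 0, m * res),
        resolution=res,
        norm_type="NONE",
    )


class TestMapColor:
    def test_zero_is_low_color(self):
        assert map_color(0.0, WHITE_RED) == (255, 255, 255)

    @pytest.mark.parametrize("value", [5.0, 7.3, 1e9])
    def test_saturation_at_and_beyond_vmax(self, value):
        assert map_color(value, WHITE_RED) == (255, 0, 0)

    def test_midpoint_rounds_half_up(self):
        assert map_color(2.5, WHITE_RED) == (255, 128, 128)

    def test_nan_maps_to_mask_color(self):
        assert map_color(float("nan"), WHITE_RED) == WHITE_RED.mask_color

    def test_monotone_nonincreasing_green_blue(self):
        """White-to-red ramp: higher values can only darken green/blue."""
        values = np.linspace(0, 6, 200)
        colors = np.array([map_color(v, WHITE_RED) for v in values])
        assert (np.diff(colors[:, 1]) <= 0).all()
        assert (np.diff(colors[:, 2]) <= 0).all()

    def test_auto_vmax_is_five_times_mean_nonzero(self):
        m = _matrix([[0.0, 2.0], [2.0, 4.0]])
        assert resolve_vmax(ColorScale(), m) == pytest.approx(5 * (8 / 3))


class TestRenderHeatmap:
    def test_identical_inputs_give_byte_identical_pixels(self):
        rng = np.random.default_rng(30)
        m = _matrix(rng.uniform(0, 5, size=(20, 20)))
        a = render_heatmap(m, WHITE_RED, pixels_per_bin=2)
        b = render_heatmap(m, WHITE_RED, pixels_per_bin=2)
        assert a.tobytes() == b.tobytes()

    def test_fully_masked_matrix_is_uniform_mask_color(self):
        vals = np.full((4, 4), np.nan)
        m = _matrix(vals, mask=np.ones((4, 4), bool))
        img = render_heatmap(m, WHITE_RED, pixels_per_bin=1)
        assert (img == np.array(WHITE_RED.mask_color)).all()

    def test_orientation_diagonal_top_left(self):
        """x runs left-to-right, y top-to-bottom: values[i, j] lands at
        pixel row j, column i."""
        vals = np.zeros((3, 3))
        vals[2, 0] = 10.0  # x bin 2, y bin 0
        img = render_heatmap(_matrix(vals), WHITE_RED, pixels_per_bin=1)
        assert tuple(img[0, 2]) == (255, 0, 0)
        assert tuple(img[2, 0]) == (255, 255, 255)

    def test_loop_outline_lands_on_predicted_bins(self, loop_container):
        """Annotation outline pixels sit exactly at the truth's bin rect."""
        reader, result, _ = loop_container
        res = result.config.resolution
        m = query_region(
            reader,
            GenomicLocus("chrS", 500_000, 2_500_000),
            GenomicLocus("chrS", 500_000, 2_500_000),
            res,
        )
        anns = parse_bedpe(result.loops_bedpe())
        color = (0, 200, 200)
        anns = [type(a)(a.anchor1, a.anchor2, color, a.label) for a in anns]
        img = render_heatmap(m, ColorScale(3.0), annotations=anns, pixels_per_bin=1)
        loop = result.config.loops[0]
        x0, _ = bin_range(m.locus_x, res)
        bx = loop.anchor1 // res - x0
        by = loop.anchor2 // res - x0
        # 1-bin anchors -> single-pixel outline at both mirror positions
        assert tuple(img[by, bx]) == color
        assert tuple(img[bx, by]) == color
        # off-outline neighbour keeps a ramp color (red/white family)
        assert tuple(img[by + 3, bx + 3]) != color

    def test_track_strip_changes_canvas_size(self):
        from hicbox.tracks import parse_signal

        m = _matrix(np.ones((10, 10)))
        t = parse_signal("c\t0\t1000\t2.0\n", "bedGraph")
        img = render_heatmap(m, WHITE_RED, tracks=[t], pixels_per_bin=2, track_px=6)
        assert img.shape == (20 + 6, 20 + 6, 3)


class TestExportFigure:
    def test_sidecar_url_rerenders_byte_identical_png(self, loop_container, tmp_path):
        reader, result, path = loop_container
        blob = open(path, "rb").read()
        bedpe = result.loops_bedpe().encode()
        with serve({"/map.hicj": blob, "/loops.bedpe": bedpe}) as base:
            session = SessionState(
                maps=(MapSource(base + "/map.hicj", "loops", "NONE", ColorScale(3.0)),),
                locus_x=GenomicLocus("chrS", 500_000, 2_500_000),
                locus_y=GenomicLocus("chrS", 500_000, 2_500_000),
                resolution=10_000,
                annotations=(AnnotationSource(base + "/loops.bedpe"),),
            )
            out = str(tmp_path / "fig.png")
            png, sidecar = export_figure(FigureSpec(session, pixels_per_bin=1), out)
            url = open(sidecar).read().strip()
            state2 = decode_url(url)
            assert state2 == session
            img2 = render_session(FigureSpec(state2, pixels_per_bin=1))
            buf = io.BytesIO()
            Image.fromarray(img2).save(buf, format="PNG")
            assert open(png, "rb").read() == buf.getvalue()

    def test_vmax_change_alters_png_but_only_cmax_in_sidecar(self, loop_container, tmp_path):
        reader, result, path = loop_container
        blob = open(path, "rb").read()
        with serve({"/map.hicj": blob}) as base:
            def make(vmax, name):
                session = SessionState(
                    maps=(MapSource(base + "/map.hicj", "m", "NONE", ColorScale(vmax)),),
                    locus_x=GenomicLocus("chrS", 0, 1_000_000),
                    locus_y=GenomicLocus("chrS", 0, 1_000_000),
                    resolution=10_000,
                )
                out = str(tmp_path / name)
                return export_figure(FigureSpec(session, pixels_per_bin=1), out)

            png1, side1 = make(2.0, "a.png")
            png2, side2 = make(8.0, "b.png")
        assert open(png1, "rb").read() != open(png2, "rb").read()
        u1, u2 = open(side1).read(), open(side2).read()
        diff = [
            (a, b)
            for a, b in zip(u1.strip().split("&"), u2.strip().split("&"))
            if a != b
        ]
        assert diff == [("cmax=2.0", "cmax=8.0")]

    def test_local_map_gets_local_marker_sidecar(self, loop_container, tmp_path):
        _, result, path = loop_container
        session = SessionState(
            maps=(MapSource(path, "m", "NONE", ColorScale(3.0)),),
            locus_x=GenomicLocus("chrS", 0, 500_000),
            locus_y=GenomicLocus("chrS", 0, 500_000),
            resolution=10_000,
        )
        out = str(tmp_path / "fig.png")
        with pytest.warns(UserWarning, match="local"):
            _, sidecar = export_figure(FigureSpec(session, pixels_per_bin=1), out)
        content = open(sidecar).read()
        assert content.startswith("local=true\n")
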