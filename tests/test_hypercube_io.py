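"""Round-trip and format-error behaviour of the ENVI cube and PNG mask I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsirow.errors import FormatError
from hsirow.hypercube import HyperCube, read_cube, read_mask, write_cube, write_mask
from hsirow.simulate import SceneConfig, generate_scene


def _random_cube(rng, shape, dtype):
    if np.issubdtype(dtype, np.integer):
        data = rng.integers(0, 1000, size=shape).astype(dtype)
    else:
        data = rng.random(shape).astype(dtype)
    wl = np.cumsum(rng.uniform(1.0, 5.0, shape[2])) + 400.0
    return HyperCube(data, wl)


@given(
    h=st.integers(1, 6),
    w=st.integers(1, 6),
    b=st.integers(1, 5),
    dtype=st.sampled_from([np.uint8, np.uint16, np.int32, np.float32, np.float64]),
    interleave=st.sampled_from(["bil", "bsq"]),
    seed=st.integers(0, 10_000),
)
def test_cube_round_trip_identity(tmp_path_factory, h, w, b, dtype, interleave, seed):
    """Any cube written in either interleave reads back bit-identically."""
    cube = _random_cube(np.random.default_rng(seed), (h, w, b), dtype)
    path = tmp_path_factory.mktemp("rt") / "cube.raw"
    write_cube(cube, path, interleave=interleave)
    back = read_cube(path)
    np.testing.assert_array_equal(back.data, cube.data)
    np.testing.assert_allclose(back.wavelengths_nm, cube.wavelengths_nm)
    assert back.data.dtype == cube.data.dtype


def test_kind_tag_and_extra_header_survive_round_trip(tmp_path):
    cube = HyperCube(
        np.ones((2, 3, 2), dtype=np.float32),
        [500.0, 600.0],
        kind="reflectance",
        extra_header={"sensor id": "demo rig"},
    )
    write_cube(cube, tmp_path / "c.bil")
    back = read_cube(tmp_path / "c.bil")
    assert back.kind == "reflectance"
    assert back.extra_header["sensor id"] == "demo rig"


def test_degenerate_single_voxel_cube_round_trips(tmp_path):
    cube = HyperCube(np.array([[[7.0]]], dtype=np.float32), [550.0])
    write_cube(cube, tmp_path / "one.bsq", interleave="bsq")
    assert read_cube(tmp_path / "one.bsq").data[0, 0, 0] == 7.0


def test_axis_convention_is_stable_across_interleaves(tmp_path):
    """data[y, x, b] must map to the same voxel whatever the file layout."""
    data = (
        np.arange(3 * 4 * 2, dtype=np.float32).reshape(3, 4, 2) * 1.0
    )  # value encodes (y, x, b) position
    cube = HyperCube(data, [500.0, 600.0])
    for interleave in ("bil", "bsq"):
        write_cube(cube, tmp_path / f"c_{interleave}", interleave=interleave)
        back = read_cube(tmp_path / f"c_{interleave}")
        assert back.data[1, 2, 1] == data[1, 2, 1]
        np.testing.assert_array_equal(back.data, data)


def test_wavelength_count_mismatch_raises_format_error(tmp_path):
    cube = HyperCube(np.ones((2, 2, 3), dtype=np.float32), [500.0, 600.0, 700.0])
    write_cube(cube, tmp_path / "c.bil")
    hdr = tmp_path / "c.bil.hdr"
    hdr.write_text(hdr.read_text().replace("bands = 3", "bands = 2"))
    with pytest.raises(FormatError, match="wavelength count|bands"):
        read_cube(tmp_path / "c.bil")


def test_missing_header_field_is_named_in_the_error(tmp_path):
    cube = HyperCube(np.ones((2, 2, 2), dtype=np.float32), [500.0, 600.0])
    write_cube(cube, tmp_path / "c.bil")
    hdr = tmp_path / "c.bil.hdr"
    hdr.write_text(
        "\n".join(
            line for line in hdr.read_text().splitlines() if not line.startswith("interleave")
        )
    )
    with pytest.raises(FormatError, match="interleave"):
        read_cube(tmp_path / "c.bil")


def test_truncated_data_file_raises_format_error(tmp_path):
    cube = HyperCube(np.ones((4, 4, 3), dtype=np.float32), [500.0, 600.0, 700.0])
    write_cube(cube, tmp_path / "c.bil")
    raw = (tmp_path / "c.bil").read_bytes()
    (tmp_path / "c.bil").write_bytes(raw[: len(raw) // 2])
    with pytest.raises(FormatError, match="size"):
        read_cube(tmp_path / "c.bil")


def test_simulator_vnir_scene_file_has_default_band_structure(tmp_path):
    """A simulator-written VNIR cube reads back with 178 bands over 400-896 nm."""
    cfg = SceneConfig(seed=3, n_plants=2, plant_spacing_px=40, vnir_height=60,
                      swir_height=20, swir_bands=12)
    vnir, _, _ = generate_scene(cfg)
    write_cube(vnir, tmp_path / "vnir.bil")
    back = read_cube(tmp_path / "vnir.bil")
    assert back.n_bands == 178
    assert back.wavelengths_nm[0] == pytest.approx(400.0)
    assert back.wavelengths_nm[-1] == pytest.approx(896.0)


@pytest.mark.parametrize(
    "mask",
    [
        np.indices((4, 4)).sum(axis=0) % 2 == 0,  # checkerboard
        np.zeros((3, 5), dtype=bool),
        np.ones((2, 2), dtype=bool),
    ],
)
def test_mask_round_trip_identity(tmp_path, mask):
    write_mask(mask, tmp_path / "m.png")
    np.testing.assert_array_equal(read_mask(tmp_path / "m.png"), mask)


def test_mask_write_rejects_non_2d():
    with pytest.raises(ValueError):
        write_mask(np.ones(4, dtype=bool), "/tmp/never.png")


def test_cube_invariants_rejected():
    with pytest.raises(ValueError, match="wavelength"):
        HyperCube(np.ones((2, 2, 3)), [500.0, 600.0])
    with pytest.raises(ValueError, match="increasing"):
        HyperCube(np.ones((2, 2, 2)), [600.0, 500.0])
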