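"""Random 3D labeled phantom generation.

A phantom is an isotropic voxel grid of integer tissue labels plus a table of
optical properties (absorption mua, scattering mus, anisotropy g, refractive
index n) per label. Inclusions are random convex polyhedra (convex hulls of
points sampled uniformly on a random sphere) and extruded ASCII letters,
dropped into a homogeneous background. Overlapping inclusions produce new
compound labels: each mask contributes a power-of-two coefficient so that
every overlap pattern accumulates to a unique label value.

Voxel convention: a voxel belongs to a shape iff its *center* lies inside the
shape; centers sit at ``(i + 0.5) * voxel_size`` mm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .io import save_json, save_volume

__all__ = [
    "OpticalProperties",
    "ShapeSpec",
    "Phantom",
    "SourceSpec",
    "sample_shape",
    "sample_optical_properties",
    "sample_simulation_config",
    "rasterize_polyhedron",
    "rasterize_convex_hull",
    "rasterize_letter",
    "compose_phantom",
    "generate_dataset",
]

MIN_GRID_DIM = 8


@dataclasses.dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue label.

    mua, mus in mm^-1; g dimensionless in [0, 1); n >= 1.
    """

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.n < 1:
            raise ValueError("refractive index n must be >= 1")

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient mus' = mus * (1 - g)."""
        return self.mus * (1.0 - self.g)

    def to_dict(self) -> dict:
        return {"mua": self.mua, "mus": self.mus, "g": self.g, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalProperties":
        return cls(mua=d["mua"], mus=d["mus"], g=d["g"], n=d["n"])


@dataclasses.dataclass(frozen=True)
class ShapeSpec:
    """Fully parameterized random inclusion (polyhedron or extruded letter)."""

    kind: Literal["polyhedron", "ascii-letter"]
    # common rigid placement
    rotation: tuple[float, float, float, float]  # unit quaternion (w, x, y, z)
    translation: tuple[float, float, float]  # mm
    # polyhedron parameters
    n_points: int | None = None
    sphere_center: tuple[float, float, float] | None = None  # mm
    sphere_radius: float | None = None  # mm
    # letter parameters
    character: str | None = None
    font_size: int | None = None
    angle_2d: float | None = None  # degrees
    thickness: int | None = None  # voxels

    def __post_init__(self):
        if self.kind == "polyhedron":
            if not (4 <= self.n_points <= 10):
                raise ValueError("polyhedron point count must be in [4, 10]")
        elif self.kind == "ascii-letter":
            if not (self.character and self.character.isascii() and self.character.isalpha()):
                raise ValueError("character must be an ASCII letter A-Z/a-z")
            if self.thickness < 1:
                raise ValueError("extrusion thickness must be >= 1 voxel")
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")


@dataclasses.dataclass
class Phantom:
    """Labeled simulation domain: integer label grid + per-label properties."""

    label_grid: np.ndarray  # 3D int array
    properties: dict[int, OpticalProperties]
    voxel_size: float  # mm, isotropic

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label_grid must be 3D")
        if not np.issubdtype(self.label_grid.dtype, np.integer):
            raise ValueError("label_grid must be integer-typed")
        if self.label_grid.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.label_grid).tolist())
        missing = present - set(self.properties)
        if missing:
            raise ValueError(f"labels without optical properties: {sorted(missing)}")
        if 0 not in self.properties:
            raise ValueError("background label 0 must have properties")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.grid_shape) * self.voxel_size

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.label_grid.astype(np.int32)))
        table = {str(k): v.to_dict() for k, v in sorted(self.properties.items())}
        h.update(json.dumps(table, sort_keys=True).encode())
        h.update(np.float64(self.voxel_size).tobytes())
        return h.hexdigest()


@dataclasses.dataclass(frozen=True)
class SourceSpec:
    """Photon source: isotropic point or collimated pencil beam."""

    kind: Literal["isotropic", "pencil"]
    position: tuple[float, float, float]  # mm
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("isotropic", "pencil"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "pencil":
            d = np.asarray(self.direction, dtype=float)
            if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
                raise ValueError("pencil direction must be a unit vector")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "position": list(self.position),
            "direction": list(self.direction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        return cls(kind=d["kind"], position=tuple(d["position"]),
                   direction=tuple(d.get("direction", (0.0, 0.0, 1.0))))


# ---------------------------------------------------------------------------
# random sampling
# ---------------------------------------------------------------------------

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def _random_quaternion(rng: np.random.Generator) -> tuple[float, float, float, float]:
    # uniform over SO(3) (Shoemake's method)
    u1, u2, u3 = rng.random(3)
    q = (
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    )
    return (q[3], q[0], q[1], q[2])  # (w, x, y, z)


def quaternion_matrix(q) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def sample_shape(rng: np.random.Generator, grid_shape, voxel_size: float = 1.0,
                 kind: str | None = None) -> ShapeSpec:
    """Draw a fully parameterized random inclusion for the given grid.

    Polyhedra and letters are equally likely unless ``kind`` forces one.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s < MIN_GRID_DIM for s in grid_shape):
        raise ValueError(f"grid dims must all be >= {MIN_GRID_DIM}, got {grid_shape}")
    extent = np.array(grid_shape) * voxel_size
    if kind is None:
        kind = "polyhedron" if rng.random() < 0.5 else "ascii-letter"
    rotation = _random_quaternion(rng)
    translation = tuple(rng.uniform(-0.1, 0.1) * extent)
    if kind == "polyhedron":
        return ShapeSpec(
            kind="polyhedron",
            rotation=rotation,
            translation=translation,
            n_points=int(rng.integers(4, 11)),
            sphere_center=tuple(rng.uniform(0.25, 0.75) * extent),
            sphere_radius=float(rng.uniform(0.1, 0.35) * extent.min()),
        )
    return ShapeSpec(
        kind="ascii-letter",
        rotation=rotation,
        translation=translation,
        character=_LETTERS[rng.integers(len(_LETTERS))],
        font_size=int(rng.integers(max(8, grid_shape[0] // 4), max(10, grid_shape[0] // 2 + 1))),
        angle_2d=float(rng.uniform(0.0, 360.0)),
        thickness=int(rng.integers(1, max(2, grid_shape[2] // 4) + 1)),
    )


def sample_optical_properties(rng: np.random.Generator,
                              n_range: tuple[float, float] = (1.0, 10.0)
                              ) -> OpticalProperties:
    """Draw tissue-like random optical properties.

    mua = |N(0.01, 0.05)| mm^-1, g ~ U[0.9, 1), mus' = |N(1, 1)| mm^-1 with
    mus = mus' / (1 - g), n ~ U over ``n_range`` (default [1, 10]; override to
    e.g. (1.33, 1.5) for physiological refractive indices).
    """
    mua = abs(rng.normal(0.01, 0.05))
    g = rng.uniform(0.9, 1.0)
    musp = abs(rng.normal(1.0, 1.0))
    mus = musp / (1.0 - g)
    n = rng.uniform(*n_range)
    return OpticalProperties(mua=mua, mus=mus, g=g, n=n)


def sample_simulation_config(rng: np.random.Generator, phantom: Phantom
                             ) -> tuple[SourceSpec, float]:
    """Draw an isotropic source strictly inside the domain and a CW time gate.

    Time gate ~ U[0.1, 1] ns.
    """
    extent = phantom.extent_mm
    eps = 0.5 * phantom.voxel_size
    position = tuple(rng.uniform(eps, e - eps) for e in extent)
    time_gate = float(rng.uniform(0.1, 1.0))
    return SourceSpec(kind="isotropic", position=position), time_gate


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _voxel_centers(grid_shape, voxel_size):
    axes = [(np.arange(s) + 0.5) * voxel_size for s in grid_shape]
    return axes


def sample_sphere_points(rng: np.random.Generator, n: int, center, radius: float
                         ) -> np.ndarray:
    """Uniform-area random points on a sphere (cos-theta inversion)."""
    z = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    s = np.sqrt(1.0 - z * z)
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    return np.asarray(center) + radius * pts


def rasterize_convex_hull(vertices: np.ndarray, grid_shape, voxel_size: float
                          ) -> np.ndarray:
    """Binary mask of voxels whose centers lie inside (or on) the convex hull."""
    verts = np.asarray(vertices, dtype=float)
    tri = Delaunay(verts)  # raises QhullError for coplanar point sets
    grid_shape = tuple(int(s) for s in grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    lo = np.maximum(np.floor(verts.min(0) / voxel_size - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(verts.max(0) / voxel_size + 0.5).astype(int),
                    np.array(grid_shape))
    if np.any(lo >= hi):
        return mask  # hull entirely outside the grid
    sub_axes = [(np.arange(lo[a], hi[a]) + 0.5) * voxel_size for a in range(3)]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    q = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside = tri.find_simplex(q) >= 0
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside.reshape(tuple(hi - lo))
    return mask


def rasterize_polyhedron(spec: ShapeSpec, grid_shape, voxel_size: float,
                         rng: np.random.Generator | None = None,
                         max_retries: int = 8) -> np.ndarray:
    """Rasterize the convex hull of the spec's sphere points into a binary mask.

    A voxel is inside iff its center lies inside (or on) the rotated and
    translated hull. Degenerate (coplanar) point draws are resampled up to
    ``max_retries`` times before raising.
    """
    if spec.kind != "polyhedron":
        raise ValueError("spec.kind must be 'polyhedron'")
    rng = np.random.default_rng(0) if rng is None else rng
    R = quaternion_matrix(spec.rotation)
    center = np.asarray(spec.sphere_center)
    last_err = None
    for _ in range(max_retries):
        pts = sample_sphere_points(rng, spec.n_points, (0.0, 0.0, 0.0), spec.sphere_radius)
        verts = (R @ pts.T).T + center + np.asarray(spec.translation)
        try:
            return rasterize_convex_hull(verts, grid_shape, voxel_size)
        except QhullError as err:  # coplanar/degenerate draw
            last_err = err
            continue
    raise ValueError(f"could not form a non-degenerate hull after {max_retries} tries") \
        from last_err


_FONT_CACHE: dict[int, object] = {}


def _load_font(size: int):
    if size not in _FONT_CACHE:
        try:
            from matplotlib import font_manager
            from PIL import ImageFont
            path = font_manager.findfont("DejaVu Sans", fallback_to_default=True)
            _FONT_CACHE[size] = ImageFont.truetype(path, size=size)
        except Exception as err:  # pragma: no cover - font always ships with matplotlib
            raise RuntimeError(
                "TrueType font unavailable (looked for DejaVu Sans via matplotlib)"
            ) from err
    return _FONT_CACHE[size]


def _render_glyph(character: str, font_size: int, angle_2d: float) -> np.ndarray:
    """Render one glyph to a binary 2D array, rotated in-plane by angle_2d degrees."""
    from PIL import Image, ImageDraw

    # render supersampled so thin strokes keep >= 50% coverage after reduction
    ss = max(1, int(np.ceil(32 / font_size)))
    font = _load_font(font_size * ss)
    pad = font_size * ss
    im = Image.new("L", (3 * pad, 3 * pad), 0)
    draw = ImageDraw.Draw(im)
    draw.text((pad, pad // 2), character, fill=255, font=font)
    arr = np.asarray(im, dtype=float) / 255.0
    if ss > 1:
        h, w = (arr.shape[0] // ss) * ss, (arr.shape[1] // ss) * ss
        arr = arr[:h, :w].reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))
    # 50% coverage threshold; floored at the peak coverage so glyphs whose
    # strokes are thinner than one voxel (e.g. 'l' at small sizes) stay solid
    thresh = min(0.5, float(arr.max()) * 0.999) if arr.max() > 0 else 0.5
    binary = arr >= thresh
    if angle_2d:
        # rotate the thresholded mask with nearest-neighbor so thin strokes
        # (e.g. 'l', 'i' at small sizes) survive the resampling
        binary = ndimage.rotate(binary.astype(np.float32), angle_2d,
                                reshape=True, order=0, mode="constant") >= 0.5
    if not binary.any():
        raise ValueError(f"glyph {character!r} rendered empty at size {font_size}")
    # crop to bounding box
    rows = np.any(binary, axis=1)
    cols = np.any(binary, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    return binary[r0:r1 + 1, c0:c1 + 1]


def rasterize_letter(spec: ShapeSpec, grid_shape, voxel_size: float) -> np.ndarray:
    """Rasterize an extruded ASCII glyph into a binary mask on the grid.

    The 2D glyph raster (thresholded at 50% coverage) is replicated along the
    extrusion axis for ``thickness`` slices, then rigidly rotated/translated in
    3D and resampled onto the grid with nearest-neighbor interpolation.
    """
    if spec.kind != "ascii-letter":
        raise ValueError("spec.kind must be 'ascii-letter'")
    glyph = _render_glyph(spec.character, spec.font_size, spec.angle_2d)
    block = np.repeat(glyph[:, :, None], spec.thickness, axis=2).astype(np.float32)

    # place block center at grid center + translation, orientation per quaternion
    R = quaternion_matrix(spec.rotation)
    grid_shape = tuple(int(s) for s in grid_shape)
    out_center_mm = np.array(grid_shape) * voxel_size / 2.0 + np.asarray(spec.translation)
    block_center_vox = (np.array(block.shape) - 1) / 2.0
    # affine_transform evaluates input_coord = matrix @ output_index + offset;
    # output index i sits at mm position (i + 0.5) * voxel_size, so
    #   block_coord = R^T ((i + 0.5) vs - out_center_mm) / vs + block_center
    # the 1e-6 shift breaks exact half-voxel ties (a glyph stroke one voxel
    # thick, centered on a voxel boundary, would otherwise round away)
    offset = (R.T @ (0.5 * voxel_size * np.ones(3) - out_center_mm)) / voxel_size \
        + block_center_vox - 1e-6
    mask = ndimage.affine_transform(
        block, R.T, offset=offset, output_shape=grid_shape,
        order=0, mode="grid-constant", cval=0.0)
    return mask >= 0.5


def compose_phantom(masks: list[np.ndarray], rng: np.random.Generator,
                    grid_shape, voxel_size: float,
                    n_range: tuple[float, float] = (1.0, 10.0)) -> Phantom:
    """Accumulate up to four binary masks into a labeled phantom.

    Mask ``i`` contributes coefficient ``2**i``, so each non-empty overlap
    pattern yields a unique accumulated label; every distinct label (background
    0 included) receives independently sampled optical properties.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if not (0 <= len(masks) <= 4):
        raise ValueError("number of masks must be between 0 and 4")
    label_grid = np.zeros(grid_shape, dtype=np.int32)
    for i, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != grid_shape:
            raise ValueError(
                f"mask {i} shape {m.shape} does not match grid {grid_shape}")
        label_grid += (1 << i) * m.astype(np.int32)
    properties = {
        int(lbl): sample_optical_properties(rng, n_range=n_range)
        for lbl in np.unique(label_grid)
    }
    if 0 not in properties:
        properties[0] = sample_optical_properties(rng, n_range=n_range)
    return Phantom(label_grid=label_grid, properties=properties, voxel_size=voxel_size)


def random_phantom(rng: np.random.Generator, grid_shape, voxel_size: float = 1.0,
                   n_shapes: int | None = None,
                   n_range: tuple[float, float] = (1.0, 10.0)) -> Phantom:
    """Draw M ~ U{0..4} random shapes (unless given) and compose a phantom."""
    if n_shapes is None:
        n_shapes = int(rng.integers(0, 5))
    masks = []
    for _ in range(n_shapes):
        spec = sample_shape(rng, grid_shape, voxel_size)
        if spec.kind == "polyhedron":
            masks.append(rasterize_polyhedron(spec, grid_shape, voxel_size, rng=rng))
        else:
            masks.append(rasterize_letter(spec, grid_shape, voxel_size))
    return compose_phantom(masks, rng, grid_shape, voxel_size, n_range=n_range)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(n_domains: int, grid_shape, out_dir, seed: int,
                     voxel_size: float = 1.0,
                     n_range: tuple[float, float] = (1.0, 10.0)) -> list[dict]:
    """Generate a catalog of random (phantom, source, time gate) records.

    Phantom label grids are saved as int16 NIfTI next to a JSON manifest; the
    manifest is byte-stable under a fixed seed. Returns the manifest records.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(root.spawn(n_domains)):
        rng = np.random.default_rng(child)
        phantom = random_phantom(rng, grid_shape, voxel_size, n_range=n_range)
        source, time_gate = sample_simulation_config(rng, phantom)
        name = f"phantom_{i:04d}"
        vol_path = out_dir / f"{name}.nii"
        try:
            save_volume(phantom.label_grid.astype(np.int16), voxel_size, vol_path)
            save_json({str(k): v.to_dict() for k, v in phantom.properties.items()},
                      out_dir / f"{name}_props.json")
        except OSError as err:
            raise OSError(f"failed writing phantom files under {out_dir}") from err
        records.append(
            {
                "phantom_path": vol_path.name,
                "properties_path": f"{name}_props.json",
                "source": source.to_dict(),
                "time_gate_ns": time_gate,
                "seed": int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF),
            }
        )
    save_json(records, out_dir / "manifest.json")
    return records


def load_phantom(out_dir, record: dict) -> Phantom:
    """Load one phantom referenced by a dataset manifest record."""
    from .io import load_volume

    out_dir = Path(out_dir)
    grid, voxel_size = load_volume(out_dir / record["phantom_path"])
    props = {
        int(k): OpticalProperties.from_dict(v)
        for k, v in json.loads((out_dir / record["properties_path"]).read_text()).items()
    }
    return Phantom(label_grid=np.asarray(grid, dtype=np.int32), properties=props,
                   voxel_size=voxel_size)
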