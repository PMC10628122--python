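"""Synthetic paired brightfield / fluorescence micrograph generator.

Emulates an acridine-orange sperm imaging experiment: each scene contains
elliptical "sperm heads" rendered in three modalities —

* brightfield (BFI): textured bright ellipses on a mid-gray background,
* dsDNA fluorescence (green channel): ellipses at an intensity proportional
  to the cell's double-stranded DNA content,
* ssDNA fluorescence (red channel): likewise for single-stranded DNA.

The two fluorescence channels share the brightfield speckle texture (up to a
per-channel affine intensity map), so cross-modality keypoint matching is
possible, and their per-cell intensity ratio fixes an analytic ground-truth
DNA fragmentation index, DFI = 100 * ss / (ss + ds).  Fluorescence frames
carry a constant-plus-jitter integer background and a known projective
misalignment relative to the brightfield frame, so the registration and
denoising stages can both be validated against exact truth.
"""

from __future__ import annotations

import dataclasses
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import transform as sktf

from .geometry import identity_homography, is_identity, make_homography, normalize_homography

__all__ = [
    "CellSpec",
    "SceneSpec",
    "SceneRender",
    "render_scene",
    "random_scene",
    "generate_donor_dataset",
]

MIN_FRAME = 64

# photometric model: in-cell brightfield value is BFI_BG + (a*ds + b*ss) * t
# where t is the shared speckle texture in [TEX_LO, 1]. With ds + ss held
# constant per dataset, the slope is invertible, i.e. the brightfield
# appearance of a head determines its fluorescence intensities.
BFI_BG = 110.0
BFI_DS_GAIN = 0.35
BFI_SS_GAIN = 0.15
TEX_LO = 0.35
TEX_SIGMA = 1.4


@dataclass(frozen=True)
class CellSpec:
    """One elliptical sperm head.

    ``center`` is ``(x, y)`` in brightfield-frame pixels; ``axes`` are the
    semi-axes ``(a, b)`` in pixels; ``angle`` is the major-axis orientation in
    degrees; the two intensities are the noise-free peak fluorescence levels
    on the 8-bit scale.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float = 0.0
    dsdna_intensity: float = 180.0
    ssdna_intensity: float = 60.0

    def __post_init__(self) -> None:
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError(f"ellipse semi-axes must be positive, got {self.axes}")
        if self.dsdna_intensity < 0 or self.ssdna_intensity < 0:
            raise ValueError("fluorescence intensities must be >= 0")
        if self.dsdna_intensity + self.ssdna_intensity <= 0:
            raise ValueError("at least one fluorescence intensity must be > 0")

    @property
    def true_dfi(self) -> float:
        """Analytic DFI in percent, 100 * ss / (ss + ds)."""
        ds, ss = self.dsdna_intensity, self.ssdna_intensity
        return 100.0 * ss / (ss + ds)


@dataclass(frozen=True)
class SceneSpec:
    """One frame triplet: geometry, photometry and misalignment."""

    frame_size: tuple[int, int] = (160, 160)  # (H, W)
    cells: tuple[CellSpec, ...] = ()
    bg_level_ds: int = 10
    bg_level_ss: int = 14
    bg_jitter: int = 1
    homography_true: np.ndarray = field(default_factory=identity_homography)
    seed: int = 0
    donor_id: str = "donor_1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "homography_true", normalize_homography(self.homography_true))
        h, w = self.frame_size
        if h < MIN_FRAME or w < MIN_FRAME:
            raise ValueError(f"frame must be at least {MIN_FRAME}x{MIN_FRAME}, got {self.frame_size}")
        if self.bg_jitter < 0:
            raise ValueError("bg_jitter must be >= 0")
        for lv in (self.bg_level_ds, self.bg_level_ss):
            if lv - self.bg_jitter < 0 or lv + self.bg_jitter > 255:
                raise ValueError("background level +- jitter must stay within [0, 255]")
        for i, cell in enumerate(self.cells):
            r0, c0, r1, c1 = cell_box(cell)
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"cell {i} (patch box {(r0, c0, r1, c1)}) extends outside the frame")
        boxes = [cell_box(c) for c in self.cells]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if _boxes_overlap(boxes[i], boxes[j]):
                    raise ValueError(f"cells {i} and {j} overlap")


def cell_box(cell: CellSpec, margin: float = 1.2) -> tuple[int, int, int, int]:
    """Half-open square patch box ``(r0, c0, r1, c1)`` around a cell."""
    x, y = cell.center
    r = int(np.ceil(margin * max(cell.axes)))
    return (int(round(y)) - r, int(round(x)) - r, int(round(y)) + r, int(round(x)) + r)


def _boxes_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def _ellipse_mask(shape: tuple[int, int], cell: CellSpec) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = cell.center
    th = np.deg2rad(cell.angle)
    ca, sa = np.cos(th), np.sin(th)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    a, b = cell.axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass
class SceneRender:
    """Rendered scene: the three frames plus exact ground truth.

    ``ds_clean``/``ss_clean`` are the noise-free fluorescence renders in
    brightfield coordinates (float, zero background) from which the truth
    DFI values are computed; ``labels`` assigns each brightfield pixel its
    cell index (-1 for background).
    """

    bfi: np.ndarray
    dsdna: np.ndarray
    ssdna: np.ndarray
    truth: pd.DataFrame
    ds_clean: np.ndarray
    ss_clean: np.ndarray
    labels: np.ndarray
    spec: SceneSpec

    def __iter__(self):  # (bfi, dsdna, ssdna, truth) tuple-unpacking
        return iter((self.bfi, self.dsdna, self.ssdna, self.truth))


def render_scene(spec: SceneSpec, frame_id: int = 0, dtype=np.uint8) -> SceneRender:
    """Render one brightfield/dsDNA/ssDNA frame triplet with ground truth.

    The fluorescence frames are rendered in brightfield coordinates, warped
    into their own (misaligned) frame by ``spec.homography_true``, and then
    offset by an additive integer background drawn i.i.d. per pixel from
    ``{bg_level - jitter, ..., bg_level + jitter}`` (cells sit on top of the
    background glow, which is what makes scalar background subtraction the
    correct denoiser).  Truth DFI is computed from the noise-free, pre-warp
    renders.
    """
    if np.dtype(dtype) not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError("dtype must be uint8 or uint16")
    h, w = spec.frame_size
    rng = np.random.default_rng(spec.seed)

    tex = gaussian_filter(rng.standard_normal((h, w)), TEX_SIGMA)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    t = TEX_LO + (1.0 - TEX_LO) * tex

    bfi = np.full((h, w), BFI_BG, dtype=float)
    ds_clean = np.zeros((h, w), dtype=float)
    ss_clean = np.zeros((h, w), dtype=float)
    labels = np.full((h, w), -1, dtype=np.int32)

    rows = []
    for i, cell in enumerate(spec.cells):
        m = _ellipse_mask((h, w), cell)
        bfi[m] = (BFI_BG + (BFI_DS_GAIN * cell.dsdna_intensity + BFI_SS_GAIN * cell.ssdna_intensity) * t)[m]
        ds_clean[m] = (cell.dsdna_intensity * t)[m]
        ss_clean[m] = (cell.ssdna_intensity * t)[m]
        labels[m] = i
        ds_sum = float(ds_clean[m].sum())
        ss_sum = float(ss_clean[m].sum())
        r0, c0, r1, c1 = cell_box(cell)
        rows.append(
            dict(
                donor=spec.donor_id,
                frame=frame_id,
                cell=i,
                x0=c0,
                y0=r0,
                x1=c1,
                y1=r1,
                true_dfi=100.0 * ss_sum / (ss_sum + ds_sum),
            )
        )
    truth = pd.DataFrame(
        rows, columns=["donor", "frame", "cell", "x0", "y0", "x1", "y1", "true_dfi"]
    )

    scale = 257 if np.dtype(dtype) == np.uint16 else 1  # 255 * 257 == 65535
    lim = 65535 if scale == 257 else 255
    bfi_q = np.clip(np.round(bfi * scale), 0, lim).astype(dtype)

    def _fluor_frame(clean: np.ndarray, bg_level: int) -> np.ndarray:
        if is_identity(spec.homography_true):
            warped = clean
        else:
            # skimage's inverse_map takes output (fluorescence-frame) coords to
            # input (brightfield-frame) coords, which is exactly H_true.
            warped = sktf.warp(
                clean,
                sktf.ProjectiveTransform(matrix=spec.homography_true),
                order=1,
                cval=0.0,
                preserve_range=True,
            )
        bg = rng.integers(bg_level - spec.bg_jitter, bg_level + spec.bg_jitter + 1, size=clean.shape)
        out = np.clip(np.round(warped) * scale + bg * scale, 0, lim)
        return out.astype(dtype)

    ds_frame = _fluor_frame(ds_clean, spec.bg_level_ds)
    ss_frame = _fluor_frame(ss_clean, spec.bg_level_ss)

    return SceneRender(
        bfi=bfi_q,
        dsdna=ds_frame,
        ssdna=ss_frame,
        truth=truth,
        ds_clean=ds_clean,
        ss_clean=ss_clean,
        labels=labels,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# donor-structured dataset generation


def _sample_cells(
    rng: np.random.Generator,
    n: int,
    frame_size: tuple[int, int],
    donor_mean_dfi: float,
    total_intensity: float,
    border_margin: int = 24,
) -> list[CellSpec]:
    """Place ``n`` non-overlapping heads; per-cell DFI ~ Normal(donor mean, 12)
    clipped to [3, 75], with ds + ss = total_intensity.

    ``border_margin`` keeps patch boxes away from the frame edge so that the
    sampled inter-modality misalignments (up to ~20 px of translation) cannot
    push a cell's box outside the fluorescence frame.
    """
    h, w = frame_size
    cells: list[CellSpec] = []
    tries = 0
    while len(cells) < n:
        tries += 1
        if tries > 500 * max(n, 1):
            raise ValueError(
                f"could not place {n} non-overlapping cells in a {h}x{w} frame"
            )
        a = rng.uniform(10.0, 14.0)
        b = rng.uniform(6.0, 9.0)
        r = int(np.ceil(1.2 * a)) + border_margin
        cx = rng.uniform(r + 1, w - r - 2)
        cy = rng.uniform(r + 1, h - r - 2)
        dfi = float(np.clip(rng.normal(donor_mean_dfi, 12.0), 3.0, 75.0))
        cand = CellSpec(
            center=(cx, cy),
            axes=(a, b),
            angle=rng.uniform(0.0, 180.0),
            dsdna_intensity=total_intensity * (1.0 - dfi / 100.0),
            ssdna_intensity=total_intensity * dfi / 100.0,
        )
        cb = cell_box(cand)
        if all(not _boxes_overlap(cb, cell_box(c)) for c in cells):
            cells.append(cand)
    return cells


def _sample_homography(rng: np.random.Generator, frame_size: tuple[int, int]) -> np.ndarray:
    h, w = frame_size
    return make_homography(
        tx=rng.uniform(-20.0, 20.0),
        ty=rng.uniform(-20.0, 20.0),
        theta_deg=rng.uniform(-5.0, 5.0),
        scale=rng.uniform(0.95, 1.05),
        center=(w / 2.0, h / 2.0),
    )


def random_scene(
    seed: int,
    frame_size: tuple[int, int] = (160, 160),
    n_cells: int = 10,
    bg_level_ds: int = 10,
    bg_level_ss: int = 14,
    bg_jitter: int = 1,
    homography: str | np.ndarray = "random",
    mean_dfi: float = 30.0,
    total_intensity: float = 240.0,
    border_margin: int = 0,
    donor_id: str = "donor_1",
) -> SceneSpec:
    """Convenience sampler: one seeded scene with ``n_cells`` random heads.

    ``homography`` is ``"random"`` (translation +-20 px, rotation +-5 deg,
    scale 0.95-1.05), ``"identity"``, or an explicit 3x3 matrix.
    """
    rng = np.random.default_rng(seed)
    cells = _sample_cells(
        rng, n_cells, frame_size, mean_dfi, total_intensity, border_margin=border_margin
    )
    if isinstance(homography, str):
        if homography == "random":
            H = _sample_homography(rng, frame_size)
        elif homography == "identity":
            H = identity_homography()
        else:
            raise ValueError("homography must be 'random', 'identity' or a 3x3 matrix")
    else:
        H = normalize_homography(homography)
    return SceneSpec(
        frame_size=frame_size,
        cells=tuple(cells),
        bg_level_ds=bg_level_ds,
        bg_level_ss=bg_level_ss,
        bg_jitter=bg_jitter,
        homography_true=H,
        seed=int(rng.integers(0, 2**31 - 1)),
        donor_id=donor_id,
    )


def generate_donor_dataset(
    out_dir: str | Path,
    n_donors: int = 6,
    cells_per_donor: int = 50,
    spec_template: SceneSpec | None = None,
    seed: int = 0,
    cells_per_frame: int = 8,
    total_intensity: float = 240.0,
    homography: str | np.ndarray = "random",
    force: bool = False,
    dtype=np.uint8,
) -> pd.DataFrame:
    """Write a donor-structured paired dataset to disk and return its truth table.

    Layout: ``<out>/donor_<k>/{bfi,dsdna,ssdna}/frame_<j>.tiff`` plus
    ``<out>/truth.csv`` and ``<out>/homographies.csv`` (the true per-frame
    fluorescence-to-brightfield transforms).  Donors differ in their mean DFI
    (drawn uniformly in [15, 45]), mimicking inter-donor sperm-quality
    variation.  ``homography`` is either ``"random"`` (a fresh misalignment
    per frame, translations within +-20 px, rotations within +-5 degrees,
    scale 0.95-1.05) or a fixed 3x3 matrix applied to every frame.
    """
    from .io import write_image  # local import to avoid cycle at module load

    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if cells_per_donor < 1:
        raise ValueError("cells_per_donor must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (pass force=True to overwrite)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    if spec_template is None:
        spec_template = SceneSpec(frame_size=(192, 192))
    ss = np.random.SeedSequence(seed)
    donor_rngs = [np.random.default_rng(s) for s in ss.spawn(n_donors)]

    truth_parts = []
    hom_rows = []
    for k in range(n_donors):
        donor = f"donor_{k + 1}"
        rng = donor_rngs[k]
        donor_mean_dfi = rng.uniform(15.0, 45.0)
        for sub in ("bfi", "dsdna", "ssdna"):
            (out / donor / sub).mkdir(parents=True, exist_ok=True)
        n_frames = int(np.ceil(cells_per_donor / cells_per_frame))
        base, extra = divmod(cells_per_donor, n_frames)
        per_frame = [base + (1 if j < extra else 0) for j in range(n_frames)]
        for j, n in enumerate(per_frame):
            cells = _sample_cells(rng, n, spec_template.frame_size, donor_mean_dfi, total_intensity)
            if isinstance(homography, str):
                if homography != "random":
                    raise ValueError("homography must be 'random' or a 3x3 matrix")
                H = _sample_homography(rng, spec_template.frame_size)
            else:
                H = normalize_homography(homography)
            spec = dataclasses.replace(
                spec_template,
                cells=tuple(cells),
                homography_true=H,
                seed=int(rng.integers(0, 2**31 - 1)),
                donor_id=donor,
            )
            render = render_scene(spec, frame_id=j, dtype=dtype)
            write_image(out / donor / "bfi" / f"frame_{j}.tiff", render.bfi)
            write_image(out / donor / "dsdna" / f"frame_{j}.tiff", render.dsdna)
            write_image(out / donor / "ssdna" / f"frame_{j}.tiff", render.ssdna)
            truth_parts.append(render.truth)
            hom_rows.append(
                dict(donor=donor, frame=j, **{f"h{r}{c}": H[r, c] for r in range(3) for c in range(3)})
            )

    truth = pd.concat(truth_parts, ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False)
    pd.DataFrame(hom_rows).to_csv(out / "homographies.csv", index=False)
    return truth
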