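"""Keypoint-based registration of fluorescence frames onto brightfield frames.

Pipeline per frame pair: SIFT keypoints and descriptors are extracted from
both modalities, matched with k=2 nearest-neighbor descriptor matching,
filtered with Lowe's ratio test, and a projective transform (homography) from
fluorescence to brightfield coordinates is fitted with RANSAC.  The RANSAC
estimate is then polished by guided re-matching: keypoints are re-paired by
geometric proximity under the current transform and the homography is refit
by least squares on progressively tighter inlier sets, which brings corner
reprojection errors to the sub-pixel level.  Finally the fluorescence frame
is warped into brightfield coordinates, per-cell patches are cropped at
brightfield-defined boxes, and each patch is resized with bilinear scaling.

Matching is performed on subpixel keypoint positions; detection runs on an
8-bit rendering of the frames while warping is applied at the original bit
depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import transform as sktf
from skimage.feature import SIFT
from skimage.measure import ransac as sk_ransac
from sklearn.base import BaseEstimator

from .geometry import is_identity, normalize_homography

logger = logging.getLogger(__name__)

__all__ = [
    "KeypointMatch",
    "PatchBox",
    "RegistrationResult",
    "InsufficientFeaturesError",
    "RegistrationError",
    "detect_and_match",
    "lowe_ratio_filter",
    "estimate_homography",
    "register_frames",
    "warp_and_crop",
    "build_paired_dataset",
    "HomographyRegistrar",
]

# SIFT sensitivity: a lowered DoG threshold and relaxed edge rejection yield
# denser keypoint sets on low-texture micrographs, which the robust fit needs.
_SIFT_KW = dict(upsampling=2, c_dog=0.006, c_edge=12)

DEFAULT_RATIO = 0.75
DEFAULT_RANSAC_PX = 3.0
# minimum RANSAC consensus size; counts are taken after one-to-one
# deduplication, and 8 well-spread correspondences determine a homography
# comfortably (4 is the mathematical minimum)
DEFAULT_MIN_INLIERS = 8


class InsufficientFeaturesError(RuntimeError):
    pass


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class KeypointMatch:
    """One k=2 descriptor match: fluorescence point, best brightfield point,
    and the two smallest descriptor distances."""

    src_pt: tuple[float, float]  # (x, y) in the fluorescence frame
    dst_pt: tuple[float, float]  # (x, y) in the brightfield frame
    dist_best: float
    dist_second: float

    def __post_init__(self) -> None:
        if self.dist_best < 0 or self.dist_second < 0:
            raise ValueError("descriptor distances must be >= 0")
        if self.dist_best > self.dist_second:
            raise ValueError("dist_best must be <= dist_second")


@dataclass(frozen=True)
class PatchBox:
    """Half-open pixel box ``[row, row+height) x [col, col+width)`` in
    brightfield-frame coordinates."""

    row: int
    col: int
    height: int
    width: int
    frame_id: object = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("box height and width must be > 0")

    @classmethod
    def from_corners(cls, r0: int, c0: int, r1: int, c1: int, frame_id=None) -> "PatchBox":
        return cls(r0, c0, r1 - r0, c1 - c0, frame_id)


@dataclass(frozen=True)
class RegistrationResult:
    homography: np.ndarray
    n_matches: int
    n_inliers: int
    rmse: float


def _as_8bit(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.dtype == np.uint8:
        return frame
    if frame.dtype == np.uint16:
        return (frame // 257).astype(np.uint8)
    lo, hi = float(frame.min()), float(frame.max())
    if hi <= lo:
        return np.zeros(frame.shape, dtype=np.uint8)
    return np.round(255.0 * (frame - lo) / (hi - lo)).astype(np.uint8)


def _extract(frame: np.ndarray, name: str) -> SIFT:
    det = SIFT(**_SIFT_KW)
    try:
        det.detect_and_extract(_as_8bit(frame))
    except RuntimeError as exc:
        raise InsufficientFeaturesError(f"insufficient features in {name} frame: {exc}") from exc
    if len(det.keypoints) < 4:
        raise InsufficientFeaturesError(
            f"insufficient features in {name} frame: only {len(det.keypoints)} keypoint(s)"
        )
    return det


def _knn_matches(det_b: SIFT, det_f: SIFT) -> list[KeypointMatch]:
    tree = cKDTree(det_b.descriptors.astype(float))
    dists, idx = tree.query(det_f.descriptors.astype(float), k=2)
    src = det_f.positions[:, ::-1].astype(float)  # subpixel (x, y)
    dst = det_b.positions[:, ::-1].astype(float)
    return [
        KeypointMatch(
            src_pt=(src[i, 0], src[i, 1]),
            dst_pt=(dst[idx[i, 0], 0], dst[idx[i, 0], 1]),
            dist_best=float(dists[i, 0]),
            dist_second=float(dists[i, 1]),
        )
        for i in range(len(src))
    ]


def _check_same_depth(bfi_frame: np.ndarray, fl_frame: np.ndarray) -> None:
    if bfi_frame.dtype != fl_frame.dtype:
        raise ValueError(
            f"frames must share a bit depth, got {bfi_frame.dtype} vs {fl_frame.dtype}"
        )


def detect_and_match(bfi_frame: np.ndarray, fl_frame: np.ndarray) -> list[KeypointMatch]:
    """SIFT keypoints in both frames, k=2 nearest-neighbor descriptor matches
    from fluorescence (source) to brightfield (destination)."""
    bfi_frame = np.asarray(bfi_frame)
    fl_frame = np.asarray(fl_frame)
    _check_same_depth(bfi_frame, fl_frame)
    det_b = _extract(bfi_frame, "brightfield")
    det_f = _extract(fl_frame, "fluorescence")
    return _knn_matches(det_b, det_f)


def lowe_ratio_filter(matches: list[KeypointMatch], ratio: float = DEFAULT_RATIO) -> list[KeypointMatch]:
    """Keep matches whose best descriptor distance is below ``ratio`` times
    the second-best; order preserved."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    return [m for m in matches if m.dist_best < ratio * m.dist_second]


def _match_arrays(matches: list[KeypointMatch]) -> tuple[np.ndarray, np.ndarray]:
    src = np.array([m.src_pt for m in matches], dtype=float).reshape(-1, 2)
    dst = np.array([m.dst_pt for m in matches], dtype=float).reshape(-1, 2)
    return src, dst


def estimate_homography(
    matches: list[KeypointMatch],
    ransac_threshold_px: float = DEFAULT_RANSAC_PX,
    seed: int = 0,
    min_inliers: int = DEFAULT_MIN_INLIERS,
    max_trials: int = 5000,
) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC homography (fluorescence -> brightfield) from filtered matches.

    Returns the normalized 3x3 matrix (refit by least squares on the RANSAC
    consensus set) and the boolean inlier mask.  Raises
    :class:`RegistrationError` with fewer than 4 matches or a consensus set
    smaller than ``min_inliers``.
    """
    if len(matches) < 4:
        raise RegistrationError(f"registration failed: need >= 4 matches, got {len(matches)}")
    # one-to-one matching: several source keypoints may share a destination
    # keypoint, but at most one of them can be geometrically correct, and the
    # duplicates let degenerate (collapse) models accumulate fake consensus.
    best_for_dst: dict[tuple[float, float], int] = {}
    for i, m in enumerate(matches):
        j = best_for_dst.get(m.dst_pt)
        if j is None or m.dist_best < matches[j].dist_best:
            best_for_dst[m.dst_pt] = i
    retained = sorted(best_for_dst.values())
    if len(retained) < 4:
        raise RegistrationError(
            f"registration failed: only {len(retained)} unique correspondences"
        )
    src, dst = _match_arrays([matches[i] for i in retained])
    model, inliers = sk_ransac(
        (src, dst),
        sktf.ProjectiveTransform,
        min_samples=4,
        residual_threshold=ransac_threshold_px,
        max_trials=max_trials,
        rng=seed,
        # rank-deficient candidates (collapse transforms) can accumulate fake
        # consensus from duplicated destination keypoints; reject them early
        is_model_valid=lambda m, *data: _valid_homography(m.params),
    )
    if model is None or inliers is None:
        raise RegistrationError("registration failed: RANSAC found no consensus")
    inliers = np.asarray(inliers, dtype=bool)
    if inliers.sum() < max(4, min_inliers):
        raise RegistrationError(
            f"registration failed: only {int(inliers.sum())} inliers "
            f"(minimum {max(4, min_inliers)})"
        )
    refit = sktf.ProjectiveTransform.from_estimate(src[inliers], dst[inliers])
    if refit and _valid_homography(refit.params):
        model = refit
    if not _valid_homography(model.params):
        raise RegistrationError("registration failed: degenerate homography estimate")
    full_mask = np.zeros(len(matches), dtype=bool)
    full_mask[np.asarray(retained)[inliers]] = True
    return normalize_homography(model.params), full_mask


def _valid_homography(H: np.ndarray) -> bool:
    H = np.asarray(H, dtype=float)
    return bool(np.all(np.isfinite(H)) and abs(H[2, 2]) > 1e-9
                and abs(np.linalg.det(H / H[2, 2])) > 1e-6)


def _refine_guided(
    H: np.ndarray, src_all: np.ndarray, dst_all: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """Polish ``H`` by geometric re-matching of the full keypoint sets.

    At each round, keypoints are paired one-to-one (each brightfield anchor
    takes the geometrically closest predicted fluorescence keypoint within
    the round's gate) and the transform is refit by iteratively reweighted
    least squares with Huber weights; the gate anneals between rounds.  When
    the RANSAC estimate shows no perspective component (negligible bottom-row
    terms) the refit is restricted to an affine model: the two unsupported
    projective degrees of freedom otherwise amplify keypoint noise into
    corner-extrapolation error.  Returns the refined homography, the final
    weighted-inlier RMSE, and the final pair count.
    """
    def _irls(fit_fn, model0):
        model = model0
        rmse, n_used = float("nan"), 0
        gate, huber = 2.5, 0.3
        tree = cKDTree(dst_all)
        for _ in range(3):
            pred = model(src_all)
            gd, gi = tree.query(pred, k=1)
            best: dict[int, int] = {}
            for i in np.flatnonzero(gd < gate):
                j = int(gi[i])
                if j not in best or gd[i] < gd[best[j]]:
                    best[j] = i
            sel = np.array(sorted(best.values()), dtype=int)
            if sel.size < 8:
                break
            s, d = src_all[sel], dst_all[gi[sel]]
            for _ in range(5):
                res = np.linalg.norm(model(s) - d, axis=1)
                wgt = np.where(res <= huber, 1.0, huber / np.maximum(res, 1e-9))
                cand = fit_fn(s, d, wgt)
                if cand is None or not _valid_homography(cand):
                    break
                model = sktf.ProjectiveTransform(matrix=cand)
            res = np.linalg.norm(model(s) - d, axis=1)
            keep = res < 1.0
            rmse = float(np.sqrt(np.mean(res[keep] ** 2))) if keep.sum() else float("nan")
            n_used = int(keep.sum())
            gate = max(0.8, gate * 0.5)
        return model, rmse, n_used

    model0 = sktf.ProjectiveTransform(matrix=H)
    model_a, rmse_a, n_a = _irls(_fit_affine_weighted, model0)
    # keep the two extra projective degrees of freedom only when they clearly
    # reduce the residual: unsupported, they turn keypoint noise into
    # corner-extrapolation error
    model_p, rmse_p, n_p = _irls(_fit_projective_weighted, model0)
    if (np.isfinite(rmse_p) and n_p >= n_a and
            (not np.isfinite(rmse_a) or rmse_p < 0.7 * rmse_a)):
        model, rmse, n_used = model_p, rmse_p, n_p
    else:
        model, rmse, n_used = model_a, rmse_a, n_a
    if not _valid_homography(model.params):
        return H, float("nan"), 0
    return normalize_homography(model.params), rmse, n_used


def _fit_affine_weighted(s: np.ndarray, d: np.ndarray, w: np.ndarray) -> np.ndarray | None:
    """Weighted least-squares affine fit s -> d; returns a 3x3 matrix."""
    sw = np.sqrt(w)
    n = len(s)
    A = np.zeros((2 * n, 6))
    b = np.zeros(2 * n)
    A[0::2, 0] = s[:, 0] * sw
    A[0::2, 1] = s[:, 1] * sw
    A[0::2, 2] = sw
    A[1::2, 3] = s[:, 0] * sw
    A[1::2, 4] = s[:, 1] * sw
    A[1::2, 5] = sw
    b[0::2] = d[:, 0] * sw
    b[1::2] = d[:, 1] * sw
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.all(np.isfinite(p)):
        return None
    return np.array([[p[0], p[1], p[2]], [p[3], p[4], p[5]], [0.0, 0.0, 1.0]])


def _fit_projective_weighted(s: np.ndarray, d: np.ndarray, w: np.ndarray) -> np.ndarray | None:
    """Weighted DLT homography fit s -> d (rows of the design matrix scaled
    by sqrt(w))."""
    sw = np.sqrt(w)
    n = len(s)
    A = np.zeros((2 * n, 9))
    x, y = s[:, 0], s[:, 1]
    u, v = d[:, 0], d[:, 1]
    A[0::2, 0] = x * sw
    A[0::2, 1] = y * sw
    A[0::2, 2] = sw
    A[0::2, 6] = -u * x * sw
    A[0::2, 7] = -u * y * sw
    A[0::2, 8] = -u * sw
    A[1::2, 3] = x * sw
    A[1::2, 4] = y * sw
    A[1::2, 5] = sw
    A[1::2, 6] = -v * x * sw
    A[1::2, 7] = -v * y * sw
    A[1::2, 8] = -v * sw
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    h = vt[-1]
    if not np.all(np.isfinite(h)) or abs(h[8]) < 1e-12:
        return None
    return h.reshape(3, 3) / h[8]


def register_frames(
    bfi_frame: np.ndarray,
    fl_frame: np.ndarray,
    ratio: float = DEFAULT_RATIO,
    ransac_threshold_px: float = DEFAULT_RANSAC_PX,
    seed: int = 0,
    min_inliers: int = DEFAULT_MIN_INLIERS,
    guided_refine: bool = True,
) -> RegistrationResult:
    """Full per-frame registration: detect, match, ratio-filter, RANSAC,
    guided refinement (the refinement re-matches over all detected keypoints,
    not only the descriptor-matched ones)."""
    bfi_frame = np.asarray(bfi_frame)
    fl_frame = np.asarray(fl_frame)
    _check_same_depth(bfi_frame, fl_frame)
    det_b = _extract(bfi_frame, "brightfield")
    det_f = _extract(fl_frame, "fluorescence")
    matches = _knn_matches(det_b, det_f)
    kept = lowe_ratio_filter(matches, ratio)
    H, inliers = estimate_homography(
        kept, ransac_threshold_px=ransac_threshold_px, seed=seed, min_inliers=min_inliers
    )
    src, dst = _match_arrays(kept)
    res = np.linalg.norm(
        sktf.ProjectiveTransform(matrix=H)(src[inliers]) - dst[inliers], axis=1
    )
    rmse = float(np.sqrt(np.mean(res**2)))
    n_inl = int(inliers.sum())
    if guided_refine:
        src_all = det_f.positions[:, ::-1].astype(float)
        dst_all = det_b.positions[:, ::-1].astype(float)
        H, g_rmse, g_n = _refine_guided(H, src_all, dst_all)
        if g_n >= 8:
            rmse, n_inl = g_rmse, g_n
    return RegistrationResult(homography=H, n_matches=len(kept), n_inliers=n_inl, rmse=rmse)


def warp_and_crop(
    fl_frame: np.ndarray,
    H: np.ndarray,
    boxes,
    out_size: int = 256,
    return_kept: bool = False,
):
    """Warp a fluorescence frame into brightfield coordinates, crop the given
    brightfield-frame boxes, and resize each crop to ``out_size`` squared
    (bilinear).

    Boxes may be :class:`PatchBox` instances or ``(r0, c0, r1, c1)`` half-open
    corner tuples.  Boxes falling outside the frame are skipped with a logged
    warning; pass ``return_kept=True`` to also get the indices of the boxes
    that produced output.
    """
    if out_size < 16:
        raise ValueError(f"out_size must be >= 16, got {out_size}")
    fl_frame = np.asarray(fl_frame)
    H = normalize_homography(H)
    if is_identity(H):
        aligned = fl_frame.astype(float)
    else:
        # warp output lives in brightfield coords; skimage's inverse_map must
        # take brightfield coords to fluorescence coords, i.e. H^{-1}.
        aligned = sktf.warp(
            fl_frame.astype(float),
            sktf.ProjectiveTransform(matrix=np.linalg.inv(H)),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
    h, w = aligned.shape
    patches, kept = [], []
    for i, box in enumerate(boxes):
        if isinstance(box, PatchBox):
            r0, c0, r1, c1 = box.row, box.col, box.row + box.height, box.col + box.width
        else:
            r0, c0, r1, c1 = box
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
            logger.warning("box %d (%s) outside %dx%d frame; skipped", i, (r0, c0, r1, c1), h, w)
            continue
        crop = aligned[r0:r1, c0:c1]
        if crop.shape != (out_size, out_size):
            crop = sktf.resize(
                crop, (out_size, out_size), order=1, anti_aliasing=False, preserve_range=True
            )
        if np.issubdtype(fl_frame.dtype, np.integer):
            info = np.iinfo(fl_frame.dtype)
            crop = np.clip(np.round(crop), info.min, info.max).astype(fl_frame.dtype)
        patches.append(crop)
        kept.append(i)
    return (patches, kept) if return_kept else patches


class HomographyRegistrar(BaseEstimator):
    """Estimator wrapper around :func:`register_frames`.

    ``fit(X, y)`` takes the fluorescence frame ``X`` and the brightfield
    frame ``y`` and estimates ``homography_`` (fluorescence -> brightfield);
    ``transform`` warps frames (optionally cropping boxes) into brightfield
    coordinates.
    """

    def __init__(
        self,
        ratio: float = DEFAULT_RATIO,
        ransac_threshold_px: float = DEFAULT_RANSAC_PX,
        min_inliers: int = DEFAULT_MIN_INLIERS,
        guided_refine: bool = True,
        seed: int = 0,
    ):
        self.ratio = ratio
        self.ransac_threshold_px = ransac_threshold_px
        self.min_inliers = min_inliers
        self.guided_refine = guided_refine
        self.seed = seed

    def fit(self, X, y):
        result = register_frames(
            bfi_frame=y,
            fl_frame=X,
            ratio=self.ratio,
            ransac_threshold_px=self.ransac_threshold_px,
            seed=self.seed,
            min_inliers=self.min_inliers,
            guided_refine=self.guided_refine,
        )
        self.homography_ = result.homography
        self.n_matches_ = result.n_matches
        self.n_inliers_ = result.n_inliers
        self.rmse_ = result.rmse
        return self

    def transform(self, X, boxes=None, out_size: int = 256):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "homography_")
        X = np.asarray(X)
        if boxes is None:  # full-frame warp, no crop or resize
            if is_identity(self.homography_):
                return X.copy()
            aligned = sktf.warp(
                X.astype(float),
                sktf.ProjectiveTransform(matrix=np.linalg.inv(self.homography_)),
                order=1,
                cval=0.0,
                preserve_range=True,
            )
            if np.issubdtype(X.dtype, np.integer):
                info = np.iinfo(X.dtype)
                aligned = np.clip(np.round(aligned), info.min, info.max).astype(X.dtype)
            return aligned
        return warp_and_crop(X, self.homography_, boxes, out_size=out_size)


def build_paired_dataset(
    dataset_root: str | Path,
    out_root: str | Path,
    size: int = 256,
    ratio: float = DEFAULT_RATIO,
    ransac_threshold_px: float = DEFAULT_RANSAC_PX,
    min_inliers: int = DEFAULT_MIN_INLIERS,
    seed: int = 0,
    guided_refine: bool = True,
) -> pd.DataFrame:
    """Build the pixel-wise paired patch dataset from a donor-structured
    frame layout (``<root>/donor_<k>/{bfi,dsdna,ssdna}/frame_<j>.tiff`` with a
    ``truth.csv`` giving per-cell patch boxes).

    For every frame, one homography is estimated per fluorescence modality;
    each cell's brightfield box is cropped from the brightfield frame and
    from both warped fluorescence frames, resized to ``size``, and written to
    ``<out>/donor_<k>/pair_<j>_<c>/{bfi,dsdna,ssdna}.tiff``.  The returned
    manifest (also written as ``manifest.csv``) records per-cell registration
    inlier counts and reprojection RMSE; frames whose registration fails are
    marked ``status=failed`` and excluded from the patch output.
    """
    from .io import read_image, write_image, write_report

    root = Path(dataset_root)
    out = Path(out_root)
    truth = pd.read_csv(root / "truth.csv")
    manifest_rows = []
    for (donor, frame_id), cells in truth.groupby(["donor", "frame"], sort=True):
        bfi = read_image(root / donor / "bfi" / f"frame_{frame_id}.tiff")
        frame_seed = seed + 7919 * int(frame_id)
        regs = {}
        status, reason = "ok", ""
        for modality in ("dsdna", "ssdna"):
            fl = read_image(root / donor / modality / f"frame_{frame_id}.tiff")
            try:
                regs[modality] = (
                    fl,
                    register_frames(
                        bfi,
                        fl,
                        ratio=ratio,
                        ransac_threshold_px=ransac_threshold_px,
                        seed=frame_seed,
                        min_inliers=min_inliers,
                        guided_refine=guided_refine,
                    ),
                )
            except (InsufficientFeaturesError, RegistrationError) as exc:
                if modality == "ssdna" and "dsdna" in regs:
                    # the two fluorescence channels are acquired through the
                    # same optics, so the dsDNA transform is a valid fallback
                    # when the dimmer ssDNA channel lacks features
                    logger.warning(
                        "ssDNA registration failed for %s frame %s (%s); "
                        "reusing the dsDNA homography", donor, frame_id, exc
                    )
                    regs[modality] = (fl, regs["dsdna"][1])
                else:
                    status, reason = "failed", f"{modality}: {exc}"
                    logger.warning(
                        "registration failed for %s frame %s: %s", donor, frame_id, exc
                    )
                    break
        boxes = [
            (int(r.y0), int(r.x0), int(r.y1), int(r.x1)) for r in cells.itertuples()
        ]
        if status == "ok":
            # drop boxes whose fluorescence-frame preimage leaves the frame:
            # their warped content would include out-of-frame fill
            fh, fw = bfi.shape
            valid = []
            for r0, c0, r1, c1 in boxes:
                corners = np.array(
                    [[c0, r0], [c1 - 1, r0], [c0, r1 - 1], [c1 - 1, r1 - 1]], dtype=float
                )
                ok_box = True
                for _, res in regs.values():
                    pre = sktf.ProjectiveTransform(matrix=res.homography).inverse(corners)
                    if (pre[:, 0].min() < 0 or pre[:, 1].min() < 0
                            or pre[:, 0].max() > fw - 1 or pre[:, 1].max() > fh - 1):
                        ok_box = False
                        break
                valid.append(ok_box)
        if status == "ok":
            bfi_patches, kept = warp_and_crop(
                bfi, np.eye(3), boxes, out_size=size, return_kept=True
            )
            warped = {
                m: warp_and_crop(fl, res.homography, boxes, out_size=size)
                for m, (fl, res) in regs.items()
            }
            mean_inl = int(np.mean([res.n_inliers for _, res in regs.values()]))
            mean_rmse = float(np.mean([res.rmse for _, res in regs.values()]))
            cell_rows = list(cells.itertuples())
            patch_idx = {pos: j for j, pos in enumerate(kept)}
            kept = [pos for pos in kept if valid[pos]]
            kept_set = set(kept)
            for pos in kept:
                j = patch_idx[pos]
                r = cell_rows[pos]
                pair_dir = out / donor / f"pair_{frame_id}_{r.cell}"
                write_image(pair_dir / "bfi.tiff", bfi_patches[j])
                write_image(pair_dir / "dsdna.tiff", warped["dsdna"][j])
                write_image(pair_dir / "ssdna.tiff", warped["ssdna"][j])
                manifest_rows.append(
                    dict(
                        donor=donor,
                        frame=int(frame_id),
                        cell=int(r.cell),
                        status="ok",
                        inliers=mean_inl,
                        rmse=mean_rmse,
                        reason="",
                    )
                )
            for pos, r in enumerate(cell_rows):
                if pos not in kept_set:
                    manifest_rows.append(
                        dict(
                            donor=donor,
                            frame=int(frame_id),
                            cell=int(r.cell),
                            status="skipped",
                            inliers=mean_inl,
                            rmse=mean_rmse,
                            reason="patch box outside frame",
                        )
                    )
        else:
            for r in cells.itertuples():
                manifest_rows.append(
                    dict(
                        donor=donor,
                        frame=int(frame_id),
                        cell=int(r.cell),
                        status="failed",
                        inliers=0,
                        rmse=float("nan"),
                        reason=reason,
                    )
                )
    manifest = pd.DataFrame(manifest_rows)
    write_report(manifest, out / "manifest.csv")
    return manifest
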