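"""End-to-end orchestration of both mosaicing methods on an image pair.

``run_vessel_pipeline`` chains preprocessing, vesselness filtering,
region-growing segmentation, skeleton block descriptors, SSD matching,
MSAC homography estimation and the mosaic merge; any stage's failure
signal becomes a self-reported failure in the returned report rather
than an exception.  ``run_affine_pipeline`` does the same for the
NMI-driven affine backend, and ``run_dual`` runs both and cross-checks
them via overlapdiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import matching, mosaic, preprocess, vessel_segmentation, vesselness
from .affine_backend import init_shift, register_affine_nmi
from .config import RegistrationConfig
from .errors import RegistrationFailure
from .failure_detection import (FailureModel, RegistrationReport, failure_alert,
                                overlapdiff, self_report)
from .image_io import GrayImage


@dataclass
class DualResult:
    vessel_report: RegistrationReport
    affine_report: RegistrationReport
    overlapdiff_pct: float | None
    flagged_for_inspection: bool
    vessel_mosaic: mosaic.MosaicResult | None = None

    def as_dict(self) -> dict:
        return {
            "vessel": self.vessel_report.as_dict(),
            "affine_nmi": self.affine_report.as_dict(),
            "overlapdiff_pct": self.overlapdiff_pct,
            "flagged_for_inspection": self.flagged_for_inspection,
        }


def run_vessel_pipeline(macula: GrayImage, onh: GrayImage,
                        config: RegistrationConfig = RegistrationConfig()
                        ) -> tuple[RegistrationReport, mosaic.MosaicResult | None]:
    """Vessel-feature homography method; macula view is the reference."""
    report = RegistrationReport(method="vessel")
    try:
        ref_img, _ = preprocess.enhance_if_needed(
            macula, th1=config.th1, tiles=config.clahe_tiles,
            clip_limit=config.clahe_clip_limit)
        mov_img, _ = preprocess.enhance_if_needed(
            onh, th1=config.th1, tiles=config.clahe_tiles,
            clip_limit=config.clahe_clip_limit)

        vr_ref = vesselness.multiscale_vesselness(
            ref_img, config.sigma_list, config.beta, config.c_fraction)
        vr_mov = vesselness.multiscale_vesselness(
            mov_img, config.sigma_list, config.beta, config.c_fraction)

        _, skel_ref = vessel_segmentation.extract_skeleton(
            vr_ref.V, vr_ref.grad_mag, config.q_vessel_seed,
            config.q_background_seed, config.region_grow_max_iter)
        _, skel_mov = vessel_segmentation.extract_skeleton(
            vr_mov.V, vr_mov.grad_mag, config.q_vessel_seed,
            config.q_background_seed, config.region_grow_max_iter)
        report.covariates["n_skeleton_ref"] = skel_ref.count
        report.covariates["n_skeleton_proj"] = skel_mov.count

        desc_ref = matching.extract_block_descriptors(vr_ref.V, skel_ref, config.block_size)
        desc_mov = matching.extract_block_descriptors(vr_mov.V, skel_mov, config.block_size)
        if len(desc_ref) == 0 or len(desc_mov) == 0:
            raise RegistrationFailure("no valid descriptor blocks")

        matches = matching.match_descriptors(desc_ref, desc_mov, th2=config.th2)
        report.n_matches = len(matches)
        if self_report(len(matches), len(matches), config.min_inliers):
            raise RegistrationFailure(f"{len(matches)} matches; cannot estimate homography")

        H = matching.estimate_homography_msac(
            matches, desc_ref.valid_points, desc_mov.valid_points,
            th3=config.th3, max_iter=config.msac_max_iter,
            confidence=config.msac_confidence, seed=config.rng_seed)
        report.n_inliers = int(H.inlier_indices.size)
        if self_report(report.n_matches, report.n_inliers, config.min_inliers):
            raise RegistrationFailure(f"{report.n_inliers} inliers; below minimum")

        inl = matches.pairs[H.inlier_indices]
        ref_pts = desc_ref.valid_points[inl[:, 0]]
        mov_pts = desc_mov.valid_points[inl[:, 1]]
        result = mosaic.warp_and_merge(macula, onh, H, projected_points=mov_pts)
        metrics = mosaic.alignment_metrics(ref_pts, mosaic.project_points(H, mov_pts))
        report.transform = H
        report.overlap_pct = result.overlap_fraction
        report.covariates.update({
            "overlap_pct": result.overlap_fraction,
            "rms_mean": metrics.rms_mean, "rms_max": metrics.rms_max,
            "d_mean": metrics.d_mean,
            "delta_x_mean": metrics.delta_x_mean,
            "delta_y_mean": metrics.delta_y_mean,
        })
        report.self_reported_failure = False
        return report, result
    except RegistrationFailure as exc:
        report.self_reported_failure = True
        report.failure_reason = str(exc)
        report.n_matches = report.n_matches or 0
        report.n_inliers = report.n_inliers or 0
        report.transform = None
        return report, None


def run_affine_pipeline(macula: GrayImage, onh: GrayImage,
                        config: RegistrationConfig = RegistrationConfig(),
                        model: FailureModel | None = None) -> RegistrationReport:
    """NMI affine method with 50%-shift initialization."""
    report = RegistrationReport(method="affine_nmi")
    try:
        init = init_shift(macula, onh, shift_fraction=config.shift_fraction,
                          laterality_flip=config.laterality_flip)
        tf = register_affine_nmi(macula, onh, init, levels=config.pyramid_levels,
                                 bins=config.nmi_bins)
        report.transform = tf
        report.overlap_pct = tf.overlap_pct
        report.covariates = {
            "similarity": tf.similarity, "nmi": tf.nmi,
            "overlap_pct": tf.overlap_pct,
            "tx": tf.params.tx, "ty": tf.params.ty,
            "rotation": tf.params.rotation, "skew": tf.params.skew,
        }
        if model is not None:
            report.failure_alert = failure_alert(model, report.covariates)
        report.self_reported_failure = False
    except RegistrationFailure as exc:
        report.self_reported_failure = True
        report.failure_reason = str(exc)
        report.transform = None
    return report


def run_dual(macula: GrayImage, onh: GrayImage,
             config: RegistrationConfig = RegistrationConfig(),
             model: FailureModel | None = None) -> DualResult:
    """Run both methods and cross-check their overlap percentages."""
    vessel_report, vessel_mosaic = run_vessel_pipeline(macula, onh, config)
    affine_report = run_affine_pipeline(macula, onh, config, model=model)
    both_ok = (vessel_report.transform is not None
               and affine_report.transform is not None)
    diff = overlapdiff(vessel_report, affine_report) if both_ok else None
    flagged = (not both_ok) or diff > config.overlapdiff_flag_threshold
    return DualResult(vessel_report=vessel_report, affine_report=affine_report,
                      overlapdiff_pct=diff, flagged_for_inspection=flagged,
                      vessel_mosaic=vessel_mosaic)


def corner_reprojection_error(H_est: np.ndarray | object, H_true: np.ndarray,
                              shape: tuple[int, int] = (768, 768)) -> float:
    """Maximum displacement of the image corners between two homographies.

    The standard scalar summary of how far an estimated transform is from
    the planted ground truth.
    """
    M = H_est.H if hasattr(H_est, "H") else np.asarray(H_est, float)
    h, w = shape
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    a = mosaic.project_points(M, corners)
    b = mosaic.project_points(np.asarray(H_true, float), corners)
    return float(np.max(np.linalg.norm(a - b, axis=1)))
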