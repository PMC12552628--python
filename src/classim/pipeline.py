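"""End-to-end experiment orchestration and evaluation metrics.

:func:`run_experiment` reproduces a whole bench experiment in software:
build a target, render a stack of frames through a fresh scatterer
realization per frame, optionally modulate, reconstruct with I-CLASS, and
score the result against the ground truth it was generated from.  Every
stage is deterministic given the config seed, and the manifest (metrics,
convergence trace, artifact paths) round-trips through JSON byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .io import save_stack, write_json
from .matrixops import psf_diagonality
from .objects import make_object
from .optics import ComplexField, PropagationConfig, fresnel_propagate
from .recon import (
    ReconResult,
    estimate_apsfs,
    estimate_frame_psfs,
    iclass_reconstruct,
    registered_correlation,
)
from .simulate import (
    FrameStack,
    NoiseParams,
    ObjectImage,
    ScreenParams,
    simulate_coherent_stack,
    simulate_incoherent_stack,
    simulate_offaxis_hologram,
)
from .optics import demodulate_offaxis

__all__ = ["ExperimentConfig", "run_experiment", "haze_metric", "align_to"]


class ScreenConfig(BaseModel):
    corr_len_px: float = 4.0
    rms_rad: float = 3 * np.pi
    pupil_radius_frac: float | None = 1.0


class NoiseConfig(BaseModel):
    photons_per_frame: float | None = None
    read_noise: float = 0.0


class ExperimentConfig(BaseModel):
    """Schema-validated description of one synthetic experiment."""

    mode: Literal["incoherent", "coherent"] = "incoherent"
    object_name: str = "bars"
    grid: int = 64
    n_frames: int = 150
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    frame_correlation: float = 0.0
    modulation: tuple[float, float] | None = None
    n_iter: int = 1000
    tol: float = 1e-6
    lowpass_frac: float | None = None
    seed: int = 0
    # coherent-mode geometry (scatterer-to-object distance and sampling)
    dz_um: float = 0.0
    wavelength_um: float = 0.6328
    pitch_um: float = 5.5
    holography: bool = False
    # carrier on exact DFT samples (18/64); clears a 0.25-Nyquist passband
    carrier_cycles: tuple[float, float] = (0.28125, 0.28125)
    ref_amplitude: float | None = None
    compute_diagonality: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.frame_correlation < 1:
            raise ValueError("frame_correlation must be in [0, 1)")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    """An experiment stage failed; carries the stage name and config hash."""

    def __init__(self, stage: str, config_hash: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (config {config_hash}): {cause}")
        self.stage = stage
        self.config_hash = config_hash


def align_to(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Cyclically shift (and possibly point-reflect) ``image`` onto ``reference``."""
    reg = registered_correlation(reference, image)
    out = image[::-1, ::-1] if reg.reflected else image
    return np.roll(out, shift=reg.shift, axis=(0, 1))


def haze_metric(recon_image: np.ndarray, truth: np.ndarray) -> float:
    """Median background intensity outside the registered object support.

    The reconstruction is registered onto the truth, floored at its
    minimum and scaled so the mean over the object support is 1; the score
    is the median of the scaled image outside the support (0 = no haze).
    """
    support = truth > 0.5 * truth.max()
    img = align_to(np.asarray(recon_image, float), truth)
    img = img - img.min()
    inside = img[support].mean()
    if inside == 0:
        raise ValueError("degenerate reconstruction: no energy on the support")
    return float(np.median(img[~support]) / inside)


def _simulate(cfg: ExperimentConfig):
    obj = make_object(cfg.object_name, cfg.grid, seed=cfg.seed)
    screen = ScreenParams(
        corr_len_px=cfg.screen.corr_len_px,
        rms_rad=cfg.screen.rms_rad,
        pupil_radius_frac=cfg.screen.pupil_radius_frac,
    )
    if cfg.mode == "incoherent":
        stack, psfs = simulate_incoherent_stack(
            ObjectImage(values=obj),
            cfg.n_frames,
            screen_params=screen,
            frame_correlation=cfg.frame_correlation,
            noise=NoiseParams(**cfg.noise.model_dump()),
            seed=cfg.seed,
        )
        return obj, obj, stack, psfs
    # coherent: the effective object is the mask propagated to the scatterer plane
    eff = obj.astype(complex)
    if cfg.dz_um != 0:
        prop = PropagationConfig(
            wavelength_um=cfg.wavelength_um,
            pitch_um=cfg.pitch_um,
            dz_um=-cfg.dz_um,
            shape=obj.shape,
        )
        eff = fresnel_propagate(
            ComplexField(field=eff, pitch_um=cfg.pitch_um, plane="obj"), prop
        ).field
    stack, apsfs = simulate_coherent_stack(
        ObjectImage(values=eff),
        n_frames=cfg.n_frames,
        screen_params=screen,
        frame_correlation=cfg.frame_correlation,
        seed=cfg.seed,
    )
    if cfg.holography:
        ref = cfg.ref_amplitude
        if ref is None:
            ref = float(np.abs(stack.frames).max())
        holos = np.stack(
            [
                simulate_offaxis_hologram(f, cfg.carrier_cycles, ref)
                for f in stack.frames
            ]
        )
        demod = np.stack(
            [demodulate_offaxis(h, cfg.carrier_cycles) for h in holos]
        )
        stack = FrameStack(
            frames=demod, mode="coherent", seed=cfg.seed, meta=dict(stack.meta)
        )
    return obj, eff, stack, apsfs


def run_experiment(cfg: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Simulate, reconstruct and evaluate one experiment; return the manifest."""
    chash = cfg.config_hash()
    try:
        truth_obj, truth_eff, stack, true_psfs = _simulate(cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", chash, e) from e
    try:
        recon = iclass_reconstruct(
            stack,
            n_iter=cfg.n_iter,
            tol=cfg.tol,
            modulation=cfg.modulation,
            lowpass_frac=cfg.lowpass_frac,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("reconstruct", chash, e) from e
    try:
        manifest = _evaluate(cfg, truth_obj, truth_eff, stack, true_psfs, recon)
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", chash, e) from e
    manifest["config"] = json.loads(cfg.model_dump_json())
    manifest["config_hash"] = chash
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_stack(stack, outdir / ("stack.tif" if stack.mode == "incoherent" else "stack.h5"))
        np.save(outdir / "object_image.npy", recon.object_image)
        write_json(outdir / "manifest.json", manifest)
        write_json(outdir / "config.json", manifest["config"])
        manifest["artifacts"] = sorted(p.name for p in outdir.iterdir())
    return manifest


def _evaluate(cfg, truth_obj, truth_eff, stack, true_psfs, recon: ReconResult) -> dict:
    metrics: dict = {}
    if cfg.mode == "incoherent":
        recon_img = recon.object_image
        truth_img = truth_obj
        mean_frame = np.asarray(stack.frames).mean(axis=0)
        metrics["r_mean_frame"] = registered_correlation(truth_img, mean_frame).r
        est = estimate_frame_psfs(stack, align_to(recon_img, truth_img))
        psf_corr = [
            registered_correlation(t.psf, e.psf).r
            for t, e in zip(true_psfs, est[: len(true_psfs)])
        ]
        metrics["psf_recovery_mean_r"] = float(np.mean(psf_corr))
        metrics["haze"] = haze_metric(recon_img, truth_img)
    else:
        truth_img = np.abs(truth_eff)
        recon_img = np.abs(recon.object_image)
        mean_frame = np.abs(np.asarray(stack.frames).mean(axis=0))
        try:
            metrics["r_mean_frame"] = registered_correlation(truth_img, mean_frame).r
        except ValueError:
            metrics["r_mean_frame"] = 0.0
        if cfg.dz_um != 0:
            prop = PropagationConfig(
                wavelength_um=cfg.wavelength_um,
                pitch_um=cfg.pitch_um,
                dz_um=cfg.dz_um,
                shape=truth_obj.shape,
            )
            back = fresnel_propagate(
                ComplexField(
                    field=recon.object_image, pitch_um=cfg.pitch_um, plane="scatt"
                ),
                prop,
            )
            metrics["r_object_plane"] = registered_correlation(
                np.abs(truth_obj), np.abs(back.field)
            ).r
        apsfs = estimate_apsfs(stack, truth_eff)
        apsf_corr = [
            registered_correlation(np.abs(t.field), np.abs(e.field)).r
            for t, e in zip(true_psfs, apsfs)
        ]
        metrics["apsf_recovery_mean_r"] = float(np.mean(apsf_corr))
    metrics["r_recon"] = registered_correlation(truth_img, recon_img).r
    if cfg.compute_diagonality and cfg.mode == "incoherent":
        metrics["psf_diagonality"] = psf_diagonality(
            np.stack([p.psf for p in true_psfs])
        )
    return {
        "metrics": metrics,
        "n_iter": recon.n_iter,
        "converged": bool(recon.converged),
        "final_update_rad": float(recon.phase_trace[-1]),
        "phase_trace": [float(x) for x in recon.phase_trace[:: max(1, len(recon.phase_trace) // 100)]],
    }
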