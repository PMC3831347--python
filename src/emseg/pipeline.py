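"""Outer-loop orchestration: intra-session alignment and fusion, initial
atlas-to-subject registration, then repeated rounds of quantile-bound
refresh -> prior constraining -> EM posterior estimation -> bias estimation
and correction -> atlas registration update, until the outer log-likelihood
stabilizes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bias_field import (BiasField, correct, estimate_bias, from_working_space,
                         to_working_space)
from .em_core import MixtureState, e_step, initialize_state, run_em
from .image_io import (ImageSession, LabelVolume, RunConfig, Volume,
                       setup_run_logging, write_label_volume, write_volume)
from .intensity_context import compute_bounds, constrain_priors, indicator_stack
from .priors import (PriorAtlas, collapse_to_superclass, hard_segmentation,
                     normalize_priors)
from .registration import (DeformableUnavailableError, SpatialTransform,
                           deformable_backend, fuse_repeats, register_affine,
                           register_rigid, resample, resample_prior_stack)

logger = logging.getLogger("emseg")

__all__ = ["PipelineResult", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, iteration: int | None, cause: Exception):
        self.stage = stage
        self.iteration = iteration
        where = stage if iteration is None else f"{stage} (outer iteration {iteration})"
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class PipelineResult:
    posteriors: np.ndarray               # (K, nx, ny, nz)
    state: MixtureState                  # working-space Gaussian parameters
    labels: LabelVolume                  # full class segmentation
    three_tissue_labels: LabelVolume
    corrected: ImageSession              # bias-corrected, linear intensity
    bias: BiasField                      # accumulated working-space field
    atlas: PriorAtlas                    # with final warped priors
    transforms: dict[str, SpatialTransform]
    outer_trace: list[float]
    em_traces: list[list[float]]
    fallback_counts: list[int]
    bounds_history: list[list[dict]]
    manifest: dict

    def class_means_linear(self) -> dict[str, np.ndarray]:
        """Posterior-weighted per-class mean of the corrected linear images."""
        Y = self.corrected.stack()
        M, N = Y.shape[0], int(np.prod(Y.shape[1:]))
        P = self.posteriors.reshape(self.posteriors.shape[0], N)
        Yf = Y.reshape(M, N)
        out = {}
        for k, name in enumerate(self.state.class_names):
            mass = P[k].sum()
            out[name] = ((Yf * P[k]).sum(axis=1) / mass if mass > 0
                         else np.full(M, np.nan))
        return out


def _stage(name: str, iteration: int | None = None):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, iteration, exc) from exc
            return False

    return _Ctx()


def _align_and_fuse(session: ImageSession, config: RunConfig) -> tuple[ImageSession, dict]:
    """Rigid-align every scan to the first scan of the first modality, then
    average repeats per modality."""
    ref = session.reference
    transforms: dict[str, SpatialTransform] = {}
    fused: dict[str, list[Volume]] = {}
    for m in session.modalities:
        aligned = []
        for r, vol in enumerate(session.channels[m]):
            key = f"intra/{m}/{r}"
            if vol is ref or np.array_equal(vol.data, ref.data):
                transforms[key] = SpatialTransform.identity()
                aligned.append(vol)
                continue
            if config.intra_register:
                tr = register_rigid(ref, vol, metric=config.registration_metric)
                transforms[key] = tr
                aligned.append(resample(vol, tr, ref.shape, ref.spacing, ref.origin))
            else:
                if not vol.same_grid(ref):
                    raise ValueError(
                        f"scan {key} is on a different grid; enable intra_register")
                transforms[key] = SpatialTransform.identity()
                aligned.append(vol)
        fused[m] = [fuse_repeats(aligned)]
    return ImageSession(list(session.modalities), fused), transforms


def _warp_atlas(atlas: PriorAtlas, fixed: Volume, config: RunConfig,
                deformable_plugin=None) -> tuple[np.ndarray, SpatialTransform]:
    """Map atlas priors onto the subject grid per the configured mode."""
    same_grid = (atlas.maps.shape[1:] == fixed.shape
                 and np.allclose(atlas.spacing, fixed.spacing)
                 and np.allclose(atlas.origin, fixed.origin))
    if config.registration_mode == "none" or atlas.template is None:
        if config.registration_mode != "none" and atlas.template is None:
            logger.warning("atlas has no template image; skipping registration")
        if not same_grid:
            raise ValueError("atlas grid differs from subject grid and no "
                             "registration template is available")
        return atlas.maps.copy(), SpatialTransform.identity()

    transform: SpatialTransform
    if config.registration_mode == "deformable":
        try:
            transform = deformable_backend(fixed, atlas.template,
                                           plugin=deformable_plugin)
        except DeformableUnavailableError as exc:
            logger.warning("deformable plug-in unavailable (%s); "
                           "falling back to affine", exc)
            rigid = register_rigid(fixed, atlas.template,
                                   metric=config.registration_metric)
            transform = register_affine(fixed, atlas.template, init=rigid,
                                        metric=config.registration_metric)
    else:
        rigid = register_rigid(fixed, atlas.template,
                               metric=config.registration_metric)
        transform = register_affine(fixed, atlas.template, init=rigid,
                                    metric=config.registration_metric)
    warped = resample_prior_stack(atlas.maps, atlas.spacing, atlas.origin,
                                  transform, fixed.shape, fixed.spacing,
                                  fixed.origin, air_index=atlas.air_index())
    return warped, transform


def run_pipeline(session: ImageSession, atlas: PriorAtlas, config: RunConfig,
                 deformable_plugin=None) -> PipelineResult:
    """Run the full iterative segmentation / bias-correction / registration
    loop and (optionally) write all artifacts to ``config.out_dir``."""
    setup_run_logging(config.out_dir, seed=config.seed)
    logger.info("run config: %s (digest %s)", config.to_dict(), config.digest())

    with _stage("intra-session alignment"):
        fused, transforms = _align_and_fuse(session, config)
    ref = fused.reference

    with _stage("atlas-to-subject registration"):
        warped, atlas_tr = _warp_atlas(atlas, ref, config, deformable_plugin)
        atlas = dataclasses.replace(atlas, warped=warped)
        transforms["atlas"] = atlas_tr

    with _stage("working-space transform"):
        eps: dict[str, float] = {}
        if config.bias_space == "log":
            chans = {}
            for m in fused.modalities:
                v, e = to_working_space(fused.fused_volume(m))
                chans[m] = [v]
                eps[m] = e
            working = ImageSession(list(fused.modalities), chans)
        else:
            working = fused

    K = atlas.n_classes
    names = atlas.class_names
    grid = ref.shape
    total_fields = {m: np.zeros(grid) for m in fused.modalities}
    state: MixtureState | None = None
    outer_trace: list[float] = []
    em_traces: list[list[float]] = []
    fallback_counts: list[int] = []
    bounds_history: list[list[dict]] = []
    corrected = working
    priors_stack = None

    def _masks() -> tuple[np.ndarray, np.ndarray]:
        """(quantile-histogram mask, bias-fit mask).  The histogram domain is
        the full image by default — the shipped quantile tables are expressed
        against whole-image histograms — while bias is always fitted over the
        atlas-defined head region."""
        head = atlas.head_mask(config.quantile_mask_threshold, use_warped=True)
        if not head.any():
            head = np.ones(grid, dtype=bool)
        if config.quantile_scope == "head":
            return head, head
        return np.ones(grid, dtype=bool), head

    for it in range(config.outer_max_iter):
        with _stage("quantile bounds", it):
            qmask, mask = _masks()
            bounds = compute_bounds(corrected, atlas, qmask)
            bounds_history.append(bounds.as_table())
        with _stage("prior constraining", it):
            norm = normalize_priors(atlas, use_warped=True)
            if config.use_context:
                ind = indicator_stack(corrected, bounds)
                priors_stack, n_fb = constrain_priors(norm, ind)
            else:
                priors_stack, n_fb = norm, 0
            fallback_counts.append(n_fb)
        with _stage("EM", it):
            if state is None:
                state = initialize_state(corrected, priors_stack, class_names=names)
            state, post, trace = run_em(corrected, state, priors_stack,
                                        max_iter=config.em_max_iter,
                                        tol=config.em_tol)
            em_traces.append(trace)
        with _stage("bias estimation", it):
            bias_it = estimate_bias(corrected, state, post, atlas,
                                    order=config.bias_order, mask=mask,
                                    space=config.bias_space)
            corrected = correct(corrected, bias_it)
            for m in fused.modalities:
                total_fields[m] += bias_it.fields[m]
        if (config.registration_mode != "none" and atlas.template is not None
                and it < config.outer_max_iter - 1):
            with _stage("registration update", it):
                m0 = fused.modalities[0]
                fixed_now = corrected.fused_volume(m0)
                if config.bias_space == "log":
                    fixed_now = from_working_space(fixed_now, eps[m0])
                warped, atlas_tr = _warp_atlas(atlas, fixed_now, config,
                                               deformable_plugin)
                atlas = dataclasses.replace(atlas, warped=warped)
                transforms[f"atlas/iter{it}"] = atlas_tr
        ll = trace[-1]
        outer_trace.append(ll)
        logger.info("outer iteration %d: log-likelihood %.6g", it, ll)
        if len(outer_trace) > 1:
            prev = outer_trace[-2]
            rel = abs(ll - prev) / max(abs(prev), np.finfo(float).tiny)
            if rel < config.outer_tol:
                logger.info("outer loop converged at iteration %d", it)
                break

    with _stage("final posterior refresh"):
        qmask, mask = _masks()
        bounds = compute_bounds(corrected, atlas, qmask)
        norm = normalize_priors(atlas, use_warped=True)
        if config.use_context:
            ind = indicator_stack(corrected, bounds)
            priors_stack, _ = constrain_priors(norm, ind)
        else:
            priors_stack = norm
        post, ll_final = e_step(corrected, state, priors_stack)
        outer_trace.append(ll_final)

    with _stage("output assembly"):
        labels = hard_segmentation(post, names=names, spacing=ref.spacing,
                                   origin=ref.origin)
        three_stack, three_names = collapse_to_superclass(post, atlas,
                                                          scheme="three-tissue")
        three_labels = hard_segmentation(three_stack, names=three_names,
                                         spacing=ref.spacing, origin=ref.origin)
        if config.bias_space == "log":
            chans = {m: [from_working_space(corrected.fused_volume(m), eps[m])]
                     for m in fused.modalities}
            corrected_linear = ImageSession(list(fused.modalities), chans)
        else:
            corrected_linear = corrected
        total_bias = BiasField(modalities=list(fused.modalities),
                               coefficients={m: np.array([]) for m in fused.modalities},
                               fields=total_fields, order=config.bias_order,
                               space=config.bias_space)
        manifest = {
            "tool": "emseg",
            "version": __version__,
            "numpy": np.__version__,
            "seed": config.seed,
            "config": {k: v for k, v in config.to_dict().items()
                       if k != "out_dir"},
            "config_digest": config.digest(),
            "modalities": list(fused.modalities),
            "n_repeats": {m: session.n_repeats(m) for m in session.modalities},
            "grid": list(grid),
            "n_classes": K,
            "outer_iterations": len(em_traces),
            "final_log_likelihood": ll_final,
        }

    result = PipelineResult(
        posteriors=post, state=state, labels=labels,
        three_tissue_labels=three_labels, corrected=corrected_linear,
        bias=total_bias, atlas=atlas, transforms=transforms,
        outer_trace=outer_trace, em_traces=em_traces,
        fallback_counts=fallback_counts, bounds_history=bounds_history,
        manifest=manifest)
    if config.out_dir is not None:
        with _stage("write outputs"):
            _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = result.corrected.reference
    safe = {n: n.replace(" ", "_").lower() for n in result.state.class_names}
    for k, name in enumerate(result.state.class_names):
        write_volume(Volume(result.posteriors[k], spacing=ref.spacing,
                            origin=ref.origin),
                     out_dir / f"posterior_{safe[name]}.nii")
    write_label_volume(result.labels, out_dir / "labels.nii")
    write_label_volume(result.three_tissue_labels, out_dir / "labels_three_tissue.nii")
    for m in result.corrected.modalities:
        write_volume(result.corrected.fused_volume(m),
                     out_dir / f"corrected_{m}.nii")
        write_volume(Volume(result.bias.fields[m], spacing=ref.spacing,
                            origin=ref.origin),
                     out_dir / f"bias_{m}.nii")
    for key, tr in result.transforms.items():
        if tr.matrix is not None:
            fname = "transform_" + key.replace("/", "_") + ".txt"
            np.savetxt(out_dir / fname, tr.matrix, fmt="%.12g")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "trace.csv", "w") as fh:
        fh.write("outer_iteration,log_likelihood\n")
        for i, ll in enumerate(result.outer_trace):
            fh.write(f"{i},{ll:.10g}\n")
    with open(out_dir / "bounds.csv", "w") as fh:
        fh.write("outer_iteration,tissue,modality,lower,upper\n")
        for i, table in enumerate(result.bounds_history):
            for row in table:
                fh.write(f"{i},{row['tissue']},{row['modality']},"
                         f"{row['lower']:.10g},{row['upper']:.10g}\n")
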