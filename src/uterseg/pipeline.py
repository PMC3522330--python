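"""End-to-end semi-automated uterine segmentation.

Stage order: FCM clustering of the enhanced-T1W image → brightest-class
selection → hole filling → opening → largest central component →
[affine registration of T1W onto enhanced-T1W → trilinear resampling] →
masked-T1W histogram → last-peak-start threshold → colon removal →
size-dependent opening/closing post-processing.

Every run produces a :class:`ProvenanceRecord` (config snapshot,
per-stage voxel counts, warnings, threshold, transform) that fully
determines the output: re-running from a provenance record reproduces
the mask.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .core import BinaryMask, IntensityVolume, PipelineConfig
from .fcm import fcm_cluster, select_enhanced_class
from .morphology import SEShape, StructuringElement, fill_holes, largest_central_component, opening
from .refine import (
    AffineTransform,
    last_peak_threshold,
    mask_intensities,
    postprocess,
    register_affine,
    resample,
    threshold_refine,
)

__all__ = ["PipelineError", "ProvenanceRecord", "run_pipeline", "run_from_provenance"]

logger = logging.getLogger("uterseg")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and provenance so far."""

    def __init__(self, stage: str, message: str, provenance=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.provenance = provenance


@dataclass
class ProvenanceRecord:
    """Complete record of one pipeline run."""

    config: dict
    stages: list = field(default_factory=list)  # {name, voxel_count, warnings, ...}
    threshold: float | None = None
    transform: dict | None = None
    version: str = __version__
    started: str = ""
    finished: str = ""

    def add_stage(self, name: str, voxel_count: int, warnings_: list, **extra) -> None:
        self.stages.append(
            {"name": name, "voxel_count": int(voxel_count), "warnings": list(warnings_), **extra}
        )
        logger.info("stage %-22s voxels=%d", name, voxel_count)

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), **kw)

    @classmethod
    def from_json(cls, s: str) -> "ProvenanceRecord":
        return cls(**json.loads(s))


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


class _catch:
    """Collect warnings emitted inside a stage into the provenance."""

    def __enter__(self):
        self._cm = warnings.catch_warnings(record=True)
        self._records = self._cm.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, *exc):
        self._cm.__exit__(*exc)
        return False

    @property
    def messages(self):
        return [str(w.message) for w in self._records]


def run_pipeline(
    t1c: IntensityVolume,
    t1: IntensityVolume,
    config: PipelineConfig | None = None,
    stage_hook=None,
) -> tuple[BinaryMask, ProvenanceRecord]:
    """Segment the uterus from a paired (enhanced-T1W, T1W) acquisition.

    ``stage_hook(name, mask_or_none)`` is invoked after each stage (used
    by the CLI to snapshot intermediate masks).  Deterministic given
    ``config.rng_seed``.  Raises :class:`PipelineError` if an
    intermediate mask empties out.
    """
    config = config or PipelineConfig()
    prov = ProvenanceRecord(config=config.to_dict(), started=_now())

    def snapshot(name, mask=None):
        if stage_hook is not None:
            stage_hook(name, mask)

    def require_nonempty(name, mask):
        if mask.voxel_count == 0:
            prov.finished = _now()
            raise PipelineError(name, "intermediate mask is empty", prov)

    # 1. FCM clustering of the enhanced image; take the brightest class
    with _catch() as w:
        U, model = fcm_cluster(t1c, config)
        candidate = select_enhanced_class(U, model, t1c.spacing)
    prov.add_stage(
        "fcm_select_enhanced",
        candidate.voxel_count,
        w.messages,
        centers=[float(v) for v in model.V],
        n_iter=model.n_iter,
        converged=bool(model.converged),
    )
    require_nonempty("fcm_select_enhanced", candidate)
    snapshot("fcm_select_enhanced", candidate)

    fill_mode = "per-slice" if config.component_mode == "per-slice" else "volume"

    # 2. fill infarcted-fibroid holes
    with _catch() as w:
        candidate = fill_holes(candidate, mode=fill_mode)
    prov.add_stage("fill_holes", candidate.voxel_count, w.messages)
    snapshot("fill_holes", candidate)

    # 3. opening: remove debris, sever weak bridges
    se = StructuringElement(
        SEShape.BALL if candidate.shape[2] > 1 else SEShape.DISK, config.opening_radius
    )
    with _catch() as w:
        candidate = opening(candidate, se)
    prov.add_stage("opening", candidate.voxel_count, w.messages, radius=se.radius)
    require_nonempty("opening", candidate)
    snapshot("opening", candidate)

    # 4. keep the largest centrally located component
    with _catch() as w:
        candidate, empty = largest_central_component(
            candidate, mode=fill_mode, score=config.component_score
        )
    prov.add_stage("largest_central_component", candidate.voxel_count, w.messages)
    require_nonempty("largest_central_component", candidate)
    snapshot("largest_central_component", candidate)

    # 5. register T1W onto the enhanced image and resample
    if config.registration_enabled:
        with _catch() as w:
            transform = register_affine(t1, t1c, config)
            t1_reg = resample(t1, transform, reference=t1c)
        prov.transform = {
            "matrix": transform.matrix.tolist(),
            "translation": transform.translation.tolist(),
            "similarity_value": transform.similarity_value,
        }
        prov.add_stage("register_resample", candidate.voxel_count, w.messages)
    else:
        if t1.shape != t1c.shape:
            raise PipelineError("register_resample", "grids differ and registration is disabled", prov)
        t1_reg = t1
        prov.add_stage("register_resample", candidate.voxel_count, ["registration skipped"])

    # 6. masked-T1W histogram; threshold at the start of the last peak
    with _catch() as w:
        values = mask_intensities(t1_reg, candidate)
        hist = last_peak_threshold(values, config)
    prov.threshold = float(hist.threshold)
    prov.add_stage(
        "last_peak_threshold",
        candidate.voxel_count,
        w.messages,
        threshold=float(hist.threshold),
        n_peaks=int(len(hist.peaks)),
        single_peak_fallback=bool(hist.single_peak_fallback),
    )

    # 7. remove the brighter-on-T1W (colon) voxels
    with _catch() as w:
        refined = threshold_refine(candidate, t1_reg, hist)
    prov.add_stage("threshold_refine", refined.voxel_count, w.messages)
    require_nonempty("threshold_refine", refined)
    snapshot("threshold_refine", refined)

    # 8. size-dependent opening/closing + central component
    with _catch() as w:
        final = postprocess(refined, config)
    prov.add_stage("postprocess", final.voxel_count, w.messages)
    require_nonempty("postprocess", final)
    snapshot("postprocess", final)

    prov.finished = _now()
    return final, prov


def run_from_provenance(
    t1c: IntensityVolume, t1: IntensityVolume, prov: ProvenanceRecord
) -> tuple[BinaryMask, ProvenanceRecord]:
    """Re-run a pipeline from a provenance record's config snapshot;
    with the same inputs this reproduces the recorded mask."""
    return run_pipeline(t1c, t1, PipelineConfig.from_dict(prov.config))
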