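"""End-to-end orchestration: read -> down-sample -> stem -> leaves -> export."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import io as cloud_io
from .config import PipelineConfig, preset
from .downsample import adaptive_downsample, upsample_labels
from .errors import DfspError, PipelineError, ValidationError
from .io import PointCloud
from .leaf import SegmentationResult, assemble_result, segment_leaves
from .stem import segment_stem

__all__ = ["PipelineOutput", "run_pipeline", "segment_cloud"]

log = logging.getLogger(__name__)


@dataclass
class PipelineOutput:
    labeled: PointCloud            # down-sampled cloud with predicted labels
    raw_labeled: Optional[PointCloud]  # labels up-sampled to the input cloud
    result: SegmentationResult
    report: dict


def segment_cloud(cloud: PointCloud, cfg: PipelineConfig) -> PipelineOutput:
    """Run the full segmentation on an in-memory cloud."""
    timings = {}

    t0 = time.perf_counter()
    work = adaptive_downsample(cloud, cfg.downsample)
    timings["downsample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        stem_idx, leaf_idx, alignment, _ = segment_stem(work, cfg.stem)
    except DfspError as exc:
        raise PipelineError("stem", str(exc)) from exc
    timings["stem"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    aligned_pts = alignment.transform(work.points)
    if len(leaf_idx):
        leaf_cloud = PointCloud(aligned_pts[leaf_idx])
        try:
            leaf_ids = segment_leaves(leaf_cloud, cfg.leaf)
        except DfspError as exc:
            raise PipelineError("leaf", str(exc)) from exc
    else:
        leaf_ids = np.zeros(0, dtype=np.int64)
    result = assemble_result(work.n, stem_idx, leaf_idx, leaf_ids, alignment)
    timings["leaf"] = time.perf_counter() - t0

    labeled = work.with_labels(result.labels)
    raw_labeled = None
    if cfg.upsample and work.n < cloud.n:
        t0 = time.perf_counter()
        raw_labeled = upsample_labels(cloud, labeled)
        timings["upsample"] = time.perf_counter() - t0

    sizes = result.instance_sizes()
    report = {
        "n_input": cloud.n,
        "n_segmented": work.n,
        "n_leaves": result.n_leaves,
        "instance_sizes": sizes,
        "parameters": cfg.to_dict(),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    return PipelineOutput(labeled, raw_labeled, result, report)


def run_pipeline(in_path: str, out_path: str,
                 cfg: Optional[PipelineConfig] = None,
                 report_path: Optional[str] = None) -> PipelineOutput:
    """File-to-file pipeline; partial outputs are removed on failure."""
    if cfg is None:
        cfg = preset("points15000")
    cloud = cloud_io.read_cloud(in_path)
    try:
        out = segment_cloud(cloud, cfg)
        final = out.raw_labeled if out.raw_labeled is not None else out.labeled
        cloud_io.write_cloud(final, out_path)
        if report_path:
            with open(report_path, "w") as fh:
                json.dump(out.report, fh, indent=2, sort_keys=True)
    except Exception:
        for p in (out_path, report_path):
            if p and os.path.exists(p):
                os.remove(p)
        raise
    return out
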