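"""Non-overlap classing, guided chunking, worker partitioning and reduction.

Two references can be filtered concurrently against one shared output only
if the regions they may write to are disjoint.  A reference's write
footprint is its search-window origin span extended by the cube extent, an
axis-aligned box of side at most ``F = NS + L - 1`` voxels.  Grid-aligned
references are binned per axis by ``grid_index mod c`` with
``c = ceil(F / Nstep)``: members of one class then differ by at least
``c * Nstep >= F`` voxels along every axis on which they differ at all, so
their footprints cannot intersect.  Clamped boundary references (the
appended trailing-edge origins) are placed greedily into the first class
they do not conflict with, or into a fresh overflow class.  Classes are
executed sequentially; within a class, references are dealt to workers in
guided chunks (halving chunk sizes, mirroring OpenMP's guided schedule) and
each worker accumulates into a private numerator/denominator pair that is
sum-reduced before the final division.

Both execution backends satisfy the same contract: "thread" runs workers as
in-process threads; "process" mirrors a coordinator/worker deployment — the
volume, profile and schedule are serialized (broadcast) to worker
processes, which return their partial accumulators for reduction.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .core_model import (
    Accumulators,
    BM4DProfile,
    ClassSchedule,
    CubeCoord,
    StageParams,
    Volume,
    validate_profile,
)
from .collaborative_filter import StageContext, finalize_estimate
from .grouping import reference_coordinates
from .transforms import Transform4D


def footprint_box(ref: CubeCoord, params: StageParams,
                  dims: tuple[int, int, int]) -> tuple[tuple[int, int], ...]:
    """Half-open per-axis voxel spans of the reference's write footprint."""
    h = (params.NS - 1) // 2
    L = params.L
    return tuple(
        (max(0, r - h), min(d - L, r + h) + L) for r, d in zip(ref, dims)
    )


def build_nonoverlap_schedule(refs: list[CubeCoord], params: StageParams,
                              dims: tuple[int, int, int]) -> ClassSchedule:
    """Partition the references into classes with pairwise disjoint footprints."""
    F = params.NS + params.L - 1
    c = math.ceil(F / params.Nstep)
    grid_classes: dict[tuple[int, int, int], list[CubeCoord]] = {}
    stragglers: list[CubeCoord] = []
    for ref in refs:
        if all(o % params.Nstep == 0 for o in ref):
            cid = tuple((o // params.Nstep) % c for o in ref)
            grid_classes.setdefault(cid, []).append(ref)
        else:
            stragglers.append(ref)

    classes = [grid_classes[cid] for cid in sorted(grid_classes)]

    # Clamped boundary references go greedily to the first class whose
    # members' footprints they do not intersect, else to a fresh overflow
    # class.  The membership test is vectorised over all boxes placed so far.
    n_total = len(refs)
    boxes = np.empty((n_total, 6), dtype=np.int64)  # x0 x1 y0 y1 z0 z1
    box_class = np.empty(n_total, dtype=np.int64)
    n_boxes = 0
    for ci, cls in enumerate(classes):
        for ref in cls:
            boxes[n_boxes] = [b for span in footprint_box(ref, params, dims)
                              for b in span]
            box_class[n_boxes] = ci
            n_boxes += 1
    for ref in stragglers:
        fb = footprint_box(ref, params, dims)
        b = np.array([v for span in fb for v in span])
        placed = boxes[:n_boxes]
        conflict = ((b[0] < placed[:, 1]) & (placed[:, 0] < b[1])
                    & (b[2] < placed[:, 3]) & (placed[:, 2] < b[3])
                    & (b[4] < placed[:, 5]) & (placed[:, 4] < b[5]))
        bad = np.unique(box_class[:n_boxes][conflict])
        free = np.setdiff1d(np.arange(len(classes)), bad,
                            assume_unique=True)
        if free.size:
            ci = int(free[0])
            classes[ci].append(ref)
        else:
            ci = len(classes)
            classes.append([ref])
        boxes[n_boxes] = b
        box_class[n_boxes] = ci
        n_boxes += 1
    return ClassSchedule(classes=classes, footprint_side=F,
                         class_counts=(c, c, c))


def chunk_guided(items: list, n_workers: int,
                 min_chunk: int = 1) -> list[tuple[int, list]]:
    """Guided chunking: chunk size = max(ceil(remaining / (2 n_workers)),
    min_chunk), assigned to workers round-robin.  Returns (worker, chunk)
    pairs in dispatch order."""
    if n_workers < 1 or min_chunk < 1:
        raise ValueError("n_workers and min_chunk must be >= 1")
    plan: list[tuple[int, list]] = []
    pos, i = 0, 0
    while pos < len(items):
        size = max(math.ceil((len(items) - pos) / (2 * n_workers)), min_chunk)
        plan.append((i % n_workers, items[pos:pos + size]))
        pos += size
        i += 1
    return plan


def reduce_accumulators(partials: list[Accumulators]) -> Accumulators:
    """Elementwise sum of partial numerators and denominators."""
    if not partials:
        raise ValueError("nothing to reduce")
    dims = partials[0].numerator.shape
    if any(p.numerator.shape != dims for p in partials):
        raise ValueError("partial accumulator dims mismatch")
    out = Accumulators.zeros(dims)
    for p in partials:
        out.numerator += p.numerator
        out.denominator += p.denominator
    return out


@dataclass
class WorkerReport:
    """Per-worker accounting of one stage's execution."""

    worker_id: int
    items_processed: int
    partial: Accumulators


def _worker_task(ctx: StageContext, worker_id: int,
                 chunks: list[list[CubeCoord]]) -> WorkerReport:
    acc = Accumulators.zeros(ctx.volume.dims)
    n = 0
    for chunk in chunks:
        try:
            for ref in chunk:
                ctx.process_reference(acc, ref)
        except Exception as exc:  # noqa: BLE001 - re-raised with chunk context
            raise RuntimeError(
                f"worker {worker_id} failed on chunk starting at "
                f"{tuple(chunk[0])} ({len(chunk)} refs): {exc}"
            ) from exc
        n += len(chunk)
    return WorkerReport(worker_id=worker_id, items_processed=n, partial=acc)


def _run_stage_parallel(ctx: StageContext, schedule: ClassSchedule,
                        n_workers: int, executor_kind: str) -> Accumulators:
    # deal each class into guided chunks; a worker keeps one ordered list
    # of chunks across classes (its accumulator is private, so the
    # class-sequential barrier is a no-op for correctness and elided here)
    per_worker: list[list[list[CubeCoord]]] = [[] for _ in range(n_workers)]
    for cls in schedule.classes:
        for worker, chunk in chunk_guided(cls, n_workers, min_chunk=1):
            per_worker[worker].append(chunk)

    if n_workers == 1:
        reports = [_worker_task(ctx, 0, per_worker[0])]
    else:
        pool_cls = (ProcessPoolExecutor if executor_kind == "process"
                    else ThreadPoolExecutor)
        with pool_cls(max_workers=n_workers) as pool:
            futures = [pool.submit(_worker_task, ctx, w, per_worker[w])
                       for w in range(n_workers) if per_worker[w]]
            reports = [f.result() for f in futures]
    reports.sort(key=lambda r: r.worker_id)  # fixed reduction order
    return reduce_accumulators([r.partial for r in reports])


def run_parallel(volume: Volume, sigma: float, profile: BM4DProfile,
                 n_workers: int = 1, placement: str = "packed",
                 executor: str = "thread",
                 return_intermediate: bool = False):
    """Two-stage filtering with the non-overlap-class parallel scheme.

    ``placement`` is advisory ("packed" | "one-per-node"): it records the
    intended worker placement in deployments that pin workers to
    processors, but makes no hardware-affinity guarantees here.  With
    ``n_workers=1`` the execution order is identical to the sequential
    `run_bm4d` path; with more workers the result agrees with it to
    floating-point reduction-order tolerance.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if placement not in ("packed", "one-per-node"):
        raise ValueError(f"unknown placement {placement!r}")
    validate_profile(profile, volume.dims)
    transforms = Transform4D(profile.spatial_transform,
                             profile.group_transform)

    def stage(vol, matching, params, mode, estimate=None) -> Volume:
        refs = reference_coordinates(vol.dims, params.L, params.Nstep)
        schedule = build_nonoverlap_schedule(refs, params, vol.dims)
        ctx = StageContext(volume=vol, matching_volume=matching, sigma=sigma,
                           params=params, mode=mode, estimate_volume=estimate,
                           transforms=transforms)
        acc = _run_stage_parallel(ctx, schedule, n_workers, executor)
        estimate_vol, _ = finalize_estimate(acc, vol)
        return estimate_vol

    pilot = stage(volume, volume, profile.ht, "ht")
    final = stage(volume, pilot, profile.wie, "wiener", estimate=pilot)
    if return_intermediate:
        return final, pilot
    return final
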