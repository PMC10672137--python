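# Methods

## Model and procedure

The filter assumes a 3D scalar volume corrupted by additive i.i.d.
zero-mean Gaussian noise of known standard deviation σ. Intensities are
normalised to [0, 1] internally and σ, τ_match and λ_4D are interpreted on
that scale; the affine used for normalisation is recorded so outputs are
written back on the source scale.

Processing is two sequential stages over the whole volume. In each stage
the volume is marched on a reference grid (step N_step per axis; the final
origin on each axis is clamped to `dim − L` so the trailing border is
covered). For each reference, candidate cubes inside an N_S-sided window
of origins (clamped at the borders, never wrapped) are ranked by the
per-voxel mean squared difference to the reference cube; candidates within
τ_match are kept, sorted ascending with ties broken by scan order, the
reference is forced to position 0, and the group is truncated to the
largest power of two ≤ min(count, M).

Stage 1 shrinks each group in the separable 4D transform domain by hard
thresholding at λ_4D·σ and aggregates with weight 1/(σ²·N_retained).
Stage 2 re-runs the matching on the stage-1 estimate, extracts the *pair*
of groups (noisy and estimate) at the matched coordinates, applies the
empirical Wiener gains W = E²/(E² + σ²) computed from the estimate's
coefficients to the noisy coefficients, and aggregates with weight
1/(σ²·‖W‖²). The final estimate is numerator/denominator wherever the
denominator is positive, with the input value as fallback elsewhere (the
fallback count is reported; under the default profile on admissible
volumes the coverage audit shows zero fallback voxels).

## Transforms

The spatial transform is the orthonormal type-II DCT (defined for any
length, used at L = 4 and 5); the group-axis transform is the full-ladder
orthonormal Haar transform on dyadic lengths. Orthonormality is what makes
the σ-scaled threshold valid in the coefficient domain, and is enforced by
test to 1e-10. The 4D transform applies the 1D transforms along x, y, z,
then the group axis, inverses in reverse order; for separable orthonormal
transforms any fixed order yields the same operator, and fixing one makes
runs bit-reproducible. Transforms are looked up in a registry by name, so
swapping them is a profile change, not a code change.

## Parameters

| Parameter | Hard-threshold | Wiener | Meaning |
|---|---|---|---|
| L | 4 | 5 | cube side (voxels) |
| M | 32 | 32 | maximum group size |
| N_step | 3 | 3 | reference-grid step (voxels) |
| N_S | 11 | 11 | search-window side (origin positions) |
| τ_match | 24.6 | 6.7 | match threshold (mean squared difference/voxel) |
| λ_4D | 2.8 | — | shrinkage multiplier |

These are the "modified profile" defaults. Distances are computed in the
raw voxel domain (no coefficient-domain prefiltering before matching), and
τ_match is compared against the per-voxel mean squared difference
directly. On the [0, 1] intensity convention adopted here the τ_match
values admit essentially every candidate in the window, so group
composition is governed by the ranking and the cap M; the convention is a
documented choice, since intensity scaling conventions for these
thresholds vary between implementations.

Design points that were genuinely open and are pinned down here:

- **DC exemption.** The hard threshold never zeroes the DC coefficient;
  thresholding it would bias flat regions toward zero.
- **Aggregation weights** are the variance-based 1/(σ²·N_retained) and
  1/(σ²·‖W‖²); they reduce to uniform averaging when groups are equally
  sparse. At σ = 0 the σ² factor is replaced by a documented epsilon
  (1e-12): weights then only need to be finite and equal.
- **No windowing taper** on aggregated cubes; uniform weights keep the
  λ_4D = 0 configuration an exact identity (tested to 1e-10).
- **Wiener gains are applied to every coefficient, including DC.** As a
  consequence a constant volume is an exact fixed point of the
  hard-threshold stage but only an approximate one of the Wiener stage:
  the output stays spatially uniform while its level is attenuated by the
  DC gain E²/(E² + σ²), i.e. a relative drift of σ²/(v²·M′·L³) for level
  v — about 1e-4 at σ = 0.25 for the default geometry. The fixed-point
  tests assert uniformity to 1e-10 and bound the drift by this closed
  form.
- σ is a single global scalar per run; no per-voxel noise maps, no
  variance-stabilising transform for Rician noise, no iterative
  re-application.

## Parallel execution

A reference's write footprint is its search-window origin span extended by
the cube extent — side F = N_S + L − 1 (interpreting N_S as a window of
cube *origins*; this is the conservative envelope and is verified by an
exhaustive pairwise-intersection oracle rather than trusted). Grid-aligned
references get per-axis class index `grid_index mod ⌈F/N_step⌉`; members
of one class then differ by at least F along every axis on which they
differ, so their footprints are disjoint. Clamped boundary references are
placed greedily in the first non-conflicting class, else in overflow
classes listed last.

Classes execute sequentially; within a class, references are dealt to
workers in guided chunks (size `max(⌈remaining/(2·n_workers)⌉,
min_chunk)`, non-increasing until the floor). Every worker accumulates
into a private numerator/denominator pair, and partials are summed in
worker-id order before the final division — because accumulators are
private, the class barrier is not needed for correctness and is elided,
which leaves the per-worker processing order (and hence the result)
independent of thread timing. A one-worker run is bit-identical to the
sequential path; multi-worker runs differ only by floating-point
reordering (observed ~1e-12 relative, contract < 1e-6).

Two backends satisfy the same contract: in-process threads (default) and
a process pool that mirrors a coordinator/worker deployment — the volume
and schedule are serialized to workers and partial accumulators returned
for reduction. The `one-per-node` placement flag is advisory only; no
hardware pinning is guaranteed.

## Synthetic data and what the tests show

The `ellipsoids` phantom is a nested set of piecewise-constant ellipsoidal
shells (distinct intensity levels in [0, 1], mild seeded jitter of centre
and axes), emulating the flat-tissue-plus-boundary structure of anatomical
volumes; `blobs` is a smooth mixture of Gaussian bumps. Noise is additive
Gaussian on the normalised scale; "25% noise" is taken as σ = 0.25 with
clipping to [0, 1]. Real acquisitions differ in ways the phantoms do not
model — Rician/Poisson noise statistics, partial-volume effects, texture,
scanner artefacts — so the efficacy tests demonstrate the pipeline's
correctness and its behaviour on piecewise-constant content, not clinical
performance.

Quality metrics follow the slice-averaged protocol: per axial slice,
RMSE, PSNR = 20·log10(1/RMSE) (peak 1, capped at 100 dB for identical
slices), and SSIM with the standard constants (Gaussian window of side
11, σ = 1.5, K1 = 0.01, K2 = 0.03), then averaged over slices.

A practical observation the acceptance script reproduces: with clipped
25% noise the effective noise level is below the nominal σ, so the Wiener
gains over-attenuate slightly and the second stage can trail the
hard-threshold stage by a fraction of a dB at that setting, while at
moderate unclipped noise (σ = 0.1) it refines the estimate as expected.

## Problem sizes

The test suite and the acceptance script run at desk scale as the
package's own standard fixture sizes: 64³ for denoising efficacy, 32³ for
serial/parallel equivalence, ≤ 20³ volumes for the exhaustive matching
oracle, and dims in [11, 40]³ for the schedule disjointness oracle. The
full 181³ brain-volume evaluation protocol is implemented and documented
in `tests/test_acceptance.py`; it requires the publicly downloadable
BrainWeb simulated T1 volume placed at `tests/data/brainweb_t1.nii[.gz]`
and several hours of single-CPU compute.

## Numerical choices and degenerate inputs

- Tie-breaks in matching use scan order (x, y, z lexicographic), making
  groups machine-independent; matching is exhaustive within the window
  (no approximate nearest-neighbour structures).
- σ = 0 runs: hard-threshold shrinkage becomes a no-op only if λ_4D = 0;
  Wiener gains are all 1, so the stage passes the noisy group through.
- Min-max normalisation of a constant-intensity volume yields all zeros
  and raises a `DegenerateRangeWarning` (and sets a flag on the source).
- Volumes smaller than N_S on any axis are rejected by profile
  validation with the offending axis named.
- Worker failures abort the run with a diagnostic naming the chunk.

## Known limitations

- No GPU offload, NUMA pinning, or fault tolerance beyond
  abort-with-diagnostic.
- No automatic σ estimation; σ is user input.
- DICOM is read-only; NRRD/MHA are unsupported.
- Exact numeric parity with other implementations of this filter family
  is not promised (transform pairs and aggregation details differ between
  implementations); the contracts here are pinned by the package's own
  oracles and tests.
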