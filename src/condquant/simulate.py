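"""Synthetic data with analytic ground truth for every pipeline stage.

Each generator is a pure function of its spec plus seed (bit-identical
reruns) and returns the dataset together with a ground-truth record
computed analytically from the spec, never from the generated pixels.
The generators emulate the study conditions of a condensate-biology
imaging workflow:

* two-phase droplet fields: hard-edged disks at a dense-phase intensity on
  a dilute background, plus camera offset and additive Gaussian read
  noise, with an optional second (RNA) channel sharing the same disks;
* FRAP traces with multiplicative acquisition photobleaching and a
  separate reference region;
* time-lapse stacks of puncta that dissolve stochastically (each punctum
  survives each frame interval with probability exp(-lambda*dt));
* identifier sets with an exactly known intersection.

Disks are hard-edged (not anti-aliased) so the analytic partition
coefficient I_dense/I_dilute and condensed fraction are exact on
noiseless fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CondquantError, PlacementError
from .frap import FRAPTrace
from .io import Image2D, ImageStack
from .metrics import GeneSet

__all__ = [
    "DropletFieldSpec",
    "DropletFieldTruth",
    "DropletField",
    "FRAPTraceSpec",
    "FRAPTruth",
    "DissolutionTruth",
    "gen_droplet_field",
    "gen_frap_trace",
    "gen_dissolution_stack",
    "gen_gene_sets",
    "WT_CELL_FRAP",
    "F85A_CELL_FRAP",
    "IN_VITRO_FRAP",
]


# ---------------------------------------------------------------------------
# droplet fields


@dataclass(frozen=True)
class DropletFieldSpec:
    """Parameters of a synthetic two-phase field.

    Intensities are detector counts. ``i_dense2``/``i_dilute2`` enable a
    second channel rendered on the same disks (an RNA channel partitioning
    into protein droplets); leave them ``None`` for single-channel fields.
    """

    shape: tuple[int, int] = (256, 256)
    n_droplets: int = 8
    radius_px: tuple[int, int] = (3, 8)
    i_dense: float = 100.0
    i_dilute: float = 10.0
    camera_offset: float = 0.0
    noise_sd: float = 0.0
    i_dense2: float | None = None
    i_dilute2: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.i_dense > self.i_dilute >= 0:
            raise CondquantError("need i_dense > i_dilute >= 0")
        if self.radius_px[0] < 1 or self.radius_px[1] < self.radius_px[0]:
            raise CondquantError(f"invalid radius range {self.radius_px}")
        if self.noise_sd < 0 or self.camera_offset < 0:
            raise CondquantError("noise_sd and camera_offset must be >= 0")


@dataclass
class DropletFieldTruth:
    """Analytic ground truth for a droplet field.

    ``pc``/``rc`` are computed from the spec intensities and the
    rasterized disk areas (centres and radii), independent of any noise
    realization.
    """

    centers: list[tuple[int, int]]
    radii: list[int]
    areas_px: list[int]
    pc: float
    rc: float
    pc2: float | None = None
    rc2: float | None = None


@dataclass
class DropletField:
    protein: Image2D
    dark: Image2D
    truth: DropletFieldTruth
    rna: Image2D | None = None


def _disk_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_range: tuple[int, int],
    max_attempts: int = 1000,
) -> tuple[list[tuple[int, int]], list[int]]:
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    rows, cols = shape
    for _ in range(n):
        for _attempt in range(max_attempts):
            r = int(rng.integers(radius_range[0], radius_range[1] + 1))
            cy = int(rng.integers(r, rows - r))
            cx = int(rng.integers(r, cols - r))
            # gap of 2 px between disks so 8-connectivity keeps them apart
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 >= (r + rr + 2) ** 2
                for (y, x), rr in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place droplet {len(centers) + 1}/{n} after "
                f"{max_attempts} attempts; use fewer or smaller droplets"
            )
    return centers, radii


def _render(
    shape: tuple[int, int],
    centers: list[tuple[int, int]],
    radii: list[int],
    i_dense: float,
    i_dilute: float,
) -> np.ndarray:
    img = np.full(shape, i_dilute, dtype=np.float64)
    for (cy, cx), r in zip(centers, radii):
        off = _disk_offsets(r)
        img[off[:, 0] + cy, off[:, 1] + cx] = i_dense
    return img


def gen_droplet_field(spec: DropletFieldSpec) -> DropletField:
    """Generate a droplet field, its dark frame, and analytic truth.

    The dark frame is ``camera_offset`` plus the same read noise as the
    field, so the full dark-subtraction step can be exercised. Analytic
    PC = i_dense/i_dilute and RC = (A_in*i_dense)/(A_in*i_dense +
    A_out*i_dilute) with areas from the rasterized disks.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_disks(rng, spec.shape, spec.n_droplets, spec.radius_px)
    areas = [len(_disk_offsets(r)) for r in radii]
    n_px = spec.shape[0] * spec.shape[1]
    a_in = sum(areas)
    a_out = n_px - a_in

    def _truth_rc(dense: float, dilute: float) -> float:
        if a_in == 0:
            return 0.0
        i_in = a_in * dense
        return i_in / (i_in + a_out * dilute)

    truth = DropletFieldTruth(
        centers=centers,
        radii=radii,
        areas_px=areas,
        pc=spec.i_dense / spec.i_dilute if spec.i_dilute > 0 else float("inf"),
        rc=_truth_rc(spec.i_dense, spec.i_dilute),
    )

    def _noisy(clean: np.ndarray) -> np.ndarray:
        out = clean + spec.camera_offset
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, size=clean.shape)
        return np.clip(out, 0.0, None)

    protein = Image2D(
        _noisy(_render(spec.shape, centers, radii, spec.i_dense, spec.i_dilute)),
        channel_name="protein",
    )
    dark_clean = np.full(spec.shape, float(spec.camera_offset))
    if spec.noise_sd > 0:
        dark_clean = np.clip(
            dark_clean + rng.normal(0.0, spec.noise_sd, size=spec.shape), 0.0, None
        )
    dark = Image2D(dark_clean, channel_name="dark")

    rna = None
    if spec.i_dense2 is not None and spec.i_dilute2 is not None:
        rna = Image2D(
            _noisy(
                _render(spec.shape, centers, radii, spec.i_dense2, spec.i_dilute2)
            ),
            channel_name="rna",
        )
        truth.pc2 = (
            spec.i_dense2 / spec.i_dilute2 if spec.i_dilute2 > 0 else float("inf")
        )
        truth.rc2 = _truth_rc(spec.i_dense2, spec.i_dilute2)
    return DropletField(protein=protein, dark=dark, truth=truth, rna=rna)


# ---------------------------------------------------------------------------
# FRAP traces


@dataclass(frozen=True)
class FRAPTraceSpec:
    """Parameters of a synthetic bleach-and-recover acquisition.

    The underlying normalized signal is 1 before the bleach and
    ``plateau - (plateau - f0) * exp(-t'/tau_s)`` after it. The observed
    BL/REF traces multiply in per-frame acquisition photobleaching
    ``(1 - acquisition_bleach_rate)**frame`` and add a background level;
    Gaussian noise of sd ``noise_sd`` is applied on the normalized scale
    of the bleach-region signal.
    """

    f0: float = 0.3
    plateau: float = 0.7
    tau_s: float = 10.0
    frame_interval_s: float = 2.0
    n_frames: int = 120
    n_prebleach: int = 5
    acquisition_bleach_rate: float = 0.0
    bg_level: float = 50.0
    bl_scale: float = 1000.0
    ref_scale: float = 800.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f0 <= self.plateau <= 1):
            raise CondquantError("need 0 <= f0 <= plateau <= 1")
        if self.tau_s <= 0:
            raise CondquantError("tau_s must be positive")
        if not (1 <= self.n_prebleach < self.n_frames):
            raise CondquantError("need 1 <= n_prebleach < n_frames")
        if not (0 <= self.acquisition_bleach_rate < 1):
            raise CondquantError("acquisition_bleach_rate must be in [0, 1)")


@dataclass
class FRAPTruth:
    f0: float
    plateau: float
    tau_s: float
    mobile_fraction: float


#: Acquisition presets emulating the three experimental FRAP settings:
#: a wild-type cell punctum (2 s/frame, 120 cycles, ~70 % recovery by 90 s),
#: a fast-exchanging mutant cell (1 s/frame, 60 cycles, ~90 % by 30 s),
#: and an in vitro droplet (30 ms/frame, 40 frames).
WT_CELL_FRAP = FRAPTraceSpec(
    f0=0.25, plateau=0.70, tau_s=20.0, frame_interval_s=2.0, n_frames=120
)
F85A_CELL_FRAP = FRAPTraceSpec(
    f0=0.25, plateau=0.90, tau_s=6.0, frame_interval_s=1.0, n_frames=60
)
IN_VITRO_FRAP = FRAPTraceSpec(
    f0=0.30, plateau=0.95, tau_s=0.2, frame_interval_s=0.03, n_frames=40,
    n_prebleach=3,
)


def gen_frap_trace(spec: FRAPTraceSpec) -> tuple[FRAPTrace, FRAPTruth]:
    """Generate a raw (BL, REF, BG) trace and its ground truth.

    Because acquisition bleaching is multiplicative and shared by BL and
    REF, the double normalization recovers the underlying curve exactly
    when noise is zero.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    t = np.arange(n, dtype=np.float64) * spec.frame_interval_s
    u = np.ones(n)
    post = np.arange(spec.n_prebleach, n)
    tp = t[post] - t[spec.n_prebleach]
    u[post] = spec.plateau - (spec.plateau - spec.f0) * np.exp(-tp / spec.tau_s)
    if spec.noise_sd > 0:
        u = u + rng.normal(0.0, spec.noise_sd, size=n)
    s = (1.0 - spec.acquisition_bleach_rate) ** np.arange(n)
    bl = u * s * spec.bl_scale + spec.bg_level
    ref = s * spec.ref_scale + spec.bg_level
    bg = np.full(n, spec.bg_level)
    trace = FRAPTrace(
        t=t,
        bl=bl,
        ref=ref,
        bg=bg,
        bleach_index=spec.n_prebleach,
        trace_id=f"sim-{spec.seed}",
    )
    mobile = (spec.plateau - spec.f0) / (1.0 - spec.f0) if spec.f0 < 1 else float("nan")
    return trace, FRAPTruth(
        f0=spec.f0, plateau=spec.plateau, tau_s=spec.tau_s, mobile_fraction=mobile
    )


# ---------------------------------------------------------------------------
# dissolution stacks


@dataclass
class DissolutionTruth:
    lambda_per_s: float
    half_life_s: float
    alive_per_frame: list[int]
    expected_survival: np.ndarray


def gen_dissolution_stack(
    n0: int,
    lambda_per_s: float,
    n_frames: int = 10,
    interval_s: float = 10.0,
    shape: tuple[int, int] = (128, 128),
    radius_px: int = 3,
    i_punctum: float = 100.0,
    i_bg: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, DissolutionTruth]:
    """Render a time-lapse of stochastically dissolving puncta.

    Frame 0 is the treatment frame with all ``n0`` puncta present; at each
    subsequent frame every surviving punctum independently survives with
    probability ``exp(-lambda_per_s * interval_s)``. Expected survival is
    the analytic ``exp(-lambda * t)``.
    """
    if n0 < 1:
        raise CondquantError("n0 must be >= 1")
    if lambda_per_s < 0:
        raise CondquantError("lambda_per_s must be >= 0")
    rng = np.random.default_rng(seed)
    centers, radii = _place_disks(
        rng, shape, n0, (radius_px, radius_px)
    )
    p_survive = float(np.exp(-lambda_per_s * interval_s))
    alive = np.ones(n0, dtype=bool)
    frames = []
    alive_per_frame = []
    for frame_idx in range(n_frames):
        if frame_idx > 0:
            alive &= rng.random(n0) < p_survive
        keep = [i for i in range(n0) if alive[i]]
        img = _render(
            shape,
            [centers[i] for i in keep],
            [radii[i] for i in keep],
            i_punctum,
            i_bg,
        )
        if noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, noise_sd, size=shape), 0.0, None)
        frames.append(Image2D(img, channel_name="puncta"))
        alive_per_frame.append(len(keep))
    t = np.arange(n_frames) * interval_s
    truth = DissolutionTruth(
        lambda_per_s=lambda_per_s,
        half_life_s=float(np.log(2) / lambda_per_s) if lambda_per_s > 0 else float("inf"),
        alive_per_frame=alive_per_frame,
        expected_survival=np.exp(-lambda_per_s * t),
    )
    return ImageStack(frames, frame_interval_s=interval_s), truth


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(
    n_query: int,
    n_reference: int,
    n_overlap: int,
    seed: int = 0,
    query_name: str = "query",
    reference_name: str = "reference",
) -> tuple[GeneSet, GeneSet]:
    """Two synthetic identifier sets sharing exactly ``n_overlap`` ids.

    Stand-in for real proteome lists when reproducing an overlap
    statistic whose set sizes and intersection are known.
    """
    if n_overlap < 0 or n_overlap > min(n_query, n_reference):
        raise CondquantError(
            f"n_overlap {n_overlap} inconsistent with sizes "
            f"({n_query}, {n_reference})"
        )
    rng = np.random.default_rng(seed)
    total = n_query + n_reference - n_overlap
    # synthetic gene symbols: SYN000001 ... in shuffled order
    pool = [f"SYN{i:06d}" for i in rng.permutation(10 * total + 10)[:total]]
    shared = pool[:n_overlap]
    query_only = pool[n_overlap : n_query]
    ref_only = pool[n_query : total]
    query = GeneSet(name=query_name, ids=frozenset(shared + query_only))
    reference = GeneSet(name=reference_name, ids=frozenset(shared + ref_only))
    return query, reference
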