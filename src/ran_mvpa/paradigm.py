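"""Block-design timeline of the rapid automatized naming (RAN) task and the
temporal-average "Letter > Color" BOLD contrast.

The task alternates 20 s blocks of fixation (NULL), color naming, number
naming, and letter naming, with the four-condition cycle repeated three
times, a 10 s lead-in before the first cycle, and a 20 s tail after the
last — 270 s in total, 135 volumes at a TR of 2 s.

The contrast of interest is computed per voxel as the mean signal over
letter-naming volumes minus the mean over color-naming volumes ("temporal
averaging"); no hemodynamic-response-function convolution or GLM is
involved.  A configurable forward shift (in volumes) compensates for the
hemodynamic lag; the default of 2 volumes (4 s at TR 2 s) is a conventional
choice, and shift 0 gives the unshifted block windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParadigmTimeline",
    "BoldSeries",
    "ContrastMap",
    "build_timeline",
    "condition_volume_indices",
    "compute_contrast",
    "DEFAULT_CYCLE_ORDER",
]

DEFAULT_CYCLE_ORDER = ("NULL", "COLOR", "NUMBER", "LETTER")


@dataclass(frozen=True)
class ParadigmTimeline:
    """Block schedule of one RAN run.

    Blocks are contiguous, non-overlapping, and half-open in time:
    a block with onset ``t0`` and length ``block_s`` covers ``[t0, t0+block_s)``.
    Volume ``i`` is acquired over ``[i*tr_s, (i+1)*tr_s)`` (0-based).
    """

    lead_in_s: float = 10.0
    block_s: float = 20.0
    cycle_order: tuple[str, ...] = DEFAULT_CYCLE_ORDER
    n_cycles: int = 3
    tail_s: float = 20.0
    tr_s: float = 2.0
    hrf_shift_volumes: int = 2

    def __post_init__(self) -> None:
        for name in ("lead_in_s", "block_s", "tail_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.cycle_order:
            raise ValueError("cycle_order must be nonempty")
        if self.hrf_shift_volumes < 0:
            raise ValueError("hrf_shift_volumes must be >= 0")
        remainder = self.total_duration_s % self.tr_s
        if remainder != 0:
            raise ValueError(
                f"total duration {self.total_duration_s} s is not divisible by "
                f"tr_s={self.tr_s} s (remainder {remainder} s)"
            )

    @property
    def total_duration_s(self) -> float:
        return (
            self.lead_in_s
            + self.n_cycles * len(self.cycle_order) * self.block_s
            + self.tail_s
        )

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration_s / self.tr_s))

    @property
    def blocks(self) -> tuple[tuple[str, float, float], ...]:
        """All (condition, onset_s, offset_s) triples in presentation order."""
        out = []
        t = self.lead_in_s
        for _ in range(self.n_cycles):
            for cond in self.cycle_order:
                out.append((cond, t, t + self.block_s))
                t += self.block_s
        return tuple(out)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.cycle_order))


@dataclass(frozen=True)
class BoldSeries:
    """A 4D BOLD series (i, j, k, t) paired with its repetition time."""

    data: np.ndarray
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class ContrastMap:
    """Per-voxel BOLD difference for one subject-visit (arbitrary signal units)."""

    data: np.ndarray
    subject: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("contrast map contains non-finite values")


def build_timeline(
    lead_in_s: float = 10.0,
    block_s: float = 20.0,
    cycle_order: tuple[str, ...] = DEFAULT_CYCLE_ORDER,
    n_cycles: int = 3,
    tail_s: float = 20.0,
    tr_s: float = 2.0,
    hrf_shift_volumes: int = 2,
) -> ParadigmTimeline:
    """Construct and validate a RAN block timeline.

    Raises ``ValueError`` when the total duration is not an integer number
    of volumes, naming the remainder.
    """
    return ParadigmTimeline(
        lead_in_s=lead_in_s,
        block_s=block_s,
        cycle_order=tuple(cycle_order),
        n_cycles=n_cycles,
        tail_s=tail_s,
        tr_s=tr_s,
        hrf_shift_volumes=hrf_shift_volumes,
    )


def condition_volume_indices(
    timeline: ParadigmTimeline,
    condition: str,
    hrf_shift_volumes: int | None = None,
) -> np.ndarray:
    """0-based volume indices covered by the given condition's blocks.

    Each block window ``[onset, offset)`` maps to the volumes acquired in it;
    every index is then shifted forward by ``hrf_shift_volumes`` to account
    for the hemodynamic lag.  A shift larger than a block deliberately pushes
    indices into the following block (no clipping within the run); indices
    past the last volume are dropped.
    """
    if hrf_shift_volumes is None:
        hrf_shift_volumes = timeline.hrf_shift_volumes
    if hrf_shift_volumes < 0:
        raise ValueError("hrf_shift_volumes must be >= 0")
    if condition not in timeline.cycle_order:
        raise ValueError(
            f"unknown condition {condition!r}; timeline has {timeline.cycle_order}"
        )
    idx: list[int] = []
    for cond, onset, offset in timeline.blocks:
        if cond != condition:
            continue
        first = int(np.ceil(onset / timeline.tr_s))
        last = int(np.ceil(offset / timeline.tr_s))  # half-open [onset, offset)
        idx.extend(range(first, last))
    shifted = np.asarray(idx, dtype=int) + hrf_shift_volumes
    shifted = shifted[shifted <= timeline.n_volumes - 1]
    if shifted.size == 0:
        raise ValueError(
            f"no volumes remain for condition {condition!r} after shifting by "
            f"{hrf_shift_volumes}"
        )
    return shifted


def compute_contrast(
    series: BoldSeries | np.ndarray,
    timeline: ParadigmTimeline,
    cond_a: str = "LETTER",
    cond_b: str = "COLOR",
    hrf_shift_volumes: int | None = None,
    subject: str = "",
    visit: str = "",
) -> ContrastMap:
    """Voxel-wise temporal-average contrast ``mean(cond_a) - mean(cond_b)``.

    The default pair (LETTER minus COLOR) is the primary "Letter > Color"
    contrast targeting visual word recognition.
    """
    if isinstance(series, np.ndarray):
        series = BoldSeries(series, tr_s=timeline.tr_s)
    if series.n_volumes != timeline.n_volumes:
        raise ValueError(
            f"series has {series.n_volumes} volumes but the timeline expects "
            f"{timeline.n_volumes}"
        )
    ia = condition_volume_indices(timeline, cond_a, hrf_shift_volumes)
    ib = condition_volume_indices(timeline, cond_b, hrf_shift_volumes)
    contrast = series.data[..., ia].mean(axis=3) - series.data[..., ib].mean(axis=3)
    return ContrastMap(data=contrast, subject=subject, visit=visit)
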