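"""Block-design experiment description.

A session consists of ``n_runs`` functional runs. Within each run, stimulus
blocks (one of four visual categories: faces, objects, headless bodies, body
parts) alternate with fixation blocks; fixation is treated as unmodeled
baseline downstream. Category order rotates across runs as a counterbalancing
surrogate, so no category occupies a fixed serial position in every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

STIMULUS_CATEGORIES: tuple[str, ...] = ("face", "object", "body", "body_part")
FIXATION = "fixation"


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel grid and timing of one functional acquisition.

    Defaults emulate a high-resolution occipito-temporal slab: anisotropic
    1.4 x 1.4 x 2.0 mm voxels, TR 3.0 s, 112 volumes per run (336 s), 8 runs.
    """

    grid_dims: tuple[int, int, int] = (24, 28, 16)
    voxel_size_mm: tuple[float, float, float] = (1.4, 1.4, 2.0)
    tr_s: float = 3.0
    n_volumes_per_run: int = 112
    n_runs: int = 8

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.grid_dims):
            raise ValueError(f"grid_dims must be >= 1, got {self.grid_dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be > 0, got {self.tr_s}")
        if self.n_volumes_per_run < 1 or self.n_runs < 1:
            raise ValueError("n_volumes_per_run and n_runs must be >= 1")

    @property
    def run_length_s(self) -> float:
        return self.n_volumes_per_run * self.tr_s

    @property
    def frame_times_s(self):
        import numpy as np

        return np.arange(self.n_volumes_per_run) * self.tr_s

    def affine(self):
        """RAS+ affine placing voxel (0,0,0) at the origin."""
        import numpy as np

        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass(frozen=True)
class BlockEvent:
    run_index: int
    onset_s: float
    duration_s: float
    condition: str

    def __post_init__(self) -> None:
        if self.run_index < 0:
            raise ValueError("run_index must be >= 0")
        if self.onset_s < 0 or self.duration_s <= 0:
            raise ValueError("onset must be >= 0 and duration > 0")
        if self.condition not in STIMULUS_CATEGORIES + (FIXATION,):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    geometry: AcquisitionGeometry
    events: tuple[BlockEvent, ...]
    condition_names: tuple[str, ...] = STIMULUS_CATEGORIES

    def __post_init__(self) -> None:
        for run in range(self.geometry.n_runs):
            run_events = sorted(self.run_events(run), key=lambda e: e.onset_s)
            seen = {e.condition for e in run_events}
            missing = set(self.condition_names) - seen
            if missing:
                raise ValueError(f"run {run} lacks categories {sorted(missing)}")
            end = 0.0
            for e in run_events:
                if e.onset_s < end - 1e-9:
                    raise ValueError(f"overlapping blocks in run {run}")
                end = e.onset_s + e.duration_s
            if end > self.geometry.run_length_s + 1e-9:
                raise ValueError(
                    f"run {run} blocks extend past run length "
                    f"({end:.1f} > {self.geometry.run_length_s:.1f} s)"
                )

    def run_events(self, run_index: int) -> tuple[BlockEvent, ...]:
        return tuple(e for e in self.events if e.run_index == run_index)

    def stimulus_events(self, run_index: int | None = None) -> tuple[BlockEvent, ...]:
        evs = self.events if run_index is None else self.run_events(run_index)
        return tuple(e for e in evs if e.condition != FIXATION)

    def category_order(self, run_index: int) -> tuple[str, ...]:
        evs = sorted(self.stimulus_events(run_index), key=lambda e: e.onset_s)
        return tuple(e.condition for e in evs)


def make_design(config: Mapping | None = None) -> ExperimentDesign:
    """Build a block design from key-value parameters.

    Recognized keys (all optional): ``n_runs``, ``block_duration_s``,
    ``fixation_duration_s``, ``blocks_per_category``, ``categories``, plus the
    :class:`AcquisitionGeometry` fields (``grid_dims``, ``voxel_size_mm``,
    ``tr_s``, ``n_volumes_per_run``).

    The default session has 8 runs with 1 block per category per run, i.e.
    4 stimulus blocks of 16 s per run, 32 across the session, each preceded
    by a fixation block and with a trailing fixation block closing the run.
    ``fixation_duration_s`` is the minimum rest length; the rest intervals
    expand equally so that stimulus blocks are spread evenly across the run
    (keeping the HRF-convolved regressors of different categories close to
    orthogonal, as in any sanely scheduled block design). Category order is
    rotated Latin-square style across runs.
    """
    cfg = dict(config or {})
    categories = tuple(cfg.pop("categories", STIMULUS_CATEGORIES))
    block_s = float(cfg.pop("block_duration_s", 16.0))
    fix_s = float(cfg.pop("fixation_duration_s", 16.0))
    per_cat = int(cfg.pop("blocks_per_category", 1))
    geom_keys = {"grid_dims", "voxel_size_mm", "tr_s", "n_volumes_per_run", "n_runs"}
    geom_kwargs = {k: cfg.pop(k) for k in list(cfg) if k in geom_keys}
    if "grid_dims" in geom_kwargs:
        geom_kwargs["grid_dims"] = tuple(geom_kwargs["grid_dims"])
    if "voxel_size_mm" in geom_kwargs:
        geom_kwargs["voxel_size_mm"] = tuple(geom_kwargs["voxel_size_mm"])
    if cfg:
        raise ValueError(f"unknown design config keys: {sorted(cfg)}")
    geometry = AcquisitionGeometry(**geom_kwargs)

    n_blocks = len(categories) * per_cat
    needed = n_blocks * (block_s + fix_s) + fix_s
    if needed > geometry.run_length_s + 1e-9:
        raise ValueError(
            f"total block time {needed:.1f} s exceeds run length "
            f"{geometry.run_length_s:.1f} s"
        )
    # spread blocks evenly: rest intervals grow from fix_s up to the value
    # that fills the run
    gap_s = (geometry.run_length_s - n_blocks * block_s) / (n_blocks + 1)

    events: list[BlockEvent] = []
    for run in range(geometry.n_runs):
        order = _rotated_order(categories, per_cat, run)
        t = 0.0
        for cond in order:
            events.append(BlockEvent(run, t, gap_s, FIXATION))
            t += gap_s
            events.append(BlockEvent(run, t, block_s, cond))
            t += block_s
        # closing fixation block to the run end
        events.append(BlockEvent(run, t, geometry.run_length_s - t, FIXATION))
    return ExperimentDesign(geometry=geometry, events=tuple(events),
                            condition_names=categories)


def _rotated_order(categories: Sequence[str], per_cat: int, run: int) -> list[str]:
    # Rotate by run index; reverse on every second pass through the rotations
    # so that up to 2k runs all receive distinct category orders.
    k = len(categories)
    base = [categories[(i + run) % k] for i in range(k)]
    if (run // k) % 2 == 1:
        base = base[::-1]
    return [c for _ in range(per_cat) for c in base]
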