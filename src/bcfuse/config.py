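"""Run configuration: one declarative YAML document, CLI flags override 1:1.

Every pipeline command resolves its configuration (defaults ← YAML ← flags)
and writes the resolved document beside its outputs, together with the seeds
used, so any run is reconstructible from its output directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from bcfuse.scene import SceneConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline knobs with the campaign-standard defaults.

    ``k``/``q`` accept an integer rank or ``"auto"`` for knee selection.
    """

    seed: int = 0
    bin_width: int = 15  # minutes
    min_visits: int = 15  # drive passes per retained segment
    max_snap_dist: float = 30.0  # meters, point-to-segment assignment
    max_gap_s: float = 60.0  # pass-splitting gap
    min_coverage: float = 0.5  # raw samples per bin, fraction of expected
    min_observed: float = 0.8  # observed-bin fraction required to impute a site
    k: int | str = 5
    q: int | str = 16
    rcond: float = 1e-10
    variogram_kind: str = "exponential"
    nmf_tol: float = 1e-6
    nmf_max_iter: int = 2000
    # evaluation
    n_iter: int = 50
    holdout_fraction: float = 0.3
    min_points: int = 300  # 1-Hz points per Lagrangian window
    day_window: tuple[int, int] = (9, 16)
    # synthetic scene (used by `simulate`)
    scene: SceneConfig = field(default_factory=SceneConfig)

    def validated(self) -> "RunConfig":
        if 1440 % self.bin_width:
            raise ValueError("bin_width must divide 1440")
        if self.min_visits < 1:
            raise ValueError("min_visits must be >= 1")
        for name in ("k", "q"):
            v = getattr(self, name)
            if not (v == "auto" or (isinstance(v, int) and v >= 1)):
                raise ValueError(f"{name} must be a positive integer or 'auto'")
        if self.variogram_kind not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram kind {self.variogram_kind!r}")
        return self


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys in the file are an error (they are silent typos otherwise);
    overrides with value None are ignored so CLI flags can default to None.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: top level must be a mapping")
        data = raw
    scene_data = data.pop("scene", {}) or {}
    known = {f.name for f in fields(RunConfig)}
    if unknown := set(data) - known:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    scene_known = {f.name for f in fields(SceneConfig)}
    if unknown := set(scene_data) - scene_known:
        raise ValueError(f"config scene: unknown keys {sorted(unknown)}")
    for key in ("day_window",):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    for key in ("decay_length_range", "drive_window"):
        if key in scene_data and scene_data[key] is not None:
            scene_data[key] = tuple(scene_data[key])
    cfg = RunConfig(**data, scene=SceneConfig(**scene_data))
    clean = {k: v for k, v in overrides.items() if v is not None}
    scene_overrides = {k: v for k, v in clean.pop("scene", {}).items() if v is not None}
    if scene_overrides:
        cfg = replace(cfg, scene=replace(cfg.scene, **scene_overrides))
    if clean:
        cfg = replace(cfg, **clean)
    return cfg.validated()


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML."""
    doc = asdict(cfg)
    doc["day_window"] = list(cfg.day_window)
    doc["scene"]["decay_length_range"] = list(cfg.scene.decay_length_range)
    doc["scene"]["drive_window"] = list(cfg.scene.drive_window)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
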