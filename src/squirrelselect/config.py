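"""Configuration objects for the squirrel search optimizer.

The squirrel search algorithm (SSA) models candidate solutions as flying
squirrels gliding between food trees of three quality tiers: a single best
"hickory" tree, a few good "acorn" trees, and ordinary "normal" trees.  All
tunable constants of the optimizer live in :class:`SSAConfig`, with defaults
taken from the standard SSA parameterization (population of 50, gliding
constant ``Gc = 1.9``, glide height ``hg = 8``, scaling factor ``sf = 18``,
predator-appearance probability ``Pdp = 0.1``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = ["SSAConfig", "load_yaml_config", "dataclass_from_mapping"]


@dataclass
class SSAConfig:
    """All tunable constants of the squirrel search optimizer.

    Parameters
    ----------
    n_squirrels : int
        Population size (number of flying squirrels). Default 50.
    n_hickory : int
        Number of squirrels assigned to the hickory (globally best) tree
        at each role refresh. Default 1.
    n_acorn : int
        Number of squirrels assigned to acorn (next best) trees. Default 3.
    gliding_constant : float
        Multiplier ``Gc`` on the glide step toward a better tree.
        Default 1.9.
    glide_height : float
        Loss-of-height constant ``hg`` in the gliding-distance formula.
        Default 8.
    scaling_factor : float
        Divisor ``sf`` that scales the gliding distance into the search
        domain. Default 18.
    predator_prob : float
        Probability ``Pdp`` that a predator appears during a glide, in which
        case the squirrel abandons the directed move and relocates uniformly
        at random inside the bounds. Default 0.1.
    lift_coeff_range : tuple of float
        Interval from which the aerodynamic lift coefficient ``CL`` is drawn
        uniformly for each glide. Default ``(0.675, 1.5)``.
    drag_coeff : float
        Fixed aerodynamic drag coefficient ``CD``. Default 0.60.  With the
        default lift range this yields gliding distances in
        ``[0.5, 1.1112]``.
    lower_bound, upper_bound : float or array-like
        Box constraints of the search space, scalar (shared by every
        dimension) or per-dimension vectors.
    max_iterations : int
        Iteration budget of the main loop.
    seed : int
        Seed of the single random stream driving the run.
    season_threshold_scale : float
        Numerator of the shrinking seasonal threshold
        ``Smin(t) = scale / 365**(t / (T / 2.5))`` that triggers winter
        relocation when every acorn squirrel is that close to the hickory
        squirrel. Default 1e-5.
    """

    n_squirrels: int = 50
    n_hickory: int = 1
    n_acorn: int = 3
    gliding_constant: float = 1.9
    glide_height: float = 8.0
    scaling_factor: float = 18.0
    predator_prob: float = 0.1
    lift_coeff_range: tuple[float, float] = (0.675, 1.5)
    drag_coeff: float = 0.60
    lower_bound: float | Sequence[float] = 0.0
    upper_bound: float | Sequence[float] = 1.0
    max_iterations: int = 100
    seed: int = 0
    season_threshold_scale: float = 1e-5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_hickory < 1 or self.n_acorn < 0:
            raise ValueError("need at least one hickory squirrel and n_acorn >= 0")
        if self.n_hickory + self.n_acorn >= self.n_squirrels:
            raise ValueError(
                f"n_hickory + n_acorn = {self.n_hickory + self.n_acorn} must be "
                f"smaller than the population size {self.n_squirrels}"
            )
        if not (0.0 <= self.predator_prob <= 1.0):
            raise ValueError(f"predator_prob must lie in [0, 1], got {self.predator_prob}")
        if min(self.gliding_constant, self.glide_height, self.scaling_factor) <= 0:
            raise ValueError("gliding_constant, glide_height and scaling_factor must be > 0")
        lo, hi = self.lift_coeff_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"lift_coeff_range must lie strictly above 0, got {self.lift_coeff_range}")
        if self.drag_coeff <= 0:
            raise ValueError("drag_coeff must be > 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        lob = np.asarray(self.lower_bound, dtype=float)
        upb = np.asarray(self.upper_bound, dtype=float)
        if not (np.all(np.isfinite(lob)) and np.all(np.isfinite(upb))):
            raise ValueError("bounds must be finite")
        if np.any(np.broadcast_arrays(lob, upb)[0] >= np.broadcast_arrays(lob, upb)[1]):
            raise ValueError("lower_bound must be strictly below upper_bound componentwise")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        """Bounds broadcast to ``dim``-vectors ``(lower, upper)``."""
        lo = np.broadcast_to(np.asarray(self.lower_bound, dtype=float), (dim,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper_bound, dtype=float), (dim,)).copy()
        if np.any(lo >= hi):
            raise ValueError("lower_bound must be strictly below upper_bound componentwise")
        return lo, hi

    def replace(self, **changes: Any) -> "SSAConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SSAConfig":
        return dataclass_from_mapping(cls, mapping)


def dataclass_from_mapping(cls, mapping: Mapping[str, Any], **overrides: Any):
    """Build a dataclass from a mapping, keeping only the fields it declares.

    Keys that do not name a field are ignored, which lets one flat YAML file
    configure several components. ``overrides`` win over the mapping.
    """
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in names}
    kwargs.update({k: v for k, v in overrides.items() if v is not None and k in names})
    return cls(**kwargs)


def load_yaml_config(path) -> dict[str, Any]:
    """Read a flat key-value YAML configuration file into a dict."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data
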