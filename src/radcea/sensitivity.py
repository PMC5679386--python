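"""One-way sensitivity analysis, tornado ordering and NMB-threshold search.

A sensitivity parameter is addressed by a dotted path into the config (list
elements are addressed by their ``name`` field, e.g.
``strategies.IORT.states.well.utility``); a tuple of paths sets several
scalars together (e.g. the same utility in both arms).  The threshold search
finds the parameter value at which the strategy preferred by net monetary
benefit flips: a 64-point coarse scan brackets sign changes of the NMB
difference, then bisection tightens the bracket to the requested tolerance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel
from pydantic import ValidationError as PydanticValidationError

from .config import AnalysisConfig
from .exceptions import (
    AmbiguousThresholdError,
    ConfigReferenceError,
    ConfigValidationError,
    RadceaError,
)
from .pipeline import evaluate_config

__all__ = [
    "SensitivityRange",
    "TornadoEntry",
    "ThresholdResult",
    "get_by_path",
    "set_by_path",
    "one_way_sweep",
    "tornado",
    "find_threshold",
]

ParamPath = Union[str, tuple[str, ...]]

COARSE_SCAN_POINTS = 64


@dataclass(frozen=True)
class SensitivityRange:
    """A one-way sweep specification over [low, high] at n_points values."""

    param_path: ParamPath
    low: float
    high: float
    n_points: int = 11
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.param_path}: low must be < high")
        if self.n_points < 2:
            raise ValueError(f"{self.param_path}: n_points must be >= 2")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return self.param_path if isinstance(self.param_path, str) else "+".join(self.param_path)


@dataclass(frozen=True)
class TornadoEntry:
    """NMB of the baseline-preferred strategy at a range's endpoints."""

    param_path: ParamPath
    label: str
    nmb_at_low: float
    nmb_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of an NMB-crossover search for one parameter.

    ``threshold`` is None when no preference flip occurs in the bounds
    ("none in range"); otherwise the NMB difference changes sign across it
    within ``tolerance``.  ``preferred_below``/``preferred_above`` name the
    strategy preferred on each side of the threshold.
    """

    param_path: ParamPath
    threshold: Optional[float]
    preferred_below: str
    preferred_above: str
    tolerance: float
    baseline_value: float

    @property
    def found(self) -> bool:
        return self.threshold is not None


# ---------------------------------------------------------------------------
# dotted-path access
# ---------------------------------------------------------------------------


def _walk(obj, segments: Sequence[str], path: str):
    for i, seg in enumerate(segments):
        if isinstance(obj, list):
            named = [x for x in obj if getattr(x, "name", None) == seg]
            if len(named) == 1:
                obj = named[0]
                continue
            try:
                obj = obj[int(seg)]
                continue
            except (ValueError, IndexError):
                raise ConfigReferenceError(
                    f"path {path!r}: no list element named {seg!r}"
                ) from None
        if isinstance(obj, dict):
            if seg not in obj:
                raise ConfigReferenceError(f"path {path!r}: no key {seg!r}")
            obj = obj[seg]
            continue
        if isinstance(obj, BaseModel) and seg in type(obj).model_fields:
            obj = getattr(obj, seg)
            continue
        raise ConfigReferenceError(f"path {path!r}: cannot resolve segment {seg!r}")
    return obj


def get_by_path(config: AnalysisConfig, path: str) -> float:
    """Resolve a dotted path to a numeric scalar."""
    value = _walk(config, path.split("."), path)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigReferenceError(f"path {path!r} resolves to non-numeric {value!r}")
    return float(value)


def set_by_path(config: AnalysisConfig, path: str, value: float) -> None:
    """Set a numeric scalar in place (use on a deep copy for sweeps)."""
    segments = path.split(".")
    parent = _walk(config, segments[:-1], path)
    leaf = segments[-1]
    get_by_path(config, path)  # type/existence check
    try:
        if isinstance(parent, dict):
            parent[leaf] = value
        else:
            setattr(parent, leaf, value)
    except PydanticValidationError as exc:
        raise ConfigValidationError(f"path {path!r}: value {value!r} invalid: {exc}") from exc


def _paths(param_path: ParamPath) -> tuple[str, ...]:
    return (param_path,) if isinstance(param_path, str) else tuple(param_path)


def perturbed(config: AnalysisConfig, param_path: ParamPath, value: float) -> AnalysisConfig:
    """Deep-copied config with the parameter(s) set to ``value``."""
    cfg = copy.deepcopy(config)
    for p in _paths(param_path):
        set_by_path(cfg, p, value)
    return cfg


# ---------------------------------------------------------------------------
# sweeps, tornado, thresholds
# ---------------------------------------------------------------------------


def _nmbs(config: AnalysisConfig, param_path: ParamPath, value: float) -> dict[str, float]:
    try:
        comparison = evaluate_config(perturbed(config, param_path, value))
    except RadceaError as exc:
        raise type(exc)(
            f"sweep of {param_path} failed at value {value:g}: {exc}"
        ) from exc
    return {name: comparison.table[name]["nmb"] for name in comparison.names}


def one_way_sweep(
    config: AnalysisConfig, rng: SensitivityRange
) -> list[tuple[float, dict[str, float]]]:
    """Evaluate per-strategy NMB at n_points equally spaced parameter values."""
    values = np.linspace(rng.low, rng.high, rng.n_points)
    return [(float(v), _nmbs(config, rng.param_path, float(v))) for v in values]


def tornado(
    config: AnalysisConfig, ranges: Sequence[SensitivityRange]
) -> list[TornadoEntry]:
    """One-way ranges ordered by descending NMB spread.

    The NMB tracked is that of the strategy preferred at baseline, matching
    the convention of tornado plots built on the highest-net-benefit arm.
    """
    if not ranges:
        raise ValueError("tornado requires at least one range")
    preferred = evaluate_config(config).preferred_by_nmb
    entries = []
    for rng in ranges:
        lo = _nmbs(config, rng.param_path, rng.low)[preferred]
        hi = _nmbs(config, rng.param_path, rng.high)[preferred]
        entries.append(
            TornadoEntry(
                param_path=rng.param_path, label=rng.name, nmb_at_low=lo, nmb_at_high=hi
            )
        )
    return sorted(entries, key=lambda e: (-e.spread, e.label))


def find_threshold(
    config: AnalysisConfig,
    param_path: ParamPath,
    bounds: tuple[float, float],
    tolerance: float | None = None,
) -> ThresholdResult:
    """Locate the parameter value where the NMB-preferred strategy flips.

    The sign of Delta-NMB (baseline-preferred strategy minus the best of the
    others) is scanned at 64 equally spaced points; exactly one sign change
    is bisected to a bracket width <= tolerance (default 1e-6 x range width).
    Zero sign changes return "none in range"; several raise
    :class:`AmbiguousThresholdError` listing the brackets.
    """
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    if tolerance is None:
        tolerance = 1e-6 * (high - low)
    preferred = evaluate_config(config).preferred_by_nmb

    def delta(x: float) -> float:
        nmbs = _nmbs(config, param_path, x)
        others = [v for k, v in nmbs.items() if k != preferred]
        return nmbs[preferred] - max(others)

    def winner(x: float) -> str:
        nmbs = _nmbs(config, param_path, x)
        return max(nmbs, key=lambda k: nmbs[k])

    xs = np.linspace(low, high, COARSE_SCAN_POINTS)
    ds = [delta(float(x)) for x in xs]
    brackets = [
        (float(xs[i]), float(xs[i + 1]))
        for i in range(len(xs) - 1)
        if np.sign(ds[i]) != np.sign(ds[i + 1])
    ]
    try:
        baseline_value = get_by_path(config, _paths(param_path)[0])
    except ConfigReferenceError:
        baseline_value = float("nan")
    if not brackets:
        side = winner(low)
        return ThresholdResult(
            param_path=param_path,
            threshold=None,
            preferred_below=side,
            preferred_above=winner(high),
            tolerance=tolerance,
            baseline_value=baseline_value,
        )
    if len(brackets) > 1:
        raise AmbiguousThresholdError(
            f"{param_path}: multiple sign changes in {bounds}: {brackets}"
        )

    a0, b0 = brackets[0]
    a, b = a0, b0
    fa = delta(a)
    while b - a > tolerance:
        mid = 0.5 * (a + b)
        fm = delta(mid)
        if np.sign(fm) == np.sign(fa) and fm != 0.0:
            a, fa = mid, fm
        else:
            b = mid
    threshold = 0.5 * (a + b)
    # sides labelled from the coarse bracket: robustly on each side of the root
    return ThresholdResult(
        param_path=param_path,
        threshold=threshold,
        preferred_below=winner(a0),
        preferred_above=winner(b0),
        tolerance=tolerance,
        baseline_value=baseline_value,
    )
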